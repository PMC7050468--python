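"""Independent reference computations used to validate the implementation.

Each oracle takes a deliberately different computational route from the code
under test: the constrained-ordination oracle solves a dense generalized
eigenproblem on raw (uncentered, unstandardized) predictors with an explicit
intercept column instead of the residual-projection + SVD route; the
distance oracle uses the spherical law of cosines instead of the haversine
form; the clustering oracle builds an explicit graph and takes connected
components.
"""

from __future__ import annotations

import math

import numpy as np
import scipy.linalg


def cca_eigenvalues_oracle(counts: np.ndarray, env: np.ndarray) -> np.ndarray:
    """Constrained-ordination eigenvalues via a generalized eigenproblem.

    counts: sites x species non-negative matrix; env: sites x parameters.
    Solves eig(A, B) with A = Z1' Pbar Dc^{-1} Pbar' Z1, B = Z1' Dr Z1,
    Z1 = [1 | env]; the nonzero real eigenvalues are the constrained
    eigenvalues, descending.
    """
    y = np.asarray(counts, dtype=float)
    grand = y.sum()
    P = y / grand
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    Pbar = P - np.outer(r, c)
    Z1 = np.column_stack([np.ones(len(r)), np.asarray(env, dtype=float)])
    A = Z1.T @ Pbar @ np.diag(1.0 / c) @ Pbar.T @ Z1
    B = Z1.T @ np.diag(r) @ Z1
    vals = scipy.linalg.eig(A, B)[0]
    vals = np.real(vals[np.abs(np.imag(vals)) < 1e-10])
    vals = np.sort(vals[vals > 1e-10])[::-1]
    return vals


def law_of_cosines_m(lat1: float, lon1: float, lat2: float, lon2: float,
                     radius: float = 6_371_000.0) -> float:
    """Great-circle distance via the spherical law of cosines."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    cosc = math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dl)
    return radius * math.acos(min(1.0, max(-1.0, cosc)))


def single_linkage_clusters_oracle(sequences: dict[str, str],
                                   threshold: float) -> list[frozenset[str]]:
    """Transitive closure of the >=threshold-identity relation via networkx."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(sequences)
    ids = list(sequences)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            sa, sb = sequences[a], sequences[b]
            ident = sum(x == y for x, y in zip(sa, sb)) / len(sa)
            if ident >= threshold:
                g.add_edge(a, b)
    return [frozenset(cc) for cc in nx.connected_components(g)]


def best_lineage_oracle(seq: str, refs: dict[str, tuple[str, str]]) -> str:
    """Brute-force all-pairs identity scan; refs: id -> (lineage, sequence)."""
    best_by_lineage: dict[str, float] = {}
    for _, (lineage, rseq) in refs.items():
        ident = sum(x == y for x, y in zip(seq, rseq)) / len(seq)
        best_by_lineage[lineage] = max(best_by_lineage.get(lineage, -1.0), ident)
    top = max(best_by_lineage.values())
    winners = [lin for lin, v in best_by_lineage.items() if v == top]
    return winners[0] if len(winners) == 1 else "unassigned"
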