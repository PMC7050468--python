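"""Pairwise sequence sharing between samples and its decay with distance.

Sharing between two samples is the Sørensen-style fraction of distinct
variants they have in common, 100 * 2*|Sa ∩ Sb| / (|Sa| + |Sb|), computed on
an HFS table (HFS10 for the headline matrix, HFS2 when even rarely shared
variants matter). The companion count statistic is the number of reads, in
the member of the pair with the smaller library, belonging to variants seen
in both. Geographic separation is the great-circle (haversine) distance;
replicate samples of one spring use a 1 m convention so they can sit on a
log-distance axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hfs import VariantTable

EARTH_RADIUS_M = 6_371_000.0
REPLICATE_DISTANCE_M = 1.0


def haversine_m(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in metres on a sphere of radius 6,371 km."""
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise ValueError(f"latitude out of range: {lat}")
    for lon in (lon1, lon2):
        if not -180.0 <= lon <= 180.0:
            raise ValueError(f"longitude out of range: {lon}")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = np.radians(lat2 - lat1)
    dlmb = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0))))


def _present(table: VariantTable, sample: str) -> set[str]:
    if sample not in table.counts.columns:
        raise KeyError(f"unknown sample {sample!r}")
    col = table.counts[sample]
    return set(col.index[col > 0])


def percent_shared(table: VariantTable, a: str, b: str) -> float:
    """Percent of distinct variants shared: 100 * 2|Sa∩Sb| / (|Sa|+|Sb|).

    Returns NaN when both samples are empty (undefined).
    """
    sa, sb = _present(table, a), _present(table, b)
    denom = len(sa) + len(sb)
    if denom == 0:
        return float("nan")
    return 100.0 * 2.0 * len(sa & sb) / denom


def shared_reads_min_sample(table: VariantTable, a: str, b: str,
                            mode: str = "reads") -> int:
    """Shared-variant count in the pair member with the smaller library.

    ``mode="reads"`` (default) sums the smaller sample's reads over variants
    present in both samples; ``mode="variants"`` counts the shared distinct
    variants instead (an alternative reading of "number of shared
    sequences"). A tie in library size is broken by lexicographic sample id
    (the smaller id is treated as the smaller sample).
    """
    if mode not in ("reads", "variants"):
        raise ValueError(f"unknown mode {mode!r}")
    sa, sb = _present(table, a), _present(table, b)
    shared = sa & sb
    if not shared:
        return 0
    if mode == "variants":
        return len(shared)
    tot_a = int(table.counts[a].sum())
    tot_b = int(table.counts[b].sum())
    if tot_a < tot_b or (tot_a == tot_b and min(a, b) == a):
        smaller = a
    else:
        smaller = b
    return int(table.counts.loc[sorted(shared), smaller].sum())


@dataclass(frozen=True)
class SharingResult:
    """Sharing statistics for one unordered sample pair."""

    sample_a: str
    sample_b: str
    percent_shared: float
    shared_reads_min_sample: int
    distance_m: float


def pairwise_matrix(
    table: VariantTable,
    sample_to_spring: pd.Series,
    springs: pd.DataFrame,
    exclusions: Iterable[str] = (),
    reads_table: VariantTable | None = None,
) -> pd.DataFrame:
    """All unordered pairwise sharing comparisons among retained samples.

    ``sample_to_spring`` maps sample id -> spring id; ``springs`` must carry
    ``latitude``/``longitude`` per spring. Samples in ``exclusions`` are
    dropped before pairing. Replicates (samples of one spring) are assigned
    the 1 m distance convention. ``reads_table`` (e.g. the HFS2 table) is
    used for the shared-read count; by default the same table serves both
    statistics.
    """
    if reads_table is None:
        reads_table = table
    excluded = set(exclusions)
    retained = [s for s in table.counts.columns if s not in excluded]
    for s in retained:
        if s not in sample_to_spring.index:
            raise KeyError(f"sample {s!r} has no spring assignment")
        spring = sample_to_spring[s]
        if spring not in springs.index:
            raise KeyError(f"sample {s!r} maps to unknown spring {spring!r}")
    rows = []
    for a, b in combinations(retained, 2):
        sp_a, sp_b = sample_to_spring[a], sample_to_spring[b]
        if sp_a == sp_b:
            dist = REPLICATE_DISTANCE_M
        else:
            dist = haversine_m(
                springs.at[sp_a, "latitude"], springs.at[sp_a, "longitude"],
                springs.at[sp_b, "latitude"], springs.at[sp_b, "longitude"],
            )
        rows.append(
            {
                "sample_a": a,
                "sample_b": b,
                "percent_shared": percent_shared(table, a, b),
                "shared_reads_min_sample": shared_reads_min_sample(reads_table, a, b),
                "distance_m": dist,
            }
        )
    return pd.DataFrame(rows)


def triangle_layout(pairs: pd.DataFrame, samples: Sequence[str]) -> pd.DataFrame:
    """Square sample-by-sample layout: percent shared below the diagonal,
    shared-read counts above, dashes on the diagonal."""
    out = pd.DataFrame("-", index=list(samples), columns=list(samples), dtype=object)
    order = {s: i for i, s in enumerate(samples)}
    for row in pairs.itertuples(index=False):
        a, b = row.sample_a, row.sample_b
        lo, hi = (a, b) if order[a] < order[b] else (b, a)
        out.at[hi, lo] = round(row.percent_shared, 1)
        out.at[lo, hi] = int(row.shared_reads_min_sample)
    return out


@dataclass(frozen=True)
class DecayFit:
    """Least-squares trend of percent shared against log10 distance."""

    slope: float
    intercept: float
    r_value: float
    p_permutation: float
    n_pairs: int
    n_permutations: int


def distance_decay(
    pairs: pd.DataFrame,
    n_permutations: int = 999,
    seed: int | None = None,
) -> DecayFit:
    """Fit percent_shared ~ log10(distance_m) and attach a permutation p-value.

    The p-value is two-sided: the fraction of label-shuffled datasets whose
    slope magnitude reaches the observed one, with the add-one convention.
    """
    df = pairs.dropna(subset=["percent_shared"])
    df = df[df["distance_m"] > 0]
    if len(df) < 3:
        raise ValueError("need at least 3 pairs with positive distance")
    x = np.log10(df["distance_m"].to_numpy(dtype=float))
    y = df["percent_shared"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: all distances equal")
    fit = stats.linregress(x, y)
    rng = np.random.default_rng(seed)
    xc = x - x.mean()
    denom = float(np.sum(xc**2))

    def slope_of(yy: np.ndarray) -> float:
        return float(np.sum(xc * (yy - yy.mean())) / denom)

    observed = slope_of(y)
    hits = 0
    for _ in range(n_permutations):
        if abs(slope_of(rng.permutation(y))) >= abs(observed):
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return DecayFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_value=float(fit.rvalue),
        p_permutation=p,
        n_pairs=len(df),
        n_permutations=n_permutations,
    )
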