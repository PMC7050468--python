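"""Geographic classification of putative ecotypes (PEs).

A PE is a cluster of sequence variants hypothesized to be an ecologically
distinct (or geographically isolated) population. Demarcations are consumed
as input — from an external demarcation tool, from synthetic ground truth,
or from the bundled identity-threshold stand-in clusterer — and the source
is always recorded so a stand-in is never silently mistaken for a real
demarcation.

Classification is abundance-based: endemism is measured on reads rather than
distinct variants, because presence/absence hides how concentrated a
population is in its home basin. A PE is endemic when all of its reads come
from one basin, near-endemic when at least a threshold fraction (default
90%) does, and multi-basin otherwise. Orthogonal flags mark predominant PEs
(>1% of reads in at least one sample) and cosmopolitan PEs (>10 reads per
sample in samples of at least two basins).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .hfs import VariantTable, hamming_identity

CLASS_ENDEMIC = "endemic"
CLASS_NEAR_ENDEMIC = "near_endemic"
CLASS_MULTI_BASIN = "multi_basin"

SOURCE_EXTERNAL = "external_map"
SOURCE_TRUTH = "truth_labels"
SOURCE_IDENTITY = "identity_clustering"


@dataclass
class PEDemarcation:
    """Variant -> putative-ecotype mapping with provenance."""

    members: dict[str, list[str]]          # pe_id -> variant ids
    lineages: dict[str, str] = field(default_factory=dict)
    source: str = SOURCE_EXTERNAL

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for pe, variants in self.members.items():
            if not variants:
                raise ValueError(f"PE {pe!r} has no members")
            for v in variants:
                if v in seen:
                    raise ValueError(f"variant {v!r} in both {seen[v]!r} and {pe!r}")
                seen[v] = pe

    def pe_of(self) -> pd.Series:
        """Variant id -> pe id."""
        mapping = {v: pe for pe, vs in self.members.items() for v in vs}
        return pd.Series(mapping, dtype=object)

    @classmethod
    def from_tsv(cls, path, source: str = SOURCE_EXTERNAL) -> "PEDemarcation":
        df = pd.read_csv(path, sep="\t", comment="#")
        members: dict[str, list[str]] = {}
        for row in df.itertuples(index=False):
            members.setdefault(str(row.pe_id), []).append(str(row.variant_id))
        return cls(members=members, source=source)

    def to_tsv(self, path, header: str | None = None) -> None:
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            fh.write(f"# source={self.source}\n")
            fh.write("variant_id\tpe_id\n")
            for pe, variants in self.members.items():
                for v in variants:
                    fh.write(f"{v}\t{pe}\n")


def pe_abundance(
    table: VariantTable,
    dem: PEDemarcation,
    sample_to_basin: Mapping[str, str] | pd.Series,
    weight: str = "reads",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Aggregate variant counts by PE.

    Returns (PE x basin counts, PE x sample counts, per-sample counts of
    variants outside any PE). ``weight="reads"`` (default) sums read
    counts, so totals are conserved: PE counts plus unassigned counts equal
    the table total. ``weight="variants"`` counts distinct variants present
    instead, for a presence-based view of the same classification.
    """
    if weight not in ("reads", "variants"):
        raise ValueError(f"unknown weight {weight!r}")
    basin_of = pd.Series(sample_to_basin)
    for s in table.counts.columns:
        if s not in basin_of.index:
            raise KeyError(f"sample {s!r} has no basin assignment")
    counts = table.counts if weight == "reads" else (table.counts > 0).astype(np.int64)
    pe_of = dem.pe_of()
    assigned = [v for v in counts.index if v in pe_of.index]
    unassigned_ids = [v for v in counts.index if v not in pe_of.index]
    pe_ids = list(dem.members)
    by_sample = pd.DataFrame(0, index=pe_ids, columns=counts.columns, dtype=np.int64)
    if assigned:
        grouped = counts.loc[assigned].groupby(pe_of.loc[assigned]).sum()
        by_sample.loc[grouped.index] = grouped.astype(np.int64)
    basins = basin_of.loc[counts.columns]
    if weight == "reads":
        by_basin = by_sample.T.groupby(basins.to_numpy()).sum().T
    else:
        # distinct variants present anywhere in the basin, per PE
        present = counts.T.groupby(basins.to_numpy()).any().T.astype(np.int64)
        by_basin = pd.DataFrame(0, index=pe_ids, columns=present.columns, dtype=np.int64)
        if assigned:
            grouped = present.loc[assigned].groupby(pe_of.loc[assigned]).sum()
            by_basin.loc[grouped.index] = grouped.astype(np.int64)
    unassigned = counts.loc[unassigned_ids].sum(axis=0)
    return by_basin, by_sample, unassigned


def flag_predominant(pe_by_sample: pd.DataFrame, threshold_fraction: float = 0.01) -> pd.Series:
    """Flag PEs contributing more than ``threshold_fraction`` of at least one
    sample's reads. Samples with zero reads are skipped."""
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must be in (0, 1)")
    sample_totals = pe_by_sample.sum(axis=0)
    nonzero = sample_totals.index[sample_totals > 0]
    if len(nonzero) == 0:
        return pd.Series(False, index=pe_by_sample.index)
    frac = pe_by_sample[nonzero] / sample_totals[nonzero]
    return (frac > threshold_fraction).any(axis=1)


def classify_endemism(pe_by_basin: pd.DataFrame, near_threshold: float = 0.90) -> pd.DataFrame:
    """Classify each PE as endemic / near-endemic / multi-basin by read share.

    ``fraction_top_basin`` is the share of a PE's reads in its best basin;
    the class is endemic at 1.0, near-endemic at >= ``near_threshold``,
    multi-basin otherwise.
    """
    if not 0.5 < near_threshold <= 1.0:
        raise ValueError("near_threshold must be in (0.5, 1]")
    totals = pe_by_basin.sum(axis=1)
    if (totals == 0).any():
        bad = list(pe_by_basin.index[totals == 0])
        raise ValueError(f"PE(s) with zero total reads: {bad}")
    frac = pe_by_basin.div(totals, axis=0)
    top_basin = frac.idxmax(axis=1)
    top_frac = frac.max(axis=1)
    labels = np.where(
        top_frac >= 1.0,
        CLASS_ENDEMIC,
        np.where(top_frac >= near_threshold, CLASS_NEAR_ENDEMIC, CLASS_MULTI_BASIN),
    )
    return pd.DataFrame(
        {
            "top_basin": top_basin,
            "fraction_top_basin": top_frac,
            "endemism_class": labels,
        },
        index=pe_by_basin.index,
    )


def flag_cosmopolitan(
    pe_by_sample: pd.DataFrame,
    sample_to_basin: Mapping[str, str] | pd.Series,
    min_per_sample: int = 10,
) -> pd.Series:
    """Flag PEs found at > ``min_per_sample`` reads in at least one sample of
    each of two or more basins."""
    if min_per_sample < 1:
        raise ValueError("min_per_sample must be >= 1")
    basin_of = pd.Series(sample_to_basin).loc[pe_by_sample.columns]
    hits = pe_by_sample > min_per_sample
    basins_hit = hits.T.groupby(basin_of.to_numpy()).any().T
    return basins_hit.sum(axis=1) >= 2


def identity_cluster_demarcation(
    table: VariantTable,
    identity_threshold: float,
) -> PEDemarcation:
    """Single-linkage identity clustering as a labelled stand-in demarcator.

    Variants are joined whenever their Hamming identity meets the threshold
    (transitive closure), separately within each lineage when lineage labels
    are present. This is a deterministic geometric stand-in for a real
    evolutionary demarcation tool, and is tagged as such in its source.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must be in (0, 1]")
    ids = list(table.counts.index)
    lineage = table.lineage if table.lineage is not None else pd.Series("", index=ids)
    parent = {v: v for v in ids}

    def find(v: str) -> str:
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            # deterministic root: keep the earlier variant id
            if ra > rb:
                ra, rb = rb, ra
            parent[rb] = ra

    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if lineage[a] != lineage[b]:
                continue
            if hamming_identity(table.sequences[a], table.sequences[b]) >= identity_threshold:
                union(a, b)
    clusters: dict[str, list[str]] = {}
    for v in ids:
        clusters.setdefault(find(v), []).append(v)
    members: dict[str, list[str]] = {}
    lineages: dict[str, str] = {}
    for k, root in enumerate(sorted(clusters), start=1):
        pe = f"PE{k:03d}"
        members[pe] = clusters[root]
        lin = {str(lineage[v]) for v in clusters[root]}
        lineages[pe] = lin.pop() if len(lin) == 1 else "mixed"
    return PEDemarcation(members=members, lineages=lineages, source=SOURCE_IDENTITY)
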