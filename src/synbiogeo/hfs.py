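"""Dereplication of amplicon reads into high-frequency sequence (HFS) tables.

An HFS-N table keeps every distinct 302-bp sequence variant with at least N
identical reads summed across all samples (HFS10 for most analyses, HFS2 for
the dispersal analysis, which must see even rarely shared variants). Variants
are assigned to the A-like or B'-like *Synechococcus* lineage by exact
(alignment-free) identity against trimmed reference segments: all sequences
are equal length by construction, so Hamming identity against each reference
is an exact replacement for a local-alignment search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGT")

LINEAGE_A = "A"
LINEAGE_B = "Bprime"
LINEAGE_UNASSIGNED = "unassigned"


class Read(NamedTuple):
    """One amplicon read attributed to a sample."""

    read_id: str
    sample: str
    sequence: str


@dataclass
class VariantTable:
    """Dereplicated variant-by-sample count matrix.

    Parameters
    ----------
    sequences : pd.Series
        Variant id -> sequence. All sequences share one length and are
        unique.
    counts : pd.DataFrame
        Variant x sample matrix of non-negative integer read counts; index
        matches ``sequences``.
    threshold : int
        The HFS minimum that has been applied (1 = unfiltered).
    lineage : pd.Series or None
        Optional per-variant label in {"A", "Bprime", "unassigned"}.
    identity : pd.Series or None
        Identity to the best-matching reference, when lineage is assigned.
    """

    sequences: pd.Series
    counts: pd.DataFrame
    threshold: int = 1
    lineage: pd.Series | None = None
    identity: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.sequences.index.equals(self.counts.index):
            raise ValueError("sequences and counts must share a variant index")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"sequences of mixed lengths: {sorted(lengths)}")
        if self.sequences.duplicated().any():
            raise ValueError("duplicate sequences among variants")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        totals = self.counts.sum(axis=1)
        if len(totals) and int(totals.min()) < self.threshold:
            raise ValueError("variant below the declared HFS threshold")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.counts.index)

    def totals(self) -> pd.Series:
        """Per-variant read totals across all samples."""
        return self.counts.sum(axis=1)

    def subset_variants(self, ids: Iterable[str], threshold: int | None = None) -> "VariantTable":
        ids = [i for i in self.counts.index if i in set(ids)]
        return VariantTable(
            sequences=self.sequences.loc[ids],
            counts=self.counts.loc[ids],
            threshold=self.threshold if threshold is None else threshold,
            lineage=None if self.lineage is None else self.lineage.loc[ids],
            identity=None if self.identity is None else self.identity.loc[ids],
        )

    def write(self, fasta_path, counts_path, header: str | None = None) -> None:
        """Write variants.fasta and a counts TSV (optionally with a comment header)."""
        records = [
            SeqRecord(Seq(seq), id=vid, description="")
            for vid, seq in self.sequences.items()
        ]
        SeqIO.write(records, str(fasta_path), "fasta")
        out = self.counts.copy()
        out.index.name = "variant"
        if self.lineage is not None:
            out["lineage"] = self.lineage
        with open(counts_path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            out.to_csv(fh, sep="\t")


@dataclass
class ReferenceSet:
    """Labelled lineage reference sequences, trimmed to the variant length."""

    sequences: pd.Series  # reference id -> sequence
    lineages: pd.Series   # reference id -> lineage label

    def __post_init__(self) -> None:
        if not self.sequences.index.equals(self.lineages.index):
            raise ValueError("reference sequences and lineages must align")
        if self.sequences.index.duplicated().any():
            raise ValueError("duplicate reference ids")
        if len(set(self.lineages)) < 1 or self.lineages.isna().any():
            raise ValueError("every reference needs a lineage label")

    @classmethod
    def from_fasta(cls, path, lineage_of=None) -> "ReferenceSet":
        """Load references; lineage parsed from a ``lineage=`` header token
        unless ``lineage_of`` (id -> label) is given."""
        seqs, lins = {}, {}
        for rec in SeqIO.parse(str(path), "fasta"):
            seqs[rec.id] = str(rec.seq).upper()
            if lineage_of is not None:
                lins[rec.id] = lineage_of(rec.id)
            else:
                tokens = dict(
                    t.split("=", 1) for t in rec.description.split() if "=" in t
                )
                if "lineage" not in tokens:
                    raise ValueError(f"reference {rec.id!r} lacks a lineage= token")
                lins[rec.id] = tokens["lineage"]
        return cls(pd.Series(seqs), pd.Series(lins))


def read_fasta_reads(path) -> list[Read]:
    """Parse a multi-FASTA of reads whose headers carry ``sample=<id>``."""
    reads = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = dict(t.split("=", 1) for t in rec.description.split() if "=" in t)
        if "sample" not in tokens:
            raise ValueError(f"read {rec.id!r} has no sample= token in its header")
        reads.append(Read(rec.id, tokens["sample"], str(rec.seq).upper()))
    return reads


def trim_and_clean(reads: Iterable[Read], target_length: int = 302) -> tuple[list[Read], pd.DataFrame]:
    """Trim reads to ``target_length`` from the 5' end and drop unusable ones.

    Reads shorter than the target, or containing characters outside ACGT
    within the trimmed window, are dropped. Returns the cleaned reads and a
    per-sample audit with kept/dropped counts.
    """
    if target_length <= 0:
        raise ValueError("target_length must be positive")
    kept: list[Read] = []
    audit: dict[str, dict[str, int]] = {}
    for read in reads:
        row = audit.setdefault(read.sample, {"kept": 0, "dropped_short": 0, "dropped_alphabet": 0})
        seq = read.sequence.upper()
        if len(seq) < target_length:
            row["dropped_short"] += 1
            continue
        seq = seq[:target_length]
        if not VALID_BASES.issuperset(seq):
            row["dropped_alphabet"] += 1
            continue
        row["kept"] += 1
        kept.append(Read(read.read_id, read.sample, seq))
    audit_df = pd.DataFrame.from_dict(audit, orient="index").fillna(0).astype(int)
    audit_df.index.name = "sample"
    return kept, audit_df


def dereplicate(reads: Iterable[Read], samples: Iterable[str] | None = None) -> VariantTable:
    """Collapse identical sequences into variants with an exact count matrix.

    Variant ids are assigned deterministically: descending total count, ties
    broken by lexicographic sequence. ``samples`` fixes the column order
    (and the known-sample universe); by default columns appear in first-seen
    order.
    """
    reads = list(reads)
    known = None if samples is None else list(samples)
    if known is not None:
        known_set = set(known)
        for read in reads:
            if read.sample not in known_set:
                raise ValueError(f"read {read.read_id!r} has unknown sample {read.sample!r}")
    per_seq: dict[str, dict[str, int]] = {}
    seen_samples: list[str] = []
    seen = set()
    for read in reads:
        per_seq.setdefault(read.sequence, {}).setdefault(read.sample, 0)
        per_seq[read.sequence][read.sample] += 1
        if read.sample not in seen:
            seen.add(read.sample)
            seen_samples.append(read.sample)
    columns = known if known is not None else seen_samples
    seqs = list(per_seq)
    totals = {s: sum(per_seq[s].values()) for s in seqs}
    seqs.sort(key=lambda s: (-totals[s], s))
    width = max(4, len(str(len(seqs))))
    ids = [f"v{i + 1:0{width}d}" for i in range(len(seqs))]
    counts = pd.DataFrame(0, index=ids, columns=columns, dtype=np.int64)
    for vid, seq in zip(ids, seqs):
        for sample, n in per_seq[seq].items():
            counts.at[vid, sample] = n
    return VariantTable(sequences=pd.Series(seqs, index=ids), counts=counts, threshold=1)


def filter_hfs(table: VariantTable, min_total: int) -> VariantTable:
    """Keep variants whose total count across all samples is >= ``min_total``.

    Column (sample) order is preserved; applying successive thresholds is
    equivalent to applying their maximum once.
    """
    if min_total < 1:
        raise ValueError("min_total must be >= 1")
    keep = table.totals() >= min_total
    ids = list(table.counts.index[keep])
    out = table.subset_variants(ids, threshold=max(min_total, table.threshold))
    return out


def hamming_identity(a: str, b: str) -> float:
    """Fraction of aligned positions at which two equal-length sequences agree."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    if not a:
        return 1.0
    matches = sum(x == y for x, y in zip(a, b))
    return matches / len(a)


def assign_lineage(table: VariantTable, refs: ReferenceSet) -> VariantTable:
    """Label each variant with the lineage of its highest-identity reference.

    An exact identity tie between two lineages yields "unassigned" with a
    warning; such variants are left out of lineage-split analyses.
    """
    ref_len = {len(s) for s in refs.sequences}
    var_len = {len(s) for s in table.sequences} or {0}
    if ref_len and ref_len != var_len:
        raise ValueError(
            f"reference length {sorted(ref_len)} != variant length {sorted(var_len)}"
        )
    labels, idents = {}, {}
    for vid, seq in table.sequences.items():
        best: dict[str, float] = {}
        for rid, rseq in refs.sequences.items():
            lin = refs.lineages[rid]
            ident = hamming_identity(seq, rseq)
            if ident > best.get(lin, -1.0):
                best[lin] = ident
        top = max(best.values())
        winners = sorted(lin for lin, ident in best.items() if ident == top)
        if len(winners) > 1:
            warnings.warn(
                f"variant {vid} ties between lineages {winners}; marked unassigned"
            )
            labels[vid] = LINEAGE_UNASSIGNED
        else:
            labels[vid] = winners[0]
        idents[vid] = top
    return replace(
        table,
        lineage=pd.Series(labels, index=table.counts.index),
        identity=pd.Series(idents, index=table.counts.index),
    )
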