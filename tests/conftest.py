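from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from synbiogeo.hfs import VariantTable, dereplicate, filter_hfs, read_fasta_reads, trim_and_clean
from synbiogeo.simulate import SimConfig, write_dataset


def make_table(counts: dict[str, dict[str, int]],
               sequences: dict[str, str] | None = None,
               samples: list[str] | None = None) -> VariantTable:
    """Small variant table from {variant: {sample: count}} dicts.

    Sequences default to distinct arbitrary 8-mers so identity-based
    operations stay meaningful.
    """
    variants = list(counts)
    if samples is None:
        samples = sorted({s for row in counts.values() for s in row})
    mat = pd.DataFrame(0, index=variants, columns=samples, dtype=np.int64)
    for v, row in counts.items():
        for s, n in row.items():
            mat.at[v, s] = n
    if sequences is None:
        bases = "ACGT"
        sequences = {
            v: "".join(bases[(i >> (2 * j)) & 3] for j in range(8))
            for i, v in enumerate(variants)
        }
    seqs = pd.Series({v: sequences[v] for v in variants})
    return VariantTable(sequences=seqs, counts=mat, threshold=1)


@pytest.fixture(scope="session")
def reference_sim(tmp_path_factory):
    """The reference synthetic dataset: default study-like configuration."""
    outdir = tmp_path_factory.mktemp("refsim")
    config = SimConfig(seed=42)
    paths = write_dataset(outdir, config)
    return config, paths


@pytest.fixture(scope="session")
def reference_tables(reference_sim):
    """Dereplicated HFS10/HFS2 tables plus metadata for the reference dataset."""
    _config, paths = reference_sim
    samples = pd.read_csv(paths["samples"], sep="\t").set_index("sample")
    springs = pd.read_csv(paths["springs"], sep="\t").set_index("spring")
    reads = read_fasta_reads(paths["reads"])
    cleaned, _audit = trim_and_clean(reads)
    table = dereplicate(cleaned, samples=list(samples.index))
    return {
        "samples": samples,
        "springs": springs,
        "table": table,
        "hfs10": filter_hfs(table, 10),
        "hfs2": filter_hfs(table, 2),
    }


@pytest.fixture(scope="session")
def driver_sim(tmp_path_factory):
    """Synthetic dataset with a single planted environmental driver (pH).

    Dispersal is cosmopolitan for every ecotype, so chemistry — not
    geography — is the only structuring force, and only pH enters the niche
    response; every other analyte is a pure noise column.
    """
    outdir = tmp_path_factory.mktemp("driversim")
    config = SimConfig(
        seed=99,
        dispersal_classes={"cosmopolitan": 1.0},
        niche_analytes=("pH",),
        niche_width=0.5,
        n_ecotypes=12,
        springs_per_basin=(2, 3),
        read_depth=(1000, 3000),
    )
    paths = write_dataset(outdir, config)
    return config, paths
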