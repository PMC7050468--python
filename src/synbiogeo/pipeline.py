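"""End-to-end pipeline: reads -> HFS tables -> sharing -> endemism -> ordination.

Every output table carries a provenance header line (stage and config hash),
and every stochastic stage draws its seed deterministically from the single
global seed, so stages can be rerun in isolation and full reruns are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from . import endemism as endemism_mod
from . import hfs as hfs_mod
from . import ordination as ord_mod
from . import sharing as sharing_mod


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run.

    Thresholds default to the conventions of the emulated study: HFS10 for
    the main table, HFS2 for dispersal, >1% predominance, >=90%
    near-endemism, >10 reads/sample cosmopolitanism, alpha 0.05.
    """

    reads: str = "reads.fasta"
    samples: str = "samples.tsv"
    springs: str = "springs.tsv"
    references: str | None = None
    pe_map: str | None = None
    truth_variants: str | None = None
    outdir: str = "results"
    target_length: int = 302
    hfs_primary: int = 10            # threshold of the main analysis table
    hfs_dispersal: int = 2           # threshold of the sharing/dispersal table
    exclusions: list[str] = field(default_factory=list)
    near_endemic_threshold: float = 0.90
    predominance_threshold: float = 0.01
    cosmopolitan_min: int = 10
    alpha: float = 0.05
    n_permutations: int = 999
    tightness_draws: int = 999
    demarcation: str = "identity_clustering"  # external_map | truth_labels | identity_clustering
    identity_threshold: float = 0.995
    density_parameter: str | None = None
    min_pe_reads: int = 1            # noise floor for endemism classification
    seed: int = 0

    def validate(self) -> None:
        if self.target_length <= 0:
            raise ValueError("target_length: must be > 0")
        if self.hfs_primary < 1 or self.hfs_dispersal < 1:
            raise ValueError("hfs_primary/hfs_dispersal: must be >= 1")
        if not 0.5 < self.near_endemic_threshold <= 1.0:
            raise ValueError("near_endemic_threshold: must be in (0.5, 1]")
        if not 0.0 < self.predominance_threshold < 1.0:
            raise ValueError("predominance_threshold: must be in (0, 1)")
        if self.cosmopolitan_min < 1:
            raise ValueError("cosmopolitan_min: must be >= 1")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha: must be in (0, 1]")
        if self.n_permutations < 99 or self.tightness_draws < 99:
            raise ValueError("n_permutations/tightness_draws: must be >= 99")
        if self.demarcation not in ("external_map", "truth_labels", "identity_clustering"):
            raise ValueError(f"demarcation: unknown source {self.demarcation!r}")
        if not 0.0 < self.identity_threshold <= 1.0:
            raise ValueError("identity_threshold: must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed (< 2^31) derived from the global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


def _write_tsv(df: pd.DataFrame, path: Path, stage: str, cfg_hash: str, index=True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# stage={stage} config={cfg_hash} synbiogeo={__version__}\n")
        df.to_csv(fh, sep="\t", index=index)


def load_variant_table(counts_path, fasta_path, threshold: int = 1) -> hfs_mod.VariantTable:
    """Rehydrate a variant table from a counts TSV plus its variants FASTA."""
    counts = pd.read_csv(counts_path, sep="\t", comment="#").set_index("variant")
    lineage = None
    if "lineage" in counts.columns:
        lineage = counts.pop("lineage")
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    sequences = pd.Series({v: seqs[v] for v in counts.index})
    return hfs_mod.VariantTable(
        sequences=sequences, counts=counts.astype(int),
        threshold=threshold, lineage=lineage,
    )


def _load_metadata(config: RunConfig):
    samples = pd.read_csv(config.samples, sep="\t", comment="#").set_index("sample")
    springs = pd.read_csv(config.springs, sep="\t", comment="#").set_index("spring")
    return samples, springs


def stage_hfs(config: RunConfig, outdir: Path, cfg_hash: str) -> dict:
    """Trim/clean, dereplicate, HFS-filter, assign lineage; write tables."""
    samples, _ = _load_metadata(config)
    raw = hfs_mod.read_fasta_reads(config.reads)
    cleaned, audit = hfs_mod.trim_and_clean(raw, config.target_length)
    table = hfs_mod.dereplicate(cleaned, samples=list(samples.index))
    primary = hfs_mod.filter_hfs(table, config.hfs_primary)
    dispersal = hfs_mod.filter_hfs(table, config.hfs_dispersal)
    if config.references:
        refs = hfs_mod.ReferenceSet.from_fasta(config.references)
        primary = hfs_mod.assign_lineage(primary, refs)
    _write_tsv(audit, outdir / "clean_audit.tsv", "hfs", cfg_hash)
    primary.write(
        outdir / "variants.fasta", outdir / "counts.tsv",
        header=f"stage=hfs config={cfg_hash} threshold={config.hfs_primary}",
    )
    dispersal.write(
        outdir / "variants_dispersal.fasta", outdir / "counts_dispersal.tsv",
        header=f"stage=hfs config={cfg_hash} threshold={config.hfs_dispersal}",
    )
    return {
        "tables": (primary, dispersal),
        "counts": {
            "reads_in": len(raw),
            "reads_clean": len(cleaned),
            "variants": len(table.counts),
            f"hfs{config.hfs_primary}": len(primary.counts),
            f"hfs{config.hfs_dispersal}": len(dispersal.counts),
        },
    }


def _reload_tables(config: RunConfig, outdir: Path):
    primary = load_variant_table(
        outdir / "counts.tsv", outdir / "variants.fasta", config.hfs_primary)
    dispersal = load_variant_table(
        outdir / "counts_dispersal.tsv", outdir / "variants_dispersal.fasta",
        config.hfs_dispersal)
    return primary, dispersal


def stage_sharing(config: RunConfig, outdir: Path, cfg_hash: str,
                  primary=None, dispersal=None) -> dict:
    """Pairwise sharing matrix on both HFS tables plus the distance-decay fit."""
    samples, springs = _load_metadata(config)
    if primary is None or dispersal is None:
        primary, dispersal = _reload_tables(config, outdir)
    sample_to_spring = samples["spring"]
    pairs = sharing_mod.pairwise_matrix(
        primary, sample_to_spring, springs,
        exclusions=config.exclusions, reads_table=dispersal,
    )
    pairs_disp = sharing_mod.pairwise_matrix(
        dispersal, sample_to_spring, springs, exclusions=config.exclusions,
    )
    sharing = pairs.rename(columns={
        "percent_shared": f"pct_shared_hfs{config.hfs_primary}",
        "shared_reads_min_sample": f"shared_reads_hfs{config.hfs_dispersal}",
    })
    sharing[f"pct_shared_hfs{config.hfs_dispersal}"] = pairs_disp["percent_shared"]
    _write_tsv(sharing, outdir / "sharing.tsv", "sharing", cfg_hash, index=False)
    decay = sharing_mod.distance_decay(
        pairs_disp, n_permutations=config.n_permutations,
        seed=stage_seed(config.seed, "decay"),
    )
    _write_tsv(pd.DataFrame([decay.__dict__]), outdir / "distance_decay.tsv",
               "sharing", cfg_hash, index=False)
    return {
        "counts": {
            "pairs": len(pairs),
            "decay_slope": decay.slope,
            "decay_p": decay.p_permutation,
        },
    }


def _demarcation(config: RunConfig, primary: hfs_mod.VariantTable) -> endemism_mod.PEDemarcation:
    if config.demarcation == "external_map":
        if not config.pe_map:
            raise ValueError("demarcation=external_map requires a pe_map path")
        return endemism_mod.PEDemarcation.from_tsv(config.pe_map)
    if config.demarcation == "truth_labels":
        if not config.truth_variants:
            raise ValueError("demarcation=truth_labels requires a truth_variants path")
        tv = pd.read_csv(config.truth_variants, sep="\t", comment="#")
        seq_to_eco = dict(zip(tv["sequence"], tv["ecotype_id"]))
        members: dict[str, list[str]] = {}
        for vid, seq in primary.sequences.items():
            eco = seq_to_eco.get(seq)
            if eco is not None:
                members.setdefault(eco, []).append(vid)
        return endemism_mod.PEDemarcation(members=members, source=endemism_mod.SOURCE_TRUTH)
    return endemism_mod.identity_cluster_demarcation(primary, config.identity_threshold)


def stage_endemism(config: RunConfig, outdir: Path, cfg_hash: str, primary=None) -> dict:
    """Demarcate PEs and classify their geographic distributions."""
    samples, _ = _load_metadata(config)
    if primary is None:
        primary, _d = _reload_tables(config, outdir)
    dem = _demarcation(config, primary)
    sample_to_basin = samples["basin"]
    by_basin, by_sample, unassigned = endemism_mod.pe_abundance(
        primary, dem, sample_to_basin)
    keep = by_basin.sum(axis=1) >= config.min_pe_reads
    classes = endemism_mod.classify_endemism(by_basin[keep], config.near_endemic_threshold)
    predominant = endemism_mod.flag_predominant(by_sample, config.predominance_threshold)
    cosmo = endemism_mod.flag_cosmopolitan(by_sample, sample_to_basin, config.cosmopolitan_min)
    report = classes.copy()
    report["n_variants"] = pd.Series({p: len(v) for p, v in dem.members.items()})
    report["total_reads"] = by_basin[keep].sum(axis=1)
    report["predominant"] = predominant.reindex(report.index)
    report["cosmopolitan"] = cosmo.reindex(report.index)
    report["demarcation_source"] = dem.source
    report.index.name = "pe_id"
    dem.to_tsv(outdir / "pe_map.tsv", header=f"stage=endemism config={cfg_hash}")
    _write_tsv(report, outdir / "endemism.tsv", "endemism", cfg_hash)
    bs = by_sample.copy()
    bs.index.name = "pe_id"
    _write_tsv(bs, outdir / "pe_by_sample.tsv", "endemism", cfg_hash)
    return {
        "dem": dem,
        "counts": {
            "pes": len(dem.members),
            "predominant": int(predominant.sum()),
            "endemic": int((classes["endemism_class"] == "endemic").sum()),
            "unassigned_reads": int(unassigned.sum()),
            "demarcation_source": dem.source,
        },
    }


def stage_ordination(config: RunConfig, outdir: Path, cfg_hash: str,
                     primary=None, dem=None) -> dict:
    """Stepwise CCA, marginal constrained variability, tightness and density."""
    samples, springs = _load_metadata(config)
    if primary is None:
        primary, _d = _reload_tables(config, outdir)
    if dem is None:
        dem = endemism_mod.PEDemarcation.from_tsv(outdir / "pe_map.tsv")
    env_cols = [c for c in springs.columns
                if c != "basin" and pd.api.types.is_numeric_dtype(springs[c])]
    env = springs.loc[samples.loc[list(primary.counts.columns), "spring"], env_cols]
    env.index = list(primary.counts.columns)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stepwise = ord_mod.stepwise_select(
            primary.counts, env, alpha=config.alpha,
            n_perm=config.n_permutations,
            seed=stage_seed(config.seed, "stepwise"),
        )
        model_params = list(stepwise["parameter"]) if len(stepwise) else env_cols
        model = ord_mod.cca_fit(primary.counts, env[model_params])
        marginal = pd.DataFrame({
            "parameter": env_cols,
            "constrained_pct": [
                ord_mod.constrained_variability(primary.counts, env, p)
                for p in env_cols
            ],
        }).sort_values("constrained_pct", ascending=False)
    dem_in_model = endemism_mod.PEDemarcation(
        members={
            pe: [v for v in vs if v in model.variant_scores.index]
            for pe, vs in dem.members.items()
            if any(v in model.variant_scores.index for v in vs)
        },
        lineages=dem.lineages, source=dem.source,
    )
    tightness = ord_mod.pe_tightness(
        model, dem_in_model, n_draws=config.tightness_draws,
        seed=stage_seed(config.seed, "tightness"),
    )
    density_param = config.density_parameter or model.parameters[0]
    curves = ord_mod.weighted_density(model, dem_in_model, density_param)
    scores = pd.concat([
        model.site_scores.assign(kind="sample"),
        model.variant_scores.assign(kind="variant"),
    ])
    scores.index.name = "id"
    _write_tsv(scores, outdir / "cca_scores.tsv", "ordination", cfg_hash)
    bi = model.biplot_scores.copy()
    bi.index.name = "parameter"
    _write_tsv(bi, outdir / "biplot.tsv", "ordination", cfg_hash)
    _write_tsv(stepwise, outdir / "stepwise.tsv", "ordination", cfg_hash, index=False)
    _write_tsv(marginal, outdir / "constrained_variability.tsv", "ordination",
               cfg_hash, index=False)
    _write_tsv(tightness, outdir / "tightness.tsv", "ordination", cfg_hash, index=False)
    _write_tsv(ord_mod.density_frame(curves), outdir / "density.tsv", "ordination",
               cfg_hash, index=False)
    return {
        "counts": {
            "selected": list(stepwise["parameter"]),
            "total_inertia": model.total_inertia,
            "constrained_inertia": model.constrained_inertia,
            "tightness_tested": int(tightness["p_value"].notna().sum()),
            "density_parameter": density_param,
        },
    }


_STAGES = ("hfs", "sharing", "endemism", "ordination")


def run_pipeline(config: RunConfig) -> dict:
    """Execute hfs -> sharing -> endemism -> ordination; return the manifest.

    Any stage error aborts the run with the stage name and context.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    manifest: dict = {
        "config_hash": cfg_hash,
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }
    state: dict = {}
    for stage in _STAGES:
        try:
            if stage == "hfs":
                result = stage_hfs(config, outdir, cfg_hash)
                state["primary"], state["dispersal"] = result["tables"]
            elif stage == "sharing":
                result = stage_sharing(config, outdir, cfg_hash,
                                       state["primary"], state["dispersal"])
            elif stage == "endemism":
                result = stage_endemism(config, outdir, cfg_hash, state["primary"])
                state["dem"] = result["dem"]
            else:
                result = stage_ordination(config, outdir, cfg_hash,
                                          state["primary"], state["dem"])
        except Exception as exc:  # noqa: BLE001 - abort with stage context
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = result["counts"]
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
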