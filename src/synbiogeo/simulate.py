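"""Synthetic hot-spring community generator with planted niche and dispersal structure.

The generator emulates the sampling design of the real survey: ~7 geothermal
basins of 1–5 springs each, duplicate mat samples per spring, per-sample
read depths spanning roughly 10²–10⁴, and basin-correlated water chemistry
(each basin draws analyte means once, springs add within-basin noise — the
way carbonate-terrace basins share high Ca/Mg/SO₄ while siliceous basins do
not).

Ecotypes are the planted truth. Each gets a home basin, a dispersal class
(endemic: confined to the home basin; regional: exponential decay with
distance outside it; cosmopolitan: everywhere), a lineage (A or B'), and a
Gaussian niche optimum in z-scored environment space. Expected abundance of
an ecotype in a sample is proportional to niche response x dispersal
kernel. Sequence variants radiate from a 302-base root per ecotype; roots of
different ecotypes differ at >= 5% of sites so reads are unambiguously
attributable. Within-ecotype variant proportions are drawn once per spring
from a stick-breaking prior, so replicate samples of one spring share
proportions while different springs may be dominated by different variants
(a founder effect). Reads are then multinomial at each sample's depth.

Identical (config, seed) pairs produce byte-identical outputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .hfs import Read, VariantTable
from .sharing import haversine_m

BASES = np.array(list("ACGT"))
SEQ_LENGTH = 302
DISPERSAL_CLASSES = ("endemic", "regional", "cosmopolitan")
LINEAGES = ("A", "Bprime")


class SimConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass(frozen=True)
class EnvParamSpec:
    """One analyte: basin-level mean range and within-basin noise."""

    name: str
    basin_mean_range: tuple[float, float]
    noise_sd: float
    nonnegative: bool = True


def default_env_params() -> list[EnvParamSpec]:
    """Analytes mirroring the survey schema, with ranges spanning the
    observed spring-to-spring variation."""
    return [
        EnvParamSpec("temperature", (50.0, 64.0), 1.0),
        EnvParamSpec("pH", (5.5, 9.2), 0.1),
        EnvParamSpec("S2", (0.0, 40.0), 1.0),
        EnvParamSpec("CaCO", (8.0, 720.0), 20.0),
        EnvParamSpec("Cl", (50.0, 350.0), 10.0),
        EnvParamSpec("Mg", (1.0, 67.0), 2.0),
        EnvParamSpec("SiO2", (23.0, 120.0), 5.0),
        EnvParamSpec("SO4", (20.0, 1300.0), 30.0),
    ]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic study.

    Defaults encode the design of the emulated survey; see the methods note
    for the rationale behind each value.
    """

    n_basins: int = 7
    springs_per_basin: tuple[int, int] = (1, 5)
    replicates_per_spring: int = 2
    basin_centroids: str | list[tuple[float, float]] = "auto"
    within_basin_spread_m: float = 2000.0
    env_params: list[EnvParamSpec] = field(default_factory=default_env_params)
    n_ecotypes: int = 24
    dispersal_classes: dict[str, float] | list[str] = field(
        default_factory=lambda: {"endemic": 0.60, "regional": 0.25, "cosmopolitan": 0.15}
    )
    dispersal_lambda_m: float = 50_000.0
    niche_width: float = 1.0
    variants_per_ecotype: tuple[int, int] = (1, 8)
    mutation_rate: float = 0.005
    read_depth: tuple[int, int] = (100, 5000)
    stick_breaking_alpha: float = 1.5
    lineage_divergence: float = 0.15
    root_divergence: float = 0.04
    lineage_dropout: tuple[str, str] | None = None  # (basin, lineage)
    niche_analytes: tuple[str, ...] | None = None   # None = niche on all analytes
    seed: int = 0

    def validate(self) -> None:
        def bad(fieldname: str, why: str):
            raise SimConfigError(f"{fieldname}: {why}")

        if self.n_basins < 1:
            bad("n_basins", "must be >= 1")
        lo, hi = self.springs_per_basin
        if lo < 1 or hi < lo:
            bad("springs_per_basin", "must be a (lo, hi) range with 1 <= lo <= hi")
        if self.replicates_per_spring < 1:
            bad("replicates_per_spring", "must be >= 1")
        if self.within_basin_spread_m < 0:
            bad("within_basin_spread_m", "must be >= 0")
        if not self.env_params:
            bad("env_params", "need at least one analyte")
        if self.n_ecotypes < 1:
            bad("n_ecotypes", "must be >= 1")
        if isinstance(self.dispersal_classes, dict):
            if not self.dispersal_classes or any(
                k not in DISPERSAL_CLASSES for k in self.dispersal_classes
            ):
                bad("dispersal_classes", f"labels must be among {DISPERSAL_CLASSES}")
            if sum(self.dispersal_classes.values()) <= 0:
                bad("dispersal_classes", "frequencies must sum to a positive value")
        else:
            if len(self.dispersal_classes) != self.n_ecotypes:
                bad("dispersal_classes", "explicit label list must match n_ecotypes")
            if any(k not in DISPERSAL_CLASSES for k in self.dispersal_classes):
                bad("dispersal_classes", f"labels must be among {DISPERSAL_CLASSES}")
        if not self.niche_width > 0:
            bad("niche_width", "must be > 0 (math.inf for a flat niche)")
        vlo, vhi = self.variants_per_ecotype
        if vlo < 1 or vhi < vlo:
            bad("variants_per_ecotype", "must be a (lo, hi) range with 1 <= lo <= hi")
        if not 0.0 <= self.mutation_rate < 0.25:
            bad("mutation_rate", "must be in [0, 0.25)")
        dlo, dhi = self.read_depth
        if dlo < 1 or dhi < dlo:
            bad("read_depth", "must be a (lo, hi) range with 1 <= lo <= hi")
        if self.dispersal_lambda_m <= 0:
            bad("dispersal_lambda_m", "must be > 0")
        if self.stick_breaking_alpha <= 0:
            bad("stick_breaking_alpha", "must be > 0")
        if not 0.0 < self.lineage_divergence < 0.5:
            bad("lineage_divergence", "must be in (0, 0.5)")
        if not 0.0 < self.root_divergence < 0.25:
            bad("root_divergence", "must be in (0, 0.25)")
        if self.niche_analytes is not None:
            names = {p.name for p in self.env_params}
            missing = [a for a in self.niche_analytes if a not in names]
            if missing:
                bad("niche_analytes", f"not in env_params: {missing}")


@dataclass
class GroundTruth:
    """Planted truth: ecotype table, variant origins, expected abundances."""

    ecotypes: pd.DataFrame          # ecotype_id x (home_basin, dispersal_class, lineage, opt_*)
    variants: pd.DataFrame          # variant_id x (ecotype_id, sequence)
    references: dict[str, str]      # lineage -> anchor sequence
    analyte_stats: pd.DataFrame     # analyte x (mean, sd) used for z-scoring
    expected_abundance: pd.DataFrame | None = None  # ecotype x sample

    def variant_origin(self) -> pd.Series:
        return self.variants["ecotype_id"]


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    # stages draw from independent deterministic streams so each operation
    # is reproducible in isolation
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stage]))


def generate_springs(config: SimConfig) -> pd.DataFrame:
    """Place springs around basin centroids and draw basin-correlated chemistry.

    Returns a table indexed by spring id with basin, latitude, longitude and
    one column per analyte.
    """
    config.validate()
    rng = _rng(config, 1)
    if config.basin_centroids == "auto":
        # centroids strung along ~10 degrees of longitude, as in the
        # Oregon-to-Yellowstone transect
        lons = np.linspace(-120.5, -110.5, config.n_basins)
        lats = rng.uniform(42.0, 46.0, size=config.n_basins)
        centroids = list(zip(lats, lons))
    else:
        centroids = list(config.basin_centroids)
        if len(centroids) != config.n_basins:
            raise SimConfigError("basin_centroids: must provide one centroid per basin")
    rows = []
    for b, (clat, clon) in enumerate(centroids):
        basin = f"basin{b + 1}"
        n_springs = int(rng.integers(config.springs_per_basin[0], config.springs_per_basin[1] + 1))
        means = {
            p.name: float(rng.uniform(*p.basin_mean_range)) for p in config.env_params
        }
        for s in range(n_springs):
            dn, de = rng.normal(0.0, config.within_basin_spread_m, size=2) if config.within_basin_spread_m > 0 else (0.0, 0.0)
            lat = clat + dn / 111_320.0
            lon = clon + de / (111_320.0 * math.cos(math.radians(clat)))
            row = {"spring": f"B{b + 1}S{s + 1}", "basin": basin,
                   "latitude": lat, "longitude": lon}
            for p in config.env_params:
                val = means[p.name] + float(rng.normal(0.0, p.noise_sd))
                if p.nonnegative:
                    val = max(val, 0.0)
                row[p.name] = val
            rows.append(row)
    return pd.DataFrame(rows).set_index("spring")


def _zscore_stats(springs: pd.DataFrame, analytes: list[str]) -> pd.DataFrame:
    stats = pd.DataFrame(
        {"mean": springs[analytes].mean(), "sd": springs[analytes].std(ddof=0)}
    )
    stats.loc[stats["sd"] < 1e-12, "sd"] = 1.0  # constant analyte: no gradient
    return stats


def generate_ecotypes(config: SimConfig, springs: pd.DataFrame) -> GroundTruth:
    """Assign each ecotype a home basin, dispersal class, lineage and niche optimum.

    Optima are drawn uniformly within the observed (z-scored) environmental
    range of the springs, so every ecotype's niche is realizable somewhere
    in the archipelago.
    """
    config.validate()
    if springs.empty:
        raise ValueError("springs table is empty")
    rng = _rng(config, 2)
    analytes = [p.name for p in config.env_params]
    stats = _zscore_stats(springs, analytes)
    z = (springs[analytes] - stats["mean"]) / stats["sd"]
    basins = sorted(springs["basin"].unique())
    if isinstance(config.dispersal_classes, dict):
        labels = list(config.dispersal_classes)
        freqs = np.array([config.dispersal_classes[k] for k in labels], dtype=float)
        freqs /= freqs.sum()
        classes = rng.choice(labels, size=config.n_ecotypes, p=freqs)
    else:
        classes = np.array(config.dispersal_classes)
    rows = []
    for e in range(config.n_ecotypes):
        row = {
            "ecotype_id": f"E{e + 1:03d}",
            "home_basin": basins[int(rng.integers(len(basins)))],
            "dispersal_class": str(classes[e]),
            "lineage": LINEAGES[e % 2],
        }
        for a in analytes:
            row[f"opt_{a}"] = float(rng.uniform(z[a].min(), z[a].max()))
        rows.append(row)
    ecotypes = pd.DataFrame(rows).set_index("ecotype_id")
    return GroundTruth(
        ecotypes=ecotypes,
        variants=pd.DataFrame(columns=["ecotype_id", "sequence"]),
        references={},
        analyte_stats=stats,
    )


def _mutate(rng: np.random.Generator, seq: np.ndarray, n_sub: int) -> np.ndarray:
    out = seq.copy()
    if n_sub <= 0:
        return out
    pos = rng.choice(len(seq), size=min(n_sub, len(seq)), replace=False)
    for p in pos:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[int(rng.integers(3))]
    return out


def radiate_variants(config: SimConfig, truth: GroundTruth) -> GroundTruth:
    """Grow 302-base variant sequences from one root per ecotype.

    Lineage anchor sequences (the reference set) diverge from each other at
    ``lineage_divergence``; ecotype roots diverge from their lineage anchor
    at ``root_divergence`` and are rejected until every pair of roots
    differs at >= 5% of sites; each variant carries Binomial(302,
    mutation_rate) substitutions from its root.
    """
    config.validate()
    rng = _rng(config, 3)
    anchor_a = rng.choice(BASES, size=SEQ_LENGTH)
    anchor_b = _mutate(rng, anchor_a, round(config.lineage_divergence * SEQ_LENGTH))
    anchors = {"A": anchor_a, "Bprime": anchor_b}
    min_diff = math.ceil(0.05 * SEQ_LENGTH)
    roots: dict[str, np.ndarray] = {}
    for eid, row in truth.ecotypes.iterrows():
        anchor = anchors[row["lineage"]]
        for _ in range(1000):
            n_sub = int(rng.binomial(SEQ_LENGTH, config.root_divergence))
            root = _mutate(rng, anchor, max(n_sub, min_diff))
            if all(int(np.sum(root != other)) >= min_diff for other in roots.values()):
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not place a sufficiently divergent root")
        roots[eid] = root
    rows = []
    k = 0
    for eid in truth.ecotypes.index:
        n_var = int(rng.integers(config.variants_per_ecotype[0], config.variants_per_ecotype[1] + 1))
        for _ in range(n_var):
            k += 1
            n_sub = int(rng.binomial(SEQ_LENGTH, config.mutation_rate))
            seq = _mutate(rng, roots[eid], n_sub)
            rows.append({"variant_id": f"tv{k:04d}", "ecotype_id": eid,
                         "sequence": "".join(seq)})
    variants = pd.DataFrame(rows).set_index("variant_id")
    return replace(
        truth,
        variants=variants,
        references={lin: "".join(seq) for lin, seq in anchors.items()},
    )


def _niche_response(z_spring: np.ndarray, optimum: np.ndarray, width: float) -> float:
    if math.isinf(width):
        return 1.0
    d2 = float(np.sum(((z_spring - optimum) / width) ** 2))
    return math.exp(-0.5 * d2)


def _dispersal_factor(
    config: SimConfig,
    dispersal_class: str,
    home_basin: str,
    spring_basin: str,
    distance_m: float,
) -> float:
    if spring_basin == home_basin:
        return 1.0
    if dispersal_class == "endemic":
        return 0.0
    if dispersal_class == "cosmopolitan":
        return 1.0
    return math.exp(-distance_m / config.dispersal_lambda_m)


def simulate_reads(
    springs: pd.DataFrame,
    truth: GroundTruth,
    config: SimConfig,
) -> tuple[list[Read], pd.DataFrame, VariantTable, GroundTruth]:
    """Draw multinomial reads per sample under the planted niche/dispersal model.

    Returns (reads, sample table, truth count table, truth with expected
    abundances filled in). Samples where every ecotype has zero expected
    abundance are emitted with zero reads, with a warning.
    """
    config.validate()
    if truth.variants.empty:
        raise ValueError("truth has no variants; run radiate_variants first")
    rng = _rng(config, 4)
    analytes = [p.name for p in config.env_params]
    z = (springs[analytes] - truth.analyte_stats["mean"]) / truth.analyte_stats["sd"]
    centroids = springs.groupby("basin")[["latitude", "longitude"]].mean()
    eco = truth.ecotypes
    opt = eco[[f"opt_{a}" for a in analytes]].to_numpy()
    if config.niche_analytes is not None:
        niche_idx = np.array([analytes.index(a) for a in config.niche_analytes])
    else:
        niche_idx = np.arange(len(analytes))
    opt = opt[:, niche_idx]
    # per-spring ecotype weights: niche response x dispersal kernel
    spring_weights = {}
    for spring, srow in springs.iterrows():
        zs = z.loc[spring].to_numpy()[niche_idx]
        w = np.empty(len(eco))
        for i, (eid, erow) in enumerate(eco.iterrows()):
            home = erow["home_basin"]
            dist = haversine_m(
                centroids.at[home, "latitude"], centroids.at[home, "longitude"],
                srow["latitude"], srow["longitude"],
            )
            niche = _niche_response(zs, opt[i], config.niche_width)
            disp = _dispersal_factor(config, erow["dispersal_class"], home, srow["basin"], dist)
            if config.lineage_dropout is not None:
                basin, lineage = config.lineage_dropout
                if srow["basin"] == basin and erow["lineage"] == lineage:
                    disp = 0.0
            w[i] = niche * disp
        spring_weights[spring] = w
    # founder effect: within-ecotype variant proportions drawn once per spring
    var_of_eco = {
        eid: list(g.index) for eid, g in truth.variants.groupby("ecotype_id")
    }
    founder: dict[tuple[str, str], np.ndarray] = {}
    for spring in springs.index:
        for eid in eco.index:
            k = len(var_of_eco.get(eid, []))
            if k == 0:
                continue
            sticks = rng.beta(1.0, config.stick_breaking_alpha, size=k)
            remaining = np.concatenate([[1.0], np.cumprod(1.0 - sticks[:-1])])
            props = sticks * remaining
            props[-1] += 1.0 - props.sum()  # truncated stick: remainder to last
            founder[(spring, eid)] = props
    # samples and depths
    sample_rows = []
    for spring, srow in springs.iterrows():
        for rep in range(config.replicates_per_spring):
            depth = int(round(math.exp(rng.uniform(
                math.log(config.read_depth[0]), math.log(config.read_depth[1])
            ))))
            sample_rows.append({
                "sample": f"{spring}_r{rep + 1}",
                "spring": spring,
                "basin": srow["basin"],
                "replicate": rep + 1,
                "depth": depth,
            })
    samples = pd.DataFrame(sample_rows).set_index("sample")
    variant_ids = list(truth.variants.index)
    vindex = {v: i for i, v in enumerate(variant_ids)}
    counts = np.zeros((len(variant_ids), len(samples)), dtype=np.int64)
    expected = pd.DataFrame(0.0, index=eco.index, columns=samples.index)
    reads: list[Read] = []
    read_no = 0
    for j, (sample, srow) in enumerate(samples.iterrows()):
        spring = srow["spring"]
        w = spring_weights[spring]
        if w.sum() <= 0:
            warnings.warn(f"sample {sample!r}: all ecotypes have zero expected abundance")
            samples.loc[sample, "depth"] = 0
            continue
        p_eco = w / w.sum()
        expected[sample] = p_eco
        p_var = np.zeros(len(variant_ids))
        for i, eid in enumerate(eco.index):
            vids = var_of_eco.get(eid, [])
            if not vids or p_eco[i] == 0:
                continue
            props = founder[(spring, eid)]
            for vid, prop in zip(vids, props):
                p_var[vindex[vid]] += p_eco[i] * prop
        p_var /= p_var.sum()
        draw = rng.multinomial(int(srow["depth"]), p_var)
        counts[:, j] = draw
        for vi in np.nonzero(draw)[0]:
            seq = truth.variants.iloc[vi]["sequence"]
            for _ in range(int(draw[vi])):
                read_no += 1
                reads.append(Read(f"r{read_no:07d}", sample, seq))
    truth_out = replace(truth, expected_abundance=expected)
    # collapse identical sequences (possible within an ecotype at low
    # mutation rates) so the truth table satisfies variant-table invariants
    cdf = pd.DataFrame(counts, index=variant_ids, columns=samples.index)
    seqs = truth.variants["sequence"]
    group = seqs.groupby(seqs.values)
    keep_ids, keep_seqs, agg = [], [], []
    for seq, members in group.groups.items():
        members = list(members)
        keep_ids.append(members[0])
        keep_seqs.append(seq)
        agg.append(cdf.loc[members].sum(axis=0))
    truth_counts = pd.DataFrame(agg, index=keep_ids)
    sampled = truth_counts.sum(axis=1) > 0  # variants that drew no reads stay in truth.variants only
    truth_counts = truth_counts[sampled]
    keep_seqs = [s for s, ok in zip(keep_seqs, sampled) if ok]
    keep_ids = list(truth_counts.index)
    order = truth_counts.sum(axis=1).sort_values(ascending=False).index
    truth_table = VariantTable(
        sequences=pd.Series(keep_seqs, index=keep_ids).loc[order],
        counts=truth_counts.loc[order].astype(np.int64),
        threshold=1,
    )
    return reads, samples, truth_table, truth_out


def truth_demarcation(table: VariantTable, truth: GroundTruth):
    """PE demarcation of a (dereplicated) variant table from planted labels.

    Variants are matched to ecotypes by exact sequence; variants whose
    sequence is not in the truth (impossible without sequencing error) are
    left out.
    """
    from .endemism import PEDemarcation, SOURCE_TRUTH

    seq_to_eco = dict(zip(truth.variants["sequence"], truth.variants["ecotype_id"]))
    members: dict[str, list[str]] = {}
    for vid, seq in table.sequences.items():
        eco = seq_to_eco.get(seq)
        if eco is not None:
            members.setdefault(eco, []).append(vid)
    lineages = {
        eid: truth.ecotypes.at[eid, "lineage"] for eid in members
    }
    return PEDemarcation(members=members, lineages=lineages, source=SOURCE_TRUTH)


def write_dataset(outdir, config: SimConfig) -> dict[str, Path]:
    """Generate a full synthetic dataset and write it to ``outdir``.

    Emits reads.fasta (headers carry ``sample=``), samples.tsv, springs.tsv,
    references.fasta, truth_ecotypes.tsv, truth_variants.tsv and
    truth_counts.tsv. Byte-identical for identical (config, seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    springs = generate_springs(config)
    truth = generate_ecotypes(config, springs)
    truth = radiate_variants(config, truth)
    reads, samples, truth_table, truth = simulate_reads(springs, truth, config)
    paths = {}

    paths["reads"] = outdir / "reads.fasta"
    with open(paths["reads"], "w") as fh:
        for read in reads:
            fh.write(f">{read.read_id} sample={read.sample}\n{read.sequence}\n")
    paths["references"] = outdir / "references.fasta"
    with open(paths["references"], "w") as fh:
        for lineage, seq in truth.references.items():
            fh.write(f">ref_{lineage} lineage={lineage}\n{seq}\n")
    paths["samples"] = outdir / "samples.tsv"
    samples.to_csv(paths["samples"], sep="\t")
    paths["springs"] = outdir / "springs.tsv"
    springs.to_csv(paths["springs"], sep="\t")
    paths["truth_ecotypes"] = outdir / "truth_ecotypes.tsv"
    truth.ecotypes.to_csv(paths["truth_ecotypes"], sep="\t")
    paths["truth_variants"] = outdir / "truth_variants.tsv"
    truth.variants.to_csv(paths["truth_variants"], sep="\t")
    paths["truth_counts"] = outdir / "truth_counts.tsv"
    truth_table.write(outdir / "truth_variants.fasta", paths["truth_counts"])
    paths["truth_variants_fasta"] = outdir / "truth_variants.fasta"
    if truth.expected_abundance is not None:
        paths["expected_abundance"] = outdir / "truth_expected_abundance.tsv"
        truth.expected_abundance.to_csv(paths["expected_abundance"], sep="\t")
    return paths
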