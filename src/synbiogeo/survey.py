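"""Bundled field-survey tables for the Northwest hot-spring *Synechococcus* study system.

Two small tables describe the sampling design this package was built around:
duplicate microbial-mat samples from 18 alkaline-to-circumneutral hot springs
grouped into 7 geothermal basins/regions (four Yellowstone basins, LaDuke,
Bozeman, and a cluster of Oregon springs), with per-spring water chemistry
(14 analytes), temperature, pH and WGS84 coordinates.

They serve two purposes: they are the schema the synthetic generator emulates,
and they are real inputs for the geographic and ordination-candidate helpers
(e.g. the 18-parameter candidate set for stepwise constrained ordination:
latitude, longitude, temperature, pH and the 14 analytes).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Chemistry analytes measured per spring, as named in the survey table.
ANALYTES = [
    "S2", "CaCO", "Ca", "Cl", "Mg", "SiO2", "Na",
    "SO4", "K", "As", "B", "Fe", "Mn", "Zn",
]

#: Physical parameters joining the analytes in the ordination candidate set.
PHYSICAL = ["longitude", "latitude", "temperature", "pH"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("synbiogeo.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_springs() -> pd.DataFrame:
    """Spring table: basin, coordinates, temperature range, pH and chemistry.

    Indexed by spring name. A ``temperature`` column (midpoint of the
    measured range) is added for use as a single ordination predictor.
    """
    df = _read("survey_springs.tsv").set_index("spring")
    df["temperature"] = (df["temp_c_min"] + df["temp_c_max"]) / 2.0
    return df


def load_samples(include_excluded: bool = True) -> pd.DataFrame:
    """Sample table: spring, basin, barcode, per-sample read totals.

    ``excluded`` flags the samples left out of the pairwise-sharing analysis
    (too few reads, or collected at an off-norm temperature or pH site);
    pass ``include_excluded=False`` to drop them, leaving the 21 retained
    samples.
    """
    df = _read("survey_samples.tsv").set_index("sample")
    df["excluded"] = df["excluded"].astype(bool)
    if not include_excluded:
        df = df[~df["excluded"]]
    return df


def default_exclusions() -> list[str]:
    """Sample ids flagged as excluded in the bundled survey table."""
    df = load_samples()
    return list(df.index[df["excluded"]])


def candidate_parameters(springs: pd.DataFrame | None = None) -> pd.DataFrame:
    """Spring-level candidate predictor matrix for constrained ordination.

    Columns are the 18 physical and chemical parameters: longitude,
    latitude, temperature (range midpoint), pH, and the 14 analytes.
    """
    if springs is None:
        springs = load_springs()
    return springs[PHYSICAL + ANALYTES].astype(float)


def sample_env(samples: pd.DataFrame | None = None,
               springs: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-sample environment: each sample inherits its spring's parameters."""
    if samples is None:
        samples = load_samples()
    params = candidate_parameters(springs)
    env = params.loc[samples["spring"]]
    env.index = samples.index
    return env
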