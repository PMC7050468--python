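"""Constrained ordination: eigen-analysis, selection, tightness, density."""

from __future__ import annotations

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from synbiogeo.endemism import PEDemarcation
from synbiogeo.ordination import (
    DegenerateDataError,
    cca_fit,
    constrained_variability,
    density_frame,
    pe_tightness,
    stepwise_select,
    weighted_density,
)

from _oracles import cca_eigenvalues_oracle


def _random_instance(rng, n=7, m=9, q=2):
    Y = rng.poisson(3, size=(n, m)).astype(float)
    Y[Y.sum(axis=1) == 0, 0] += 1
    zero_cols = Y.sum(axis=0) == 0
    Y[:, zero_cols] += rng.integers(1, 3, size=(n, int(zero_cols.sum())))
    Z = rng.normal(size=(n, q)) * rng.uniform(0.5, 10, q) + rng.uniform(-3, 3, q)
    counts = pd.DataFrame(Y.T, index=[f"v{i}" for i in range(m)],
                          columns=[f"s{i}" for i in range(n)])
    env = pd.DataFrame(Z, index=counts.columns, columns=[f"p{i}" for i in range(q)])
    return counts, env


class TestCcaFit:
    def test_eigenvalues_match_dense_generalized_eigen_oracle(self):
        rng = np.random.default_rng(17)
        counts, env = _random_instance(rng, n=6, m=5, q=2)
        model = cca_fit(counts, env)
        oracle = cca_eigenvalues_oracle(counts.T.to_numpy(), env.to_numpy())
        assert len(model.eigenvalues) == len(oracle)
        np.testing.assert_allclose(model.eigenvalues, oracle, atol=1e-8)

    def test_saturated_sample_contrasts_recover_full_inertia(self):
        """With a full set of sample indicator contrasts the constrained
        space spans everything and CCA degenerates to CA."""
        rng = np.random.default_rng(23)
        counts, _ = _random_instance(rng, n=6, m=8)
        env = pd.DataFrame(np.eye(6)[:, :5], index=counts.columns,
                           columns=[f"d{i}" for i in range(5)])
        model = cca_fit(counts, env)
        assert model.constrained_inertia == pytest.approx(model.total_inertia, rel=1e-10)

    def test_proportional_sample_profiles_are_degenerate(self):
        counts = pd.DataFrame(
            {"s1": [2, 4, 6], "s2": [1, 2, 3], "s3": [10, 20, 30]},
            index=["v1", "v2", "v3"], dtype=float)
        env = pd.DataFrame({"p": [0.0, 1.0, 2.0]}, index=counts.columns)
        with pytest.raises(DegenerateDataError):
            cca_fit(counts, env)

    def test_constant_env_column_is_an_error_naming_it(self):
        rng = np.random.default_rng(29)
        counts, env = _random_instance(rng)
        env["flatline"] = 3.14
        with pytest.raises(ValueError, match="flatline"):
            cca_fit(counts, env)

    def test_all_zero_rows_and_columns_dropped_with_warning(self):
        rng = np.random.default_rng(31)
        counts, env = _random_instance(rng)
        counts.loc["vdead"] = 0
        with pytest.warns(UserWarning, match="vdead"):
            model = cca_fit(counts, env)
        assert "vdead" not in model.variant_scores.index

    def test_invariant_to_count_rescaling_and_env_affine_maps(self):
        rng = np.random.default_rng(37)
        counts, env = _random_instance(rng)
        base = cca_fit(counts, env)
        scaled = cca_fit(counts * 7.5, env * 10.0 - 3.0)
        np.testing.assert_allclose(base.eigenvalues, scaled.eigenvalues, atol=1e-10)
        np.testing.assert_allclose(base.total_inertia, scaled.total_inertia, atol=1e-10)

    def test_constrained_plus_residual_eigenvalues_equal_total(self):
        rng = np.random.default_rng(41)
        for _ in range(5):
            counts, env = _random_instance(rng)
            model = cca_fit(counts, env)
            assert model.constrained_inertia + model.residual_eigenvalues.sum() == \
                pytest.approx(model.total_inertia, abs=1e-8)

    def test_eigenvalues_nonincreasing_and_bounded(self):
        rng = np.random.default_rng(43)
        counts, env = _random_instance(rng, q=3)
        model = cca_fit(counts, env)
        lam = model.eigenvalues
        assert (lam >= 0).all()
        assert (np.diff(lam) <= 1e-12).all()
        assert model.constrained_inertia <= model.total_inertia + 1e-12
        assert len(lam) <= min(3, counts.shape[1] - 1, counts.shape[0] - 1)

    def test_matches_vegan_reference_implementation(self, tmp_path):
        """Independent cross-check against the standard R implementation."""
        rng = np.random.default_rng(47)
        counts, env = _random_instance(rng, n=6, m=5, q=2)
        model = cca_fit(counts, env)
        counts.T.to_csv(tmp_path / "y.tsv", sep="\t")
        env.to_csv(tmp_path / "z.tsv", sep="\t")
        script = textwrap.dedent("""
            suppressMessages(library(vegan))
            y <- read.table("y.tsv", header=TRUE, row.names=1, sep="\\t")
            z <- read.table("z.tsv", header=TRUE, row.names=1, sep="\\t")
            m <- cca(y ~ ., data=z)
            cat(m$tot.chi, m$CCA$eig, sep="\\n")
        """)
        out = subprocess.run(
            ["Rscript", "-e", script], cwd=tmp_path,
            capture_output=True, text=True, check=True,
        )
        values = [float(x) for x in out.stdout.split()]
        assert values[0] == pytest.approx(model.total_inertia, abs=1e-6)
        np.testing.assert_allclose(model.eigenvalues, values[1:], atol=1e-6)


class TestConstrainedVariability:
    def test_perfect_single_predictor_on_two_profile_data_explains_100pct(self):
        # two distinct sample profiles perfectly separated by the parameter
        counts = pd.DataFrame(
            {"s1": [10, 0, 5], "s2": [20, 0, 10], "s3": [0, 8, 4], "s4": [0, 4, 2]},
            index=["v1", "v2", "v3"], dtype=float)
        env = pd.DataFrame({"g": [0.0, 0.0, 1.0, 1.0], "noise": [0.3, -1, 0.5, 2.0]},
                           index=counts.columns)
        assert constrained_variability(counts, env, "g") == pytest.approx(100.0, abs=1e-8)

    def test_scale_invariance_of_a_duplicated_parameter(self):
        rng = np.random.default_rng(53)
        counts = pd.DataFrame(rng.poisson(4, size=(6, 8)) + 1.0,
                              index=[f"v{i}" for i in range(6)],
                              columns=[f"s{i}" for i in range(8)])
        env = pd.DataFrame({"p": rng.normal(size=8)}, index=counts.columns)
        env["p10"] = env["p"] * 10.0
        a = constrained_variability(counts, env, "p")
        b = constrained_variability(counts, env, "p10")
        assert a == pytest.approx(b, abs=1e-10)

    def test_unknown_parameter_is_an_error(self):
        rng = np.random.default_rng(59)
        counts, env = _random_instance(rng)
        with pytest.raises(KeyError):
            constrained_variability(counts, env, "nope")


class TestStepwiseSelect:
    def test_alpha_one_selects_until_no_inertia_remains(self):
        rng = np.random.default_rng(61)
        counts, env = _random_instance(rng, n=8, m=10, q=3)
        out = stepwise_select(counts, env, alpha=1.0, n_perm=99, seed=0)
        assert (out["added_inertia"] > 0).all()
        full = cca_fit(counts, env)
        assert out["added_inertia"].sum() == pytest.approx(full.constrained_inertia, abs=1e-8)

    def test_duplicated_column_of_selected_parameter_never_enters(self):
        rng = np.random.default_rng(67)
        counts, env = _random_instance(rng, n=8, m=10, q=2)
        env["p0_copy"] = env["p0"] * 2.0 + 1.0
        out = stepwise_select(counts, env, alpha=1.0, n_perm=99, seed=0)
        assert not (("p0" in set(out["parameter"])) and ("p0_copy" in set(out["parameter"])))

    def test_planted_driver_is_selected_first(self, driver_sim, tmp_path):
        """The analyte carrying the only niche signal must enter the model
        first, and its marginal constrained variability must beat every
        noise analyte's."""
        from synbiogeo.hfs import dereplicate, filter_hfs, read_fasta_reads, trim_and_clean
        _config, paths = driver_sim
        samples = pd.read_csv(paths["samples"], sep="\t").set_index("sample")
        springs = pd.read_csv(paths["springs"], sep="\t").set_index("spring")
        reads = read_fasta_reads(paths["reads"])
        cleaned, _ = trim_and_clean(reads)
        table = filter_hfs(dereplicate(cleaned, samples=list(samples.index)), 10)
        env_cols = [c for c in springs.columns if c not in ("basin",)]
        env = springs.loc[samples.loc[list(table.counts.columns), "spring"], env_cols]
        env.index = list(table.counts.columns)
        out = stepwise_select(table.counts, env, alpha=0.05, n_perm=199, seed=1)
        assert len(out) >= 1
        assert out.iloc[0]["parameter"] == "pH"
        assert out.iloc[0]["p_value"] <= 0.05
        analytes = [c for c in env_cols if c not in ("latitude", "longitude")]
        marginals = {p: constrained_variability(table.counts, env, p) for p in analytes}
        assert max(marginals, key=marginals.get) == "pH"


class TestPeTightness:
    def _model(self, seed=71, n=10, m=20):
        rng = np.random.default_rng(seed)
        counts, env = _random_instance(rng, n=n, m=m, q=2)
        return cca_fit(counts, env)

    def test_whole_variant_set_has_p_one(self):
        model = self._model()
        dem = PEDemarcation(members={"all": list(model.variant_scores.index)})
        out = pe_tightness(model, dem, n_draws=199, seed=3)
        assert out.loc[0, "p_value"] == 1.0

    def test_singleton_pe_gets_no_p_value(self):
        model = self._model()
        dem = PEDemarcation(members={"solo": [model.variant_scores.index[0]]})
        out = pe_tightness(model, dem, n_draws=199, seed=3)
        assert out.loc[0, "p_value"] is None or pd.isna(out.loc[0, "p_value"])

    def test_member_missing_from_model_is_an_error(self):
        model = self._model()
        dem = PEDemarcation(members={"ghost": ["not_a_variant", model.variant_scores.index[0]]})
        with pytest.raises(KeyError, match="ghost"):
            pe_tightness(model, dem, n_draws=199, seed=3)

    def test_deterministic_under_fixed_seed(self):
        model = self._model()
        ids = list(model.variant_scores.index)
        dem = PEDemarcation(members={"p1": ids[:4], "p2": ids[4:9]})
        a = pe_tightness(model, dem, n_draws=199, seed=5)
        b = pe_tightness(model, dem, n_draws=199, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestWeightedDensity:
    def _model_and_dem(self):
        rng = np.random.default_rng(73)
        counts, env = _random_instance(rng, n=10, m=15, q=2)
        model = cca_fit(counts, env)
        ids = list(model.variant_scores.index)
        dem = PEDemarcation(members={"p1": ids[:5], "p2": ids[5:9], "solo": [ids[9]]})
        return model, dem

    def test_densities_integrate_to_one(self):
        model, dem = self._model_and_dem()
        curves = weighted_density(model, dem, model.parameters[0])
        for c in curves:
            assert np.trapezoid(c.density, c.grid) == pytest.approx(1.0, abs=1e-6)
            assert (c.density >= 0).all()

    def test_single_variant_pe_is_a_gaussian_bump_at_its_projection(self):
        model, dem = self._model_and_dem()
        param = model.parameters[0]
        curves = {c.pe_id: c for c in weighted_density(model, dem, param)}
        solo = dem.members["solo"][0]
        direction = model.biplot_scores.loc[param].to_numpy()[:2]
        unit = direction / np.linalg.norm(direction)
        expected = float(model.variant_scores.loc[solo].to_numpy()[:2] @ unit)
        mode = curves["solo"].grid[np.argmax(curves["solo"].density)]
        assert mode == pytest.approx(expected, abs=curves["solo"].bandwidth / 4)

    def test_zero_weight_pe_is_an_error(self):
        model, dem = self._model_and_dem()
        weights = model.variant_totals.copy()
        weights[dem.members["p1"]] = 0.0
        with pytest.raises(ValueError, match="p1"):
            weighted_density(model, dem, model.parameters[0], weights=weights)

    def test_density_frame_is_tidy(self):
        model, dem = self._model_and_dem()
        curves = weighted_density(model, dem, model.parameters[0], grid_size=64)
        df = density_frame(curves)
        assert set(df["pe_id"]) == set(dem.members)
        assert len(df) == 64 * len(dem.members)

    def test_ph_specialist_modes_are_ordered_with_planted_optima(self, driver_sim):
        """Two ecotypes planted at opposite ends of the pH niche axis must
        produce density modes in the same order along the pH arrow."""
        from synbiogeo.hfs import dereplicate, filter_hfs, read_fasta_reads, trim_and_clean
        from synbiogeo.simulate import truth_demarcation
        import pandas as pd
        _config, paths = driver_sim
        samples = pd.read_csv(paths["samples"], sep="\t").set_index("sample")
        springs = pd.read_csv(paths["springs"], sep="\t").set_index("spring")
        eco = pd.read_csv(paths["truth_ecotypes"], sep="\t").set_index("ecotype_id")
        reads = read_fasta_reads(paths["reads"])
        cleaned, _ = trim_and_clean(reads)
        table = filter_hfs(dereplicate(cleaned, samples=list(samples.index)), 10)
        env = springs.loc[samples.loc[list(table.counts.columns), "spring"], ["pH"]]
        env.index = list(table.counts.columns)
        model = cca_fit(table.counts, env)
        tv = pd.read_csv(paths["truth_variants"], sep="\t")
        seq_to_eco = dict(zip(tv["sequence"], tv["ecotype_id"]))
        members: dict[str, list[str]] = {}
        for vid, seq in table.sequences.items():
            members.setdefault(seq_to_eco[seq], []).append(vid)
        detected = eco.loc[sorted(members)].sort_values("opt_pH")
        low, high = detected.index[0], detected.index[-1]
        dem = PEDemarcation(members={low: members[low], high: members[high]})
        curves = {c.pe_id: c for c in weighted_density(model, dem, "pH")}
        mode = {pe: c.grid[np.argmax(c.density)] for pe, c in curves.items()}
        assert mode[low] < mode[high]
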