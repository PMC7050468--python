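"""Constrained ordination (CCA) and its attendant permutation statistics.

Canonical correspondence analysis relates a variant-by-sample abundance
matrix to environmental predictors under a unimodal response model. The
implementation follows the classical eigen-analysis: the abundance matrix is
converted to chi-square-standardized residuals

    Q̄ = D_r^{-1/2} (P - r cᵀ) D_c^{-1/2},      P = Y / y₊₊,

with row (sample) masses r and column (variant) masses c; Q̄ is projected,
with row weights r, onto the standardized environmental columns; and the
fitted matrix is decomposed by SVD. Squared singular values are the
constrained eigenvalues; their sum is the constrained inertia; ‖Q̄‖² is the
total inertia (the matrix chi-square statistic over the grand total).

Scores default to the "species" scaling (scaling 2): variant scores are
weighted-average scores scaled by sqrt(eigenvalue), sample scores are
linear-combination scores with unit weighted variance, and parameter arrows
are weighted correlations of the standardized predictors with the sample
scores. Axis signs are fixed by making the largest-magnitude variant loading
positive on each axis.

On top of the fitted model: forward stepwise parameter selection with a
permutation pseudo-F test, a per-PE cluster-tightness permutation test in
the ordination plane, and an abundance-weighted kernel density of each PE
along one parameter's arrow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .endemism import PEDemarcation

_TOL = 1e-12


class DegenerateDataError(ValueError):
    """Raised when the abundance matrix carries no chi-square variation."""


@dataclass
class CCAModel:
    """A fitted constrained ordination.

    eigenvalues are per constrained axis, non-increasing;
    ``residual_eigenvalues`` are the unconstrained ones, so the two sets sum
    to ``total_inertia``.
    """

    eigenvalues: np.ndarray
    site_scores: pd.DataFrame      # sample x axis (linear-combination scores)
    variant_scores: pd.DataFrame   # variant x axis (scaling-2 species scores)
    biplot_scores: pd.DataFrame    # parameter x axis (weighted correlations)
    total_inertia: float
    constrained_inertia: float
    residual_eigenvalues: np.ndarray
    parameters: list[str]
    variant_totals: pd.Series      # reads per variant, for weighted densities
    scaling: str = "species"

    @property
    def axes(self) -> list[str]:
        return list(self.site_scores.columns)


def _prepare(counts: pd.DataFrame, env: pd.DataFrame):
    """Validate and align inputs; return (Y sites x species, Z sites x params)."""
    Y = counts.T.astype(float)  # rows = samples (sites), columns = variants
    if (Y.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    row_ok = Y.sum(axis=1) > 0
    col_ok = Y.sum(axis=0) > 0
    if not row_ok.all():
        warnings.warn(f"dropping all-zero sample(s): {list(Y.index[~row_ok])}")
        Y = Y.loc[row_ok]
    if not col_ok.all():
        warnings.warn(f"dropping all-zero variant(s): {list(Y.columns[~col_ok])}")
        Y = Y.loc[:, col_ok]
    if Y.size == 0 or Y.to_numpy().sum() <= 0:
        raise DegenerateDataError("no positive counts")
    missing = [s for s in Y.index if s not in env.index]
    if missing:
        raise KeyError(f"samples without environment rows: {missing}")
    Z = env.loc[Y.index].astype(float)
    if not np.isfinite(Z.to_numpy()).all():
        raise ValueError("environment matrix contains non-finite values")
    return Y, Z


def _chi_residuals(Y: pd.DataFrame):
    y = Y.to_numpy(dtype=float)
    grand = y.sum()
    P = y / grand
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    E = np.outer(r, c)
    Qbar = (P - E) / np.sqrt(E)
    total = float((Qbar**2).sum())
    return Qbar, r, c, total


def _standardize(Z: pd.DataFrame, r: np.ndarray) -> pd.DataFrame:
    """Weighted z-scoring of predictor columns (weights = row masses)."""
    out = {}
    for name in Z.columns:
        x = Z[name].to_numpy(dtype=float)
        mean = float(np.sum(r * x))
        sd = float(np.sqrt(np.sum(r * (x - mean) ** 2)))
        if sd < 1e-12 * max(1.0, abs(mean)):
            raise ValueError(f"constant environmental column: {name!r}")
        out[name] = (x - mean) / sd
    return pd.DataFrame(out, index=Z.index)


def cca_fit(counts: pd.DataFrame, env: pd.DataFrame) -> CCAModel:
    """Fit a CCA of a variant-by-sample count matrix on environment columns.

    Parameters
    ----------
    counts : pd.DataFrame
        Variant x sample non-negative abundance matrix.
    env : pd.DataFrame
        Sample x parameter matrix; every counts sample needs a row.
    """
    Y, Z = _prepare(counts, env)
    Qbar, r, c, total = _chi_residuals(Y)
    if total < _TOL:
        raise DegenerateDataError(
            "total inertia is zero (all sample profiles identical)"
        )
    Zstd = _standardize(Z, r)
    Zw = np.sqrt(r)[:, None] * Zstd.to_numpy()
    # weighted least-squares projection of Qbar onto the predictor space
    Qb, _ = np.linalg.qr(Zw)
    rank = int(np.linalg.matrix_rank(Zw, tol=1e-10))
    fitted = Qb @ (Qb.T @ Qbar)
    U, s, Vt = np.linalg.svd(fitted, full_matrices=False)
    max_axes = min(rank, Y.shape[0] - 1, Y.shape[1] - 1)
    lam = s**2
    keep = min(max_axes, int(np.sum(lam > max(total, 1.0) * 1e-12)))
    lam = lam[:keep]
    U, s, Vt = U[:, :keep], s[:keep], Vt[:keep]
    # axis sign: largest-magnitude variant loading positive
    v_raw = Vt.T / np.sqrt(c)[:, None]
    for k in range(keep):
        col = v_raw[:, k] * s[k]
        j = int(np.argmax(np.abs(col)))
        if col[j] < 0:
            U[:, k] *= -1
            v_raw[:, k] *= -1
    axes = [f"CCA{k + 1}" for k in range(keep)]
    site = U / np.sqrt(r)[:, None]
    variant = v_raw * s[None, :]
    biplot = Zw.T @ U  # weighted correlation of each predictor with site scores
    resid = Qbar - fitted
    s_resid = np.linalg.svd(resid, compute_uv=False)
    resid_lam = (s_resid**2)[(s_resid**2) > max(total, 1.0) * 1e-12]
    return CCAModel(
        eigenvalues=lam,
        site_scores=pd.DataFrame(site, index=Y.index, columns=axes),
        variant_scores=pd.DataFrame(variant, index=Y.columns, columns=axes),
        biplot_scores=pd.DataFrame(biplot, index=Zstd.columns, columns=axes),
        total_inertia=total,
        constrained_inertia=float(lam.sum()),
        residual_eigenvalues=resid_lam,
        parameters=list(Zstd.columns),
        variant_totals=Y.sum(axis=0),
    )


def constrained_variability(counts: pd.DataFrame, env: pd.DataFrame, parameter: str) -> float:
    """Percent of total inertia constrained by one parameter alone."""
    if parameter not in env.columns:
        raise KeyError(f"unknown parameter {parameter!r}")
    model = cca_fit(counts, env[[parameter]])
    return 100.0 * model.constrained_inertia / model.total_inertia


def stepwise_select(
    counts: pd.DataFrame,
    env: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Forward stepwise selection of environmental parameters for a CCA.

    At each step the candidate adding the most constrained inertia is tested
    by permuting the residuals of the current (reduced) model and comparing
    its pseudo-F against the permutation distribution of the *maximum*
    pseudo-F over all remaining candidates; it enters if p <= alpha. Using
    the max-F null accounts for picking the best of many candidates, keeping
    the probability of any selection on pure noise near alpha. With
    alpha >= 1 the test is skipped and selection runs until the added
    inertia is numerically zero.

    Returns a table with one row per selected parameter: step, parameter,
    added_inertia, added_pct, pseudo_F, p_value.
    """
    if not 0.0 < alpha:
        raise ValueError("alpha must be positive")
    if alpha < 1.0 and n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    Y, Z = _prepare(counts, env)
    Qbar, r, c, total = _chi_residuals(Y)
    if total < _TOL:
        raise DegenerateDataError("total inertia is zero")
    Zstd = _standardize(Z, r)
    Zw = np.sqrt(r)[:, None] * Zstd.to_numpy()
    n = Y.shape[0]
    rng = np.random.default_rng(seed)
    names = list(Zstd.columns)
    selected: list[int] = []
    basis = np.empty((n, 0))  # orthonormal basis of the selected predictor space
    rows = []
    while len(selected) < len(names):
        remaining = [j for j in range(len(names)) if j not in selected]
        # orthonormalize each candidate against the current basis
        qcols, cand = [], []
        for j in remaining:
            z = Zw[:, j].copy()
            if basis.shape[1]:
                z = z - basis @ (basis.T @ z)
            nrm = np.linalg.norm(z)
            if nrm < 1e-10:
                continue  # collinear with already-selected parameters
            qcols.append(z / nrm)
            cand.append(j)
        if not cand:
            break
        Qc = np.column_stack(qcols)
        proj = Qc.T @ Qbar                      # k x m
        added = (proj**2).sum(axis=1)
        best = int(np.argmax(added))
        if added[best] <= max(total, 1.0) * 1e-12:
            break
        sel_inertia = float(((basis.T @ Qbar) ** 2).sum()) if basis.shape[1] else 0.0
        df_resid = n - 2 - len(selected)
        if df_resid <= 0:
            break

        def pseudo_f(add: np.ndarray, model0: float, total_star: float) -> np.ndarray:
            resid = total_star - model0 - add
            return add / np.maximum(resid, _TOL) * df_resid

        f_obs = pseudo_f(added, sel_inertia, total)[best]
        if alpha >= 1.0:
            p = np.nan
        else:
            fitted0 = basis @ (basis.T @ Qbar) if basis.shape[1] else np.zeros_like(Qbar)
            resid0 = Qbar - fitted0
            hits = 0
            for _ in range(n_perm):
                Qstar = fitted0 + resid0[rng.permutation(n)]
                model0_star = (
                    float(((basis.T @ Qstar) ** 2).sum()) if basis.shape[1] else 0.0
                )
                total_star = float((Qstar**2).sum())
                add_star = ((Qc.T @ Qstar) ** 2).sum(axis=1)
                f_star = pseudo_f(add_star, model0_star, total_star)
                if f_star.max() >= f_obs:
                    hits += 1
            p = (1 + hits) / (1 + n_perm)
            if p > alpha:
                break
        j = cand[best]
        rows.append(
            {
                "step": len(selected) + 1,
                "parameter": names[j],
                "added_inertia": float(added[best]),
                "added_pct": 100.0 * float(added[best]) / total,
                "pseudo_F": float(f_obs),
                "p_value": p,
            }
        )
        selected.append(j)
        basis = np.column_stack([basis, Qc[:, best]])
    return pd.DataFrame(
        rows, columns=["step", "parameter", "added_inertia", "added_pct", "pseudo_F", "p_value"]
    )


@dataclass(frozen=True)
class TightnessTest:
    """Cluster-tightness permutation result for one PE."""

    pe_id: str
    n_members: int
    observed_tightness: float | None
    n_draws: int
    p_value: float | None
    seed: int | None


def pe_tightness(
    model: CCAModel,
    dem: PEDemarcation,
    n_draws: int = 999,
    seed: int | None = None,
    n_axes: int = 2,
) -> pd.DataFrame:
    """Probability that a PE's variants cluster as tightly by chance.

    Tightness is the mean pairwise Euclidean distance among a PE's variant
    scores on the first ``n_axes`` constrained axes; the null draws
    ``n_draws`` uniform same-size subsets of all scored variants without
    replacement. p = (1 + #{null <= observed}) / (1 + n_draws). Singleton
    PEs have no defined tightness and get no p-value.
    """
    if n_draws < 99:
        raise ValueError("n_draws must be >= 99")
    scores = model.variant_scores.iloc[:, : min(n_axes, model.variant_scores.shape[1])]
    pool = scores.to_numpy()
    index = {v: i for i, v in enumerate(scores.index)}
    rng = np.random.default_rng(seed)
    rows = []
    for pe, members in dem.members.items():
        missing = [v for v in members if v not in index]
        if missing:
            raise KeyError(f"PE {pe!r} members absent from the model: {missing}")
        k = len(members)
        if k < 2:
            rows.append(TightnessTest(pe, k, None, n_draws, None, seed))
            continue
        pts = pool[[index[v] for v in members]]
        observed = float(pdist(pts).mean())
        hits = 0
        tie_tol = 1e-9 * max(1.0, observed)  # summation-order float noise is a tie
        for _ in range(n_draws):
            sub = pool[rng.choice(len(pool), size=k, replace=False)]
            if float(pdist(sub).mean()) <= observed + tie_tol:
                hits += 1
        p = (1 + hits) / (1 + n_draws)
        rows.append(TightnessTest(pe, k, observed, n_draws, p, seed))
    return pd.DataFrame([t.__dict__ for t in rows])


@dataclass
class DensityCurve:
    """Abundance-weighted density of one PE along a parameter's arrow."""

    pe_id: str
    parameter: str
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float


def weighted_density(
    model: CCAModel,
    dem: PEDemarcation,
    parameter: str,
    weights: pd.Series | None = None,
    bandwidth: float | None = None,
    grid_size: int = 512,
    n_axes: int = 2,
) -> list[DensityCurve]:
    """Gaussian KDE of each PE's variants projected onto a parameter's arrow.

    Variant scores on the first ``n_axes`` constrained axes are projected
    onto the unit vector of the parameter's biplot arrow; each variant is
    weighted by its total read count (or ``weights``). One bandwidth —
    Silverman's rule on the pooled projections with the Kish effective
    sample size — and one grid are shared by all PEs so curves are
    comparable; each curve is normalized to integrate to 1 on the grid.
    """
    if parameter not in model.biplot_scores.index:
        raise KeyError(f"parameter {parameter!r} has no biplot vector in the model")
    n_axes = min(n_axes, model.variant_scores.shape[1])
    direction = model.biplot_scores.loc[parameter].to_numpy()[:n_axes]
    nrm = np.linalg.norm(direction)
    if nrm < _TOL:
        raise ValueError(f"parameter {parameter!r} has a zero-length arrow")
    unit = direction / nrm
    proj = model.variant_scores.iloc[:, :n_axes].to_numpy() @ unit
    proj = pd.Series(proj, index=model.variant_scores.index)
    w = model.variant_totals if weights is None else weights
    w = w.reindex(proj.index).fillna(0.0).astype(float)
    if bandwidth is None:
        ww = w / w.sum()
        mu = float(np.sum(ww * proj))
        sigma = float(np.sqrt(np.sum(ww * (proj - mu) ** 2)))
        neff = float(w.sum() ** 2 / np.sum(w**2))
        bandwidth = sigma * (4.0 / (3.0 * neff)) ** 0.2
        if bandwidth < _TOL:
            bandwidth = max(1e-3, 1e-3 * (abs(mu) + 1.0))
    lo = float(proj.min()) - 3.0 * bandwidth
    hi = float(proj.max()) + 3.0 * bandwidth
    grid = np.linspace(lo, hi, grid_size)
    curves = []
    for pe, members in dem.members.items():
        pw = w.reindex(members).fillna(0.0).to_numpy()
        if pw.sum() <= 0:
            raise ValueError(f"PE {pe!r} has zero total weight")
        centers = proj.reindex(members).to_numpy()
        z = (grid[:, None] - centers[None, :]) / bandwidth
        dens = (np.exp(-0.5 * z**2) @ pw) / (pw.sum() * bandwidth * np.sqrt(2 * np.pi))
        area = np.trapezoid(dens, grid)
        curves.append(DensityCurve(pe, parameter, grid, dens / area, bandwidth))
    return curves


def density_frame(curves: Iterable[DensityCurve]) -> pd.DataFrame:
    """Tidy long-format table of density curves for writing to TSV."""
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "pe_id": c.pe_id,
                    "parameter": c.parameter,
                    "position": c.grid,
                    "density": c.density,
                    "bandwidth": c.bandwidth,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
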