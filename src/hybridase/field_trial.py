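"""Replicated field-trial analysis: outliers, trend covariates, contrasts.

Implements the agronomic arm of a hybrid-vs-parents study run as a
randomized complete block design (RCBD) at one or more locations:

1. flag outliers by externally studentized residuals under a saturated
   trend model (genotype + block + 4th-degree row/column polynomials);
2. backward-eliminate the polynomial trend covariates, highest order
   first, keeping lower orders whenever a higher order on the same axis
   is significant (the hierarchy rule);
3. least-squares fit of ``trait ~ genotype + block + retained covariates``
   giving adjusted genotype means and their covariance;
4. single-degree-of-freedom linear contrasts — in particular the
   mid-parent heterosis contrast F1 − (P1 + P2)/2 — with optional
   one-sided p-values;
5. an inverse-variance pooled analysis across locations with
   Satterthwaite degrees of freedom.

Block is fitted as a fixed effect; for the balanced designs this module
targets, genotype contrast estimates coincide with the mixed-model
(random-block) estimates, and the pooled stage's per-location weighting
provides the separate residual variance per location.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModelSpec",
    "ContrastResult",
    "LocationFit",
    "mid_parent_difference",
    "external_studentized_residuals",
    "flag_outliers",
    "select_trend_covariates",
    "fit_location_model",
    "contrast",
    "pooled_analysis",
    "heterosis_report",
    "HeterosisReport",
    "MID_PARENT_F1",
    "MID_PARENT_F2",
]


class DiagnosticsError(ValueError):
    """The data cannot support the requested diagnostic (e.g. too few df)."""


class MissingLevelError(ValueError):
    """A genotype level required by the analysis has no plots."""


@dataclass
class ModelSpec:
    """Analysis settings for one location model."""

    max_poly_degree: int = 4
    alpha_covariate: float = 0.05
    outlier_threshold: float = 3.0
    include_block: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha_covariate < 1:
            raise ValueError("alpha_covariate must lie in (0, 1)")
        if self.outlier_threshold <= 0:
            raise ValueError("outlier_threshold must be positive")


@dataclass
class ContrastResult:
    """A single-degree-of-freedom linear contrast of genotype means."""

    label: str
    estimate: float
    std_error: float
    p_value: float
    one_sided: bool
    df: float
    note: str = ""


@dataclass
class LocationFit:
    """Adjusted genotype means from one location's least-squares fit."""

    location: str
    trait: str
    means: pd.Series
    cov: pd.DataFrame
    resid_var: float
    df_resid: float
    n_obs: int
    covariates: tuple[str, ...] = ()


def mid_parent_difference(f1_mean: float, p1_mean: float, p2_mean: float) -> float:
    """F1 mean minus the mid-parent value (the parents' average)."""
    for v in (f1_mean, p1_mean, p2_mean):
        if not np.isfinite(v):
            raise ValueError("means must be finite")
    return f1_mean - (p1_mean + p2_mean) / 2.0


#: Mid-parent contrast coefficients for the hybrid and selfed progeny.
MID_PARENT_F1: dict[str, float] = {"F1": 1.0, "parent1": -0.5, "parent2": -0.5}
MID_PARENT_F2: dict[str, float] = {"F2": 1.0, "parent1": -0.5, "parent2": -0.5}


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

def _covariate_column(plots: pd.DataFrame, name: str) -> np.ndarray:
    """Centered polynomial covariate, e.g. ``row^3`` -> (row - mean)**3."""
    axis, deg = name.split("^")
    x = plots[axis].to_numpy(dtype=float)
    return (x - x.mean()) ** int(deg)


def _design(
    plots: pd.DataFrame,
    covariates: Sequence[str],
    include_block: bool,
) -> tuple[pd.DataFrame, list[str]]:
    """Build the model matrix.

    Genotype uses cell-means coding (one column per level, no intercept);
    block is sum-to-zero coded and covariate columns are mean-centered, so
    each genotype coefficient is the adjusted mean at the average block
    and covariate value.
    """
    genos = sorted(plots["genotype"].unique())
    cols: dict[str, np.ndarray] = {}
    for g in genos:
        cols[f"genotype[{g}]"] = (plots["genotype"] == g).to_numpy(dtype=float)
    if include_block:
        blocks = sorted(plots["block"].unique())
        if len(blocks) > 1:
            last = blocks[-1]
            for b in blocks[:-1]:
                col = (plots["block"] == b).to_numpy(dtype=float)
                col -= (plots["block"] == last).to_numpy(dtype=float)
                cols[f"block[{b}]"] = col
    for name in covariates:
        c = _covariate_column(plots, name)
        cols[name] = c - c.mean()
    X = pd.DataFrame(cols, index=plots.index)
    return X, [f"genotype[{g}]" for g in genos]


def _ols(X: pd.DataFrame, y: np.ndarray):
    """Least squares with named coefficients; returns (beta, cov_unit, rss, df)."""
    Xv = X.to_numpy(dtype=float)
    beta, _, rank, _ = np.linalg.lstsq(Xv, y, rcond=None)
    resid = y - Xv @ beta
    rss = float(resid @ resid)
    if rss <= 1e-10 * max(1.0, float(y @ y)):  # exact (noise-free) fit
        rss = 0.0
    df = len(y) - rank
    cov_unit = np.linalg.pinv(Xv.T @ Xv)
    return pd.Series(beta, index=X.columns), cov_unit, rss, df


def _full_poly_covariates(plots: pd.DataFrame, max_degree: int) -> list[str]:
    covs = []
    for axis in ("row", "column"):
        if plots[axis].nunique() > 1:
            covs.extend(f"{axis}^{d}" for d in range(1, max_degree + 1))
    return covs


# ---------------------------------------------------------------------------
# Outliers
# ---------------------------------------------------------------------------

def external_studentized_residuals(
    plots: pd.DataFrame, spec: ModelSpec, trait: str
) -> pd.Series:
    """Externally studentized residuals under the saturated trend model.

    The model has genotype, block and the full ``max_poly_degree``
    row/column polynomials; each residual is scaled by the error variance
    estimated with that observation left out, so it follows a t
    distribution under the model.
    """
    import statsmodels.api as sm
    from statsmodels.stats.outliers_influence import OLSInfluence

    data = plots.dropna(subset=[trait])
    covs = _full_poly_covariates(data, spec.max_poly_degree)
    X, _ = _design(data, covs, spec.include_block)
    y = data[trait].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X.to_numpy(dtype=float))
    if len(y) - rank < 2:
        raise DiagnosticsError(
            f"only {len(y) - rank} residual df under the outlier-screen model; need >= 2"
        )
    res = sm.OLS(y, X.to_numpy(dtype=float)).fit()
    if res.ssr <= 1e-10 * max(1.0, float(y @ y)):  # exact fit: no outliers
        return pd.Series(0.0, index=data.index, name="studentized_residual")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t_ext = OLSInfluence(res).resid_studentized_external
    return pd.Series(t_ext, index=data.index, name="studentized_residual")


def flag_outliers(
    plots: pd.DataFrame, spec: ModelSpec, trait: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-pass outlier screen via externally studentized residuals.

    Drops plots whose externally studentized residual under the saturated
    trend model exceeds ``spec.outlier_threshold`` in magnitude (one
    pass, no iteration). Returns ``(retained, dropped)``.
    """
    data = plots.dropna(subset=[trait])
    t_ext = external_studentized_residuals(data, spec, trait)
    bad = t_ext.abs() > spec.outlier_threshold
    return data.loc[~bad], data.loc[bad]


# ---------------------------------------------------------------------------
# Trend-covariate selection
# ---------------------------------------------------------------------------

def _drop_term_pvalue(
    plots: pd.DataFrame, trait: str, covariates: list[str], term: str, include_block: bool
) -> float:
    """Partial F-test p-value for removing ``term`` from the current model.

    Because only the highest-order term on an axis is ever tested, this
    equals its sequential (Type-1) test with covariates ordered by degree.
    """
    y = plots[trait].to_numpy(dtype=float)
    X1, _ = _design(plots, covariates, include_block)
    reduced = [c for c in covariates if c != term]
    X0, _ = _design(plots, reduced, include_block)
    _, _, rss1, df1 = _ols(X1, y)
    _, _, rss0, _ = _ols(X0, y)
    if df1 <= 0:
        raise DiagnosticsError("no residual df left to test covariates")
    if rss0 <= rss1:  # term numerically redundant
        return 1.0
    f = (rss0 - rss1) / (rss1 / df1)
    return float(stats.f.sf(f, 1, df1))


def select_trend_covariates(
    plots: pd.DataFrame, spec: ModelSpec, trait: str
) -> list[str]:
    """Backward elimination of row/column polynomial trend covariates.

    Starting from the full degree-``max_poly_degree`` polynomials on both
    axes, repeatedly tests the highest remaining order on each axis at
    ``alpha_covariate`` and removes non-significant terms, highest order
    first (ties between axes at equal degree: the larger p goes first).
    Once an axis's highest remaining order is significant the axis is
    frozen — every lower order on it is retained (hierarchy rule).
    Constant row or column coordinates are excluded a priori.
    """
    data = plots.dropna(subset=[trait])
    retained = _full_poly_covariates(data, spec.max_poly_degree)
    frozen: set[str] = set()
    while True:
        tops: dict[str, str] = {}
        for axis in ("row", "column"):
            if axis in frozen:
                continue
            degs = [int(c.split("^")[1]) for c in retained if c.startswith(f"{axis}^")]
            if degs:
                tops[axis] = f"{axis}^{max(degs)}"
        if not tops:
            break
        pvals = {
            term: _drop_term_pvalue(data, trait, retained, term, spec.include_block)
            for term in tops.values()
        }
        removable = []
        for axis, term in tops.items():
            if pvals[term] < spec.alpha_covariate:
                frozen.add(axis)  # significant top order: keep whole axis
            else:
                removable.append(term)
        if not removable:
            break
        drop = max(removable, key=lambda t: (int(t.split("^")[1]), pvals[t]))
        retained.remove(drop)
    return sorted(retained)


# ---------------------------------------------------------------------------
# Model fit and contrasts
# ---------------------------------------------------------------------------

def fit_location_model(
    plots: pd.DataFrame,
    spec: ModelSpec,
    trait: str,
    covariates: Sequence[str] = (),
    location: str = "",
) -> LocationFit:
    """Least-squares fit returning adjusted genotype means and covariance.

    Assumes outliers are already removed and covariates already selected.
    With zero residual df the means are still returned but their
    covariance (and any p-value downstream) is NaN.
    """
    data = plots.dropna(subset=[trait])
    counts = data["genotype"].value_counts()
    empty = [g for g, n in counts.items() if n == 0]
    if data.empty or empty:
        raise MissingLevelError(f"genotypes without plots: {empty or 'all'}")
    X, mean_cols = _design(data, covariates, spec.include_block)
    y = data[trait].to_numpy(dtype=float)
    beta, cov_unit, rss, df = _ols(X, y)
    resid_var = rss / df if df > 0 else float("nan")
    cov = pd.DataFrame(cov_unit * resid_var, index=X.columns, columns=X.columns)
    genos = [c[len("genotype[") : -1] for c in mean_cols]
    means = pd.Series(beta[mean_cols].to_numpy(), index=genos, name=trait)
    return LocationFit(
        location=location or str(data["location"].iloc[0]) if "location" in data else location,
        trait=trait,
        means=means,
        cov=cov.loc[mean_cols, mean_cols].set_axis(genos).set_axis(genos, axis=1),
        resid_var=resid_var,
        df_resid=float(df),
        n_obs=len(data),
        covariates=tuple(covariates),
    )


def contrast(
    fit: LocationFit,
    coefficients: Mapping[str, float],
    one_sided: bool = False,
    alternative: str = "greater",
    label: str = "",
) -> ContrastResult:
    """Single-df linear contrast of adjusted genotype means.

    ``coefficients`` maps genotype -> weight and must sum to zero. With
    ``one_sided=True`` the p-value is half the two-sided p when the
    estimate has the hypothesized sign (``alternative``), else one minus
    that half.
    """
    total = sum(coefficients.values())
    if abs(total) > 1e-8:
        raise ValueError(f"contrast coefficients sum to {total}, not 0")
    missing = [g for g in coefficients if g not in fit.means.index]
    if missing:
        raise MissingLevelError(f"contrast references absent genotypes: {missing}")
    c = pd.Series(0.0, index=fit.means.index)
    for g, w in coefficients.items():
        c[g] = w
    est = float(c @ fit.means)
    var = float(c @ fit.cov @ c)
    se = float(np.sqrt(var)) if var >= 0 else float("nan")
    zero_est = abs(est) <= 1e-8 * max(1.0, float(fit.means.abs().max()))
    if not np.isfinite(se) or fit.df_resid <= 0:
        p2 = float("nan")
    elif se == 0:  # noise-free fit: the estimate is exact
        p2 = 1.0 if zero_est else 0.0
    else:
        t = est / se
        p2 = float(2 * stats.t.sf(abs(t), fit.df_resid))
    if one_sided and np.isfinite(p2):
        sign_ok = est >= 0 if alternative == "greater" else est <= 0
        p = p2 / 2 if sign_ok else 1 - p2 / 2
    else:
        p = p2
    return ContrastResult(
        label=label or "+".join(f"{w:+g}*{g}" for g, w in coefficients.items()),
        estimate=est,
        std_error=se,
        p_value=p,
        one_sided=one_sided,
        df=fit.df_resid,
    )


def pooled_analysis(results: Sequence[ContrastResult]) -> ContrastResult:
    """Inverse-variance pooled contrast across locations.

    Weights each location by 1/SE²; the pooled SE is 1/sqrt(sum of
    weights) and the reference t distribution uses Satterthwaite degrees
    of freedom. A single estimable location is passed through with a
    warning note.
    """
    usable = [r for r in results if np.isfinite(r.std_error) and r.std_error > 0]
    if not usable:
        raise ValueError("no location with a finite contrast standard error")
    if len(usable) == 1:
        return replace(usable[0], note="single-location result (pooling degenerate)")
    w = np.array([1.0 / r.std_error**2 for r in usable])
    e = np.array([r.estimate for r in usable])
    dfs = np.array([r.df for r in usable])
    est = float((w * e).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    df_satt = float(w.sum() ** 2 / ((w**2 / dfs).sum()))
    t = est / se
    p2 = float(2 * stats.t.sf(abs(t), df_satt))
    one_sided = all(r.one_sided for r in usable)
    if one_sided:
        sign_ok = est >= 0
        p = p2 / 2 if sign_ok else 1 - p2 / 2
    else:
        p = p2
    return ContrastResult(
        label=usable[0].label,
        estimate=est,
        std_error=se,
        p_value=p,
        one_sided=one_sided,
        df=df_satt,
    )


# ---------------------------------------------------------------------------
# Heterosis report
# ---------------------------------------------------------------------------

@dataclass
class HeterosisReport:
    """Per-trait, per-location and pooled mid-parent contrast table."""

    table: pd.DataFrame
    inbreeding_depression: dict[str, bool] = field(default_factory=dict)
    dropped_outliers: pd.DataFrame | None = None
    gaps: list[str] = field(default_factory=list)

    def formatted(self) -> str:
        """Contrast-table text: estimate with bracketed p per cell."""
        tab = self.table.copy()
        tab["cell"] = [
            f"{e:.4g} [{p:.2f}]" if np.isfinite(p) else f"{e:.4g} [--]"
            for e, p in zip(tab["estimate"], tab["p_value"])
        ]
        wide = tab.pivot_table(
            index=["location", "contrast"], columns="trait", values="cell", aggfunc="first"
        )
        return wide.to_string()


def _class_genotype(plots: pd.DataFrame, entry_class: str) -> str | None:
    g = plots.loc[plots["entry_class"] == entry_class, "genotype"].unique()
    return str(g[0]) if len(g) == 1 else (str(g[0]) if len(g) else None)


def heterosis_report(
    plots: pd.DataFrame,
    traits: Sequence[str] | None = None,
    spec: ModelSpec | None = None,
    one_sided_traits: Sequence[str] = ("yield", "harvestable_protein"),
    screen_outliers: bool = True,
    select_covariates: bool = True,
) -> HeterosisReport:
    """Full agronomic pipeline: F1/F2 vs mid-parent per trait and location.

    For each trait and location this removes outliers (single pass),
    selects trend covariates, fits the location model and evaluates the
    F1-vs-midparent and F2-vs-midparent contrasts; locations are then
    pooled by inverse variance. Yield and harvestable protein use
    one-sided p-values (hypothesized direction: F1 above mid-parent).
    ``harvestable_protein`` is derived per plot as yield × protein/100
    (kg/ha) when absent. Diagnostics that the data cannot support (e.g.
    too few residual df on a means-only fixture) are skipped and recorded
    in ``gaps``.
    """
    spec = spec or ModelSpec()
    plots = plots.copy()
    if (
        traits is not None
        and "harvestable_protein" in traits
        and "harvestable_protein" not in plots.columns
        and {"yield", "protein"} <= set(plots.columns)
    ):
        # derived column: yield (kg/ha) x protein (g/100g) / 100
        plots["harvestable_protein"] = plots["yield"] * plots["protein"] / 100.0
    design_cols = {"location", "block", "row", "column", "genotype", "entry_class"}
    if traits is None:
        traits = [c for c in plots.columns if c not in design_cols]

    rows = []
    gaps: list[str] = []
    dropped_frames = []
    inbreeding: dict[str, bool] = {}
    locations = sorted(plots["location"].unique())
    for trait in traits:
        per_loc: dict[str, list[ContrastResult]] = {"F1_vs_midparent": [], "F2_vs_midparent": []}
        one_sided = trait in one_sided_traits
        for loc in locations:
            sub = plots[plots["location"] == loc].dropna(subset=[trait])
            if sub.empty:
                gaps.append(f"{trait}@{loc}: no data")
                continue
            if screen_outliers:
                try:
                    sub, dropped = flag_outliers(sub, spec, trait)
                    if len(dropped):
                        dropped_frames.append(dropped.assign(trait=trait))
                except DiagnosticsError as err:
                    gaps.append(f"{trait}@{loc}: outlier screen skipped ({err})")
            covs: list[str] = []
            if select_covariates:
                try:
                    covs = select_trend_covariates(sub, spec, trait)
                except DiagnosticsError as err:
                    gaps.append(f"{trait}@{loc}: covariate selection skipped ({err})")
            fit = fit_location_model(sub, spec, trait, covs, location=str(loc))
            g = {cls: _class_genotype(sub, cls) for cls in ("parent1", "parent2", "F1", "F2")}
            for progeny, lab in (("F1", "F1_vs_midparent"), ("F2", "F2_vs_midparent")):
                if g["parent1"] is None or g["parent2"] is None or g[progeny] is None:
                    gaps.append(f"{trait}@{loc}: {lab} not estimable (missing entry class)")
                    continue
                coeffs = {g[progeny]: 1.0, g["parent1"]: -0.5, g["parent2"]: -0.5}
                if len(coeffs) < 3:
                    gaps.append(f"{trait}@{loc}: {lab} degenerate entry classes")
                    continue
                res = contrast(fit, coeffs, one_sided=one_sided, label=lab)
                per_loc[lab].append(res)
                rows.append(
                    {
                        "trait": trait,
                        "location": str(loc),
                        "contrast": lab,
                        "estimate": res.estimate,
                        "se": res.std_error,
                        "p_value": res.p_value,
                        "one_sided": res.one_sided,
                        "df": res.df,
                    }
                )
            if trait == "yield" and g["F1"] and g["F2"]:
                f1m = sub.loc[sub["genotype"] == g["F1"], trait].mean()
                f2m = sub.loc[sub["genotype"] == g["F2"], trait].mean()
                inbreeding[str(loc)] = bool(f2m < f1m)
        if len(locations) > 1:
            for lab, results in per_loc.items():
                try:
                    pooled = pooled_analysis(results)
                except ValueError:
                    gaps.append(f"{trait}@pooled: {lab} not poolable")
                    continue
                rows.append(
                    {
                        "trait": trait,
                        "location": "pooled",
                        "contrast": lab,
                        "estimate": pooled.estimate,
                        "se": pooled.std_error,
                        "p_value": pooled.p_value,
                        "one_sided": pooled.one_sided,
                        "df": pooled.df,
                    }
                )
    table = pd.DataFrame(
        rows,
        columns=["trait", "location", "contrast", "estimate", "se", "p_value", "one_sided", "df"],
    )
    dropped = pd.concat(dropped_frames, ignore_index=True) if dropped_frames else None
    return HeterosisReport(
        table=table, inbreeding_depression=inbreeding, dropped_outliers=dropped, gaps=gaps
    )
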