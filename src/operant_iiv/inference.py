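"""Strain comparison and temporal-trend statistics on phenotypic dispersion.

The battery mirrors a standard IIV analysis of a two-group operant study:

* **Kruskal–Wallis** rank test on session-averaged PD per rat (one value per
  rat by default, avoiding pseudo-replication; a per-rat-session unit is
  available).  With two groups the H statistic is chi-square with 1 df.
* **General linear model** on log-transformed PD: ``y = log(PD + offset)``
  averaged per rat over sessions, one-way fixed-effect ANOVA ``y ~ strain``
  giving an F test with (1, N-2) df and fitted group means with t-based 95%
  confidence intervals (pooled residual variance).
* **Variance proportion** eta^2 = SS_between / SS_total from the same
  one-way decomposition.
* **Among-sessions model** — repeated-measures ANOVA on log PD with rat as
  subject, between-subject factor strain, within-subject factor session
  (categorical), and their interaction; plus a per-strain linear slope of
  log PD on session index for sign reporting.
* **Within-sessions model** — the same machinery on per-segment mean
  absolute deviations (averaged over sessions), within-subject factor
  segment; per-strain linear slopes are fitted on the *raw* (count-scale)
  deviations by default, with rat-clustered standard errors.

The log transform uses a ``+1`` offset by default because PD can be exactly
zero (a session with identical segment counts); the offset is configurable
and echoed into every report.  P-values are two-sided and uncorrected across
traits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import pingouin as pg

from sklearn.base import BaseEstimator

from .traits import TRAITS

__all__ = [
    "StrainComparison",
    "TrendFit",
    "kruskal_wallis",
    "glm_log_pd",
    "variance_proportion",
    "strain_comparison",
    "among_sessions_model",
    "within_sessions_model",
    "StrainDispersionComparison",
    "AmongSessionsTrend",
    "WithinSessionsTrend",
]


@dataclass(frozen=True)
class StrainComparison:
    """Two-group comparison of dispersion for one trait."""

    trait: str
    kw_H: float
    kw_p: float
    glm_F: float
    glm_p: float
    #: strain -> (mean of log(PD+offset), 95% CI half-width)
    mean_log_by_strain: dict[str, tuple[float, float]]
    #: strain -> back-transformed mean, exp(mean_log) - offset
    mean_backtransformed_by_strain: dict[str, float]
    variance_proportion: float
    log_offset: float
    kw_unit: str


@dataclass(frozen=True)
class TrendFit:
    """Repeated-measures trend analysis for one trait.

    ``effect_p_values`` holds the p-values for the group (strain) effect, the
    temporal index (session or segment) effect, and their interaction.
    ``slope_by_strain`` maps strain -> (beta, se); ``pooled_slope`` is the
    common slope across strains.  A degenerate (exactly collinear) fit
    reports se = 0 and the strain appears in ``degenerate_strains``; its
    slope p-value is NaN.
    """

    trait: str
    scope: str  # "among_sessions" | "within_sessions"
    effect_p_values: dict[str, float]
    slope_by_strain: dict[str, tuple[float, float]]
    pooled_slope: tuple[float, float]
    slope_scale: str  # "log" | "raw"
    degenerate_strains: tuple[str, ...] = ()


def kruskal_wallis(values_by_group: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected, midranks) and chi-square p-value.

    All-identical pooled values return ``(0.0, 1.0)`` (no rank separation).
    """
    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        empty = [k for k, v in values_by_group.items() if len(v) == 0]
        raise ValueError(f"empty group(s): {empty}")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    res = st.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def _per_rat_log_averages(records: pd.DataFrame, trait: str,
                          log_offset: float) -> pd.DataFrame:
    sub = records.loc[records["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no records for trait {trait!r}")
    y = np.log(sub["pd"].to_numpy(dtype=float) + log_offset)
    if not np.all(np.isfinite(y)):
        raise ValueError("log transform produced non-finite values; "
                         "check pd values and log_offset")
    per_rat = (sub.assign(y=y).groupby(["rat_id", "strain"], sort=False)["y"]
               .mean().reset_index())
    return per_rat


def _two_strains(per_rat: pd.DataFrame) -> list[str]:
    strains = list(dict.fromkeys(per_rat["strain"]))
    if len(strains) != 2:
        raise ValueError(f"expected exactly two strains, found {strains}")
    for s in strains:
        if (per_rat["strain"] == s).sum() < 2:
            raise ValueError(f"strain {s!r} has fewer than 2 rats (no residual df)")
    return strains


def glm_log_pd(records: pd.DataFrame, trait: str, log_offset: float = 1.0
               ) -> tuple[float, float, dict[str, tuple[float, float]]]:
    """One-way fixed-effect model of per-rat mean log(PD+offset) on strain.

    Returns ``(F, p, means)`` with F on (1, N-2) df and
    ``means[strain] = (fitted mean of y, t-based 95% CI half-width)`` using
    the pooled residual variance.
    """
    per_rat = _per_rat_log_averages(records, trait, log_offset)
    strains = _two_strains(per_rat)
    y = per_rat["y"].to_numpy()
    x = (per_rat["strain"] == strains[1]).to_numpy(dtype=float)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    F, p = float(model.fvalue), float(model.f_pvalue)
    n = y.size
    tcrit = st.t.ppf(0.975, n - 2)
    mse = float(model.mse_resid)
    means = {}
    for s in strains:
        ys = y[(per_rat["strain"] == s).to_numpy()]
        means[s] = (float(ys.mean()), float(tcrit * np.sqrt(mse / ys.size)))
    return F, p, means


def variance_proportion(records: pd.DataFrame, trait: str,
                        log_offset: float = 1.0) -> float:
    """eta^2 = SS_between / SS_total of per-rat mean log(PD+offset) by strain.

    Zero total variance is reported as 0 with a warning.
    """
    per_rat = _per_rat_log_averages(records, trait, log_offset)
    _two_strains(per_rat)
    y = per_rat["y"].to_numpy()
    ss_total = float(np.sum((y - y.mean()) ** 2))
    if ss_total == 0.0:
        warnings.warn("zero total variance; variance proportion defined as 0")
        return 0.0
    ss_within = 0.0
    for _, g in per_rat.groupby("strain"):
        yg = g["y"].to_numpy()
        ss_within += float(np.sum((yg - yg.mean()) ** 2))
    return (ss_total - ss_within) / ss_total


def strain_comparison(records: pd.DataFrame, trait: str, log_offset: float = 1.0,
                      kw_unit: str = "rat") -> StrainComparison:
    """Full two-group comparison for one trait (rank test, GLM, eta^2)."""
    if kw_unit not in ("rat", "rat-session"):
        raise ValueError("kw_unit must be 'rat' or 'rat-session'")
    sub = records.loc[records["trait"] == trait]
    if kw_unit == "rat":
        unit = sub.groupby(["rat_id", "strain"], sort=False)["pd"].mean().reset_index()
    else:
        unit = sub
    values_by_group = {s: g["pd"].to_numpy() for s, g in unit.groupby("strain", sort=False)}
    H, kw_p = kruskal_wallis(values_by_group)
    F, glm_p, means = glm_log_pd(records, trait, log_offset)
    eta2 = variance_proportion(records, trait, log_offset)
    back = {s: float(np.exp(m) - log_offset) for s, (m, _) in means.items()}
    return StrainComparison(
        trait=trait, kw_H=H, kw_p=kw_p, glm_F=F, glm_p=glm_p,
        mean_log_by_strain=means, mean_backtransformed_by_strain=back,
        variance_proportion=eta2, log_offset=log_offset, kw_unit=kw_unit,
    )


def _check_balanced(df: pd.DataFrame, index_col: str) -> None:
    levels = df.groupby("rat_id")[index_col].agg(lambda s: tuple(sorted(s)))
    if levels.nunique() != 1:
        raise ValueError(
            f"unbalanced design: rats do not share the same set of {index_col} "
            "levels (listwise completeness required)"
        )


def _mixed_anova_p(df: pd.DataFrame, dv: str, within: str,
                   correction: bool) -> dict[str, float]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.mixed_anova(data=df, dv=dv, within=within, between="strain",
                             subject="rat_id", correction=correction)
    aov = aov.set_index("Source")
    # column naming varies across pingouin versions (p-unc vs p_unc)
    aov.columns = [c.replace("-", "_") for c in aov.columns]
    pcol = "p_GG_corr" if correction and "p_GG_corr" in aov.columns else "p_unc"

    def pval(source, col):
        v = aov.loc[source, col]
        return float(v) if np.isfinite(v) else float(aov.loc[source, "p_unc"])

    return {
        "group": float(aov.loc["strain", "p_unc"]),
        "index": pval(within, pcol),
        "interaction": pval("Interaction", pcol),
    }


def _strain_slope(df: pd.DataFrame, ycol: str, xcol: str
                  ) -> tuple[float, float, bool]:
    """OLS slope of y on x with rat-clustered SE; flags degenerate fits."""
    y = df[ycol].to_numpy(dtype=float)
    X = sm.add_constant(df[xcol].to_numpy(dtype=float))
    ols = sm.OLS(y, X)
    fit = ols.fit()
    beta = float(fit.params[1])
    if float(fit.ssr) <= 1e-12 * max(1.0, float(np.sum(y ** 2))):
        # exactly collinear input: slope is exact, no sampling variability
        return beta, 0.0, True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        robust = ols.fit(cov_type="cluster",
                         cov_kwds={"groups": df["rat_id"].to_numpy()})
    se = float(np.sqrt(robust.cov_params()[1, 1]))
    return beta, se, False


def _trend_fit(df: pd.DataFrame, trait: str, scope: str, index_col: str,
               slope_col: str, slope_scale: str,
               sphericity_correction: bool) -> TrendFit:
    _check_balanced(df, index_col)
    effect_p = _mixed_anova_p(df, "y_log", index_col, sphericity_correction)
    slopes = {}
    degenerate = []
    for s, g in df.groupby("strain", sort=False):
        beta, se, degen = _strain_slope(g, slope_col, index_col)
        slopes[s] = (beta, se)
        if degen:
            degenerate.append(s)
            warnings.warn(
                f"degenerate trend fit for strain {s!r} ({trait}, {scope}): "
                "zero residual variance, SE reported as 0 and p as NaN")
    pooled = _strain_slope(df, slope_col, index_col)[:2]
    return TrendFit(trait=trait, scope=scope, effect_p_values=effect_p,
                    slope_by_strain=slopes, pooled_slope=pooled,
                    slope_scale=slope_scale,
                    degenerate_strains=tuple(degenerate))


def among_sessions_model(records: pd.DataFrame, trait: str,
                         log_offset: float = 1.0,
                         sphericity_correction: bool = False) -> TrendFit:
    """Among-sessions (day-to-day) trend in dispersion.

    Repeated-measures ANOVA on ``log(PD+offset)`` with rat as subject,
    between-subject factor strain, within-subject factor session
    (categorical), plus per-strain linear slopes of log PD on session index.
    Requires every rat to have one PD per session (balanced).
    """
    sub = records.loc[records["trait"] == trait].copy()
    if sub.empty:
        raise ValueError(f"no records for trait {trait!r}")
    sub["y_log"] = np.log(sub["pd"].astype(float) + log_offset)
    return _trend_fit(sub, trait, "among_sessions", "session",
                      "y_log", "log", sphericity_correction)


def within_sessions_model(segdev: pd.DataFrame, trait: str,
                          log_offset: float = 1.0, slope_scale: str = "raw",
                          sphericity_correction: bool = False) -> TrendFit:
    """Within-session (segment-to-segment) trend in dispersion.

    Repeated-measures ANOVA on ``log(mean_abs_dev+offset)`` with
    within-subject factor segment, plus per-strain linear slopes of the
    per-segment deviations on segment index (1..K).  Slopes are fitted on
    the raw count-scale deviations by default (``slope_scale="raw"``) or on
    the log scale (``"log"``), with rat-clustered SEs.
    """
    if slope_scale not in ("raw", "log"):
        raise ValueError("slope_scale must be 'raw' or 'log'")
    sub = segdev.loc[segdev["trait"] == trait].copy()
    if sub.empty:
        raise ValueError(f"no records for trait {trait!r}")
    sub["y_log"] = np.log(sub["mean_abs_dev"].astype(float) + log_offset)
    slope_col = "mean_abs_dev" if slope_scale == "raw" else "y_log"
    return _trend_fit(sub, trait, "within_sessions", "segment",
                      slope_col, slope_scale, sphericity_correction)


# --------------------------------------------------------------------------
# estimator-style front ends


class StrainDispersionComparison(BaseEstimator):
    """Fit the two-group comparison battery for every trait in a PD table.

    Fitted attributes
    -----------------
    results_ : dict trait -> StrainComparison
    comparison_table_ : DataFrame in the conventional report layout
        (trait, chi2, p, F, p, mean +/- CI per strain, eta^2).
    """

    def __init__(self, log_offset: float = 1.0, kw_unit: str = "rat"):
        self.log_offset = log_offset
        self.kw_unit = kw_unit

    def fit(self, X: pd.DataFrame, y=None):
        self.results_ = {
            t: strain_comparison(X, t, self.log_offset, self.kw_unit)
            for t in TRAITS if (X["trait"] == t).any()
        }
        rows = []
        for t, r in self.results_.items():
            row = {"trait": t, "kw_chi2": r.kw_H, "kw_p": r.kw_p,
                   "glm_F": r.glm_F, "glm_p": r.glm_p}
            for s, (m, hw) in r.mean_log_by_strain.items():
                row[f"mean_log_{s}"] = m
                row[f"ci95_halfwidth_{s}"] = hw
                row[f"mean_backtransformed_{s}"] = r.mean_backtransformed_by_strain[s]
            row["eta2"] = r.variance_proportion
            rows.append(row)
        self.comparison_table_ = pd.DataFrame(rows)
        return self

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).comparison_table_


class AmongSessionsTrend(BaseEstimator):
    """Among-sessions repeated-measures trend fits, one per trait.

    Fitted attribute ``fits_``: dict trait -> TrendFit.
    """

    def __init__(self, log_offset: float = 1.0, sphericity_correction: bool = False):
        self.log_offset = log_offset
        self.sphericity_correction = sphericity_correction

    def fit(self, X: pd.DataFrame, y=None):
        self.fits_ = {
            t: among_sessions_model(X, t, self.log_offset, self.sphericity_correction)
            for t in TRAITS if (X["trait"] == t).any()
        }
        return self


class WithinSessionsTrend(BaseEstimator):
    """Within-session segment-trend fits, one per trait.

    Fitted attribute ``fits_``: dict trait -> TrendFit.
    """

    def __init__(self, log_offset: float = 1.0, slope_scale: str = "raw",
                 sphericity_correction: bool = False):
        self.log_offset = log_offset
        self.slope_scale = slope_scale
        self.sphericity_correction = sphericity_correction

    def fit(self, X: pd.DataFrame, y=None):
        self.fits_ = {
            t: within_sessions_model(X, t, self.log_offset, self.slope_scale,
                                     self.sphericity_correction)
            for t in TRAITS if (X["trait"] == t).any()
        }
        return self
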