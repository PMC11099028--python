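"""Trends of within-plot BEF coefficients with soil age.

The per-plot BEF coefficient (Spearman rho) is regressed on log10(soil
age) with random intercepts for parent material, climate class,
vegetation type and location (chronosequence) — crossed variance
components estimated by REML.  Soils are also binned into the
power-series age groups 2..7 (group g spans [10^(g-1), 10^g) years,
group 2 everything younger than 10^2), with linear and quadratic fits of
the group means, and the analysis is repeated separately for drylands
(aridity index < 0.5) and non-drylands.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

RANDOM_FACTORS = (
    "parent_material",
    "climate_class",
    "vegetation_type",
    "chronosequence_id",  # "location"
)


@dataclass
class TrendFit:
    """A fitted BEF-vs-log10(age) trend."""

    response: str
    slope: float
    se: float
    tvalue: float
    p: float
    intercept: float
    vcomp: dict[str, float] = field(default_factory=dict)
    dropped_factors: list[str] = field(default_factory=list)
    n: int = 0
    method: str = "REML"
    aic: float = float("nan")


def plot_covariates(samples: pd.DataFrame) -> pd.DataFrame:
    """Aggregate the sample table to one row per plot: numeric columns
    averaged across the plot's samples, categoricals taken as-is."""
    meta = samples.copy()
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    num = meta.select_dtypes(include=[np.number]).columns
    cat = [c for c in meta.columns if c not in num and c != "plot_id"]
    agg = {c: "mean" for c in num}
    agg.update({c: "first" for c in cat})
    out = meta.groupby("plot_id", sort=True).agg(agg)
    out["logage"] = np.log10(out["soil_age_years"])
    return out


def bef_family(
    bef: pd.DataFrame,
    diversity_index: str = "multidiversity",
    function_target: str = "MF_avg",
) -> pd.DataFrame:
    """Select one (diversity index, function target) family of BEF records,
    dropping degenerate (NaN-rho) plots."""
    sel = bef[
        (bef["diversity_index"] == diversity_index)
        & (bef["function_target"] == function_target)
    ].copy()
    return sel[~sel["rho"].isna()]


def fit_bef_age_lmm(
    befs: pd.DataFrame,
    samples: pd.DataFrame,
    response_name: str = "BEF",
    min_plots: int = 10,
) -> TrendFit:
    """Mixed-effects trend of per-plot BEF coefficients on log10(age).

    Random intercepts enter as crossed variance components for parent
    material, climate class, vegetation type and chronosequence
    (location).  Factors with a single observed level are dropped up
    front; variance components that collapse to ~0, or a fit that fails
    to converge, trigger a reduction chain whose last resort is plain
    OLS — the fitted method is recorded, never an error.
    """
    plots = plot_covariates(samples)
    data = befs.set_index("plot_id").join(plots, how="inner", rsuffix="_plot")
    data = data[~data["rho"].isna()]
    n = len(data)
    if n < min_plots:
        raise ValueError(f"fit_bef_age_lmm needs >= {min_plots} plots, got {n}")
    if np.ptp(data["rho"].to_numpy()) == 0:
        raise ValueError("response is constant; trend undefined")
    if (data["soil_age_years"] <= 0).any():
        raise ValueError("soil ages must be positive")

    dropped = [f for f in RANDOM_FACTORS if data[f].nunique() < 2]
    for f in dropped:
        logger.info("fit_bef_age_lmm: dropping single-level factor %r", f)
    factors = [f for f in RANDOM_FACTORS if f not in dropped]

    while factors:
        vcf = {f: f"0 + C({f})" for f in factors}
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(
                    "rho ~ logage",
                    data,
                    groups=np.ones(n),
                    re_formula="0",
                    vc_formula=vcf,
                )
                res = model.fit(reml=True)
            vcomp = dict(zip(model.exog_vc.names, np.asarray(res.vcomp, dtype=float)))
            near_zero = [f for f, v in vcomp.items() if v < 1e-6]
            if res.converged and not near_zero:
                k = 2 + len(vcomp) + 1  # fixed effects + vcomps + residual
                return TrendFit(
                    response=response_name,
                    slope=float(res.params["logage"]),
                    se=float(res.bse["logage"]),
                    tvalue=float(res.tvalues["logage"]),
                    p=float(res.pvalues["logage"]),
                    intercept=float(res.params["Intercept"]),
                    vcomp=vcomp,
                    dropped_factors=dropped,
                    n=n,
                    method="REML",
                    aic=float(-2 * res.llf + 2 * k),
                )
            if not res.converged:
                logger.info(
                    "fit_bef_age_lmm(%s): non-convergence with factors %s; reducing",
                    response_name, factors,
                )
                factors = factors[:-1]
            else:
                for f in near_zero:
                    logger.info(
                        "fit_bef_age_lmm(%s): variance of %r collapsed to 0; dropped",
                        response_name, f,
                    )
                dropped += near_zero
                factors = [f for f in factors if f not in near_zero]
        except (np.linalg.LinAlgError, ValueError) as exc:
            logger.info(
                "fit_bef_age_lmm(%s): %s with factors %s; reducing", response_name, exc, factors
            )
            dropped.append(factors[-1])
            factors = factors[:-1]

    ols = smf.ols("rho ~ logage", data).fit()
    return TrendFit(
        response=response_name,
        slope=float(ols.params["logage"]),
        se=float(ols.bse["logage"]),
        tvalue=float(ols.tvalues["logage"]),
        p=float(ols.pvalues["logage"]),
        intercept=float(ols.params["Intercept"]),
        vcomp={},
        dropped_factors=dropped,
        n=n,
        method="OLS",
        aic=float(ols.aic),
    )


def bin_age_groups(age_years: float) -> int:
    """Power-series age group: group g spans [10^(g-1), 10^g) years for
    g in 3..7, group 2 is everything below 10^2.  Ages above 10^7 are
    clamped to group 7 with a warning."""
    if not np.isfinite(age_years) or age_years <= 0:
        raise ValueError(f"soil age must be positive and finite, got {age_years}")
    if age_years > 1e7:
        logger.warning("bin_age_groups: age %g > 1e7 years, clamped to group 7", age_years)
        return 7
    g = int(np.floor(np.log10(age_years))) + 1
    return int(np.clip(g, 2, 7))


@dataclass
class GroupTrend:
    """Group means and the linear / quadratic fits over age groups."""

    group_stats: pd.DataFrame  # age_group, mean, se, n
    linear: dict[str, float]
    quadratic: dict[str, float]
    empty_groups: list[int] = field(default_factory=list)


def group_trend(befs: pd.DataFrame, samples: pd.DataFrame) -> GroupTrend:
    """Mean BEF per power-series age group, with degree-1 and degree-2
    polynomial fits of the group means against the group index."""
    plots = plot_covariates(samples)
    data = befs.set_index("plot_id").join(plots[["soil_age_years"]], how="inner")
    data = data[~data["rho"].isna()]
    data["age_group"] = data["soil_age_years"].map(bin_age_groups)

    stats_rows = []
    for g, grp in data.groupby("age_group", sort=True):
        r = grp["rho"].to_numpy()
        stats_rows.append(
            dict(
                age_group=int(g),
                mean_rho=float(r.mean()),
                se_rho=float(r.std(ddof=1) / np.sqrt(len(r))) if len(r) > 1 else np.nan,
                n=len(r),
            )
        )
    gs = pd.DataFrame(stats_rows)
    empty = [g for g in range(2, 8) if g not in set(gs["age_group"])]
    if empty:
        logger.info("group_trend: empty age group(s) %s omitted from fits", empty)
    if len(gs) < 3:
        raise ValueError(f"group_trend needs >= 3 populated groups, got {len(gs)}")

    x = gs["age_group"].to_numpy(dtype=float)
    y = gs["mean_rho"].to_numpy(dtype=float)

    def _polyfit(deg: int) -> dict[str, float]:
        X = np.vander(x, deg + 1, increasing=True)
        res = sm.OLS(y, X).fit()
        out = {f"b{i}": float(res.params[i]) for i in range(deg + 1)}
        out["r2"] = float(res.rsquared)
        out["p"] = float(res.f_pvalue) if len(x) > deg + 1 else np.nan
        return out

    lin = _polyfit(1)
    quad = _polyfit(2) if len(gs) >= 4 else {"b0": np.nan, "b1": np.nan, "b2": np.nan,
                                             "r2": np.nan, "p": np.nan}
    return GroupTrend(gs, lin, quad, empty)


def stratify_aridity(
    befs: pd.DataFrame,
    samples: pd.DataFrame,
    boundary: float = 0.5,
) -> dict[str, object]:
    """Split plots into drylands (AI < boundary) and non-drylands
    (AI >= boundary; the boundary itself goes to the wetter class) and
    fit the age trend separately per stratum.

    Plots with missing aridity index are excluded with a log message.
    Returns ``{"partition": plot->stratum, "dryland": TrendFit|None,
    "non_dryland": TrendFit|None}``.
    """
    plots = plot_covariates(samples)
    ai = plots["aridity_index"]
    missing = ai.index[ai.isna()]
    for p in missing:
        logger.warning("stratify_aridity: plot %s has no aridity index; excluded", p)
    partition = pd.Series(
        np.where(ai < boundary, "dryland", "non_dryland"), index=ai.index
    )[~ai.isna()]

    out: dict[str, object] = {"partition": partition, "boundary": boundary}
    for stratum in ("dryland", "non_dryland"):
        ids = set(partition.index[partition == stratum])
        sub = befs[befs["plot_id"].isin(ids)]
        sub_samples = samples[samples["plot_id"].isin(ids)]
        try:
            out[stratum] = fit_bef_age_lmm(
                sub, sub_samples, response_name=f"BEF[{stratum}]"
            )
        except ValueError as exc:
            logger.warning("stratify_aridity: %s stratum not fitted (%s)", stratum, exc)
            out[stratum] = None
    return out
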