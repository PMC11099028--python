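"""Within-plot BEF statistics: Spearman coefficients (exact small-sample
p-values), false-discovery-rate adjustment, and normality diagnostics.

The local BEF relationship of a plot is the Spearman rank correlation,
across the plot's replicate samples, between a diversity index
(multidiversity or per-group richness) and a function index (averaged or
threshold multifunctionality, or an individual oriented function proxy).
With five samples per plot the usual large-sample p-value is unreliable,
so for n <= 8 the two-sided p is computed exactly by enumerating all n!
rank permutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: switch to exact permutation p-values at or below this sample size
EXACT_P_MAX_N = 8


@dataclass(frozen=True)
class BefRecord:
    """One within-plot BEF coefficient."""

    plot_id: str
    chronosequence_id: str
    diversity_index: str
    function_target: str
    rho: float
    p: float
    n: int


@lru_cache(maxsize=8)
def _perm_matrix(n: int) -> np.ndarray:
    """All n! permutations of 0..n-1 as an (n!, n) index array."""
    return np.array(list(permutations(range(n))), dtype=np.intp)


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def exact_p_from_ranks(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p: share of the n! permutations of ``ry`` whose
    rank correlation with ``rx`` is at least ``|rho_obs|`` in magnitude.

    Works with tied (average) ranks; the permutation distribution then
    depends on the tie structure of both arguments.
    """
    n = len(rx)
    perms = _perm_matrix(n)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    if denom == 0:
        return np.nan
    rho_perm = (ryc[perms] @ rxc) / denom
    # tolerance absorbs float noise so |rho_perm| == |rho_obs| counts
    return float(np.mean(np.abs(rho_perm) >= abs(rho_obs) - 1e-12))


def spearman(x: np.ndarray | pd.Series, y: np.ndarray | pd.Series) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of average ranks (so ties are
    handled).  For n <= 8 the p-value is exact by enumeration of all n!
    rank permutations; for larger n the large-sample approximation from
    :func:`scipy.stats.spearmanr` is used.  Constant input yields
    ``(nan, nan)`` — such records are flagged and excluded downstream.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = len(x)
    if n < 3:
        raise ValueError(f"spearman needs n >= 3, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (np.nan, np.nan)
    rx, ry = _rank(x), _rank(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    rho = float((rxc @ ryc) / np.sqrt((rxc**2).sum() * (ryc**2).sum()))
    if n <= EXACT_P_MAX_N:
        p = exact_p_from_ranks(rx, ry, rho)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return (rho, p)


def fdr_adjust(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    p_(i) * m / i with a monotone pass from the largest rank down,
    capped at 1.  NaNs (degenerate records) are passed through and do
    not count toward m.
    """
    arr = np.asarray(pvalues, dtype=float)
    mask = ~np.isnan(arr)
    if np.any((arr[mask] < 0) | (arr[mask] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(arr.shape, np.nan)
    if mask.sum() > 0:
        out[mask] = multipletests(arr[mask], method="fdr_bh")[1]
    return out


def bef_per_plot(
    diversity: pd.DataFrame,
    mf: pd.DataFrame,
    functions_oriented: pd.DataFrame | None,
    samples: pd.DataFrame,
    min_samples: int = 3,
) -> pd.DataFrame:
    """Within-plot Spearman BEF coefficients for every
    (diversity index, function target) family.

    Diversity indices: ``multidiversity`` and the four per-group richness
    columns of ``diversity``.  Function targets: every column of ``mf``
    (MF_avg and the threshold counts) plus, if given, every row of the
    oriented function matrix (individual proxies).  One record per plot
    per family; plots with fewer than ``min_samples`` usable samples are
    skipped with a warning, and constant pairs yield NaN rho (flagged by
    ``degenerate``).

    Returns a long DataFrame with columns plot_id, chronosequence_id,
    diversity_index, function_target, rho, p, n, degenerate.
    """
    div_cols = ["multidiversity"] + [
        c for c in diversity.columns if c.startswith("richness_")
    ]
    targets = pd.DataFrame(index=mf.index)
    for c in mf.columns:
        targets[c] = mf[c]
    if functions_oriented is not None:
        for fname in functions_oriented.index:
            targets[fname] = functions_oriented.loc[fname]

    meta = samples.set_index("sample_id") if "sample_id" in samples.columns else samples
    records: list[dict] = []
    for plot_id, plot_samples in meta.groupby("plot_id", sort=True):
        ids = [s for s in plot_samples.index if s in diversity.index and s in targets.index]
        if len(ids) < min_samples:
            logger.warning(
                "bef_per_plot: plot %s has %d usable samples (< %d), skipped",
                plot_id, len(ids), min_samples,
            )
            continue
        chrono = str(plot_samples["chronosequence_id"].iloc[0])
        dsub = diversity.loc[ids]
        tsub = targets.loc[ids]
        for d in div_cols:
            xv = dsub[d].to_numpy(dtype=float)
            for t in targets.columns:
                yv = tsub[t].to_numpy(dtype=float)
                rho, p = spearman(xv, yv)
                records.append(
                    dict(
                        plot_id=str(plot_id),
                        chronosequence_id=chrono,
                        diversity_index=d,
                        function_target=t,
                        rho=rho,
                        p=p,
                        n=len(ids),
                        degenerate=bool(np.isnan(rho)),
                    )
                )
    return pd.DataFrame.from_records(records)


def adjust_bef(bef: pd.DataFrame, family: str = "per_pair") -> pd.DataFrame:
    """Attach FDR-adjusted p-values.

    ``family="per_pair"`` (default): each (diversity index, function
    target) pair across plots is one multiple-testing family.
    ``family="global"``: all records form a single family.
    """
    out = bef.copy()
    if family == "per_pair":
        out["p_adj"] = (
            out.groupby(["diversity_index", "function_target"], sort=False)["p"]
            .transform(lambda s: pd.Series(fdr_adjust(s), index=s.index))
        )
    elif family == "global":
        out["p_adj"] = fdr_adjust(out["p"])
    else:
        raise ValueError(f"unknown FDR family {family!r}")
    out.attrs["fdr_family"] = family
    return out


@dataclass
class NormalitySummary:
    """Distributional diagnostics for a family of BEF coefficients."""

    n: int
    skewness: float
    excess_kurtosis: float
    shapiro_w: float | None
    shapiro_p: float | None
    note: str = ""


def normality(rhos: np.ndarray | pd.Series) -> NormalitySummary:
    """Skewness (Fisher g1), excess kurtosis (g2) and, for n >= 8, the
    Shapiro-Wilk test of the BEF coefficient distribution."""
    arr = np.asarray(rhos, dtype=float)
    arr = arr[~np.isnan(arr)]
    n = len(arr)
    if n < 3:
        raise ValueError(f"normality needs n >= 3 non-missing values, got {n}")
    if np.ptp(arr) == 0:
        raise ValueError("normality: constant input has zero variance")
    g1 = float(stats.skew(arr, bias=True))
    g2 = float(stats.kurtosis(arr, fisher=True, bias=True))
    if n >= 8:
        w, p = stats.shapiro(arr)
        return NormalitySummary(n, g1, g2, float(w), float(p))
    return NormalitySummary(
        n, g1, g2, None, None, note=f"Shapiro-Wilk omitted (n={n} < 8)"
    )


def normality_by_family(bef: pd.DataFrame) -> pd.DataFrame:
    """Normality diagnostics per (diversity index, function target) family."""
    rows = []
    for (d, t), grp in bef.groupby(["diversity_index", "function_target"], sort=False):
        arr = grp["rho"].to_numpy(dtype=float)
        arr = arr[~np.isnan(arr)]
        if len(arr) < 3 or np.ptp(arr) == 0:
            continue
        s = normality(arr)
        rows.append(
            dict(
                diversity_index=d,
                function_target=t,
                n=s.n,
                skewness=s.skewness,
                excess_kurtosis=s.excess_kurtosis,
                shapiro_w=s.shapiro_w,
                shapiro_p=s.shapiro_p,
                note=s.note,
            )
        )
    return pd.DataFrame(rows)
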