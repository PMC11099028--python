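"""Environmental drivers of the within-plot BEF relationship.

Four complementary analyses:

* :func:`akaike_importance` — exhaustive least-squares enumeration of
  predictor subsets, small-sample-corrected Akaike weights, and
  per-predictor summed weights (importance; significant at >= 0.8 by
  default).
* :func:`pearson_screen` — two-sided Pearson correlations of plot-level
  covariates with the BEF coefficient, marked at 0.05 / 0.01.
* :func:`dominant_taxon_proportions` — per-sample read proportions of
  named dominant taxa, for composition-shift screens.
* :func:`fit_path_model` — recursive path analysis over observed
  variables (OLS per equation, which is the ML estimator for recursive
  models), with chi-square and RMSEA fit statistics and direct /
  indirect / total effects by path tracing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from chronobef.community import ORGANISM_GROUPS, OtuTable

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Akaike-weight importance
# --------------------------------------------------------------------------

def _aicc(rss: float, n: int, n_coef: int) -> float:
    """Small-sample corrected AIC for a Gaussian least-squares fit.

    ``n_coef`` counts the regression coefficients (incl. intercept); the
    residual variance adds one more estimated parameter.
    """
    k = n_coef + 1
    if n - k - 1 <= 0:
        return np.inf
    ll = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1)
    return -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def akaike_importance(
    response: pd.Series | np.ndarray,
    predictors: pd.DataFrame,
    max_terms: int | None = None,
    cutoff: float = 0.8,
) -> pd.DataFrame:
    """Per-predictor summed Akaike weights over every predictor subset.

    Every subset of the columns of ``predictors`` (up to ``max_terms``
    terms; at most 12 predictors in total) is fitted by least squares
    with an intercept, AICc is computed, weights
    ``w_m = exp(-delta_m / 2)`` are normalised over the model set, and
    each predictor's importance is the sum of the weights of the models
    containing it.

    Returns a DataFrame indexed by predictor with columns
    ``importance``, ``significant`` (importance >= cutoff) and
    ``n_models``; the weights themselves are in ``attrs["weights"]``.
    """
    y = np.asarray(response, dtype=float)
    X = predictors.astype(float)
    names = list(X.columns)
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate predictor column(s): {dupes}")
    k = len(names)
    if k > 12:
        raise ValueError(f"akaike_importance enumerates 2^k models; k={k} > 12")
    n = len(y)
    if n != len(X):
        raise ValueError("response and predictors must have equal length")

    corr = np.corrcoef(X.to_numpy().T) if k > 1 else np.ones((1, 1))
    for i, j in combinations(range(k), 2):
        if abs(corr[i, j]) > 1 - 1e-12:
            raise ValueError(
                f"predictors {names[i]!r} and {names[j]!r} are perfectly "
                "collinear (|r| = 1)"
            )

    max_terms = k if max_terms is None else min(max_terms, k)
    Xmat = X.to_numpy()
    models: list[tuple[tuple[int, ...], float]] = []
    for size in range(max_terms + 1):
        for subset in combinations(range(k), size):
            cols = np.column_stack([np.ones(n)] + [Xmat[:, j] for j in subset])
            coef, _, _, _ = np.linalg.lstsq(cols, y, rcond=None)
            rss = float(((y - cols @ coef) ** 2).sum())
            models.append((subset, _aicc(max(rss, 1e-300), n, cols.shape[1])))

    aiccs = np.array([m[1] for m in models])
    delta = aiccs - aiccs.min()
    w = np.exp(-delta / 2)
    w /= w.sum()

    importance = np.zeros(k)
    n_models = np.zeros(k, dtype=int)
    for (subset, _), wm in zip(models, w):
        for j in subset:
            importance[j] += wm
            n_models[j] += 1
    out = pd.DataFrame(
        dict(importance=importance, significant=importance >= cutoff, n_models=n_models),
        index=pd.Index(names, name="predictor"),
    )
    out.attrs["weights"] = {m[0]: float(wm) for m, wm in zip(models, w)}
    out.attrs["cutoff"] = cutoff
    return out


# --------------------------------------------------------------------------
# Pearson screens
# --------------------------------------------------------------------------

def pearson_screen(
    bef: pd.Series,
    env: pd.DataFrame,
    min_plots: int = 10,
) -> pd.DataFrame:
    """Two-sided Pearson correlation of each covariate with the per-plot
    BEF coefficient; constant covariates are skipped with a log message.

    Returns a DataFrame indexed by covariate with ``r``, ``p``, ``n``
    and ``sig`` ('**' p<0.01, '*' p<0.05, '' otherwise).
    """
    common = bef.index.intersection(env.index)
    if len(common) < min_plots:
        raise ValueError(
            f"pearson_screen needs >= {min_plots} plots, got {len(common)}"
        )
    rows = []
    y = bef.loc[common].astype(float)
    for cov in env.columns:
        x = env.loc[common, cov]
        if not np.issubdtype(np.asarray(x).dtype, np.number):
            continue
        mask = ~(x.isna() | y.isna())
        xs, ys = x[mask].to_numpy(dtype=float), y[mask].to_numpy()
        if len(xs) < 3 or np.ptp(xs) == 0 or np.ptp(ys) == 0:
            logger.info("pearson_screen: covariate %r constant or empty; skipped", cov)
            continue
        r, p = stats.pearsonr(xs, ys)
        rows.append(
            dict(
                covariate=cov,
                r=float(r),
                p=float(p),
                n=int(len(xs)),
                sig="**" if p < 0.01 else ("*" if p < 0.05 else ""),
            )
        )
    return pd.DataFrame(rows).set_index("covariate")


# --------------------------------------------------------------------------
# Dominant-taxon proportions
# --------------------------------------------------------------------------

def dominant_taxon_proportions(
    otu_tables: dict[str, OtuTable],
    taxonomy: pd.DataFrame,
    taxa: list[str] | None = None,
) -> pd.DataFrame:
    """Per-sample read proportion of each named taxon within its group's
    table (taxon reads / total reads of that group in the sample).

    ``taxonomy`` maps otu_id -> (group, taxon).  If ``taxa`` is None,
    every taxon present in the taxonomy (except 'Other') is reported.
    Taxa absent from the counts yield an all-zero column with a warning.

    Returns samples x taxa, columns named ``<group>:<taxon>``.
    """
    tax = taxonomy.set_index("otu_id")
    frames = {}
    for group in ORGANISM_GROUPS:
        if group not in otu_tables:
            continue
        counts = otu_tables[group].counts
        totals = counts.sum(axis=0).astype(float)
        totals[totals == 0] = 1.0
        gtax = tax[tax["group"] == group]
        wanted = (
            [t for t in gtax["taxon"].unique() if t != "Other"]
            if taxa is None
            else taxa
        )
        for taxon in wanted:
            otus = gtax.index[gtax["taxon"] == taxon]
            otus = counts.index.intersection(otus)
            col = f"{group}:{taxon}"
            if len(otus) == 0:
                logger.warning(
                    "dominant_taxon_proportions: taxon %r absent from %s counts",
                    taxon, group,
                )
                frames[col] = pd.Series(0.0, index=counts.columns)
            else:
                frames[col] = counts.loc[otus].sum(axis=0) / totals
    out = pd.DataFrame(frames)
    out.index.name = "sample_id"
    return out


# --------------------------------------------------------------------------
# Recursive path analysis
# --------------------------------------------------------------------------

@dataclass
class PathModel:
    """A recursive (acyclic) path model over observed variables.

    ``edges`` are (parent, child) pairs.  After :func:`fit_path_model`,
    ``coefficients`` holds the standardized path coefficient per edge,
    ``effects`` the direct / indirect / total effect of every variable
    on every descendant, and chi2 / df / p / rmsea the global fit.
    """

    edges: list[tuple[str, str]]
    variables: list[str] = field(default_factory=list)
    coefficients: dict[tuple[str, str], float] = field(default_factory=dict)
    residual_variances: dict[str, float] = field(default_factory=dict)
    effects: pd.DataFrame | None = None
    chi2: float = float("nan")
    df: int = -1
    p: float = float("nan")
    rmsea: float = float("nan")
    n: int = 0
    saturated: bool = False

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from(self.edges)
        return g


def fit_path_model(spec: PathModel, data: pd.DataFrame) -> PathModel:
    """Fit a recursive path model by OLS-per-equation (the maximum-
    likelihood estimator for recursive systems of observed variables).

    All variables are standardized to unit variance, so coefficients are
    standardized path weights.  The implied covariance is assembled from
    the path coefficients and residual (co)variances; the likelihood-
    ratio statistic chi2 = (n-1) * F_ML compares it with the observed
    covariance, with df = p(p+1)/2 minus the number of free parameters,
    and RMSEA = sqrt(max(chi2 - df, 0) / (df * (n - 1))).  A saturated
    model reproduces the observed covariance exactly (chi2 = 0, df = 0;
    p and RMSEA undefined).
    """
    variables = sorted({v for e in spec.edges for v in e})
    if spec.variables:
        extra = [v for v in spec.variables if v not in variables]
        variables = variables + extra
    g = nx.DiGraph()
    g.add_nodes_from(variables)
    g.add_edges_from(spec.edges)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("path model specification contains a cycle")
    missing = [v for v in variables if v not in data.columns]
    if missing:
        raise ValueError(f"data is missing path-model variable(s) {missing}")

    order = list(nx.topological_sort(g))
    z = data[order].astype(float)
    z = (z - z.mean()) / z.std(ddof=1)
    n = len(z)
    S = z.cov().to_numpy()  # ddof=1; correlation matrix of the variables
    p = len(order)
    idx = {v: i for i, v in enumerate(order)}

    exog = [v for v in order if g.in_degree(v) == 0]
    endog = [v for v in order if g.in_degree(v) > 0]

    B = np.zeros((p, p))
    psi = np.zeros((p, p))
    ex_idx = [idx[v] for v in exog]
    psi[np.ix_(ex_idx, ex_idx)] = S[np.ix_(ex_idx, ex_idx)]

    coefficients: dict[tuple[str, str], float] = {}
    residual_variances: dict[str, float] = {}
    for child in endog:
        parents = list(g.predecessors(child))
        pi = [idx[v] for v in parents]
        ci = idx[child]
        b = np.linalg.solve(S[np.ix_(pi, pi)], S[pi, ci])
        B[ci, pi] = b
        resid = float(S[ci, ci] - b @ S[pi, ci])
        psi[ci, ci] = resid
        residual_variances[child] = resid
        for parent, coef in zip(parents, b):
            coefficients[(parent, child)] = float(coef)

    inv_ImB = np.linalg.inv(np.eye(p) - B)
    sigma = inv_ImB @ psi @ inv_ImB.T

    q = len(exog)
    free = len(spec.edges) + len(endog) + q * (q + 1) // 2
    df = p * (p + 1) // 2 - free

    sign_S, logdet_S = np.linalg.slogdet(S)
    sign_T, logdet_T = np.linalg.slogdet(sigma)
    if sign_S <= 0 or sign_T <= 0:
        raise ValueError("singular covariance; check for collinear variables")
    f_ml = logdet_T - logdet_S + float(np.trace(S @ np.linalg.inv(sigma))) - p
    chi2 = max((n - 1) * f_ml, 0.0)
    if df > 0:
        pval = float(stats.chi2.sf(chi2, df))
        rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))
        saturated = False
    else:
        pval, rmsea, saturated = np.nan, np.nan, True
        chi2 = 0.0 if df == 0 else chi2

    # path-tracing effects along directed edges only
    total = inv_ImB - np.eye(p)
    rows = []
    for s in order:
        for t in order:
            if s == t:
                continue
            tot = total[idx[t], idx[s]]
            direct = B[idx[t], idx[s]]
            if abs(tot) > 1e-12 or abs(direct) > 1e-12:
                rows.append(
                    dict(
                        source=s,
                        target=t,
                        direct=float(direct),
                        indirect=float(tot - direct),
                        total=float(tot),
                    )
                )
    effects = pd.DataFrame(rows)

    return PathModel(
        edges=list(spec.edges),
        variables=order,
        coefficients=coefficients,
        residual_variances=residual_variances,
        effects=effects,
        chi2=float(chi2),
        df=int(df),
        p=pval,
        rmsea=rmsea,
        n=n,
        saturated=saturated,
    )


#: default structural hypothesis for the driver analysis: soil age and
#: climate shape plant cover, carbon and microbial biomass, which in turn
#: (with a direct age path) determine the within-plot BEF coefficient
DEFAULT_PATH_EDGES = [
    ("logage", "plant_cover"),
    ("MAP", "plant_cover"),
    ("MAT", "plant_cover"),
    ("logage", "soc"),
    ("plant_cover", "soc"),
    ("soc", "microbial_biomass"),
    ("MAP", "microbial_biomass"),
    ("logage", "rho"),
    ("microbial_biomass", "rho"),
    ("plant_cover", "rho"),
    ("soc", "rho"),
]
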