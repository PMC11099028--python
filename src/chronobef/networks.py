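"""Per-plot co-occurrence networks across the four organism groups, and
their topological traits.

For each plot, OTUs from all groups are pooled (as within-group relative
abundances), filtered by prevalence, and every pair is tested by
Spearman correlation across the plot's replicate samples.  Pairs passing
the |rho| and p cutoffs become signed, undirected edges.  Eight traits
summarise each network: node count, edge count, positive and negative
edge counts, average degree, graph density, Freeman degree
centralization, and modularity of a greedily optimised partition.

With five samples per plot the exact two-sided Spearman p-values are
coarse (the smallest attainable value is 2/5! = 0.0167, reached only at
|rho| = 1), so the default cutoffs admit only perfectly concordant or
discordant pairs; the cutoffs are recorded with every result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import greedy_modularity_communities, modularity
from scipy import stats

from chronobef.bef_stats import EXACT_P_MAX_N, _perm_matrix, exact_p_from_ranks
from chronobef.community import ORGANISM_GROUPS, OtuTable

logger = logging.getLogger(__name__)


@dataclass
class NetworkParams:
    """Edge cutoffs and prevalence filter for network construction."""

    rho_cutoff: float = 0.6
    p_cutoff: float = 0.05
    prevalence_min: int | None = None  # None = present in all plot samples

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho_cutoff <= 1.0):
            raise ValueError(f"rho_cutoff must lie in [0, 1], got {self.rho_cutoff}")
        if not (0.0 < self.p_cutoff <= 1.0):
            raise ValueError(f"p_cutoff must lie in (0, 1], got {self.p_cutoff}")


@dataclass
class CooccurrenceNetwork:
    """Signed undirected co-occurrence network for one plot."""

    plot_id: str
    edges: pd.DataFrame  # columns: node_a, node_b, rho, sign
    n_candidates: int  # OTUs passing the prevalence filter
    params: NetworkParams
    graph: nx.Graph = field(repr=False, default_factory=nx.Graph)
    empty: bool = False


@dataclass
class NetworkMetrics:
    """The eight topological traits of one plot's network."""

    plot_id: str
    nodes: int
    edges: int
    positive_edges: int
    negative_edges: int
    average_degree: float
    density: float
    centralization: float
    modularity: float
    empty: bool = False


def _tiefree_p_table(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Sorted |rho| values and their exact two-sided p for tie-free ranks.

    For tie-free data the permutation distribution of Spearman's rho
    depends only on n, so one table serves every pair.
    """
    perms = _perm_matrix(n)
    base = np.arange(1, n + 1, dtype=float)
    c = base - base.mean()
    denom = (c**2).sum()
    rho = (c[perms] @ c) / denom
    abs_rho = np.sort(np.unique(np.round(np.abs(rho), 12)))
    pvals = np.array([np.mean(np.abs(rho) >= r - 1e-12) for r in abs_rho])
    return abs_rho, pvals


def _exact_p_lookup(abs_rho_obs: np.ndarray, table: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    grid, pvals = table
    idx = np.searchsorted(grid, abs_rho_obs - 1e-9, side="left")
    idx = np.clip(idx, 0, len(grid) - 1)
    return pvals[idx]


def build_network(
    otu_tables: dict[str, OtuTable],
    plot_sample_ids: list[str],
    plot_id: str,
    params: NetworkParams | None = None,
) -> CooccurrenceNetwork:
    """Build one plot's co-occurrence network.

    Parameters
    ----------
    otu_tables
        Raw count tables per organism group (full study); the plot's
        columns are selected here.
    plot_sample_ids
        The plot's sample ids (>= 3 required).
    params
        Cutoffs; defaults |rho| >= 0.6, p <= 0.05, prevalence = all
        samples of the plot.

    Notes
    -----
    Abundances are converted to within-group per-sample proportions
    before pooling, correlations are Spearman across the plot's samples
    with exact permutation p-values (n <= 8), and edge sign is the sign
    of rho.  The graph keeps only nodes incident to at least one edge;
    the prevalence-passing candidate count is reported separately.
    """
    if params is None:
        params = NetworkParams()
    n = len(plot_sample_ids)
    if n < 3:
        raise ValueError(f"plot {plot_id}: need >= 3 samples, got {n}")
    prev_min = params.prevalence_min if params.prevalence_min is not None else n

    blocks = []
    ids: list[str] = []
    for group in ORGANISM_GROUPS:
        if group not in otu_tables:
            continue
        sub = otu_tables[group].counts[plot_sample_ids]
        totals = sub.sum(axis=0).to_numpy(dtype=float)
        totals[totals == 0] = 1.0
        rel = sub.to_numpy(dtype=float) / totals
        present = (sub.to_numpy() > 0).sum(axis=1) >= prev_min
        blocks.append(rel[present])
        ids.extend(np.asarray(sub.index)[present])
    if not blocks or sum(b.shape[0] for b in blocks) == 0:
        logger.warning("plot %s: no OTUs pass the prevalence filter", plot_id)
        return CooccurrenceNetwork(
            plot_id, _empty_edges(), 0, params, nx.Graph(), empty=True
        )

    rel = np.vstack(blocks)
    m = rel.shape[0]
    if m < 2:
        return CooccurrenceNetwork(
            plot_id, _empty_edges(), m, params, nx.Graph(), empty=True
        )

    ranks = stats.rankdata(rel, axis=1)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    ok = norms > 0  # constant rows can't correlate
    norms[~ok] = 1.0
    unit = centered / norms[:, None]
    rho = unit @ unit.T
    np.clip(rho, -1.0, 1.0, out=rho)

    iu, ju = np.triu_indices(m, k=1)
    valid = ok[iu] & ok[ju]
    pass_rho = np.abs(rho[iu, ju]) >= params.rho_cutoff - 1e-12
    cand = np.flatnonzero(valid & pass_rho)

    if n <= EXACT_P_MAX_N:
        has_ties = np.array([len(np.unique(r)) < n for r in ranks])
        table = _tiefree_p_table(n)
        pvals = np.empty(len(cand))
        for k, idx in enumerate(cand):
            i, j = iu[idx], ju[idx]
            if has_ties[i] or has_ties[j]:
                pvals[k] = exact_p_from_ranks(ranks[i], ranks[j], rho[i, j])
            else:
                pvals[k] = _exact_p_lookup(np.abs(rho[i, j : j + 1]), table)[0]
    else:
        # t-approximation for larger plots
        r = rho[iu[cand], ju[cand]]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt((n - 2) / np.clip(1 - r**2, 1e-12, None))
        pvals = 2 * stats.t.sf(np.abs(t), df=n - 2)

    keep = cand[pvals <= params.p_cutoff + 1e-12]
    ids_arr = np.asarray(ids)
    rows = pd.DataFrame(
        dict(
            node_a=ids_arr[iu[keep]],
            node_b=ids_arr[ju[keep]],
            rho=rho[iu[keep], ju[keep]],
        )
    )
    rows["sign"] = np.where(rows["rho"] >= 0, "+", "-")

    graph = nx.Graph()
    for a, b, r in zip(rows["node_a"], rows["node_b"], rows["rho"]):
        graph.add_edge(a, b, rho=float(r), sign="+" if r >= 0 else "-")
    return CooccurrenceNetwork(plot_id, rows, m, params, graph, empty=len(rows) == 0)


def _empty_edges() -> pd.DataFrame:
    return pd.DataFrame(columns=["node_a", "node_b", "rho", "sign"])


def network_metrics(net: CooccurrenceNetwork) -> NetworkMetrics:
    """Compute the eight topological traits of one network.

    Modularity uses greedy agglomerative (Clauset-Newman-Moore)
    optimisation on the unsigned graph; edge signs are reported
    separately.  Empty networks yield zero counts with ``empty=True``;
    centralization needs at least 3 nodes and modularity at least one
    edge, otherwise NaN.
    """
    g = net.graph
    n_nodes = g.number_of_nodes()
    n_edges = g.number_of_edges()
    if n_edges == 0:
        return NetworkMetrics(net.plot_id, 0, 0, 0, 0, 0.0, 0.0, np.nan, np.nan, empty=True)

    pos = sum(1 for _, _, d in g.edges(data=True) if d["sign"] == "+")
    neg = n_edges - pos
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    avg_degree = 2.0 * n_edges / n_nodes
    density = 2.0 * n_edges / (n_nodes * (n_nodes - 1)) if n_nodes > 1 else 0.0
    if n_nodes >= 3:
        centralization = float(
            (degrees.max() - degrees).sum() / ((n_nodes - 1) * (n_nodes - 2))
        )
    else:
        centralization = np.nan
    communities = greedy_modularity_communities(g)
    q = float(modularity(g, communities))
    return NetworkMetrics(
        net.plot_id, n_nodes, n_edges, pos, neg, avg_degree, density, centralization, q
    )


def networks_per_plot(
    otu_tables: dict[str, OtuTable],
    samples: pd.DataFrame,
    params: NetworkParams | None = None,
) -> tuple[list[CooccurrenceNetwork], pd.DataFrame]:
    """Build one network per plot and tabulate the eight traits.

    Returns the networks and a metrics DataFrame (one row per plot) with
    the cutoffs used recorded in ``DataFrame.attrs["params"]``.
    """
    if params is None:
        params = NetworkParams()
    meta = samples.set_index("sample_id") if "sample_id" in samples.columns else samples
    nets: list[CooccurrenceNetwork] = []
    rows = []
    for plot_id, grp in meta.groupby("plot_id", sort=True):
        ids = list(grp.index)
        if len(ids) < 3:
            logger.warning("plot %s: fewer than 3 samples, network skipped", plot_id)
            continue
        net = build_network(otu_tables, ids, str(plot_id), params)
        nets.append(net)
        rows.append(network_metrics(net).__dict__)
    metrics = pd.DataFrame(rows)
    metrics.attrs["params"] = dict(
        rho_cutoff=params.rho_cutoff,
        p_cutoff=params.p_cutoff,
        prevalence_min=params.prevalence_min,
    )
    return nets, metrics
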