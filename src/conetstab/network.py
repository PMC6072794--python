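"""Spearman correlation sets, thresholded positive co-occurrence networks,
node/network metrics, Girvan-Newman modules, and G(n,m) random-graph nulls.

A network is built per (treatment x sampling) community set: after the
prevalence filter, all taxon pairs are rank-correlated; pairs with rho > 0.6
and p < 0.01 (both configurable) become edges, negative pairs are kept in a
parallel signed set for antagonism proportions, and isolated taxa are left
out of the graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.base import BaseEstimator

from .otu import OtuTable

logger = logging.getLogger("conetstab")


# -- correlation sets ------------------------------------------------------

@dataclass
class CorrelationSet:
    """All-pairs Spearman rho and p for one community set.

    ``rho`` and ``p`` are symmetric (taxa x taxa) arrays; excluded (constant)
    taxa are listed separately. ``pairs()`` yields the upper triangle.
    """

    taxon_ids: list[str]
    rho: np.ndarray
    p: np.ndarray
    n_samples: int
    label: str = ""
    excluded_taxa: list[str] = field(default_factory=list)

    def pairs(self) -> pd.DataFrame:
        iu, ju = np.triu_indices(len(self.taxon_ids), k=1)
        ids = np.asarray(self.taxon_ids)
        return pd.DataFrame(
            {
                "taxon_a": ids[iu],
                "taxon_b": ids[ju],
                "rho": self.rho[iu, ju],
                "p": self.p[iu, ju],
            }
        )

    def triu_values(self) -> tuple[np.ndarray, np.ndarray]:
        iu, ju = np.triu_indices(len(self.taxon_ids), k=1)
        return self.rho[iu, ju], self.p[iu, ju]


def spearman_matrix(table: OtuTable, label: str = "") -> CorrelationSet:
    """All-pairs Spearman rank correlation with the t-approximation p-value.

    rho is the Pearson correlation of mid-ranks (average ties; zeros tie at
    the bottom); two-sided p from t = rho*sqrt((n-2)/(1-rho^2)) on n-2 df,
    with |rho| = 1 mapped to the smallest positive float. Constant taxa have
    undefined rank correlation and are excluded (logged).
    """
    x = table.matrix().astype(float)
    n = x.shape[1]
    if n < 4:
        raise ValueError("need at least 4 samples for correlation analysis")
    const = np.all(x == x[:, [0]], axis=1)
    excluded = [t for t, c in zip(table.taxon_ids, const) if c]
    if excluded:
        logger.info("spearman: excluded %d constant taxa", len(excluded))
        x = x[~const]
    ids = [t for t, c in zip(table.taxon_ids, const) if not c]
    ranks = stats.rankdata(x, axis=1)
    rho = np.corrcoef(ranks)
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rho) >= 1.0 - 1e-12] = np.finfo(float).tiny
    np.fill_diagonal(p, 1.0)
    return CorrelationSet(ids, rho, p, n, label=label, excluded_taxa=excluded)


def spearman_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided permutation p for one pair (feasible for n <= 10)."""
    from itertools import permutations

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    hits = total = 0
    for perm in permutations(ry):
        hits += abs(np.corrcoef(rx, perm)[0, 1]) >= obs - 1e-12
        total += 1
    return hits / total


# -- thresholded network ---------------------------------------------------

class CooccurrenceNetwork(BaseEstimator):
    """Estimator building a positive co-occurrence network from one table.

    ``fit`` runs the prevalence-filtered table through Spearman correlation,
    thresholds edges at ``rho > rho_min`` and ``p < p_max`` (positive only),
    attaches node attributes, and computes node and network metrics.

    Parameters
    ----------
    rho_min, p_max : edge thresholds (defaults 0.6 and 0.01).
    degree_norm : 'n-1' (default; degree/(n-1), bounded in [0,1]) or
        'edges' (degree/(2m), the share of all edge endpoints).

    Attributes
    ----------
    graph_ : networkx.Graph with edge attr rho, node attrs.
    correlations_ : CorrelationSet of all pairs.
    signed_pairs_ : DataFrame of pairs with |rho| > rho_min and p < p_max.
    node_metrics_ : DataFrame (degree, normalised_degree, betweenness).
    clustering_coefficient_ : global transitivity.
    """

    def __init__(self, rho_min: float = 0.6, p_max: float = 0.01, degree_norm: str = "n-1"):
        self.rho_min = rho_min
        self.p_max = p_max
        self.degree_norm = degree_norm

    def fit(self, table: OtuTable, y=None, label: str = "") -> "CooccurrenceNetwork":
        cset = spearman_matrix(table, label=label)
        self.correlations_ = cset
        self.graph_, self.signed_pairs_ = threshold_network(
            cset, rho_min=self.rho_min, p_max=self.p_max
        )
        rel = table.relative_abundance().mean(axis=1)
        for v in self.graph_.nodes:
            self.graph_.nodes[v]["mean_relabund"] = float(rel[v])
        self.node_metrics_ = node_metrics(self.graph_, degree_norm=self.degree_norm)
        self.clustering_coefficient_ = transitivity(self.graph_)
        return self


def threshold_network(
    cset: CorrelationSet, rho_min: float = 0.6, p_max: float = 0.01,
    bh_correct: bool = False,
) -> tuple[nx.Graph, pd.DataFrame]:
    """Positive co-occurrence graph + the parallel signed significant set.

    Edges: rho > rho_min and p < p_max. Signed set: |rho| > rho_min and
    p < p_max (used for negative-correlation proportions). Isolated taxa are
    excluded from the graph. ``bh_correct`` applies Benjamini-Hochberg
    adjustment across all pairs before the p gate (off by default, mirroring
    the raw-threshold convention).
    """
    pairs = cset.pairs()
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        pairs = pairs.assign(p=multipletests(pairs["p"], method="fdr_bh")[1])
    signed = pairs[(pairs["rho"].abs() > rho_min) & (pairs["p"] < p_max)].reset_index(drop=True)
    positive = signed[signed["rho"] > 0]
    g = nx.Graph(label=cset.label)
    for row in positive.itertuples(index=False):
        g.add_edge(row.taxon_a, row.taxon_b, rho=float(row.rho))
    if g.number_of_edges() == 0:
        logger.warning("threshold_network: no edges survive rho>%.3g, p<%.3g", rho_min, p_max)
    return g, signed


# -- node and network metrics ---------------------------------------------

def node_metrics(graph: nx.Graph, degree_norm: str = "n-1") -> pd.DataFrame:
    """Degree, normalised degree and (unnormalised) betweenness per node."""
    if degree_norm not in ("n-1", "edges"):
        raise ValueError("degree_norm must be 'n-1' or 'edges'")
    n = graph.number_of_nodes()
    m = graph.number_of_edges()
    deg = dict(graph.degree())
    if degree_norm == "n-1":
        denom = max(n - 1, 1)
    else:
        denom = max(2 * m, 1)
    btw = nx.betweenness_centrality(graph, normalized=False)
    return pd.DataFrame(
        {
            "taxon_id": list(graph.nodes),
            "degree": [deg[v] for v in graph.nodes],
            "normalised_degree": [deg[v] / denom for v in graph.nodes],
            "betweenness": [btw[v] for v in graph.nodes],
        }
    ).set_index("taxon_id", drop=False)


def transitivity(graph: nx.Graph) -> float:
    """Global clustering coefficient: 3 * triangles / connected triples."""
    return float(nx.transitivity(graph))


# -- Girvan-Newman modules -------------------------------------------------

@dataclass
class ModuleResult:
    membership: dict
    modularity_Q: float
    n_modules: int


def _partition_of(graph: nx.Graph) -> list[set]:
    return [set(c) for c in nx.connected_components(graph)]


def detect_modules(graph: nx.Graph, method: str = "auto", max_exact_edges: int = 2000) -> ModuleResult:
    """Edge-betweenness (Girvan-Newman) divisive module detection.

    Iteratively removes the edge of highest edge-betweenness (ties broken by
    lexicographically smallest edge), recording the component partition each
    time it refines; returns the nested partition maximising Newman-Girvan
    modularity Q (ties -> fewer modules). Above ``max_exact_edges`` edges the
    C implementation in igraph is used instead (same divisive algorithm).
    """
    n = graph.number_of_nodes()
    if n == 0:
        return ModuleResult({}, 0.0, 0)
    if graph.number_of_edges() == 0:
        return ModuleResult({v: i for i, v in enumerate(graph.nodes)}, 0.0, n)
    if method == "auto":
        method = "exact" if graph.number_of_edges() <= max_exact_edges else "igraph"
    if method == "igraph":
        return _detect_modules_igraph(graph)

    work = graph.copy()
    best_partition = _partition_of(work)
    best_q = nx.community.modularity(graph, best_partition)
    best_k = len(best_partition)
    n_comp = best_k
    while work.number_of_edges() > 0:
        eb = nx.edge_betweenness_centrality(work, normalized=False)
        max_val = max(eb.values())
        candidates = sorted(
            tuple(sorted(e)) for e, v in eb.items() if v >= max_val - 1e-9
        )
        work.remove_edge(*candidates[0])
        parts = _partition_of(work)
        if len(parts) > n_comp:
            n_comp = len(parts)
            q = nx.community.modularity(graph, parts)
            if q > best_q + 1e-12 or (abs(q - best_q) <= 1e-12 and len(parts) < best_k):
                best_q, best_partition, best_k = q, parts, len(parts)
    membership = {}
    for i, part in enumerate(sorted(best_partition, key=lambda s: sorted(s)[0])):
        for v in part:
            membership[v] = i
    return ModuleResult(membership, float(best_q), len(best_partition))


def _detect_modules_igraph(graph: nx.Graph) -> ModuleResult:
    import igraph as ig

    nodes = list(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in graph.edges]
    g = ig.Graph(n=len(nodes), edges=edges)
    dendro = g.community_edge_betweenness(directed=False)
    clustering = dendro.as_clustering()
    membership = {v: clustering.membership[index[v]] for v in nodes}
    parts: dict[int, set] = {}
    for v, mod in membership.items():
        parts.setdefault(mod, set()).add(v)
    q = nx.community.modularity(graph, list(parts.values()))
    return ModuleResult(membership, float(q), len(parts))


# -- random-graph null -----------------------------------------------------

@dataclass
class NullModelResult:
    ensemble_size: int
    observed_clustering: float
    null_mean: float
    null_sd: float
    empirical_p: float


def random_network_null(graph: nx.Graph, ensemble: int = 1000, seed: int = 0) -> NullModelResult:
    """Compare observed transitivity with uniform G(n,m) random graphs.

    Each null graph has exactly the observed node and edge counts;
    empirical_p = (1 + #{null clustering >= observed}) / (1 + ensemble).
    """
    n = graph.number_of_nodes()
    m = graph.number_of_edges()
    if n == 0 or m == 0:
        raise ValueError("null model needs a non-empty network")
    obs = transitivity(graph)
    rng = np.random.default_rng(seed)
    null = np.empty(ensemble)
    for i in range(ensemble):
        g = nx.gnm_random_graph(n, m, seed=int(rng.integers(2 ** 31)))
        null[i] = nx.transitivity(g)
    p = (1.0 + np.sum(null >= obs - 1e-12)) / (1.0 + ensemble)
    return NullModelResult(ensemble, obs, float(null.mean()), float(null.std(ddof=1)), float(p))


# -- summaries -------------------------------------------------------------

def membership_overlap(graph_a: nx.Graph, graph_b: nx.Graph) -> float:
    """Jaccard index of the two node-id sets."""
    a, b = set(graph_a.nodes), set(graph_b.nodes)
    if not a and not b:
        logger.warning("membership_overlap: both networks empty; returning 0")
        return 0.0
    return len(a & b) / len(a | b)


def network_summary(graph: nx.Graph, eligible_taxa: int) -> dict:
    """Node/edge counts, inclusion proportion, transitivity, Q and density."""
    if eligible_taxa <= 0:
        raise ValueError("eligible_taxa must be positive")
    n = graph.number_of_nodes()
    m = graph.number_of_edges()
    mod = detect_modules(graph) if m else ModuleResult({}, 0.0, 0)
    return {
        "nodes": n,
        "edges": m,
        "inclusion_proportion": n / eligible_taxa,
        "clustering_coefficient": transitivity(graph),
        "modularity_Q": mod.modularity_Q,
        "n_modules": mod.n_modules,
        "density": nx.density(graph) if n > 1 else 0.0,
    }


# -- fast array-level helpers (large presets) ------------------------------

def edge_arrays(cset: CorrelationSet, rho_min: float = 0.6, p_max: float = 0.01):
    """Array view of the thresholded sets for large networks.

    Returns (pos_i, pos_j, neg_count, pos_count) where pos_i/pos_j index the
    positive-edge pairs in ``cset.taxon_ids`` order.
    """
    iu, ju = np.triu_indices(len(cset.taxon_ids), k=1)
    rho = cset.rho[iu, ju]
    p = cset.p[iu, ju]
    sig = (np.abs(rho) > rho_min) & (p < p_max)
    pos = sig & (rho > 0)
    neg = sig & (rho < 0)
    return iu[pos], ju[pos], int(neg.sum()), int(pos.sum())


def fast_network_stats(cset: CorrelationSet, rho_min: float = 0.6, p_max: float = 0.01) -> dict:
    """Inclusion, mean normalised degree, transitivity and negative share
    computed directly from arrays (no networkx graph), for large presets."""
    t = len(cset.taxon_ids)
    pos_i, pos_j, n_neg, n_pos = edge_arrays(cset, rho_min, p_max)
    deg = np.bincount(pos_i, minlength=t) + np.bincount(pos_j, minlength=t)
    in_net = deg > 0
    n_nodes = int(in_net.sum())
    if n_nodes > 1:
        a = sparse.coo_matrix(
            (np.ones(len(pos_i)), (pos_i, pos_j)), shape=(t, t)
        ).tocsr()
        a = a + a.T
        tri = (a @ a).multiply(a).sum() / 6.0
        triples = float(np.sum(deg * (deg - 1)) / 2.0)
        trans = 3.0 * tri / triples if triples > 0 else 0.0
        mean_norm_deg = float(deg[in_net].mean() / (n_nodes - 1))
    else:
        trans = 0.0
        mean_norm_deg = 0.0
    rho_all, _ = cset.triu_values()
    return {
        "nodes": n_nodes,
        "edges": n_pos,
        "inclusion_proportion": n_nodes / t,
        "mean_normalised_degree": mean_norm_deg,
        "clustering_coefficient": float(trans),
        "mean_abs_rho": float(np.abs(rho_all).mean()),
        "negative_significant": n_neg,
        "positive_significant": n_pos,
        "prop_negative_significant": n_neg / (n_neg + n_pos) if (n_neg + n_pos) else np.nan,
    }
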