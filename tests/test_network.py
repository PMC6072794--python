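import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import conetstab as cs
from conetstab.network import (
    CorrelationSet,
    detect_modules,
    edge_arrays,
    fast_network_stats,
    membership_overlap,
    node_metrics,
    random_network_null,
    spearman_matrix,
    threshold_network,
    transitivity,
)
from conetstab.otu import OtuTable

from conftest import random_table


# -- independent oracles ----------------------------------------------------

def betweenness_oracle(g: nx.Graph) -> dict:
    """Unnormalised betweenness via adjacency-matrix powers (path counts)."""
    nodes = list(g.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    a = nx.to_numpy_array(g, nodelist=nodes)
    # sigma[d] = number of shortest paths when distance is d
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0)
    sigma = np.eye(n)
    power = np.eye(n)
    for d in range(1, n):
        power = power @ a
        newly = (dist == np.inf) & (power > 0)
        dist[newly] = d
        sigma = np.where(newly, power, sigma)
    b = dict.fromkeys(nodes, 0.0)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(dist[s, t]):
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if dist[s, v] + dist[v, t] == dist[s, t]:
                    b[nodes[v]] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return b


def transitivity_oracle(g: nx.Graph) -> float:
    a = nx.to_numpy_array(g)
    triangles = np.trace(a @ a @ a) / 6.0
    deg = a.sum(axis=1)
    triples = (deg * (deg - 1) / 2).sum()
    return 3.0 * triangles / triples if triples > 0 else 0.0


def modularity_oracle(g: nx.Graph, parts) -> float:
    m = g.number_of_edges()
    q = 0.0
    for part in parts:
        within = sum(1 for u, v in g.edges if u in part and v in part)
        deg = sum(d for _, d in g.degree(part))
        q += within / m - (deg / (2 * m)) ** 2
    return q


def best_partition_exhaustive(g: nx.Graph) -> float:
    """Max modularity over every partition of the node set (Bell-number scan)."""
    nodes = list(g.nodes)

    def partitions(seq):
        if not seq:
            yield []
            return
        first, rest = seq[0], seq[1:]
        for smaller in partitions(rest):
            for i, subset in enumerate(smaller):
                yield smaller[:i] + [subset | {first}] + smaller[i + 1:]
            yield [{first}] + smaller

    return max(modularity_oracle(g, p) for p in partitions(nodes))


# -- Spearman ----------------------------------------------------------------

def _table(cols, index=None):
    return OtuTable(pd.DataFrame(cols, index=index or [f"t{i}" for i in range(len(next(iter(cols.values()))))]))


class TestSpearman:
    def test_monotone_pairs(self):
        t = _table({f"S{i}": [i + 1, 10 + 2 * i, 9 - i] for i in range(5)})
        cset = spearman_matrix(t)
        i, j, k = [cset.taxon_ids.index(x) for x in ("t0", "t1", "t2")]
        assert cset.rho[i, j] == pytest.approx(1.0)
        assert cset.rho[i, k] == pytest.approx(-1.0)
        assert cset.p[i, j] == np.finfo(float).tiny

    def test_mid_rank_ties_match_pearson_on_ranks_oracle(self):
        x = np.array([1, 2, 2, 4], dtype=float)
        y = np.array([2, 1, 3, 4], dtype=float)
        t = _table({f"S{i}": [int(x[i]), int(y[i])] for i in range(4)})
        cset = spearman_matrix(t)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert cset.rho[0, 1] == pytest.approx(oracle, abs=1e-12)
        # and agrees with scipy's own implementation
        assert cset.rho[0, 1] == pytest.approx(stats.spearmanr(x, y).statistic, abs=1e-12)

    def test_t_approximation_p_matches_scipy(self):
        rng = np.random.default_rng(0)
        t = random_table(rng, n_taxa=6, n_samples=20, depth=400)
        cset = spearman_matrix(t)
        x = t.counts.loc[cset.taxon_ids].to_numpy()
        for i, j in itertools.combinations(range(len(cset.taxon_ids)), 2):
            ref = stats.spearmanr(x[i], x[j])
            assert cset.rho[i, j] == pytest.approx(ref.statistic, abs=1e-10)
            if abs(ref.statistic) < 1:
                assert cset.p[i, j] == pytest.approx(ref.pvalue, rel=1e-8)

    def test_constant_taxon_excluded(self):
        t = _table({f"S{i}": [7, i, 2 * i] for i in range(6)})
        cset = spearman_matrix(t)
        assert cset.excluded_taxa == ["t0"]
        assert "t0" not in cset.taxon_ids

    @given(st.integers(0, 10 ** 6))
    def test_invariant_to_strictly_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        t = random_table(rng, n_taxa=4, n_samples=10, depth=300)
        cset1 = spearman_matrix(t)
        transformed = t.counts.loc[cset1.taxon_ids].astype(float)
        transformed.iloc[0] = np.exp(transformed.iloc[0] / 50.0)
        transformed.iloc[1] = transformed.iloc[1] ** 3
        cset2 = CorrelationSet(
            cset1.taxon_ids,
            np.corrcoef(stats.rankdata(transformed.to_numpy(), axis=1)),
            cset1.p, cset1.n_samples,
        )
        np.testing.assert_allclose(cset1.rho, cset2.rho, atol=1e-10)


# -- thresholding -------------------------------------------------------------

def _cset(pairs, ids=("a", "b", "c")):
    n = len(ids)
    rho = np.eye(n)
    p = np.ones((n, n)) * 1e-12
    for (i, j), (r, pv) in pairs.items():
        rho[i, j] = rho[j, i] = r
        p[i, j] = p[j, i] = pv
    return CorrelationSet(list(ids), rho, p, n_samples=36)


class TestThreshold:
    def test_rule_gates(self):
        cset = _cset({(0, 1): (0.7, 0.001), (0, 2): (0.7, 0.02), (1, 2): (-0.9, 1e-6)})
        g, signed = threshold_network(cset, rho_min=0.6, p_max=0.01)
        assert set(g.edges) == {("a", "b")}
        # negative pair excluded from the network but kept in the signed set
        assert set(map(tuple, signed[["taxon_a", "taxon_b"]].to_numpy())) == {
            ("a", "b"), ("b", "c")
        }
        assert "c" not in g.nodes  # isolated node dropped

    def test_edge_set_monotone_in_thresholds(self):
        rng = np.random.default_rng(6)
        t = random_table(rng, n_taxa=15, n_samples=12, depth=500)
        cset = spearman_matrix(t)
        loose, _ = threshold_network(cset, rho_min=0.3, p_max=0.2)
        tight, _ = threshold_network(cset, rho_min=0.5, p_max=0.05)
        canon = lambda g: {frozenset(e) for e in g.edges}
        assert canon(tight).issubset(canon(loose))

    def test_bh_adjustment_prunes_borderline_edges(self):
        rng = np.random.default_rng(14)
        t = random_table(rng, n_taxa=20, n_samples=10, depth=500)
        cset = spearman_matrix(t)
        raw, _ = threshold_network(cset, rho_min=0.3, p_max=0.1)
        bh, _ = threshold_network(cset, rho_min=0.3, p_max=0.1, bh_correct=True)
        canon = lambda g: {frozenset(e) for e in g.edges}
        assert canon(bh).issubset(canon(raw))

    def test_empty_network_warned_not_fatal(self):
        cset = _cset({(0, 1): (0.1, 0.9)})
        g, signed = threshold_network(cset)
        assert g.number_of_edges() == 0 and len(signed) == 0


# -- node metrics ------------------------------------------------------------

class TestNodeMetrics:
    def test_path_graph_closed_form(self):
        g = nx.path_graph(["A", "B", "C"])
        nm = node_metrics(g)
        assert list(nm["betweenness"]) == [0, 1, 0]
        np.testing.assert_allclose(nm["normalised_degree"], [0.5, 1.0, 0.5])

    def test_complete_graph(self):
        g = nx.complete_graph(4)
        nm = node_metrics(g)
        assert (nm["betweenness"] == 0).all()
        assert (nm["normalised_degree"] == 1.0).all()
        assert transitivity(g) == pytest.approx(1.0)

    def test_edges_normalisation_variant(self):
        g = nx.path_graph(3)
        nm = node_metrics(g, degree_norm="edges")
        np.testing.assert_allclose(nm["normalised_degree"], [0.25, 0.5, 0.25])

    def test_betweenness_matches_path_count_oracle_on_random_graphs(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            m = int(rng.integers(9, 19))
            g = nx.gnm_random_graph(10, m, seed=int(rng.integers(2 ** 31)))
            nm = node_metrics(g)
            oracle = betweenness_oracle(g)
            for v in g.nodes:
                assert nm.loc[v, "betweenness"] == pytest.approx(oracle[v], abs=1e-9)
            assert transitivity(g) == pytest.approx(transitivity_oracle(g), abs=1e-12)


# -- modules ------------------------------------------------------------------

def two_triangles_bridge() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])
    return g


class TestModules:
    def test_two_triangle_bridge_hand_value(self):
        g = two_triangles_bridge()
        mod = detect_modules(g)
        assert mod.modularity_Q == pytest.approx(6 / 7 - 0.5, abs=1e-9)
        groups = {}
        for v, c in mod.membership.items():
            groups.setdefault(c, set()).add(v)
        assert sorted(map(sorted, groups.values())) == [[0, 1, 2], [3, 4, 5]]
        # the two-module split is also the exhaustive optimum
        assert mod.modularity_Q == pytest.approx(best_partition_exhaustive(g), abs=1e-9)

    def test_disconnected_components_each_a_module(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (0, 2), (10, 11), (11, 12), (10, 12)])
        mod = detect_modules(g)
        assert mod.n_modules == 2
        assert mod.membership[0] == mod.membership[1] == mod.membership[2]
        assert mod.membership[0] != mod.membership[10]

    def test_single_clique_q_zero(self):
        mod = detect_modules(nx.complete_graph(5))
        assert mod.modularity_Q == pytest.approx(0.0, abs=1e-12)
        assert mod.n_modules == 1

    def test_planted_sbm_recovered_exactly(self):
        rng = np.random.default_rng(12)
        sizes = [6, 6, 6]
        g = nx.stochastic_block_model(sizes, [[0.95, 0.04, 0.04],
                                              [0.04, 0.95, 0.04],
                                              [0.04, 0.04, 0.95]], seed=5)
        mod = detect_modules(g)
        planted = {v: v // 6 for v in g.nodes}
        mapping = {}
        for v in g.nodes:
            mapping.setdefault(mod.membership[v], set()).add(planted[v])
        assert mod.n_modules == 3
        assert all(len(s) == 1 for s in mapping.values())

    def test_igraph_path_agrees_on_bridge_graph(self):
        g = two_triangles_bridge()
        exact = detect_modules(g, method="exact")
        fast = detect_modules(g, method="igraph")
        assert fast.modularity_Q == pytest.approx(exact.modularity_Q, abs=1e-9)


# -- nulls and summaries ------------------------------------------------------

class TestNullModel:
    def test_null_graphs_preserve_n_m_and_density_expectation(self):
        g = nx.gnm_random_graph(40, 120, seed=1)
        res = random_network_null(g, ensemble=300, seed=2)
        assert res.ensemble_size == 300
        # G(n,m) expected clustering ~ density = 2m/(n(n-1))
        density = 2 * 120 / (40 * 39)
        assert abs(res.null_mean - density) < 3 * res.null_sd / np.sqrt(300) + 0.01

    def test_union_of_cliques_has_minimal_p(self):
        g = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(6))
        g = nx.disjoint_union(g, nx.complete_graph(5))
        res = random_network_null(g, ensemble=199, seed=3)
        assert res.observed_clustering == pytest.approx(1.0)
        assert res.empirical_p == pytest.approx(1 / 200)


class TestSummaries:
    def test_membership_overlap_values(self):
        def graph_of(nodes):
            g = nx.Graph()
            g.add_nodes_from(nodes)
            return g

        a = graph_of(range(1, 11))
        assert membership_overlap(a, graph_of(range(1, 11))) == 1.0
        assert membership_overlap(a, graph_of(range(20, 25))) == 0.0
        assert membership_overlap(a, graph_of(range(6, 16))) == pytest.approx(5 / 15)
        assert membership_overlap(nx.Graph(), nx.Graph()) == 0.0

    def test_network_summary_inclusion(self):
        g = nx.gnm_random_graph(40, 60, seed=0)
        s = cs.network_summary(g, eligible_taxa=100)
        assert s["inclusion_proportion"] == pytest.approx(0.40)
        with pytest.raises(ValueError):
            cs.network_summary(g, eligible_taxa=0)

    def test_fast_stats_agree_with_graph_route(self):
        rng = np.random.default_rng(10)
        t = random_table(rng, n_taxa=30, n_samples=14, depth=800)
        cset = spearman_matrix(t)
        g, signed = threshold_network(cset, rho_min=0.4, p_max=0.1)
        fast = fast_network_stats(cset, rho_min=0.4, p_max=0.1)
        assert fast["nodes"] == g.number_of_nodes()
        assert fast["edges"] == g.number_of_edges()
        if g.number_of_edges():
            assert fast["clustering_coefficient"] == pytest.approx(transitivity(g), abs=1e-12)
            nm = node_metrics(g)
            assert fast["mean_normalised_degree"] == pytest.approx(
                nm["normalised_degree"].mean(), abs=1e-12
            )

    def test_denser_couplings_increase_inclusion(self):
        incl = {}
        for name, part in (("sparse", 0.2), ("dense", 0.6)):
            cfg = cs.preset(
                "strong_coupling", participation=part, neg_frac=0.0,
                treatments=("control",), samplings=("pre_drought",),
            )
            t, _, _ = cs.generate(cfg, seed=21)
            t2 = cs.prevalence_filter(t)
            stats_ = fast_network_stats(spearman_matrix(t2))
            incl[name] = stats_["inclusion_proportion"]
        assert incl["dense"] > incl["sparse"]
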