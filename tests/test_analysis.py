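"""Network statistics against brute-force oracles and analytic cases."""

import math
import warnings

import networkx as nx
import numpy as np
import pytest

from conftest import random_graph
from ddinet.analysis import (
    assortativity_r,
    centrality_components,
    centrality_report,
    correlation_profile,
    degree_distribution,
    disorder_summary,
    ivi,
    knn_by_degree,
    mean_degree_by_strain,
    pearson,
    randomize_preserving_degrees,
    remaining_degree_distributions,
)
from ddinet.core import Protein, ProteinCatalog
from ddinet.network import network_from_edges


# ---------------------------------------------------------------- oracles

def brute_betweenness(g):
    """Independent shortest-path-count betweenness over unordered pairs."""
    nodes = list(g.nodes)
    dist = dict(nx.all_pairs_shortest_path_length(g))
    sigma = {}
    for m in nodes:
        for n in nodes:
            if n in dist.get(m, {}):
                sigma[(m, n)] = _count_paths(g, m, n, dist[m])
    bc = {}
    for i in nodes:
        total = 0.0
        for mi, m in enumerate(nodes):
            for n in nodes[mi + 1:]:
                if m == i or n == i or n not in dist.get(m, {}):
                    continue
                if i in dist[m] and n in dist[i] and \
                        dist[m][i] + dist[i][n] == dist[m][n]:
                    total += sigma[(m, i)] * sigma[(i, n)] / sigma[(m, n)]
        bc[i] = total
    return bc


def _count_paths(g, m, n, dist_m):
    if m == n:
        return 1
    # DP over BFS layers: paths(v) = sum of paths(u) for predecessors u
    counts = {m: 1}
    order = sorted((v for v in dist_m if dist_m[v] <= dist_m[n]),
                   key=lambda v: dist_m[v])
    for v in order:
        if v == m:
            continue
        counts[v] = sum(counts.get(u, 0) for u in g.neighbors(v)
                        if dist_m.get(u, -1) == dist_m[v] - 1)
    return counts[n]


def brute_assortativity(g):
    """Definitional double sum over the joint remaining-degree distribution,
    built here from scratch: r = sum_jk jk (e_jk - q_j q_k) / sigma_q^2."""
    deg = dict(g.degree())
    m2 = 2 * g.number_of_edges()
    q, e = {}, {}
    for u, v in g.edges():
        ju, jv = deg[u] - 1, deg[v] - 1
        q[ju] = q.get(ju, 0.0) + 1.0 / m2
        q[jv] = q.get(jv, 0.0) + 1.0 / m2
        e[(ju, jv)] = e.get((ju, jv), 0.0) + 1.0 / m2
        e[(jv, ju)] = e.get((jv, ju), 0.0) + 1.0 / m2
    mean_q = sum(k * p for k, p in q.items())
    var_q = sum(k * k * p for k, p in q.items()) - mean_q ** 2
    if var_q < 1e-300:
        return None
    total = 0.0
    for (j, k), ejk in e.items():
        total += j * k * ejk
    total -= mean_q ** 2
    return total / var_q


def brute_knn(g):
    deg = dict(g.degree())
    acc = {}
    for i in g.nodes:
        if deg[i] == 0:
            continue
        knn_i = np.mean([deg[j] for j in g.neighbors(i)])
        acc.setdefault(deg[i], []).append(knn_i)
    return {k: float(np.mean(v)) for k, v in acc.items()}


# ------------------------------------------------------------ centralities

class TestCentralityComponents:
    def test_star_graph_hand_values(self):
        g = nx.star_graph(3)  # center 0 + three leaves
        rep = centrality_components(g, ell=1)
        assert rep.loc[0, "degree"] == 3 and rep.loc[1, "degree"] == 1
        assert (rep["h_index"] == 1).all()
        assert rep.loc[0, "neighborhood_connectivity"] == 1
        assert rep.loc[1, "neighborhood_connectivity"] == 3
        assert rep.loc[0, "betweenness"] == 3 and rep.loc[1, "betweenness"] == 0
        # no triangles -> f(c)=1; CR(center)=sum(k_leaf+1)=6, CR(leaf)=4
        assert rep.loc[0, "cluster_rank"] == 6 and rep.loc[1, "cluster_rank"] == 4
        assert (rep["collective_influence"] == 0).all()
        assert rep.loc[0, "lh_sum"] == 3 and rep.loc[1, "lh_sum"] == 1

    def test_complete_graph_is_vertex_transitive(self):
        rep = centrality_components(nx.complete_graph(5))
        for col in rep.columns:
            assert rep[col].nunique() == 1

    def test_betweenness_matches_brute_force(self):
        rng = np.random.default_rng(10)
        for _ in range(12):
            g = random_graph(rng, int(rng.integers(6, 25)), 0.2)
            rep = centrality_components(g, ell=2)
            oracle = brute_betweenness(g)
            for node in g.nodes:
                assert rep.loc[node, "betweenness"] == pytest.approx(
                    oracle[node], abs=1e-9)

    def test_collective_influence_shell_definition(self):
        g = nx.path_graph(6)  # 0-1-2-3-4-5
        rep = centrality_components(g, ell=2)
        # node 2: k=2; shell at distance exactly 2 = {0, 4}, degrees 1 and 2
        assert rep.loc[2, "collective_influence"] == (2 - 1) * ((1 - 1) + (2 - 1))

    def test_ell_capped_at_eccentricity(self):
        g = nx.path_graph(3)
        rep = centrality_components(g, ell=10)
        # center eccentricity 1: shell = both leaves (degree 1 each)
        assert rep.loc[1, "collective_influence"] == (2 - 1) * 0
        # leaf eccentricity 2: shell = far leaf
        assert rep.loc[0, "collective_influence"] == 0  # k-1 = 0

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            centrality_components(nx.Graph())


class TestIVI:
    def test_vertex_transitive_graphs_constant(self):
        for g in (nx.cycle_graph(8), nx.complete_graph(6)):
            scores = ivi(centrality_components(g))
            assert scores.nunique() == 1

    def test_max_is_exactly_100_on_non_regular_graphs(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            g = random_graph(rng, 20, 0.2)
            degs = {d for _, d in g.degree()}
            if len(degs) < 2:
                continue
            scores = ivi(centrality_components(g))
            assert scores.max() == pytest.approx(100.0)
            assert scores.min() >= 1.0

    def test_node_relabeling_permutes_scores(self):
        rng = np.random.default_rng(12)
        g = random_graph(rng, 15, 0.25)
        mapping = dict(zip(g.nodes, rng.permutation(list(g.nodes))))
        h = nx.relabel_nodes(g, mapping)
        s_g = ivi(centrality_components(g))
        s_h = ivi(centrality_components(h))
        for node in g.nodes:
            assert s_h[mapping[node]] == pytest.approx(s_g[node], rel=1e-12)

    def test_star_center_is_unique_maximum(self):
        rep = centrality_components(nx.star_graph(7))
        scores = ivi(rep)
        assert scores.idxmax() == 0
        assert scores.drop(0).max() < scores[0]

    def test_single_node_scores_one(self):
        g = nx.Graph()
        g.add_node("only")
        assert centrality_report(g)["ivi"]["only"] == 1.0


# ------------------------------------------------------- degree statistics

class TestAssortativity:
    def test_star_is_perfectly_disassortative(self):
        for n in (3, 5, 10):
            assert assortativity_r(nx.star_graph(n)) == pytest.approx(-1.0)

    def test_regular_graphs_return_undefined_sentinel(self):
        assert assortativity_r(nx.cycle_graph(6)) is None
        assert assortativity_r(nx.complete_graph(5)) is None

    def test_matches_definitional_double_sum(self):
        rng = np.random.default_rng(13)
        checked = 0
        while checked < 25:
            g = random_graph(rng, int(rng.integers(8, 50)), 0.15)
            if g.number_of_edges() == 0:
                continue
            expected = brute_assortativity(g)
            got = assortativity_r(g)
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected, abs=1e-9)
            checked += 1

    def test_remaining_degree_normalizations(self):
        rng = np.random.default_rng(14)
        for _ in range(10):
            g = random_graph(rng, 30, 0.15)
            if g.number_of_edges() == 0:
                continue
            q, e = remaining_degree_distributions(g)
            assert sum(q.values()) == pytest.approx(1.0, abs=1e-12)
            assert sum(e.values()) == pytest.approx(1.0, abs=1e-12)
            for k in q:  # marginal consistency: sum_j e_jk = q_k
                assert sum(v for (j, kk), v in e.items() if kk == k) \
                    == pytest.approx(q[k], abs=1e-12)

    def test_edgeless_graph_rejected(self):
        g = nx.Graph()
        g.add_nodes_from([1, 2])
        with pytest.raises(ValueError):
            assortativity_r(g)


class TestDegreeDistribution:
    def test_star_counts(self):
        pk = degree_distribution(nx.star_graph(3))
        assert pk == {1: pytest.approx(0.75), 3: pytest.approx(0.25)}

    def test_regular_graph_single_mass(self):
        assert degree_distribution(nx.cycle_graph(7)) == {2: pytest.approx(1.0)}

    def test_normalization_on_random_graphs(self):
        rng = np.random.default_rng(15)
        for _ in range(10):
            g = random_graph(rng, 40, 0.1)
            assert sum(degree_distribution(g).values()) == pytest.approx(1.0, abs=1e-12)


class TestKnn:
    def test_star_and_complete(self):
        knn = knn_by_degree(nx.star_graph(3))
        assert knn == {1: pytest.approx(3.0), 3: pytest.approx(1.0)}
        assert knn_by_degree(nx.complete_graph(4)) == {3: pytest.approx(3.0)}

    def test_matches_brute_force(self):
        rng = np.random.default_rng(16)
        for _ in range(15):
            g = random_graph(rng, int(rng.integers(5, 50)), 0.2)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                got = knn_by_degree(g)
            expected = brute_knn(g)
            assert set(got) == set(expected)
            for k in got:
                assert got[k] == pytest.approx(expected[k], abs=1e-9)


# --------------------------------------------------------------- null model

class TestRandomization:
    def test_degree_sequence_exactly_preserved(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            g = random_graph(rng, 30, 0.15)
            if g.number_of_edges() < 2:
                continue
            gr = randomize_preserving_degrees(g, seed=int(rng.integers(2**31)))
            assert dict(gr.degree()) == dict(g.degree())

    def test_same_seed_identical_output(self):
        rng = np.random.default_rng(18)
        g = random_graph(rng, 25, 0.2)
        g1 = randomize_preserving_degrees(g, seed=5)
        g2 = randomize_preserving_degrees(g, seed=5)
        assert set(g1.edges()) == set(g2.edges())

    def test_rewiring_actually_moves_edges(self):
        rng = np.random.default_rng(19)
        g = random_graph(rng, 100, 0.06)
        overlaps = []
        for seed in range(5):
            gr = randomize_preserving_degrees(g, seed=seed)
            inter = set(map(frozenset, gr.edges())) & set(map(frozenset, g.edges()))
            overlaps.append(len(inter) / g.number_of_edges())
        assert min(overlaps) < 1.0

    def test_bipartite_structure_preserved(self, small_world):
        left = [f"L{i}" for i in range(12)]
        right = [f"R{i}" for i in range(10)]
        rng = np.random.default_rng(20)
        g = nx.Graph()
        for n in left:
            g.add_node(n, side="host")
        for n in right:
            g.add_node(n, side="bacterial")
        for l in left:
            for r in right:
                if rng.random() < 0.3:
                    g.add_edge(l, r)
        gr = randomize_preserving_degrees(g, seed=3)
        assert dict(gr.degree()) == dict(g.degree())
        for u, v in gr.edges():
            assert {gr.nodes[u]["side"], gr.nodes[v]["side"]} == {"host", "bacterial"}

    def test_unswappable_graph_returned_with_warning(self):
        g = nx.Graph([(1, 2)])
        with pytest.warns(UserWarning):
            gr = randomize_preserving_degrees(g, seed=0)
        assert set(gr.edges()) == {(1, 2)}


class TestCorrelationProfile:
    def test_z_symmetric_and_deterministic(self):
        rng = np.random.default_rng(21)
        g = random_graph(rng, 40, 0.12)
        p1 = correlation_profile(g, n_rand=30, seed=2)
        p2 = correlation_profile(g, n_rand=30, seed=2)
        assert p1.z == p2.z
        for (b1, b2), z in p1.z.items():
            assert p1.z[(b2, b1)] == pytest.approx(z, abs=1e-12)

    def test_profile_separates_structured_from_randomized_graphs(self):
        """A graph with strong degree-degree structure (barbell: cliques
        bridged by a path) shows a far louder z-profile than its own
        degree-preserving randomization scored against the same kind of
        ensemble; the standardized self-null residuals stay near the
        |Z| ~ 0.8 level expected of a typical ensemble draw."""
        g = nx.barbell_graph(8, 12)
        structured = correlation_profile(g, n_rand=100, seed=3)
        g_rand = randomize_preserving_degrees(g, seed=5)
        null = correlation_profile(g_rand, n_rand=100, seed=3)
        assert structured.mean_abs_z() > 2.0
        assert null.mean_abs_z() < 1.5
        assert null.mean_abs_z() < structured.mean_abs_z() / 2

    def test_zero_variance_bins_reported_missing_not_infinite(self):
        g = nx.star_graph(4)  # all randomizations identical
        profile = correlation_profile(g, n_rand=10, seed=0)
        assert profile.z == {}
        assert profile.missing  # bins exist but carry no variance
        assert all(np.isfinite(v) for v in profile.z.values())


# ------------------------------------------------------------ correlations

class TestPearson:
    def test_exact_linear_relations(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson(x, [2 * v for v in x]) == pytest.approx(1.0)
        assert pearson(x, [-v + 4 for v in x]) == pytest.approx(-1.0)

    def test_matches_definitional_formula(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            x, y = rng.random(50), rng.random(50)
            expected = float(np.cov(x, y, bias=True)[0, 1] / (x.std() * y.std()))
            assert pearson(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_sentinel_and_length_guard(self):
        assert pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]) is None
        with pytest.raises(ValueError):
            pearson([1.0, 2.0], [1.0, 2.0])


class TestStrainDegrees:
    def catalog(self):
        return ProteinCatalog([
            Protein("H1", "human", ("PF1",)), Protein("H2", "human", ("PF2",)),
            Protein("H3", "human", ("PF3",)),
            Protein("B1", "s1", ("PF4",)), Protein("B2", "s1", ("PF5",)),
            Protein("B3", "s2", ("PF6",)),
        ])

    def test_mean_degree_per_strain(self):
        net = network_from_edges(
            [("B1", "H1", 0.99), ("B1", "H2", 0.99), ("B2", "H1", 0.99),
             ("B2", "H2", 0.99), ("B2", "H3", 0.99), ("B2", "H3", 0.99)][:5],
            self.catalog())
        table, r = mean_degree_by_strain(net, self.catalog(),
                                         {"s1": 0.6, "s2": 0.4})
        with_b1 = table.set_index("strain")
        assert with_b1.loc["s1", "mean_degree"] == pytest.approx((2 + 3) / 2)
        # s2 has no network protein -> omitted; < 3 strains -> r undefined
        assert "s2" not in with_b1.index and r is None

    def test_unknown_strain_raises(self):
        net = network_from_edges([("B3", "H1", 0.99)], self.catalog())
        with pytest.raises(ValueError, match="s2"):
            mean_degree_by_strain(net, self.catalog(), {"s1": 1.0})


class TestDisorderSummary:
    def test_any_disorder_fraction(self):
        table = {"a": 0.0, "b": 0.1, "c": 0.5}
        sides = {k: "host" for k in table}
        curve = disorder_summary(table, sides).set_index("threshold")["fraction"]
        assert curve.loc[0.0] == pytest.approx(2 / 3)
        assert curve.loc[0.5] == pytest.approx(1 / 3)

    def test_all_zero_curve(self):
        curve = disorder_summary({"a": 0.0, "b": 0.0}, {"a": "host", "b": "host"})
        assert (curve["fraction"] == 0).all()

    def test_monotone_nonincreasing_on_random_tables(self):
        rng = np.random.default_rng(24)
        table = {f"p{i}": float(v) for i, v in enumerate(rng.random(100))}
        sides = {k: ("host" if i % 2 else "bacterial")
                 for i, k in enumerate(table)}
        df = disorder_summary(table, sides)
        for _, sub in df.groupby("side"):
            fr = sub.sort_values("threshold")["fraction"].to_numpy()
            assert np.all(np.diff(fr) <= 1e-12)

    def test_out_of_range_values_rejected(self):
        with pytest.raises(ValueError):
            disorder_summary({"a": 1.5}, {"a": "host"})
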