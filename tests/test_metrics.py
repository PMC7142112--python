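"""Clustering, efficiency, small-worldness, modularity, rich clubs, heavy tails."""

import itertools

import networkx as nx
import numpy as np
import pytest

from rewirenet import (
    NullEnsembleConfig,
    WeightedGraph,
    assortativity,
    clustering_coefficient,
    compute_metrics,
    degree_preserving_null,
    efficiency,
    fit_heavy_tail,
    modularity_spectral,
    modularity_value,
    outlier_proportion,
    rich_club_curve,
    rich_club_normalized,
    rich_club_topological,
    rich_club_weighted,
    rich_club_weighted_normalized,
    shuffle_weights,
    small_worldness,
)

from conftest import graph_from_edges, random_weighted_graph


def to_networkx(g):
    G = nx.from_numpy_array(g.adjacency)
    return G


class TestClustering:
    def test_binary_triangle_and_star(self, triangle_binary, star5):
        assert clustering_coefficient(triangle_binary) == pytest.approx(1.0)
        assert clustering_coefficient(star5) == pytest.approx(0.0)

    def test_weighted_triangle_geometric_mean(self):
        # per-node Onnela value on max-normalized weights, by direct enumeration
        g = graph_from_edges(3, [(0, 1, 1.0), (1, 2, 1.0), (0, 2, 0.5)])
        w = np.array([1.0, 1.0, 0.5])
        expected = (np.prod(w) ** (1 / 3))  # same for every node here
        assert clustering_coefficient(g) == pytest.approx(expected)

    def test_matches_networkx_onnela(self):
        g = random_weighted_graph(15, 0.4, seed=20)
        ours = clustering_coefficient(g)
        theirs = nx.average_clustering(to_networkx(g), weight="weight")
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_permutation_invariance(self):
        g = random_weighted_graph(12, 0.5, seed=21)
        perm = np.random.default_rng(0).permutation(12)
        gp = WeightedGraph(g.adjacency[np.ix_(perm, perm)])
        assert clustering_coefficient(gp) == pytest.approx(clustering_coefficient(g))


class TestEfficiency:
    def test_complete_graph_is_one(self):
        g = WeightedGraph(1.0 - np.eye(6), is_binary=True)
        assert efficiency(g) == pytest.approx(1.0)

    def test_disconnected_pair_contributes_zero(self):
        g = WeightedGraph(np.zeros((2, 2)))
        assert efficiency(g) == 0.0

    def test_weighted_path_by_hand(self):
        # lengths 1/w: distances (1, 2, 3) -> E = (1 + 1/2 + 1/3)/3
        g = graph_from_edges(3, [(0, 1, 1.0), (1, 2, 0.5)])
        assert efficiency(g) == pytest.approx((1 + 0.5 + 1 / 3) / 3)

    def test_matches_networkx_binary(self):
        g = random_weighted_graph(14, 0.3, seed=22, weights="binary")
        assert efficiency(g) == pytest.approx(nx.global_efficiency(to_networkx(g)))

    def test_heavier_edges_raise_efficiency(self):
        light = graph_from_edges(3, [(0, 1, 0.5), (1, 2, 0.5)])
        heavy = graph_from_edges(3, [(0, 1, 1.0), (1, 2, 1.0)])
        assert efficiency(heavy) > efficiency(light)


class TestSmallWorldness:
    def test_er_graph_scores_near_one(self):
        g = random_weighted_graph(50, 0.2, seed=23)
        s = small_worldness(g, NullEnsembleConfig(n_nulls=30, seed=1))
        assert s == pytest.approx(1.0, abs=0.15)

    def test_ring_of_cliques_exceeds_one(self):
        # modular toy graph: high clustering at matched density
        edges = []
        for b in range(4):
            block = range(4 * b, 4 * b + 4)
            edges += [(i, j, 1.0) for i, j in itertools.combinations(block, 2)]
        edges += [(3, 4, 1.0), (7, 8, 1.0), (11, 12, 1.0), (15, 0, 1.0)]
        g = graph_from_edges(16, edges)
        assert small_worldness(g, NullEnsembleConfig(n_nulls=30, seed=2)) > 1.0


class TestModularity:
    def test_two_disjoint_cliques_half(self, two_cliques):
        q, labels = modularity_spectral(two_cliques)
        assert q == pytest.approx(0.5)
        assert np.unique(labels).size == 2
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1

    def test_complete_graph_trivial_partition(self):
        g = WeightedGraph(1.0 - np.eye(8), is_binary=True)
        q, labels = modularity_spectral(g)
        assert q == pytest.approx(0.0)
        assert np.unique(labels).size == 1

    def test_matches_exhaustive_search_small_graph(self, bridged_cliques):
        # brute-force maximum over all partitions of 8 nodes
        def partitions(nodes):
            if not nodes:
                yield []
                return
            head, rest = nodes[0], nodes[1:]
            for part in partitions(rest):
                for i in range(len(part)):
                    yield part[:i] + [[head] + part[i]] + part[i + 1:]
                yield [[head]] + part

        best = -1.0
        for part in partitions(list(range(8))):
            labels = np.empty(8, dtype=int)
            for ci, block in enumerate(part):
                labels[block] = ci
            best = max(best, modularity_value(bridged_cliques, labels))
        q, _ = modularity_spectral(bridged_cliques)
        assert q == pytest.approx(best, abs=1e-9)

    def test_q_value_matches_networkx(self):
        g = random_weighted_graph(20, 0.3, seed=24)
        q, labels = modularity_spectral(g)
        communities = [set(np.flatnonzero(labels == c)) for c in np.unique(labels)]
        q_nx = nx.community.modularity(to_networkx(g), communities, weight="weight")
        assert q == pytest.approx(q_nx, abs=1e-10)

    def test_never_below_trivial_partition(self):
        for seed in range(3):
            g = random_weighted_graph(15, 0.4, seed=30 + seed)
            q, _ = modularity_spectral(g)
            assert q >= 0.0


class TestOutliersAndAssortativity:
    def test_regular_graph_no_outliers(self):
        g = WeightedGraph(1.0 - np.eye(10), is_binary=True)
        assert outlier_proportion(g) == 0.0

    def test_documented_bounds_at_paper_density(self):
        # <k> = 18.24, sigma = sqrt(18.24): bounds [5.43, 31.05]
        A = np.zeros((100, 100))
        # build a graph with 912 edges where node 0 has degree 40
        rng = np.random.default_rng(0)
        A[0, 1:41] = A[1:41, 0] = 1.0
        iu, ju = np.triu_indices(100, k=1)
        free = [(i, j) for i, j in zip(iu, ju) if A[i, j] == 0 and i != 0]
        pick = rng.choice(len(free), 912 - 40, replace=False)
        for idx in pick:
            i, j = free[idx]
            A[i, j] = A[j, i] = 1.0
        g = WeightedGraph(A, is_binary=True)
        assert g.edge_count == 912
        d = g.degrees
        outliers = np.flatnonzero((d < 18.24 - 3 * np.sqrt(18.24)) | (d > 18.24 + 3 * np.sqrt(18.24)))
        assert 0 in outliers
        assert outlier_proportion(g) == pytest.approx(outliers.size / 100)

    def test_star_hub_is_outlier_leaves_are_not(self):
        g = graph_from_edges(100, [(0, i, 1) for i in range(1, 100)])
        # <k> = 1.98; hub degree 99 out of bounds, leaves (1) within
        assert outlier_proportion(g) == pytest.approx(0.01)

    def test_star_assortativity_minus_one(self, star5):
        assert assortativity(star5) == pytest.approx(-1.0)

    def test_two_disjoint_edges_undefined(self):
        g = graph_from_edges(4, [(0, 1, 1), (2, 3, 1)])
        assert np.isnan(assortativity(g))

    def test_path4_by_hand_and_networkx(self, path4):
        # edges (0,1),(1,2),(2,3): endpoint degree pairs (1,2),(2,2),(2,1)
        x = np.array([1, 2, 2, 2, 2, 1], dtype=float)
        y = np.array([2, 1, 2, 2, 1, 2], dtype=float)
        expected = np.corrcoef(x, y)[0, 1]
        assert assortativity(path4) == pytest.approx(expected)
        assert assortativity(path4) == pytest.approx(
            nx.degree_assortativity_coefficient(to_networkx(path4))
        )


class TestRichClub:
    def test_complete_graph_phi_one(self):
        g = WeightedGraph(1.0 - np.eye(8), is_binary=True)
        for k in range(1, 6):
            assert rich_club_topological(g, k) == 1.0

    def test_club_of_one_undefined(self, star5):
        assert np.isnan(rich_club_topological(star5, 1))

    def test_toy_graph_exhaustive_count(self):
        # 3-clique of high-degree nodes {0,1,2} plus pendant nodes
        edges = [(0, 1, 1), (1, 2, 1), (0, 2, 1), (0, 3, 1), (1, 4, 1), (2, 5, 1)]
        g = graph_from_edges(6, edges)
        # club at k=1: nodes with degree > 1 = {0,1,2}; 3 internal edges
        assert rich_club_topological(g, 1) == pytest.approx(1.0)
        # matches networkx rich-club coefficient (binary definition)
        nx_phi = nx.rich_club_coefficient(to_networkx(g), normalized=False)
        assert rich_club_topological(g, 1) == pytest.approx(nx_phi[1])

    def test_club_size_monotone_in_threshold(self):
        g = random_weighted_graph(30, 0.3, seed=25)
        d = g.degrees
        sizes = [(d > k).sum() for k in range(d.max())]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_null_preserves_degrees_and_weights(self):
        g = random_weighted_graph(25, 0.3, seed=26)
        null = degree_preserving_null(g, swaps_per_edge=10, rng=np.random.default_rng(3))
        assert np.array_equal(null.degrees, g.degrees)
        assert np.allclose(np.sort(null.weights), np.sort(g.weights))
        assert not np.allclose(null.adjacency, g.adjacency)  # actually shuffled

    def test_er_self_normalization_near_one(self):
        g = random_weighted_graph(40, 0.35, seed=27)
        n_nulls = 40
        table = rich_club_normalized(g, NullEnsembleConfig(n_nulls=n_nulls, seed=4))
        d = g.degrees
        ok = table.dropna()[[(d > k).sum() >= 8 for k in table.dropna().index]]
        # the observed graph is one draw from its own null family: its phi
        # must sit within ~3 null standard deviations of the null mean
        null_std = ok["phi_rand_sem"] * np.sqrt(n_nulls)
        dev = (ok["phi"] - ok["phi_rand_mean"]).abs()
        assert np.all(dev <= 3 * null_std + 0.02)

    def test_weighted_all_equal_weights_identically_one(self):
        g = graph_from_edges(6, [(0, 1, 0.5), (1, 2, 0.5), (0, 2, 0.5), (2, 3, 0.5),
                                 (3, 4, 0.5), (4, 5, 0.5)], binary=False)
        table = rich_club_weighted_normalized(g, NullEnsembleConfig(n_nulls=10, seed=5))
        ok = table["phi_w_norm"].dropna()
        assert np.allclose(ok, 1.0)

    def test_weighted_club_exact_permutation_average(self):
        # 5-node graph small enough to average over all weight permutations
        edges = [(0, 1, 0.9), (0, 2, 0.7), (1, 2, 0.5), (2, 3, 0.3), (3, 4, 0.1)]
        g = graph_from_edges(5, edges)
        k = 1  # club: degree > 1 = {0, 1, 2, 3}
        w = [e[2] for e in edges]
        positions_in_club = [True, True, True, True, False]  # (3,4) leaves the club
        exact = np.mean([
            sum(wp for wp, inside in zip(perm, positions_in_club) if inside)
            for perm in itertools.permutations(w)
        ])
        phi_w = rich_club_weighted(g, k)
        table = rich_club_weighted_normalized(g, NullEnsembleConfig(n_nulls=400, seed=6))
        assert phi_w == pytest.approx(sum(w[:4]))
        assert table.loc[k, "phi_w_rand_mean"] == pytest.approx(exact, rel=0.02)

    def test_binary_graph_rejected(self, two_cliques):
        with pytest.raises(ValueError):
            rich_club_weighted_normalized(two_cliques)


class TestHeavyTail:
    def test_power_law_parameter_recovery(self):
        # continuous power law, alpha = 2.5, x_min = 1
        rng = np.random.default_rng(7)
        x = (1 - rng.random(10_000)) ** (-1 / 1.5)
        fit = fit_heavy_tail(x)
        assert fit.alpha == pytest.approx(2.5, abs=0.05)

    def test_exponential_sample_rejected_as_power_law(self):
        rng = np.random.default_rng(8)
        x = rng.exponential(5.0, 3000) + 1.0
        fit = fit_heavy_tail(x)
        r, p = fit.comparisons["exponential"]
        assert r < 0  # exponential fits better than power law
        assert not fit.prefers_power_law_over("exponential")

    def test_power_law_preferred_over_exponential_when_true(self):
        rng = np.random.default_rng(9)
        x = (1 - rng.random(5000)) ** (-1 / 1.2)
        fit = fit_heavy_tail(x)
        assert fit.prefers_power_law_over("exponential")

    def test_fixed_xmin_mle(self):
        rng = np.random.default_rng(10)
        x = 2.0 * (1 - rng.random(20_000)) ** (-1 / 1.7)
        fit = fit_heavy_tail(x, x_min=2.0)
        assert fit.alpha == pytest.approx(2.7, abs=0.05)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_heavy_tail([1.0] * 100)
        with pytest.raises(ValueError):
            fit_heavy_tail([1.0, 2.0, 3.0])


class TestReport:
    def test_full_report_round_trip(self):
        g = random_weighted_graph(30, 0.3, seed=28)
        report = compute_metrics(g, NullEnsembleConfig(n_nulls=10, seed=9),
                                 rich_club=True, heavy_tail=True)
        d = report.to_dict()
        for key in ("clustering", "efficiency", "small_worldness", "modularity",
                    "outlier_proportion", "assortativity", "rich_club", "heavy_tail"):
            assert key in d
        assert 0 <= d["clustering"] <= 1
        assert d["modularity"] >= 0

    def test_weight_shuffle_preserves_topology(self):
        g = random_weighted_graph(20, 0.3, seed=29)
        shuffled = shuffle_weights(g, np.random.default_rng(11))
        assert np.array_equal(shuffled.adjacency > 0, g.adjacency > 0)
        assert np.allclose(np.sort(shuffled.weights), np.sort(g.weights))

    def test_metrics_permutation_invariant(self):
        g = random_weighted_graph(18, 0.4, seed=31)
        perm = np.random.default_rng(1).permutation(18)
        gp = WeightedGraph(g.adjacency[np.ix_(perm, perm)])
        assert efficiency(gp) == pytest.approx(efficiency(g))
        assert outlier_proportion(gp) == pytest.approx(outlier_proportion(g))
        assert assortativity(gp) == pytest.approx(assortativity(g))
        assert modularity_spectral(gp)[0] == pytest.approx(modularity_spectral(g)[0], abs=0.05)
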