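import networkx as nx
import numpy as np
import pytest

from netlie import (
    BinaryGraph,
    auc,
    auc_summary,
    characteristic_path_length,
    clustering_coefficient,
    global_efficiency,
    local_efficiency,
    metric_curves,
    normalized_metrics,
    random_reference_ensemble,
    select_sparsity_range,
    sparsity_grid,
    threshold_at_sparsity,
)
from netlie.errors import (
    DegenerateThresholdError,
    InvalidParameterError,
    NoValidRangeError,
    UndefinedPathError,
)
from netlie.graph_metrics import MetricCurves, RandomEnsemble
from tests._oracles import (
    characteristic_path_length_oracle,
    clustering_oracle,
    global_efficiency_oracle,
    local_efficiency_oracle,
)


def adj_of(graph):
    return nx.to_numpy_array(graph, dtype=np.uint8)


TRIANGLE = adj_of(nx.complete_graph(3))
STAR4 = adj_of(nx.star_graph(3))  # one hub, three leaves
K4 = adj_of(nx.complete_graph(4))
K4_MINUS_EDGE = K4.copy()
K4_MINUS_EDGE[0, 1] = K4_MINUS_EDGE[1, 0] = 0
P3 = adj_of(nx.path_graph(3))
C5 = adj_of(nx.cycle_graph(5))


class TestClosedFormValues:
    @pytest.mark.parametrize(
        "adj, expected",
        [(TRIANGLE, 1.0), (STAR4, 0.0), (K4_MINUS_EDGE, 5.0 / 6.0), (K4, 1.0)],
    )
    def test_clustering(self, adj, expected):
        assert clustering_coefficient(adj) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize(
        "adj, expected", [(K4, 1.0), (P3, 4.0 / 3.0), (C5, 1.5)]
    )
    def test_characteristic_path_length(self, adj, expected):
        assert characteristic_path_length(adj) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize(
        "adj, expected",
        [(K4, 1.0), (P3, 5.0 / 6.0), (np.zeros((4, 4), np.uint8), 0.0)],
    )
    def test_global_efficiency(self, adj, expected):
        assert global_efficiency(adj) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize(
        "adj, expected", [(K4, 1.0), (STAR4, 0.0), (TRIANGLE, 1.0)]
    )
    def test_local_efficiency(self, adj, expected):
        assert local_efficiency(adj) == pytest.approx(expected, abs=1e-15)

    def test_edgeless_graph_has_no_path_length(self):
        with pytest.raises(UndefinedPathError):
            characteristic_path_length(np.zeros((4, 4), np.uint8))


class TestAgainstNetworkxOnRandomGraphs:
    """networkx as an independent route for the same definitions."""

    @pytest.mark.parametrize("seed", range(8))
    def test_all_four_metrics(self, seed):
        g = nx.gnp_random_graph(30, 0.15, seed=seed)
        adj = adj_of(g)
        assert clustering_coefficient(adj) == pytest.approx(nx.average_clustering(g), abs=1e-12)
        assert global_efficiency(adj) == pytest.approx(nx.global_efficiency(g), abs=1e-12)
        assert local_efficiency(adj) == pytest.approx(nx.local_efficiency(g), abs=1e-12)
        if nx.is_connected(g):
            assert characteristic_path_length(adj) == pytest.approx(
                nx.average_shortest_path_length(g), abs=1e-12
            )

    def test_dense_fallback_matches_bitset_path(self, rng):
        # graphs above the one-word bitset limit exercise the dense kernels
        g = nx.gnp_random_graph(70, 0.1, seed=4)
        adj = adj_of(g)
        assert clustering_coefficient(adj) == pytest.approx(nx.average_clustering(g), abs=1e-12)
        assert global_efficiency(adj) == pytest.approx(nx.global_efficiency(g), abs=1e-12)
        assert local_efficiency(adj) == pytest.approx(nx.local_efficiency(g), abs=1e-12)

    def test_metric_bounds_on_1000_random_graphs(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            n = int(rng.integers(5, 30))
            upper = np.triu(rng.random((n, n)) < rng.uniform(0.05, 0.6), k=1)
            adj = (upper | upper.T).astype(np.uint8)
            for value in (
                clustering_coefficient(adj),
                global_efficiency(adj),
                local_efficiency(adj),
            ):
                assert 0.0 <= value <= 1.0


class TestThresholding:
    def test_reference_edge_count_at_quarter_sparsity(self, rng):
        C = np.corrcoef(rng.standard_normal((48, 200)))
        g = threshold_at_sparsity(C, 0.25)
        assert g.n_edges == 282  # round(0.25 * 48*47/2)

    def test_full_sparsity_is_complete_graph(self, rng):
        C = np.corrcoef(rng.standard_normal((48, 200)))
        g = threshold_at_sparsity(C, 1.0)
        assert g.n_edges == 48 * 47 // 2 == 1128

    def test_keeps_strongest_absolute_correlations(self):
        C = np.eye(4)
        C[0, 1] = C[1, 0] = -0.9
        C[2, 3] = C[3, 2] = 0.5
        C[0, 2] = C[2, 0] = 0.1
        g = threshold_at_sparsity(C, 2 / 6)
        assert g.adjacency[0, 1] == 1 and g.adjacency[2, 3] == 1

    def test_positive_ranking_ignores_negative_edges(self):
        C = np.eye(4)
        C[0, 1] = C[1, 0] = -0.9
        C[2, 3] = C[3, 2] = 0.5
        g = threshold_at_sparsity(C, 1 / 6, edge_rank="positive")
        assert g.adjacency[2, 3] == 1 and g.adjacency[0, 1] == 0

    def test_tie_break_is_lexicographic_and_stable(self):
        C = np.eye(5)
        # all off-diagonal correlations tied: keep the lexicographically first pairs
        iu = np.triu_indices(5, 1)
        C[iu] = 0.4
        C.T[iu] = 0.4
        g1 = threshold_at_sparsity(C, 3 / 10)
        g2 = threshold_at_sparsity(C, 3 / 10)
        expected = {(0, 1), (0, 2), (0, 3)}
        kept = set(zip(*np.nonzero(np.triu(g1.adjacency, 1))))
        assert kept == expected
        assert (g1.adjacency == g2.adjacency).all()

    def test_zero_edge_threshold_rejected(self):
        with pytest.raises(DegenerateThresholdError):
            threshold_at_sparsity(np.eye(4), 0.01)
        with pytest.raises(InvalidParameterError):
            threshold_at_sparsity(np.eye(4), 1.5)


class TestRandomEnsemble:
    def test_degree_sequences_preserved_exactly(self):
        for seed in range(10):
            g = BinaryGraph(adj_of(nx.gnp_random_graph(30, 0.2, seed=seed)), 1.0)
            ens = random_reference_ensemble(g, n_random=10, seed=seed)
            for member in ens.graphs:
                assert (member.degree_sequence() == g.degree_sequence()).all()

    def test_rewiring_destroys_lattice_clustering(self):
        lattice = BinaryGraph(adj_of(nx.watts_strogatz_graph(48, 8, 0.0, seed=0)), 1.0)
        ens = random_reference_ensemble(lattice, n_random=100, seed=1)
        mean_cp = np.mean([clustering_coefficient(m) for m in ens.graphs])
        assert mean_cp < clustering_coefficient(lattice)

    def test_same_seed_identical_ensemble(self):
        g = BinaryGraph(adj_of(nx.gnp_random_graph(20, 0.3, seed=2)), 1.0)
        a = random_reference_ensemble(g, n_random=5, seed=7)
        b = random_reference_ensemble(g, n_random=5, seed=7)
        for ga, gb in zip(a.graphs, b.graphs):
            assert (ga.adjacency == gb.adjacency).all()

    def test_swap_resistant_graph_warns_and_keeps_degrees(self):
        # every star edge shares the hub, so no double-edge swap can apply
        star = BinaryGraph(adj_of(nx.star_graph(6)), 1.0)
        with pytest.warns(UserWarning, match="swap"):
            ens = random_reference_ensemble(star, n_random=3, seed=0)
        for member in ens.graphs:
            assert (member.degree_sequence() == star.degree_sequence()).all()


class TestNormalizedMetrics:
    def test_self_ensemble_normalizes_to_one(self):
        g = BinaryGraph(adj_of(nx.gnp_random_graph(20, 0.3, seed=3)), 1.0)
        ens = RandomEnsemble([g, g, g], 3, 10, 0)
        gamma, lam, sigma = normalized_metrics(g, ens)
        assert gamma == pytest.approx(1.0, abs=1e-15)
        assert lam == pytest.approx(1.0, abs=1e-15)
        assert sigma == pytest.approx(1.0, abs=1e-15)

    def test_er_graph_is_its_own_null(self):
        g = BinaryGraph(adj_of(nx.gnp_random_graph(48, 0.3, seed=5)), 1.0)
        gamma, lam, _ = normalized_metrics(g, random_reference_ensemble(g, 100, seed=6))
        assert 0.8 <= gamma <= 1.2
        assert 0.95 <= lam <= 1.05

    def test_small_world_graph_exceeds_sigma_floor(self):
        g = BinaryGraph(adj_of(nx.watts_strogatz_graph(48, 8, 0.1, seed=7)), 1.0)
        _, _, sigma = normalized_metrics(g, random_reference_ensemble(g, 100, seed=8))
        assert sigma > 1.1


class TestGridAndAUC:
    def test_reference_grid_has_24_levels(self):
        grid = sparsity_grid(0.25, 0.48, 0.01)
        assert grid.size == 24
        assert grid[0] == 0.25 and grid[-1] == 0.48

    @pytest.mark.parametrize(
        "values, delta, expected",
        [
            (np.ones(24), 0.01, 0.24),
            ([0.5, 0.7], 0.01, 0.012),
            (np.zeros(10), 0.01, 0.0),
        ],
    )
    def test_rectangular_rule(self, values, delta, expected):
        assert auc(values, delta) == pytest.approx(expected, abs=1e-15)

    def test_trapezoid_rule_available(self):
        assert auc([0.0, 1.0], 0.1, rule="trapezoid") == pytest.approx(0.05)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidParameterError):
            auc([], 0.01)
        with pytest.raises(InvalidParameterError):
            auc([1.0], -0.1)


@pytest.fixture(scope="module")
def curves():
    rng = np.random.default_rng(21)
    base = rng.standard_normal((48, 300))
    C = np.corrcoef(base)
    return metric_curves(C, sparsity_grid(), n_random=10, seed=5), C


class TestMetricCurves:

    def test_global_efficiency_monotone_on_nested_grid(self, curves):
        c, _ = curves
        assert (np.diff(c["e_glob"]) >= -1e-12).all()

    def test_complete_graph_limit(self, rng):
        C = np.corrcoef(rng.standard_normal((10, 50)))
        c = metric_curves(C, [1.0], n_random=5, seed=1)
        for name in ("cp", "lp", "e_glob", "e_loc"):
            assert c[name][0] == pytest.approx(1.0, abs=1e-15)

    def test_deterministic_given_seed(self, curves):
        c, C = curves
        again = metric_curves(C, sparsity_grid(), n_random=10, seed=5)
        for name in c.values:
            np.testing.assert_array_equal(c[name], again[name])

    def test_auc_summary_bounds(self, curves):
        c, _ = curves
        s = auc_summary(c)
        span = 0.48 - 0.25 + 0.01
        for name in ("e_glob", "e_loc"):
            assert 0.0 <= s.auc[name] <= span + 1e-12


class TestSelectSparsityRange:
    def make_curves(self, sigma_values, grid, n_nodes=48):
        values = {name: np.ones(len(grid)) for name in ("cp", "lp", "gamma", "lambda", "sigma", "e_glob", "e_loc")}
        values["sigma"] = np.asarray(sigma_values, float)
        return MetricCurves(np.asarray(grid), values, n_nodes)

    def test_degree_criterion_closed_form_for_48_nodes(self):
        # mean degree 47*S > 2 ln 48 = 7.74 first holds at S = 0.17
        grid = sparsity_grid(0.10, 0.50, 0.01)
        curves = self.make_curves(np.full(grid.size, 2.0), grid)
        s_min, s_max = select_sparsity_range([curves])
        assert s_min == pytest.approx(0.17)
        assert s_max == pytest.approx(0.50)

    def test_sigma_ceiling_caps_the_range(self):
        grid = sparsity_grid(0.10, 0.50, 0.01)
        sigma = np.where(grid <= 0.48, 2.0, 1.05)
        curves = self.make_curves(sigma, grid)
        _, s_max = select_sparsity_range([curves])
        assert s_max == pytest.approx(0.48)

    def test_group_mean_sigma_is_used(self):
        grid = sparsity_grid(0.10, 0.50, 0.01)
        high = self.make_curves(np.full(grid.size, 1.6), grid)
        low = self.make_curves(np.full(grid.size, 0.8), grid)
        # mean sigma 1.2 > 1.1 everywhere
        s_min, s_max = select_sparsity_range([high, low])
        assert (s_min, s_max) == (pytest.approx(0.17), pytest.approx(0.50))

    def test_empty_range_raises(self):
        grid = sparsity_grid(0.10, 0.50, 0.01)
        curves = self.make_curves(np.full(grid.size, 1.0), grid)  # sigma never above floor
        with pytest.raises(NoValidRangeError):
            select_sparsity_range([curves])

    def test_synthetic_small_world_cohort_recovers_usable_range(self):
        # correlation matrices from small-world-coupled signals must yield
        # s_min = 0.17 (closed form) and a sigma ceiling at or above it
        from netlie import correlation_matrix, generate_ground_truth_network, simulate_timecourses

        grid = sparsity_grid(0.12, 0.50, 0.01)
        all_curves = []
        for seed in range(3):
            net = generate_ground_truth_network(48, seed=seed)
            ts = simulate_timecourses(net, 4000, coupling=0.5, seed=100 + seed)
            C = correlation_matrix(ts)
            all_curves.append(metric_curves(C, grid, n_random=10, seed=seed))
        s_min, s_max = select_sparsity_range(all_curves)
        assert s_min == pytest.approx(0.17)
        assert s_min < s_max
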