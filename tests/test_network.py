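import itertools

import numpy as np
import pytest

from fnirsnet.montage import load_montage
from fnirsnet.network import (
    DEFAULT_SPARSITIES,
    MetricCurve,
    ThresholdedGraph,
    auc,
    density_between,
    density_within,
    global_efficiency,
    inter_density,
    intra_density,
    proportional_threshold,
    sparsity_sweep,
    weighted_clustering,
)
from fnirsnet.synth import build_target_fc


def random_graph(rng, n, p=0.5, negative=False):
    w = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    mask = rng.random(len(iu[0])) < p
    vals = rng.uniform(-1 if negative else 0.05, 1.5, len(iu[0])) * mask
    w[iu] = vals
    w += w.T
    np.fill_diagonal(w, 0.0)
    w[w < 0] = 0.0
    return ThresholdedGraph(weights=w, sparsity=p)


def brute_clustering(w):
    n = w.shape[0]
    adj = w > 0
    c = np.zeros(n)
    for i in range(n):
        k = adj[i].sum()
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for l in range(n):
                if j != i and l != i and j != l:
                    total += (w[i, j] * w[j, l] * w[l, i]) ** (1 / 3)
        c[i] = total / (k * (k - 1))
    return c.mean(), c


def brute_efficiency(w):
    """All-pairs shortest paths by exhaustive simple-path enumeration."""
    n = w.shape[0]
    nodes = range(n)
    inv_sum = 0.0
    for i in nodes:
        for j in nodes:
            if i == j:
                continue
            best = np.inf
            stack = [(i, frozenset([i]), 0.0)]
            while stack:
                node, seen, dist = stack.pop()
                if dist >= best:
                    continue
                for k in nodes:
                    if w[node, k] > 0 and k not in seen:
                        nd = dist + 1.0 / w[node, k]
                        if k == j:
                            best = min(best, nd)
                        elif nd < best:
                            stack.append((k, seen | {k}, nd))
            if np.isfinite(best):
                inv_sum += 1.0 / best
    return inv_sum / (n * (n - 1))


class TestProportionalThreshold:
    def test_full_sparsity_keeps_all_positive_edges(self):
        z = np.abs(np.random.default_rng(0).normal(size=(29, 29))) + 0.1
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0)
        g = proportional_threshold(z, 1.0)
        assert g.adjacency.sum() // 2 == 406

    def test_ten_percent_keeps_41_edges(self):
        z = np.abs(np.random.default_rng(1).normal(size=(29, 29)))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0)
        g = proportional_threshold(z, 0.10)
        assert g.adjacency.sum() // 2 == 41  # round(0.10 * 406)

    def test_unique_maximum_edge_retained_first(self):
        z = np.zeros((29, 29))
        z[3, 17] = z[17, 3] = 2.5
        z[1, 2] = z[2, 1] = 0.1
        g = proportional_threshold(z, 1 / 406)
        assert g.weights[3, 17] == 2.5
        assert g.adjacency.sum() == 2

    def test_surviving_negative_weights_dropped_and_counted(self):
        z = np.full((29, 29), -0.5)
        np.fill_diagonal(z, 0)
        g = proportional_threshold(z, 0.10)
        assert g.adjacency.sum() == 0
        assert g.n_dropped_negative == 41

    @pytest.mark.parametrize("s", [0.0, -0.1, 1.5])
    def test_sparsity_range_validated(self, s):
        with pytest.raises(ValueError, match="sparsity"):
            proportional_threshold(np.zeros((29, 29)), s)


class TestClosedForms:
    def test_triangle_clustering_is_edge_weight(self):
        w = np.array([[0, .5, .5], [.5, 0, .5], [.5, .5, 0]])
        C, c = weighted_clustering(ThresholdedGraph(weights=w, sparsity=1.0))
        np.testing.assert_allclose(c, 0.5)
        assert C == pytest.approx(0.5)

    def test_uniform_complete_graph_c_equals_e_equals_w(self):
        w = 0.7 * (1 - np.eye(8))
        g = ThresholdedGraph(weights=w, sparsity=1.0)
        assert weighted_clustering(g)[0] == pytest.approx(0.7)
        assert global_efficiency(g)[0] == pytest.approx(0.7)

    def test_three_node_unit_path_efficiency(self):
        w = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        E, d = global_efficiency(ThresholdedGraph(weights=w, sparsity=1.0))
        assert E == pytest.approx(5 / 6)
        assert d[0, 2] == pytest.approx(2.0)

    def test_empty_graph_metrics_zero(self):
        g = ThresholdedGraph(weights=np.zeros((6, 6)), sparsity=0.1)
        assert weighted_clustering(g)[0] == 0.0
        assert global_efficiency(g)[0] == 0.0

    def test_negative_weights_rejected_by_clustering(self):
        w = np.array([[0, -.5], [-.5, 0]])
        with pytest.raises(ValueError, match="negative"):
            weighted_clustering(ThresholdedGraph(weights=w, sparsity=1.0))

    def test_direct_edge_distance_mode(self):
        w = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        E, d = global_efficiency(ThresholdedGraph(weights=w, sparsity=1.0),
                                 distance="direct")
        assert np.isinf(d[0, 2])
        assert E == pytest.approx(4 / 6)


class TestOracleEquivalence:
    def test_clustering_matches_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            g = random_graph(rng, int(rng.integers(3, 11)), p=rng.uniform(0.2, 0.9))
            C, c = weighted_clustering(g)
            Cb, cb = brute_clustering(g.weights)
            np.testing.assert_allclose(c, cb, atol=1e-12)
            assert C == pytest.approx(Cb, abs=1e-12)

    def test_efficiency_matches_exhaustive_paths(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            g = random_graph(rng, int(rng.integers(3, 9)), p=rng.uniform(0.2, 0.9))
            assert global_efficiency(g)[0] == pytest.approx(
                brute_efficiency(g.weights), abs=1e-12)

    def test_clustering_agrees_with_networkx_convention(self):
        # independent cross-check: networkx normalises weights by the max;
        # with max weight 1 the conventions coincide
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(9)
        g = random_graph(rng, 10, p=0.6)
        g.weights[g.weights > 0] /= g.weights.max()
        G = nx.from_numpy_array(g.weights)
        ours = weighted_clustering(g)[1]
        theirs = nx.clustering(G, weight="weight")
        np.testing.assert_allclose(ours, [theirs[i] for i in range(10)],
                                   atol=1e-10)


class TestDensities:
    def _graph(self, edges, n=29):
        w = np.zeros((n, n))
        for i, j in edges:
            w[i - 1, j - 1] = w[j - 1, i - 1] = 0.5
        return ThresholdedGraph(weights=w, sparsity=0.1)

    def test_single_cross_edge(self, montage):
        g = self._graph([(3, 4)])  # left-only 3, right-only 4
        assert inter_density(g, montage) == pytest.approx(1 / 169)

    def test_midline_edges_never_counted_inter(self, montage):
        g = self._graph([(1, 2), (1, 5), (2, 5), (1, 3), (2, 4)])
        assert inter_density(g, montage) == 0.0

    def test_midline_pair_counts_in_both_hemispheres(self, montage):
        g = self._graph([(1, 2)])
        assert intra_density(g, montage, "left") == pytest.approx(1 / 120)
        assert intra_density(g, montage, "right") == pytest.approx(1 / 120)

    def test_complete_graph_densities_one(self, montage):
        w = 0.5 * (1 - np.eye(29))
        g = ThresholdedGraph(weights=w, sparsity=1.0)
        assert inter_density(g, montage) == 1.0
        assert intra_density(g, montage, "left") == 1.0
        assert intra_density(g, montage, "right") == 1.0

    def test_density_helpers_match_brute_force(self):
        rng = np.random.default_rng(10)
        for _ in range(30):
            n = int(rng.integers(4, 11))
            g = random_graph(rng, n, p=0.5)
            adj = g.adjacency
            nodes = list(range(1, n + 1))
            half = n // 2
            a, b = set(nodes[:half]), set(nodes[half:])
            expect = sum(adj[i - 1, j - 1] for i in a for j in b) / (len(a) * len(b))
            assert density_between(adj, a, b) == pytest.approx(expect)
            expect_w = sum(adj[i - 1, j - 1] for i, j in
                           itertools.combinations(sorted(a), 2)) / \
                (len(a) * (len(a) - 1) / 2)
            assert density_within(adj, a) == pytest.approx(expect_w)


class TestSweepAndAUC:
    @pytest.fixture(scope="class")
    def z(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(29, 500))
        z = np.arctanh(np.clip(np.corrcoef(x), -0.999, 0.999))
        np.fill_diagonal(z, 0)
        return z

    def test_nine_points_per_indicator(self, z, montage):
        curve = sparsity_sweep(z, montage)
        assert list(curve.sparsities) == [0.10, 0.15, 0.20, 0.25, 0.30,
                                          0.35, 0.40, 0.45, 0.50]
        assert all(len(v) == 9 for v in curve.values.values())

    def test_densities_nondecreasing_in_sparsity(self, z, montage):
        curve = sparsity_sweep(z, montage)
        for ind in ("K-inter", "K-intra.L", "K-intra.R"):
            assert np.all(np.diff(curve.values[ind]) >= 0)
            assert np.all((curve.values[ind] >= 0) & (curve.values[ind] <= 1))

    def test_efficiency_nondecreasing_for_positive_matrix(self, montage):
        z = build_target_fc(0.6, 0.6, 0.3)  # all-positive weights
        np.fill_diagonal(z, 0)
        curve = sparsity_sweep(z, montage)
        assert np.all(np.diff(curve.values["E"]) >= -1e-12)

    def test_relabeling_invariance(self, z, montage):
        rng = np.random.default_rng(12)
        perm = rng.permutation(29)
        inv = {old + 1: new + 1 for new, old in enumerate(perm)}
        rois = {f"{r.name}_{r.hemisphere}": sorted(inv[c] for c in r.channels)
                for r in montage.rois}
        perm_montage = load_montage({"n_channels": 29, "rois": rois})
        zp = z[np.ix_(perm, perm)]
        a = sparsity_sweep(z, montage)
        b = sparsity_sweep(zp, perm_montage)
        for ind in a.values:
            np.testing.assert_allclose(a.values[ind], b.values[ind], atol=1e-12)

    def test_constant_curve_auc(self):
        curve = MetricCurve(sparsities=DEFAULT_SPARSITIES,
                            values={"C": np.full(9, 0.7)})
        assert auc(curve)["C"] == pytest.approx(0.7 * 0.40)

    def test_linear_curve_auc(self):
        curve = MetricCurve(sparsities=DEFAULT_SPARSITIES,
                            values={"E": np.linspace(0, 1, 9)})
        assert auc(curve)["E"] == pytest.approx(0.20)

    def test_random_curve_matches_manual_trapezoid(self):
        rng = np.random.default_rng(13)
        v = rng.random(9)
        s = DEFAULT_SPARSITIES
        manual = sum((v[i] + v[i + 1]) / 2 * (s[i + 1] - s[i]) for i in range(8))
        curve = MetricCurve(sparsities=s, values={"x": v})
        assert auc(curve)["x"] == pytest.approx(manual, abs=1e-15)
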