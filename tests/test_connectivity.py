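"""Connectivity tests: estimators vs closed forms, graph metrics vs oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import emodyn as e
from emodyn.connectivity import (
    DegenerateInputWarning,
    BrainNetwork,
    characteristic_path_length,
    clustering_coefficient,
    dynamic_network,
    mutual_information,
    network_feature_series,
    pearson,
    plv,
    sliding_windows,
    threshold_proportional,
)
from emodyn.core import ValidationError
from emodyn.preprocess import bandpass

from conftest import FS, make_sine


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def brute_clustering(adj: np.ndarray) -> float:
    n = adj.shape[0]
    vals = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            vals.append(0.0)
            continue
        links = sum(adj[a, b] for a, b in itertools.combinations(nbrs, 2))
        vals.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(vals)) if vals else 0.0


def brute_path_length(adj: np.ndarray) -> tuple[float, bool]:
    n = adj.shape[0]
    dists = []
    fragmented = False
    for s in range(n):
        dist = {s: 0}
        frontier = [s]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in range(n):
                    if adj[u, v] and v not in dist:
                        dist[v] = d
                        nxt.append(v)
            frontier = nxt
        for t in range(n):
            if t == s:
                continue
            if t in dist:
                dists.append(dist[t])
            else:
                fragmented = True
    return (float(np.mean(dists)) if dists else 0.0), fragmented


# ---------------------------------------------------------------------------
# Pairwise estimators
# ---------------------------------------------------------------------------

class TestMutualInformation:
    def test_independent_signals_below_permutation_null(self):
        rng = np.random.default_rng(42)
        x = rng.standard_normal(4096)
        y = rng.standard_normal(4096)
        observed = mutual_information(x, y, 16)
        null = []
        for _ in range(200):
            null.append(mutual_information(rng.permutation(x), y, 16))
        assert observed < np.percentile(null, 95)

    def test_gaussian_closed_form(self, rng):
        rho = 0.9
        n = 100_000
        x = rng.standard_normal(n)
        y = rho * x + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
        expected = -0.5 * np.log(1 - rho ** 2)
        assert abs(mutual_information(x, y, 16) - expected) < 0.1

    def test_self_information_is_bin_entropy(self, rng):
        x = rng.standard_normal(4096)
        mi = mutual_information(x, x, 16)
        assert abs(mi - np.log(16)) / np.log(16) < 0.02

    def test_symmetry(self, rng):
        x, y = rng.standard_normal((2, 512))
        assert mutual_information(x, y) == pytest.approx(mutual_information(y, x))

    def test_constant_input_degenerate(self, rng):
        with pytest.warns(DegenerateInputWarning):
            assert mutual_information(np.ones(128), rng.standard_normal(128)) == 0.0

    def test_input_validation(self, rng):
        with pytest.raises(ValidationError):
            mutual_information(np.zeros(32), np.zeros(32))
        with pytest.raises(ValidationError):
            mutual_information(rng.normal(size=128), rng.normal(size=128), n_bins=1)


class TestPearsonPLV:
    def test_pearson_perfect_anticorrelation(self, rng):
        x = rng.standard_normal(256)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_plv_self_locking(self, rng):
        x = bandpass(rng.standard_normal(1024), FS, (8, 13))
        assert plv(x, x) == pytest.approx(1.0)

    def test_plv_independent_noise_near_zero(self, rng):
        x = rng.standard_normal(4096)
        y = rng.standard_normal(4096)
        assert plv(x, y) <= 0.1

    def test_estimator_symmetry(self, rng):
        x, y = rng.standard_normal((2, 512))
        assert pearson(x, y) == pytest.approx(pearson(y, x))
        assert plv(x, y) == pytest.approx(plv(y, x))


class TestSlidingWindows:
    @pytest.mark.parametrize("t_s,w,s,expected", [
        (60, 4, 2, 29),
        (4, 4, 2, 1),
        (3, 4, 2, 0),
    ])
    def test_window_count(self, t_s, w, s, expected):
        wins = sliding_windows(int(t_s * FS), FS, w, s)
        assert len(wins) == expected

    @given(t=st.integers(1, 5000), w=st.integers(1, 50), s=st.integers(1, 50))
    def test_count_formula_and_bounds(self, t, w, s):
        wins = sliding_windows(t, 1.0, w, s)
        expected = (t - w) // s + 1 if t >= w else 0
        assert len(wins) == expected
        assert all(stop <= t and stop - start == w for start, stop in wins)


class TestDynamicNetwork:
    def test_single_window_reduces_to_pairwise_call(self, rng):
        x = rng.standard_normal((2, 512))
        tensor = dynamic_network({"b": x}, fs=FS, estimator="mi",
                                 window_s=4.0, step_s=4.0)
        assert tensor.values.shape == (1, 1, 2, 2)
        direct = mutual_information(x[0], x[1])
        assert tensor.values[0, 0, 0, 1] == pytest.approx(direct)

    def test_unknown_estimator_lists_choices(self, rng):
        with pytest.raises(ValidationError, match="mi.*pearson.*plv"):
            dynamic_network({"b": rng.standard_normal((2, 512))}, fs=FS,
                            estimator="granger")

    def test_channel_permutation_equivariance(self, rng):
        x = rng.standard_normal((4, 1024))
        perm = [2, 0, 3, 1]
        t1 = dynamic_network({"b": x}, fs=FS).values
        t2 = dynamic_network({"b": x[perm]}, fs=FS).values
        assert np.allclose(t2, t1[:, :, perm][:, :, :, perm])

    def test_slices_symmetric_zero_diagonal(self, rng):
        for est in ("mi", "pearson", "plv"):
            t = dynamic_network({"b": rng.standard_normal((4, 1024))},
                                fs=FS, estimator=est).values
            assert np.allclose(t, np.swapaxes(t, 2, 3))
            assert np.all(t[:, :, range(4), range(4)] == 0)
            if est != "pearson":
                assert np.all(t >= 0)

    def test_planted_coupling_recovered(self):
        """A kappa=0.9 alpha-coupled pair out-ranks the median pair MI in
        >= 90% of seeded trials."""
        from emodyn.preprocess import decompose_bands
        from emodyn.synth import CouplingEntry, CouplingSpec

        spec = CouplingSpec({"X": (CouplingEntry(0, 1, "alpha", 0.9),)})
        cfg = e.SimConfig(n_subjects=1, trials_per_subject=1,
                          trial_duration=8.0, coupling=spec)
        hits = 0
        n_trials = 50
        for s in range(n_trials):
            rec = e.generate_trial(cfg, "X", np.random.default_rng(500 + s))
            alpha = decompose_bands(rec)["alpha"]
            t = dynamic_network({"alpha": alpha}, estimator="mi")
            mean_mi = t.values[0].mean(axis=0)
            iu = np.triu_indices(rec.n_channels, 1)
            hits += mean_mi[0, 1] > np.median(mean_mi[iu])
        assert hits >= 0.9 * n_trials


class TestThresholding:
    def test_edge_count_rounding(self, rng):
        w = np.abs(rng.standard_normal((32, 32)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        net = threshold_proportional(w, 0.1)
        assert net.n_edges == 50  # round(0.1 * 496)

    def test_full_density_gives_complete_graph(self, rng):
        w = np.abs(rng.standard_normal((6, 6)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        net = threshold_proportional(w, 1.0)
        assert net.n_edges == 15

    def test_tie_break_is_deterministic_by_index(self):
        w = np.ones((4, 4)) - np.eye(4)
        net = threshold_proportional(w, 0.5)  # keep 3 of 6 equal edges
        expected = np.zeros((4, 4), dtype=int)
        for i, j in [(0, 1), (0, 2), (0, 3)]:
            expected[i, j] = expected[j, i] = 1
        assert np.array_equal(net.adjacency, expected)

    @given(n=st.integers(2, 8), density=st.floats(0, 1), seed=st.integers(0, 100))
    def test_density_contract(self, n, density, seed):
        rng = np.random.default_rng(seed)
        w = np.abs(rng.standard_normal((n, n)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        net = threshold_proportional(w, density)
        assert net.n_edges == round(density * n * (n - 1) / 2)


class TestGraphMetrics:
    def test_complete_graph(self):
        k5 = BrainNetwork(np.ones((5, 5), dtype=int) - np.eye(5, dtype=int))
        assert clustering_coefficient(k5) == pytest.approx(1.0)
        assert characteristic_path_length(k5).value == pytest.approx(1.0)

    def test_star_has_no_triangles(self):
        adj = np.zeros((6, 6), dtype=int)
        adj[0, 1:] = adj[1:, 0] = 1
        assert clustering_coefficient(BrainNetwork(adj)) == 0.0

    def test_path_graph_p4(self):
        adj = np.zeros((4, 4), dtype=int)
        for i in range(3):
            adj[i, i + 1] = adj[i + 1, i] = 1
        res = characteristic_path_length(BrainNetwork(adj))
        assert res.value == pytest.approx(10 / 6)
        assert not res.fragmented

    def test_fragmented_graph_flagged(self):
        adj = np.zeros((4, 4), dtype=int)
        adj[0, 1] = adj[1, 0] = adj[2, 3] = adj[3, 2] = 1
        res = characteristic_path_length(BrainNetwork(adj))
        assert res.value == pytest.approx(1.0)
        assert res.fragmented

    def test_random_graphs_match_brute_force_and_networkx(self, rng):
        import networkx as nx

        for _ in range(25):
            n = 10
            adj = (rng.random((n, n)) < 0.3).astype(int)
            adj = np.triu(adj, 1)
            adj = adj + adj.T
            net = BrainNetwork(adj)
            assert clustering_coefficient(net) == pytest.approx(brute_clustering(adj))
            assert clustering_coefficient(net) == pytest.approx(
                nx.average_clustering(nx.from_numpy_array(adj)))
            val, frag = brute_path_length(adj)
            res = characteristic_path_length(net)
            assert res.value == pytest.approx(val)
            assert res.fragmented == frag

    def test_exhaustive_small_graphs(self):
        """Both metrics agree with brute force on every graph of <= 5 nodes."""
        for n in range(2, 6):
            pairs = list(itertools.combinations(range(n), 2))
            for bits in range(2 ** len(pairs)):
                adj = np.zeros((n, n), dtype=int)
                for b, (i, j) in enumerate(pairs):
                    if (bits >> b) & 1:
                        adj[i, j] = adj[j, i] = 1
                net = BrainNetwork(adj)
                assert clustering_coefficient(net) == pytest.approx(
                    brute_clustering(adj))
                val, frag = brute_path_length(adj)
                res = characteristic_path_length(net)
                assert res.value == pytest.approx(val)
                assert res.fragmented == frag


class TestNetworkExport:
    def test_matrix_and_edge_list_csv(self, tmp_path):
        from emodyn.connectivity import write_network_csv

        adj = np.zeros((3, 3), dtype=int)
        adj[0, 1] = adj[1, 0] = adj[1, 2] = adj[2, 1] = 1
        net = BrainNetwork(adj)
        names = ["F3", "F4", "Cz"]
        mat = tmp_path / "net.csv"
        write_network_csv(net, mat, fmt="matrix", channel_names=names)
        lines = mat.read_text().strip().splitlines()
        assert lines[0] == ",F3,F4,Cz"
        assert lines[1] == "F3,0,1,0"
        edges = tmp_path / "edges.csv"
        write_network_csv(net, edges, fmt="edges", channel_names=names)
        rows = edges.read_text().strip().splitlines()
        assert rows == ["source,target", "F3,F4", "F4,Cz"]
        with pytest.raises(ValidationError):
            write_network_csv(net, tmp_path / "x.csv", fmt="graphml")


class TestNetworkFeatureSeries:
    def _tensor(self, rng, n_windows):
        vals = np.abs(rng.standard_normal((5, n_windows, 8, 8)))
        vals = (vals + np.swapaxes(vals, 2, 3)) / 2
        vals[:, :, range(8), range(8)] = 0
        return e.ConnectivityTensor(vals, ("delta", "theta", "alpha", "beta", "gamma"),
                                    tuple(2.0 * k for k in range(n_windows)),
                                    4.0, 2.0, "mi")

    def test_sixty_named_features(self, rng):
        feats = network_feature_series(self._tensor(rng, 5))
        assert len(feats) == 60
        assert "net_alpha_clustering_mean" in feats

    def test_single_window_sd_and_slope_zero(self, rng):
        feats = network_feature_series(self._tensor(rng, 1))
        assert all(v == 0.0 for k, v in feats.items()
                   if k.endswith(("_sd", "_slope")))

    def test_constant_windows_mean_equals_single(self, rng):
        t1 = self._tensor(rng, 1)
        vals = np.repeat(t1.values, 3, axis=1)
        t3 = e.ConnectivityTensor(vals, t1.bands, (0.0, 2.0, 4.0), 4.0, 2.0, "mi")
        f1 = network_feature_series(t1)
        f3 = network_feature_series(t3)
        for k in f1:
            if k.endswith("_mean"):
                assert f3[k] == pytest.approx(f1[k])
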