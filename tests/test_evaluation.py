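import numpy as np
import pytest
from sklearn.metrics import silhouette_score

from sctrnnpb import (
    NetworkConfig,
    activity_profile,
    averaged_mse,
    init_params,
    mean_estimated_variance,
    silhouette_index,
    tolerance_map,
)
from sctrnnpb.evaluation import closed_loop_mse_at
from sctrnnpb.preprocessing import TargetSequence


class TestAveragedMSE:
    def test_perfect_predictions(self):
        t = np.random.default_rng(0).uniform(-0.9, 0.9, (6, 3))
        assert averaged_mse([t[1:]], [t]) == 0.0

    def test_constant_offset(self):
        t = np.zeros((5, 2))
        pred = np.full((4, 2), 0.1)
        assert averaged_mse([pred], [t]) == pytest.approx(0.01)

    def test_matches_flat_recomputation(self):
        """steps -> features -> sequences averaging equals the explicit
        loop when sequences have equal length; with unequal lengths it
        weights sequences equally (order is fixed and documented)."""
        rng = np.random.default_rng(4)
        targets = [rng.uniform(-1, 1, (7, 3)) for _ in range(4)]
        preds = [t[1:] + rng.normal(0, 0.1, (6, 3)) for t in targets]
        expected = np.mean([np.mean((p - t[1:]) ** 2) for p, t in zip(preds, targets)])
        assert averaged_mse(preds, targets) == pytest.approx(expected, abs=1e-12)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            averaged_mse([], [])

    def test_mean_variance_same_averaging(self):
        vs = [np.full((4, 2), 0.5), np.full((9, 2), 1.5)]
        assert mean_estimated_variance(vs) == pytest.approx(1.0)


class TestSilhouette:
    def test_two_tight_clusters(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.01, (10, 2))
        b = rng.normal(0, 0.01, (10, 2)) + [1.0, 0.0]
        pts = np.vstack([a, b])
        labels = np.array([0] * 10 + [1] * 10)
        assert silhouette_index(pts, labels) > 0.95

    def test_coincident_points_zero(self):
        pts = np.zeros((6, 2))
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert silhouette_index(pts, labels) == 0.0

    def test_two_singletons_zero(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0]])
        assert silhouette_index(pts, np.array([0, 1])) == 0.0

    def test_single_cluster_raises(self):
        with pytest.raises(ValueError):
            silhouette_index(np.zeros((3, 2)), np.array([1, 1, 1]))

    def test_matches_sklearn(self):
        """Cross-check against the reference implementation on a generic
        configuration (no singletons, no coincident points)."""
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(40, 2))
        labels = rng.integers(0, 3, size=40)
        ours = silhouette_index(pts, labels)
        ref = silhouette_score(pts, labels, metric="euclidean")
        assert ours == pytest.approx(ref, abs=1e-12)


@pytest.fixture(scope="module")
def untrained_setup():
    config = NetworkConfig(n_input=3, n_lower=8, n_pb=2, K=1.0, seed=4)
    params = init_params(config)
    rng = np.random.default_rng(11)
    targets = [
        TargetSequence(i, (i % 2) + 1, rng.uniform(-0.9, 0.9, (int(rng.integers(5, 9)), 3)))
        for i in range(4)
    ]
    return config, params, targets


class TestToleranceMap:
    def test_infinite_threshold_counts_all(self, untrained_setup):
        config, params, targets = untrained_setup
        tm = tolerance_map(params, config, targets, grid_resolution=5,
                           mse_threshold=np.inf)
        assert np.all(tm.counts == len(targets))

    def test_untrained_network_counts_zero_almost_everywhere(self, untrained_setup):
        config, params, targets = untrained_setup
        tm = tolerance_map(params, config, targets, grid_resolution=9,
                           mse_threshold=0.005)
        assert tm.counts.sum() <= 0.02 * tm.counts.size * len(targets)

    def test_grid_layout(self, untrained_setup):
        config, params, targets = untrained_setup
        tm = tolerance_map(params, config, targets, grid_resolution=5, pb_limit=0.8)
        np.testing.assert_allclose(tm.grid, np.linspace(-0.8, 0.8, 5))
        assert tm.counts.shape == (5, 5)

    def test_counts_match_direct_closed_loop(self, untrained_setup):
        """Map counts agree with independently computed closed-loop MSEs."""
        config, params, targets = untrained_setup
        tm = tolerance_map(params, config, targets, grid_resolution=3,
                           mse_threshold=0.05, pb_limit=0.9)
        g1, g2 = np.meshgrid(tm.grid, tm.grid, indexing="ij")
        pts = np.column_stack([g1.ravel(), g2.ravel()])
        mse = closed_loop_mse_at(params, config, targets, pts)
        np.testing.assert_array_equal(
            tm.counts.ravel(), (mse < 0.05).sum(axis=1)
        )

    def test_resolution_validation(self, untrained_setup):
        config, params, targets = untrained_setup
        with pytest.raises(ValueError):
            tolerance_map(params, config, targets, grid_resolution=1)


def test_plot_pb_space_writes_figure(tmp_path):
    from sctrnnpb.evaluation import plot_pb_space

    rng = np.random.default_rng(0)
    train_pb = rng.uniform(-0.9, 0.9, (12, 2))
    labels = np.repeat([1, 2, 3], 4)
    out = tmp_path / "pb.png"
    plot_pb_space(train_pb, labels, test_pb=train_pb[:3], test_labels=labels[:3],
                  path=str(out))
    assert out.exists() and out.stat().st_size > 0


class TestActivityProfile:
    def test_zero_network_zero_range(self):
        config = NetworkConfig(n_input=2, n_lower=4, n_pb=1, K=0.0, seed=0)
        params = init_params(config)
        for key in ("w_xl", "w_ll", "w_pl"):
            getattr(params, key)[:] = 0.0
        targets = [TargetSequence(0, 1, np.random.default_rng(0).uniform(-0.5, 0.5, (6, 2)))]
        prof = activity_profile(params, config, targets, np.zeros((1, 1)))
        np.testing.assert_allclose(prof.activity_range, 0.0, atol=1e-15)
        assert prof.fraction_inactive == 1.0

    def test_saturated_neuron_has_near_zero_range(self):
        """|a| = 30 with modest input weights saturates tanh at +-1."""
        config = NetworkConfig(n_input=1, n_lower=2, n_pb=1, K=0.0, seed=1)
        params = init_params(config)
        params.a_l[:] = [30.0, 0.0]
        params.w_xl[:] = [[0.5], [0.5]]
        params.w_ll[:] = 0.0
        params.w_pl[:] = 0.0
        rng = np.random.default_rng(2)
        targets = [TargetSequence(0, 1, rng.uniform(-0.9, 0.9, (20, 1)))]
        prof = activity_profile(params, config, targets, np.zeros((1, 1)),
                                epsilon_active=0.05)
        assert prof.activity_range[0] < 0.01   # saturated
        assert prof.activity_range[1] > 0.1    # responsive
        assert prof.fraction_inactive == 0.5
        np.testing.assert_allclose(prof.abs_threshold, [30.0, 0.0])

    def test_low_k_thresholds_small(self):
        """K = 0.001 keeps every |a_i| below 1 (std ~0.032)."""
        config = NetworkConfig(n_input=2, n_lower=200, n_pb=1, K=0.001, seed=3)
        params = init_params(config)
        assert np.all(np.abs(params.a_l) < 1.0)
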