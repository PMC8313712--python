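import numpy as np
import pytest
from scipy import stats

from sctrnnpb import (
    NetworkConfig,
    NeuronIndexSets,
    forward_sequence,
    forward_step,
    init_params,
    load_checkpoint,
    nll_step,
    save_checkpoint,
    sequence_nll,
)
from sctrnnpb.network import PaddedBatch, _forward_batch, batch_nll


class TestInitParams:
    def test_k_zero_thresholds_exactly_zero(self):
        config = NetworkConfig(n_input=2, n_lower=10, K=0.0, seed=1)
        params = init_params(config)
        np.testing.assert_array_equal(params.a_l, np.zeros(10))

    def test_threshold_variance_matches_k(self):
        """K is the *variance*: at K=1000 and n=500 the sample variance
        must lie in a 99% chi-squared confidence band around 1000."""
        config = NetworkConfig(n_input=9, n_lower=500, K=1000.0, seed=123)
        params = init_params(config)
        n = 500
        s2 = params.a_l.var(ddof=1)
        lo = 1000.0 * stats.chi2.ppf(0.005, n - 1) / (n - 1)
        hi = 1000.0 * stats.chi2.ppf(0.995, n - 1) / (n - 1)
        assert lo < s2 < hi

    def test_seed_determinism(self):
        config = NetworkConfig(n_input=3, n_lower=7, K=1.0, seed=9)
        a, b = init_params(config), init_params(config)
        for key in ("w_xl", "w_ll", "w_pl", "a_l", "w_ly", "a_y", "w_lv", "a_v"):
            np.testing.assert_array_equal(getattr(a, key), getattr(b, key))

    def test_weight_scale_respects_fan_in(self):
        config = NetworkConfig(n_input=4, n_lower=100, K=1.0, seed=0)
        params = init_params(config)
        assert np.abs(params.w_xl).max() <= 1 / np.sqrt(4)
        assert np.abs(params.w_ll).max() <= 1 / np.sqrt(100)
        assert np.abs(params.w_pl).max() <= 1 / np.sqrt(2)


class TestForwardStep:
    def test_zero_network_produces_unit_variance(self, tiny_config):
        params = init_params(tiny_config)
        for key in ("w_xl", "w_ll", "w_pl", "w_ly", "w_lv"):
            getattr(params, key)[:] = 0.0
        params.a_l[:] = 0.0
        u, l, y, v = forward_step(
            params, tiny_config,
            np.zeros(tiny_config.n_lower), np.zeros(2), np.zeros(2),
        )
        np.testing.assert_array_equal(u, 0.0)
        np.testing.assert_array_equal(l, 0.0)
        np.testing.assert_array_equal(y, 0.0)
        np.testing.assert_allclose(v, 1.0 + tiny_config.variance_floor)

    def test_hand_computed_step(self, tiny_config, tiny_params):
        """Independent evaluation of one leaky-integrator update."""
        rng = np.random.default_rng(0)
        u_prev = rng.normal(size=3)
        x = rng.normal(size=2)
        pb = rng.normal(size=2)
        u, l, y, v = forward_step(tiny_params, tiny_config, u_prev, x, pb)
        p = np.tanh(pb)
        tau = tiny_params.tau
        for i in range(3):
            drive = (
                sum(tiny_params.w_xl[i, j] * x[j] for j in range(2))
                + sum(tiny_params.w_ll[i, j] * np.tanh(u_prev[j]) for j in range(3))
                + sum(tiny_params.w_pl[i, j] * p[j] for j in range(2))
                + tiny_params.a_l[i]
            )
            expected = drive / tau + (1 - 1 / tau) * u_prev[i]
            assert u[i] == pytest.approx(expected, abs=1e-12)
            assert l[i] == pytest.approx(np.tanh(expected), abs=1e-12)
        for i in range(2):
            um = sum(tiny_params.w_ly[i, j] * l[j] for j in range(3)) + tiny_params.a_y[i]
            assert y[i] == pytest.approx(np.tanh(um), abs=1e-12)
            uv = sum(tiny_params.w_lv[i, j] * l[j] for j in range(3)) + tiny_params.a_v[i]
            assert v[i] == pytest.approx(np.exp(uv) + tiny_config.variance_floor, abs=1e-12)

    def test_leak_closed_form(self, tiny_config):
        """With zero drive, u_t = (1 - 1/tau)^t u_0 exactly."""
        params = init_params(tiny_config)
        for key in ("w_xl", "w_ll", "w_pl"):
            getattr(params, key)[:] = 0.0
        params.a_l[:] = 0.0
        u = np.array([1.0, -2.0, 0.5])
        u0 = u.copy()
        for t in range(1, 6):
            u, *_ = forward_step(params, tiny_config, u, np.zeros(2), np.zeros(2))
            np.testing.assert_allclose(u, (1 - 1 / params.tau) ** t * u0, atol=1e-14)

    def test_tau_one_has_no_leak(self):
        config = NetworkConfig(n_input=2, n_lower=3, K=1.0, tau_lower=1.0, seed=5)
        params = init_params(config)
        u_prev = np.array([5.0, -5.0, 1.0])
        u, *_ = forward_step(params, config, u_prev, np.zeros(2), np.zeros(2))
        # at tau=1 the update equals the drive term; u_prev only enters
        # through l_{t-1}
        drive = params.w_ll @ np.tanh(u_prev) + params.a_l
        np.testing.assert_allclose(u, drive, atol=1e-12)

    def test_non_finite_input_rejected(self, tiny_config, tiny_params):
        with pytest.raises(FloatingPointError):
            forward_step(tiny_params, tiny_config, np.zeros(3),
                         np.array([np.nan, 0.0]), np.zeros(2))


class TestForwardSequence:
    def test_trace_invariants_random_network(self, tiny_config, tiny_params):
        rng = np.random.default_rng(8)
        targets = rng.uniform(-0.9, 0.9, size=(12, 2))
        for mode in ("teacher_forced", "closed_loop"):
            trace = forward_sequence(tiny_params, tiny_config, targets,
                                     np.array([0.3, -0.2]), mode=mode)
            assert trace.n_steps == 11
            assert np.all(np.isfinite(trace.u_lower))
            assert np.all(np.abs(trace.y_mean) < 1)
            assert np.all(np.abs(trace.lower) < 1)
            assert np.all(trace.variance >= tiny_config.variance_floor)

    def test_pb_activity_constant(self, tiny_config, tiny_params):
        trace = forward_sequence(
            tiny_params, tiny_config, np.zeros((6, 2)), np.array([0.5, -1.0])
        )
        np.testing.assert_array_equal(trace.pb_activity, np.tanh([0.5, -1.0]))

    def test_perfect_network_closed_loop_equals_teacher_forced(self, tiny_config):
        """A network predicting a constant-zero target exactly generates the
        same trajectory open- and closed-loop."""
        params = init_params(tiny_config)
        for key in ("w_xl", "w_ll", "w_pl", "w_ly", "w_lv"):
            getattr(params, key)[:] = 0.0
        params.a_l[:] = 0.0
        targets = np.zeros((8, 2))
        tf = forward_sequence(params, tiny_config, targets, np.zeros(2), "teacher_forced")
        cl = forward_sequence(params, tiny_config, targets, np.zeros(2), "closed_loop")
        np.testing.assert_array_equal(tf.y_mean, cl.y_mean)
        np.testing.assert_array_equal(tf.y_mean, np.zeros((7, 2)))

    def test_sampled_closed_loop_generation(self, tiny_config, tiny_params):
        """With sampling on, fed-back values are drawn from the predicted
        Gaussian: trajectories differ from the deterministic mean path but
        are reproducible under a fixed generator."""
        targets = np.zeros((10, 2))
        det = forward_sequence(tiny_params, tiny_config, targets,
                               np.zeros(2), "closed_loop")
        s1 = forward_sequence(tiny_params, tiny_config, targets, np.zeros(2),
                              "closed_loop", sample_noise=True,
                              rng=np.random.default_rng(0))
        s2 = forward_sequence(tiny_params, tiny_config, targets, np.zeros(2),
                              "closed_loop", sample_noise=True,
                              rng=np.random.default_rng(0))
        np.testing.assert_array_equal(s1.y_mean, s2.y_mean)
        assert not np.allclose(s1.inputs[1:], det.inputs[1:])

    def test_too_short_sequence_raises(self, tiny_config, tiny_params):
        with pytest.raises(ValueError):
            forward_sequence(tiny_params, tiny_config, np.zeros((1, 2)), np.zeros(2))

    def test_batched_pass_matches_sequential(self, tiny_config, tiny_params):
        """The padded batch forward agrees with per-sequence traces."""
        rng = np.random.default_rng(4)
        seqs = [rng.uniform(-0.9, 0.9, size=(n, 2)) for n in (5, 9, 7)]
        pb = rng.normal(size=(3, 2))
        batch = PaddedBatch(seqs)
        fwd = _forward_batch(tiny_params, tiny_config, batch, pb)
        for i, s in enumerate(seqs):
            trace = forward_sequence(tiny_params, tiny_config, s, pb[i])
            n = s.shape[0] - 1
            np.testing.assert_allclose(fwd["Y"][:n, i], trace.y_mean, atol=1e-12)
            np.testing.assert_allclose(fwd["V"][:n, i], trace.variance, atol=1e-12)


class TestNLL:
    def test_exact_values(self):
        assert nll_step(1.0, 1.0, 1.0) == pytest.approx(np.log(2 * np.pi) / 2)
        assert nll_step(2.0, 1.0, 1.0) == pytest.approx(np.log(2 * np.pi) / 2 + 0.5)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            nll_step(0.0, 0.0, 0.0)

    def test_minimum_over_variance_at_squared_error(self):
        """For fixed error e, L(v) is minimized at v = e^2 with value
        ln(2 pi e^2)/2 + 1/2 (stationary point of the NLL in v)."""
        e = 0.37
        v_star = e**2
        expected = np.log(2 * np.pi * e**2) / 2 + 0.5
        assert nll_step(e, 0.0, v_star) == pytest.approx(expected)
        for v in (v_star * 0.5, v_star * 0.9, v_star * 1.1, v_star * 2.0):
            assert nll_step(e, 0.0, v) > expected

    def test_sequence_nll_additivity(self, tiny_config):
        """Two perfect unit-variance steps sum to 2 * ln(2 pi)/2."""
        params = init_params(tiny_config)
        for key in ("w_xl", "w_ll", "w_pl", "w_ly", "w_lv"):
            getattr(params, key)[:] = 0.0
        params.a_l[:] = 0.0
        targets = np.zeros((3, 2))
        trace = forward_sequence(params, tiny_config, targets, np.zeros(2))
        total = sequence_nll(trace, targets)
        per_step = np.log(2 * np.pi * (1 + tiny_config.variance_floor)) / 2
        assert total == pytest.approx(2 * 2 * per_step)  # 2 steps x 2 features

    def test_sequence_nll_against_brute_force(self, tiny_config, tiny_params):
        rng = np.random.default_rng(21)
        targets = rng.uniform(-0.9, 0.9, size=(7, 2))
        pb = rng.normal(size=2)
        trace = forward_sequence(tiny_params, tiny_config, targets, pb)
        total = sequence_nll(trace, targets)
        brute = 0.0
        for k in range(trace.n_steps):
            for j in range(2):
                y, v, t = trace.y_mean[k, j], trace.variance[k, j], targets[k + 1, j]
                brute += np.log(2 * np.pi * v) / 2 + (t - y) ** 2 / (2 * v)
        assert total == pytest.approx(brute, abs=1e-12)
        # and against the batched accumulator
        batch = PaddedBatch([targets])
        fwd = _forward_batch(tiny_params, tiny_config, batch, pb[None])
        assert batch_nll(fwd, batch) == pytest.approx(brute, abs=1e-10)

    def test_misaligned_lengths_raise(self, tiny_config, tiny_params):
        targets = np.zeros((5, 2))
        trace = forward_sequence(tiny_params, tiny_config, targets, np.zeros(2))
        with pytest.raises(ValueError):
            sequence_nll(trace, np.zeros((6, 2)))


class TestIndexSets:
    def test_disjoint_and_sized(self):
        config = NetworkConfig(n_input=9, n_lower=50, n_pb=2, K=1.0)
        idx = NeuronIndexSets.from_config(config)
        all_idx = [*idx.pb, *idx.lower, *idx.inputs, *idx.mean, *idx.variance]
        assert len(all_idx) == len(set(all_idx)) == 2 + 50 + 9 * 3
        assert len(idx.mean) == len(idx.variance) == len(idx.inputs) == 9


def test_checkpoint_round_trip(tmp_path, tiny_config, tiny_params):
    pb = np.array([[0.1, -0.2], [0.3, 0.4]])
    path = tmp_path / "ckpt.json"
    save_checkpoint(path, tiny_params, tiny_config, pb_internal=pb,
                    extra={"note": "unit"})
    params, config, pb2, scaler_json, extra = load_checkpoint(path)
    assert config == tiny_config
    assert extra == {"note": "unit"}
    np.testing.assert_array_equal(pb2, pb)
    for key in ("w_xl", "w_ll", "w_pl", "a_l", "w_ly", "a_y", "w_lv", "a_v"):
        np.testing.assert_array_equal(getattr(params, key), getattr(tiny_params, key))
    assert params.tau == tiny_params.tau
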