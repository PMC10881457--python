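"""Readout training: RLS correctness, teaching signals, co-training."""

import math

import numpy as np
import pytest

from striatal_chunking import (
    ChunkProtocol,
    NormalizerState,
    ReservoirParams,
    RLSState,
    TeachingConfig,
    TrainingConfig,
    error,
    generate_input,
    init_weights,
    normalize,
    readout,
    rls_update,
    teaching_signal,
    train_pair,
)


class TestReadout:
    def test_zero_weights(self):
        assert readout(np.zeros(5), np.ones(5)) == 0.0

    def test_unit_vector_selects_neuron(self):
        w = np.zeros(5)
        w[3] = 1.0
        r = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        assert readout(w, r) == pytest.approx(0.4)

    def test_matches_elementwise_sum_oracle(self, rng):
        w = rng.normal(size=5)
        r = rng.normal(size=5)
        assert readout(w, r) == pytest.approx(sum(w[i] * r[i] for i in range(5)))


class TestNormalizer:
    def test_constant_stream_standardizes_to_zero(self):
        state = NormalizerState(time_constant=100.0)
        for _ in range(2000):
            zhat = normalize(3.7, state, dt=1.0)
        assert abs(zhat) < 1e-6
        assert state.running_mean == pytest.approx(3.7, rel=1e-6)

    def test_alternating_stream_approaches_unit_scale(self):
        """+-1 alternation: closed-form stationary EMA statistics.

        With rate a, the stationary mean alternates +-a/(2-a) ~ 0 and the
        squared-deviation average approaches 1, so |zhat| -> 1.
        """
        state = NormalizerState(time_constant=50.0)
        z = 1.0
        for _ in range(5000):
            zhat = normalize(z, state, dt=1.0)
            z = -z
        a = 1.0 / 50.0
        assert abs(state.running_mean) <= a / (2 - a) + 1e-9
        assert abs(zhat) == pytest.approx(1.0, abs=0.02)

    def test_zero_variance_never_nan(self):
        state = NormalizerState()
        for _ in range(10):
            zhat = normalize(0.0, state, dt=1.0)
        assert math.isfinite(zhat)

    def test_bias_corrected_early_statistics(self):
        """Shortly into a stream the mean estimate already tracks the data."""
        state = NormalizerState(time_constant=10_000.0)
        for _ in range(100):
            normalize(5.0, state, dt=1.0)
        assert state.running_mean == pytest.approx(5.0, rel=1e-9)


class TestTeachingSignal:
    def test_zero_input_zero_under_both_modes(self):
        for rectify in (True, False):
            cfg = TeachingConfig(rectify=rectify)
            assert teaching_signal(0.0, cfg) == 0.0

    def test_rectification_boundary_at_beta_3(self):
        assert teaching_signal(-3.0, TeachingConfig(rectify=True)) == 0.0
        assert teaching_signal(-3.0, TeachingConfig(rectify=False)) == pytest.approx(
            math.tanh(-1.0)
        )

    def test_positive_branch_value(self):
        assert teaching_signal(3.0, TeachingConfig()) == pytest.approx(math.tanh(1.0))

    def test_error_signal_arithmetic(self):
        assert error(0.5, 0.5, 1.0) == 0.0
        assert error(0.7, 0.5, 1.0) == pytest.approx(0.2)
        assert error(0.7, 0.5, -1.0) == pytest.approx(1.2)


class TestRLS:
    def test_zero_error_leaves_weights_but_updates_P(self):
        rls = RLSState.create(4, alpha=10.0)
        P0 = rls.P.copy()
        w = np.ones(4)
        r = np.array([1.0, 0.5, -0.5, 2.0])
        rls, w2 = rls_update(rls, w, r, e=0.0)
        np.testing.assert_array_equal(w2, w)
        assert not np.array_equal(rls.P, P0)

    def test_single_step_closed_form(self):
        """From P = I/alpha the shift is -e r / (alpha + ||r||^2)."""
        alpha, e = 25.0, 0.8
        r = np.array([1.0, -2.0, 0.5])
        rls = RLSState.create(3, alpha)
        w = np.zeros(3)
        _, w2 = rls_update(rls, w, r, e)
        expected = -e * r / (alpha + r @ r)
        np.testing.assert_allclose(w2, expected, rtol=1e-12)

    def test_one_pass_equals_ridge_solution(self, rng):
        """RLS over a fixed sample solves ridge regression exactly."""
        alpha = 7.0
        R = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        rls = RLSState.create(5, alpha)
        w = np.zeros(5)
        for i in range(20):
            e = w @ R[i] - y[i]
            rls, w = rls_update(rls, w, R[i], e)
        w_ridge = np.linalg.solve(R.T @ R + alpha * np.eye(5), R.T @ y)
        assert np.linalg.norm(w - w_ridge) / np.linalg.norm(w_ridge) < 1e-10

    def test_P_stays_symmetric_positive_definite(self, rng):
        rls = RLSState.create(6, alpha=3.0)
        w = np.zeros(6)
        for i in range(500):
            r = rng.normal(size=6)
            rls, w = rls_update(rls, w, r, e=float(rng.normal()))
            if i % 100 == 0:
                np.linalg.cholesky((rls.P + rls.P.T) / 2)
                assert np.allclose(rls.P, rls.P.T, atol=1e-10)


def _pair_setup(seed, protocol, n=60, tau=10.0):
    params = ReservoirParams(n_neurons=n, n_readout=n, tau=tau)
    w1 = init_weights(params, protocol.alphabet_size, seed)
    w2 = init_weights(params, protocol.alphabet_size, seed + 1)
    return params, w1, w2


class TestTrainPair:
    def test_zero_training_window_preserves_weights(self, small_protocol):
        params, w1, w2 = _pair_setup(0, small_protocol)
        sig = generate_input(small_protocol, seed=5)
        res = train_pair(
            w1, w2, params, params, TeachingConfig(),
            TrainingConfig(t_train_ms=0.0), sig, seed=3,
        )
        np.testing.assert_array_equal(res.weights_1.readout, w1.readout)
        np.testing.assert_array_equal(res.weights_2.readout, w2.readout)

    def test_weights_frozen_after_training_window(self, small_protocol):
        """Training on [0, T) then simulating further equals training on a
        stream truncated at T: no update occurs past the window."""
        params, w1, w2 = _pair_setup(1, small_protocol)
        sig = generate_input(small_protocol, seed=6)  # 2 s stream
        cut = sig.truncated(1000)  # first 1 s
        res_full = train_pair(
            w1, w2, params, params, TeachingConfig(),
            TrainingConfig(t_train_ms=1000.0), sig, seed=4,
        )
        res_cut = train_pair(
            w1, w2, params, params, TeachingConfig(),
            TrainingConfig(t_train_ms=1000.0), cut, seed=4,
        )
        np.testing.assert_array_equal(
            res_full.weights_1.readout, res_cut.weights_1.readout
        )

    def test_determinism(self, small_protocol):
        params, w1, w2 = _pair_setup(2, small_protocol)
        sig = generate_input(small_protocol, seed=7)
        a = train_pair(w1, w2, params, params, TeachingConfig(),
                       TrainingConfig(t_train_ms=None), sig, seed=5)
        b = train_pair(w1, w2, params, params, TeachingConfig(),
                       TrainingConfig(t_train_ms=None), sig, seed=5)
        np.testing.assert_array_equal(a.weights_1.readout, b.weights_1.readout)
        np.testing.assert_array_equal(a.z_train_2, b.z_train_2)

    def test_consensus_training_correlates_readouts(self):
        """kappa = (1, 1): trained readout traces correlate positively on a
        shared stream in the majority of seeds."""
        protocol = ChunkProtocol(total_duration=5000.0)
        wins = 0
        n_seeds = 5
        for seed in range(n_seeds):
            params, w1, w2 = _pair_setup(10 + seed, protocol, n=100)
            sig = generate_input(protocol, seed=100 + seed)
            res = train_pair(w1, w2, params, params, TeachingConfig(),
                             TrainingConfig(t_train_ms=None), sig, seed=seed)
            # correlation over the trained half of the run
            c = np.corrcoef(res.z_train_1[2500:], res.z_train_2[2500:])[0, 1]
            wins += c > 0
        assert wins > n_seeds / 2

    def test_competitive_training_can_anticorrelate(self):
        """kappa = (-1, -1), unrectified: some seeds show anti-correlated
        readouts (competitive dynamics)."""
        protocol = ChunkProtocol(total_duration=5000.0)
        cfg = TeachingConfig(kappa_1=-1.0, kappa_2=-1.0, rectify=False)
        corrs = []
        for seed in range(5):
            params, w1, w2 = _pair_setup(20 + seed, protocol, n=100)
            sig = generate_input(protocol, seed=200 + seed)
            res = train_pair(w1, w2, params, params, cfg,
                             TrainingConfig(t_train_ms=None), sig, seed=seed)
            corrs.append(np.corrcoef(res.z_train_1[2500:], res.z_train_2[2500:])[0, 1])
        assert min(corrs) < 0
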