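"""Firing-rate model: scaling, clamping, integration, Lyapunov spectra."""

import numpy as np
import pytest

from intflex import synthetic
from intflex.model import (
    ModelParams,
    lyapunov_spectrum,
    scale_offdiagonal,
    set_recurrent,
    shuffle_edges,
    sigmoid,
    simulate,
    simulate_clamped,
    steady_state_input,
    windowed_model_int,
)


def offdiag_rowsums(W):
    off = ~np.eye(W.shape[0], dtype=bool)
    return W[off].reshape(W.shape[0], -1).sum(axis=1)


class TestConnectomeOps:
    def test_scaling_sets_mean_offdiagonal_rowsum_to_two(self, rng):
        W = rng.lognormal(size=(50, 50))
        np.fill_diagonal(W, 0.0)
        Ws = scale_offdiagonal(W)
        assert offdiag_rowsums(Ws).mean() == pytest.approx(2.0, abs=1e-9)

    def test_homogeneous_weights_give_every_rowsum_two(self):
        W = np.full((30, 30), 0.7)
        np.fill_diagonal(W, 0.0)
        assert np.allclose(offdiag_rowsums(scale_offdiagonal(W)), 2.0)

    def test_scaling_is_idempotent(self, rng):
        W = rng.lognormal(size=(40, 40))
        np.fill_diagonal(W, 0.0)
        once = scale_offdiagonal(W)
        assert np.allclose(scale_offdiagonal(once), once)

    def test_scaling_leaves_diagonal_untouched(self, rng):
        W = rng.lognormal(size=(20, 20))
        np.fill_diagonal(W, 3.3)
        assert np.all(np.diag(scale_offdiagonal(W)) == 3.3)

    def test_all_zero_offdiagonal_rejected(self):
        with pytest.raises(ValueError):
            scale_offdiagonal(np.eye(5))

    def test_set_recurrent(self, rng):
        W = rng.lognormal(size=(20, 20))
        np.fill_diagonal(W, 0.0)
        W2 = set_recurrent(W, 2.5)
        assert np.all(np.diag(W2) == 2.5)
        off = ~np.eye(20, dtype=bool)
        assert np.array_equal(W2[off], W[off])
        assert np.all(np.diag(set_recurrent(W, 0.0)) == 0.0)

    def test_shuffle_preserves_weight_multiset_and_diagonal(self, rng):
        W = rng.lognormal(size=(30, 30))
        np.fill_diagonal(W, 1.0)
        Ws = shuffle_edges(W, fraction=1.0, seed=0)
        off = ~np.eye(30, dtype=bool)
        assert np.array_equal(np.sort(Ws[off]), np.sort(W[off]))
        assert np.array_equal(np.diag(Ws), np.diag(W))

    def test_partial_shuffle_leaves_most_entries(self, rng):
        W = rng.lognormal(size=(40, 40))
        np.fill_diagonal(W, 0.0)
        Ws = shuffle_edges(W, fraction=0.2, seed=1)
        off = ~np.eye(40, dtype=bool)
        assert (Ws[off] == W[off]).mean() >= 0.8

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            shuffle_edges(np.ones((5, 5)), fraction=0.0)


class TestSteadyStateInput:
    def test_uncoupled_half_rate_needs_input_three(self):
        # logit(0.5) = 0, so the input just cancels the bias
        val = steady_state_input(np.zeros((4, 4)), 0.5, np.zeros(4), region=0)
        assert val == pytest.approx(3.0)

    def test_substitution_returns_target_exactly(self, small_connectome, rng):
        W = small_connectome
        x = rng.uniform(0.1, 0.9, W.shape[0])
        for target in (0.1, 0.6):
            itil = steady_state_input(W, target, x)
            u = (W @ x - np.diag(W) * x) + np.diag(W) * target - 3.0 + itil
            assert np.allclose(sigmoid(u), target, atol=1e-12)

    @pytest.mark.parametrize("bad", [0.0, 1.0, 1.5])
    def test_target_outside_open_interval_rejected(self, bad):
        with pytest.raises(ValueError):
            steady_state_input(np.zeros((3, 3)), bad, np.zeros(3))


class TestSimulate:
    def test_uncoupled_noiseless_rest_reaches_fixed_point(self):
        p = ModelParams(noise_sd=0.0, duration=30.0, discard=20.0, seed=0)
        res = simulate(p, np.zeros((5, 5)))
        assert np.allclose(res.rates[-1], 1.0 / (1.0 + np.exp(1.5)), atol=1e-6)

    def test_uncoupled_noiseless_stimulated_fixed_point(self):
        p = ModelParams(noise_sd=0.0, input=1.0, duration=30.0, discard=20.0,
                        seed=0)
        res = simulate(p, np.zeros((5, 5)))
        assert np.allclose(res.rates[-1], 1.0 / (1.0 + np.exp(1.0)), atol=1e-6)

    def test_rates_stay_in_unit_interval(self, small_connectome):
        p = ModelParams(duration=40.0, discard=10.0, seed=2)
        res = simulate(p, small_connectome)
        assert res.rates.min() > 0.0 and res.rates.max() < 1.0

    def test_seeded_reproducibility(self, small_connectome):
        p = ModelParams(duration=20.0, discard=5.0, seed=9)
        r1 = simulate(p, small_connectome)
        r2 = simulate(p, small_connectome)
        assert np.array_equal(r1.rates, r2.rates)

    def test_initial_conditions_forgotten_after_discard(self):
        # noiseless uncoupled relaxation: post-discard trajectory is at the
        # fixed point regardless of the random initial state
        for seed in (0, 1):
            p = ModelParams(noise_sd=0.0, duration=30.0, discard=20.0, seed=seed)
            res = simulate(p, np.zeros((3, 3)))
            assert np.allclose(res.rates, 1.0 / (1.0 + np.exp(1.5)), atol=1e-6)

    def test_windowed_model_int_window_count(self, small_connectome):
        p = ModelParams(duration=60.0, discard=20.0, seed=3)
        res = simulate(p, small_connectome)
        tbl = windowed_model_int(res)
        assert tbl.window.nunique() == 4  # 40 retained s -> 4 windows
        conv = tbl[tbl.converged]
        assert (conv.tau_s > 0).all()


class TestClamping:
    @pytest.mark.parametrize("target", [0.1, 0.6])
    def test_mean_rate_reaches_target(self, small_connectome, target):
        p = ModelParams(duration=80.0, discard=40.0, seed=4)
        res = simulate_clamped(p, small_connectome, target)
        assert res.rates.mean() == pytest.approx(target, abs=0.02)

    def test_mean_rate_error_shrinks_with_controller_time_constant(
        self, small_connectome
    ):
        errs = []
        for tau_i in (0.5, 0.05, 0.005):
            p = ModelParams(duration=60.0, discard=30.0, tau_input=tau_i, seed=5)
            res = simulate_clamped(p, small_connectome, 0.1)
            errs.append(abs(res.rates.mean() - 0.1))
        assert errs[0] > errs[-1]

    def test_input_trace_recorded_per_region(self, small_connectome):
        p = ModelParams(duration=30.0, discard=20.0, seed=6)
        res = simulate_clamped(p, small_connectome, 0.3)
        assert res.input_trace.shape == res.rates.shape


class TestLyapunov:
    def test_uncoupled_exponents_equal_node_decay_rate(self):
        p = ModelParams(noise_sd=0.0, seed=0)
        lam = lyapunov_spectrum(p, np.zeros((6, 6)), n_steps=2000)
        assert np.allclose(lam, -1.0 / p.tau_node, rtol=0.01)

    def test_spectrum_sorted_descending(self, small_connectome):
        lam = lyapunov_spectrum(ModelParams(seed=1), small_connectome,
                                n_steps=1500)
        assert np.all(np.diff(lam) <= 1e-12)

    def test_default_configuration_not_chaotic(self, small_connectome):
        lam = lyapunov_spectrum(ModelParams(seed=1), small_connectome,
                                n_steps=3000)
        assert lam[0] <= 1e-3

    def test_independent_of_deviation_basis(self, small_connectome):
        # finite-time exponents of a clustered spectrum converge only ~1/T,
        # so two random orthonormal starts agree to finite-time precision
        p = ModelParams(seed=2)
        l1 = lyapunov_spectrum(p, small_connectome, n_steps=3000, seed=10)
        l2 = lyapunov_spectrum(p, small_connectome, n_steps=3000, seed=11)
        # tolerance in units of the node decay rate 1/tau
        assert np.abs(l1 - l2).max() * p.tau_node < 0.05

    def test_matches_fixed_point_eigenvalue_oracle(self, small_connectome):
        # noise-free dynamics settle at a fixed point, where the true
        # spectrum is the real part of the Jacobian eigenvalues
        from intflex.model import _jacobian, simulate

        p = ModelParams(noise_sd=0.0, duration=60.0, discard=50.0, seed=3)
        xfix = simulate(p, small_connectome).rates[-1]
        J = _jacobian(xfix, small_connectome, p, p.input)
        top_true = np.linalg.eigvals(J).real.max()
        lam = lyapunov_spectrum(p, small_connectome, n_steps=6000, seed=4)
        assert abs(lam[0] - top_true) * p.tau_node < 0.05
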