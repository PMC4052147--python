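"""Particle-filter building blocks: weights, resampling, ESS, decode."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ppdecode as pp
from ppdecode import (
    StateModel,
    decode,
    effective_sample_size,
    log_weight_update,
    systematic_resample,
)
from ppdecode.binning import bin_spikes


class TestEffectiveSampleSize:
    def test_uniform_weights(self):
        assert effective_sample_size(np.full(64, 1 / 64)) == pytest.approx(64)

    def test_one_hot(self):
        w = np.zeros(10)
        w[3] = 1.0
        assert effective_sample_size(w) == pytest.approx(1.0)

    def test_direct_formula(self):
        assert effective_sample_size([0.5, 0.25, 0.25]) == pytest.approx(1 / 0.375)


class TestLogWeightUpdate:
    def test_identical_intensities_leave_weights_unchanged(self):
        prior = np.log([0.2, 0.3, 0.5])
        lam = np.full((3, 4), 7.0)
        w = log_weight_update(prior, np.array([0, 1, 0, 0]), lam, 0.01)
        np.testing.assert_allclose(w, [0.2, 0.3, 0.5])

    def test_two_particle_likelihood_ratio(self):
        # dN=1, λ = (10, 20) Hz, Δ = 10 ms: weights ∝ λΔ e^{−λΔ}
        lam = np.array([[10.0], [20.0]])
        w = log_weight_update(np.log([0.5, 0.5]), np.array([1]), lam, 0.01)
        raw = np.array([0.1 * np.exp(-0.1), 0.2 * np.exp(-0.2)])
        np.testing.assert_allclose(w, raw / raw.sum())
        np.testing.assert_allclose(w, [0.35591, 0.64409], atol=5e-6)

    def test_no_spikes_equal_rates_uniform(self):
        lam = np.full((5, 3), 4.0)
        w = log_weight_update(np.log(np.full(5, 0.2)), np.zeros(3), lam, 0.01)
        np.testing.assert_allclose(w, 0.2)

    def test_weights_normalized_after_update(self):
        rng = np.random.default_rng(0)
        lam = rng.gamma(2, 5, (100, 20))
        dn = (rng.random(20) < 0.1).astype(int)
        w = log_weight_update(np.log(np.full(100, 0.01)), dn, lam, 0.01)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_total_underflow_raises_degeneracy(self):
        lam = np.full((3, 1), 1e6)  # λΔ = 1e4: e^{-1e4} underflows
        prior = np.full(3, -np.inf)
        with pytest.raises(pp.WeightDegeneracyError):
            log_weight_update(prior, np.array([0]), lam, 0.01)


class TestSystematicResample:
    def test_uniform_weights_identity_at_zero_offset(self):
        idx = systematic_resample(np.full(4, 0.25), 0.0)
        np.testing.assert_array_equal(idx, [0, 1, 2, 3])

    def test_degenerate_posterior_copies_winner(self):
        w = np.zeros(5)
        w[2] = 1.0
        np.testing.assert_array_equal(systematic_resample(w, 0.7), [2] * 5)

    def test_hand_traced_stratified_inversion(self):
        idx = systematic_resample(np.array([0.1, 0.6, 0.3]), 0.5, n_samples=5)
        np.testing.assert_array_equal(idx, [1, 1, 1, 2, 2])

    def test_unnormalized_weights_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            systematic_resample(np.array([0.5, 0.2]), 0.1)

    def test_tree_and_serial_scan_agree(self):
        rng = np.random.default_rng(1)
        w = rng.dirichlet(np.ones(257))
        u = 0.37
        np.testing.assert_array_equal(
            systematic_resample(w, u, scan="tree"),
            systematic_resample(w, u, scan="serial"),
        )

    @given(st.integers(0, 10_000))
    def test_copy_counts_within_floor_ceil(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 60))
        w = rng.dirichlet(np.ones(n) * rng.uniform(0.2, 3.0))
        idx = systematic_resample(w, float(rng.random()))
        counts = np.bincount(idx, minlength=n)
        assert np.all(counts >= np.floor(n * w))
        assert np.all(counts <= np.ceil(n * w))

    def test_resampling_unbiased_in_expectation(self):
        # mean of resampled states over many draws ≈ weighted mean
        rng = np.random.default_rng(2)
        n = 64
        w = rng.dirichlet(np.ones(n))
        states = rng.standard_normal(n)
        draws = 10_000
        means = np.empty(draws)
        for d in range(draws):
            means[d] = states[systematic_resample(w, rng.random())].mean()
        se = means.std(ddof=1) / np.sqrt(draws)
        assert abs(means.mean() - w @ states) < 4 * se


class TestDecode:
    @staticmethod
    def _empty_session(n_bins=50, dt=0.01):
        return bin_spikes([], dt, n_bins * dt)

    def test_prior_only_filter_keeps_initial_mean(self):
        # no neurons, Q = 0, A = identity: trajectory pinned at initial mean
        m = StateModel(A=np.eye(2), Q=np.zeros((2, 2)), kind="mov", n_kinematic=2)
        res = decode(
            self._empty_session(),
            [],
            m,
            n_particles=100,
            seed=3,
            init_mean=np.array([1.5, -2.0]),
            init_cov=np.zeros((2, 2)),
        )
        np.testing.assert_allclose(res.trajectory, np.tile([1.5, -2.0], (50, 1)))

    def test_same_seed_identical_result(self, small_session):
        spikes, kin, truth, cfg = small_session
        from ppdecode.binning import build_history_covariates
        from ppdecode.state_space import fit_transition

        hist = build_history_covariates(spikes, cfg.history_length)
        trans = fit_transition(kin, hist, kind="full")
        a = decode(spikes, truth, trans, n_particles=100, seed=12, hist=hist)
        b = decode(spikes, truth, trans, n_particles=100, seed=12, hist=hist)
        np.testing.assert_array_equal(a.trajectory, b.trajectory)
        np.testing.assert_array_equal(a.ess_trace, b.ess_trace)

    def test_ess_bounds_and_finite_trajectory(self, small_session):
        spikes, kin, truth, cfg = small_session
        from ppdecode.binning import build_history_covariates
        from ppdecode.state_space import fit_transition

        hist = build_history_covariates(spikes, cfg.history_length)
        trans = fit_transition(kin, hist, kind="full")
        res = decode(spikes, truth, trans, n_particles=100, seed=1, hist=hist)
        assert np.all(np.isfinite(res.trajectory))
        assert np.all(res.ess_trace >= 1.0 - 1e-9)
        assert np.all(res.ess_trace <= 100 + 1e-9)

    def test_decoding_beats_constant_mean_baseline(self, small_session):
        spikes, kin, truth, cfg = small_session
        res = pp.run_session(
            spikes, kin, train_bins=6000, kinds=("full",), n_particles=200,
            decode_seed=5,
        )
        # z-scored truth has unit variance: the train-mean predictor scores ~1
        assert res["full"]["pos_rmse"] < 1.0


class TestSMCDecoderEstimator:
    def test_sklearn_param_interface(self):
        dec = pp.SMCDecoder(kind="mov", n_particles=55)
        assert dec.get_params()["n_particles"] == 55
        dec.set_params(n_particles=77)
        assert dec.n_particles == 77

    def test_predict_before_fit_rejected(self, small_session):
        spikes, _, _, _ = small_session
        with pytest.raises(RuntimeError, match="not fitted"):
            pp.SMCDecoder().predict(spikes)
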