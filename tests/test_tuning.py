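"""Tuning-model evaluation, fitting, and history-length selection."""

import numpy as np
import pytest

import ppdecode as pp
from ppdecode import (
    PointProcessGLM,
    TuningParams,
    fit_tuning,
    intensity,
    select_history_length,
)
from ppdecode.binning import build_history_covariates


def make_params(alpha0=0.0, alpha=(0.0, 0.0), beta=(), kind=None, wl=0.1):
    kind = kind or ("full" if len(beta) else "mov")
    return TuningParams(
        alpha0=alpha0,
        alpha=np.asarray(alpha, float),
        beta=np.asarray(beta, float),
        kind=kind,
        window_length=wl,
        bin_width=0.01,
    )


class TestIntensity:
    def test_all_zero_parameters_give_unit_rate(self):
        p = make_params()
        assert intensity(p, [3.0, -1.0]) == pytest.approx(1.0)

    def test_background_rate_only(self):
        p = make_params(alpha0=np.log(10.0))
        assert intensity(p, [0.5, 0.5]) == pytest.approx(10.0)

    def test_direct_evaluation_with_history(self):
        p = make_params(alpha0=1.0, alpha=(0.5, -0.2), beta=(0.1,))
        # exp(1 + 0.5 − 0.2 + 0.2) = exp(1.5)
        assert intensity(p, [1.0, 1.0], [2.0]) == pytest.approx(np.exp(1.5))

    def test_dimension_mismatch_rejected(self):
        p = make_params(alpha=(0.5, -0.2))
        with pytest.raises(ValueError, match="dimension"):
            intensity(p, [1.0, 2.0, 3.0])

    def test_monotone_in_positive_coefficient(self):
        p = make_params(alpha=(0.7, 0.0))
        xs = np.column_stack([np.linspace(-2, 2, 9), np.zeros(9)])
        lam = intensity(p, xs)
        assert np.all(np.diff(lam) > 0)

    def test_mov_kind_ignores_history(self):
        p = make_params(alpha0=0.5, alpha=(0.1, 0.1), kind="mov")
        assert intensity(p, [1.0, 1.0]) == intensity(p, [1.0, 1.0], H=None)


class TestFitTuning:
    def test_constant_rate_recovers_background(self):
        # homogeneous 8 Hz neuron, kinematics-free fit
        rng = np.random.default_rng(0)
        T, dt = 200.0, 0.01
        n = int(T / dt)
        y = (rng.random(n) < -np.expm1(-8.0 * dt)).astype(int)
        glm = PointProcessGLM(kind="mov", n_kinematic=1, bin_width=dt)
        glm.fit(np.zeros((n, 1)), y)
        se = glm.stderr_[0]
        assert abs(glm.alpha0_ - np.log(8.0)) < 3 * se

    def test_zero_spike_neuron_rejected(self):
        glm = PointProcessGLM(kind="mov", n_kinematic=1)
        with pytest.raises(ValueError, match="no spikes"):
            glm.fit(np.zeros((100, 1)), np.zeros(100))

    def test_parameter_recovery_single_replicate(self, small_session):
        spikes, kin, truth, cfg = small_session
        hist = build_history_covariates(spikes, cfg.history_length)
        params = fit_tuning(
            np.minimum(spikes.counts[:, 0], 1), kin, hist, kind="full",
            bin_width=cfg.bin_width,
        )
        err = np.abs(params.coef_vector() - truth[0].coef_vector())
        assert np.all(err < 5 * params.stderr + 0.05)

    def test_full_model_loglik_dominates_mov(self, small_session):
        spikes, kin, _, cfg = small_session
        hist = build_history_covariates(spikes, cfg.history_length)
        y = np.minimum(spikes.counts[:, 1], 1)
        full = fit_tuning(y, kin, hist, kind="full", bin_width=cfg.bin_width)
        mov = fit_tuning(y, kin, None, kind="mov", bin_width=cfg.bin_width)
        assert full.log_likelihood >= mov.log_likelihood

    def test_refit_is_deterministic(self, small_session):
        spikes, kin, _, cfg = small_session
        hist = build_history_covariates(spikes, cfg.history_length)
        y = np.minimum(spikes.counts[:, 2], 1)
        a = fit_tuning(y, kin, hist, kind="full", bin_width=cfg.bin_width)
        b = fit_tuning(y, kin, hist, kind="full", bin_width=cfg.bin_width)
        np.testing.assert_array_equal(a.coef_vector(), b.coef_vector())

    def test_json_round_trip(self, small_session):
        spikes, kin, _, cfg = small_session
        y = np.minimum(spikes.counts[:, 3], 1)
        p = fit_tuning(y, kin, None, kind="mov", bin_width=cfg.bin_width)
        q = TuningParams.from_json(p.to_json())
        np.testing.assert_allclose(q.coef_vector(), p.coef_vector())
        assert q.kind == p.kind


class TestSelectHistoryLength:
    def test_single_candidate_returned_unchanged(self, small_session):
        spikes, kin, _, _ = small_session
        best, aucs = select_history_length(spikes, kin, [0.1], train_bins=6000)
        assert best == 0.1
        assert set(aucs) == {0.1}
        assert 0.0 <= aucs[0.1] <= 1.0

    def test_non_multiple_candidate_rejected(self, small_session):
        spikes, kin, _, _ = small_session
        with pytest.raises(ValueError, match="multiple"):
            select_history_length(spikes, kin, [0.015], train_bins=6000)

    def test_uncoupled_ensemble_flat_auc_curve(self):
        # β = 0: window length carries no information, curve flat within noise
        cfg = pp.SimulationConfig(
            n_neurons=8, duration=200.0, seed=9, coupling_scale=0.0
        )
        rng = np.random.default_rng(cfg.seed)
        kin = pp.simulate_kinematics(cfg, rng)
        tun = pp.draw_true_tuning(cfg, rng)
        spikes = pp.simulate_ensemble(kin, tun, rng=rng)
        _, aucs = select_history_length(
            spikes, kin, [0.02, 0.1, 0.2], train_bins=10_000
        )
        vals = np.array(list(aucs.values()))
        assert vals.max() - vals.min() < 0.02
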