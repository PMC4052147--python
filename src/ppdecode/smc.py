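"""Sequential Monte Carlo filtering of kinematics from point-process spikes.

Each 10-ms bin the filter (i) propagates N_s weighted kinematic particles
through the linear transition model, (ii) multiplies each particle's weight
by the joint point-process likelihood of the observed binary spike vector
under every neuron's tuning model, (iii) normalises (in the log domain with
max-subtraction), records the weighted posterior mean, and (iv) applies
systematic resampling, resetting the weights to 1/N_s. Cumulative weights
for the resampler come from the balanced-tree prefix scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from sklearn.base import BaseEstimator

from .binning import SpikeTrainSet, build_history_covariates
from .scan import inclusive_scan
from .state_space import StateModel, fit_transition, propagate
from .tuning import KinematicSeries, PointProcessGLM, TuningParams

__all__ = [
    "ParticleSet",
    "DecodeResult",
    "WeightDegeneracyError",
    "effective_sample_size",
    "log_weight_update",
    "systematic_resample",
    "decode",
    "SMCDecoder",
]


class WeightDegeneracyError(RuntimeError):
    """All importance weights underflowed to zero at one bin."""


@dataclass
class ParticleSet:
    states: np.ndarray  # [N_s, D]
    weights: np.ndarray  # normalized, sums to 1
    step: int = 0

    @property
    def n_particles(self) -> int:
        return self.states.shape[0]

    def mean(self) -> np.ndarray:
        return self.weights @ self.states


@dataclass
class DecodeResult:
    """Posterior-mean trajectory plus filter diagnostics."""

    trajectory: np.ndarray  # [n_bins, D]
    ess_trace: np.ndarray  # [n_bins]
    config: dict = field(default_factory=dict)
    degeneracy_events: list = field(default_factory=list)  # bin indices


def effective_sample_size(weights) -> float:
    """ESS = 1 / Σ w_i² of a normalized weight vector."""
    w = np.asarray(weights, dtype=float)
    return float(1.0 / np.sum(w * w))


def log_weight_update(prior_log_weights, dN_k, intensities, bin_width: float):
    """Multiply prior weights by the joint bin likelihood; normalize stably.

    ``intensities`` is [N_s × C] (λ in Hz per particle per neuron), ``dN_k``
    the binary spike vector over neurons. Raises WeightDegeneracyError if
    every weight underflows.
    """
    lw = np.asarray(prior_log_weights, dtype=float)
    lam = np.asarray(intensities, dtype=float)
    dn = np.minimum(np.asarray(dN_k), 1).astype(float)
    if lam.ndim != 2 or lam.shape[0] != lw.size or lam.shape[1] != dn.size:
        raise ValueError("inconsistent shapes in weight update")
    lamdt = lam * bin_width
    spiking = dn > 0
    ll = -lamdt.sum(axis=1)
    if np.any(spiking):
        with np.errstate(divide="ignore"):
            ll = ll + np.sum(np.log(lamdt[:, spiking]), axis=1)
    lw = lw + ll
    m = np.max(lw)
    if not np.isfinite(m):
        raise WeightDegeneracyError("all importance weights vanished")
    w = np.exp(lw - m)
    return w / w.sum()


def systematic_resample(
    weights, u: float, n_samples: int | None = None, scan: str = "tree"
) -> np.ndarray:
    """Systematic (stratified inverse-CDF) resampling with one shared draw.

    Positions p_i = (i + u)/n are inverted against the cumulative weights;
    index_i is the smallest j with p_i < cumsum(w)[j]. The copy count of
    particle j is ⌊n w_j⌋ or ⌈n w_j⌉. ``n_samples`` defaults to the number
    of weights.
    """
    w = np.asarray(weights, dtype=float)
    if not 0.0 <= u < 1.0:
        raise ValueError("u must lie in [0, 1)")
    if abs(w.sum() - 1.0) > 1e-8:
        raise ValueError(f"weights are not normalized (sum {w.sum():.3e})")
    if scan == "tree":
        cum = inclusive_scan(w)
    elif scan == "serial":
        cum = np.cumsum(w)
    else:
        raise ValueError(f"unknown scan mode {scan!r}")
    cum = cum / cum[-1]  # absorb roundoff so the last edge is exactly 1
    n = w.size if n_samples is None else int(n_samples)
    positions = (np.arange(n) + u) / n
    idx = np.searchsorted(cum, positions, side="right")
    return np.minimum(idx, w.size - 1)


def decode(
    spikes: SpikeTrainSet,
    tuning: list[TuningParams],
    transition: StateModel,
    n_particles: int = 1000,
    seed: int = 0,
    *,
    hist=None,
    init_mean=None,
    init_cov=None,
    scan: str = "tree",
    kernel_bandwidth: float | None = None,
) -> DecodeResult:
    """Run the particle filter over every bin of ``spikes``.

    ``hist`` may supply precomputed ensemble-history covariates for the
    decode span (e.g. built from the whole session so early windows are
    complete); otherwise it is built from ``spikes`` alone. Initial
    particles are drawn from N(init_mean, init_cov) (defaults: standard
    normal in the normalized kinematic space). Fully reproducible from
    ``seed``; ``kernel_bandwidth`` (the posterior kernel width δ) is
    recorded in the config but not needed for the mean output.
    """
    if n_particles < 2:
        raise ValueError("need at least 2 particles")
    if not tuning:
        kinds = {transition.kind}
    else:
        kinds = {p.kind for p in tuning}
        if len(kinds) > 1:
            raise ValueError("tuning models must share one kind")
        if len({p.bin_width for p in tuning}) > 1:
            raise ValueError("tuning models must share the bin width")
    kind = kinds.pop()
    dt = spikes.bin_width
    D = transition.n_kinematic
    C = spikes.n_neurons
    n_bins = spikes.n_bins

    if kind == "full":
        if hist is None:
            wl = tuning[0].window_length if tuning else 0.1
            hist = build_history_covariates(spikes, wl)
        Hmat = np.asarray(hist.H, dtype=float)
    else:
        Hmat = np.zeros((n_bins, C))

    if tuning:
        A0 = np.array([p.alpha0 for p in tuning])
        Amat = np.column_stack([p.alpha for p in tuning])  # [D, C]
        Bmat = (
            np.column_stack([p.beta for p in tuning])  # [C, C]
            if kind == "full"
            else np.zeros((C, C))
        )
    dN = np.minimum(spikes.counts, 1)

    rng = np.random.default_rng(seed)
    init_mean = np.zeros(D) if init_mean is None else np.asarray(init_mean, float)
    init_cov = np.eye(D) if init_cov is None else np.asarray(init_cov, float)
    wc, Vc = np.linalg.eigh(init_cov)
    L0 = Vc * np.sqrt(np.clip(wc, 0.0, None))
    states = init_mean + rng.standard_normal((n_particles, D)) @ L0.T
    weights = np.full(n_particles, 1.0 / n_particles)

    trajectory = np.empty((n_bins, D))
    ess = np.empty(n_bins)
    events: list[int] = []

    for k in range(n_bins):
        H_prev = Hmat[k - 1] if k > 0 else Hmat[0]
        noise = rng.standard_normal((n_particles, D))
        states = propagate(states, H_prev, transition, noise)
        if tuning:
            eta = A0 + Hmat[k] @ Bmat + states @ Amat
            lam = np.exp(np.clip(eta, -50.0, 50.0))
            try:
                weights = log_weight_update(np.log(weights), dN[k], lam, dt)
            except WeightDegeneracyError:
                weights = np.full(n_particles, 1.0 / n_particles)
                events.append(k)
        trajectory[k] = weights @ states
        ess[k] = effective_sample_size(weights)
        idx = systematic_resample(weights, rng.random(), scan=scan)
        states = states[idx]
        weights = np.full(n_particles, 1.0 / n_particles)

    return DecodeResult(
        trajectory=trajectory,
        ess_trace=ess,
        config={
            "n_particles": n_particles,
            "seed": seed,
            "tuning_kind": kind,
            "transition_kind": transition.kind,
            "scan": scan,
            "kernel_bandwidth": kernel_bandwidth,
        },
        degeneracy_events=events,
    )


def _subset_spikes(spikes: SpikeTrainSet, keep: np.ndarray) -> SpikeTrainSet:
    return SpikeTrainSet(
        spike_times=[spikes.spike_times[j] for j in keep],
        bin_width=spikes.bin_width,
        duration=spikes.duration,
        counts=spikes.counts[:, keep],
    )


def _slice_spikes(spikes: SpikeTrainSet, start: int, stop: int) -> SpikeTrainSet:
    dt = spikes.bin_width
    t0, t1 = start * dt, stop * dt
    times = [t[(t >= t0) & (t < t1)] - t0 for t in spikes.spike_times]
    return SpikeTrainSet(
        spike_times=times,
        bin_width=dt,
        duration=(stop - start) * dt,
        counts=spikes.counts[start:stop],
    )


class SMCDecoder(BaseEstimator):
    """End-to-end encode/decode pipeline as a fit/predict estimator.

    ``fit(spikes, kin)`` on a training span z-scores the kinematic columns
    (training mean/SD), fits one tuning GLM per neuron and the linear
    transition model (both of the configured ``kind``); ``predict`` runs
    the particle filter over a test span and returns the posterior-mean
    trajectory in the normalized kinematic space (``inverse_transform``
    maps back to raw units).

    Neurons that never spike in the training span are dropped from the
    ensemble (their tuning model would be degenerate); ``kept_neurons_``
    records the surviving indices.
    """

    def __init__(
        self,
        kind: str = "full",
        window_length: float = 0.1,
        n_particles: int = 1000,
        random_state: int = 0,
        likelihood: str = "bernoulli",
        scan: str = "tree",
    ):
        self.kind = kind
        self.window_length = window_length
        self.n_particles = n_particles
        self.random_state = random_state
        self.likelihood = likelihood
        self.scan = scan

    def _transform_kin(self, kin: KinematicSeries) -> np.ndarray:
        return (kin.x - self.scaler_mean_) / self.scaler_scale_

    def inverse_transform(self, traj: np.ndarray) -> np.ndarray:
        return traj * self.scaler_scale_ + self.scaler_mean_

    def fit(self, spikes: SpikeTrainSet, kin: KinematicSeries):
        if spikes.n_bins != kin.n_bins:
            raise ValueError("spikes and kinematics must share the bin grid")
        self.scaler_mean_ = kin.x.mean(axis=0)
        self.scaler_scale_ = kin.x.std(axis=0)
        if np.any(self.scaler_scale_ <= 0):
            raise ValueError("constant kinematic column; cannot standardize")
        Xz = self._transform_kin(kin)

        keep = np.nonzero(spikes.counts.sum(axis=0) > 0)[0]
        sub = _subset_spikes(spikes, keep)
        self.kept_neurons_ = keep
        hist = (
            build_history_covariates(sub, self.window_length)
            if self.kind == "full"
            else None
        )
        design = Xz if hist is None else np.hstack([Xz, hist.H])
        counts = np.minimum(sub.counts, 1)
        self.tunings_ = []
        for j in range(sub.n_neurons):
            glm = PointProcessGLM(
                kind=self.kind,
                n_kinematic=kin.n_dims,
                bin_width=spikes.bin_width,
                window_length=self.window_length,
                likelihood=self.likelihood,
            )
            glm.fit(design, counts[:, j])
            params = glm.params_
            params.scaler = {
                "mean": self.scaler_mean_.tolist(),
                "scale": self.scaler_scale_.tolist(),
            }
            self.tunings_.append(params)

        kin_z = KinematicSeries(t=kin.t, x=Xz)
        self.transition_ = fit_transition(kin_z, hist, kind=self.kind)
        self.init_mean_ = Xz.mean(axis=0)
        self.init_cov_ = np.cov(Xz, rowvar=False)
        return self

    def predict(
        self, spikes: SpikeTrainSet, bins: tuple[int, int] | None = None
    ) -> DecodeResult:
        """Decode the span ``bins = (start, stop)`` of a session.

        ``spikes`` is the whole-session spike set so that history windows
        at the start of the span are complete.
        """
        if not hasattr(self, "tunings_"):
            raise RuntimeError("SMCDecoder is not fitted")
        start, stop = bins if bins is not None else (0, spikes.n_bins)
        sub = _subset_spikes(spikes, self.kept_neurons_)
        if self.kind == "full":
            hist_full = build_history_covariates(sub, self.window_length)
            hist = type(hist_full)(
                H=hist_full.H[start:stop], window_length=hist_full.window_length
            )
        else:
            hist = None
        return decode(
            _slice_spikes(sub, start, stop),
            self.tunings_,
            self.transition_,
            n_particles=self.n_particles,
            seed=self.random_state,
            hist=hist,
            init_mean=self.init_mean_,
            init_cov=self.init_cov_,
            scan=self.scan,
        )
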