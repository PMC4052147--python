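"""Coupled-ensemble spike-train and kinematics simulator.

Emulates a target-pursuit motor session: smooth 2D joystick kinematics
sampled at 20 Hz (velocity and acceleration obtained by first differences,
as in the recordings the package targets) interpolated to the 10-ms bin
grid, and an ensemble of neurons whose conditional intensities follow the
log-linear tuning model with kinematic modulation and sparse, mixed-sign
ensemble coupling through the recent-history counts H. Spikes are emitted
at most once per bin with probability 1 − exp(−λΔ) — the >99 % binary-bin
regime of 10-ms windows — and the event time inside a spiking bin is the
first arrival of a rate-λ process conditioned on at least one arrival, so
time-rescaling under the true intensity is calibrated.

Default statistics target a cortical multielectrode session: 40 neurons,
400 s, mean rates in the 4–11 Hz range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .binning import SpikeTrainSet
from .tuning import KinematicSeries, TuningParams

__all__ = [
    "SimulationConfig",
    "simulate_kinematics",
    "draw_true_tuning",
    "simulate_ensemble",
    "make_dataset",
]

# nominal stationary sds of (pos, vel, acc) for the default process, used
# to put per-column tuning modulation on a comparable scale
_KIN_SD = (1.0, 0.8, 1.4)


@dataclass
class SimulationConfig:
    """Generative settings for one synthetic session."""

    n_neurons: int = 40
    duration: float = 400.0  # seconds
    bin_width: float = 0.01
    history_length: float = 0.1
    seed: int = 0
    # kinematic process (jerk-driven damped oscillator, per axis)
    sample_rate: float = 20.0  # Hz of the source kinematic sampling
    gamma: float = 3.0  # jerk damping, 1/s
    theta: float = 3.0  # velocity damping, 1/s^2
    kappa: float = 2.0  # position restoring, 1/s^3
    sigma: float = 3.0  # jerk noise scale
    # tuning generation
    base_rate_range: tuple = (4.5, 9.0)  # Hz, exp(alpha0) drawn log-uniform
    kin_modulation: tuple = (0.25, 0.25, 0.10)  # depth per (pos, vel, acc)
    coupling_density: float = 0.2  # fraction of incoming connections
    # total coupling drive: per-link sd is coupling_sd / sqrt(density * C),
    # keeping the summed-coupling variance independent of ensemble size
    coupling_sd: float = 0.8
    # cross-links are inhibition-dominated (mean shift in units of the
    # per-link sd), which keeps positive feedback loops from running away
    coupling_mean_shift: float = -0.5
    self_coupling_mean: float = -0.5  # refractory self-history, stabilises bursts
    self_coupling_sd: float = 0.1
    coupling_scale: float = 1.0  # 0 → uncoupled (beta = 0) control session


def simulate_kinematics(config: SimulationConfig, rng=None) -> KinematicSeries:
    """Smooth 2D kinematics on the bin grid.

    Position follows a mean-reverting third-order linear process at the
    source rate; the velocity column is diff(position)/dt_src and the
    acceleration column diff(velocity)/dt_src (zero-padded at the start),
    then all six columns are linearly interpolated to the Δ grid.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    dt = 1.0 / config.sample_rate
    n_src = int(round(config.duration * config.sample_rate)) + 1
    pos = np.zeros((n_src, 2))
    vel = np.zeros(2)
    acc = np.zeros(2)
    sq = config.sigma * np.sqrt(dt)
    noise = rng.standard_normal((n_src - 1, 2))
    for n in range(1, n_src):
        pos[n] = pos[n - 1] + dt * vel
        vel = vel + dt * acc
        acc = acc + dt * (
            -config.gamma * acc - config.theta * vel - config.kappa * pos[n - 1]
        ) + sq * noise[n - 1]

    v = np.zeros_like(pos)
    v[1:] = np.diff(pos, axis=0) / dt
    a = np.zeros_like(pos)
    a[1:] = np.diff(v, axis=0) / dt
    src = np.hstack([pos, v, a])
    t_src = np.arange(n_src) * dt

    n_bins = int(round(config.duration / config.bin_width))
    t = np.arange(n_bins) * config.bin_width
    x = np.column_stack([np.interp(t, t_src, src[:, i]) for i in range(6)])
    return KinematicSeries(t=t, x=x)


def draw_true_tuning(config: SimulationConfig, rng=None) -> list[TuningParams]:
    """Random ground-truth full tuning models for the ensemble."""
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    C = config.n_neurons
    lo, hi = config.base_rate_range
    mod = np.repeat(config.kin_modulation, 2) / np.repeat(_KIN_SD, 2)
    out = []
    for j in range(C):
        alpha0 = rng.uniform(np.log(lo), np.log(hi))
        alpha = rng.normal(0.0, mod)
        beta = np.zeros(C)
        links = rng.random(C) < config.coupling_density
        links[j] = False
        link_sd = config.coupling_sd / np.sqrt(max(config.coupling_density * C, 4.0))
        beta[links] = rng.normal(
            config.coupling_mean_shift * link_sd, link_sd, links.sum()
        )
        beta[j] = rng.normal(config.self_coupling_mean, config.self_coupling_sd)
        beta *= config.coupling_scale
        out.append(
            TuningParams(
                alpha0=alpha0,
                alpha=alpha,
                beta=beta,
                kind="full",
                window_length=config.history_length,
                bin_width=config.bin_width,
            )
        )
    return out


def simulate_ensemble(
    kin: KinematicSeries,
    true_tuning: list[TuningParams],
    seed: int = 0,
    rng=None,
) -> SpikeTrainSet:
    """Generate the ensemble spike trains causally from the tuning models.

    Bins are visited in order; each λ_j uses the realized past spikes as
    the history covariate. Any λΔ > 5 aborts with a stability error.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    C = len(true_tuning)
    if C == 0:
        raise ValueError("need at least one tuning model")
    dt = true_tuning[0].bin_width
    wl = true_tuning[0].window_length
    if any(p.bin_width != dt or p.window_length != wl for p in true_tuning):
        raise ValueError("tuning models must share bin width and window length")
    if any(p.beta.size != C for p in true_tuning):
        raise ValueError("coupling vectors must span the ensemble")
    L = int(round(wl / dt))
    n_bins = kin.n_bins

    A0 = np.array([p.alpha0 for p in true_tuning])
    Amat = np.column_stack([p.alpha for p in true_tuning])
    Bmat = np.column_stack([p.beta for p in true_tuning])
    base = A0 + kin.x @ Amat  # [n_bins, C]

    U = rng.random((n_bins, C))
    V = rng.random((n_bins, C))
    counts = np.zeros((n_bins, C), dtype=np.int64)
    lam_store = np.empty((n_bins, C))
    H = np.zeros(C)
    ring = np.zeros((L, C))
    for k in range(n_bins):
        lam = np.exp(base[k] + H @ Bmat)
        if np.any(lam * dt > 5.0):
            j = int(np.argmax(lam))
            raise RuntimeError(
                f"runaway self-excitation: neuron {j} reached λΔ = "
                f"{lam[j] * dt:.2f} at bin {k}"
            )
        lam_store[k] = lam
        sp = U[k] < -np.expm1(-lam * dt)
        counts[k] = sp
        old = ring[k % L]
        H += sp - old
        ring[k % L] = sp

    # event time within a spiking bin: first arrival of a rate-λ process
    # conditioned on >= 1 arrival in the bin (truncated exponential)
    spike_times = []
    for j in range(C):
        ks = np.nonzero(counts[:, j])[0]
        lam = lam_store[ks, j]
        p = -np.expm1(-lam * dt)
        off = -np.log1p(-V[ks, j] * p) / lam
        spike_times.append(ks * dt + off)
    return SpikeTrainSet(
        spike_times=spike_times,
        bin_width=dt,
        duration=n_bins * dt,
        counts=counts,
    )


def make_dataset(config: SimulationConfig, outdir) -> dict:
    """Write spikes.tsv, kin.tsv and truth.json for one session."""
    from . import io as ppio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    kin = simulate_kinematics(config, rng)
    tuning = draw_true_tuning(config, rng)
    spikes = simulate_ensemble(kin, tuning, rng=rng)

    paths = {
        "spikes": outdir / "spikes.tsv",
        "kin": outdir / "kin.tsv",
        "truth": outdir / "truth.json",
    }
    ppio.write_spikes_tsv(paths["spikes"], spikes)
    ppio.write_kinematics_tsv(paths["kin"], kin)
    truth = {
        "config": asdict(config),
        "tuning": [json.loads(p.to_json()) for p in tuning],
        "mean_rates_hz": spikes.mean_rates().tolist(),
    }
    paths["truth"].write_text(json.dumps(truth, sort_keys=True, indent=1))
    return {k: str(v) for k, v in paths.items()}
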