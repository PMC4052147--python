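"""Decoding-accuracy metrics and the full/mov model comparison protocol.

A comparison runs, per synthetic session: split the session into a training
and a test span, fit the complete pipeline (tuning GLMs + transition model)
for each model kind on the training span, decode the test span, and score
root-mean-square error per kinematic dimension in the normalized kinematic
space. Session-level RMSEs are aggregated across sessions (averaged, not
pooled over bins, matching the paired-test structure) and compared with a
left-tail paired Student t-test against the alternative that the full
model's error is smaller.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .binning import SpikeTrainSet
from .simulate import SimulationConfig, draw_true_tuning, simulate_ensemble, simulate_kinematics
from .smc import SMCDecoder
from .tuning import KinematicSeries

__all__ = [
    "rmse",
    "paired_left_tail_ttest",
    "ComparisonReport",
    "run_session",
    "run_comparison",
]

_DIMS = ("pos_x", "pos_y", "vel_x", "vel_y", "acc_x", "acc_y")


def rmse(true_series, est_series) -> float:
    """Root mean square error between two equal-length series."""
    a = np.asarray(true_series, dtype=float)
    b = np.asarray(est_series, dtype=float)
    if a.shape != b.shape or a.size < 1:
        raise ValueError("series must be equal-length and non-empty")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def paired_left_tail_ttest(errors_a, errors_b) -> float:
    """p-value of the paired t-test with alternative mean(a − b) < 0.

    Small p supports that the errors in ``a`` are systematically smaller
    than their session-matched counterparts in ``b``.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length samples with n >= 2")
    d = a - b
    if np.std(d) == 0:
        raise ValueError("degenerate test: all paired differences identical")
    res = stats.ttest_rel(a, b, alternative="less")
    return float(res.pvalue)


@dataclass
class ComparisonReport:
    """Per-dimension decoding accuracy of two model kinds across sessions."""

    rmse_by_dim: dict  # kind -> [n_sessions, 6] list
    pos_rmse: dict  # kind -> [n_sessions] combined 2D position RMSE
    improvement_pct: dict  # dim name (+ "position") -> percent
    p_values: dict  # dim name (+ "position") -> left-tail p, full vs mov
    n_sessions: int
    seeds: list
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def conv(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(type(o))

        return json.dumps(self.__dict__, sort_keys=True, indent=1, default=conv)


def run_session(
    spikes: SpikeTrainSet,
    kin: KinematicSeries,
    train_bins: int,
    kinds=("mov", "full"),
    n_particles: int = 1000,
    window_length: float = 0.1,
    decode_seed: int = 0,
    likelihood: str = "bernoulli",
    n_decode_runs: int = 1,
) -> dict:
    """Fit and decode one session; per-kind per-dimension RMSE.

    ``n_decode_runs`` independent filter realizations (seeds decode_seed,
    decode_seed+1, ...) are averaged per kind, reducing the Monte-Carlo
    variance of the RMSE estimate. Returns ``{kind: {"rmse_by_dim": (6,),
    "pos_rmse": float, "ess_min": float, "degeneracy_events": int}}``;
    RMSE in normalized units of the training-span scaler of each pipeline.
    """
    if not 0 < train_bins < spikes.n_bins:
        raise ValueError("session shorter than the requested training split")
    from .smc import _slice_spikes  # split helper

    train_kin = KinematicSeries(t=kin.t[:train_bins], x=kin.x[:train_bins])
    out = {}
    for kind in kinds:
        dec = SMCDecoder(
            kind=kind,
            window_length=window_length,
            n_particles=n_particles,
            random_state=decode_seed,
            likelihood=likelihood,
        )
        dec.fit(_slice_spikes(spikes, 0, train_bins), train_kin)
        true_z = (kin.x[train_bins:] - dec.scaler_mean_) / dec.scaler_scale_
        per_dim_runs, pos_runs, ess_min, degen = [], [], np.inf, 0
        for r in range(n_decode_runs):
            dec.set_params(random_state=decode_seed + r)
            res = dec.predict(spikes, bins=(train_bins, spikes.n_bins))
            per_dim_runs.append(
                [rmse(true_z[:, i], res.trajectory[:, i]) for i in range(kin.n_dims)]
            )
            pos_runs.append(
                float(np.sqrt(np.mean((true_z[:, :2] - res.trajectory[:, :2]) ** 2)))
            )
            ess_min = min(ess_min, float(res.ess_trace.min()))
            degen += len(res.degeneracy_events)
        out[kind] = {
            "rmse_by_dim": np.mean(per_dim_runs, axis=0),
            "pos_rmse": float(np.mean(pos_runs)),
            "ess_min": ess_min,
            "degeneracy_events": degen,
            "result": res,
        }
    return out


def _make_session(config: SimulationConfig):
    rng = np.random.default_rng(config.seed)
    kin = simulate_kinematics(config, rng)
    tuning = draw_true_tuning(config, rng)
    spikes = simulate_ensemble(kin, tuning, rng=rng)
    return spikes, kin, tuning


def run_comparison(
    sessions,
    train_seconds: float = 200.0,
    kinds=("mov", "full"),
    n_particles: int = 1000,
    window_length: float = 0.1,
    decode_seed: int = 0,
    likelihood: str = "bernoulli",
    n_decode_runs: int = 1,
) -> ComparisonReport:
    """Model comparison over several sessions.

    ``sessions`` is a list of SimulationConfig (simulated on the fly) or of
    ``(spikes, kin)`` pairs. The first ``train_seconds`` of each session
    train the pipelines; the remainder is decoded and scored.
    """
    if len(sessions) < 2:
        raise ValueError("need at least 2 sessions for the paired t-test")
    per_kind = {k: [] for k in kinds}
    pos_per_kind = {k: [] for k in kinds}
    seeds = []
    for s in sessions:
        if isinstance(s, SimulationConfig):
            spikes, kin, _ = _make_session(s)
            seeds.append(s.seed)
        else:
            spikes, kin = s
            seeds.append(None)
        train_bins = int(round(train_seconds / spikes.bin_width))
        res = run_session(
            spikes,
            kin,
            train_bins,
            kinds=kinds,
            n_particles=n_particles,
            window_length=window_length,
            decode_seed=decode_seed,
            likelihood=likelihood,
            n_decode_runs=n_decode_runs,
        )
        for k in kinds:
            per_kind[k].append(res[k]["rmse_by_dim"])
            pos_per_kind[k].append(res[k]["pos_rmse"])

    rmse_by_dim = {k: np.array(v) for k, v in per_kind.items()}
    pos_rmse = {k: np.array(v) for k, v in pos_per_kind.items()}
    improvement = {}
    p_values = {}
    if set(kinds) >= {"mov", "full"}:
        mov = rmse_by_dim["mov"].mean(axis=0)
        full = rmse_by_dim["full"].mean(axis=0)
        for i, name in enumerate(_DIMS):
            improvement[name] = float((mov[i] - full[i]) / mov[i] * 100.0)
            p_values[name] = paired_left_tail_ttest(
                rmse_by_dim["full"][:, i], rmse_by_dim["mov"][:, i]
            )
        pm, pf = pos_rmse["mov"].mean(), pos_rmse["full"].mean()
        improvement["position"] = float((pm - pf) / pm * 100.0)
        p_values["position"] = paired_left_tail_ttest(
            pos_rmse["full"], pos_rmse["mov"]
        )
    return ComparisonReport(
        rmse_by_dim={k: v.tolist() for k, v in rmse_by_dim.items()},
        pos_rmse={k: v.tolist() for k, v in pos_rmse.items()},
        improvement_pct=improvement,
        p_values=p_values,
        n_sessions=len(sessions),
        seeds=seeds,
        config={
            "train_seconds": train_seconds,
            "n_particles": n_particles,
            "window_length": window_length,
            "decode_seed": decode_seed,
            "likelihood": likelihood,
            "n_decode_runs": n_decode_runs,
        },
    )
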