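"""Spike binning, the point-process bin likelihood, and ensemble-history
covariates.

A spike train on (0, T] is treated as a point process observed in fine bins
of width Δ (10 ms by default). With conditional intensity λ(t), the
probability of the binary count dN in one bin is well approximated by

    P(dN) = exp(dN · log(λΔ) − λΔ),

and the recent ensemble activity of neuron j at time t is the number of its
spikes in the strict past window [t − l, t).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpikeTrainSet",
    "HistoryCovariates",
    "bin_spikes",
    "observation_logprob",
    "build_history_covariates",
]

# relative tolerance used to snap spike times sitting on a bin edge into the
# later (half-open convention) bin despite float division wobble
_EDGE_TOL = 1e-9


@dataclass
class SpikeTrainSet:
    """Per-neuron spike times plus binned counts over a common grid.

    Bins are half-open, 0-based: bin k covers [k·Δ, (k+1)·Δ); a spike
    exactly on an edge belongs to the later bin.
    """

    spike_times: list  # list of 1-d sorted arrays, seconds
    bin_width: float
    duration: float
    counts: np.ndarray = field(repr=False)  # [n_bins, C] int

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[1]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def mean_rates(self) -> np.ndarray:
        """Empirical mean firing rate per neuron, Hz."""
        return self.counts.sum(axis=0) / (self.n_bins * self.bin_width)


@dataclass
class HistoryCovariates:
    """H[k, j] = number of neuron-j spikes in [t_k − l, t_k), t_k = k·Δ."""

    H: np.ndarray  # [n_bins, C] int
    window_length: float


def _bin_index(times: np.ndarray, bin_width: float) -> np.ndarray:
    r = times / bin_width
    idx = np.floor(r)
    nearest = np.rint(r)
    on_edge = np.abs(r - nearest) <= _EDGE_TOL * np.maximum(nearest, 1.0)
    idx[on_edge] = nearest[on_edge]
    return idx.astype(np.int64)


def bin_spikes(spike_times, bin_width: float, duration: float) -> SpikeTrainSet:
    """Bin per-neuron event times into counts on a common half-open grid.

    ``duration`` should be a positive multiple of ``bin_width``; a trailing
    partial bin is dropped. Spikes at or beyond the last full bin edge are
    ignored.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    n_bins = int(np.floor(duration / bin_width + _EDGE_TOL))
    if n_bins < 1:
        raise ValueError("duration shorter than one bin")

    cleaned = []
    for j, t in enumerate(spike_times):
        t = np.asarray(t, dtype=float)
        if t.ndim != 1:
            raise ValueError(f"neuron {j}: spike times must be a 1-d sequence")
        if t.size and np.any(np.diff(t) < 0):
            raise ValueError(f"neuron {j}: spike times must be nondecreasing")
        if t.size and t[0] < 0:
            raise ValueError(f"neuron {j}: negative spike time")
        cleaned.append(t)

    counts = np.zeros((n_bins, len(cleaned)), dtype=np.int64)
    for j, t in enumerate(cleaned):
        if t.size == 0:
            continue
        idx = _bin_index(t, bin_width)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        np.add.at(counts[:, j], idx, 1)
    return SpikeTrainSet(
        spike_times=cleaned,
        bin_width=bin_width,
        duration=n_bins * bin_width,
        counts=counts,
    )


def observation_logprob(dN, intensity, bin_width: float):
    """Log-probability of binary bin counts under intensity λ (Hz).

    Returns ``dN·log(λΔ) − λΔ`` elementwise. Counts above 1 are clamped to
    1 with a warning (multi-spike bins are rare at Δ = 10 ms).
    """
    lam = np.asarray(intensity, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("intensity must be strictly positive")
    dN = np.asarray(dN)
    if np.any(dN > 1):
        warnings.warn(
            f"{int(np.sum(dN > 1))} bin(s) with count > 1 clamped to 1 "
            "for the bin likelihood",
            stacklevel=2,
        )
        dN = np.minimum(dN, 1)
    lamdt = lam * bin_width
    return dN * np.log(lamdt) - lamdt


def build_history_covariates(
    spikes: SpikeTrainSet, window_length: float
) -> HistoryCovariates:
    """Sum counts over the l/Δ bins strictly preceding each bin.

    Bins before t = 0 contribute nothing, so the first few rows are partial
    windows. Raw (unclamped) counts are summed.
    """
    dt = spikes.bin_width
    ratio = window_length / dt
    n_lag = int(round(ratio))
    if n_lag < 1 or abs(ratio - n_lag) > 1e-6:
        raise ValueError(
            f"window_length {window_length} is not a positive multiple of "
            f"bin_width {dt}"
        )
    cum = np.vstack(
        [np.zeros((1, spikes.n_neurons), dtype=np.int64), np.cumsum(spikes.counts, axis=0)]
    )
    k = np.arange(spikes.n_bins)
    lo = np.maximum(k - n_lag, 0)
    H = cum[k] - cum[lo]
    return HistoryCovariates(H=H, window_length=n_lag * dt)
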