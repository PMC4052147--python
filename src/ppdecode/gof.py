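"""Goodness-of-fit for conditional-intensity models.

Two complementary assessments of how well a fitted intensity λ(t) explains
an observed spike train:

* ROC analysis — threshold λ(t) at every level c to predict spike/no-spike
  per bin; the area under the TPR-vs-FPR curve (AUC) is the probability
  that a random spike bin receives a higher intensity than a random
  non-spike bin (ties counted half).
* Time-rescaling KS analysis — under the true intensity the transformed
  inter-spike intervals z_j = 1 − exp(−∫ λ dt) are i.i.d. uniform on
  [0, 1); the KS plot compares their order statistics with uniform
  quantiles b_k = (k − 1/2)/n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = ["RocResult", "KsResult", "roc_auc", "time_rescale", "ks_summary"]


@dataclass
class RocResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


@dataclass
class KsResult:
    z_sorted: np.ndarray
    b: np.ndarray
    ks_stat: float
    band_95: float
    n: int

    @property
    def within_band(self) -> bool:
        return self.ks_stat <= self.band_95


def roc_auc(intensity_series, spike_series) -> RocResult:
    """ROC curve and AUC of per-bin spike prediction by thresholding λ."""
    lam = np.asarray(intensity_series, dtype=float)
    dn = np.minimum(np.asarray(spike_series), 1).astype(int)
    if lam.shape != dn.shape or lam.ndim != 1:
        raise ValueError("intensity and spike series must be equal-length vectors")
    n_spike = int(dn.sum())
    if n_spike == 0 or n_spike == dn.size:
        raise ValueError("AUC undefined: need at least one spike and one non-spike bin")
    fpr, tpr, thr = roc_curve(dn, lam, drop_intermediate=False)
    auc = float(roc_auc_score(dn, lam))
    return RocResult(thresholds=thr, tpr=tpr, fpr=fpr, auc=auc)


def time_rescale(
    spike_times,
    intensity_per_bin,
    bin_width: float,
    *,
    one_event_per_bin: bool = False,
) -> np.ndarray:
    """Rescaled inter-spike intervals under a piecewise-constant intensity.

    z_j = 1 − exp(−∫_{u_j}^{u_{j+1}} λ(t) dt), j = 1..J−1, with the
    integral evaluated exactly (partial bins prorated, not snapped).

    With ``one_event_per_bin=True`` the conditional intensity is treated as
    vanishing from each event to the end of its bin. This is the exact
    conditional intensity of a generator that emits at most one event per
    bin with probability 1 − exp(−λΔ) (the binary-bin regime), whose
    process is dead for the remainder of a spiking bin; without the
    correction such data carry an O(λΔ) calibration bias.
    """
    u = np.asarray(spike_times, dtype=float)
    lam = np.asarray(intensity_per_bin, dtype=float)
    if u.size < 2:
        raise ValueError("time rescaling needs at least 2 spikes")
    if np.any(np.diff(u) < 0):
        raise ValueError("spike times must be nondecreasing")
    if np.any(lam < 0):
        raise ValueError("intensity must be nonnegative")
    t_max = lam.size * bin_width
    if u[0] < 0 or u[-1] > t_max + 1e-9:
        raise ValueError("spike times fall outside the intensity support")
    # cumulative integral Λ(t) is piecewise linear with knots at bin edges
    edges = np.arange(lam.size + 1) * bin_width
    Lambda = np.concatenate([[0.0], np.cumsum(lam) * bin_width])
    Lu = np.interp(u, edges, Lambda)
    integrals = np.diff(Lu)
    if one_event_per_bin:
        # drop the dead segment from each event to its bin's right edge
        k = np.minimum((u[:-1] / bin_width).astype(int), lam.size - 1)
        bin_end = np.interp((k + 1) * bin_width, edges, Lambda)
        integrals = np.maximum(Lu[1:] - np.maximum(bin_end, Lu[:-1]), 0.0)
    return -np.expm1(-integrals)


def ks_summary(z) -> KsResult:
    """KS statistic of z against uniform quantiles, with the 95% band.

    The band is the large-sample approximation 1.36/√n.
    """
    z = np.sort(np.asarray(z, dtype=float))
    n = z.size
    if n < 1:
        raise ValueError("empty rescaled-time vector")
    b = (np.arange(1, n + 1) - 0.5) / n
    ks = float(np.max(np.abs(z - b)))
    return KsResult(z_sorted=z, b=b, ks_stat=ks, band_95=1.36 / np.sqrt(n), n=n)
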