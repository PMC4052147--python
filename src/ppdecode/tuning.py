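"""Log-linear conditional-intensity (tuning) models and their fitting.

The "full" tuning model expresses a neuron's conditional intensity as

    λ(x_t, H_t) = exp(α0 + Σ_i α_i x_t^i + Σ_j β_j H_t^j),

where x_t is the D-dimensional kinematic vector, H_t^j is the recent spike
count of ensemble neuron j in the strict past window [t − l, t) (including
the target neuron's own history), exp(α0) is the background rate, and the
β_j capture ensemble coupling. The "mov" reduction drops the history term.

Fitting maximises the exact likelihood of the binary bin observations,
P(spike in bin) = 1 − exp(−λΔ): a binomial GLM with a complementary
log-log link and offset log Δ. The Poisson point-process form
Σ dN log(λΔ) − λΔ (its Δ→0 limit) is available via ``likelihood``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .binning import HistoryCovariates, SpikeTrainSet, build_history_covariates
from .gof import roc_auc

__all__ = [
    "TuningParams",
    "KinematicSeries",
    "PointProcessGLM",
    "intensity",
    "fit_tuning",
    "select_history_length",
]


@dataclass
class KinematicSeries:
    """Bin-aligned kinematics: columns (pos_x, pos_y, vel_x, vel_y, acc_x, acc_y)."""

    t: np.ndarray  # [n_bins] bin left-edge times, seconds
    x: np.ndarray  # [n_bins, D]
    columns: tuple = ("pos_x", "pos_y", "vel_x", "vel_y", "acc_x", "acc_y")

    @property
    def n_bins(self) -> int:
        return self.x.shape[0]

    @property
    def n_dims(self) -> int:
        return self.x.shape[1]


@dataclass
class TuningParams:
    """Parameter set of one neuron's tuning model (α0, α, β, kind, l, Δ)."""

    alpha0: float
    alpha: np.ndarray
    beta: np.ndarray  # empty for kind="mov"
    kind: str  # "mov" | "full"
    window_length: float
    bin_width: float
    # optional fit metadata
    converged: bool | None = None
    log_likelihood: float | None = None
    stderr: np.ndarray | None = field(default=None, repr=False)
    scaler: dict | None = None  # {"mean": [...], "scale": [...]} of the kin columns

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.kind not in ("mov", "full"):
            raise ValueError(f"unknown tuning kind {self.kind!r}")
        if self.kind == "mov" and self.beta.size:
            raise ValueError("mov tuning model must have empty beta")
        if not np.isfinite(self.alpha0):
            raise ValueError("alpha0 must be finite")

    def coef_vector(self) -> np.ndarray:
        return np.concatenate([[self.alpha0], self.alpha, self.beta])

    def to_json(self) -> str:
        d = asdict(self)
        d["alpha"] = self.alpha.tolist()
        d["beta"] = self.beta.tolist()
        d["stderr"] = None if self.stderr is None else np.asarray(self.stderr).tolist()
        d["window_length_s"] = d.pop("window_length")
        d["bin_width_s"] = d.pop("bin_width")
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "TuningParams":
        d = json.loads(s)
        d["window_length"] = d.pop("window_length_s")
        d["bin_width"] = d.pop("bin_width_s")
        if d.get("stderr") is not None:
            d["stderr"] = np.asarray(d["stderr"])
        return cls(**d)


def intensity(params: TuningParams, x, H=None):
    """Evaluate λ (Hz) for kinematic vector(s) x and history vector(s) H.

    Accepts a single vector or a [n, D] / [n, C] batch; for kind="mov" the
    history argument is ignored.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != params.alpha.size:
        raise ValueError(
            f"kinematic dimension {x.shape[1]} != {params.alpha.size}"
        )
    eta = params.alpha0 + x @ params.alpha
    if params.kind == "full":
        if H is None:
            raise ValueError("full tuning model requires a history vector")
        H = np.atleast_2d(np.asarray(H, dtype=float))
        if H.shape[1] != params.beta.size:
            raise ValueError(f"history dimension {H.shape[1]} != {params.beta.size}")
        eta = eta + H @ params.beta
    lam = np.exp(np.clip(eta, -50.0, 50.0))
    return lam if lam.size > 1 else float(lam[0])


class PointProcessGLM(BaseEstimator):
    """Point-process GLM for one neuron's binary bin counts.

    Parameters
    ----------
    kind : {"full", "mov"}
        Whether the design includes the ensemble-history block.
    n_kinematic : int
        Number of leading kinematic columns in X; the remaining columns
        are ensemble-history counts (kind="full" only).
    bin_width : float
        Bin width Δ in seconds (enters as offset log Δ).
    window_length : float
        History window l in seconds (recorded in the fitted parameters).
    likelihood : {"bernoulli", "poisson"}
        "bernoulli" fits the exact binary-observation likelihood
        (binomial GLM, cloglog link); "poisson" fits the point-process
        pseudo-likelihood Σ dN log(λΔ) − λΔ.
    max_iter, tol : IRLS stopping rule.

    Attributes
    ----------
    alpha0_, alpha_, beta_ : fitted coefficients
    stderr_ : Wald standard errors, ordered (α0, α, β)
    converged_ : bool
    log_likelihood_ : float, maximised log-likelihood
    params_ : TuningParams
    """

    def __init__(
        self,
        kind: str = "full",
        n_kinematic: int = 6,
        bin_width: float = 0.01,
        window_length: float = 0.1,
        likelihood: str = "bernoulli",
        max_iter: int = 100,
        tol: float = 1e-8,
    ):
        self.kind = kind
        self.n_kinematic = n_kinematic
        self.bin_width = bin_width
        self.window_length = window_length
        self.likelihood = likelihood
        self.max_iter = max_iter
        self.tol = tol

    def _design(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-d [n_bins, n_features]")
        if self.kind == "mov":
            X = X[:, : self.n_kinematic]
        elif X.shape[1] < self.n_kinematic:
            raise ValueError("X has fewer columns than n_kinematic")
        return sm.add_constant(X, has_constant="add")

    def fit(self, X, y):
        """Fit on design X = [kinematics | history counts], y = bin counts."""
        D = self._design(X)
        y = np.minimum(np.asarray(y), 1).astype(float)
        if y.shape[0] != D.shape[0]:
            raise ValueError("X and y have different numbers of bins")
        if y.sum() < 1:
            raise ValueError("cannot fit a tuning model to a neuron with no spikes")
        offset = np.full(y.shape[0], np.log(self.bin_width))
        if self.likelihood == "bernoulli":
            family = sm.families.Binomial(link=sm.families.links.CLogLog())
        elif self.likelihood == "poisson":
            family = sm.families.Poisson()
        else:
            raise ValueError(f"unknown likelihood {self.likelihood!r}")

        # deterministic initialisation: background rate at the mean rate
        start = np.zeros(D.shape[1])
        start[0] = np.log(max(y.mean() / self.bin_width, 1e-3))
        model = sm.GLM(y, D, family=family, offset=offset)
        res = model.fit(
            start_params=start, maxiter=self.max_iter, tol=self.tol, disp=0
        )
        self.converged_ = bool(res.converged)
        self.log_likelihood_ = float(res.llf)
        coefs = np.asarray(res.params, dtype=float)
        self.stderr_ = np.asarray(res.bse, dtype=float)
        self.alpha0_ = float(coefs[0])
        nk = self.n_kinematic
        self.alpha_ = coefs[1 : 1 + nk]
        self.beta_ = coefs[1 + nk :] if self.kind == "full" else np.empty(0)
        self.params_ = TuningParams(
            alpha0=self.alpha0_,
            alpha=self.alpha_,
            beta=self.beta_,
            kind=self.kind,
            window_length=self.window_length,
            bin_width=self.bin_width,
            converged=self.converged_,
            log_likelihood=self.log_likelihood_,
            stderr=self.stderr_,
        )
        return self

    def predict(self, X):
        """Conditional intensity λ (Hz) per bin."""
        if not hasattr(self, "params_"):
            raise RuntimeError("PointProcessGLM is not fitted")
        X = np.asarray(X, dtype=float)
        nk = self.n_kinematic
        H = X[:, nk:] if self.kind == "full" else None
        lam = intensity(self.params_, X[:, :nk], H)
        return np.atleast_1d(lam)

    def score(self, X, y):
        """Mean point-process log-likelihood per bin (Eq-2 form)."""
        from .binning import observation_logprob

        lam = self.predict(X)
        return float(
            np.mean(observation_logprob(np.minimum(y, 1), lam, self.bin_width))
        )

    def wald_interval(self, level: float = 0.95) -> np.ndarray:
        """[n_coef, 2] Wald confidence limits, ordered (α0, α, β)."""
        from scipy.stats import norm

        q = norm.ppf(0.5 + level / 2)
        c = np.concatenate([[self.alpha0_], self.alpha_, self.beta_])
        return np.column_stack([c - q * self.stderr_, c + q * self.stderr_])


def fit_tuning(
    target_counts,
    kin: KinematicSeries,
    hist: HistoryCovariates | None,
    kind: str = "full",
    bin_width: float | None = None,
    likelihood: str = "bernoulli",
) -> TuningParams:
    """Fit one neuron's tuning model; returns its TuningParams.

    ``target_counts`` is the neuron's binned 0/1 series; ``hist`` holds the
    ensemble-history counts (required for kind="full").
    """
    if kind == "full":
        if hist is None:
            raise ValueError("full tuning model requires history covariates")
        X = np.hstack([kin.x, hist.H])
        wl = hist.window_length
    else:
        X = kin.x
        wl = hist.window_length if hist is not None else 0.0
    est = PointProcessGLM(
        kind=kind,
        n_kinematic=kin.n_dims,
        bin_width=bin_width if bin_width is not None else _infer_dt(kin),
        window_length=wl,
        likelihood=likelihood,
    )
    est.fit(X, target_counts)
    return est.params_


def _infer_dt(kin: KinematicSeries) -> float:
    if kin.n_bins < 2:
        raise ValueError("cannot infer bin width from a single bin")
    return float(kin.t[1] - kin.t[0])


def select_history_length(
    spikes: SpikeTrainSet,
    kin: KinematicSeries,
    candidate_lengths,
    train_bins: int,
    likelihood: str = "bernoulli",
):
    """Choose the history window l by held-out spike-prediction AUC.

    For each candidate l a full tuning model is fitted per neuron on the
    first ``train_bins`` bins; held-out AUC on the remaining bins is
    averaged across neurons. Returns ``(best_length, {l: mean_auc})``;
    ties break toward the shorter window. Neurons that never spike in the
    training span or are constant in the test span are skipped.
    """
    candidates = list(candidate_lengths)
    if not candidates:
        raise ValueError("need at least one candidate window length")
    dt = spikes.bin_width
    for l in candidates:
        if abs(l / dt - round(l / dt)) > 1e-6:
            raise ValueError(f"candidate {l} is not a multiple of bin width {dt}")
    if not 0 < train_bins < spikes.n_bins:
        raise ValueError("train_bins must split the session")

    counts = np.minimum(spikes.counts, 1)
    mean_auc: dict[float, float] = {}
    for l in candidates:
        hist = build_history_covariates(spikes, l)
        X = np.hstack([kin.x, hist.H])
        aucs = []
        for j in range(spikes.n_neurons):
            y_tr = counts[:train_bins, j]
            y_te = counts[train_bins:, j]
            if y_tr.sum() < 1 or y_te.sum() in (0, y_te.size):
                continue
            est = PointProcessGLM(
                kind="full",
                n_kinematic=kin.n_dims,
                bin_width=dt,
                window_length=l,
                likelihood=likelihood,
            )
            est.fit(X[:train_bins], y_tr)
            lam = est.predict(X[train_bins:])
            aucs.append(roc_auc(lam, y_te).auc)
        if not aucs:
            raise ValueError("no neuron usable for AUC at window %.3f" % l)
        mean_auc[l] = float(np.mean(aucs))
    best = max(sorted(candidates), key=lambda l: (mean_auc[l], -l))
    return best, mean_auc
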