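"""Linear-Gaussian kinematic transition model over the augmented state.

The kinematic vector evolves as

    x_k = A s_{k-1} + w,   s_{k-1} = [x_{k-1}, H_{k-1}],   w ~ N(0, Q),

where H_{k-1} is the observed ensemble-history vector (known from past
spikes at decode time and therefore treated as an exogenous regressor, not
a modelled state). The "mov" kind drops the history block, reducing to the
usual random-walk-with-drift kinematic prior. A and Q are estimated by
ordinary least squares / residual covariance, the MLE for this
linear-Gaussian form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .binning import HistoryCovariates
from .tuning import KinematicSeries

__all__ = ["StateModel", "LinearTransition", "fit_transition", "propagate"]


@dataclass
class StateModel:
    """Evolution matrix A [D × (D+C)] (mov: [D × D]) and noise covariance Q."""

    A: np.ndarray
    Q: np.ndarray
    kind: str
    n_kinematic: int

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        if not np.allclose(self.Q, self.Q.T, atol=1e-10):
            raise ValueError("Q must be symmetric")

    @property
    def noise_chol(self) -> np.ndarray:
        """L with L L' = Q via symmetric eigendecomposition, eigenvalues
        floored at 0 (tolerance 1e-10 · trace)."""
        if not hasattr(self, "_L"):
            w, V = np.linalg.eigh(self.Q)
            tol = 1e-10 * max(np.trace(self.Q), 1e-300)
            if np.any(w < -tol):
                raise np.linalg.LinAlgError(
                    f"Q has negative eigenvalue {w.min():.3e} beyond tolerance"
                )
            self._L = V * np.sqrt(np.clip(w, 0.0, None))
        return self._L

    def to_json(self) -> str:
        return json.dumps(
            {
                "A": self.A.tolist(),
                "Q": self.Q.tolist(),
                "kind": self.kind,
                "n_kinematic": self.n_kinematic,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, s: str) -> "StateModel":
        d = json.loads(s)
        return cls(
            A=np.asarray(d["A"]),
            Q=np.asarray(d["Q"]),
            kind=d["kind"],
            n_kinematic=d["n_kinematic"],
        )


class LinearTransition(BaseEstimator):
    """OLS estimator of the transition model.

    fit(S, Y) regresses each row of Y (x_k) on S (s_{k-1}); fitted
    attributes are ``A_`` and ``Q_`` (residual sample covariance) and
    ``model_`` (a StateModel).
    """

    def __init__(self, kind: str = "full", n_kinematic: int = 6):
        self.kind = kind
        self.n_kinematic = n_kinematic

    def fit(self, S, Y):
        S = np.asarray(S, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if S.ndim != 2 or Y.ndim != 2 or S.shape[0] != Y.shape[0]:
            raise ValueError("S and Y must be 2-d with matching rows")
        if S.shape[0] < S.shape[1] + 2:
            raise ValueError(
                f"need at least {S.shape[1] + 2} training rows, got {S.shape[0]}"
            )
        rank = np.linalg.matrix_rank(S)
        if rank < S.shape[1]:
            var = S.var(axis=0)
            bad = [int(i) for i in np.where(var <= 1e-12 * max(var.max(), 1.0))[0]]
            raise ValueError(
                f"regressor matrix is rank deficient (rank {rank} < "
                f"{S.shape[1]}); near-constant columns: {bad}"
            )
        At, _, _, _ = np.linalg.lstsq(S, Y, rcond=None)
        self.A_ = At.T
        resid = Y - S @ At
        self.Q_ = (resid.T @ resid) / resid.shape[0]
        self.model_ = StateModel(
            A=self.A_, Q=self.Q_, kind=self.kind, n_kinematic=self.n_kinematic
        )
        return self


def fit_transition(
    kin: KinematicSeries, hist: HistoryCovariates | None, kind: str = "full"
) -> StateModel:
    """Estimate A, Q from a training span (deterministic)."""
    X = kin.x
    if kind == "full":
        if hist is None:
            raise ValueError("full transition model requires history covariates")
        S = np.hstack([X[:-1], hist.H[:-1]])
    elif kind == "mov":
        S = X[:-1]
    else:
        raise ValueError(f"unknown kind {kind!r}")
    est = LinearTransition(kind=kind, n_kinematic=kin.n_dims)
    est.fit(S, X[1:])
    return est.model_


def propagate(states, H_prev, model: StateModel, noise_draws) -> np.ndarray:
    """One-step particle propagation x' = A [x; H_prev] + L n.

    ``states`` is [N_s × D]; ``noise_draws`` a [N_s × D] standard-normal
    matrix from a seeded generator. Weights are untouched.
    """
    states = np.asarray(states, dtype=float)
    D = model.n_kinematic
    Ax = model.A[:, :D]
    mean = states @ Ax.T
    if model.A.shape[1] > D:
        H_prev = np.asarray(H_prev, dtype=float)
        mean = mean + model.A[:, D:] @ H_prev
    return mean + np.asarray(noise_draws, dtype=float) @ model.noise_chol.T
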