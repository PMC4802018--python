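"""Confidence-weighted Markov-chain smoothing of per-frame registrations.

Per-frame translation estimates of a sequence are treated as observations
of a first-order Markov chain over poses.  The state probability of frame
``i`` is a normal distribution centered on the per-frame optimum ``T_i'``
with covariance ``Sigma_i`` derived from a confidence regression: the
objective value ``rho`` correlates with the registration error, so a
linear model ``e(rho)`` (fitted on annotated data) predicts the error and
sets the per-frame standard deviation.  The transition probability prefers
small frame-to-frame motion: over whole breathing cycles the chamber moves
about a mean position, so transitions are zero-mean normal with velocity
covariance ``Sigma_v`` estimated from annotated trajectories (velocities =
frame differences times the frame rate ``r``).

The maximum a posteriori sequence minimizes the convex quadratic

    sum_i (T_i - T_i')^T Sigma_i^-1 (T_i - T_i')
    + r^2 * sum_{i>=2} (T_i - T_{i-1})^T Sigma_v^-1 (T_i - T_{i-1})

which is solved by quasi-Newton (BFGS) iterations started at the
unfiltered estimates.  The state space is translation-only, matching the
registration module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from ._util import logger
from .projection import RigidTransform
from .registration import FrameRegistration

__all__ = [
    "ConfidenceModel",
    "TransitionModel",
    "Trajectory",
    "evaluate_trajectory",
    "fit_confidence",
    "fit_transition",
    "smooth",
    "smooth_translations",
]

#: minimum predicted error (mm): keeps Sigma_i positive-definite
ERROR_FLOOR_MM = 0.1
#: ridge added to a degenerate velocity covariance, (mm/s)^2
SIGMA_V_RIDGE = 1e-6


@dataclass
class ConfidenceModel:
    """Linear error predictor ``e(rho) = intercept + slope * rho`` (mm).

    Predictions are clamped to ``floor`` (> 0) so the derived state
    covariance stays positive-definite even where the regression would
    predict a non-positive error.
    """

    slope: float
    intercept: float
    floor: float = ERROR_FLOOR_MM

    def predict(self, rho) -> np.ndarray:
        e = self.intercept + self.slope * np.asarray(rho, dtype=float)
        return np.maximum(e, self.floor)

    def state_covariance(self, rho: float) -> np.ndarray:
        """Isotropic 3x3 covariance with sd equal to the predicted error."""
        e = float(self.predict(rho))
        return (e**2) * np.eye(3)

    def to_dict(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept, "floor": self.floor}

    @classmethod
    def from_dict(cls, d: dict) -> "ConfidenceModel":
        return cls(slope=d["slope"], intercept=d["intercept"], floor=d["floor"])


@dataclass
class TransitionModel:
    """Velocity covariance ``Sigma_v`` ((mm/s)^2) of the chamber motion."""

    Sigma_v: np.ndarray

    def __post_init__(self):
        S = np.asarray(self.Sigma_v, dtype=float).reshape(3, 3)
        if not np.allclose(S, S.T, atol=1e-9):
            raise ValueError("Sigma_v must be symmetric")
        if np.linalg.eigvalsh(S).min() <= 0:
            raise ValueError("Sigma_v must be positive-definite")
        self.Sigma_v = S

    def to_dict(self) -> dict:
        return {"Sigma_v": self.Sigma_v.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "TransitionModel":
        return cls(Sigma_v=np.asarray(d["Sigma_v"], dtype=float))


@dataclass
class Trajectory:
    """Per-sequence registration series with filtering state.

    ``frames`` holds the per-frame results (pose ``T_i'`` and objective
    value ``rho_i``); ``frame_rate`` is in frames/s.  ``Sigma_i`` and
    ``filtered`` are populated by :func:`smooth`.
    """

    frames: list[FrameRegistration]
    frame_rate: float
    Sigma_i: list[np.ndarray] = field(default_factory=list)
    filtered: list[RigidTransform] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def translations(self) -> np.ndarray:
        return np.array([f.T_prime.t for f in self.frames], dtype=float)

    @property
    def rho_values(self) -> np.ndarray:
        return np.array([f.rho_value for f in self.frames], dtype=float)


def fit_confidence(training) -> ConfidenceModel:
    """Ordinary least squares of observed error (mm) on objective value rho.

    ``training`` is a sequence of ``(rho, observed_error_mm)`` pairs.  At
    least two distinct rho values are required.  The clamp floor is the
    smallest positive fitted value, never below 0.1 mm.
    """
    data = np.asarray(list(training), dtype=float)
    if data.ndim != 2 or data.shape[1] != 2 or data.shape[0] < 2:
        raise ValueError("need at least two (rho, error) pairs")
    rho, err = data[:, 0], data[:, 1]
    if np.ptp(rho) == 0:
        raise ValueError("all rho values identical: regression is undetermined")
    A = np.stack([rho, np.ones_like(rho)], axis=1)
    (slope, intercept), *_ = np.linalg.lstsq(A, err, rcond=None)
    fitted = intercept + slope * rho
    pos = fitted[fitted > 0]
    floor = max(ERROR_FLOOR_MM, float(pos.min())) if pos.size else ERROR_FLOOR_MM
    return ConfidenceModel(slope=float(slope), intercept=float(intercept), floor=floor)


def fit_transition(trajectories) -> TransitionModel:
    """Estimate the velocity covariance from ground-truth translation series.

    ``trajectories`` is a sequence of ``(translations (n, 3) mm, frame_rate)``
    pairs.  Velocities are successive differences scaled by the frame rate;
    the chamber moves about a mean position, so a zero mean is imposed and
    ``Sigma_v`` is the raw second-moment matrix of the pooled velocities.
    A degenerate (rank-deficient) covariance — e.g. motion confined to one
    axis — is regularized by adding a small ridge, and logged.
    """
    vels = []
    for translations, rate in trajectories:
        t = np.asarray(translations, dtype=float)
        if t.ndim != 2 or t.shape[1] != 3:
            raise ValueError("each trajectory must be an (n, 3) translation series")
        if t.shape[0] >= 2:
            vels.append(np.diff(t, axis=0) * float(rate))
    if not vels:
        raise ValueError("no trajectory with at least two frames")
    V = np.concatenate(vels, axis=0)
    Sigma = (V.T @ V) / V.shape[0]
    if np.linalg.eigvalsh(Sigma).min() < SIGMA_V_RIDGE:
        logger.warning(
            "velocity covariance is (near-)singular; adding ridge %g (mm/s)^2", SIGMA_V_RIDGE
        )
        Sigma = Sigma + SIGMA_V_RIDGE * np.eye(3)
    return TransitionModel(Sigma_v=Sigma)


def smooth_translations(
    t_prime: np.ndarray,
    state_covs,
    Sigma_v: np.ndarray,
    frame_rate: float,
) -> np.ndarray:
    """MAP chain smoothing of raw translations; returns the filtered (n, 3).

    Minimizes the convex quadratic chain objective by BFGS started at the
    unfiltered series.  ``state_covs`` is a sequence of n 3x3 per-frame
    covariances; all covariances must be positive-definite.
    """
    t_prime = np.asarray(t_prime, dtype=float)
    n = t_prime.shape[0]
    if n == 0:
        return t_prime.copy()
    state_inv = []
    for S in state_covs:
        S = np.asarray(S, dtype=float).reshape(3, 3)
        if np.linalg.eigvalsh(S).min() <= 0:
            raise ValueError("state covariance must be positive-definite")
        state_inv.append(np.linalg.inv(S))
    Sigma_v = np.asarray(Sigma_v, dtype=float).reshape(3, 3)
    if np.linalg.eigvalsh(Sigma_v).min() <= 0:
        raise ValueError("transition covariance must be positive-definite")
    B = float(frame_rate) ** 2 * np.linalg.inv(Sigma_v)

    if n == 1:
        return t_prime.copy()

    def split(x):
        return x.reshape(n, 3)

    def fun(x):
        X = split(x)
        dx = X - t_prime
        val = sum(float(dx[i] @ state_inv[i] @ dx[i]) for i in range(n))
        dv = X[1:] - X[:-1]
        val += float(np.einsum("ij,jk,ik->", dv, B, dv))
        return val

    def jac(x):
        X = split(x)
        g = np.empty_like(X)
        for i in range(n):
            g[i] = 2.0 * state_inv[i] @ (X[i] - t_prime[i])
        dv = (X[1:] - X[:-1]) @ B.T  # B symmetric
        g[1:] += 2.0 * dv
        g[:-1] -= 2.0 * dv
        return g.ravel()

    res = optimize.minimize(
        fun,
        t_prime.ravel(),
        jac=jac,
        method="BFGS",
        options={"gtol": 1e-12, "maxiter": 5000},
    )
    x = res.x

    # Iterative refinement, still by BFGS: near the optimum the remaining
    # decrease (~eps^2 of the objective) drowns in the float noise of the
    # large objective constant, stalling the line search.  The increment
    # J(x+d) - J(x) = g(x).d + d.(g(x+d) - g(x))/2 of a quadratic is exact
    # and free of that constant, so minimizing it recovers the lost digits.
    for _ in range(3):
        g0 = jac(x)
        if np.linalg.norm(g0, np.inf) == 0.0:
            break

        def dfun(d, x=x, g0=g0):
            return float(g0 @ d + 0.5 * d @ (jac(x + d) - g0))

        def djac(d, x=x):
            return jac(x + d)

        dres = optimize.minimize(
            dfun, np.zeros_like(x), jac=djac, method="BFGS",
            options={"gtol": 1e-14, "maxiter": 1000},
        )
        if not np.any(dres.x):
            break
        x = x + dres.x
    return x.reshape(n, 3)


def smooth(
    trajectory: Trajectory,
    confidence: ConfidenceModel,
    transition: TransitionModel,
) -> list[RigidTransform]:
    """Filter a trajectory; populates and returns ``trajectory.filtered``."""
    covs = [confidence.state_covariance(r) for r in trajectory.rho_values]
    filtered = smooth_translations(
        trajectory.translations, covs, transition.Sigma_v, trajectory.frame_rate
    )
    trajectory.Sigma_i = covs
    trajectory.filtered = [RigidTransform(t) for t in filtered]
    return trajectory.filtered


def evaluate_trajectory(filtered, truth) -> dict:
    """Euclidean per-frame errors (mm) of a trajectory against ground truth."""
    f = np.asarray(
        [t.t if isinstance(t, RigidTransform) else t for t in filtered], dtype=float
    )
    g = np.asarray(
        [t.t if isinstance(t, RigidTransform) else t for t in truth], dtype=float
    )
    if f.shape != g.shape:
        raise ValueError("trajectory lengths disagree")
    errors = np.linalg.norm(f - g, axis=1)
    return {
        "per_frame": errors,
        "mean": float(errors.mean()),
        "median": float(np.median(errors)),
        "sd": float(errors.std()),
        "max": float(errors.max()),
    }
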