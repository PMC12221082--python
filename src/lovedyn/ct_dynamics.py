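"""Deterministic mathematics of the bivariate Ornstein–Uhlenbeck process.

The latent state eta(t) = (felt love, expressed love) follows the linear SDE

    d eta(t) = (A eta(t) + b) dt + S dW(t)

with drift matrix ``A`` (1/hour), continuous-time intercept ``b``
(scale points/hour) and diffusion coefficient ``S`` (scale points/sqrt(hour)).
Everything in this module is a deterministic function of those parameters:
exact discretisation over an arbitrary gap, stationary moments, and the
lag curves exp(A*delta) whose diagonals are the inertia of each channel and
whose off-diagonals are the cross-influences.

Variable order is fixed globally as (felt, expressed): element [0, 1] of any
2x2 quantity is the effect of expressed love on felt love.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm, solve_continuous_lyapunov
from scipy.optimize import minimize_scalar

logger = logging.getLogger("lovedyn")

#: Fixed channel order for every 2-vector / 2x2 matrix in the package.
CHANNELS = ("felt", "expressed")

#: Row labels for the four drift entries, in (row-major) matrix order.
DRIFT_LABELS = (
    "felt love inertia",
    "expressed love inertia",
    "expressed->felt cross-influence",
    "felt->expressed cross-influence",
)

#: (row, col) index of each DRIFT_LABELS entry in the drift matrix.
DRIFT_INDEX = ((0, 0), (1, 1), (0, 1), (1, 0))


def _as_drift(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.shape != (2, 2) or not np.all(np.isfinite(a)):
        raise ValueError("drift must be a finite 2x2 matrix")
    return a


def is_stationary(drift) -> bool:
    """True when both eigenvalues of the drift matrix have negative real part.

    For a 2x2 matrix this is trace < 0 and determinant > 0.
    """
    a = _as_drift(drift)
    return bool(np.trace(a) < 0 and np.linalg.det(a) > 0)


def _require_stationary(drift) -> np.ndarray:
    a = _as_drift(drift)
    if not is_stationary(a):
        raise ValueError(
            "drift matrix is not stationary (needs eigenvalues with "
            f"negative real part); got {a.tolist()}"
        )
    return a


@dataclass
class CTParams:
    """One person's full continuous-time model parameterisation.

    Parameters
    ----------
    drift
        2x2 drift matrix A, units 1/hour; diagonals negative for a
        mean-reverting (stationary) system.
    ct_intercept
        Continuous-time intercept b, scale points/hour.  Zero by default:
        the observed mean level lives in ``manifest_intercept`` instead
        (the two are not jointly identified).
    diffusion
        2x2 lower-triangular diffusion coefficient S; S @ S.T is the
        instantaneous innovation covariance.
    manifest_intercept
        Per-person constant offset tau between latent state and observed
        response, scale points (0-100 scale).
    meas_sd
        Measurement-error standard deviations for the two items.
    """

    drift: np.ndarray
    diffusion: np.ndarray
    manifest_intercept: np.ndarray = field(default_factory=lambda: np.zeros(2))
    ct_intercept: np.ndarray = field(default_factory=lambda: np.zeros(2))
    meas_sd: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self):
        self.drift = _as_drift(self.drift)
        self.diffusion = np.asarray(self.diffusion, dtype=float).reshape(2, 2)
        self.ct_intercept = np.asarray(self.ct_intercept, dtype=float).reshape(2)
        self.manifest_intercept = np.asarray(
            self.manifest_intercept, dtype=float
        ).reshape(2)
        self.meas_sd = np.asarray(self.meas_sd, dtype=float).reshape(2)
        if np.any(self.meas_sd < 0):
            raise ValueError("meas_sd must be nonnegative")

    @property
    def innovation_cov(self) -> np.ndarray:
        """Instantaneous innovation covariance S @ S.T (always PSD)."""
        return self.diffusion @ self.diffusion.T

    @property
    def stationary(self) -> bool:
        return is_stationary(self.drift)


def discrete_drift(drift, delta: float) -> np.ndarray:
    """Exact discrete-time autoregressive matrix exp(A * delta).

    ``delta`` is the time gap in hours.  The diagonal entries of the result
    are the inertia of felt and expressed love over that gap; off-diagonals
    are the cross-influences.
    """
    a = _as_drift(drift)
    if not np.isfinite(delta) or delta < 0:
        raise ValueError(f"delta must be finite and >= 0, got {delta}")
    return expm(a * float(delta))


def discrete_intercept(drift, ct_intercept, delta: float) -> np.ndarray:
    """Exact discrete intercept A^-1 (exp(A delta) - I) b over a gap."""
    a = _as_drift(drift)
    b = np.asarray(ct_intercept, dtype=float).reshape(2)
    if not np.isfinite(delta) or delta < 0:
        raise ValueError(f"delta must be finite and >= 0, got {delta}")
    if abs(np.linalg.det(a)) < 1e-300:
        raise np.linalg.LinAlgError("drift matrix is singular")
    return np.linalg.solve(a, (discrete_drift(a, delta) - np.eye(2)) @ b)


def stationary_moments(params: CTParams) -> tuple[np.ndarray, np.ndarray]:
    """Stationary mean -A^-1 b and covariance G of the latent process.

    G solves the continuous Lyapunov equation A G + G A' + S S' = 0.
    """
    a = _require_stationary(params.drift)
    mean = -np.linalg.solve(a, params.ct_intercept)
    cov = solve_continuous_lyapunov(a, -params.innovation_cov)
    cov = 0.5 * (cov + cov.T)
    return mean, cov


def discrete_noise_cov(params: CTParams, delta: float) -> np.ndarray:
    """Transition noise covariance Q(delta) = G - exp(A d) G exp(A d)'."""
    _require_stationary(params.drift)
    if not np.isfinite(delta) or delta < 0:
        raise ValueError(f"delta must be finite and >= 0, got {delta}")
    _, g = stationary_moments(params)
    e = discrete_drift(params.drift, delta)
    q = g - e @ g @ e.T
    return 0.5 * (q + q.T)


@dataclass
class LagCurve:
    """exp(A*delta) over a grid of lags: inertia and cross-influence curves.

    ``values[i]`` is the full 2x2 matrix at ``lags[i]``; diagonals are the
    felt/expressed inertia curves, ``values[:, 0, 1]`` the expressed->felt
    cross-influence and ``values[:, 1, 0]`` the felt->expressed one.
    """

    lags: np.ndarray
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag_hours": self.lags,
                "felt_inertia": self.values[:, 0, 0],
                "expressed_inertia": self.values[:, 1, 1],
                "expressed_to_felt": self.values[:, 0, 1],
                "felt_to_expressed": self.values[:, 1, 0],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def lag_curves(drift, lags) -> LagCurve:
    """Evaluate exp(A*delta) over an increasing grid of positive lags."""
    a = _as_drift(drift)
    lags = np.asarray(lags, dtype=float)
    if lags.size == 0:
        raise ValueError("lag grid must be non-empty")
    if np.any(lags <= 0) or np.any(np.diff(lags) <= 0):
        raise ValueError("lags must be positive and strictly increasing")
    values = np.stack([expm(a * d) for d in lags])
    return LagCurve(lags=lags, values=values)


_CROSS_INDEX = {"expressed_to_felt": (0, 1), "felt_to_expressed": (1, 0)}


def peak_cross_lag(
    drift, which: str, search_horizon: float = 24.0
) -> tuple[float, float] | None:
    """Lag (hours) maximising |exp(A*delta)| for one cross-influence entry.

    ``which`` is ``"expressed_to_felt"`` or ``"felt_to_expressed"``.  Returns
    ``(lag, value)`` with the signed entry value at the peak, or ``None``
    when the entry is identically zero on the horizon (e.g. diagonal drift).
    Resolution is better than 0.01 h: coarse grid scan followed by bounded
    scalar refinement.
    """
    a = _require_stationary(drift)
    if which not in _CROSS_INDEX:
        raise ValueError(f"which must be one of {sorted(_CROSS_INDEX)}")
    if search_horizon <= 0:
        raise ValueError("search_horizon must be positive")
    i, j = _CROSS_INDEX[which]

    grid = np.linspace(search_horizon / 2400, search_horizon, 2400)
    vals = np.array([expm(a * d)[i, j] for d in grid])
    if np.max(np.abs(vals)) < 1e-14:
        return None
    k = int(np.argmax(np.abs(vals)))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    res = minimize_scalar(
        lambda d: -abs(expm(a * d)[i, j]),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-4},
    )
    lag = float(res.x)
    return lag, float(expm(a * lag)[i, j])
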