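"""Exact Gaussian likelihood for irregularly timed bivariate EMA series.

The measurement model is y(t) = eta(t) + tau + eps(t) with diagonal Gaussian
measurement error, and eta follows the OU process of :mod:`.ct_dynamics`.
Because both the latent transition over an arbitrary gap and the measurement
are Gaussian, the marginal likelihood of the observed responses is available
exactly from a continuous-discrete Kalman filter: predict with
exp(A*delta) / Q(delta) per inter-prompt gap, update with whichever of the
two items was answered at that prompt.

``joint_gaussian_loglik`` builds the full 2T-dimensional joint normal of the
observation stack instead and serves as an independent brute-force oracle
for the filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .ct_dynamics import CTParams, discrete_drift, stationary_moments

_DIFFUSE_VAR = 1.0e7  # prior variance per channel under diffuse initialisation


@dataclass
class ObservationSeries:
    """One person's irregularly timed bivariate responses.

    ``times`` are hours since the person's first retained prompt, strictly
    increasing.  ``values`` is (T, 2) on the 0-100 scale with NaN for a
    missing component; order (felt, expressed).
    """

    person_id: object
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float).reshape(-1)
        self.values = np.asarray(self.values, dtype=float).reshape(-1, 2)
        if self.times.size == 0:
            raise ValueError("series needs at least one occasion")
        if self.times.size != self.values.shape[0]:
            raise ValueError("times and values length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"times not strictly increasing for {self.person_id}")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValueError(f"responses outside [0, 100] for {self.person_id}")

    @property
    def n_occasions(self) -> int:
        return self.times.size

    @classmethod
    def _unchecked(cls, person_id, times, values):
        """Construct without the 0-100 range check (unclipped simulations)."""
        obj = object.__new__(cls)
        obj.person_id = person_id
        obj.times = np.asarray(times, dtype=float).reshape(-1)
        obj.values = np.asarray(values, dtype=float).reshape(-1, 2)
        return obj


@njit(cache=True)
def _expm2(a11, a12, a21, a22, dt):
    """Closed-form matrix exponential of a 2x2 matrix times dt."""
    m11 = a11 * dt
    m12 = a12 * dt
    m21 = a21 * dt
    m22 = a22 * dt
    s = 0.5 * (m11 + m22)
    disc = 0.25 * (m11 - m22) ** 2 + m12 * m21
    if disc > 1e-12:
        q = math.sqrt(disc)
        ch = math.cosh(q)
        sh = math.sinh(q) / q
    elif disc < -1e-12:
        q = math.sqrt(-disc)
        ch = math.cos(q)
        sh = math.sin(q) / q
    else:
        # repeated eigenvalue: series expansion of cosh/sinhc at 0
        ch = 1.0 + disc / 2.0
        sh = 1.0 + disc / 6.0
    es = math.exp(s)
    e11 = es * (ch + sh * (m11 - s))
    e12 = es * sh * m12
    e21 = es * sh * m21
    e22 = es * (ch + sh * (m22 - s))
    return e11, e12, e21, e22


@njit(cache=True)
def _kalman_core(
    times, y, a11, a12, a21, a22, g11, g12, g22, mu1, mu2, tau1, tau2,
    v1, v2, p011, p012, p022,
):
    """Continuous-discrete Kalman filter log-likelihood, hand-unrolled 2x2.

    ``g``: stationary latent covariance; ``mu``: stationary latent mean;
    ``tau``: manifest intercept; ``v``: measurement variances; ``p0``:
    initial state covariance.  NaN in ``y`` marks a missing component.
    Returns -inf on a non-positive innovation variance.
    """
    m1 = mu1
    m2 = mu2
    p11 = p011
    p12 = p012
    p22 = p022
    ll = 0.0
    t_prev = times[0]
    log2pi = 1.8378770664093453
    for k in range(times.shape[0]):
        if k > 0:
            dt = times[k] - t_prev
            t_prev = times[k]
            e11, e12, e21, e22 = _expm2(a11, a12, a21, a22, dt)
            # predicted mean: mu + E (m - mu)
            d1 = m1 - mu1
            d2 = m2 - mu2
            m1 = mu1 + e11 * d1 + e12 * d2
            m2 = mu2 + e21 * d1 + e22 * d2
            # predicted cov: E P E' + Q, Q = G - E G E'
            # EP = E @ P
            ep11 = e11 * p11 + e12 * p12
            ep12 = e11 * p12 + e12 * p22
            ep21 = e21 * p11 + e22 * p12
            ep22 = e21 * p12 + e22 * p22
            epe11 = ep11 * e11 + ep12 * e12
            epe12 = ep11 * e21 + ep12 * e22
            epe22 = ep21 * e21 + ep22 * e22
            # EG = E @ G
            eg11 = e11 * g11 + e12 * g12
            eg12 = e11 * g12 + e12 * g22
            eg21 = e21 * g11 + e22 * g12
            eg22 = e21 * g12 + e22 * g22
            ege11 = eg11 * e11 + eg12 * e12
            ege12 = eg11 * e21 + eg12 * e22
            ege22 = eg21 * e21 + eg22 * e22
            p11 = epe11 + g11 - ege11
            p12 = epe12 + g12 - ege12
            p22 = epe22 + g22 - ege22
        y1 = y[k, 0]
        y2 = y[k, 1]
        o1 = not math.isnan(y1)
        o2 = not math.isnan(y2)
        if o1 and o2:
            # bivariate update
            s11 = p11 + v1
            s12 = p12
            s22 = p22 + v2
            det = s11 * s22 - s12 * s12
            if det <= 0.0 or s11 <= 0.0:
                return -np.inf
            r1 = y1 - (m1 + tau1)
            r2 = y2 - (m2 + tau2)
            # r' S^-1 r
            q1 = (s22 * r1 - s12 * r2) / det
            q2 = (-s12 * r1 + s11 * r2) / det
            ll += -0.5 * (2.0 * log2pi + math.log(det) + r1 * q1 + r2 * q2)
            # K = P H' S^-1, H = I
            k11 = (p11 * s22 - p12 * s12) / det
            k12 = (-p11 * s12 + p12 * s11) / det
            k21 = (p12 * s22 - p22 * s12) / det
            k22 = (-p12 * s12 + p22 * s11) / det
            m1 += k11 * r1 + k12 * r2
            m2 += k21 * r1 + k22 * r2
            n11 = (1.0 - k11) * p11 - k12 * p12
            n12 = (1.0 - k11) * p12 - k12 * p22
            n22 = -k21 * p12 + (1.0 - k22) * p22
            p11 = n11
            p12 = n12
            p22 = n22
        elif o1:
            s = p11 + v1
            if s <= 0.0:
                return -np.inf
            r = y1 - (m1 + tau1)
            ll += -0.5 * (log2pi + math.log(s) + r * r / s)
            k1 = p11 / s
            k2 = p12 / s
            m1 += k1 * r
            m2 += k2 * r
            n11 = p11 - k1 * p11
            n12 = p12 - k1 * p12
            n22 = p22 - k2 * p12
            p11 = n11
            p12 = n12
            p22 = n22
        elif o2:
            s = p22 + v2
            if s <= 0.0:
                return -np.inf
            r = y2 - (m2 + tau2)
            ll += -0.5 * (log2pi + math.log(s) + r * r / s)
            k1 = p12 / s
            k2 = p22 / s
            m1 += k1 * r
            m2 += k2 * r
            n11 = p11 - k1 * p12
            n12 = p12 - k1 * p22
            n22 = p22 - k2 * p22
            p11 = n11
            p12 = n12
            p22 = n22
        # neither observed: pure prediction, nothing to update
    return ll


def kalman_loglik(
    series: ObservationSeries, params: CTParams, init: str = "stationary"
) -> float:
    """Exact log marginal density of the observed components of one series.

    ``init="stationary"`` starts the filter at the stationary distribution
    of the latent OU process (requires a stationary drift); ``"diffuse"``
    starts at mean zero with a large (1e7) diagonal covariance.
    """
    if init not in ("stationary", "diffuse"):
        raise ValueError("init must be 'stationary' or 'diffuse'")
    if init == "stationary":
        mu, g = stationary_moments(params)  # raises on non-stationary drift
        p0 = g
    else:
        if not params.stationary:
            raise ValueError("diffuse init still needs a stationary drift "
                             "for the transition noise covariance")
        mu, g = stationary_moments(params)
        mu = np.zeros(2)
        p0 = np.eye(2) * _DIFFUSE_VAR
    a = params.drift
    v = params.meas_sd**2
    return float(
        _kalman_core(
            series.times,
            series.values,
            a[0, 0], a[0, 1], a[1, 0], a[1, 1],
            g[0, 0], g[0, 1], g[1, 1],
            mu[0], mu[1],
            params.manifest_intercept[0], params.manifest_intercept[1],
            v[0], v[1],
            p0[0, 0], p0[0, 1], p0[1, 1],
        )
    )


def joint_gaussian_loglik(series: ObservationSeries, params: CTParams) -> float:
    """Brute-force joint-normal log-density of the observation stack.

    Builds the dense 2T x 2T covariance of the stacked observations under
    the stationary model, Cov(eta(t), eta(s)) = exp(A|t-s|) G for t >= s,
    drops missing rows/columns, and evaluates one multivariate normal
    density.  Dense construction: limited to T <= 50.
    """
    t = series.n_occasions
    if t > 50:
        raise ValueError("dense oracle limited to <= 50 occasions")
    mu, g = stationary_moments(params)
    times = series.times
    cov = np.zeros((2 * t, 2 * t))
    for i in range(t):
        for j in range(i + 1):
            block = discrete_drift(params.drift, times[i] - times[j]) @ g
            cov[2 * i : 2 * i + 2, 2 * j : 2 * j + 2] = block
            cov[2 * j : 2 * j + 2, 2 * i : 2 * i + 2] = block.T
    cov[np.diag_indices(2 * t)] += np.tile(params.meas_sd**2, t)
    mean = np.tile(mu + params.manifest_intercept, t)
    y = series.values.reshape(-1)
    keep = np.isfinite(y)
    y = y[keep]
    mean = mean[keep]
    cov = cov[np.ix_(keep, keep)]
    n = y.size
    if n == 0:
        return 0.0
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        try:
            chol = np.linalg.cholesky(cov + 1e-8 * np.eye(n))
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "joint covariance not positive definite after jitter"
            ) from exc
    resid = np.linalg.solve(chol, y - mean)
    return float(
        -0.5 * n * np.log(2 * np.pi)
        - np.sum(np.log(np.diag(chol)))
        - 0.5 * resid @ resid
    )
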