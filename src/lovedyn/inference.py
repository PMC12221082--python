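"""Hierarchical Bayesian estimation of person-specific OU dynamics.

Model
-----
Each person p has an 8-dimensional parameter vector on an unconstrained
sampling scale,

    theta_p = (th_a11, th_a22, a12, a21, th_d1, th_d2, tau1, tau2),

where the drift diagonals are mapped through a strictly-negative softplus
bijection a_ii = -log(1 + exp(th_aii)), the diffusion standard deviations
through the strictly-positive softplus d_i = log(1 + exp(th_di)), and the
off-diagonal drift entries and manifest intercepts are unconstrained.  The
continuous-time intercept b is fixed at zero: the person's mean level lives
entirely in tau (b and tau are not jointly identified).  Random effects are
independent normals on the sampling scale,

    theta_pk ~ Normal(mu_k, sigma_k),

with weakly informative hyperpriors, and the two measurement-error SDs are
shared across persons with half-normal priors.  The likelihood of each
person's series is the exact continuous-discrete Kalman filter of
:mod:`.state_space`; drift proposals whose determinant is non-positive
(non-stationary systems) receive zero likelihood, so every retained draw is
stationary.

Sampler
-------
Adaptive Metropolis-within-Gibbs: per-person 8-dimensional random-walk
Metropolis with Haario covariance adaptation during warmup; conjugate Gibbs
updates for the group means; scalar adaptive Metropolis on the log group
SDs and (jointly) on the log measurement SDs.  Convergence is summarised by
split-R-hat and bulk ESS (arviz) on all group-level parameters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from numba import njit

from .ct_dynamics import CTParams
from .state_space import ObservationSeries, _kalman_core

logger = logging.getLogger("lovedyn")

#: Order of the per-person transformed parameter vector.
PARAM_NAMES = (
    "th_a11", "th_a22", "a12", "a21", "th_d1", "th_d2", "tau1", "tau2",
)

#: Natural-scale drift entries in reporting order, matching Table-2-style rows.
DRIFT_FEATURES = (
    "felt_inertia", "expressed_inertia", "expressed_to_felt", "felt_to_expressed",
)

FEATURE_LABELS = {
    "felt_inertia": "felt love inertia",
    "expressed_inertia": "expressed love inertia",
    "expressed_to_felt": "expressed→felt cross-influence",
    "felt_to_expressed": "felt→expressed cross-influence",
}

#: theta index of each DRIFT_FEATURES entry (transformed scale).
_FEATURE_THETA = {"felt_inertia": 0, "expressed_inertia": 1,
                  "expressed_to_felt": 2, "felt_to_expressed": 3}


# ---------------------------------------------------------------------------
# transforms

def softplus(x):
    x = np.asarray(x, dtype=float)
    return np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0.0)


def softplus_inv(y):
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("softplus_inv needs positive input")
    return y + np.log1p(-np.exp(-y))


def transform(params: CTParams) -> np.ndarray:
    """Map natural CTParams to the 8-vector sampling scale (see PARAM_NAMES)."""
    a = params.drift
    d = np.diag(params.diffusion)
    if not np.all(np.isfinite(a)) or np.any(np.diag(a) >= 0) or np.any(d <= 0):
        raise ValueError("transform needs finite params, negative drift "
                         "diagonal and positive diffusion SDs")
    return np.array([
        softplus_inv(-a[0, 0]), softplus_inv(-a[1, 1]), a[0, 1], a[1, 0],
        softplus_inv(d[0]), softplus_inv(d[1]),
        params.manifest_intercept[0], params.manifest_intercept[1],
    ])


def untransform(theta, meas_sd=(0.0, 0.0)) -> CTParams:
    """Inverse of :func:`transform`; measurement SDs are supplied separately."""
    theta = np.asarray(theta, dtype=float).reshape(8)
    if not np.all(np.isfinite(theta)):
        raise ValueError("non-finite transformed parameters")
    drift = np.array([
        [-softplus(theta[0]), theta[2]],
        [theta[3], -softplus(theta[1])],
    ])
    return CTParams(
        drift=drift,
        diffusion=np.diag(softplus(theta[4:6])),
        manifest_intercept=theta[6:8].copy(),
        meas_sd=np.asarray(meas_sd, dtype=float),
    )


def natural_drift_entries(theta: np.ndarray) -> np.ndarray:
    """Natural-scale (a11, a22, a12, a21) from transformed draws (vectorised).

    ``theta`` has the parameter axis last; returns the same shape with the
    last axis reduced to the four drift entries in DRIFT_FEATURES order.
    """
    theta = np.asarray(theta, dtype=float)
    out = np.empty(theta.shape[:-1] + (4,))
    out[..., 0] = -softplus(theta[..., 0])
    out[..., 1] = -softplus(theta[..., 1])
    out[..., 2] = theta[..., 2]
    out[..., 3] = theta[..., 3]
    return out


# ---------------------------------------------------------------------------
# fast per-person likelihood (sampling-scale parameter vector)

@njit(cache=True)
def _sp(x):
    if x > 0.0:
        return x + math.log1p(math.exp(-x))
    return math.log1p(math.exp(x))


@njit(cache=True)
def _theta_loglik(theta, v1, v2, times, y):
    """Kalman log-likelihood at one transformed parameter vector.

    Returns -inf for non-stationary drift or invalid stationary covariance.
    """
    a11 = -_sp(theta[0])
    a22 = -_sp(theta[1])
    a12 = theta[2]
    a21 = theta[3]
    det = a11 * a22 - a12 * a21
    if det <= 1e-12:
        return -np.inf
    d1 = _sp(theta[4])
    d2 = _sp(theta[5])
    # stationary covariance: A G + G A' = -diag(d1^2, d2^2); the 3x3 linear
    # system in (g11, g12, g22) has determinant 4 tr(A) det(A), solved in
    # closed form (Cramer) so degenerate proposals are rejected, not raised
    s = a11 + a22
    b0 = -d1 * d1
    b2 = -d2 * d2
    det_m = 4.0 * s * det
    if abs(det_m) < 1e-30:
        return -np.inf
    g11 = (2.0 * b0 * (s * a22 - a12 * a21) + 2.0 * a12 * a12 * b2) / det_m
    g12 = (-2.0 * a11 * a12 * b2 - 2.0 * a21 * a22 * b0) / det_m
    g22 = (2.0 * a11 * (s * b2 - 0.0) - 2.0 * a12 * a21 * b2
           + 2.0 * a21 * a21 * b0) / det_m
    if g11 <= 0.0 or g22 <= 0.0 or g11 * g22 - g12 * g12 <= 0.0:
        return -np.inf
    return _kalman_core(
        times, y, a11, a12, a21, a22, g11, g12, g22,
        0.0, 0.0, theta[6], theta[7], v1, v2, g11, g12, g22,
    )


@njit(cache=True)
def _cohort_loglik(theta, v1, v2, tflat, yflat, offs):
    """Per-person log-likelihoods for the whole cohort (flat storage)."""
    p_count = offs.shape[0] - 1
    out = np.empty(p_count)
    for p in range(p_count):
        out[p] = _theta_loglik(
            theta[p], v1, v2, tflat[offs[p]:offs[p + 1]],
            yflat[offs[p]:offs[p + 1]],
        )
    return out


# ---------------------------------------------------------------------------
# priors and configuration

@dataclass
class GroupPrior:
    """Weakly informative hyperpriors on the sampling scale.

    ``mean_loc``/``mean_scale`` parameterise normal priors on the eight
    group means; ``sd_scale`` the half-normal priors on the eight group
    SDs; ``meas_sd_scale`` the half-normal priors on the two shared
    measurement-error SDs (scale points).
    """

    mean_loc: np.ndarray = field(default_factory=lambda: np.array(
        [-0.35, -0.35, 0.0, 0.0, 0.0, 0.0, 50.0, 50.0]))
    mean_scale: np.ndarray = field(default_factory=lambda: np.array(
        [1.0, 1.0, 0.5, 0.5, 5.0, 5.0, 20.0, 20.0]))
    sd_scale: np.ndarray = field(default_factory=lambda: np.array(
        [1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 10.0, 10.0]))
    meas_sd_scale: np.ndarray = field(default_factory=lambda: np.array(
        [10.0, 10.0]))

    def __post_init__(self):
        for name in ("mean_scale", "sd_scale", "meas_sd_scale"):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"{name} entries must be positive")


@dataclass
class MCMCConfig:
    """Sampler settings: 2 chains x 3000 iterations, first half warmup."""

    chains: int = 2
    iterations: int = 3000
    warmup_frac: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.chains < 1 or self.iterations < 100:
            raise ValueError("need chains >= 1 and iterations >= 100")
        if not 0 < self.warmup_frac < 1:
            raise ValueError("warmup_frac must be in (0, 1)")

    @property
    def warmup(self) -> int:
        return int(self.iterations * self.warmup_frac)


MIN_OCCASIONS = 3  # fewer cannot inform a bivariate dynamic model

#: Person-block Metropolis sweeps per Gibbs scan (mixing vs cost).
_PERSON_SWEEPS = 12
#: Repetitions of the group translation / rescale moves per scan.
_GROUP_MOVE_REPS = 4
#: Coordinate pairs for ridge-directed joint translations
#: (theta indices: 0 th_a11, 1 th_a22, 2 a12, 4 th_d1, 5 th_d2).
_PAIR_MOVES = ((0, 4), (1, 5), (1, 2))
#: Repetitions of the shared measurement-SD update per scan.
_MEAS_REPS = 5


def _check_series(all_persons):
    for s in all_persons:
        if s.n_occasions < MIN_OCCASIONS:
            raise ValueError(
                f"person {s.person_id!r} has {s.n_occasions} occasions; "
                f"at least {MIN_OCCASIONS} required"
            )


def log_posterior(
    all_persons: list[ObservationSeries],
    theta: np.ndarray,
    mu: np.ndarray,
    sigma: np.ndarray,
    meas_sd: np.ndarray,
    prior: GroupPrior | None = None,
) -> float:
    """Joint log posterior density of the hierarchical model.

    ``theta`` is (P, 8) on the sampling scale; ``mu``/``sigma`` the group
    means/SDs; ``meas_sd`` the two shared measurement SDs.  The density is
    with respect to (theta, mu, sigma, meas_sd) on their natural supports
    (sigma, meas_sd positive).
    """
    prior = prior or GroupPrior()
    _check_series(all_persons)
    theta = np.asarray(theta, dtype=float).reshape(len(all_persons), 8)
    mu = np.asarray(mu, dtype=float).reshape(8)
    sigma = np.asarray(sigma, dtype=float).reshape(8)
    meas_sd = np.asarray(meas_sd, dtype=float).reshape(2)
    if np.any(sigma <= 0) or np.any(meas_sd <= 0):
        return -np.inf
    v1, v2 = meas_sd**2
    total = 0.0
    for p, s in enumerate(all_persons):
        total += _theta_loglik(theta[p], v1, v2, s.times, s.values)
    if not np.isfinite(total):
        return -np.inf
    # random effects
    total += float(np.sum(
        -0.5 * ((theta - mu) / sigma) ** 2 - np.log(sigma)
        - 0.5 * math.log(2 * math.pi)
    ))
    # hyperpriors
    total += float(np.sum(
        -0.5 * ((mu - prior.mean_loc) / prior.mean_scale) ** 2
        - np.log(prior.mean_scale) - 0.5 * math.log(2 * math.pi)
    ))
    total += float(np.sum(_half_normal_logpdf(sigma, prior.sd_scale)))
    total += float(np.sum(_half_normal_logpdf(meas_sd, prior.meas_sd_scale)))
    return total


def _half_normal_logpdf(x, scale):
    x = np.asarray(x, dtype=float)
    scale = np.asarray(scale, dtype=float)
    return (0.5 * math.log(2 / math.pi) - np.log(scale)
            - 0.5 * (x / scale) ** 2)


# ---------------------------------------------------------------------------
# posterior container

@dataclass
class GroupPosterior:
    """Posterior draws of the hierarchical model.

    Draw arrays are (chains, draws, ...); ``theta`` is (chains, draws, P, 8)
    on the sampling scale.  ``rhat``/``ess`` cover all group-level
    parameters; ``converged`` is False when any split-R-hat exceeds 1.05.
    """

    person_ids: list
    theta: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    meas_sd: np.ndarray
    rhat: dict
    ess: dict
    converged: bool
    n_nonstationary: int = 0

    @property
    def n_persons(self) -> int:
        return len(self.person_ids)

    def natural_person_draws(self) -> np.ndarray:
        """(chains, draws, P, 4) natural-scale drift entries per person."""
        return natural_drift_entries(self.theta)

    def group_feature_draws(self, mode: str = "person_average") -> np.ndarray:
        """(chains, draws, 4) group-level natural drift-entry draws.

        ``person_average``: per draw, the cohort mean of person-level
        natural-scale entries (population mean of the person parameters).
        ``transformed_mean``: the natural transform of the group-mean
        transformed parameters.
        """
        if mode == "person_average":
            return self.natural_person_draws().mean(axis=2)
        if mode == "transformed_mean":
            return natural_drift_entries(self.mu[..., :4][..., [0, 1, 2, 3]])
        raise ValueError("mode must be 'person_average' or 'transformed_mean'")


def _diagnostics(mu, sigma, meas_sd):
    """Split-R-hat and bulk ESS for every group-level parameter."""
    data = {}
    for k, name in enumerate(PARAM_NAMES):
        data[f"mu_{name}"] = mu[:, :, k]
        data[f"sigma_{name}"] = sigma[:, :, k]
    data["meas_sd_felt"] = meas_sd[:, :, 0]
    data["meas_sd_expressed"] = meas_sd[:, :, 1]
    idata = az.convert_to_dataset(data)
    rhat = {k: float(v.values) for k, v in az.rhat(idata).items()}
    ess = {k: float(v.values) for k, v in az.ess(idata).items()}
    return rhat, ess


# ---------------------------------------------------------------------------
# sampler

def _person_init(times, values):
    """Crude data-driven start: gap-aware VAR fit mapped through a matrix log.

    Regresses centred responses on their previous occasion (gaps up to 3x
    the median), takes A ~ logm(Phi)/mean-gap, shrinks off-diagonals until
    stationary, and backs diffusion out of the stationary-covariance
    relation.  Falls back to a generic mean-reverting start when the series
    is too short or the estimate degenerates.
    """
    from scipy.linalg import logm

    ok = np.isfinite(values).all(axis=1)
    v = values[ok]
    t = times[ok]
    mean = v.mean(axis=0) if v.size else np.array([50.0, 50.0])
    sds = v.std(axis=0) if len(v) > 2 else np.array([10.0, 10.0])
    sds = np.maximum(sds, 2.0)
    fallback = np.array([
        softplus_inv(0.5), softplus_inv(0.5), 0.0, 0.0,
        float(softplus_inv(max(0.8 * sds[0], 0.5))),
        float(softplus_inv(max(0.8 * sds[1], 0.5))),
        mean[0], mean[1],
    ])
    if len(v) < 10:
        return fallback, sds
    dt = np.diff(t)
    med = np.median(dt)
    use = dt <= 3.0 * med
    if use.sum() < 8:
        return fallback, sds
    x0 = (v[:-1] - mean)[use]
    x1 = (v[1:] - mean)[use]
    try:
        phi = np.linalg.lstsq(x0, x1, rcond=None)[0].T
        a = np.real(logm(phi)) / float(dt[use].mean())
    except Exception:
        return fallback, sds
    if not np.all(np.isfinite(a)):
        return fallback, sds
    a[0, 0] = min(a[0, 0], -0.02)
    a[1, 1] = min(a[1, 1], -0.02)
    for _ in range(12):
        from .ct_dynamics import is_stationary
        if is_stationary(a):
            break
        a[0, 1] *= 0.5
        a[1, 0] *= 0.5
    else:
        return fallback, sds
    g = np.cov(v.T) * 0.8 + 1e-3 * np.eye(2)
    d = np.sqrt(np.clip(np.diag(-(a @ g + g @ a.T)), 0.25, None))
    theta = np.array([
        float(softplus_inv(-a[0, 0])), float(softplus_inv(-a[1, 1])),
        a[0, 1], a[1, 0],
        float(softplus_inv(d[0])), float(softplus_inv(d[1])),
        mean[0], mean[1],
    ])
    return theta, sds


def _initial_state(series_list, prior, rng):
    p_count = len(series_list)
    theta = np.zeros((p_count, 8))
    stds = []
    for i, s in enumerate(series_list):
        theta[i], sds = _person_init(s.times, s.values)
        stds.append(sds)
    theta += rng.normal(0.0, 0.05, size=theta.shape)
    mu = theta.mean(axis=0) + rng.normal(0.0, 0.05, size=8)
    sigma = np.maximum(theta.std(axis=0), 0.1 * prior.sd_scale)
    meas = np.maximum(0.4 * np.mean(stds, axis=0), 1.0)
    meas *= np.exp(rng.normal(0.0, 0.05, size=2))
    return theta, mu, sigma, meas


def _run_chain(series_list, prior, n_iter, warmup, rng):
    p_count = len(series_list)
    times = [s.times for s in series_list]
    ys = [s.values for s in series_list]
    # flat storage for whole-cohort likelihood sweeps
    offs = np.concatenate([[0], np.cumsum([t.size for t in times])]).astype(
        np.int64)
    tflat = np.concatenate(times)
    yflat = np.concatenate(ys, axis=0)

    theta, mu, sigma, meas = _initial_state(series_list, prior, rng)
    v = meas**2
    ll = np.array([
        _theta_loglik(theta[p], v[0], v[1], times[p], ys[p])
        for p in range(p_count)
    ])
    # fall back towards the prior centre for any invalid start
    for p in range(p_count):
        tries = 0
        while not np.isfinite(ll[p]) and tries < 50:
            theta[p] = mu + rng.normal(0, 0.1, 8)
            ll[p] = _theta_loglik(theta[p], v[0], v[1], times[p], ys[p])
            tries += 1
        if not np.isfinite(ll[p]):
            raise RuntimeError(
                f"could not initialise person {series_list[p].person_id!r}")

    # Haario adaptation state per person
    base_scale = np.array([0.3, 0.3, 0.1, 0.05, 0.2, 0.2, 1.5, 1.5])
    run_mean = theta.copy()
    run_cov = np.stack([np.diag(base_scale**2)] * p_count)
    chols = np.stack([np.diag(base_scale)] * p_count)
    log_s = np.full(p_count, math.log(2.38**2 / 8))
    sig_step = np.full(8, 0.3)
    trans_step = np.array([0.2, 0.2, 0.05, 0.02, 0.3, 0.3, 1.0, 1.0])
    resc_step = np.full(8, 0.2)
    pair_step = np.full(len(_PAIR_MOVES), 1.0)
    meas_step = 0.1

    keep = n_iter - warmup
    out_theta = np.empty((keep, p_count, 8))
    out_mu = np.empty((keep, 8))
    out_sigma = np.empty((keep, 8))
    out_meas = np.empty((keep, 2))

    sqrt8 = 2.38**2 / 8
    for it in range(n_iter):
        adapting = it < warmup
        gamma = min(1.0, 10.0 / math.sqrt(it + 1))

        # --- person blocks: adaptive random-walk Metropolis, several sweeps
        for _ in range(_PERSON_SWEEPS):
            z = rng.standard_normal((p_count, 8))
            logu = np.log(rng.random(p_count))
            for p in range(p_count):
                prop = theta[p] + math.exp(0.5 * log_s[p]) * (chols[p] @ z[p])
                ll_prop = _theta_loglik(prop, v[0], v[1], times[p], ys[p])
                if np.isfinite(ll_prop):
                    dprior = np.sum(
                        -0.5 * ((prop - mu) / sigma) ** 2
                        + 0.5 * ((theta[p] - mu) / sigma) ** 2
                    )
                    accept = logu[p] < ll_prop - ll[p] + dprior
                else:
                    accept = False
                if accept:
                    theta[p] = prop
                    ll[p] = ll_prop
                if adapting:
                    log_s[p] += gamma * ((1.0 if accept else 0.0) - 0.25)
                    delta = theta[p] - run_mean[p]
                    run_mean[p] += gamma * delta
                    run_cov[p] += gamma * (np.outer(delta, delta) - run_cov[p])
                    if it >= 50 and it % 20 == 0:
                        try:
                            chols[p] = np.linalg.cholesky(
                                run_cov[p] + 1e-8 * np.eye(8))
                        except np.linalg.LinAlgError:
                            pass

        # --- group moves.  Person-level ridges (e.g. diffusion versus
        # measurement noise) require all persons to move together;
        # individual Metropolis steps cannot do that.  Two coherent moves
        # per coordinate: a translation of every person's theta_k together
        # with mu_k, and a rescale of the spread around mu_k together with
        # sigma_k (a non-centred group-SD update).
        for _ in range(_GROUP_MOVE_REPS):
            for k in range(8):
                # translation
                delta = trans_step[k] * rng.standard_normal()
                theta_prop = theta.copy()
                theta_prop[:, k] = theta[:, k] + delta
                ll_prop_all = _cohort_loglik(theta_prop, v[0], v[1],
                                             tflat, yflat, offs)
                if np.all(np.isfinite(ll_prop_all)):
                    mu_new = mu[k] + delta
                    dpost = (
                        np.sum(ll_prop_all) - np.sum(ll)
                        - 0.5 * ((mu_new - prior.mean_loc[k])
                                 / prior.mean_scale[k]) ** 2
                        + 0.5 * ((mu[k] - prior.mean_loc[k])
                                 / prior.mean_scale[k]) ** 2
                    )
                    acc = math.log(rng.random()) < dpost
                else:
                    acc = False
                if acc:
                    theta = theta_prop
                    mu[k] += delta
                    ll = ll_prop_all
                if adapting:
                    trans_step[k] *= math.exp(
                        gamma * ((1.0 if acc else 0.0) - 0.25) * 0.5)
                    trans_step[k] = min(max(trans_step[k], 1e-4), 10.0)

                # rescale: theta'_k = mu_k + c (theta_k - mu_k), sigma'_k =
                # c sigma_k; Hastings ratio carries the +log c Jacobian
                # remainder (the random-effect quadratic is invariant).
                c = math.exp(resc_step[k] * rng.standard_normal())
                theta_prop = theta.copy()
                theta_prop[:, k] = mu[k] + c * (theta[:, k] - mu[k])
                sig_new = c * sigma[k]
                ll_prop_all = _cohort_loglik(theta_prop, v[0], v[1],
                                             tflat, yflat, offs)
                if np.all(np.isfinite(ll_prop_all)):
                    dpost = (
                        np.sum(ll_prop_all) - np.sum(ll)
                        - 0.5 * (sig_new / prior.sd_scale[k]) ** 2
                        + 0.5 * (sigma[k] / prior.sd_scale[k]) ** 2
                        + math.log(c)
                    )
                    acc = math.log(rng.random()) < dpost
                else:
                    acc = False
                if acc:
                    theta = theta_prop
                    sigma[k] = sig_new
                    ll = ll_prop_all
                if adapting:
                    resc_step[k] *= math.exp(
                        gamma * ((1.0 if acc else 0.0) - 0.25) * 0.5)
                    resc_step[k] = min(max(resc_step[k], 1e-4), 2.0)

            # paired translations along adaptively estimated ridge
            # directions (inertia with its channel's diffusion, and the
            # expressed inertia with the expressed->felt cross-effect):
            # likelihood ridges couple these coordinates, so axis-aligned
            # translations stall across them.
            for pi, (ka, kb) in enumerate(_PAIR_MOVES):
                c2 = run_cov[:, [ka, kb]][:, :, [ka, kb]].mean(axis=0)
                try:
                    ch2 = np.linalg.cholesky(c2 + 1e-10 * np.eye(2))
                except np.linalg.LinAlgError:
                    continue
                d2 = pair_step[pi] * (ch2 @ rng.standard_normal(2))
                theta_prop = theta.copy()
                theta_prop[:, ka] += d2[0]
                theta_prop[:, kb] += d2[1]
                ll_prop_all = _cohort_loglik(theta_prop, v[0], v[1],
                                             tflat, yflat, offs)
                if np.all(np.isfinite(ll_prop_all)):
                    dpost = np.sum(ll_prop_all) - np.sum(ll)
                    for k, dk in ((ka, d2[0]), (kb, d2[1])):
                        dpost += (
                            -0.5 * ((mu[k] + dk - prior.mean_loc[k])
                                    / prior.mean_scale[k]) ** 2
                            + 0.5 * ((mu[k] - prior.mean_loc[k])
                                     / prior.mean_scale[k]) ** 2
                        )
                    acc = math.log(rng.random()) < dpost
                else:
                    acc = False
                if acc:
                    theta = theta_prop
                    mu[ka] += d2[0]
                    mu[kb] += d2[1]
                    ll = ll_prop_all
                if adapting:
                    pair_step[pi] *= math.exp(
                        gamma * ((1.0 if acc else 0.0) - 0.25) * 0.5)
                    pair_step[pi] = min(max(pair_step[pi], 1e-4), 10.0)

        # --- group means: conjugate Gibbs
        prec = p_count / sigma**2 + 1.0 / prior.mean_scale**2
        mean = (theta.sum(axis=0) / sigma**2
                + prior.mean_loc / prior.mean_scale**2) / prec
        mu = mean + rng.standard_normal(8) / np.sqrt(prec)

        # --- group SDs: Metropolis on log sigma
        for k in range(8):
            prop = sigma[k] * math.exp(sig_step[k] * rng.standard_normal())
            dev = theta[:, k] - mu[k]
            cur = (-p_count * math.log(sigma[k])
                   - 0.5 * np.sum(dev**2) / sigma[k] ** 2
                   - 0.5 * (sigma[k] / prior.sd_scale[k]) ** 2
                   + math.log(sigma[k]))
            new = (-p_count * math.log(prop)
                   - 0.5 * np.sum(dev**2) / prop**2
                   - 0.5 * (prop / prior.sd_scale[k]) ** 2
                   + math.log(prop))
            acc = math.log(rng.random()) < new - cur
            if acc:
                sigma[k] = prop
            if adapting:
                sig_step[k] *= math.exp(gamma * ((1.0 if acc else 0.0) - 0.44)
                                        * 0.5)
                sig_step[k] = min(max(sig_step[k], 1e-3), 5.0)

        # --- shared measurement SDs: joint Metropolis on log scale
        for _ in range(_MEAS_REPS):
            prop_meas = meas * np.exp(meas_step * rng.standard_normal(2))
            vp = prop_meas**2
            ll_prop_all = _cohort_loglik(theta, vp[0], vp[1],
                                         tflat, yflat, offs)
            if np.all(np.isfinite(ll_prop_all)):
                dpost = (
                    np.sum(ll_prop_all) - np.sum(ll)
                    + np.sum(_half_normal_logpdf(prop_meas,
                                                 prior.meas_sd_scale))
                    - np.sum(_half_normal_logpdf(meas, prior.meas_sd_scale))
                    + np.sum(np.log(prop_meas) - np.log(meas))
                )
                acc = math.log(rng.random()) < dpost
            else:
                acc = False
            if acc:
                meas = prop_meas
                v = vp
                ll = ll_prop_all
            if adapting:
                meas_step *= math.exp(
                    gamma * ((1.0 if acc else 0.0) - 0.3) * 0.5)
                meas_step = min(max(meas_step, 1e-3), 2.0)

        if it >= warmup:
            j = it - warmup
            out_theta[j] = theta
            out_mu[j] = mu
            out_sigma[j] = sigma
            out_meas[j] = meas

    return out_theta, out_mu, out_sigma, out_meas


def fit_hierarchical(
    all_persons: list[ObservationSeries],
    prior: GroupPrior | None = None,
    config: MCMCConfig | None = None,
) -> GroupPosterior:
    """Sample the hierarchical posterior for a cohort of EMA series.

    Returns a :class:`GroupPosterior` with draws, split-R-hat and bulk ESS
    per group-level parameter; a non-converged run (any R-hat > 1.05, or a
    single chain) is flagged via ``converged=False`` and a warning, never
    silently.
    """
    prior = prior or GroupPrior()
    config = config or MCMCConfig()
    if len(all_persons) < 2:
        raise ValueError("hierarchical fit needs at least 2 persons")
    _check_series(all_persons)

    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    chains_out = []
    for c in range(config.chains):
        rng = np.random.default_rng(seeds[c])
        chains_out.append(_run_chain(
            all_persons, prior, config.iterations, config.warmup, rng))
        logger.info("chain %d/%d finished", c + 1, config.chains)

    theta = np.stack([c[0] for c in chains_out])
    mu = np.stack([c[1] for c in chains_out])
    sigma = np.stack([c[2] for c in chains_out])
    meas = np.stack([c[3] for c in chains_out])

    if config.chains >= 2:
        rhat, ess = _diagnostics(mu, sigma, meas)
        converged = all(r <= 1.05 for r in rhat.values() if np.isfinite(r))
    else:
        rhat, ess = {}, {}
        converged = False
    if not converged:
        logger.warning("fit flagged non-converged (max R-hat %s)",
                       max(rhat.values()) if rhat else "n/a: single chain")

    nat = natural_drift_entries(theta)
    det = nat[..., 0] * nat[..., 1] - nat[..., 2] * nat[..., 3]
    n_bad = int(np.sum(det <= 0))
    if n_bad:
        logger.warning("%d non-stationary draws flagged", n_bad)

    return GroupPosterior(
        person_ids=[s.person_id for s in all_persons],
        theta=theta, mu=mu, sigma=sigma, meas_sd=meas,
        rhat=rhat, ess=ess, converged=converged, n_nonstationary=n_bad,
    )


# ---------------------------------------------------------------------------
# summaries

def summarize_group(
    post: GroupPosterior, mode: str = "person_average"
) -> pd.DataFrame:
    """Group-level drift-entry summary: posterior mean and 95% CI per feature.

    Rows are the four drift entries (inertias and cross-influences) on the
    natural scale; see :meth:`GroupPosterior.group_feature_draws` for the
    two summary modes.
    """
    draws = post.group_feature_draws(mode=mode).reshape(-1, 4)
    rows = []
    for k, feat in enumerate(DRIFT_FEATURES):
        lo, hi = np.quantile(draws[:, k], [0.025, 0.975])
        rows.append({
            "feature": FEATURE_LABELS[feat],
            "mean": float(draws[:, k].mean()),
            "ci_lower": float(lo),
            "ci_upper": float(hi),
        })
    return pd.DataFrame(rows)


def person_point_estimates(post: GroupPosterior) -> pd.DataFrame:
    """Posterior-mean drift entries per person, natural scale.

    Columns are DRIFT_FEATURES, indexed by person_id; these are the
    person-level point estimates used for trait associations.
    """
    nat = post.natural_person_draws()  # (chains, draws, P, 4)
    est = nat.reshape(-1, post.n_persons, 4).mean(axis=0)
    return pd.DataFrame(est, columns=list(DRIFT_FEATURES)).assign(
        person_id=post.person_ids
    ).set_index("person_id")
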