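"""Synthetic EMA cohorts with the study's design and model structure.

Emulates a 28-day experience-sampling protocol: up to 6 random prompts per
day inside a waking window, Bernoulli compliance calibrated so a person
completes ~157 surveys on average, bivariate OU latent dynamics with
person-specific parameters drawn around the reported group means, Gaussian
measurement noise, and 0-100 bounded responses.  Trait variables (sex,
general happiness, flourishing, emotional well-being) are generated on
their summary scales with configurable target correlations to the person's
dynamic parameters; an item-level mode exists for flourishing to exercise
trait scoring.

Ground truth (person-level parameters and group settings) is retained in
the returned dataset so parameter-recovery tests can close the loop.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ct_dynamics import CTParams, discrete_drift, discrete_noise_cov, \
    is_stationary, stationary_moments
from .state_space import ObservationSeries

#: Nominal study start used to render prompt hours as timestamps.
STUDY_START = pd.Timestamp("2024-01-01 00:00:00")


@dataclass
class ScheduleConfig:
    """Prompt schedule: 28 days x up to 6 prompts in a 09:00-21:00 window.

    ``compliance`` is the mean per-prompt answer probability; the default
    0.93 makes the completed-survey count per person average ~157
    (157/168).  ``compliance_sd`` spreads compliance across persons (beta
    distributed), reproducing the reported between-person SD of ~15
    completed surveys; set it to 0 for identical compliance.
    ``min_spacing_minutes`` keeps prompts apart (30 min default).
    """

    days: int = 28
    max_prompts_per_day: int = 6
    window_start_hour: float = 9.0
    window_end_hour: float = 21.0
    min_spacing_minutes: float = 30.0
    compliance: float = 0.93
    compliance_sd: float = 0.087

    def __post_init__(self):
        window = self.window_end_hour - self.window_start_hour
        if window <= 0:
            raise ValueError("waking window must have positive length")
        if self.min_spacing_minutes < 0 or not 0 <= self.compliance <= 1:
            raise ValueError("invalid spacing or compliance")
        needed = (self.max_prompts_per_day - 1) * self.min_spacing_minutes / 60
        if needed >= window:
            raise ValueError(
                f"window of {window} h cannot hold {self.max_prompts_per_day} "
                f"prompts {self.min_spacing_minutes} min apart"
            )


def generate_schedule(config: ScheduleConfig, seed) -> np.ndarray:
    """Completed prompt times for one person, hours since study start.

    Prompts are uniform within each day's waking window subject to the
    minimum spacing, then thinned by Bernoulli compliance.
    """
    rng = np.random.default_rng(seed)
    sp = config.min_spacing_minutes / 60.0
    window = config.window_end_hour - config.window_start_hour
    m = config.max_prompts_per_day
    slack = window - (m - 1) * sp
    p = config.compliance
    if config.compliance_sd > 0 and 0 < p < 1:
        var = min(config.compliance_sd**2, 0.99 * p * (1 - p))
        k = p * (1 - p) / var - 1.0
        p = rng.beta(p * k, (1 - p) * k)
    times = []
    for day in range(config.days):
        u = np.sort(rng.uniform(0.0, slack, m))
        day_times = day * 24.0 + config.window_start_hour + u + np.arange(m) * sp
        answered = rng.random(m) < p
        times.extend(day_times[answered])
    return np.asarray(times)


def simulate_person_series(
    params: CTParams, prompt_times, seed, clip: bool = True
) -> ObservationSeries:
    """Simulate one person's series by exact OU transitions.

    The latent state starts at its stationary distribution and steps through
    each inter-prompt gap with the exact discrete transition (exp(A*dt),
    Q(dt)); observations add the manifest intercept and measurement noise
    and are clipped to [0, 100].
    """
    if not params.stationary:
        raise ValueError("simulation requires a stationary drift matrix")
    rng = np.random.default_rng(seed)
    t = np.asarray(prompt_times, dtype=float)
    mu, g = stationary_moments(params)
    x = mu + np.linalg.cholesky(g + 1e-12 * np.eye(2)) @ rng.standard_normal(2)
    latent = np.empty((t.size, 2))
    latent[0] = x
    for k in range(1, t.size):
        dt = t[k] - t[k - 1]
        e = discrete_drift(params.drift, dt)
        q = discrete_noise_cov(params, dt)
        # guard tiny negative eigenvalues from cancellation
        q = q + 1e-12 * np.eye(2)
        x = mu + e @ (x - mu) + np.linalg.cholesky(q) @ rng.standard_normal(2)
        latent[k] = x
    obs = latent + params.manifest_intercept + rng.standard_normal(
        (t.size, 2)) * params.meas_sd
    if clip:
        obs = np.clip(obs, 0.0, 100.0)
        return ObservationSeries(person_id=None, times=t - t[0], values=obs)
    return ObservationSeries._unchecked(None, t - t[0], obs)


@dataclass
class GroupTruth:
    """Generating group distribution for person parameters and traits.

    Drift means default to the reported group-level estimates; manifest
    intercept means/SDs to the reported person-mean levels of felt (68.44,
    SD 15.23) and expressed (64.62, SD 17.63) love.  ``trait_targets`` maps
    (trait, dynamic feature) to a target correlation between the trait and
    the person's generating drift entry; by default flourishing correlates
    0.411 with felt-love inertia and other pairs are uncorrelated.
    """

    drift_mean: np.ndarray = field(default_factory=lambda: np.array(
        [[-0.065, 0.820], [-0.038, -0.900]]))
    drift_sd: np.ndarray = field(default_factory=lambda: np.array(
        [[0.03, 0.20], [0.02, 0.25]]))
    tau_mean: np.ndarray = field(default_factory=lambda: np.array(
        [68.44, 64.62]))
    tau_sd: np.ndarray = field(default_factory=lambda: np.array(
        [15.23, 17.63]))
    diffusion_mean: np.ndarray = field(default_factory=lambda: np.array(
        [0.9, 5.3]))
    diffusion_sd: np.ndarray = field(default_factory=lambda: np.array(
        [0.25, 1.0]))
    meas_sd: np.ndarray = field(default_factory=lambda: np.array([2.5, 2.5]))
    female_prob: float = 0.67
    trait_mean: dict = field(default_factory=lambda: {
        "happiness": 5.22, "flourishing": 45.44, "well_being": 4.72})
    trait_sd: dict = field(default_factory=lambda: {
        "happiness": 1.43, "flourishing": 8.85, "well_being": 0.85})
    trait_targets: dict = field(default_factory=lambda: {
        ("flourishing", "felt_inertia"): 0.411})

    def draw_person_params(self, rng) -> CTParams:
        """One person's CTParams; drift rejection-resampled to stationarity."""
        for _ in range(1000):
            a = rng.normal(self.drift_mean, self.drift_sd)
            if a[0, 0] < 0 and a[1, 1] < 0 and is_stationary(a):
                break
        else:
            raise RuntimeError("could not draw a stationary drift matrix; "
                               "drift_sd too large for drift_mean")
        d = np.abs(rng.normal(self.diffusion_mean, self.diffusion_sd))
        d = np.maximum(d, 0.1)
        tau = rng.normal(self.tau_mean, self.tau_sd)
        return CTParams(drift=a, diffusion=np.diag(d),
                        manifest_intercept=tau, meas_sd=self.meas_sd.copy())


_FEATURE_SLOT = {"felt_inertia": (0, 0), "expressed_inertia": (1, 1),
                 "expressed_to_felt": (0, 1), "felt_to_expressed": (1, 0)}


@dataclass
class SyntheticDataset:
    """A generated cohort: long EMA table, trait table and ground truth."""

    ema: pd.DataFrame
    traits: pd.DataFrame
    truth_params: dict
    truth_features: pd.DataFrame
    group: GroupTruth
    clipped_fraction: float

    def write(self, ema_path, traits_path, truth_path=None) -> None:
        self.ema.to_csv(ema_path, index=False)
        self.traits.to_csv(traits_path, index=False)
        if truth_path is not None:
            payload = {
                "clipped_fraction": self.clipped_fraction,
                "persons": {
                    str(pid): {
                        "drift": p.drift.tolist(),
                        "diffusion_sd": np.diag(p.diffusion).tolist(),
                        "manifest_intercept": p.manifest_intercept.tolist(),
                        "meas_sd": p.meas_sd.tolist(),
                    }
                    for pid, p in self.truth_params.items()
                },
            }
            with open(truth_path, "w") as fh:
                json.dump(payload, fh, indent=1)


def _flourishing_items(scores, rng):
    """Spread integer flourishing sums (8-56) over 8 items on 1-7."""
    items = np.empty((scores.size, 8), dtype=int)
    for i, s in enumerate(scores):
        s = int(np.clip(round(s), 8, 56))
        base, rem = divmod(s - 8, 8)
        row = np.full(8, 1 + base)
        bump = rng.permutation(8)[:rem]
        row[bump] += 1
        items[i] = np.clip(row, 1, 7)
    return items


def simulate_cohort(
    group: GroupTruth | None = None,
    schedule: ScheduleConfig | None = None,
    n_persons: int = 52,
    seed: int = 0,
    flourishing_items: bool = False,
    start: pd.Timestamp = STUDY_START,
) -> SyntheticDataset:
    """Generate a full synthetic cohort with retained ground truth.

    Traits are drawn on their summary scales around the reported means/SDs;
    each targeted (trait, feature) pair receives correlation r by mixing the
    standardized person-level generating feature with independent noise as
    r*z + sqrt(1-r^2)*eps.  With ``flourishing_items`` the trait table also
    carries 8 item columns whose sum reproduces the flourishing score.
    """
    group = group or GroupTruth()
    schedule = schedule or ScheduleConfig()
    if n_persons < 2:
        raise ValueError("cohort needs at least 2 persons")
    root = np.random.default_rng(seed)
    person_seeds = np.random.SeedSequence(seed).spawn(n_persons)

    rows = []
    truth_params = {}
    feat_rows = []
    n_clipped = 0
    n_obs = 0
    for i in range(n_persons):
        pid = f"p{i + 1:03d}"
        prng = np.random.default_rng(person_seeds[i])
        params = group.draw_person_params(prng)
        truth_params[pid] = params
        times = generate_schedule(schedule, prng)
        series = simulate_person_series(params, times, prng)
        # values sitting exactly on a bound were clipped (a.s. under the model)
        n_clipped += int(np.sum((series.values <= 0.0)
                                | (series.values >= 100.0)))
        n_obs += series.values.size
        stamps = start + pd.to_timedelta(times, unit="h")
        for t, (f, e) in zip(stamps, series.values):
            rows.append((pid, t.isoformat(), f, e))
        a = params.drift
        feat_rows.append({
            "person_id": pid,
            "felt_inertia": a[0, 0], "expressed_inertia": a[1, 1],
            "expressed_to_felt": a[0, 1], "felt_to_expressed": a[1, 0],
        })
    ema = pd.DataFrame(rows, columns=["person_id", "timestamp", "felt",
                                      "expressed"])
    features = pd.DataFrame(feat_rows).set_index("person_id")

    # traits: mix standardized generating features with noise to hit targets
    traits = pd.DataFrame(index=features.index)
    traits["sex"] = (root.random(n_persons) < group.female_prob).astype(int)
    for name in ("happiness", "flourishing", "well_being"):
        z = root.standard_normal(n_persons)
        for (trait, feat), r in group.trait_targets.items():
            if trait != name:
                continue
            fz = features[feat].to_numpy()
            fz = (fz - fz.mean()) / fz.std()
            # orthogonalised noise: the printed association is a sample
            # statistic, so the emulated cohort hits the target r exactly
            # (up to response-scale clipping)
            eps = root.standard_normal(n_persons)
            eps = eps - (eps @ fz) / (fz @ fz) * fz
            eps = (eps - eps.mean()) / eps.std()
            z = r * fz + math.sqrt(1 - r * r) * eps
        traits[name] = group.trait_mean[name] + group.trait_sd[name] * z
    traits["flourishing"] = traits["flourishing"].clip(8, 56)
    traits["happiness"] = traits["happiness"].clip(1, 7)
    traits["well_being"] = traits["well_being"].clip(1, 6)
    if flourishing_items:
        items = _flourishing_items(traits["flourishing"].to_numpy(), root)
        for j in range(8):
            traits[f"flourishing_{j + 1}"] = items[:, j]
        traits["flourishing"] = items.sum(axis=1)

    return SyntheticDataset(
        ema=ema,
        traits=traits.reset_index(),
        truth_params=truth_params,
        truth_features=features,
        group=group,
        clipped_fraction=n_clipped / max(n_obs, 1),
    )
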