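"""Hierarchical model: transforms, joint density, sampler behaviour."""

import numpy as np
import pytest
from scipy.stats import chisquare

import lovedyn as ld
from lovedyn import inference as inf
from .conftest import random_stationary_params


class TestTransforms:
    def test_round_trip_identity(self, rng):
        for _ in range(50):
            p = random_stationary_params(rng)
            p.diffusion = np.diag(np.abs(np.diag(p.diffusion)) + 0.1)
            theta = inf.transform(p)
            back = inf.untransform(theta, meas_sd=p.meas_sd)
            assert np.allclose(back.drift, p.drift, atol=1e-12)
            assert np.allclose(back.diffusion, p.diffusion, atol=1e-12)
            assert np.allclose(back.manifest_intercept, p.manifest_intercept)

    def test_negative_limit_of_drift_diagonal(self):
        p = inf.untransform([-40, -40, 0, 0, 1, 1, 50, 50])
        assert -1e-15 < p.drift[0, 0] < 0

    def test_softplus_map_at_zero(self):
        # declared map: diffusion sd = log(1 + e^theta); theta=0 -> ln 2
        p = inf.untransform([0.0, 0.0, 0, 0, 0.0, 0.0, 50, 50])
        assert p.diffusion[0, 0] == pytest.approx(np.log(2.0))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            inf.untransform([np.nan, 0, 0, 0, 1, 1, 50, 50])


def _tiny_cohort(rng, n_persons=3, days=4):
    ds = ld.simulate_cohort(schedule=ld.ScheduleConfig(days=days),
                            n_persons=n_persons, seed=int(rng.integers(2**31)))
    return ld.clean_series(ds.ema), ds


class TestLogPosterior:
    def test_finite_at_reasonable_point(self, rng):
        series, _ = _tiny_cohort(rng)
        theta = np.stack([
            inf.transform(ld.CTParams(
                drift=np.array([[-0.1, 0.5], [-0.05, -0.9]]),
                diffusion=np.diag([1.5, 7.0]),
                manifest_intercept=np.nanmean(s.values, axis=0)))
            for s in series
        ])
        lp = inf.log_posterior(series, theta, theta.mean(0),
                               np.ones(8), np.array([5.0, 5.0]))
        assert np.isfinite(lp)

    def test_duplicate_person_adds_its_terms(self, rng):
        """An identical extra person adds exactly lik + random-effect terms."""
        series, _ = _tiny_cohort(rng, n_persons=2)
        theta1 = np.stack([
            inf.transform(ld.CTParams(
                drift=np.array([[-0.1, 0.5], [-0.05, -0.9]]),
                diffusion=np.diag([1.5, 7.0]),
                manifest_intercept=np.nanmean(s.values, axis=0)))
            for s in series
        ])
        mu, sig = theta1.mean(0), np.ones(8)
        meas = np.array([5.0, 5.0])
        base = inf.log_posterior(series, theta1, mu, sig, meas)

        dup = series + [series[-1]]
        theta2 = np.vstack([theta1, theta1[-1]])
        more = inf.log_posterior(dup, theta2, mu, sig, meas)

        lik = ld.kalman_loglik(
            series[-1], inf.untransform(theta2[-1], meas_sd=meas))
        re = float(np.sum(
            -0.5 * ((theta1[-1] - mu) / sig) ** 2 - np.log(sig)
            - 0.5 * np.log(2 * np.pi)))
        assert more - base == pytest.approx(lik + re, abs=1e-6)

    def test_too_few_occasions_names_person(self):
        s = ld.ObservationSeries("shorty", [0.0, 1.0],
                                 [[50, 50], [51, 49]])
        with pytest.raises(ValueError, match="shorty"):
            inf.log_posterior([s], np.zeros((1, 8)), np.zeros(8),
                              np.ones(8), np.ones(2))


class TestFitHierarchical:
    def test_single_chain_smoke_flagged_nonconverged(self, rng):
        series, _ = _tiny_cohort(rng, n_persons=2)
        post = ld.fit_hierarchical(
            series, config=ld.MCMCConfig(chains=1, iterations=120, seed=0))
        assert not post.converged
        assert post.theta.shape[0] == 1 and post.n_persons == 2
        assert np.all(np.isfinite(post.mu))

    def test_seed_reproducibility(self, rng):
        series, _ = _tiny_cohort(rng)
        cfg = ld.MCMCConfig(chains=1, iterations=150, seed=9)
        a = ld.fit_hierarchical(series, config=cfg)
        b = ld.fit_hierarchical(series, config=cfg)
        assert np.array_equal(a.mu, b.mu)
        assert np.array_equal(a.theta, b.theta)

    def test_needs_two_persons(self, rng):
        series, _ = _tiny_cohort(rng, n_persons=2)
        with pytest.raises(ValueError):
            ld.fit_hierarchical(series[:1])

    def test_retained_draws_are_stationary(self, rng):
        series, _ = _tiny_cohort(rng)
        post = ld.fit_hierarchical(
            series, config=ld.MCMCConfig(chains=2, iterations=200, seed=2))
        nat = post.natural_person_draws()
        det = nat[..., 0] * nat[..., 1] - nat[..., 2] * nat[..., 3]
        assert np.all(det > 0)
        assert post.n_nonstationary == 0


class TestSummaries:
    @staticmethod
    def _degenerate_posterior(value=0.82):
        theta = np.zeros((1, 1, 2, 8))
        theta[..., 2] = value
        theta[..., 0] = 1.0
        return inf.GroupPosterior(
            person_ids=["a", "b"], theta=theta,
            mu=np.zeros((1, 1, 8)), sigma=np.ones((1, 1, 8)),
            meas_sd=np.ones((1, 1, 2)), rhat={}, ess={}, converged=True)

    def test_degenerate_posterior_collapses_ci(self):
        s = inf.summarize_group(self._degenerate_posterior())
        row = s[s.feature == "expressed→felt cross-influence"].iloc[0]
        assert row["mean"] == row.ci_lower == row.ci_upper == 0.82

    def test_normal_draws_quantiles(self, rng):
        theta = np.zeros((2, 20000, 1, 8))
        theta[..., 2] = rng.normal(0.82, 0.1, (2, 20000, 1))
        post = inf.GroupPosterior(
            person_ids=["a"], theta=theta, mu=np.zeros((2, 20000, 8)),
            sigma=np.ones((2, 20000, 8)), meas_sd=np.ones((2, 20000, 2)),
            rhat={}, ess={}, converged=True)
        s = inf.summarize_group(post)
        row = s[s.feature == "expressed→felt cross-influence"].iloc[0]
        assert row["mean"] == pytest.approx(0.82, abs=0.005)
        assert row.ci_lower == pytest.approx(0.624, abs=0.01)
        assert row.ci_upper == pytest.approx(1.016, abs=0.01)

    def test_single_draw_point_estimates(self):
        post = self._degenerate_posterior()
        est = inf.person_point_estimates(post)
        assert list(est.index) == ["a", "b"]
        assert np.allclose(est["expressed_to_felt"], 0.82)
        assert np.allclose(est["felt_inertia"], -np.log1p(np.exp(1.0)))

    def test_shrinkage_toward_group_mean(self, rng):
        """Person estimates of weakly identified entries pool strongly."""
        ds = ld.simulate_cohort(schedule=ld.ScheduleConfig(days=6),
                                n_persons=10, seed=77)
        series = ld.clean_series(ds.ema)
        post = ld.fit_hierarchical(
            series, config=ld.MCMCConfig(chains=1, iterations=500, seed=1))
        est = inf.person_point_estimates(post)
        truth = ds.truth_features
        assert est["felt_to_expressed"].std() < truth["felt_to_expressed"].std()


class TestCalibration:
    def test_prior_predictive_ranks_roughly_uniform(self):
        """Simulation-based-calibration spot check on the tau_1 group mean.

        Hyperparameters are drawn from the model's own prior, person
        parameters from the random-effect distribution (rejected to
        stationarity, matching the model's effective prior), data from the
        generative model, and the posterior refitted; the rank of the true
        group mean among posterior draws should not be grossly non-uniform.
        Tiny cohorts keep posteriors wide, so the check mostly guards
        against gross density/Jacobian errors.
        """
        prior = ld.GroupPrior()
        sched = ld.ScheduleConfig(days=3, compliance=1.0, compliance_sd=0.0)
        reps, bins = 24, 6
        ranks = []
        for rep in range(reps):
            rrng = np.random.default_rng(1000 + rep)
            mu = rrng.normal(prior.mean_loc, prior.mean_scale)
            sigma = np.abs(rrng.normal(0.0, prior.sd_scale))
            meas = np.abs(rrng.normal(0.0, prior.meas_sd_scale)) + 0.3
            series = []
            for p in range(2):
                for _ in range(200):
                    theta = rrng.normal(mu, sigma)
                    params = inf.untransform(theta, meas_sd=meas)
                    if params.stationary:
                        break
                else:
                    pytest.skip("prior draw stuck non-stationary")
                times = ld.generate_schedule(sched, rrng)
                s = ld.simulate_person_series(params, times, rrng, clip=False)
                s.person_id = f"p{p}"
                series.append(s)
            post = ld.fit_hierarchical(
                series, prior=prior,
                config=ld.MCMCConfig(chains=1, iterations=300,
                                     seed=3000 + rep))
            draws = post.mu[0, ::10, 6]
            ranks.append(int(np.sum(draws < mu[6])) * bins
                         // (draws.size + 1))
        counts = np.bincount(ranks, minlength=bins)[:bins]
        _, pval = chisquare(counts)
        assert pval > 0.001
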