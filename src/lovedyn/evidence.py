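"""Trait-association statistics: correlations, Bayes factors, power.

Associations between person-level dynamic parameters and trait measures are
summarised by Pearson correlations (point-biserial for binary sex) together
with the default two-sided Bayes factor for a correlation: a symmetric
stretched-beta(1/k, 1/k) prior of width k on the population correlation rho
over (-1, 1), and the exact sampling density of the observed r given rho and
n under bivariate normality.  BF10 is the ratio of the marginal likelihood
of r under that prior to its density at rho = 0, computed by adaptive
quadrature.

The same exact sampling density drives the correlation power analysis: the
smallest n at which the two-sided level-alpha t-test of rho = 0 reaches the
target power under a true rho.  The exact distribution matters here - the
Fisher-z approximation gives a different (larger) minimum n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, special, stats

#: Evidence thresholds on BF10: (1,3] anecdotal, (3,10] substantial,
#: >10 strong, <=1 favours the null.
EVIDENCE_THRESHOLDS = (1.0, 3.0, 10.0)


@dataclass
class CorrelationEvidence:
    """One trait-dynamic association: r, n, BF10 and its evidence category."""

    r: float
    n: int
    bf10: float
    category: str

    def cell(self, digits: int = 3) -> str:
        """Render as printed-table cell, e.g. ``0.411*[14.778]``."""
        star = "*" if self.bf10 > EVIDENCE_THRESHOLDS[2] else ""
        return f"{self.r:.{digits}f}{star}[{self.bf10:.{digits}f}]"


def pearson_r(x, y) -> float:
    """Product-moment correlation; point-biserial when one input is binary."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    return float(np.corrcoef(x, y)[0, 1])


def _log_r_density(r: float, rho: float, n: int) -> float:
    """Log exact sampling density of the sample correlation r | rho, n."""
    lg = (
        math.log(n - 2)
        + special.gammaln(n - 1)
        - 0.5 * math.log(2 * math.pi)
        - special.gammaln(n - 0.5)
        + 0.5 * (n - 1) * math.log1p(-rho * rho)
        + 0.5 * (n - 4) * math.log1p(-r * r)
        - (n - 1.5) * math.log1p(-rho * r)
    )
    h = special.hyp2f1(0.5, 0.5, n - 0.5, 0.5 * (1.0 + rho * r))
    return lg + math.log(h)


def r_density(r: float, rho: float, n: int) -> float:
    """Exact density of the sample correlation under bivariate normality."""
    if n < 4:
        raise ValueError("density requires n >= 4")
    if abs(r) >= 1:
        return 0.0
    return math.exp(_log_r_density(r, rho, n))


def correlation_bf10(r: float, n: int, prior_width: float = 1.0) -> float:
    """Default two-sided Bayes factor for a Pearson correlation.

    Alternative prior: stretched beta(1/width, 1/width) on rho over (-1, 1)
    (uniform for width 1, the default of standard Bayesian-correlation
    software).  Symmetric in the sign of r.
    """
    if n < 4:
        raise ValueError("bf10 requires n >= 4")
    if abs(r) >= 1:
        raise ValueError("|r| = 1 gives a divergent Bayes factor")
    if prior_width <= 0:
        raise ValueError("prior_width must be positive")
    a = 1.0 / prior_width
    log_prior_norm = special.betaln(a, a) + (2 * a - 1) * math.log(2)
    log_f0 = _log_r_density(r, 0.0, n)

    def integrand(rho):
        logp = (a - 1) * math.log1p(-rho * rho) - log_prior_norm
        return math.exp(_log_r_density(r, rho, n) + logp - log_f0)

    val, _ = integrate.quad(
        integrand, -1.0, 1.0, points=[r], epsabs=0, epsrel=1e-9, limit=200
    )
    return float(val)


def evidence_category(bf10: float) -> str:
    """Map BF10 to the conventional evidence label (boundaries closed above)."""
    if bf10 <= 0:
        raise ValueError("bf10 must be positive")
    lo, mid, hi = EVIDENCE_THRESHOLDS
    if bf10 <= lo:
        return "favors-null"
    if bf10 <= mid:
        return "anecdotal"
    if bf10 <= hi:
        return "substantial"
    return "strong"


def correlation_power(rho: float, n: int, alpha: float = 0.05) -> float:
    """Exact power of the two-sided level-alpha t-test of rho = 0 at size n."""
    if n < 4:
        raise ValueError("power needs n >= 4")
    t_crit = stats.t.ppf(1 - alpha / 2, df=n - 2)
    r_crit = t_crit / math.sqrt(t_crit**2 + n - 2)
    upper, _ = integrate.quad(
        lambda r: r_density(r, rho, n), r_crit, 1.0, epsabs=1e-12, limit=200
    )
    lower, _ = integrate.quad(
        lambda r: r_density(r, rho, n), -1.0, -r_crit, epsabs=1e-12, limit=200
    )
    return float(upper + lower)


def min_n_for_correlation_power(
    rho: float, alpha: float = 0.05, power: float = 0.80, n_max: int = 10_000
) -> int:
    """Smallest n reaching the target power for a true correlation rho."""
    if not 0 < abs(rho) < 1:
        raise ValueError("rho must satisfy 0 < |rho| < 1")
    for n in range(4, n_max + 1):
        if correlation_power(rho, n, alpha=alpha) >= power:
            return n
    raise RuntimeError(f"no n <= {n_max} reaches power {power}")


def monte_carlo_power(
    rho: float, n: int, alpha: float = 0.05, reps: int = 200_000, seed: int = 0
) -> float:
    """Simulation estimate of the test's power (independent check).

    Draws ``reps`` bivariate-normal datasets of size n at correlation rho
    and reports the rejection rate of the two-sided t-test of rho = 0.
    """
    rng = np.random.default_rng(seed)
    t_crit = stats.t.ppf(1 - alpha / 2, df=n - 2)
    r_crit = t_crit / math.sqrt(t_crit**2 + n - 2)
    rejected = 0
    chunk = 20_000
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        x = rng.standard_normal((m, n))
        e = rng.standard_normal((m, n))
        y = rho * x + math.sqrt(1 - rho * rho) * e
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        r = (xc * yc).sum(axis=1) / np.sqrt(
            (xc**2).sum(axis=1) * (yc**2).sum(axis=1)
        )
        rejected += int(np.sum(np.abs(r) > r_crit))
        done += m
    return rejected / reps


#: Trait columns expected in a scored trait table, in printed order.
TRAIT_COLUMNS = ("sex", "happiness", "flourishing", "well_being")

#: Dynamic-feature columns expected from person-level point estimates.
DYNAMIC_COLUMNS = (
    "felt_inertia",
    "expressed_inertia",
    "expressed_to_felt",
    "felt_to_expressed",
)


def associate(
    dynamics: pd.DataFrame,
    traits: pd.DataFrame,
    prior_width: float = 1.0,
) -> pd.DataFrame:
    """Grid of CorrelationEvidence: 4 dynamic features x 4 trait measures.

    Both frames are keyed by ``person_id`` (index or column).  Pairwise
    complete observations are used per cell; every cell needs >= 4 pairs.
    """
    dyn = dynamics.set_index("person_id") if "person_id" in dynamics else dynamics
    tr = traits.set_index("person_id") if "person_id" in traits else traits
    unmatched = sorted(set(dyn.index).symmetric_difference(tr.index))
    if unmatched:
        raise ValueError(f"person ids not present in both tables: {unmatched}")
    tr = tr.loc[dyn.index]
    out = pd.DataFrame(index=list(DYNAMIC_COLUMNS), columns=list(TRAIT_COLUMNS),
                       dtype=object)
    for d in DYNAMIC_COLUMNS:
        for t in TRAIT_COLUMNS:
            pair = pd.concat([dyn[d], tr[t]], axis=1).dropna()
            if len(pair) < 4:
                raise ValueError(f"fewer than 4 complete pairs for {d} vs {t}")
            r = pearson_r(pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy())
            if abs(r) >= 1.0 - 1e-12:  # perfect correlation: BF diverges
                bf, cat = math.inf, "strong"
            else:
                bf = correlation_bf10(r, len(pair), prior_width=prior_width)
                cat = evidence_category(bf)
            out.loc[d, t] = CorrelationEvidence(
                r=r, n=len(pair), bf10=bf, category=cat
            )
    return out
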