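"""Retrospective design analysis and sample-size planning.

Given an assumed true standardized effect size d and a study's total sample
size n, a two-sided t test at level alpha has a retrospective power, a
probability that a significant estimate carries the wrong sign (Type S
error), and an expected exaggeration factor of significant estimates
(Type M error).  With lambda = |d| sqrt(n), df = n - 1 and t* the two-sided
critical value,

    power  = 1 - F(t* - lambda; df) + F(-t* - lambda; df)
    Type S = F(-t* - lambda; df) / power

where F is the central-t CDF (the estimate is modeled as true effect plus
central-t noise in standard-error units).  Type M is estimated by seeded
Monte Carlo over that same sampling model, conditioning on significance.
Sample-size planning inverts the normal approximation
n = ((z_{1-alpha/2} + z_{power}) / |d|)^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import ValidationError


@dataclass(frozen=True)
class EffectSummary:
    """A condition contrast: mean difference, pooled SD, standardized size."""

    mean_diff: float
    pooled_sd: float

    def __post_init__(self):
        if not (self.pooled_sd > 0):
            raise ValidationError(
                [f"pooled SD must be positive, got {self.pooled_sd}"]
            )

    @property
    def es(self) -> float:
        return self.mean_diff / self.pooled_sd


@dataclass(frozen=True)
class DesignAnalysis:
    """Retrospective power, Type S and Type M at a given alpha and df.

    ``type_m`` is ``inf`` (with ``type_m_defined`` False) for a zero
    assumed effect, where any significant estimate exaggerates infinitely.
    """

    power: float
    type_s: float
    type_m: float
    alpha: float
    df: int

    @property
    def type_m_defined(self) -> bool:
        return np.isfinite(self.type_m)


@dataclass(frozen=True)
class EmpiricalStudy:
    """Printed summary of a published two-group study.

    ``mean_diff`` and ``pooled_sd`` are in outcome units; ``reported_t`` is
    the test statistic the original authors printed.  Optional per-condition
    summaries (means/sds/ns dicts keyed by condition) enable the
    prior-weighted t recomputation.
    """

    question_id: str
    n_total: int
    mean_diff: float
    pooled_sd: float
    reported_t: float | None = None
    means: dict | None = None
    sds: dict | None = None
    ns: dict | None = None

    def __post_init__(self):
        if self.n_total < 2:
            raise ValidationError([f"n_total must be >= 2, got {self.n_total}"])

    @property
    def effect(self) -> EffectSummary:
        return EffectSummary(self.mean_diff, self.pooled_sd)


def _spread_pair(prior):
    """Accept a ConsensusPrior, an (mu, sigma) pair, or any mu/sigma object."""
    if hasattr(prior, "mu") and hasattr(prior, "sigma"):
        mu, sigma = float(prior.mu), float(prior.sigma)
    else:
        mu, sigma = (float(x) for x in prior)
    if not (sigma > 0):
        raise ValidationError([f"prior spread must be positive, got {sigma}"])
    return mu, sigma


def effect_size(control_prior, treatment_prior) -> EffectSummary:
    """Standardized effect implied by a pair of condition priors.

    mean_diff = mu_treatment - mu_control; the pooled SD is the
    root-mean-square of the two spreads (the equal-n pooled-SD analogue);
    es = mean_diff / pooled_sd.
    """
    mu_c, sd_c = _spread_pair(control_prior)
    mu_t, sd_t = _spread_pair(treatment_prior)
    return EffectSummary(
        mean_diff=mu_t - mu_c,
        pooled_sd=float(np.sqrt((sd_c ** 2 + sd_t ** 2) / 2.0)),
    )


def retrodesign(es: float, n_total: int, alpha: float = 0.05,
                n_sims: int = 1_000_000, seed: int = 0) -> DesignAnalysis:
    """Retrospective power, Type S and Type M for a two-sided t test.

    ``es`` is the assumed true standardized effect, ``n_total`` the study's
    total sample size (one-sample convention: lambda = |es| sqrt(n),
    df = n - 1).  Type M uses ``n_sims`` seeded draws of
    lambda + central-t noise, conditioning on |estimate| exceeding the
    critical value.  At es = 0 power equals alpha exactly, Type S is 1/2,
    and Type M is flagged infinite.
    """
    if n_total < 2:
        raise ValidationError([f"n_total must be >= 2, got {n_total}"])
    if not (0.0 < alpha < 1.0):
        raise ValidationError([f"alpha must be in (0, 1), got {alpha}"])
    df = n_total - 1
    tstar = stats.t.ppf(1.0 - alpha / 2.0, df)
    lam = abs(es) * np.sqrt(n_total)
    p_wrong = stats.t.cdf(-tstar - lam, df)
    p_right = 1.0 - stats.t.cdf(tstar - lam, df)
    power = float(p_wrong + p_right)
    type_s = float(p_wrong / power)
    if es == 0:
        return DesignAnalysis(power=power, type_s=type_s, type_m=np.inf,
                              alpha=alpha, df=df)
    rng = np.random.Generator(np.random.PCG64(seed))
    est = lam + rng.standard_t(df, size=int(n_sims))
    sig = np.abs(est) > tstar
    if not np.any(sig):
        type_m = np.nan
    else:
        type_m = float(np.mean(np.abs(est[sig])) / lam)
    return DesignAnalysis(power=power, type_s=type_s, type_m=type_m,
                          alpha=alpha, df=df)


def sample_size_for_power(es: float, target_power: float = 0.80,
                          alpha: float = 0.05) -> int:
    """Total sample size reaching ``target_power`` for effect ``es``.

    Normal approximation ``n = ((z_{1-alpha/2} + z_{power}) / |es|)^2``,
    rounded to the nearest integer.  A zero effect needs an infinite sample
    and is an error.
    """
    if es == 0:
        raise ValidationError(["zero effect size: required sample is infinite"])
    if not (0.0 < alpha < 1.0) or not (0.0 < target_power < 1.0):
        raise ValidationError(["alpha and target_power must be in (0, 1)"])
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    z_b = stats.norm.ppf(target_power)
    n = ((z_a + z_b) / abs(es)) ** 2
    return int(np.floor(n + 0.5))


def welch_t(mean1, sd1, n1, mean2, sd2, n2):
    """Unequal-variances (Welch) t statistic and Welch-Satterthwaite df
    from group summaries; group 1 minus group 2."""
    v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    return float(t), float(df)


def prior_weighted_t(study: EmpiricalStudy, control_prior, treatment_prior):
    """Recompute a study's t statistic with consensus priors mixed in.

    Each condition's summary is a weighted average of the empirical value
    (weight: the condition's sample size) and the prior (weight: one
    observation)::

        mean_k = (n_k xbar_k + mu_k) / (n_k + 1)
        sd_k   = (n_k sd_k + sigma_k) / (n_k + 1)

    and the Welch t of the weighted summaries is returned with counts
    n_k + 1 (Welch-Satterthwaite df).  SDs are combined linearly, not on
    the variance scale.  Returns ``(t, df)``; treatment minus control.
    """
    if not (study.means and study.sds and study.ns):
        raise ValidationError(
            ["prior-weighted t needs per-condition means, SDs and ns; "
             "a mean difference and pooled SD alone are insufficient"]
        )
    mu_c, sd_c = _spread_pair(control_prior)
    mu_t, sd_t = _spread_pair(treatment_prior)
    out = {}
    for cond, mu_p, sd_p in (("control", mu_c, sd_c), ("treatment", mu_t, sd_t)):
        try:
            n_k = study.ns[cond]
            xbar = study.means[cond]
            sd_k = study.sds[cond]
        except KeyError as err:
            raise ValidationError(
                [f"missing condition-level summary for {cond!r}"]
            ) from err
        out[cond] = (
            (n_k * xbar + mu_p) / (n_k + 1),
            (n_k * sd_k + sd_p) / (n_k + 1),
            n_k + 1,
        )
    (m_c, s_c, n_c), (m_t, s_t, n_t) = out["control"], out["treatment"]
    return welch_t(m_t, s_t, n_t, m_c, s_c, n_c)
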