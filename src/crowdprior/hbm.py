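"""Hierarchical Bayesian estimation and aggregation of elicited beliefs.

One model per question.  Each participant i holds a Gaussian belief
N(m_ic, s_ic^2) about the outcome in condition c; the elicited cumulative
probability at a (standardized) quantile prompt q is a noisy version of
Phi((q - m)/s).  Response noise is Beta-distributed in mean-precision form
(mean tied to the belief CDF, shared precision kappa), inflated with point
masses at exactly 0 and exactly 1 for contaminant boundary responses that a
continuous belief cannot produce.  Participant parameters are partially
pooled:

    m_ic ~ Normal(mu_c, tau)          s_ic ~ Normal(sigma_c, gamma), s > 0
    p ~ phi_v Beta(mean=Phi((q-m)/s), prec=kappa) + phi_0 d(0) + phi_1 d(1)

with priors mu_c ~ N(0,1), sigma_c, tau, gamma ~ half-N(0,1),
kappa ~ half-N(0, 10) and phi ~ Dirichlet(1, 1, 8) favoring valid
responses.  The consensus prior for condition c is the posterior median of
(mu_c, sigma_c), mapped back to outcome units; rho, the share of
contaminants that are ones, is derived as phi_1 / (phi_0 + phi_1).

Sampling
--------
A seeded Metropolis-within-Gibbs scheme, independent chains initialized
from prior draws:

* phi has a conjugate Dirichlet full conditional (the boundary-response
  counts are fixed by the data), drawn exactly each sweep;
* each mu_c has a conjugate normal full conditional, drawn exactly;
* participant (m, s) pairs take joint random-walk Metropolis steps in
  (m, log s), vectorized across participants;
* tau, gamma, sigma_c and kappa take scalar random-walk steps on the log
  scale (the positive-truncation normalizer Phi(sigma_c / gamma) is part of
  the s-likelihood and enters those conditionals).

Proposal scales adapt toward standard acceptance targets during warmup and
are frozen afterwards, so the retained draws come from a fixed transition
kernel.  Everything derives from the single config seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, ndtr

from .io import ConsensusPrior, QuestionDataset, ValidationError

__all__ = [
    "McmcConfig", "ScalingRecord", "PosteriorSamples", "HbmModel",
    "standardize_prompts", "fit_hbm", "consensus_from_posterior",
    "diagnostics", "pooling_coefficient", "ConvergenceWarning",
]

_MEAN_CLIP = 1e-9


class ConvergenceWarning(UserWarning):
    """Sampler diagnostics exceeded their thresholds at the given budget."""


@dataclass(frozen=True)
class McmcConfig:
    """Sampler budget and model hyper-prior settings.

    ``chains`` independent chains each run ``warmup`` adaptation sweeps
    followed by ``draws * thin`` sampling sweeps, keeping every ``thin``-th
    state.  ``seed`` is mandatory — every random element (initialization,
    proposals) derives from it.  ``mh_reps`` is the number of
    participant-level Metropolis refreshes per sweep.
    """

    seed: int
    chains: int = 5
    warmup: int = 1000
    draws: int = 600
    thin: int = 5
    mh_reps: int = 3
    kappa_prior_scale: float = 10.0
    #: scale of the half-normal prior on the consensus spreads sigma_c;
    #: the standard model uses 1.0 (standardized prompts) — larger values
    #: give a flatter, less boundary-pulling prior
    sigma_prior_scale: float = 1.0
    dirichlet_weights: tuple[float, float, float] = (1.0, 1.0, 8.0)

    def __post_init__(self):
        if self.seed is None:
            raise ValidationError(["mcmc config requires an explicit seed"])
        for name in ("chains", "warmup", "draws", "thin", "mh_reps"):
            if getattr(self, name) < 1:
                raise ValidationError([f"{name} must be >= 1"])


@dataclass(frozen=True)
class ScalingRecord:
    """Affine standardization x -> (x - center) / scale of prompt values."""

    center: float
    scale: float

    def __post_init__(self):
        if not (self.scale > 0):
            raise ValidationError([f"scale must be positive, got {self.scale}"])

    def forward(self, x):
        return (np.asarray(x, dtype=float) - self.center) / self.scale

    def inverse(self, z):
        return np.asarray(z, dtype=float) * self.scale + self.center


@dataclass
class PosteriorSamples:
    """Posterior draws plus the scaling needed to undo standardization.

    ``draws`` maps parameter names ("mu_c[control]", "tau",
    "m[p001,treatment]", ...) to arrays of shape (n_chains, n_draws), all on
    the standardized prompt scale.
    """

    draws: dict
    n_chains: int
    n_draws: int
    scaling: ScalingRecord
    conditions: tuple
    participants: tuple
    question_id: str = ""
    attrs: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, arr in self.draws.items():
            if arr.shape != (self.n_chains, self.n_draws):
                raise ValidationError(
                    [f"draw array {name!r} has shape {arr.shape}, expected "
                     f"({self.n_chains}, {self.n_draws})"]
                )

    def stacked(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def to_dataframe(self) -> pd.DataFrame:
        """One row per draw x chain, one column per scalar parameter."""
        n = self.n_chains * self.n_draws
        data = {"chain": np.repeat(np.arange(self.n_chains), self.n_draws),
                "draw": np.tile(np.arange(self.n_draws), self.n_chains)}
        for name, arr in self.draws.items():
            data[name] = arr.reshape(n)
        return pd.DataFrame(data)


def standardize_prompts(dataset: QuestionDataset):
    """Center and scale a question's prompts by their pooled mean and SD.

    The pooled moments use every prompt value in the question (both
    conditions, all participants; population-SD convention, divisor n).
    Guess fields are transformed with the same map so record invariants are
    preserved.  Returns ``(standardized dataset, ScalingRecord)``.
    """
    from .io import standardized_copy

    values = np.array([c for r in dataset.records for c in r.prompts], dtype=float)
    if values.size == 0:
        raise ValidationError([f"question {dataset.question_id!r} has no records"])
    if not np.all(np.isfinite(values)):
        raise ValidationError(["non-finite prompt values"])
    center = float(values.mean())
    scale = float(values.std())  # ddof=0
    if scale == 0:
        raise ValidationError(
            [f"question {dataset.question_id!r}: pooled prompt SD is zero"]
        )
    scaling = ScalingRecord(center, scale)
    out = QuestionDataset(
        dataset.question_id,
        [standardized_copy(r, center, scale) for r in dataset.records],
        dataset.outcome_scale,
    )
    return out, scaling


def _log_ndtr(x):
    from scipy.special import log_ndtr
    return log_ndtr(x)


class _CondData:
    """Flat response arrays for one condition, grouped by participant."""

    def __init__(self, records):
        grouped: dict[str, list] = {}
        for rec in records:
            if rec.degenerate:
                continue
            grouped.setdefault(rec.participant_id, []).extend(
                zip(rec.prompts, rec.probs)
            )
        self.pids = list(grouped)
        q, p, part = [], [], []
        for i, pairs in enumerate(grouped.values()):
            for c, prob in pairs:
                q.append(c)
                p.append(prob)
                part.append(i)
        self.q = np.asarray(q, dtype=float)
        self.p = np.asarray(p, dtype=float)
        self.part = np.asarray(part, dtype=int)
        self.valid = (self.p > 0.0) & (self.p < 1.0)
        self.n_participants = len(self.pids)
        self.n_zero = int(np.sum(self.p == 0.0))
        self.n_one = int(np.sum(self.p == 1.0))
        # precompute response log terms that do not depend on parameters
        self.qv = self.q[self.valid]
        self.pv = self.p[self.valid]
        self.part_v = self.part[self.valid]
        self.log_pv = np.log(self.pv) if self.pv.size else self.pv
        self.log1m_pv = np.log1p(-self.pv) if self.pv.size else self.pv


class HbmModel:
    """Model data and likelihood pieces for one (standardized) question.

    ``include_mixture=False`` drops the zero/one inflation — any dataset
    containing exact boundary responses then has log-likelihood -inf, which
    is precisely why the mixture is in the model.
    """

    def __init__(self, dataset: QuestionDataset, config: McmcConfig,
                 include_mixture: bool = True):
        self.config = config
        self.include_mixture = include_mixture
        self.conditions = dataset.conditions
        if not self.conditions:
            raise ValidationError(["dataset has no records"])
        self.question_id = dataset.question_id
        participants = dataset.participants()
        if len(participants) == 1:
            warnings.warn(
                "single-participant dataset: consensus is driven almost "
                "entirely by the priors (heavy shrinkage)",
                ConvergenceWarning, stacklevel=3,
            )
        self.participants = tuple(participants)
        self.K = len(self.conditions)
        self.cond_data = [
            _CondData(dataset.by_condition(c)) for c in self.conditions
        ]
        self.n_zero = sum(d.n_zero for d in self.cond_data)
        self.n_one = sum(d.n_one for d in self.cond_data)
        self.n_valid = sum(int(d.valid.sum()) for d in self.cond_data)
        self._alpha = np.asarray(config.dirichlet_weights, dtype=float)

    def response_loglik_by_participant(self, k: int, m, s, kappa):
        """Per-participant sums of valid-response Beta log densities for
        condition ``k`` at belief parameters (m, s) (arrays over that
        condition's participants)."""
        d = self.cond_data[k]
        if d.qv.size == 0:
            return np.zeros(d.n_participants)
        mean = ndtr((d.qv - m[d.part_v]) / s[d.part_v])
        mean = np.clip(mean, _MEAN_CLIP, 1.0 - _MEAN_CLIP)
        a = mean * kappa
        b = kappa - a
        ll = ((a - 1.0) * d.log_pv + (b - 1.0) * d.log1m_pv
              + math.lgamma(kappa) - gammaln(a) - gammaln(b))
        return np.bincount(d.part_v, weights=ll,
                           minlength=d.n_participants)

    def total_response_loglik(self, state) -> float:
        total = 0.0
        for k in range(self.K):
            total += float(np.sum(self.response_loglik_by_participant(
                k, state["m"][k], state["s"][k], state["kappa"]
            )))
        return total

    def log_likelihood(self, state) -> float:
        """Full-data log likelihood of the responses given a state dict
        (keys mu, sigma, tau, gamma, kappa, phi, m, s)."""
        phi = np.asarray(state["phi"], dtype=float)
        if self.include_mixture:
            with np.errstate(divide="ignore"):
                lphi = np.log(phi)
            ll = (self.n_zero * lphi[0] + self.n_one * lphi[1]
                  + self.n_valid * lphi[2])
        else:
            if self.n_zero or self.n_one:
                # a pure Beta likelihood has no mass at exactly 0 or 1
                return -np.inf
            ll = 0.0
        if not np.isfinite(ll):
            return -np.inf
        return float(ll + self.total_response_loglik(state))

    def initial_state(self, rng: np.random.Generator) -> dict:
        """Chain-starting state: prior draws for the consensus layer, with
        participant beliefs seeded at their single-subject least-squares
        fits and kappa at a moment-matched residual estimate (both jittered
        per chain).

        Purely prior-drawn participant beliefs almost never resemble the
        observed responses, and the posterior has a spurious low-precision
        mode (responses read as pure Beta noise around homogeneous beliefs)
        that captures chains started there; seeding the participant layer
        from the data puts every chain on the data-supported side of that
        divide while leaving the consensus layer overdispersed.
        """
        state = self.draw_from_prior(rng)
        ls = self._least_squares_anchor()
        for k in range(self.K):
            m0 = np.array(state["m"][k])
            s0 = np.array(state["s"][k])
            for i, (mu_hat, s_hat) in ls["fits"][k].items():
                m0[i] = mu_hat + 0.1 * rng.standard_normal()
                s0[i] = s_hat * math.exp(0.1 * rng.standard_normal())
            state["m"][k] = m0
            state["s"][k] = s0
        if ls["kappa"] is not None:
            state["kappa"] = ls["kappa"] * math.exp(0.3 * rng.standard_normal())
        return state

    def _least_squares_anchor(self):
        """Single-subject least-squares fits and a moment-matched kappa,
        computed once per dataset and shared across chains."""
        if getattr(self, "_ls_cache", None) is not None:
            return self._ls_cache
        from .mle import fit_participant_gaussian

        fits = []
        resid_num, resid_den = 0.0, 0.0
        for data in self.cond_data:
            cond_fits = {}
            for i in range(data.n_participants):
                sel = data.part_v == i
                if sel.sum() < 3:
                    continue
                try:
                    bp = fit_participant_gaussian(data.qv[sel], data.pv[sel])
                except ValidationError:
                    continue
                if not bp.identifiable:
                    continue
                mu_hat = bp.mu
                s_hat = float(np.clip(bp.sigma, 0.05, 10.0))
                cond_fits[i] = (mu_hat, s_hat)
                mean = ndtr((data.qv[sel] - mu_hat) / s_hat)
                resid_num += float(np.sum(mean * (1.0 - mean)))
                resid_den += float(np.sum((data.pv[sel] - mean) ** 2))
            fits.append(cond_fits)
        kappa = None
        if resid_den > 0:
            kappa = float(np.clip(max(resid_num / resid_den - 1.0, 2.0),
                                  2.0, 300.0))
        self._ls_cache = {"fits": fits, "kappa": kappa}
        return self._ls_cache

    def draw_from_prior(self, rng: np.random.Generator) -> dict:
        """A full state drawn from the priors (scales floored at 0.05 so no
        chain starts in a numerically degenerate corner)."""
        mu = rng.normal(0.0, 1.0, self.K)
        sigma = np.maximum(
            np.abs(rng.normal(0.0, self.config.sigma_prior_scale, self.K)), 0.05
        )
        tau = max(abs(rng.normal(0.0, 1.0)), 0.05)
        gamma = max(abs(rng.normal(0.0, 1.0)), 0.05)
        kappa = max(abs(rng.normal(0.0, self.config.kappa_prior_scale)), 1.0)
        phi = np.maximum(rng.dirichlet(self._alpha), 1e-4)
        phi = phi / phi.sum()
        m, s = [], []
        for k in range(self.K):
            n = self.cond_data[k].n_participants
            m.append(rng.normal(mu[k], tau, n))
            draws = np.abs(rng.normal(sigma[k], gamma, n))
            s.append(np.maximum(draws, 1e-3))
        return {"mu": mu, "sigma": sigma, "tau": tau, "gamma": gamma,
                "kappa": kappa, "phi": phi, "m": m, "s": s}


class _GibbsSampler:
    """Adaptive Metropolis-within-Gibbs for :class:`HbmModel`."""

    _TARGET_JOINT = 0.30   # 2-d participant proposals
    _TARGET_SCALAR = 0.44

    def __init__(self, model: HbmModel, rng: np.random.Generator):
        self.model = model
        self.rng = rng
        self.state = model.initial_state(rng)
        K = model.K
        self.step_part = [np.full(2, 0.4) for _ in range(K)]  # (m, log s)
        self.step_sigma = np.full(K, 0.3)
        self.step_tau = 0.3
        self.step_gamma = 0.3
        self.step_kappa = 0.3
        self.step_nc_tau = 0.3
        self.step_nc_sigma = np.full(K, 0.3)
        self.step_nc_gamma = 0.3
        self.step_gk = 0.25
        self._acc: dict = {}
        self._cache_resp = [
            model.response_loglik_by_participant(
                k, self.state["m"][k], self.state["s"][k], self.state["kappa"]
            )
            for k in range(K)
        ]

    # -- bookkeeping for adaptation -----------------------------------------

    def _track(self, name, accepted, count=1):
        acc, tot = self._acc.get(name, (0.0, 0))
        self._acc[name] = (acc + float(accepted), tot + count)

    def _adapt(self):
        def factor(name, target):
            acc, tot = self._acc.get(name, (0.0, 0))
            if tot == 0:
                return 1.0
            return math.exp((acc / tot - target) * 0.8)

        for k in range(self.model.K):
            self.step_part[k] *= factor(f"part{k}", self._TARGET_JOINT)
            self.step_sigma[k] *= factor(f"sigma{k}", self._TARGET_SCALAR)
            self.step_nc_sigma[k] *= factor(f"nc_sigma{k}", self._TARGET_SCALAR)
        self.step_tau *= factor("tau", self._TARGET_SCALAR)
        self.step_gamma *= factor("gamma", self._TARGET_SCALAR)
        self.step_kappa *= factor("kappa", self._TARGET_SCALAR)
        self.step_nc_tau *= factor("nc_tau", self._TARGET_SCALAR)
        self.step_nc_gamma *= factor("nc_gamma", self._TARGET_SCALAR)
        self.step_gk *= factor("gk", self._TARGET_JOINT)
        self._acc = {}

    # -- individual updates --------------------------------------------------

    def _update_phi(self):
        m = self.model
        if not m.include_mixture:
            self.state["phi"] = np.array([0.0, 0.0, 1.0])
            return
        alpha = m._alpha + np.array([m.n_zero, m.n_one, m.n_valid])
        self.state["phi"] = self.rng.dirichlet(alpha)

    def _update_mu(self):
        # conjugate: prior N(0,1), likelihood m_i ~ N(mu_k, tau)
        st = self.state
        tau2 = st["tau"] ** 2
        for k in range(self.model.K):
            n = st["m"][k].size
            prec = 1.0 + n / tau2
            mean = np.sum(st["m"][k]) / tau2 / prec
            st["mu"][k] = self.rng.normal(mean, 1.0 / math.sqrt(prec))

    def _update_participants(self, adapt: bool):
        st = self.state
        rng = self.rng
        for k in range(self.model.K):
            n = st["m"][k].size
            if n == 0:
                continue
            sc_m, sc_ls = self.step_part[k]
            for _ in range(self.model.config.mh_reps):
                m_new = st["m"][k] + sc_m * rng.standard_normal(n)
                ls_new = np.log(st["s"][k]) + sc_ls * rng.standard_normal(n)
                s_new = np.exp(ls_new)
                ll_new = self.model.response_loglik_by_participant(
                    k, m_new, s_new, st["kappa"]
                )
                # priors; the Phi(sigma/gamma) normalizer is constant in (m, s)
                def lp(mv, sv):
                    return (-0.5 * ((mv - st["mu"][k]) / st["tau"]) ** 2
                            - 0.5 * ((sv - st["sigma"][k]) / st["gamma"]) ** 2
                            + np.log(sv))  # log-scale proposal Jacobian
                log_r = (ll_new + lp(m_new, s_new)
                         - self._cache_resp[k] - lp(st["m"][k], st["s"][k]))
                accept = np.log(rng.random(n)) < log_r
                st["m"][k] = np.where(accept, m_new, st["m"][k])
                st["s"][k] = np.where(accept, s_new, st["s"][k])
                self._cache_resp[k] = np.where(accept, ll_new, self._cache_resp[k])
                if adapt:
                    self._track(f"part{k}", np.sum(accept), n)

    def _scalar_mh(self, name, value, step, log_target, adapt):
        prop = value * math.exp(step * self.rng.standard_normal())
        log_r = log_target(prop) + math.log(prop) \
            - log_target(value) - math.log(value)
        accepted = math.log(self.rng.random()) < log_r
        if adapt:
            self._track(name, accepted)
        return prop if accepted else value

    def _update_tau(self, adapt):
        st = self.state
        m_all = np.concatenate(st["m"]) if st["m"] else np.empty(0)
        mu_all = np.concatenate([
            np.full(st["m"][k].size, st["mu"][k]) for k in range(self.model.K)
        ])

        def target(tau):
            return (-0.5 * float(np.sum(((m_all - mu_all) / tau) ** 2))
                    - m_all.size * math.log(tau) - 0.5 * tau ** 2)

        st["tau"] = self._scalar_mh("tau", st["tau"], self.step_tau, target, adapt)

    def _update_sigma(self, adapt):
        st = self.state
        s0 = self.model.config.sigma_prior_scale
        for k in range(self.model.K):
            s = st["s"][k]

            def target(sig):
                return (-0.5 * float(np.sum(((s - sig) / st["gamma"]) ** 2))
                        - s.size * float(_log_ndtr(sig / st["gamma"]))
                        - 0.5 * (sig / s0) ** 2)

            st["sigma"][k] = self._scalar_mh(
                f"sigma{k}", st["sigma"][k], self.step_sigma[k], target, adapt
            )

    def _update_gamma(self, adapt):
        st = self.state

        def target(gam):
            out = -0.5 * (gam / 1.0) ** 2
            for k in range(self.model.K):
                s = st["s"][k]
                out += (-0.5 * float(np.sum(((s - st["sigma"][k]) / gam) ** 2))
                        - s.size * (math.log(gam)
                                    + float(_log_ndtr(st["sigma"][k] / gam))))
            return out

        st["gamma"] = self._scalar_mh("gamma", st["gamma"], self.step_gamma,
                                      target, adapt)

    def _update_kappa(self, adapt):
        # uses the cached response log-likelihood for the current state, so
        # one update costs a single likelihood evaluation at the proposal
        st = self.state
        sk = self.model.config.kappa_prior_scale
        kap = st["kappa"]
        prop = kap * math.exp(self.step_kappa * self.rng.standard_normal())
        ll_prop = [self.model.response_loglik_by_participant(
            k, st["m"][k], st["s"][k], prop) for k in range(self.model.K)]
        log_r = (sum(float(np.sum(v)) for v in ll_prop)
                 - sum(float(np.sum(v)) for v in self._cache_resp)
                 - 0.5 * ((prop / sk) ** 2 - (kap / sk) ** 2)
                 + math.log(prop) - math.log(kap))
        accepted = math.log(self.rng.random()) < log_r
        if accepted:
            st["kappa"] = prop
            self._cache_resp = ll_prop
        if adapt:
            self._track("kappa", accepted)

    # -- interweaved (non-centered) scale updates ---------------------------
    # With few responses per participant the centered conditionals for the
    # hierarchy scales form a funnel (small gamma pins the s_i, which pin
    # gamma).  These moves hold the standardized residuals fixed and propose
    # the scale jointly with the participant values, which crosses the
    # funnel in one step.  In each, the participant-prior terms reduce to
    # constants (residuals unchanged) and the -log(scale) density factors
    # cancel against the reparameterization Jacobian, leaving the response
    # likelihood, any truncation normalizers, and the half-normal prior.

    def _response_ll_at(self, m_all, s_all):
        st = self.state
        return [self.model.response_loglik_by_participant(
            k, m_all[k], s_all[k], st["kappa"]) for k in range(self.model.K)]

    def _update_tau_noncentered(self, adapt):
        st = self.state
        tau = st["tau"]
        prop = tau * math.exp(self.step_nc_tau * self.rng.standard_normal())
        ratio = prop / tau
        m_new = [st["mu"][k] + ratio * (st["m"][k] - st["mu"][k])
                 for k in range(self.model.K)]
        ll_new = self._response_ll_at(m_new, st["s"])
        log_r = (sum(float(np.sum(v)) for v in ll_new)
                 - sum(float(np.sum(v)) for v in self._cache_resp)
                 - 0.5 * (prop ** 2 - tau ** 2)
                 + math.log(prop) - math.log(tau))
        accepted = math.log(self.rng.random()) < log_r
        if accepted:
            st["tau"] = prop
            st["m"] = m_new
            self._cache_resp = ll_new
        if adapt:
            self._track("nc_tau", accepted)

    def _update_sigma_noncentered(self, adapt):
        st = self.state
        s0 = self.model.config.sigma_prior_scale
        for k in range(self.model.K):
            sig = st["sigma"][k]
            prop = sig * math.exp(
                self.step_nc_sigma[k] * self.rng.standard_normal()
            )
            s_new = prop + (st["s"][k] - sig)
            if np.any(s_new <= 0):
                if adapt:
                    self._track(f"nc_sigma{k}", False)
                continue
            ll_new = self.model.response_loglik_by_participant(
                k, st["m"][k], s_new, st["kappa"]
            )
            n = s_new.size
            log_r = (float(np.sum(ll_new)) - float(np.sum(self._cache_resp[k]))
                     - n * (float(_log_ndtr(prop / st["gamma"]))
                            - float(_log_ndtr(sig / st["gamma"])))
                     - 0.5 * ((prop / s0) ** 2 - (sig / s0) ** 2)
                     + math.log(prop) - math.log(sig))
            accepted = math.log(self.rng.random()) < log_r
            if accepted:
                st["sigma"][k] = prop
                st["s"][k] = s_new
                self._cache_resp[k] = ll_new
            if adapt:
                self._track(f"nc_sigma{k}", accepted)

    def _update_gamma_noncentered(self, adapt):
        st = self.state
        gam = st["gamma"]
        prop = gam * math.exp(self.step_nc_gamma * self.rng.standard_normal())
        ratio = prop / gam
        s_new = [st["sigma"][k] + ratio * (st["s"][k] - st["sigma"][k])
                 for k in range(self.model.K)]
        if any(np.any(s <= 0) for s in s_new):
            if adapt:
                self._track("nc_gamma", False)
            return
        ll_new = self._response_ll_at(st["m"], s_new)
        log_r = (sum(float(np.sum(v)) for v in ll_new)
                 - sum(float(np.sum(v)) for v in self._cache_resp)
                 - 0.5 * (prop ** 2 - gam ** 2)
                 + math.log(prop) - math.log(gam))
        for k in range(self.model.K):
            n = st["s"][k].size
            log_r -= n * (float(_log_ndtr(st["sigma"][k] / prop))
                          - float(_log_ndtr(st["sigma"][k] / gam)))
        accepted = math.log(self.rng.random()) < log_r
        if accepted:
            st["gamma"] = prop
            st["s"] = s_new
            self._cache_resp = ll_new
        if adapt:
            self._track("nc_gamma", accepted)

    def _update_gamma_kappa_joint(self, adapt):
        """Joint non-centered move along the gamma-kappa ridge: response
        noise attributed to the Beta precision trades off against belief
        heterogeneity, so the two mix slowly one coordinate at a time."""
        st = self.state
        gam, kap = st["gamma"], st["kappa"]
        z = self.rng.standard_normal(2)
        gam_p = gam * math.exp(self.step_gk * z[0])
        kap_p = kap * math.exp(self.step_gk * z[1])
        ratio = gam_p / gam
        s_new = [st["sigma"][k] + ratio * (st["s"][k] - st["sigma"][k])
                 for k in range(self.model.K)]
        if any(np.any(s <= 0) for s in s_new):
            if adapt:
                self._track("gk", False)
            return
        ll_new = [self.model.response_loglik_by_participant(
            k, st["m"][k], s_new[k], kap_p) for k in range(self.model.K)]
        sk = self.model.config.kappa_prior_scale
        log_r = (sum(float(np.sum(v)) for v in ll_new)
                 - sum(float(np.sum(v)) for v in self._cache_resp)
                 - 0.5 * (gam_p ** 2 - gam ** 2)
                 - 0.5 * ((kap_p / sk) ** 2 - (kap / sk) ** 2)
                 + math.log(gam_p) - math.log(gam)
                 + math.log(kap_p) - math.log(kap))
        for k in range(self.model.K):
            n = st["s"][k].size
            log_r -= n * (float(_log_ndtr(st["sigma"][k] / gam_p))
                          - float(_log_ndtr(st["sigma"][k] / gam)))
        accepted = math.log(self.rng.random()) < log_r
        if accepted:
            st["gamma"] = gam_p
            st["kappa"] = kap_p
            st["s"] = s_new
            self._cache_resp = ll_new
        if adapt:
            self._track("gk", accepted)

    def sweep(self, adapt: bool):
        self._update_phi()
        self._update_participants(adapt)
        self._update_mu()
        self._update_tau(adapt)
        self._update_sigma(adapt)
        self._update_gamma(adapt)
        self._update_kappa(adapt)
        self._update_tau_noncentered(adapt)
        self._update_sigma_noncentered(adapt)
        self._update_gamma_noncentered(adapt)
        self._update_gamma_kappa_joint(adapt)
        self._update_kappa(adapt)
        self._update_gamma(adapt)
        self._update_gamma_noncentered(adapt)
        self._update_gamma_kappa_joint(adapt)
        self._update_kappa(adapt)

    def run(self, warmup: int, draws: int, thin: int, record):
        for i in range(warmup):
            self.sweep(adapt=True)
            if (i + 1) % 50 == 0:
                self._adapt()
        for j in range(draws * thin):
            self.sweep(adapt=False)
            if (j + 1) % thin == 0:
                record(self.state)


def _hyper_names(conditions):
    names = [f"mu_c[{c}]" for c in conditions]
    names += [f"sigma_c[{c}]" for c in conditions]
    names += ["tau", "gamma", "kappa", "phi[zero]", "phi[one]", "phi[valid]"]
    return names


def fit_hbm(dataset: QuestionDataset, config: McmcConfig,
            standardize: bool = True,
            include_participants: bool = True) -> PosteriorSamples:
    """Fit the hierarchical consensus model to one question.

    Prompts are standardized by their pooled mean/SD (unless
    ``standardize=False``, in which case an identity scaling is recorded);
    ``config.chains`` independent chains are run from prior-drawn starting
    states.  Emits a :class:`ConvergenceWarning` naming the offending
    parameters when any split R-hat is >= 1.1 at this budget.  Set
    ``include_participants=False`` to keep only the hyperparameter draws.
    """
    if standardize:
        std_dataset, scaling = standardize_prompts(dataset)
    else:
        std_dataset, scaling = dataset, ScalingRecord(0.0, 1.0)
    model = HbmModel(std_dataset, config)
    chain_seeds = np.random.SeedSequence(config.seed).spawn(config.chains)

    names = _hyper_names(model.conditions) + ["rho"]
    part_names = []
    if include_participants:
        for k, cond in enumerate(model.conditions):
            for pid in model.cond_data[k].pids:
                part_names += [f"m[{pid},{cond}]", f"s[{pid},{cond}]"]
    draws = {n: np.empty((config.chains, config.draws))
             for n in names + part_names}

    for ci in range(config.chains):
        rng = np.random.Generator(np.random.PCG64(chain_seeds[ci]))
        sampler = _GibbsSampler(model, rng)
        slot = {"i": 0}

        def record(state, ci=ci, slot=slot):
            i = slot["i"]
            for k, cond in enumerate(model.conditions):
                draws[f"mu_c[{cond}]"][ci, i] = state["mu"][k]
                draws[f"sigma_c[{cond}]"][ci, i] = state["sigma"][k]
            draws["tau"][ci, i] = state["tau"]
            draws["gamma"][ci, i] = state["gamma"]
            draws["kappa"][ci, i] = state["kappa"]
            phi = state["phi"]
            draws["phi[zero]"][ci, i] = phi[0]
            draws["phi[one]"][ci, i] = phi[1]
            draws["phi[valid]"][ci, i] = phi[2]
            draws["rho"][ci, i] = (
                phi[1] / (phi[0] + phi[1]) if (phi[0] + phi[1]) > 0 else 0.5
            )
            if include_participants:
                for k, cond in enumerate(model.conditions):
                    for j, pid in enumerate(model.cond_data[k].pids):
                        draws[f"m[{pid},{cond}]"][ci, i] = state["m"][k][j]
                        draws[f"s[{pid},{cond}]"][ci, i] = state["s"][k][j]
            slot["i"] += 1

        sampler.run(config.warmup, config.draws, config.thin, record)

    samples = PosteriorSamples(
        draws=draws,
        n_chains=config.chains,
        n_draws=config.draws,
        scaling=scaling,
        conditions=model.conditions,
        participants=model.participants,
        question_id=dataset.question_id,
        attrs={"hyper_names": _hyper_names(model.conditions)},
    )
    diag = diagnostics(samples)
    samples.attrs["diagnostics"] = diag
    bad = diag.loc[diag["rhat"] >= 1.1, "parameter"].tolist()
    if bad:
        warnings.warn(
            f"question {dataset.question_id!r}: split R-hat >= 1.1 for "
            f"{bad}; increase warmup/draws",
            ConvergenceWarning, stacklevel=2,
        )
    return samples


def consensus_from_posterior(samples: PosteriorSamples):
    """Posterior-median consensus priors, inverse-transformed to outcome units.

    Returns a dict mapping condition to a :class:`ConsensusPrior` tagged
    ``hbm``: mu is the posterior median of mu_c mapped through the scaling
    record, sigma the posterior median of sigma_c times the scale.
    """
    if samples.scaling is None:
        raise ValidationError(["posterior lacks its scaling record"])
    out = {}
    for cond in samples.conditions:
        mu = float(np.median(samples.stacked(f"mu_c[{cond}]")))
        sigma = float(np.median(samples.stacked(f"sigma_c[{cond}]")))
        out[cond] = ConsensusPrior(
            question_id=samples.question_id,
            condition=cond,
            method="hbm",
            mu=float(samples.scaling.inverse(mu)),
            sigma=sigma * samples.scaling.scale,
        )
    return out


def diagnostics(samples: PosteriorSamples) -> pd.DataFrame:
    """Split R-hat and effective sample size for every scalar parameter.

    Returns a DataFrame (parameter, rhat, ess) with a ``converged`` attr:
    True when all R-hat < 1.1 and every hyperparameter ESS >= 200.
    """
    import arviz as az

    if samples.n_chains < 2:
        raise ValidationError(["R-hat requires at least two chains"])
    cached = samples.attrs.get("diagnostics")
    if cached is not None:
        return cached
    names = [n for n in samples.draws if n != "rho"]
    # one stacked variable: identical numbers, without per-variable overhead
    stacked = np.stack([samples.draws[n] for n in names], axis=-1)
    idata = az.from_dict({"theta": stacked})
    rhat = np.atleast_1d(az.rhat(idata, method="split")["theta"].values)
    ess = np.atleast_1d(az.ess(idata)["theta"].values)
    df = pd.DataFrame({"parameter": names, "rhat": rhat, "ess": ess})
    hyper = set(samples.attrs.get("hyper_names", _hyper_names(samples.conditions)))
    ok = bool(
        (df["rhat"] < 1.1).all()
        and (df.loc[df["parameter"].isin(hyper), "ess"] >= 200).all()
    )
    df.attrs["converged"] = ok
    return df


def pooling_coefficient(samples: PosteriorSamples,
                        mle_fits: pd.DataFrame) -> pd.DataFrame:
    """Per-participant pooling of m and s toward the consensus center.

    pooling = (unpooled MLE - posterior median) /
              (unpooled MLE - posterior median of the hyperparameter center),
    clipped to [0, 1]: 0 means the hierarchical estimate sits at the
    individual MLE (no pooling), 1 means it sits at the grand mean
    (infinite pooling).  ``mle_fits`` is the per-participant table from
    :func:`crowdprior.mle.fit_question_mle` (outcome units).
    """
    sc = samples.scaling
    rows = []
    fits = mle_fits.set_index(["participant_id", "condition"])
    for cond in samples.conditions:
        grand_m = float(sc.inverse(np.median(samples.stacked(f"mu_c[{cond}]"))))
        grand_s = float(np.median(samples.stacked(f"sigma_c[{cond}]")) * sc.scale)
        for pid in samples.participants:
            if f"m[{pid},{cond}]" not in samples.draws:
                continue
            if (pid, cond) not in fits.index:
                raise ValidationError(
                    [f"participant {pid!r}/{cond} missing from the MLE table"]
                )
            unpooled_m = float(fits.loc[(pid, cond), "mu"])
            unpooled_s = float(fits.loc[(pid, cond), "sigma"])
            post_m = float(sc.inverse(np.median(samples.stacked(f"m[{pid},{cond}]"))))
            post_s = float(np.median(samples.stacked(f"s[{pid},{cond}]")) * sc.scale)
            for par, unpooled, post, grand in (
                ("m", unpooled_m, post_m, grand_m),
                ("s", unpooled_s, post_s, grand_s),
            ):
                denom = unpooled - grand
                if denom == 0:
                    val = 1.0
                else:
                    val = float(np.clip((unpooled - post) / denom, 0.0, 1.0))
                rows.append({"participant_id": pid, "condition": cond,
                             "parameter": par, "pooling": val})
    return pd.DataFrame(rows)
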