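"""Per-participant Gaussian belief fitting and median aggregation.

Each participant's belief about an outcome is modeled as a Gaussian
N(mu, sigma^2); its parameters are recovered by least squares between the
participant's elicited cumulative probabilities and the Gaussian CDF
evaluated at the quantile prompts.  A consensus prior per condition is the
independent median of the participant-level mu and sigma estimates —
robust, so occasional extreme individual fits do not move it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtr

from .io import ConsensusPrior, QuestionDataset, ValidationError

#: sigma at `SIGMA_CEILING_FACTOR * (c3 - c1)` flags a non-identifiable fit
SIGMA_CEILING_FACTOR = 100.0


@dataclass(frozen=True)
class BeliefParams:
    """A fitted Gaussian belief for one participant-condition.

    ``sse`` is the attained squared-error loss; ``identifiable`` is False
    for flat probability triples (any mu with sigma -> inf fits equally
    well) or fits that ran into the sigma ceiling; ``converged`` reports
    optimizer status.
    """

    mu: float
    sigma: float
    sse: float
    converged: bool = True
    identifiable: bool = True


def _loss(mu: float, sigma: float, prompts, probs) -> float:
    pred = ndtr((np.asarray(prompts) - mu) / sigma)
    return float(np.sum((np.asarray(probs) - pred) ** 2))


def _start_points(prompts, probs):
    """Deterministic multi-start grid plus a quantile-inversion start.

    The grid spans the prompt range in mu and (0.1x, 10x) the prompt spread
    in sigma.  When at least two probabilities are distinct and interior,
    regressing prompts on their normal scores gives a near-exact start for
    consistent responses.
    """
    c1, c3 = min(prompts), max(prompts)
    spread = c3 - c1
    starts = [
        (mu0, s0)
        for mu0 in np.linspace(c1, c3, 5)
        for s0 in np.geomspace(0.1 * spread, 10.0 * spread, 5)
    ]
    interior = [(c, p) for c, p in zip(prompts, probs) if 0.0 < p < 1.0]
    if len(interior) >= 2:
        cs = np.array([c for c, _ in interior])
        zs = stats.norm.ppf([p for _, p in interior])
        if np.ptp(zs) > 0:
            slope, intercept = np.polyfit(zs, cs, 1)
            if slope > 0:
                # tried first: near-exact for consistent responses
                starts.insert(0, (float(intercept), float(slope)))
    return starts


def fit_participant_gaussian(prompts, probs) -> BeliefParams:
    """Fit N(mu, sigma^2) to (prompt, cumulative probability) pairs.

    Minimizes ``sum_i (p_i - Phi((c_i - mu)/sigma))^2`` by deterministic
    multi-start local optimization (lowest loss wins; ties broken toward
    the smaller sigma).  The usual input is one elicitation triple; pairs
    from several blocks of the same participant may be concatenated.  Flat
    probability responses are non-identifiable and returned with sigma
    capped at the ceiling rather than fitted.

    Raises
    ------
    ValidationError
        If fewer than three pairs are given or the prompts, sorted, are not
        strictly increasing.
    """
    order = np.argsort(np.asarray(prompts, dtype=float), kind="stable")
    prompts = tuple(float(prompts[i]) for i in order)
    probs = tuple(float(probs[i]) for i in order)
    if len(prompts) < 3 or len(prompts) != len(probs):
        raise ValidationError(["need at least three (prompt, prob) pairs"])
    if not all(a < b for a, b in zip(prompts, prompts[1:])):
        raise ValidationError(
            [f"prompts must be strictly increasing, got {prompts}"]
        )
    ceiling = SIGMA_CEILING_FACTOR * (max(prompts) - min(prompts))
    if min(probs) == max(probs):
        mu = float(np.median(prompts))
        return BeliefParams(
            mu=mu, sigma=ceiling, sse=_loss(mu, ceiling, prompts, probs),
            converged=True, identifiable=False,
        )

    best = None
    for mu0, s0 in _start_points(prompts, probs):
        res = optimize.minimize(
            lambda x: _loss(x[0], np.exp(x[1]), prompts, probs),
            x0=[mu0, np.log(s0)],
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000},
        )
        cand = (res.fun, np.exp(res.x[1]), res.x[0], bool(res.success))
        if best is None or cand[:2] < best[:2]:
            best = cand
        if best[0] < 1e-16:  # consistent responses inverted exactly
            break
    sse, sigma, mu, ok = best
    identifiable = sigma < ceiling
    sigma = min(sigma, ceiling)
    return BeliefParams(mu=float(mu), sigma=float(sigma), sse=float(sse),
                        converged=ok, identifiable=identifiable)


def aggregate_median(params, question_id: str, condition: str) -> ConsensusPrior:
    """Median-aggregate participant fits into one consensus prior.

    mu and sigma medians are taken independently (even counts use the mean
    of the two middle values).  Non-identifiable fits are excluded; zero
    usable fits is an error.
    """
    usable = [p for p in params if p.identifiable and p.converged]
    n_dropped = len(list(params)) - len(usable)
    if not usable:
        raise ValidationError(
            [f"no usable participant fits for {question_id}/{condition} "
             f"({n_dropped} non-identifiable or unconverged)"]
        )
    return ConsensusPrior(
        question_id=question_id,
        condition=condition,
        method="mle-median",
        mu=float(np.median([p.mu for p in usable])),
        sigma=float(np.median([p.sigma for p in usable])),
    )


def fit_question_mle(dataset: QuestionDataset):
    """Fit every participant in a question and aggregate per condition.

    Returns ``(priors, fits)``: a dict mapping condition to its
    ``mle-median`` :class:`ConsensusPrior`, and a DataFrame of
    per-participant fits (participant_id, condition, mu, sigma, sse,
    converged, identifiable).  Degenerate-interval records are skipped.
    """
    if len(dataset.conditions) < 2:
        raise ValidationError(
            [f"question {dataset.question_id!r} needs both conditions, "
             f"has {dataset.conditions}"]
        )
    rows = []
    priors = {}
    for condition in dataset.conditions:
        grouped: dict[str, list] = {}
        for rec in dataset.by_condition(condition):
            if rec.degenerate:
                continue
            grouped.setdefault(rec.participant_id, []).extend(
                zip(rec.prompts, rec.probs)
            )
        fits = []
        for pid, pairs in grouped.items():
            bp = fit_participant_gaussian(
                [c for c, _ in pairs], [p for _, p in pairs]
            )
            fits.append(bp)
            rows.append({
                "participant_id": pid,
                "condition": condition,
                "mu": bp.mu, "sigma": bp.sigma, "sse": bp.sse,
                "converged": bp.converged, "identifiable": bp.identifiable,
            })
        try:
            priors[condition] = aggregate_median(
                fits, dataset.question_id, condition
            )
        except ValidationError as err:
            raise ValidationError(
                [f"condition {condition!r}: {err.errors[0]}"]
            ) from err
    return priors, pd.DataFrame(rows)


def fit_r_squared(fits: pd.DataFrame, dataset: QuestionDataset) -> float:
    """R^2 of fitted vs elicited probabilities across a question's records.

    One minus the ratio of total fit SSE to the total variance of the
    elicited probabilities — a summary of how well Gaussian beliefs explain
    the responses.
    """
    lookup: dict[tuple, list] = {}
    for r in dataset.records:
        lookup.setdefault((r.participant_id, r.condition), []).extend(r.probs)
    all_probs, sse = [], 0.0
    for _, row in fits.iterrows():
        if not row["identifiable"]:
            continue
        all_probs.extend(lookup[(row["participant_id"], row["condition"])])
        sse += row["sse"]
    all_probs = np.asarray(all_probs)
    total = float(np.sum((all_probs - all_probs.mean()) ** 2))
    if total == 0:
        return 1.0
    return 1.0 - sse / total
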