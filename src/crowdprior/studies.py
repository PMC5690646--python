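"""Bundled example: eight published two-group psychology studies.

These are the printed summary statistics of the eight studies used as the
elicitation questions (font clarity and trait admission, desire and
perceived distance, luxury goods and depressive feelings, superstition and
golf putting, infant numerical mapping, competitor count and motivation,
verb aspect and memory, and enclosure of upsetting objects).  For each
question the table carries the condition-mean difference and pooled SD as
reported by the original study ("empirical") and as implied by the two
aggregation methods applied to the elicitation survey ("mle", "hbm"),
together with the study's total sample size and reported t value.

They serve as worked-example inputs for the design-analysis operations; no
code here recomputes them.
"""

from __future__ import annotations

from .design import EffectSummary, EmpiricalStudy

#: question_id -> {"n": total N, "t": reported t}
STUDY_SIZES = {
    "q1": {"n": 33, "t": 2.26},
    "q2": {"n": 90, "t": -2.00},
    "q3": {"n": 50, "t": 2.00},
    "q4": {"n": 28, "t": 2.14},
    "q5": {"n": 24, "t": 2.37},
    "q6": {"n": 74, "t": 2.02},
    "q7": {"n": 56, "t": 8.00},
    "q8": {"n": 80, "t": -2.24},
}

#: question_id -> source -> (mean difference, pooled SD) in outcome units
SUMMARIES = {
    "q1": {"empirical": (0.01, 0.28), "mle": (-3.61, 11.63), "hbm": (-0.70, 32.39)},
    "q2": {"empirical": (-2.90, 9.58), "mle": (0.47, 2.97), "hbm": (2.54, 17.90)},
    "q3": {"empirical": (0.36, 0.90), "mle": (2.11, 8.41), "hbm": (2.96, 22.78)},
    "q4": {"empirical": (1.85, 2.86), "mle": (1.17, 5.21), "hbm": (0.93, 11.32)},
    "q5": {"empirical": (3.80, 10.86), "mle": (1.86, 24.55), "hbm": (45.83, 627.11)},
    "q6": {"empirical": (4.20, 12.66), "mle": (6.89, 192.04), "hbm": (173.62, 2696.71)},
    "q7": {"empirical": (1.11, 8.31), "mle": (0.01, 4.76), "hbm": (0.60, 11.43)},
    "q8": {"empirical": (-0.46, 1.29), "mle": (-0.48, 2.24), "hbm": (-0.60, 5.57)},
}

QUESTIONS = tuple(STUDY_SIZES)
SOURCES = ("empirical", "mle", "hbm")


def summary(question_id: str, source: str = "empirical") -> EffectSummary:
    """The (mean difference, pooled SD) contrast for one question/source."""
    mean_diff, pooled_sd = SUMMARIES[question_id][source]
    return EffectSummary(mean_diff=mean_diff, pooled_sd=pooled_sd)


def study(question_id: str) -> EmpiricalStudy:
    """The empirical study record (printed difference, pooled SD, N, t)."""
    mean_diff, pooled_sd = SUMMARIES[question_id]["empirical"]
    return EmpiricalStudy(
        question_id=question_id,
        n_total=STUDY_SIZES[question_id]["n"],
        mean_diff=mean_diff,
        pooled_sd=pooled_sd,
        reported_t=STUDY_SIZES[question_id]["t"],
    )
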