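"""Data model, validation and file I/O for elicitation responses.

An elicitation session asks each participant, for every question and
condition, for a best / minimum / maximum guess of the outcome, then for
cumulative probability estimates at three quantile prompts placed inside
the stated [minimum, maximum] interval.  This module defines the record
types carrying those responses, the prompt-placement rule, per-record
validation, and CSV/JSON round-tripping.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import pandas as pd

logger = logging.getLogger(__name__)

CONDITIONS = ("control", "treatment")

#: canonical CSV column names; remappable via a schema dict
MANDATORY_COLUMNS = (
    "participant_id", "question_id", "condition",
    "best", "lo", "hi", "p1", "p2", "p3",
)
PROMPT_COLUMNS = ("c1", "c2", "c3")

#: relative tolerance for checking recorded prompts against the placement
#: rule; prompts may be stored with rounding.
PROMPT_RTOL = 1e-6


class ValidationError(ValueError):
    """Raised when a record violates the elicitation constraints.

    Attributes
    ----------
    errors : list of str
        Field-level messages, one per violated constraint.
    """

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


class DegenerateIntervalWarning(UserWarning):
    """A zero-width [lo, hi] interval: prompts collapse to a single point."""


def compute_quantile_prompts(lo: float, hi: float) -> tuple[float, float, float]:
    """Place the three quantile prompts inside the interval ``[lo, hi]``.

    The prompts sit one sixth of the interval width in from each end, with
    the middle prompt at the interval midpoint::

        c1 = lo + (hi - lo) / 6
        c2 = lo + (hi - lo) / 2
        c3 = hi - (hi - lo) / 6

    so ``c1 < c2 < c3`` whenever ``hi > lo``, and ``c1 + c3 == lo + hi``.
    A zero-width interval yields three equal prompts and a
    :class:`DegenerateIntervalWarning`.

    Raises
    ------
    ValidationError
        If either endpoint is non-finite or ``hi < lo``.
    """
    if not (math.isfinite(lo) and math.isfinite(hi)):
        raise ValidationError([f"interval endpoints must be finite, got ({lo}, {hi})"])
    if hi < lo:
        raise ValidationError([f"interval maximum {hi} is below minimum {lo}"])
    if hi == lo:
        warnings.warn(
            f"zero-width interval [{lo}, {hi}]: prompts are degenerate",
            DegenerateIntervalWarning,
            stacklevel=2,
        )
    width = hi - lo
    return (lo + width / 6.0, lo + width / 2.0, hi - width / 6.0)


@dataclass(frozen=True)
class ElicitationRecord:
    """One participant's responses for one question in one condition.

    ``prompts`` are the quantile prompts (outcome units) the participant was
    shown; ``probs`` are the cumulative probability estimates they gave at
    those prompts.  Invariants (``lo <= best <= hi``, weakly monotone probs,
    prompts consistent with the placement rule) are checked by
    :func:`validate_record`, not at construction.
    """

    participant_id: str
    question_id: str
    condition: str
    best: float
    lo: float
    hi: float
    prompts: tuple[float, float, float]
    probs: tuple[float, float, float]
    #: elicitation block index; ordinary single-pass elicitations use 0.
    #: Multi-block designs (several nested intervals per participant) carry
    #: one record per block, all describing the same underlying belief.
    block: int = 0

    @property
    def degenerate(self) -> bool:
        """True when the stated interval has zero width (hi == lo)."""
        return self.hi == self.lo

    @property
    def flat(self) -> bool:
        """True when all three probability responses are identical."""
        return self.probs[0] == self.probs[1] == self.probs[2]


def validate_record(record: ElicitationRecord) -> ElicitationRecord:
    """Check a record against the elicitation constraints.

    Returns the record unchanged when every invariant holds; otherwise
    raises :class:`ValidationError` carrying one message per violation.
    """
    errors = []
    for name in ("best", "lo", "hi"):
        if not math.isfinite(getattr(record, name)):
            errors.append(f"'{name}' is not finite")
    if record.condition not in CONDITIONS:
        errors.append(
            f"'condition' must be one of {CONDITIONS}, got {record.condition!r}"
        )
    if not errors:
        if record.lo > record.best:
            errors.append("'best' guess is below the minimum guess 'lo'")
        if record.best > record.hi:
            errors.append("'best' guess is above the maximum guess 'hi'")
    p1, p2, p3 = record.probs
    for i, p in enumerate(record.probs, start=1):
        if not (math.isfinite(p) and 0.0 <= p <= 1.0):
            errors.append(f"'p{i}' = {p} is outside [0, 1]")
    if math.isfinite(p1) and math.isfinite(p2) and math.isfinite(p3):
        if not (p1 <= p2 <= p3):
            errors.append(
                f"probability estimates must be weakly monotone, got {record.probs}"
            )
    if record.hi >= record.lo and all(math.isfinite(v) for v in (record.lo, record.hi)):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateIntervalWarning)
            expected = compute_quantile_prompts(record.lo, record.hi)
        scale = max(abs(record.hi), abs(record.lo), 1.0)
        for name, got, want in zip(PROMPT_COLUMNS, record.prompts, expected):
            if abs(got - want) > PROMPT_RTOL * scale:
                errors.append(
                    f"prompt '{name}' = {got} inconsistent with interval "
                    f"({record.lo}, {record.hi}); expected {want}"
                )
    if errors:
        raise ValidationError(errors)
    return record


@dataclass
class QuestionDataset:
    """All records for one question, covering both conditions.

    Each participant appears at most once per condition; models are fit to
    one question at a time.
    """

    question_id: str
    records: list[ElicitationRecord] = field(default_factory=list)
    outcome_scale: str = ""

    def __post_init__(self):
        seen = set()
        for rec in self.records:
            if rec.question_id != self.question_id:
                raise ValidationError(
                    [f"record for question {rec.question_id!r} in dataset "
                     f"{self.question_id!r}"]
                )
            key = (rec.participant_id, rec.condition, rec.block)
            if key in seen:
                raise ValidationError(
                    [f"duplicate record for participant {rec.participant_id!r} "
                     f"in condition {rec.condition!r} (block {rec.block})"]
                )
            seen.add(key)

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(c for c in CONDITIONS if any(r.condition == c for r in self.records))

    def by_condition(self, condition: str) -> list[ElicitationRecord]:
        return [r for r in self.records if r.condition == condition]

    def participants(self) -> list[str]:
        out = []
        for r in self.records:
            if r.participant_id not in out:
                out.append(r.participant_id)
        return out


@dataclass(frozen=True)
class ConsensusPrior:
    """A single Gaussian prior for one question-condition.

    ``method`` records how the participant beliefs were aggregated:
    ``"mle-median"`` (independent medians of per-participant least-squares
    fits) or ``"hbm"`` (posterior medians of the hierarchical consensus
    parameters).
    """

    question_id: str
    condition: str
    method: str
    mu: float
    sigma: float

    def __post_init__(self):
        if not (self.sigma > 0):
            raise ValidationError(
                [f"consensus sigma must be positive, got {self.sigma}"]
            )


def _coerce_schema(schema: dict | None) -> dict:
    mapping = {name: name for name in MANDATORY_COLUMNS + PROMPT_COLUMNS}
    if schema:
        mapping.update(schema)
    return mapping


def read_responses(path, schema: dict | None = None) -> list[QuestionDataset]:
    """Read a CSV of elicitation responses into per-question datasets.

    One row per participant x question x condition.  ``schema`` maps
    canonical column names (``participant_id``, ``question_id``,
    ``condition``, ``best``, ``lo``, ``hi``, ``c1``..``c3``, ``p1``..``p3``)
    to the file's actual headers.  The prompt columns are optional: when
    absent the prompts are recomputed from (lo, hi) with
    :func:`compute_quantile_prompts`.

    Rows failing validation are excluded and logged with their row number;
    duplicated participant-condition rows within a question are an error.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValidationError([f"no data rows in {path}"])
    mapping = _coerce_schema(schema)
    missing = [mapping[c] for c in MANDATORY_COLUMNS if mapping[c] not in df.columns]
    if missing:
        raise ValidationError([f"missing mandatory columns: {missing}"])
    have_prompts = all(mapping[c] in df.columns for c in PROMPT_COLUMNS)

    datasets: dict[str, list[ElicitationRecord]] = {}
    seen: set[tuple] = set()
    n_excluded = 0
    for idx, row in df.iterrows():
        qid = str(row[mapping["question_id"]])
        block = int(row["block"]) if "block" in df.columns else 0
        key = (qid, str(row[mapping["participant_id"]]),
               str(row[mapping["condition"]]), block)
        if key in seen:
            raise ValidationError(
                [f"row {idx}: duplicate participant-condition row {key}"]
            )
        seen.add(key)
        lo = float(row[mapping["lo"]])
        hi = float(row[mapping["hi"]])
        try:
            if have_prompts:
                prompts = tuple(float(row[mapping[c]]) for c in PROMPT_COLUMNS)
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", DegenerateIntervalWarning)
                    prompts = compute_quantile_prompts(lo, hi)
            record = ElicitationRecord(
                participant_id=str(row[mapping["participant_id"]]),
                question_id=qid,
                condition=str(row[mapping["condition"]]),
                best=float(row[mapping["best"]]),
                lo=lo,
                hi=hi,
                prompts=prompts,
                probs=tuple(float(row[mapping[f"p{i}"]]) for i in (1, 2, 3)),
                block=block,
            )
            validate_record(record)
        except ValidationError as err:
            n_excluded += 1
            logger.warning("row %d excluded: %s", idx, err)
            continue
        datasets.setdefault(qid, []).append(record)
    if n_excluded:
        logger.info("excluded %d invalid row(s) from %s", n_excluded, path)
    return [QuestionDataset(qid, records) for qid, records in datasets.items()]


def write_responses(datasets, path) -> None:
    """Write datasets back to the CSV schema :func:`read_responses` accepts."""
    rows = []
    for ds in datasets if isinstance(datasets, (list, tuple)) else [datasets]:
        for r in ds.records:
            rows.append({
                "participant_id": r.participant_id,
                "question_id": r.question_id,
                "condition": r.condition,
                "best": r.best, "lo": r.lo, "hi": r.hi,
                "c1": r.prompts[0], "c2": r.prompts[1], "c3": r.prompts[2],
                "p1": r.probs[0], "p2": r.probs[1], "p3": r.probs[2],
                "block": r.block,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_consensus(priors, path) -> None:
    """Write consensus priors as a JSON list, one object per
    question x condition x method.  Refuses empty collections and
    non-positive spreads."""
    priors = list(priors)
    if not priors:
        raise ValidationError(["refusing to write an empty consensus collection"])
    payload = []
    for p in priors:
        if not (p.sigma > 0):
            raise ValidationError(
                [f"consensus prior for {p.question_id}/{p.condition} has "
                 f"non-positive sigma {p.sigma}"]
            )
        payload.append({
            "question_id": p.question_id,
            "condition": p.condition,
            "method": p.method,
            "mu": p.mu,
            "sigma": p.sigma,
        })
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_consensus(path) -> list[ConsensusPrior]:
    """Read back a consensus-prior JSON file written by :func:`write_consensus`."""
    with open(path) as fh:
        payload = json.load(fh)
    return [ConsensusPrior(**obj) for obj in payload]


def standardized_copy(record: ElicitationRecord, center: float, scale: float) -> ElicitationRecord:
    """Affine-transform a record's outcome-unit fields to (x - center)/scale."""
    f = lambda x: (x - center) / scale
    return replace(
        record,
        best=f(record.best), lo=f(record.lo), hi=f(record.hi),
        prompts=tuple(f(c) for c in record.prompts),
    )
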