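"""Core domain objects for t-FAB normative scoring.

The telephone-based Frontal Assessment Battery (t-FAB) consists of four
tasks scored 0-3 each.  Two of them (*Conceptualization* and *Mental
flexibility*) form subtest 1, shared between the two administration
versions; *Sensitivity to interference* and *Inhibitory control* exist in a
motor-response (M) and a verbal-response (V) variant, forming subtest 2-M
and 2-V.  Totals range 0-12.

A raw score (RS) is converted to an adjusted score (AS) by adding a fitted
demographic correction, and the AS is then classified into an Equivalent
Score (ES) band: ES 0 = impaired (below the outer tolerance limit),
ES 1 = borderline, ES 2-4 = normal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

__all__ = [
    "OUTCOMES",
    "TASKS",
    "TRANSFORMS",
    "ES_LABELS",
    "ValidationError",
    "DomainError",
    "ModelError",
    "ScoreRecord",
    "Term",
    "AdjustmentEquation",
    "ToleranceLimits",
    "EquivalentScoreTable",
    "OutcomeNorm",
    "NormativeModel",
    "round2",
    "compute_scores",
    "adjust_score",
    "lookup_es",
    "score_participant",
]

#: derived score names, in reporting order
OUTCOMES = ("tFAB_M", "tFAB_V", "tFAB_1", "tFAB_2M", "tFAB_2V")

#: the six task columns of a cohort file
TASKS = (
    "conceptualization",
    "mental_flexibility",
    "interference_M",
    "inhibition_M",
    "interference_V",
    "inhibition_V",
)

#: which tasks feed each derived score
_SCORE_TASKS = {
    "tFAB_1": ("conceptualization", "mental_flexibility"),
    "tFAB_2M": ("interference_M", "inhibition_M"),
    "tFAB_2V": ("interference_V", "inhibition_V"),
}

TRANSFORMS = {
    "identity": lambda x: x,
    "square": lambda x: x**2,
    "cube": lambda x: x**3,
    "log10": math.log10,
    "ln": math.log,
    "reciprocal": lambda x: 1.0 / x,
}

ES_LABELS = {0: "impaired", 1: "borderline", 2: "normal", 3: "normal", 4: "normal"}


class ValidationError(ValueError):
    """A record or cohort violates the score-model contract."""


class DomainError(ValueError):
    """A demographic value is outside the domain of a transform."""


class ModelError(ValueError):
    """A normative model object is malformed."""


def round2(x: float) -> float:
    """Round to 2 decimals, halves away from zero (grid/table convention)."""
    return float(Decimal(x).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# records and derived scores
# ---------------------------------------------------------------------------


@dataclass
class ScoreRecord:
    """One participant: demographics, task scores, optional group/companions."""

    id: str
    age: float
    education: float
    sex: str  # "M" or "F"
    conceptualization: int | None = None
    mental_flexibility: int | None = None
    interference_M: int | None = None
    inhibition_M: int | None = None
    interference_V: int | None = None
    inhibition_V: int | None = None
    group: str | None = None
    companion_scores: dict[str, float] = field(default_factory=dict)

    def task(self, name: str) -> int | None:
        return getattr(self, name)

    def validate(self) -> None:
        if not (math.isfinite(self.age) and math.isfinite(self.education)):
            raise ValidationError(f"record {self.id!r}: age/education must be finite")
        if self.education <= 0:
            raise ValidationError(
                f"record {self.id!r}: education must be > 0 (got {self.education})"
            )
        if self.sex not in ("M", "F"):
            raise ValidationError(f"record {self.id!r}: sex must be 'M' or 'F'")
        for t in TASKS:
            v = self.task(t)
            if v is not None and v not in (0, 1, 2, 3):
                raise ValidationError(
                    f"record {self.id!r}: task {t} = {v!r} not in {{0,1,2,3}}"
                )


def compute_scores(
    record: ScoreRecord, *, allow_missing: bool = False
) -> dict[str, int]:
    """Derive subtest and total scores from the six task scores.

    tFAB_1 = conceptualization + mental_flexibility, tFAB_2M/2V likewise for
    the interference/inhibition pairs, and the totals are tFAB_1 + tFAB_2M/2V.
    With ``allow_missing`` the families whose tasks are absent are simply
    omitted; otherwise a missing or out-of-range task raises
    :class:`ValidationError` naming the field.
    """
    record.validate()
    out: dict[str, int] = {}
    for sub, tasks in _SCORE_TASKS.items():
        vals = [record.task(t) for t in tasks]
        missing = [t for t, v in zip(tasks, vals) if v is None]
        if missing:
            if allow_missing:
                continue
            raise ValidationError(
                f"record {record.id!r}: missing task score(s) {', '.join(missing)}"
            )
        out[sub] = int(sum(vals))
    if "tFAB_1" in out and "tFAB_2M" in out:
        out["tFAB_M"] = out["tFAB_1"] + out["tFAB_2M"]
    if "tFAB_1" in out and "tFAB_2V" in out:
        out["tFAB_V"] = out["tFAB_1"] + out["tFAB_2V"]
    return out


# ---------------------------------------------------------------------------
# demographic adjustment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Term:
    """One ``coefficient * (transform(variable) - center)`` adjustment term."""

    transform: str
    variable: str  # "age", "education" or "sex"
    coefficient: float
    center: float

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ModelError(f"unknown transform {self.transform!r}")
        if self.variable not in ("age", "education", "sex"):
            raise ModelError(f"unknown adjustment variable {self.variable!r}")
        if not (math.isfinite(self.coefficient) and math.isfinite(self.center)):
            raise ModelError("term coefficient/center must be finite")


@dataclass(frozen=True)
class AdjustmentEquation:
    """AS = RS + sum of coefficient * (transform(variable) - center) terms."""

    outcome: str
    terms: tuple[Term, ...] = ()

    def adjustment(self, age: float, education: float, sex: str | None = None) -> float:
        if education <= 0:
            raise DomainError(f"education must be > 0 (got {education})")
        total = 0.0
        for t in self.terms:
            if t.variable == "age":
                x = float(age)
            elif t.variable == "education":
                x = float(education)
            else:  # sex indicator, M = 1, F = 0
                if sex is None:
                    raise DomainError("equation has a sex term but sex is missing")
                x = 1.0 if sex == "M" else 0.0
            total += t.coefficient * (TRANSFORMS[t.transform](x) - t.center)
        return total


def adjust_score(
    eq: AdjustmentEquation,
    rs: float,
    age: float,
    education: float,
    sex: str | None = None,
) -> float:
    """Adjusted score AS = RS + demographic adjustment, unrounded.

    The adjusted scale is an open regression scale: no clamping to [0, 12].
    Report with :func:`round2`; classification also rounds first.
    """
    if not math.isfinite(rs):
        raise ValidationError("raw score must be finite")
    return float(rs) + eq.adjustment(age, education, sex)


# ---------------------------------------------------------------------------
# tolerance limits and Equivalent Scores
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToleranceLimits:
    """Non-parametric outer/inner tolerance limits for the worst-5% region.

    The outer limit (oTL) is the order statistic below which the population
    5th centile lies with >= `confidence`; scores at or below it are
    confidently impaired.  The inner limit (iTL) bounds the region from
    above.  Ranks are 1-based positions in the ascending sorted sample.
    """

    oTL: float | None
    iTL: float | None
    rank_outer: int | None
    rank_inner: int | None
    n: int
    coverage: float = 0.05
    confidence: float = 0.95

    def __post_init__(self) -> None:
        if self.rank_outer is not None and self.rank_inner is not None:
            if not (1 <= self.rank_outer < self.rank_inner <= self.n):
                raise ModelError(
                    f"tolerance ranks ({self.rank_outer}, {self.rank_inner}) "
                    f"invalid for n={self.n}"
                )
            if self.oTL is not None and self.iTL is not None and self.oTL > self.iTL:
                raise ModelError("outer TL above inner TL")


@dataclass(frozen=True)
class EquivalentScoreTable:
    """Adjusted-score cut points mapping to ES 0-4.

    ``boundaries = (b01, b12, b23, b34)`` at 2-decimal resolution:
    ES0: AS <= b01; ES1: b01 < AS < b12; ES2: b12 <= AS < b23;
    ES3: b23 <= AS < b34; ES4: AS >= b34.  AS is rounded to 2 decimals
    before comparison, so the bands are the closed printed intervals.
    """

    boundaries: tuple[float, float, float, float]
    labels: Mapping[int, str] = field(default_factory=lambda: dict(ES_LABELS))

    def __post_init__(self) -> None:
        b = tuple(self.boundaries)
        if len(b) != 4 or any(not math.isfinite(x) for x in b):
            raise ModelError("ES table needs four finite boundaries")
        if not all(b[i] < b[i + 1] for i in range(3)):
            raise ModelError(f"ES boundaries not strictly increasing: {b}")

    def lookup(self, adjusted: float) -> tuple[int, str]:
        if not math.isfinite(adjusted):
            raise ValidationError("adjusted score must be finite")
        a = round2(adjusted)
        b01, b12, b23, b34 = self.boundaries
        if a <= b01:
            es = 0
        else:
            es = 1 + sum(a >= cut for cut in (b12, b23, b34))
        return es, self.labels[es]


def lookup_es(table: EquivalentScoreTable, adjusted: float) -> tuple[int, str]:
    """Classify an adjusted score into (ES, clinical label)."""
    return table.lookup(adjusted)


# ---------------------------------------------------------------------------
# the per-outcome bundle and whole-model container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OutcomeNorm:
    """Adjustment equation + tolerance limits + ES table for one score."""

    equation: AdjustmentEquation
    tolerance: ToleranceLimits | None = None
    es_table: EquivalentScoreTable | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        # b01 must equal the (rounded) outer tolerance limit
        if (
            self.es_table is not None
            and self.tolerance is not None
            and self.tolerance.oTL is not None
        ):
            if abs(self.es_table.boundaries[0] - round2(self.tolerance.oTL)) > 1e-9:
                raise ModelError(
                    f"{self.equation.outcome}: ES0 boundary "
                    f"{self.es_table.boundaries[0]} != outer TL "
                    f"{round2(self.tolerance.oTL)}"
                )


@dataclass(frozen=True)
class NormativeModel:
    """Per-outcome norms plus the demographic range they were derived on."""

    outcomes: Mapping[str, OutcomeNorm]
    n: int
    age_range: tuple[float, float]
    education_range: tuple[float, float]
    version: str = "user"
    metadata: Mapping[str, object] = field(default_factory=dict)

    def covers(self, age: float, education: float) -> bool:
        return (
            self.age_range[0] <= age <= self.age_range[1]
            and self.education_range[0] <= education <= self.education_range[1]
        )


def score_participant(
    model: NormativeModel, record: ScoreRecord
) -> dict[str, dict[str, object]]:
    """Raw -> adjusted -> ES for every model outcome the record supports.

    Records outside the model's demographic coverage are still scored but
    each entry carries ``extrapolated=True`` so clinical use degrades loudly.
    Score families whose task scores are missing are omitted.
    """
    raw = compute_scores(record, allow_missing=True)
    extrapolated = not model.covers(record.age, record.education)
    out: dict[str, dict[str, object]] = {}
    for name, norm in model.outcomes.items():
        if name not in raw:
            continue
        as_unrounded = adjust_score(
            norm.equation, raw[name], record.age, record.education, record.sex
        )
        entry: dict[str, object] = {
            "raw": raw[name],
            "adjusted": round2(as_unrounded),
            "adjusted_unrounded": as_unrounded,
            "extrapolated": extrapolated,
        }
        if norm.es_table is not None:
            es, label = norm.es_table.lookup(as_unrounded)
            entry["es"] = es
            entry["label"] = label
        else:
            entry["es"] = None
            entry["label"] = None
            if "no_outer_TL" in norm.flags:
                entry["flags"] = norm.flags
        out[name] = entry
    if not out:
        warnings.warn(
            f"record {record.id!r}: no scorable outcome (all task scores missing)",
            stacklevel=2,
        )
    return out
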