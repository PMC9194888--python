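"""Derivation of normative models from a cohort.

The pipeline follows the Equivalent Score method: raw scores are adjusted
for significant demographic confounders selected by a stepwise (forward)
regression over candidate transforms, non-parametric tolerance limits are
placed on the ranked adjusted scores, and ES band thresholds are read off
the order statistics.

Exposed both functionally (``fit_adjustment``, ``tolerance_limit_ranks``,
``derive_es_thresholds``, ``build_normative_model``) and as a model/results
pair (:class:`NormativeStandardization` / :class:`NormingResults`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import (
    OUTCOMES,
    TRANSFORMS,
    AdjustmentEquation,
    EquivalentScoreTable,
    ModelError,
    NormativeModel,
    OutcomeNorm,
    Term,
    ToleranceLimits,
    ValidationError,
    round2,
)

__all__ = [
    "StepwiseSpec",
    "ESScheme",
    "FitReport",
    "CollapsedBandsError",
    "fit_adjustment",
    "tolerance_limit_ranks",
    "derive_es_thresholds",
    "build_normative_model",
    "NormativeStandardization",
    "NormingResults",
]


class CollapsedBandsError(ModelError):
    """Too few distinct adjusted scores to separate the ES bands."""


#: candidate transforms screened per demographic variable
DEFAULT_CANDIDATES: dict[str, tuple[str, ...]] = {
    "age": ("identity", "square", "cube"),
    "education": ("identity", "log10", "ln", "reciprocal"),
    "sex": ("identity",),
}


@dataclass(frozen=True)
class StepwiseSpec:
    """Forward-selection settings for the demographic adjustment."""

    candidates: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CANDIDATES)
    )
    entry_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.entry_alpha < 1:
            raise ValueError("entry_alpha must be in (0, 1)")


@dataclass(frozen=True)
class ESScheme:
    """Placement rule for the intermediate ES thresholds.

    b01 is the outer tolerance limit and the ES4 band starts at the sample
    median.  The two intermediate cut points default to the order statistics
    at centiles obtained by splitting the standard-normal interval
    [z = -1.645, z = 0] into four equal z-segments (Phi at the first two
    interior split points: 0.1086 and 0.2054).
    """

    centiles: tuple[float, float] = (0.1086, 0.2054)

    def __post_init__(self) -> None:
        c = self.centiles
        if len(c) != 2 or not (0 < c[0] < c[1] < 0.5):
            raise ValueError("centiles must satisfy 0 < c1 < c2 < 0.5")


@dataclass(frozen=True)
class FitReport:
    """Diagnostics of one stepwise adjustment fit."""

    outcome: str
    n: int
    r_squared: float
    slopes: dict[str, float]  # "(transform)variable" -> regression slope
    pvalues: dict[str, float]
    considered: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# stepwise demographic adjustment
# ---------------------------------------------------------------------------


def _design_column(df: pd.DataFrame, variable: str, transform: str) -> np.ndarray:
    if variable == "sex":
        return (df["sex"].to_numpy() == "M").astype(float)
    x = df[variable].to_numpy(dtype=float)
    if transform in ("log10", "ln", "reciprocal") and np.any(x <= 0):
        raise ValidationError(f"{variable} must be > 0 for transform {transform}")
    return np.array([TRANSFORMS[transform](v) for v in x])


def fit_adjustment(
    records: pd.DataFrame,
    outcome: str,
    spec: StepwiseSpec | None = None,
) -> tuple[AdjustmentEquation, FitReport]:
    """Forward-stepwise selection of the demographic adjustment equation.

    At each step every not-yet-entered variable is screened over its
    candidate transforms; the (variable, transform) pair with the largest
    R-squared gain enters if its slope is significant at ``entry_alpha``.
    The returned equation negates the regression slopes and centers each
    transformed variable at its cohort mean, so AS = RS - b*(f(x) - mean).
    """
    spec = spec or StepwiseSpec()
    df = records.dropna(subset=[outcome, "age", "education", "sex"])
    n = len(df)
    if n < 30:
        raise ValidationError(f"need >= 30 complete records, got {n}")
    y = df[outcome].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValidationError(f"outcome {outcome!r} has zero variance")

    candidates: dict[str, tuple[str, ...]] = {}
    considered = []
    for var, transforms in spec.candidates.items():
        col = _design_column(df, var, transforms[0])
        if np.ptp(col) == 0:
            warnings.warn(f"predictor {var!r} has zero variance; excluded")
            continue
        candidates[var] = transforms
        considered.append(var)

    selected: list[tuple[str, str]] = []  # (variable, transform)
    while True:
        base = [_design_column(df, v, t) for v, t in selected]
        best = None
        for var, transforms in candidates.items():
            if any(v == var for v, _ in selected):
                continue
            for tr in transforms:
                col = _design_column(df, var, tr)
                X = sm.add_constant(np.column_stack(base + [col]))
                if np.linalg.matrix_rank(X) < X.shape[1]:
                    continue
                res = sm.OLS(y, X).fit()
                if best is None or res.rsquared > best[0]:
                    best = (res.rsquared, var, tr, res.pvalues[-1])
        if best is None:
            break
        _, var, tr, pval = best
        if pval < spec.entry_alpha:
            selected.append((var, tr))
        else:
            break

    if selected:
        cols = [_design_column(df, v, t) for v, t in selected]
        X = sm.add_constant(np.column_stack(cols))
        res = sm.OLS(y, X).fit()
        slopes = {f"{t}({v})": float(res.params[i + 1]) for i, (v, t) in enumerate(selected)}
        pvals = {f"{t}({v})": float(res.pvalues[i + 1]) for i, (v, t) in enumerate(selected)}
        terms = tuple(
            Term(
                transform=t,
                variable=v,
                coefficient=-float(res.params[i + 1]),
                center=float(np.mean(_design_column(df, v, t))),
            )
            for i, (v, t) in enumerate(selected)
        )
        r2 = float(res.rsquared)
    else:
        slopes, pvals, terms, r2 = {}, {}, (), 0.0

    eq = AdjustmentEquation(outcome=outcome, terms=terms)
    report = FitReport(
        outcome=outcome,
        n=n,
        r_squared=r2,
        slopes=slopes,
        pvalues=pvals,
        considered=tuple(considered),
    )
    return eq, report


# ---------------------------------------------------------------------------
# non-parametric tolerance limits
# ---------------------------------------------------------------------------


def tolerance_limit_ranks(
    n: int, coverage: float = 0.05, confidence: float = 0.95
) -> tuple[int | None, int | None]:
    """Order-statistic ranks of the outer and inner tolerance limits.

    ``rank_outer`` is the largest r with P[Binomial(n, coverage) >= r] >=
    confidence: the r-th smallest adjusted score lies below the population
    `coverage` centile with at least `confidence` probability.
    ``rank_inner`` is the smallest s with P[Binomial(n, coverage) <= s-1] >=
    confidence.  Exact binomial CDF, no normal approximation.  For n too
    small (n <= 58 at the defaults) no outer rank exists and None is
    returned in its place.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 < coverage < 1 and 0 < confidence < 1):
        raise ValueError("coverage and confidence must be in (0, 1)")
    r = np.arange(1, n + 1)
    sf = stats.binom.sf(r - 1, n, coverage)  # P[X >= r]
    ok_outer = np.nonzero(sf >= confidence)[0]
    rank_outer = int(r[ok_outer[-1]]) if ok_outer.size else None
    cdf = stats.binom.cdf(r - 1, n, coverage)  # P[X <= s-1]
    ok_inner = np.nonzero(cdf >= confidence)[0]
    rank_inner = int(r[ok_inner[0]]) if ok_inner.size else None
    return rank_outer, rank_inner


def compute_tolerance_limits(
    adjusted: np.ndarray,
    coverage: float = 0.05,
    confidence: float = 0.95,
) -> ToleranceLimits:
    """Tolerance limits of an adjusted-score sample (ascending sort)."""
    a = np.sort(np.asarray(adjusted, dtype=float))
    n = a.size
    ro, ri = tolerance_limit_ranks(n, coverage, confidence)
    return ToleranceLimits(
        oTL=float(a[ro - 1]) if ro is not None else None,
        iTL=float(a[ri - 1]) if ri is not None else None,
        rank_outer=ro,
        rank_inner=ri,
        n=n,
        coverage=coverage,
        confidence=confidence,
    )


# ---------------------------------------------------------------------------
# Equivalent Score thresholds
# ---------------------------------------------------------------------------


def derive_es_thresholds(
    adjusted: np.ndarray,
    tl: ToleranceLimits,
    scheme: ESScheme | None = None,
) -> EquivalentScoreTable:
    """ES band cut points from the ranked adjusted scores.

    b01 = outer tolerance limit; ES4 starts at the sample median; the two
    intermediate cut points sit at the order statistics whose ranks are
    nearest to n*p for the scheme centiles, so ES1/ES2/ES3 partition the
    interval (oTL, median).  All boundaries are reported at 2-decimal
    resolution; band membership uses closed printed intervals.
    """
    scheme = scheme or ESScheme()
    a = np.sort(np.asarray(adjusted, dtype=float))
    n = a.size
    if tl.rank_outer is None or tl.oTL is None:
        raise ModelError("no outer tolerance limit: ES0 undefined for this sample")
    if np.unique(np.round(a, 2)).size < 5:
        raise CollapsedBandsError(
            "fewer than 5 distinct adjusted-score values; ES bands collapse"
        )
    b01 = round2(tl.oTL)
    cuts = []
    for p in scheme.centiles:
        r = int(np.clip(round(n * p), 1, n))
        # scores <= this order statistic stay in the lower band
        cuts.append(round2(float(a[r - 1])) + 0.01)
    b12, b23 = (round2(c) for c in cuts)
    b34 = round2(float(np.median(a)))
    boundaries = (b01, b12, b23, b34)
    if not all(boundaries[i] < boundaries[i + 1] for i in range(3)):
        raise CollapsedBandsError(
            f"derived ES boundaries not strictly increasing: {boundaries}"
        )
    return EquivalentScoreTable(boundaries)


# ---------------------------------------------------------------------------
# model class / results
# ---------------------------------------------------------------------------


class NormativeStandardization:
    """Derive a :class:`~tfab.core.NormativeModel` from a normative cohort.

    Parameters
    ----------
    data
        Cohort DataFrame with ``id, age, education, sex`` and either the six
        task columns (derived scores are computed) or the outcome columns
        themselves.
    outcomes
        Score names to standardize; defaults to every derivable outcome.
    stepwise, scheme
        Selection and threshold-placement settings.

    Examples
    --------
    >>> from tfab.synthetic import NormativeCohortSpec, generate_normative
    >>> cohort = generate_normative(NormativeCohortSpec(seed=7))
    >>> res = NormativeStandardization(cohort).fit()
    >>> model = res.model
    """

    def __init__(
        self,
        data: pd.DataFrame,
        outcomes: tuple[str, ...] | None = None,
        stepwise: StepwiseSpec | None = None,
        scheme: ESScheme | None = None,
        coverage: float = 0.05,
        confidence: float = 0.95,
    ) -> None:
        df = data.copy()
        from .io import attach_derived_scores  # late import; io depends on core only

        df = attach_derived_scores(df)
        available = [o for o in OUTCOMES if o in df.columns]
        self.outcomes = tuple(outcomes) if outcomes else tuple(available)
        missing = [o for o in self.outcomes if o not in df.columns]
        if missing:
            raise ValidationError(f"outcomes not derivable from data: {missing}")
        # stable sort by id: reproducible tie-breaking of ranked scores
        self.data = df.sort_values("id", kind="stable").reset_index(drop=True)
        self.stepwise = stepwise or StepwiseSpec()
        self.scheme = scheme or ESScheme()
        self.coverage = coverage
        self.confidence = confidence

    @classmethod
    def from_csv(cls, path, **kwargs) -> "NormativeStandardization":
        from .io import read_cohort

        df, _ = read_cohort(path)
        return cls(df, **kwargs)

    def fit(self) -> "NormingResults":
        outcomes: dict[str, OutcomeNorm] = {}
        reports: dict[str, FitReport] = {}
        flags: list[str] = []
        for name in self.outcomes:
            eq, report = fit_adjustment(self.data, name, self.stepwise)
            reports[name] = report
            sub = self.data.dropna(subset=[name, "age", "education", "sex"])
            adjusted = np.array(
                [
                    eq.adjustment(r.age, r.education, r.sex) + getattr(r, name)
                    for r in sub.itertuples()
                ]
            )
            tl = compute_tolerance_limits(adjusted, self.coverage, self.confidence)
            if tl.rank_outer is None:
                flags.append(f"{name}: no outer TL at n={tl.n}")
                outcomes[name] = OutcomeNorm(
                    equation=eq, tolerance=tl, es_table=None, flags=("no_outer_TL",)
                )
                continue
            table = derive_es_thresholds(adjusted, tl, self.scheme)
            outcomes[name] = OutcomeNorm(equation=eq, tolerance=tl, es_table=table)
        model = NormativeModel(
            outcomes=outcomes,
            n=len(self.data),
            age_range=(float(self.data["age"].min()), float(self.data["age"].max())),
            education_range=(
                float(self.data["education"].min()),
                float(self.data["education"].max()),
            ),
            version="user",
            metadata={
                "entry_alpha": self.stepwise.entry_alpha,
                "scheme_centiles": list(self.scheme.centiles),
                "coverage": self.coverage,
                "confidence": self.confidence,
                "flags": flags,
            },
        )
        return NormingResults(model, reports, self)


class NormingResults:
    """Fitted normative standardization: the model plus fit diagnostics."""

    def __init__(
        self,
        model: NormativeModel,
        reports: dict[str, FitReport],
        parent: NormativeStandardization,
    ) -> None:
        self.model = model
        self.reports = reports
        self._parent = parent

    def score(self, record) -> dict:
        from .core import score_participant

        return score_participant(self.model, record)

    def to_json(self, path) -> None:
        from .io import write_model

        write_model(self.model, path)

    def summary(self) -> str:
        """Plain-text derivation report: equations, p-values, ranks, bands."""
        lines = [
            "Normative standardization",
            "=" * 60,
            f"n = {self.model.n}   age {self.model.age_range}   "
            f"education {self.model.education_range}",
            "",
        ]
        for name, norm in self.model.outcomes.items():
            rep = self.reports[name]
            lines.append(f"{name}  (R^2 = {rep.r_squared:.4f}, n = {rep.n})")
            if norm.equation.terms:
                for t in norm.equation.terms:
                    key = f"{t.transform}({t.variable})"
                    lines.append(
                        f"  + {t.coefficient:+.6f} * [{t.transform}({t.variable})"
                        f" - {t.center:.6f}]   (p = {rep.pvalues[key]:.2e})"
                    )
            else:
                lines.append("  no significant demographic predictor; AS = RS")
            tl = norm.tolerance
            if tl is not None and tl.rank_outer is not None:
                lines.append(
                    f"  oTL = {round2(tl.oTL)} (rank {tl.rank_outer})   "
                    f"iTL = {round2(tl.iTL)} (rank {tl.rank_inner})"
                )
            else:
                lines.append("  no outer tolerance limit (n too small)")
            if norm.es_table is not None:
                b = norm.es_table.boundaries
                lines.append(
                    f"  ES bands: 0: <= {b[0]} | 1: {b[0]}..{b[1]} | "
                    f"2: {b[1]}..{b[2]} | 3: {b[2]}..{b[3]} | 4: >= {b[3]}"
                )
            lines.append("")
        return "\n".join(lines)


def build_normative_model(
    records: pd.DataFrame,
    outcomes: tuple[str, ...] | None = None,
    spec: StepwiseSpec | None = None,
    scheme: ESScheme | None = None,
) -> NormativeModel:
    """One-call derivation: stepwise adjustment -> tolerance limits -> ES."""
    return NormativeStandardization(
        records, outcomes=outcomes, stepwise=spec, scheme=scheme
    ).fit().model
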