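"""The published t-FAB normative model.

Adjustment equations, tolerance limits and Equivalent-Score bands from the
Italian standardization of the telephone-based Frontal Assessment Battery
(normative sample N = 346, ages 18-96, education 4-23 years).  Coefficients
and centering constants are kept at full printed precision (6 decimals).

The age effect (on the motor-response scores only) enters through age cubed;
the education effect through log10, ln or the reciprocal depending on the
outcome.  Centers are the normative-sample means of the *transformed*
variables, so a participant at the centers is adjusted by exactly 0.
"""

from __future__ import annotations

from .core import (
    AdjustmentEquation,
    EquivalentScoreTable,
    NormativeModel,
    OutcomeNorm,
    Term,
    ToleranceLimits,
)

__all__ = ["PUBLISHED_MODEL", "PUBLISHED_VERSION"]

PUBLISHED_VERSION = "it-2022-n346"

_AGE3_CENTER = 167162.855491
_LOG10_EDU_CENTER = 1.106787
_RECIP_EDU_CENTER = 0.083175
_LN_EDU_CENTER = 2.548471

_EQUATIONS = {
    "tFAB_M": AdjustmentEquation(
        "tFAB_M",
        (
            Term("cube", "age", 0.000002, _AGE3_CENTER),
            Term("log10", "education", -3.484874, _LOG10_EDU_CENTER),
        ),
    ),
    "tFAB_V": AdjustmentEquation(
        "tFAB_V", (Term("reciprocal", "education", 15.62586, _RECIP_EDU_CENTER),)
    ),
    "tFAB_1": AdjustmentEquation(
        "tFAB_1", (Term("ln", "education", -1.020062, _LN_EDU_CENTER),)
    ),
    "tFAB_2M": AdjustmentEquation(
        "tFAB_2M",
        (
            Term("cube", "age", 0.000001, _AGE3_CENTER),
            Term("log10", "education", -1.462853, _LOG10_EDU_CENTER),
        ),
    ),
    "tFAB_2V": AdjustmentEquation(
        "tFAB_2V", (Term("reciprocal", "education", 5.921931, _RECIP_EDU_CENTER),)
    ),
}

# outer TL, inner TL, and the four band cut points (b01, b12, b23, b34):
# ES0 <= b01 < ES1 < b12 <= ES2 < b23 <= ES3 < b34 <= ES4, at 2-dp resolution.
_NORMS = {
    "tFAB_M": (8.07, 8.77, (8.07, 9.46, 10.51, 11.04)),
    "tFAB_V": (8.48, 9.00, (8.48, 9.84, 10.69, 10.94)),
    "tFAB_1": (3.54, 4.07, (3.54, 4.50, 4.85, 5.46)),
    "tFAB_2M": (3.16, 4.00, (3.16, 4.91, 5.67, 5.85)),
    "tFAB_2V": (3.00, 5.00, (3.00, 5.78, 5.87, 6.00)),
}

_N = 346
# outer/inner order-statistic ranks for n=346, coverage 5%, confidence 95%
_RANK_OUTER, _RANK_INNER = 11, 25


def _build() -> NormativeModel:
    outcomes = {}
    for name, eq in _EQUATIONS.items():
        otl, itl, bounds = _NORMS[name]
        outcomes[name] = OutcomeNorm(
            equation=eq,
            tolerance=ToleranceLimits(
                oTL=otl, iTL=itl, rank_outer=_RANK_OUTER, rank_inner=_RANK_INNER, n=_N
            ),
            es_table=EquivalentScoreTable(bounds),
        )
    return NormativeModel(
        outcomes=outcomes,
        n=_N,
        age_range=(18.0, 96.0),
        education_range=(4.0, 23.0),
        version=PUBLISHED_VERSION,
    )


PUBLISHED_MODEL: NormativeModel = _build()
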