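"""ROC discrimination of clinical vs normative cohorts.

The AUC is the tie-corrected Mann-Whitney probability that a random case
scores more "case-like" than a random control.  Impairment lowers t-FAB
scores, so the default orientation treats lower scores as case-like.
Standard errors come from the DeLong structural-components estimator
(Hanley-McNeil available for comparability with older calculators), and
study planning uses Obuchowski's binormal-variance sample-size formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ROCResult",
    "ROCSampleSizeSpec",
    "roc_auc",
    "roc_sample_size",
    "group_roc_table",
]


@dataclass(frozen=True)
class ROCResult:
    auc: float
    se: float
    ci95: tuple[float, float]
    n_cases: int
    n_controls: int
    direction: str
    se_method: str
    flags: tuple[str, ...] = ()


def _midrank_placements(cases: np.ndarray, controls: np.ndarray):
    """DeLong structural components: per-case and per-control placements."""
    n1, n0 = cases.size, controls.size
    combined = np.concatenate([cases, controls])
    r_all = stats.rankdata(combined)
    r_cases = stats.rankdata(cases)
    r_controls = stats.rankdata(controls)
    # V10_i = P_hat[case i beats a random control] (ties count 1/2)
    v10 = (r_all[:n1] - r_cases) / n0
    v01 = 1.0 - (r_all[n1:] - r_controls) / n1
    return v10, v01


def roc_auc(
    cases: np.ndarray,
    controls: np.ndarray,
    direction: str = "lower_score_is_case",
    se_method: str = "delong",
) -> ROCResult:
    """AUC with SE and 95% CI for a two-group marker comparison.

    AUC equals (wins + half-ties) / (n_cases * n_controls) after orienting
    the marker so that cases tend high; with the default direction the
    scores are negated first.
    """
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both groups must be non-empty")
    if direction not in ("lower_score_is_case", "higher_score_is_case"):
        raise ValueError(f"unknown direction {direction!r}")
    if se_method not in ("delong", "hanley_mcneil"):
        raise ValueError(f"unknown se_method {se_method!r}")
    sign = -1.0 if direction == "lower_score_is_case" else 1.0
    x, y = sign * cases, sign * controls
    n1, n0 = x.size, y.size

    v10, v01 = _midrank_placements(x, y)
    auc = float(v10.mean())

    flags: tuple[str, ...] = ()
    if n1 < 2 or n0 < 2:
        flags = ("unstable: a group has < 2 members",)
        se = float("nan")
    elif se_method == "delong":
        s10 = v10.var(ddof=1)
        s01 = v01.var(ddof=1)
        se = math.sqrt(s10 / n1 + s01 / n0)
    else:  # Hanley & McNeil binegative-exponential approximation
        q1 = auc / (2 - auc)
        q2 = 2 * auc**2 / (1 + auc)
        se = math.sqrt(
            (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2))
            / (n1 * n0)
        )
    if math.isnan(se):
        ci = (float("nan"), float("nan"))
    else:
        z = stats.norm.ppf(0.975)
        ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))
    return ROCResult(
        auc=auc,
        se=se,
        ci95=ci,
        n_cases=n1,
        n_controls=n0,
        direction=direction,
        se_method=se_method,
        flags=flags,
    )


@dataclass(frozen=True)
class ROCSampleSizeSpec:
    """Design of a single-test ROC study against the null AUC of 0.5."""

    auc_alt: float
    kappa: float = 1.0  # controls per case
    alpha: float = 0.05
    power: float = 0.90
    sided: str = "one"  # reproduces the published designs; "two" available

    def __post_init__(self) -> None:
        if not 0.5 < self.auc_alt < 1:
            raise ValueError("auc_alt must be in (0.5, 1)")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValueError("alpha and power must be in (0, 1)")
        if self.sided not in ("one", "two"):
            raise ValueError("sided must be 'one' or 'two'")


def roc_sample_size(spec: ROCSampleSizeSpec) -> dict[str, int]:
    """Obuchowski's binormal-variance minimum sample sizes.

    With a = sqrt(2) * Phi^-1(AUC), the variance of the AUC estimate under
    the alternative is approximated by
    ``V_A = 0.0099 * exp(-a^2/2) * [(5a^2 + 8) + (a^2 + 8)/kappa]`` and the
    null variance by ``V_0 = 0.0792 * (1 + 1/kappa)``; the case count is
    ``ceil[(z_{1-alpha} sqrt(V_0) + z_{power} sqrt(V_A))^2 / (AUC - 0.5)^2]``
    and controls are ``ceil(kappa * n_cases)``.
    """
    a = math.sqrt(2) * stats.norm.ppf(spec.auc_alt)
    va = 0.0099 * math.exp(-(a**2) / 2) * ((5 * a**2 + 8) + (a**2 + 8) / spec.kappa)
    v0 = 0.0792 * (1 + 1 / spec.kappa)
    alpha = spec.alpha if spec.sided == "one" else spec.alpha / 2
    za = stats.norm.ppf(1 - alpha)
    zp = stats.norm.ppf(spec.power)
    n_cases = math.ceil(
        (za * math.sqrt(v0) + zp * math.sqrt(va)) ** 2 / (spec.auc_alt - 0.5) ** 2
    )
    return {"n_cases": int(n_cases), "n_controls": int(math.ceil(spec.kappa * n_cases))}


def group_roc_table(
    data: pd.DataFrame,
    score_columns: tuple[str, ...] = ("tFAB_M", "tFAB_V"),
    group_column: str = "group",
    reference: str = "HP",
    direction: str = "lower_score_is_case",
    se_method: str = "delong",
    subgroup: pd.Series | None = None,
) -> pd.DataFrame:
    """One ROC row per clinical group (and optional subgroup) per outcome.

    Every non-reference level of ``group_column`` is compared against the
    reference (normative) rows.  ``subgroup`` is an optional alignable
    series (e.g. a companion-test ES split) whose levels further partition
    each clinical group.  Groups with < 2 members are flagged unstable but
    still computed.
    """
    if reference not in set(data[group_column].dropna()):
        raise ValueError(f"reference group {reference!r} absent from {group_column!r}")
    ref = data[data[group_column] == reference]
    rows = []
    clin = data[data[group_column] != reference]
    keys = [group_column] + ([subgroup.name] if subgroup is not None else [])
    if subgroup is not None:
        clin = clin.assign(**{subgroup.name: subgroup})
    for key, sub in clin.groupby(keys, dropna=False, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        for col in score_columns:
            cases = sub[col].dropna().to_numpy()
            controls = ref[col].dropna().to_numpy()
            res = roc_auc(cases, controls, direction=direction, se_method=se_method)
            rows.append(
                {
                    "group": key[0],
                    **({"subgroup": key[1]} if len(key) > 1 else {}),
                    "outcome": col,
                    "auc": res.auc,
                    "se": res.se,
                    "ci_low": res.ci95[0],
                    "ci_high": res.ci95[1],
                    "n_cases": res.n_cases,
                    "n_controls": res.n_controls,
                    "flags": "; ".join(res.flags),
                }
            )
    return pd.DataFrame(rows)
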