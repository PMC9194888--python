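"""Seeded synthetic cohorts with the statistical structure of the study.

The normative generator emulates a healthy-adult sample of N = 346 with the
published age x education x sex stratification, discrete 0-12 totals with a
heavy ceiling (targets 35.8% at 12 for the motor version, 39.3% for the
verbal one), an education effect on all scores and an age effect on the
motor-response scores only (the published adjustment equations serve as the
generating truth).  The clinical generator reproduces the group-level
means/SDs of the neurological cohorts.  Every generator is deterministic
given its seed.

The generative model is a continuous propensity
``anchor - sum(coef * (f(x) - center)) + Normal(0, latent_sd)``
discretized by round-then-truncate; the anchor is calibrated by bisection
on the seeded sample so the ceiling fraction hits its target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import TASKS, AdjustmentEquation
from .published import PUBLISHED_MODEL

__all__ = [
    "STRATA",
    "CLINICAL_DEFAULTS",
    "NormativeCohortSpec",
    "ClinicalCohortSpec",
    "generate_normative",
    "generate_clinical",
    "generate_clinical_suite",
    "generate_rater_data",
]

# (edu_lo, edu_hi, age_lo, age_hi, sex) -> count; the published normative
# sample stratification (rows: education bands; columns: age bands).
_AGE_BANDS = ((18, 30), (31, 45), (46, 60), (61, 70), (71, 80), (81, 96))
_EDU_BANDS = ((4, 5), (6, 8), (9, 12), (13, 16), (17, 23))
_COUNTS = {  # (edu_band_idx, age_band_idx): (males, females)
    (0, 0): (0, 0), (0, 1): (0, 0), (0, 2): (0, 0),
    (0, 3): (1, 2), (0, 4): (1, 2), (0, 5): (1, 8),
    (1, 0): (5, 0), (1, 1): (2, 2), (1, 2): (8, 13),
    (1, 3): (4, 2), (1, 4): (3, 4), (1, 5): (2, 3),
    (2, 0): (1, 1), (2, 1): (0, 1), (2, 2): (2, 12),
    (2, 3): (4, 5), (2, 4): (3, 2), (2, 5): (1, 1),
    (3, 0): (33, 29), (3, 1): (9, 11), (3, 2): (21, 43),
    (3, 3): (5, 13), (3, 4): (1, 3), (3, 5): (0, 1),
    (4, 0): (13, 20), (4, 1): (4, 5), (4, 2): (9, 11),
    (4, 3): (7, 7), (4, 4): (2, 0), (4, 5): (1, 2),
}

#: flat stratum table: (edu_band, age_band, sex, count); total = 346
STRATA: tuple[tuple[tuple[int, int], tuple[int, int], str, int], ...] = tuple(
    (_EDU_BANDS[e], _AGE_BANDS[a], sex, c)
    for (e, a), (m, f) in sorted(_COUNTS.items())
    for sex, c in (("M", m), ("F", f))
    if c > 0
)


def _default_true_adjustment() -> dict[str, AdjustmentEquation]:
    return {
        "tFAB_M": PUBLISHED_MODEL.outcomes["tFAB_M"].equation,
        "tFAB_V": PUBLISHED_MODEL.outcomes["tFAB_V"].equation,
    }


@dataclass
class NormativeCohortSpec:
    """Study conditions of the emulated normative sample."""

    seed: int
    n: int = 346
    strata: tuple = STRATA
    true_adjustment: dict[str, AdjustmentEquation] = field(
        default_factory=_default_true_adjustment
    )
    latent_sd: float = 1.3
    version_rho: float = 0.7  # within-person correlation of the two versions
    ceiling_target: dict[str, float] = field(
        default_factory=lambda: {"tFAB_M": 0.358, "tFAB_V": 0.393}
    )

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.latent_sd <= 0:
            raise ValueError("latent_sd must be > 0")
        if not 0 <= self.version_rho <= 1:
            raise ValueError("version_rho must be in [0, 1]")
        for k, v in self.ceiling_target.items():
            if not 0 < v < 1:
                raise ValueError(f"ceiling_target[{k!r}] = {v} not in (0, 1)")
        if sum(c for *_, c in self.strata) <= 0:
            raise ValueError("strata counts must be positive")


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def _calibrate_anchor(g_plus_e: np.ndarray, target: float, top: float = 12.0) -> float:
    """Smallest anchor whose seeded ceiling fraction matches the target.

    The ceiling fraction mean(anchor + g + e >= top - 0.5) is a step
    function of the anchor, nondecreasing, with steps of 1/n; bisection on
    a fixed sample is deterministic.
    """
    lo, hi = -30.0, 50.0
    frac = lambda anchor: float(np.mean(anchor + g_plus_e >= top - 0.5))
    for _ in range(60):
        mid = (lo + hi) / 2
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return hi


def _decompose(m_tot: np.ndarray, v_tot: np.ndarray) -> pd.DataFrame:
    """Split totals into the six task scores with a shared subtest 1.

    t1 is placed near its typical share of the total (~48%) within the
    feasible window; each subtest total of k becomes tasks (min(3, k),
    k - min(3, k)).  Deterministic; analyses use subtests/totals only.
    """
    lo = np.maximum.reduce([np.zeros_like(m_tot), m_tot - 6, v_tot - 6])
    hi = np.minimum.reduce([np.full_like(m_tot, 6), m_tot, v_tot])
    t1 = np.clip(_round_half_up(0.48 * (m_tot + v_tot) / 2), lo, hi)
    t2m = m_tot - t1
    t2v = v_tot - t1
    out = pd.DataFrame(
        {
            "conceptualization": np.minimum(3, t1),
            "mental_flexibility": t1 - np.minimum(3, t1),
            "interference_M": np.minimum(3, t2m),
            "inhibition_M": t2m - np.minimum(3, t2m),
            "interference_V": np.minimum(3, t2v),
            "inhibition_V": t2v - np.minimum(3, t2v),
        }
    )
    return out.astype(int)


def generate_normative(spec: NormativeCohortSpec) -> pd.DataFrame:
    """Synthetic healthy-adult cohort as a standard cohort DataFrame."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    counts = np.array([c for *_, c in spec.strata], dtype=float)
    idx = rng.choice(len(spec.strata), size=spec.n, p=counts / counts.sum())
    ages = np.empty(spec.n, dtype=int)
    edus = np.empty(spec.n, dtype=int)
    sexes = np.empty(spec.n, dtype=object)
    for i, k in enumerate(idx):
        (e_lo, e_hi), (a_lo, a_hi), sex, _ = spec.strata[k]
        ages[i] = rng.integers(a_lo, a_hi + 1)
        edus[i] = rng.integers(e_lo, e_hi + 1)
        sexes[i] = sex

    # demographic signal: negate the adjustment so that the published
    # correction exactly removes it (raw scores fall with age, rise with edu)
    z0 = rng.standard_normal(spec.n)
    totals: dict[str, np.ndarray] = {}
    for name, eq in spec.true_adjustment.items():
        g = np.array(
            [-eq.adjustment(a, e, s) for a, e, s in zip(ages, edus, sexes)]
        )
        zi = rng.standard_normal(spec.n)
        noise = spec.latent_sd * (
            np.sqrt(spec.version_rho) * z0 + np.sqrt(1 - spec.version_rho) * zi
        )
        target = spec.ceiling_target.get(name)
        if target is None:
            anchor = 0.0
        else:
            anchor = _calibrate_anchor(g + noise, target)
        totals[name] = np.clip(_round_half_up(anchor + g + noise), 0, 12).astype(int)

    m_tot = totals.get("tFAB_M", np.zeros(spec.n, dtype=int))
    v_tot = totals.get("tFAB_V", m_tot)
    tasks = _decompose(m_tot, v_tot)
    df = pd.DataFrame(
        {
            "id": [f"hp{i:04d}" for i in range(1, spec.n + 1)],
            "age": ages,
            "education": edus,
            "sex": sexes,
        }
    )
    df = pd.concat([df, tasks], axis=1)
    df["group"] = "HP"
    return df


# ---------------------------------------------------------------------------
# clinical cohorts
# ---------------------------------------------------------------------------

#: per-group generator defaults: n, age (mean, sd, range), education
#: (mean, sd, range), t-FAB-M (mean, sd), t-FAB-V (mean, sd), MMSE-ES band
CLINICAL_DEFAULTS: dict[str, dict] = {
    "pooled": dict(n=40, age=(73.1, 11.5, (38, 91)), edu=(13.3, 4.39, (5, 18)),
                   m=(8.63, 2.66), v=(9.3, 2.17), mmse_es=None),
    "EPD": dict(n=6, age=(76.0, 5.06, (70, 82)), edu=(14.0, 5.18, (5, 18)),
                m=(9.0, 3.23), v=(9.5, 3.02), mmse_es=None),
    "SVD_mmse_gt1": dict(n=14, age=(76.07, 8.87, (56, 87)), edu=(12.0, 4.37, (5, 18)),
                         m=(9.43, 1.99), v=(10.0, 1.71), mmse_es=2),
    "SVD_mmse_le1": dict(n=6, age=(81.33, 7.97, (68, 91)), edu=(14.5, 3.94, (8, 18)),
                         m=(7.5, 3.89), v=(8.67, 2.25), mmse_es=1),
    "stroke_L": dict(n=5, age=(54.6, 12.42, (38, 67)), edu=(14.0, 4.18, (8, 18)),
                     m=(10.0, 2.35), v=(9.8, 1.79), mmse_es=None),
    "stroke_R": dict(n=5, age=(68.8, 9.73, (54, 78)), edu=(13.8, 5.31, (8, 18)),
                     m=(7.4, 1.67), v=(9.4, 1.67), mmse_es=None),
    "MD": dict(n=4, age=(74.5, 9.98, (60, 82)), edu=(13.5, 4.8, (8, 18)),
               m=(6.75, 2.22), v=(6.75, 2.22), mmse_es=None),
}


@dataclass
class ClinicalCohortSpec:
    """One clinical group: marginal moments of demographics and scores."""

    seed: int
    group: str = "pooled"
    n: int | None = None
    m_mean: float | None = None
    m_sd: float | None = None
    v_mean: float | None = None
    v_sd: float | None = None
    version_rho: float = 0.7

    def resolved(self) -> dict:
        key = self.group if self.group in CLINICAL_DEFAULTS else "pooled"
        d = dict(CLINICAL_DEFAULTS[key])
        if self.n is not None:
            d["n"] = self.n
        if self.m_mean is not None or self.m_sd is not None:
            d["m"] = (self.m_mean or d["m"][0], self.m_sd or d["m"][1])
        if self.v_mean is not None or self.v_sd is not None:
            d["v"] = (self.v_mean or d["v"][0], self.v_sd or d["v"][1])
        if d["n"] < 1:
            raise ValueError("n must be >= 1")
        if d["m"][1] <= 0 or d["v"][1] <= 0:
            raise ValueError("score SDs must be > 0")
        return d


def generate_clinical(spec: ClinicalCohortSpec) -> pd.DataFrame:
    """Synthetic clinical group with the published group means/SDs."""
    d = spec.resolved()
    rng = np.random.default_rng(spec.seed)
    n = d["n"]
    a_mean, a_sd, a_range = d["age"]
    e_mean, e_sd, e_range = d["edu"]
    ages = np.clip(_round_half_up(rng.normal(a_mean, a_sd, n)), *a_range).astype(int)
    edus = np.clip(_round_half_up(rng.normal(e_mean, e_sd, n)), *e_range).astype(int)
    sexes = np.where(rng.random(n) < 0.5, "M", "F")

    rho = spec.version_rho
    z0 = rng.standard_normal(n)
    zm = rng.standard_normal(n)
    zv = rng.standard_normal(n)
    m_lat = d["m"][0] + d["m"][1] * (np.sqrt(rho) * z0 + np.sqrt(1 - rho) * zm)
    v_lat = d["v"][0] + d["v"][1] * (np.sqrt(rho) * z0 + np.sqrt(1 - rho) * zv)
    m_tot = np.clip(_round_half_up(m_lat), 0, 12).astype(int)
    v_tot = np.clip(_round_half_up(v_lat), 0, 12).astype(int)

    label = {"SVD_mmse_gt1": "SVD", "SVD_mmse_le1": "SVD"}.get(spec.group, spec.group)
    df = pd.DataFrame(
        {
            "id": [f"{spec.group.lower()}{i:03d}" for i in range(1, n + 1)],
            "age": ages,
            "education": edus,
            "sex": sexes,
        }
    )
    df = pd.concat([df, _decompose(m_tot, v_tot)], axis=1)
    df["group"] = label
    if d["mmse_es"] is not None:
        df["mmse_es"] = d["mmse_es"]
    return df


def generate_clinical_suite(seed: int) -> pd.DataFrame:
    """All clinical groups (N = 40 total) as one cohort DataFrame."""
    frames = []
    for i, group in enumerate(
        ("EPD", "SVD_mmse_gt1", "SVD_mmse_le1", "stroke_L", "stroke_R", "MD")
    ):
        frames.append(generate_clinical(ClinicalCohortSpec(seed=seed + i, group=group)))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# reliability designs
# ---------------------------------------------------------------------------


def generate_rater_data(
    cohort: pd.DataFrame | int,
    icc_target: float,
    n_raters: int = 2,
    seed: int = 0,
    mean: float = 6.0,
    total_sd: float = 2.0,
    integer: bool = True,
) -> np.ndarray:
    """Subjects x raters matrix with a chosen population ICC.

    Subject and error variances are set so that
    sigma_s^2 / (sigma_s^2 + sigma_e^2) = ``icc_target``; integer rounding
    (the score scale is discrete) is applied after composition and slightly
    attenuates the estimated ICC.
    """
    if not 0 < icc_target < 1:
        raise ValueError("icc_target must be in (0, 1)")
    n = len(cohort) if isinstance(cohort, pd.DataFrame) else int(cohort)
    if n < 2 or n_raters < 2:
        raise ValueError("need >= 2 subjects and >= 2 raters")
    rng = np.random.default_rng(seed)
    sigma_s = total_sd * np.sqrt(icc_target)
    sigma_e = total_sd * np.sqrt(1 - icc_target)
    subj = rng.normal(0.0, sigma_s, size=(n, 1))
    err = rng.normal(0.0, sigma_e, size=(n, n_raters))
    mat = mean + subj + err
    if integer:
        mat = _round_half_up(mat)
    return mat
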