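"""Norm derivation: stepwise adjustment, tolerance limits, ES thresholds."""

import json

import numpy as np
import pandas as pd
import pytest

from tfab.core import ModelError, ValidationError
from tfab.io import attach_derived_scores, write_model
from tfab.norming import (
    CollapsedBandsError,
    ESScheme,
    NormativeStandardization,
    StepwiseSpec,
    build_normative_model,
    compute_tolerance_limits,
    derive_es_thresholds,
    fit_adjustment,
    tolerance_limit_ranks,
)
from tfab.published import PUBLISHED_MODEL
from tfab.synthetic import NormativeCohortSpec, generate_normative


def oracle_tolerance_ranks(n, coverage=0.05, confidence=0.95):
    """Independent oracle: binomial CDF by recursive pmf accumulation."""
    q = coverage / (1 - coverage)
    pmf = np.empty(n + 1)
    pmf[0] = (1 - coverage) ** n
    for k in range(n):
        pmf[k + 1] = pmf[k] * (n - k) / (k + 1) * q
    cdf = np.cumsum(pmf)
    rank_outer = None
    for r in range(n, 0, -1):  # P[X >= r] = 1 - cdf[r-1]
        if 1 - cdf[r - 1] >= confidence - 1e-12:
            rank_outer = r
            break
    rank_inner = None
    for s in range(1, n + 1):  # P[X <= s-1] = cdf[s-1]
        if cdf[s - 1] >= confidence - 1e-12:
            rank_inner = s
            break
    return rank_outer, rank_inner


class TestToleranceLimitRanks:
    def test_outer_limit_first_exists_at_n_59(self):
        # 1 - 0.95^58 = 0.9489 < 0.95 <= 1 - 0.95^59 = 0.9515
        assert tolerance_limit_ranks(58) == (None, 7)
        assert tolerance_limit_ranks(59)[0] == 1

    def test_matches_exhaustive_enumeration_up_to_2000(self):
        for n in range(1, 2001):
            assert tolerance_limit_ranks(n) == oracle_tolerance_ranks(n), n

    @pytest.mark.parametrize("n", [1_000, 10_000])
    def test_ranks_track_coverage_asymptotically(self, n):
        ro, ri = tolerance_limit_ranks(n)
        band = 3 * np.sqrt(n * 0.05 * 0.95)
        assert abs(ro - 0.05 * n) <= band
        assert abs(ri - 0.05 * n) <= band

    def test_limits_are_observed_order_statistics(self, rng):
        a = rng.normal(10, 1.5, size=500)
        tl = compute_tolerance_limits(a)
        s = np.sort(a)
        assert tl.oTL == s[tl.rank_outer - 1]
        assert tl.iTL == s[tl.rank_inner - 1]
        assert tl.oTL <= tl.iTL

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            tolerance_limit_ranks(0)


class TestDeriveESThresholds:
    def test_uniform_sample_median_band(self):
        a = np.linspace(0, 12, 1000)
        tl = compute_tolerance_limits(a)
        table = derive_es_thresholds(a, tl)
        b = table.boundaries
        assert b[3] == pytest.approx(6.0, abs=0.02)  # ES4 starts at the median
        assert all(b[i] < b[i + 1] for i in range(3))
        assert b[0] == pytest.approx(tl.oTL, abs=0.005)

    def test_identical_scores_collapse(self):
        a = np.full(500, 9.0)
        tl = compute_tolerance_limits(a)
        with pytest.raises(CollapsedBandsError):
            derive_es_thresholds(a, tl)

    def test_band_occupancy_matches_centile_targets(self, rng):
        # Monte-Carlo check of the equal-z centile scheme on a large sample
        a = rng.normal(10, 1.5, size=5000)
        tl = compute_tolerance_limits(a)
        table = derive_es_thresholds(a, tl)
        es = np.array([table.lookup(v)[0] for v in a])
        occ = np.bincount(es, minlength=5) / a.size
        scheme = ESScheme()
        expected = (
            tl.rank_outer / a.size,
            scheme.centiles[0] - tl.rank_outer / a.size,
            scheme.centiles[1] - scheme.centiles[0],
            0.5 - scheme.centiles[1],
        )
        for got, want in zip(occ[:4], expected):
            assert got == pytest.approx(want, abs=0.01)
        assert occ.sum() == pytest.approx(1.0)
        assert np.all(np.diff(np.sort(es)) >= 0)

    def test_missing_outer_limit_is_explicit(self, rng):
        a = rng.normal(10, 1.5, size=40)
        tl = compute_tolerance_limits(a)
        assert tl.rank_outer is None
        with pytest.raises(ModelError, match="outer"):
            derive_es_thresholds(a, tl)


class TestFitAdjustment:
    def test_pure_noise_selects_nothing(self, rng):
        n = 500
        df = pd.DataFrame(
            {
                "id": [f"r{i}" for i in range(n)],
                "age": rng.integers(18, 96, n),
                "education": rng.integers(4, 23, n),
                "sex": rng.choice(["M", "F"], n),
                "score": rng.normal(8.0, 1.0, n),
            }
        )
        eq, report = fit_adjustment(df, "score")
        assert eq.terms == ()
        assert report.r_squared == 0.0

    def test_log10_education_effect_recovered(self, rng):
        n = 1000
        edu = rng.integers(4, 24, n).astype(float)
        score = 12 - 2 * (np.log10(edu) - np.mean(np.log10(edu))) + rng.normal(0, 0.5, n)
        df = pd.DataFrame(
            {
                "id": [f"r{i}" for i in range(n)],
                "age": rng.integers(18, 96, n),
                "education": edu,
                "sex": rng.choice(["M", "F"], n),
                "score": score,
            }
        )
        eq, _ = fit_adjustment(df, "score")
        assert [(t.variable, t.transform) for t in eq.terms] == [("education", "log10")]
        # negated slope: the equation *adds back* what education took away
        assert eq.terms[0].coefficient == pytest.approx(2.0, abs=0.15)
        assert eq.terms[0].center == pytest.approx(np.mean(np.log10(edu)))

    def test_published_style_effects_recovered_at_study_scale(self):
        spec = NormativeCohortSpec(
            seed=11, n=346, latent_sd=1.0,
            ceiling_target={"tFAB_M": 0.05, "tFAB_V": 0.05},
        )
        coh = attach_derived_scores(generate_normative(spec))
        eq, _ = fit_adjustment(coh, "tFAB_M")
        assert {t.variable for t in eq.terms} == {"age", "education"}
        # sign contract independent of the (collinear) transform chosen:
        # the correction grows with age and shrinks with education
        assert eq.adjustment(90, 13) > eq.adjustment(30, 13)
        assert eq.adjustment(50, 5) > eq.adjustment(50, 18)

    def test_sex_can_enter_when_it_matters(self, rng):
        n = 400
        sex = rng.choice(["M", "F"], n)
        df = pd.DataFrame(
            {
                "id": [f"r{i}" for i in range(n)],
                "age": rng.integers(18, 96, n),
                "education": rng.integers(4, 23, n),
                "sex": sex,
                "score": 8 + 1.5 * (sex == "M") + rng.normal(0, 1, n),
            }
        )
        eq, _ = fit_adjustment(df, "score")
        assert any(t.variable == "sex" for t in eq.terms)

    def test_small_cohorts_rejected(self, rng):
        df = pd.DataFrame(
            {
                "id": list("abcde"),
                "age": [30, 40, 50, 60, 70],
                "education": [8, 10, 12, 14, 16],
                "sex": list("MFMFM"),
                "score": [1, 2, 3, 4, 5],
            }
        )
        with pytest.raises(ValidationError, match="30"):
            fit_adjustment(df, "score")

    def test_constant_outcome_rejected(self, rng):
        n = 50
        df = pd.DataFrame(
            {
                "id": [f"r{i}" for i in range(n)],
                "age": rng.integers(18, 96, n),
                "education": rng.integers(4, 23, n),
                "sex": rng.choice(["M", "F"], n),
                "score": np.full(n, 12.0),
            }
        )
        with pytest.raises(ValidationError, match="variance"):
            fit_adjustment(df, "score")


class TestBuildNormativeModel:
    def test_end_to_end_recovery_within_ten_percent(self):
        spec = NormativeCohortSpec(
            seed=11, n=5000, latent_sd=1.0,
            ceiling_target={"tFAB_M": 0.05, "tFAB_V": 0.05},
        )
        coh = attach_derived_scores(generate_normative(spec))
        model = build_normative_model(coh, outcomes=("tFAB_M", "tFAB_V"))
        truth_m = {
            (t.variable, t.transform): t.coefficient
            for t in spec.true_adjustment["tFAB_M"].terms
        }
        got_m = {
            (t.variable, t.transform): t.coefficient
            for t in model.outcomes["tFAB_M"].equation.terms
        }
        assert set(got_m) == set(truth_m)
        for key, coef in truth_m.items():
            assert abs(got_m[key] - coef) / abs(coef) < 0.10
        truth_v = {
            (t.variable, t.transform): t.coefficient
            for t in spec.true_adjustment["tFAB_V"].terms
        }
        got_v = {
            (t.variable, t.transform): t.coefficient
            for t in model.outcomes["tFAB_V"].equation.terms
        }
        assert set(got_v) == set(truth_v)
        for key, coef in truth_v.items():
            assert abs(got_v[key] - coef) / abs(coef) < 0.10

    def test_self_classification_tail_matches_coverage(self, normative_cohort):
        res = NormativeStandardization(
            normative_cohort, outcomes=("tFAB_M",)
        ).fit()
        norm = res.model.outcomes["tFAB_M"]
        es0 = sum(
            norm.es_table.lookup(
                norm.equation.adjustment(r.age, r.education, r.sex) + r.tFAB_M
            )[0]
            == 0
            for r in normative_cohort.itertuples()
        )
        n = len(normative_cohort)
        # ES0 occupancy = rank_outer/n by construction, below coverage 5%
        assert es0 / n == pytest.approx(norm.tolerance.rank_outer / n, abs=0.01)
        assert es0 / n <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n)

    def test_small_cohort_flagged_no_outer_limit(self):
        coh = generate_normative(NormativeCohortSpec(seed=5, n=40))
        model = build_normative_model(coh, outcomes=("tFAB_M",))
        norm = model.outcomes["tFAB_M"]
        assert norm.es_table is None
        assert "no_outer_TL" in norm.flags
        assert model.metadata["flags"]

    def test_rederivation_is_byte_identical(self, normative_cohort, tmp_path):
        p1, p2 = tmp_path / "m1.json", tmp_path / "m2.json"
        write_model(build_normative_model(normative_cohort), p1)
        write_model(build_normative_model(normative_cohort.copy()), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_derived_model_satisfies_outer_limit_invariant(self, normative_cohort):
        model = build_normative_model(normative_cohort, outcomes=("tFAB_V",))
        norm = model.outcomes["tFAB_V"]
        assert norm.es_table.boundaries[0] == pytest.approx(norm.tolerance.oTL, abs=0.005)
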