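"""Construct validity, reliability, factorial structure and equivalence.

Implements the analytic toolkit of a cognitive-screening standardization
study: Pearson/Spearman correlations chosen by a skewness/kurtosis
normality rule with Bonferroni-adjusted flags, intraclass correlations for
test-retest and inter-rater reliability, a principal component analysis of
the task correlation matrix, the two one-sided tests (TOST) procedure for
equivalence of paired scores, and the sample-size calculators used to plan
such a study (TOST normal approximation; noncentral-F multiple regression).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationConfig",
    "TOSTResult",
    "ICCResult",
    "PCAResult",
    "correlation_matrix",
    "icc",
    "pca_monocomponent",
    "tost_paired",
    "tost_paired_sample_size",
    "regression_sample_size",
]


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrelationConfig:
    """Method-selection rule and multiple-comparison family.

    A variable counts as normal when |skewness| < ``skew_threshold`` and
    |excess kurtosis| < ``kurtosis_threshold``; Pearson is used only when
    both members of a pair pass, Spearman otherwise.  Significance flags
    use the Bonferroni-adjusted level ``alpha / family_size``.
    """

    skew_threshold: float = 1.0
    kurtosis_threshold: float = 3.0
    family_size: int = 1
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.skew_threshold <= 0 or self.kurtosis_threshold <= 0:
            raise ValueError("normality thresholds must be positive")
        if self.family_size < 1:
            raise ValueError("family_size must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @property
    def adjusted_alpha(self) -> float:
        return self.alpha / self.family_size


def is_normalish(x: np.ndarray, config: CorrelationConfig) -> bool:
    """Skew/kurtosis screen used to pick Pearson vs Spearman."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if np.ptp(x) == 0:
        return False
    return (
        abs(stats.skew(x)) < config.skew_threshold
        and abs(stats.kurtosis(x)) < config.kurtosis_threshold
    )


def correlation_matrix(
    data: pd.DataFrame, config: CorrelationConfig | None = None
) -> pd.DataFrame:
    """All pairwise correlations with per-pair method choice.

    Pairwise deletion of missing values; two-tailed p-values; the
    ``significant`` column applies the Bonferroni-adjusted alpha.  Constant
    columns yield an undefined coefficient (NaN, method ``"undefined"``).
    """
    config = config or CorrelationConfig()
    cols = list(data.columns)
    rows = []
    for a, b in itertools.combinations(cols, 2):
        pair = data[[a, b]].dropna()
        x, y = pair[a].to_numpy(float), pair[b].to_numpy(float)
        n = len(pair)
        if n < 4:
            raise ValueError(f"pair ({a}, {b}): need >= 4 complete pairs, got {n}")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((a, b, "undefined", np.nan, np.nan, n, False))
            continue
        if is_normalish(x, config) and is_normalish(y, config):
            r, p = stats.pearsonr(x, y)
            method = "pearson"
        else:
            r, p = stats.spearmanr(x, y)
            method = "spearman"
        rows.append((a, b, method, float(r), float(p), n, bool(p < config.adjusted_alpha)))
    return pd.DataFrame(
        rows, columns=["var1", "var2", "method", "coefficient", "p", "n", "significant"]
    )


# ---------------------------------------------------------------------------
# intraclass correlation
# ---------------------------------------------------------------------------

# pingouin type labels: ICC(A,1) = two-way random, absolute agreement,
# single rater; ICC(C,1) = two-way mixed, consistency, single rater
ICC_MODELS = {
    "two_way_random_absolute_single": "ICC(A,1)",
    "two_way_mixed_consistency_single": "ICC(C,1)",
}


@dataclass(frozen=True)
class ICCResult:
    model: str
    value: float
    ci95: tuple[float, float]
    n_subjects: int
    n_raters: int


def icc(
    ratings: np.ndarray | pd.DataFrame,
    model: str = "two_way_random_absolute_single",
) -> ICCResult:
    """Single-rater intraclass correlation of a subjects x raters matrix.

    Default is the two-way random-effects, absolute-agreement, single-rater
    coefficient (ICC(2,1)); the two-way mixed consistency variant (ICC(3,1))
    is available for designs where raters are fixed.  Point estimate and
    95% CI via variance components (pingouin's F-distribution bounds).
    """
    if model not in ICC_MODELS:
        raise ValueError(f"unknown ICC model {model!r}; choose from {list(ICC_MODELS)}")
    mat = np.asarray(ratings, dtype=float)
    if mat.ndim != 2 or mat.shape[1] < 2 or mat.shape[0] < 5:
        raise ValueError("ratings must be a (>=5 subjects) x (>=2 raters) matrix")
    if not np.all(np.isfinite(mat)):
        raise ValueError("ratings matrix must be complete")
    n, k = mat.shape
    if np.allclose(mat.var(axis=1), 0) and np.allclose(mat, mat[:, :1]):
        # identical columns: perfect reliability, CI degenerate
        return ICCResult(model, 1.0, (1.0, 1.0), n, k)
    if np.ptp(mat.mean(axis=1)) == 0:
        warnings.warn("zero between-subject variance; ICC reported as 0")
        return ICCResult(model, 0.0, (0.0, 0.0), n, k)

    import pingouin as pg

    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": mat.ravel(),
        }
    )
    tab = pg.intraclass_corr(
        data=long, targets="subject", raters="rater", ratings="score"
    ).set_index("Type")
    row = tab.loc[ICC_MODELS[model]]
    ci_col = "CI95%" if "CI95%" in tab.columns else "CI95"
    lo, hi = (float(v) for v in row[ci_col])
    return ICCResult(model, float(row["ICC"]), (lo, hi), n, k)


# ---------------------------------------------------------------------------
# principal component analysis of the task correlation matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PCAResult:
    eigenvalues: np.ndarray
    pct_variance_pc1: float
    loadings_pc1: np.ndarray
    n_retained: int


def pca_monocomponent(task_scores: np.ndarray | pd.DataFrame) -> PCAResult:
    """PCA of the correlation matrix of the entered task scores.

    Eigenvalues sum to the number of variables; components are retained by
    the eigenvalue > 1 rule; first-component loadings are the eigenvector
    scaled by sqrt(lambda_1), sign-fixed so their sum is positive.
    """
    X = np.asarray(task_scores, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need an n x p matrix with p >= 2")
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("constant column: correlation undefined")
    R = np.corrcoef(X, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    if np.min(eigval) < -1e-8:
        warnings.warn("correlation matrix numerically rank-deficient")
    eigval = np.clip(eigval, 0.0, None)
    v1 = eigvec[:, 0]
    if v1.sum() < 0:
        v1 = -v1
    loadings = v1 * math.sqrt(eigval[0])
    p = X.shape[1]
    return PCAResult(
        eigenvalues=eigval,
        pct_variance_pc1=float(eigval[0] / p * 100.0),
        loadings_pc1=loadings,
        n_retained=int(np.sum(eigval > 1.0)),
    )


# ---------------------------------------------------------------------------
# TOST equivalence for dependent samples
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TOSTResult:
    n: int
    mean_diff: float
    sd_diff: float
    dz: float
    bounds_dz: tuple[float, float]
    t_lower: float
    t_upper: float
    p_lower: float
    p_upper: float
    equivalent: bool
    alpha: float
    # companion two-tailed paired t-test of the difference against 0
    t_paired: float
    p_paired: float

    @property
    def df(self) -> int:
        return self.n - 1


def tost_paired(
    x: np.ndarray,
    y: np.ndarray,
    bounds_dz: float | tuple[float, float] = 0.5,
    alpha: float = 0.05,
) -> TOSTResult:
    """Two one-sided tests for equivalence of paired scores.

    The equivalence bounds are standardized (Cohen's dz units) and converted
    to raw units via the standard deviation of the paired differences.
    Equivalence is declared when both one-sided tests reject at ``alpha``,
    i.e. the mean difference is significantly above the lower bound and
    below the upper bound.  A conventional paired t-test against 0 is
    reported alongside.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.isscalar(bounds_dz):
        lo_dz, hi_dz = -abs(float(bounds_dz)), abs(float(bounds_dz))
    else:
        lo_dz, hi_dz = (float(b) for b in bounds_dz)
        if lo_dz >= hi_dz:
            raise ValueError("lower bound must be below upper bound")
    d = x - y
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    if sd_diff == 0:
        raise ValueError("zero variance of differences: TOST undefined")
    se = sd_diff / math.sqrt(n)
    t_lower = (mean_diff - lo_dz * sd_diff) / se
    t_upper = (mean_diff - hi_dz * sd_diff) / se
    p_lower = float(stats.t.sf(t_lower, n - 1))  # H0: diff <= lower bound
    p_upper = float(stats.t.cdf(t_upper, n - 1))  # H0: diff >= upper bound
    t_paired = mean_diff / se
    p_paired = float(2 * stats.t.sf(abs(t_paired), n - 1))
    return TOSTResult(
        n=n,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        dz=mean_diff / sd_diff,
        bounds_dz=(lo_dz, hi_dz),
        t_lower=float(t_lower),
        t_upper=float(t_upper),
        p_lower=p_lower,
        p_upper=p_upper,
        equivalent=bool(max(p_lower, p_upper) < alpha),
        alpha=alpha,
        t_paired=float(t_paired),
        p_paired=p_paired,
    )


def tost_paired_sample_size(
    bound_dz: float,
    alpha: float = 0.05,
    power: float = 0.95,
    exact: bool = False,
) -> int:
    """Minimum pairs for the symmetric-bounds paired TOST at a true dz of 0.

    Default is the normal-approximation design formula
    ``n = ceil[(z_{1-alpha} + z_{1-(1-power)/2})^2 / bound^2]``.
    With ``exact=True`` the smallest n whose exact central-t TOST power
    reaches ``power`` is returned instead (always >= the approximation).
    """
    if bound_dz == 0:
        raise ValueError("bound must be nonzero (infinite n otherwise)")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    b = abs(float(bound_dz))
    za = stats.norm.ppf(1 - alpha)
    zb = stats.norm.ppf(1 - (1 - power) / 2)
    n = int(math.ceil((za + zb) ** 2 / b**2))
    if n < 2:
        warnings.warn("bound so wide that n < 2; floored to 2")
        n = 2
    if not exact:
        return n

    def exact_power(m: int) -> float:
        lim = b * math.sqrt(m) - stats.t.ppf(1 - alpha, m - 1)
        if lim <= 0:
            return 0.0
        return float(2 * stats.t.cdf(lim, m - 1) - 1)

    m = max(n - 5, 3)
    while exact_power(m) < power:
        m += 1
    return m


# ---------------------------------------------------------------------------
# multiple-regression sample size (noncentral F)
# ---------------------------------------------------------------------------


def regression_sample_size(
    f2: float,
    u: int,
    alpha: float = 0.05,
    power: float = 0.95,
    noncentrality: str = "u+v+1",
) -> int:
    """Minimum N for a fixed-effects multiple regression F test.

    Finds the smallest denominator df v such that a noncentral
    F(u, v, lambda) test at level ``alpha`` reaches ``power``, and returns
    n = u + v + 1.  The noncentrality convention is explicit because power
    software differs: ``"u+v+1"`` uses lambda = f2*(u+v+1) (the total-N
    convention); ``"v"`` uses lambda = f2*v (error-df convention).
    """
    if f2 <= 0:
        raise ValueError("f2 must be > 0")
    if u < 1:
        raise ValueError("u must be >= 1")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    if noncentrality not in ("u+v+1", "v"):
        raise ValueError("noncentrality must be 'u+v+1' or 'v'")

    def achieved(v: int) -> float:
        lam = f2 * (u + v + 1) if noncentrality == "u+v+1" else f2 * v
        crit = stats.f.ppf(1 - alpha, u, v)
        return float(stats.ncf.sf(crit, u, v, lam))

    # bracket by doubling, then bisect (power is increasing in v)
    lo, hi = 1, 2
    while achieved(hi) < power:
        lo, hi = hi, hi * 2
        if hi > 10_000_000:
            raise RuntimeError("requested power unreachable")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if achieved(mid) >= power:
            hi = mid
        else:
            lo = mid
    v = hi if achieved(hi) >= power else hi + 1
    if achieved(lo) >= power:
        v = lo
    return u + v + 1
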