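"""Group comparison and observer-agreement statistics.

The analysis contract is the one used throughout small-cohort imaging
studies: every continuous covariate is first checked for normality
(Shapiro-Wilk); normally distributed covariates are compared between
groups with a two-sided t-test (Welch's unequal-variance form by
default) and summarised as mean +/- SD, the rest with the Mann-Whitney
test and median (IQR). Group comparisons can also be recomputed from
printed summary statistics alone (mean, SD, n per group) via the Welch
formulas, which is how published results are audited when raw
measurements are unavailable.

Observer agreement uses the intraclass correlation coefficient from a
two-way random-effects ANOVA decomposition (subjects x raters). The
mean squares are

    MSB  between subjects,   MSJ  between raters,   MSE  residual,

and with n subjects and k raters the four reported forms are

    agreement,  single   (MSB - MSE) / (MSB + (k-1) MSE + k (MSJ - MSE)/n)
    agreement,  average  (MSB - MSE) / (MSB + (MSJ - MSE)/n)
    consistency, single  (MSB - MSE) / (MSB + (k-1) MSE)
    consistency, average (MSB - MSE) / MSB

Absolute-agreement forms charge systematic rater shifts to the error;
consistency forms do not. Confidence intervals follow the standard
F-distribution bounds for each form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DegenerateTableError, ValidationError

__all__ = [
    "GroupComparison",
    "AgreementResult",
    "test_normality",
    "compare_groups",
    "compare_groups_from_summary",
    "compute_icc",
    "ICC_VARIANTS",
]

ICC_VARIANTS = (
    "agreement_single",
    "agreement_average",
    "consistency_single",
    "consistency_average",
)


@dataclass(frozen=True)
class GroupComparison:
    labels: tuple[str, str]
    n: tuple[int, int]
    summaries: tuple[dict, dict]  # per group: mean/sd and median/iqr
    test_name: str  # "t" | "mann_whitney"
    statistic: float
    p_value: float
    ci_95_of_difference: tuple[float, float]
    df: float | None = None

    def __post_init__(self) -> None:
        lo, hi = self.ci_95_of_difference
        if lo > hi:
            raise ValidationError("ci_95_of_difference must satisfy low <= high")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError("p_value must lie in [0, 1]")


@dataclass(frozen=True)
class AgreementResult:
    icc: float
    ci_95: tuple[float, float]
    variant: str
    n_subjects: int
    n_raters: int

    def __post_init__(self) -> None:
        if self.icc > 1.0 + 1e-12:
            raise ValidationError("icc cannot exceed 1")
        lo, hi = self.ci_95
        if not (lo - 1e-9 <= self.icc <= hi + 1e-9):
            raise ValidationError("ci_95 must contain the ICC point estimate")


def test_normality(values) -> tuple[float, float]:
    """Shapiro-Wilk test. Returns (W, p). Needs 3 <= n <= 5000 and
    non-constant data."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValidationError(f"need a 1-D sample with n >= 3, got n = {x.size}")
    if x.size > 5000:
        raise ValidationError("Shapiro-Wilk is unreliable above n = 5000")
    if np.ptp(x) == 0:
        raise ValidationError("constant sample: W is undefined for zero variance")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def _summarise(x: np.ndarray) -> dict:
    q25, q75 = np.percentile(x, [25, 75])
    return {
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
        "median": float(np.median(x)),
        "iqr": (float(q25), float(q75)),
    }


def _welch_summary(m1, s1, n1, m2, s2, n2, alpha=0.05):
    """Welch t, Welch-Satterthwaite df, two-sided p and CI of (m1 - m2),
    from summary statistics alone."""
    a, b = s1 * s1 / n1, s2 * s2 / n2
    se = np.sqrt(a + b)
    t = (m1 - m2) / se
    df = (a + b) ** 2 / (a * a / (n1 - 1) + b * b / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    tc = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(t), float(df), float(p), (float(m1 - m2 - tc * se), float(m1 - m2 + tc * se))


def _pooled_t_summary(m1, s1, n1, m2, s2, n2, alpha=0.05):
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1 * s1 + (n2 - 1) * s2 * s2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (m1 - m2) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    tc = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(t), float(df), float(p), (float(m1 - m2 - tc * se), float(m1 - m2 + tc * se))


def _hodges_lehmann_ci(a: np.ndarray, b: np.ndarray, alpha=0.05) -> tuple[float, float]:
    """Distribution-free CI of the location shift a - b from the ordered
    pairwise differences (normal approximation for the rank cut-off)."""
    diffs = np.sort((a[:, None] - b[None, :]).ravel())
    n1, n2 = a.size, b.size
    N = n1 * n2
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    sigma = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    k = int(np.floor(N / 2.0 - z * sigma))
    k = max(k, 0)
    return float(diffs[k]), float(diffs[min(N - 1 - k, N - 1)])


def compare_groups(a, b, alpha: float = 0.05, labels=("A", "B"),
                   equal_var: bool = False) -> GroupComparison:
    """Two-group comparison with a normality gate.

    If both groups pass Shapiro-Wilk at ``alpha``, a two-sided t-test is
    used (Welch by default; ``equal_var=True`` pools variances) with the
    95% CI of the mean difference. Otherwise the two-sided Mann-Whitney
    test is used (exact enumeration for small tie-free samples, normal
    approximation with tie correction otherwise) with a Hodges-Lehmann
    shift CI. Zero-variance groups cannot be normality-tested and fall
    through to the rank branch.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValidationError("both groups need n >= 3")
    try:
        normal = test_normality(x)[1] > alpha and test_normality(y)[1] > alpha
    except ValidationError:
        normal = False
    summ = (_summarise(x), _summarise(y))
    if normal:
        res = sps.ttest_ind(x, y, equal_var=equal_var)
        fn = _pooled_t_summary if equal_var else _welch_summary
        _, df, _, ci = fn(
            x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size
        )
        return GroupComparison(
            labels=tuple(labels), n=(x.size, y.size), summaries=summ,
            test_name="t", statistic=float(res.statistic),
            p_value=float(res.pvalue), ci_95_of_difference=ci, df=df,
        )
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return GroupComparison(
        labels=tuple(labels), n=(x.size, y.size), summaries=summ,
        test_name="mann_whitney", statistic=float(res.statistic),
        p_value=min(float(res.pvalue), 1.0),
        ci_95_of_difference=_hodges_lehmann_ci(x, y),
    )


def compare_groups_from_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    labels=("A", "B"), equal_var: bool = False,
) -> GroupComparison:
    """Welch t-test recomputed from published summary statistics.

    Audits a printed group comparison when the raw measurements are not
    available: the t statistic, Welch-Satterthwaite degrees of freedom,
    two-sided p-value and 95% CI of the mean difference all follow from
    (mean, SD, n) per group.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValidationError("both SDs must be > 0")
    if n1 < 2 or n2 < 2:
        raise ValidationError("both group sizes must be >= 2")
    fn = _pooled_t_summary if equal_var else _welch_summary
    t, df, p, ci = fn(mean1, sd1, n1, mean2, sd2, n2)
    summ = tuple(
        {"mean": m, "sd": s, "median": None, "iqr": None}
        for m, s in ((mean1, sd1), (mean2, sd2))
    )
    return GroupComparison(
        labels=tuple(labels), n=(int(n1), int(n2)), summaries=summ,
        test_name="t", statistic=t, p_value=p, ci_95_of_difference=ci, df=df,
    )


def _two_way_mean_squares(table: np.ndarray):
    """Mean squares of the two-way (subjects x raters) crossed layout."""
    n, k = table.shape
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_tot = np.sum((table - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    msb = ss_rows / (n - 1)
    msj = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)
    return msb, msj, mse


def compute_icc(table, variant: str = "agreement_single",
                alpha: float = 0.05) -> AgreementResult:
    """Two-way random-effects ICC of a complete subjects x raters table.

    ``variant`` selects absolute agreement vs consistency and
    single-measure vs average-measure (see module docstring for the
    mean-squares formulas). The 95% CI uses the exact F bounds for the
    consistency forms and the Satterthwaite-approximate F bounds for the
    agreement forms.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValidationError("table must be 2-D (subjects x raters)")
    n, k = t.shape
    if n < 5:
        raise ValidationError(f"need >= 5 subjects, got {n}")
    if k < 2:
        raise ValidationError(f"need >= 2 raters, got {k}")
    if not np.all(np.isfinite(t)):
        raise ValidationError("table must be complete (no missing cells)")
    if variant not in ICC_VARIANTS:
        raise ValidationError(f"variant must be one of {ICC_VARIANTS}, got {variant!r}")

    msb, msj, mse = _two_way_mean_squares(t)
    scale = max(np.ptp(t), 1.0) ** 2
    if msb <= 1e-14 * scale:
        raise DegenerateTableError(
            "no between-subject variance: the ICC is undefined for this table"
        )
    # identical columns give MSE = 0; keep the point estimates exact and
    # nudge MSE only inside the CI formulas so the F bounds stay finite
    mse_ci = mse if mse > 0 else msb * 1e-12

    if variant == "agreement_single":
        icc = (msb - mse) / (msb + (k - 1) * mse + k * (msj - mse) / n)
    elif variant == "agreement_average":
        icc = (msb - mse) / (msb + (msj - mse) / n)
    elif variant == "consistency_single":
        icc = (msb - mse) / (msb + (k - 1) * mse)
    else:
        icc = (msb - mse) / msb

    if variant.startswith("consistency"):
        fstat = msb / mse_ci
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = fstat / sps.f.ppf(1 - alpha / 2, df1, df2)
        fu = fstat * sps.f.ppf(1 - alpha / 2, df2, df1)
        if variant.endswith("single"):
            lo, hi = (fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1)
        else:
            lo, hi = 1 - 1 / fl, 1 - 1 / fu
    else:
        r1 = (msb - mse) / (msb + (k - 1) * mse + k * (msj - mse) / n)
        fj = msj / mse_ci
        vn = (k - 1) * (n - 1) * (k * r1 * fj + n * (1 + (k - 1) * r1) - k * r1) ** 2
        vd = (n - 1) * k**2 * r1**2 * fj**2 + (n * (1 + (k - 1) * r1) - k * r1) ** 2
        v = vn / vd
        f2u = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f2l = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msb - f2u * mse_ci) / (
            f2u * (k * msj + (k * n - k - n) * mse_ci) + n * msb
        )
        hi = n * (f2l * msb - mse_ci) / (
            k * msj + (k * n - k - n) * mse_ci + n * f2l * msb
        )
        if variant.endswith("average"):
            lo = lo * k / (1 + lo * (k - 1))
            hi = hi * k / (1 + hi * (k - 1))

    lo = float(min(lo, icc))
    hi = float(np.clip(max(hi, icc), None, 1.0))
    return AgreementResult(
        icc=float(icc), ci_95=(lo, hi), variant=variant, n_subjects=n, n_raters=k
    )
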