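"""Cohort-level statistics.

The study design is two matched groups (MAD and MMA, n = 17 each) measured
before (T0) and after (T1) treatment.  This module provides the tests that
design calls for: pooled-variance Student t between groups, paired t within
group, Kolmogorov–Smirnov normality with a Lilliefors-style Monte-Carlo p
(parameters are estimated, so the textbook KS null is anticonservative),
age-adjusted ANCOVA, Pearson correlation, a 2×2 chi-square, the
noncentral-t sample-size calculation for a paired design, and the
apnea–hypopnea-index treatment-success rule.  No multiplicity correction is
applied; report builders record how many tests they ran.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import StatisticsError, ValidationError


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test (two-sided unless noted)."""

    test: str
    statistic: float
    df: float | tuple
    p: float
    estimate: float
    n: tuple

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0):
            raise StatisticsError(f"p-value out of range: {self.p}")


Summary = tuple  # (n, mean, sd)


def _as_summary(x) -> tuple[int, float, float]:
    """Accept a raw sample or an (n, mean, sd) triple."""
    if isinstance(x, tuple) and len(x) == 3 and np.isscalar(x[0]):
        n, m, s = int(x[0]), float(x[1]), float(x[2])
    else:
        arr = np.asarray(x, dtype=float)
        if arr.ndim != 1:
            raise ValidationError("sample must be 1-D")
        n, m, s = len(arr), float(arr.mean()), float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    if n < 2:
        raise StatisticsError("need n >= 2 per group")
    return n, m, s


def student_t(a, b, welch: bool = False) -> TestResult:
    """Two-sample t test; pooled variance by default, Welch optionally.

    ``a`` and ``b`` are raw 1-D samples or summary triples ``(n, mean, sd)``.
    The estimate is the mean difference a − b.
    """
    n1, m1, s1 = _as_summary(a)
    n2, m2, s2 = _as_summary(b)
    if s1 == 0.0 and s2 == 0.0:
        raise StatisticsError("both groups are constant; t statistic undefined")
    t, p = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=not welch)
    if welch:
        v1, v2 = s1 * s1 / n1, s2 * s2 / n2
        df = (v1 + v2) ** 2 / (v1 * v1 / (n1 - 1) + v2 * v2 / (n2 - 1))
    else:
        df = n1 + n2 - 2
    return TestResult("student_t" if not welch else "welch_t",
                      float(t), float(df), float(p), m1 - m2, (n1, n2))


def paired_t(x0: Sequence[float], x1: Sequence[float]) -> TestResult:
    """Paired t test: one-sample t on the differences x1 − x0."""
    x0 = np.asarray(x0, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    if x0.shape != x1.shape or x0.ndim != 1:
        raise ValidationError("paired samples must be 1-D and equal length")
    if len(x0) < 2:
        raise StatisticsError("paired t needs n >= 2")
    d = x1 - x0
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise StatisticsError("paired t undefined: all within-pair differences are identical "
                              "(zero difference variance)")
    t, p = sps.ttest_1samp(d, 0.0)
    return TestResult("paired_t", float(t), len(d) - 1, float(p),
                      float(d.mean()), (len(d),))


def ks_normality(x: Sequence[float], reps: int = 10_000, seed: int = 0,
                 lilliefors: bool = True) -> TestResult:
    """Kolmogorov–Smirnov test of normality with estimated parameters.

    The KS statistic is computed against N(x̄, s²).  Because the parameters
    are estimated from the same sample, the default p-value is obtained by
    seeded Monte-Carlo simulation of the null (Lilliefors construction,
    ``reps`` draws); ``lilliefors=False`` returns the plain — and
    anticonservative — asymptotic KS p instead.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 5:
        raise StatisticsError("KS normality test needs a 1-D sample with n >= 5")
    s = x.std(ddof=1)
    if s == 0.0:
        raise StatisticsError("constant sample: normality test undefined")
    n = len(x)
    d_obs = _lilliefors_stat(np.sort((x - x.mean()) / s))
    if not lilliefors:
        p = float(sps.kstest((x - x.mean()) / s, "norm").pvalue)
        return TestResult("ks_normality", d_obs, n, p, d_obs, (n,))
    rng = np.random.default_rng(seed)
    null = rng.standard_normal((reps, n))
    null = (null - null.mean(axis=1, keepdims=True)) / null.std(axis=1, ddof=1, keepdims=True)
    null.sort(axis=1)
    d_null = _lilliefors_stat(null)
    p = (1.0 + np.sum(d_null >= d_obs)) / (reps + 1.0)
    return TestResult("ks_normality_lilliefors", d_obs, n, float(p), d_obs, (n,))


def _lilliefors_stat(sorted_z: np.ndarray) -> np.ndarray | float:
    """KS sup-distance of sorted standardized samples against Φ (vectorized)."""
    z = np.atleast_2d(sorted_z)
    reps, n = z.shape
    cdf = sps.norm.cdf(z)
    i = np.arange(1, n + 1)
    d_plus = (i / n - cdf).max(axis=1)
    d_minus = (cdf - (i - 1) / n).max(axis=1)
    d = np.maximum(d_plus, d_minus)
    return float(d[0]) if np.ndim(sorted_z) == 1 else d


def ancova_group_age(y: Sequence[float], group: Sequence, age: Sequence[float]
                     ) -> tuple[float, float]:
    """Age-adjusted group comparison: linear model y ~ group + age.

    Returns ``(p_age, p_group)`` from Type II F tests — the two adjustment
    columns of a multifactorial analysis with a two-level group factor and a
    continuous age covariate.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = pd.DataFrame({"y": np.asarray(y, dtype=float),
                       "group": np.asarray(group).astype(str),
                       "age": np.asarray(age, dtype=float)})
    if df.isna().any().any():
        raise ValidationError("ANCOVA inputs must not contain missing values")
    if df["group"].nunique() != 2:
        raise ValidationError(f"ANCOVA needs exactly two groups, got {df['group'].nunique()}")
    if df["age"].nunique() < 2:
        raise StatisticsError("age covariate is constant; model is rank deficient")
    fit = smf.ols("y ~ C(group) + age", data=df).fit()
    table = anova_lm(fit, typ=2)
    return float(table.loc["age", "PR(>F)"]), float(table.loc["C(group)", "PR(>F)"])


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson r with the two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValidationError("correlation needs two equal-length 1-D samples, n >= 3")
    if x.std() == 0.0 or y.std() == 0.0:
        raise StatisticsError("correlation undefined for a constant input")
    r, p = sps.pearsonr(x, y)
    return TestResult("pearson", float(r), len(x) - 2, float(p), float(r), (len(x),))


def chi_square_2x2(counts) -> TestResult:
    """Pearson chi-square on a 2×2 table, without continuity correction."""
    c = np.asarray(counts)
    if c.shape != (2, 2):
        raise ValidationError("counts must be a 2x2 table")
    if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
        if not np.all(c == np.floor(c)) or np.any(c < 0):
            raise ValidationError("counts must be nonnegative integers")
        c = c.astype(int)
    if np.any(c.sum(axis=0) == 0) or np.any(c.sum(axis=1) == 0):
        raise StatisticsError("chi-square undefined: a table margin is zero")
    chi2, p, dof, _ = sps.chi2_contingency(c, correction=False)
    return TestResult("chi_square", float(chi2), int(dof), float(p),
                      float(chi2), tuple(int(v) for v in c.sum(axis=1)))


@dataclass(frozen=True)
class PowerSpec:
    """Target effect and error rates for a paired-design power calculation.

    ``mean_diff`` and ``sd_diff`` are the expected mean and standard
    deviation of within-pair differences, in the units of the measure.
    """

    mean_diff: float
    sd_diff: float
    alpha: float = 0.05
    power: float = 0.90

    def __post_init__(self):
        if self.sd_diff <= 0:
            raise ValidationError("sd_diff must be positive")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValidationError("alpha and power must lie in (0, 1)")
        if self.mean_diff == 0:
            raise ValidationError("mean_diff must be nonzero (no detectable effect)")

    @property
    def effect_size(self) -> float:
        return abs(self.mean_diff) / self.sd_diff


def paired_t_power(n: int, effect_size: float, alpha: float = 0.05) -> float:
    """Two-sided paired-t power at sample size ``n`` via the noncentral t."""
    if n < 2:
        return 0.0
    df = n - 1
    t_crit = sps.t.ppf(1.0 - alpha / 2.0, df)
    ncp = effect_size * np.sqrt(n)
    return float(1.0 - sps.nct.cdf(t_crit, df, ncp) + sps.nct.cdf(-t_crit, df, ncp))


def sample_size_paired_t(spec: PowerSpec) -> int:
    """Smallest n with two-sided paired-t power ≥ the target.

    Power is computed exactly from the noncentral t distribution with
    noncentrality (|mean_diff|/sd_diff)·√n and n − 1 degrees of freedom;
    power is monotone in n so the search terminates.
    """
    d = spec.effect_size
    n = 2
    while paired_t_power(n, d, spec.alpha) < spec.power:
        n += 1
        if n > 10_000_000:  # pragma: no cover - unreachable for valid specs
            raise StatisticsError("sample size search did not terminate")
    return n


def classify_treatment_success(ahi_t0: float, ahi_t1: float) -> bool:
    """Apnea–hypopnea-index success rule for appliance therapy.

    Success iff the post-treatment AHI is below 10 events/hour or has
    dropped by at least 50% from baseline.
    """
    if ahi_t0 < 0 or ahi_t1 < 0:
        raise ValidationError("AHI cannot be negative")
    return bool(ahi_t1 < 10.0 or ahi_t1 <= 0.5 * ahi_t0)
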