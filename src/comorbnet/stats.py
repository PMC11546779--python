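"""Cohort-level statistics: descriptive moments, seasonal profiles and 2x2 inference.

Covers the statistical surface of the discharge analysis: per-variable
descriptive summaries (bias-corrected sample moments), yearly admission
counts, sex-stratified monthly percentage profiles, the Yates-corrected
chi-squared test and Woolf odds-ratio confidence interval for 2x2 tables,
and pairwise Pearson correlation matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .records import Cohort, PatientRecord

__all__ = [
    "DescriptiveSummary",
    "MonthlyProfile",
    "TwoByTwoTable",
    "OddsRatioResult",
    "describe",
    "yearly_counts",
    "monthly_profile",
    "chi2_yates",
    "odds_ratio_woolf",
    "reconstruct_counts",
    "pearson_matrix",
]


@dataclass(frozen=True)
class DescriptiveSummary:
    count: int
    mean: float
    sd: float
    min: float
    q1: float
    median: float
    q3: float
    max: float
    skewness: float  # NaN when undefined (n < 3 or zero variance)
    excess_kurtosis: float  # NaN when undefined (n < 4 or zero variance)

    def to_series(self) -> pd.Series:
        """Row layout mirroring the descriptive table of the analysis."""
        return pd.Series({
            "Count": self.count, "Mean": self.mean, "Standard deviation": self.sd,
            "Minimum value": self.min, "First quartile (25%)": self.q1,
            "Median quartile (50%)": self.median, "Third quartile (75%)": self.q3,
            "Maximum value": self.max, "Skewness": self.skewness,
            "Kurtosis": self.excess_kurtosis,
        })


@dataclass(frozen=True)
class MonthlyProfile:
    """Per-sex vectors of 12 percentages (calendar month -> % of that sex's cases)."""

    cohort_label: str
    female_pct: tuple[float, ...]
    male_pct: tuple[float, ...]
    empty_sexes: frozenset[str] = field(default_factory=frozenset)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"month": range(1, 13), "F_pct": self.female_pct, "M_pct": self.male_pct}
        )


@dataclass(frozen=True)
class TwoByTwoTable:
    """Counts a,b / c,d: exposed-case, exposed-noncase, unexposed-case, unexposed-noncase."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 counts must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class OddsRatioResult:
    or_: float
    ci_low: float
    ci_high: float
    confidence: float
    log_se: float


def describe(values: Sequence[float]) -> DescriptiveSummary:
    """Descriptive summary with sample (n-1) sd and bias-corrected moments.

    Quartiles use linear interpolation between order statistics.  Skewness and
    excess kurtosis are the bias-corrected sample versions (a normal sample
    has excess kurtosis ~0); with fewer than 3 (skewness) or 4 (kurtosis)
    observations, or zero variance, the moment is reported as NaN.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("describe requires at least one value")
    n = x.size
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    q1, med, q3 = np.percentile(x, [25, 50, 75], method="linear")
    degenerate = sd == 0.0
    skew = float(sps.skew(x, bias=False)) if n >= 3 and not degenerate else math.nan
    kurt = (float(sps.kurtosis(x, fisher=True, bias=False))
            if n >= 4 and not degenerate else math.nan)
    return DescriptiveSummary(
        count=n, mean=float(np.mean(x)), sd=sd, min=float(x.min()),
        q1=float(q1), median=float(med), q3=float(q3), max=float(x.max()),
        skewness=skew, excess_kurtosis=kurt,
    )


def yearly_counts(records: Sequence[PatientRecord]) -> dict[int, int]:
    """Admission counts per year; gap years within the observed span count 0."""
    if not records:
        return {}
    years = [r.admission_ts.year for r in records]
    lo, hi = min(years), max(years)
    counts = {y: 0 for y in range(lo, hi + 1)}
    for y in years:
        counts[y] += 1
    return counts


def monthly_profile(c: Cohort) -> MonthlyProfile:
    """Sex-stratified seasonal profile, all years pooled.

    For each sex, the entry for calendar month m is 100 x (cases of that sex
    admitted in month m) / (total cases of that sex), so each sex's vector
    sums to 100.  A sex with no cases gets an all-zero vector and is flagged
    in ``empty_sexes``.
    """
    if not c.records:
        raise ValueError("monthly_profile requires a non-empty cohort")
    vectors: dict[str, tuple[float, ...]] = {}
    empty: set[str] = set()
    for sex in ("F", "M"):
        months = [r.admission_ts.month for r in c.records if r.sex == sex]
        if not months:
            empty.add(sex)
            vectors[sex] = tuple(0.0 for _ in range(12))
            continue
        total = len(months)
        counts = [0] * 12
        for m in months:
            counts[m - 1] += 1
        vectors[sex] = tuple(100.0 * k / total for k in counts)
    return MonthlyProfile(c.label, vectors["F"], vectors["M"], frozenset(empty))


def chi2_yates(t: TwoByTwoTable) -> tuple[float, float]:
    """Chi-squared test for a 2x2 table with Yates continuity correction (df=1)."""
    arr = t.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("chi-squared requires all marginals > 0")
    res = sps.chi2_contingency(arr, correction=True)
    return float(res.statistic), float(res.pvalue)


def odds_ratio_woolf(t: TwoByTwoTable, confidence: float = 0.95) -> OddsRatioResult:
    """Sample odds ratio ad/bc with the Woolf log-normal confidence interval.

    CI = exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)); no continuity
    correction is applied, so all four cells must be positive.
    """
    if min(t.a, t.b, t.c, t.d) == 0:
        raise ValueError("Woolf odds ratio requires all four cells > 0")
    or_ = (t.a * t.d) / (t.b * t.c)
    log_se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    z = sps.norm.ppf(0.5 + confidence / 2)
    lo, hi = math.exp(math.log(or_) - z * log_se), math.exp(math.log(or_) + z * log_se)
    return OddsRatioResult(or_=or_, ci_low=lo, ci_high=hi,
                           confidence=confidence, log_se=log_se)


def reconstruct_counts(total: int, pct: float) -> tuple[int, int]:
    """Recover (k, total-k) from a printed percentage, rounding half away from zero."""
    if not 0 <= pct <= 100:
        raise ValueError("pct must be in [0, 100]")
    k = int(math.floor(total * pct / 100 + 0.5))
    return k, total - k


def pearson_matrix(series: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix of named, aligned series.

    Requires at least two series of equal length >= 3 with nonzero variance;
    the diagonal is exactly 1 and the matrix is symmetric.
    """
    if len(series) < 2:
        raise ValueError("need at least two series")
    lengths = {len(v) for v in series.values()}
    if len(lengths) != 1:
        raise ValueError("series must have equal length")
    if lengths.pop() < 3:
        raise ValueError("series must have length >= 3")
    names = list(series)
    mat = np.asarray([series[n] for n in names], dtype=float)
    for name, row in zip(names, mat):
        if np.std(row) == 0:
            raise ValueError(f"series {name!r} has zero variance")
    r = np.corrcoef(mat)
    np.fill_diagonal(r, 1.0)
    r = (r + r.T) / 2
    return pd.DataFrame(r, index=names, columns=names)
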