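"""Agreement statistics: limits of agreement, ICC, Bland-Altman.

The reliability analysis treats each measurement context (a rater, a
session, or a device) as a "measurer" of the same subjects and asks how
well measurers agree:

* 95% limits of agreement (LoA): ``mean +/- 1.96 * SD`` of a list of
  differences; measurements beyond the upper limit are flagged as
  outliers.
* Two-way random, absolute-agreement intraclass correlation, ICC(A,1)
  in McGraw-Wong terms, computed from the two-way ANOVA mean squares.
  Absolute agreement penalises systematic measurer offsets, not just
  inconsistency, which is what an inter-device comparison needs.
* Bland-Altman summaries: pairwise bias, LoA of the differences, and
  95% confidence intervals for the bias and for each agreement limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .metrics import DifferencePair

__all__ = [
    "LoaSummary",
    "MeasurementTable",
    "BlandAltmanSummary",
    "limits_of_agreement",
    "loa_from_stats",
    "flag_outliers",
    "icc_two_way_random",
    "bland_altman",
]

Z_95 = 1.96


@dataclass(frozen=True)
class LoaSummary:
    """95% limits of agreement: mean +/- 1.96 * SD (n-1 denominator SD)."""

    n: int
    mean: float
    sd: float
    lower: float
    upper: float
    unit: str = "um"

    def __post_init__(self) -> None:
        if not (self.upper >= self.mean >= self.lower):
            raise ValueError("limits of agreement must bracket the mean")


@dataclass(frozen=True)
class MeasurementTable:
    """Complete subjects x measurers matrix of measurements (e.g. areas, mm^2)."""

    subjects: tuple[str, ...]
    measurers: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n, k = len(self.subjects), len(self.measurers)
        if v.shape != (n, k):
            raise ValueError(f"values shape {v.shape} does not match {n} subjects x {k} measurers")
        if n < 2 or k < 2:
            raise ValueError("ICC needs at least 2 subjects and 2 measurers")
        if not np.all(np.isfinite(v)):
            raise ValueError("measurement table must be complete (no missing cells)")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "subjects", tuple(self.subjects))
        object.__setattr__(self, "measurers", tuple(self.measurers))

    @property
    def n(self) -> int:
        return len(self.subjects)

    @property
    def k(self) -> int:
        return len(self.measurers)


@dataclass(frozen=True)
class BlandAltmanSummary:
    """Pairwise agreement: bias, limits of agreement, and their 95% CIs."""

    pairs: tuple[tuple[float, float], ...]  # (mean of pair, difference a-b)
    bias: float
    loa: LoaSummary
    ci_bias: tuple[float, float]
    ci_lower_loa: tuple[float, float]
    ci_upper_loa: tuple[float, float]


def loa_from_stats(mean: float, sd: float, n: int = 0, unit: str = "um") -> LoaSummary:
    """Limits of agreement from an already-computed mean and SD.

    Useful when only summary statistics are available (e.g. a published
    mean +/- SD of per-scan differences).
    """
    if sd < 0:
        raise ValueError("sd must be non-negative")
    return LoaSummary(
        n=n, mean=mean, sd=sd, lower=mean - Z_95 * sd, upper=mean + Z_95 * sd, unit=unit
    )


def limits_of_agreement(values: Sequence[float], unit: str = "um") -> LoaSummary:
    """95% limits of agreement of a list of values: mean +/- 1.96 * SD.

    SD uses the n-1 denominator (sample standard deviation).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("limits of agreement need at least 2 values")
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    return loa_from_stats(mean, sd, n=v.size, unit=unit)


def flag_outliers(records: Sequence[DifferencePair], loa: LoaSummary) -> list[tuple[str, str]]:
    """Identify records whose mean absolute difference exceeds the LoA.

    Only the upper limit matters: the records carry absolute differences,
    which cannot meaningfully breach a lower bound.  The comparison is a
    strict inequality, so a record exactly at the limit is not flagged.
    Returns ``(scan_id, segment_label)`` pairs.
    """
    if loa.unit != "um":
        raise ValueError(f"LoA summary is in {loa.unit!r}, records are in um")
    return [
        (r.scan_id, r.segment_label)
        for r in records
        if r.mean_abs_diff_um > loa.upper
    ]


def _anova_mean_squares(values: np.ndarray) -> tuple[float, float, float]:
    """Two-way (subjects x measurers, one observation per cell) mean squares.

    Returns (MSR, MSC, MSE): between-subjects (rows), between-measurers
    (columns) and residual mean squares.
    """
    n, k = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    resid = values - row_means[:, None] - col_means[None, :] + grand
    ss_err = float(np.sum(resid**2))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_two_way_random(table: MeasurementTable, average: bool = False) -> float:
    """Two-way random, absolute-agreement intraclass correlation.

    Single-measure ICC(A,1) by default::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    where MSR, MSC, MSE are the between-subject, between-measurer and
    residual mean squares of the two-way ANOVA (computed internally).
    With ``average=True`` the average-measure variant ICC(A,k) is
    returned instead.  A table with zero total variance has no defined
    ICC and raises.
    """
    v = table.values
    if np.ptp(v) == 0:
        raise ValueError("ICC undefined: measurement table has zero total variance")
    n, k = table.n, table.k
    msr, msc, mse = _anova_mean_squares(v)
    if average:
        denom = msr + (msc - mse) / n
    else:
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise ValueError("ICC undefined: degenerate ANOVA decomposition")
    return float((msr - mse) / denom)


def bland_altman(a: Sequence[float], b: Sequence[float], unit: str = "mm2") -> BlandAltmanSummary:
    """Bland-Altman agreement summary for paired measurements.

    Differences follow the fixed sign convention ``a - b``.  The CI of
    the bias is ``bias +/- t(0.975, n-1) * sd / sqrt(n)``; the CI of each
    agreement limit is ``limit +/- t(0.975, n-1) * sd * sqrt(3/n)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired inputs must be equal-length 1-D sequences")
    if a.size < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    diffs = a - b
    loa = limits_of_agreement(diffs, unit=unit)
    n = a.size
    tcrit = float(stats.t.ppf(0.975, n - 1))
    se_bias = loa.sd / np.sqrt(n)
    se_limit = loa.sd * np.sqrt(3.0 / n)
    return BlandAltmanSummary(
        pairs=tuple(zip(((a + b) / 2.0).tolist(), diffs.tolist())),
        bias=loa.mean,
        loa=loa,
        ci_bias=(loa.mean - tcrit * se_bias, loa.mean + tcrit * se_bias),
        ci_lower_loa=(loa.lower - tcrit * se_limit, loa.lower + tcrit * se_limit),
        ci_upper_loa=(loa.upper - tcrit * se_limit, loa.upper + tcrit * se_limit),
    )
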