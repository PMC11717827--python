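"""Agreement statistics and report tables for fusion-accuracy studies.

Implements the statistical layer such a validation study reports: paired
t-tests with t-based 95% confidence intervals, Pearson reliability between
replicate measurement series, the duplicate measurement error (DME — the
standard deviation of paired differences divided by sqrt(2), i.e. the
per-measurement error when two replicates share the true value), and
clinical-acceptability binning at the 2 mm / 2 deg and 3 mm / 3 deg cut
points.  Sample standard deviations use the n-1 denominator; tests are
two-sided at alpha = 0.05 with no multiple-testing correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .fusion_workflows import OUTCOMES, PAIRS, CohortResult

__all__ = [
    "PairedComparison",
    "paired_t",
    "pearson_reliability",
    "dme",
    "mean_ci",
    "clinical_bins",
    "build_report",
    "ConstantSeriesError",
]


class ConstantSeriesError(ValueError):
    """Pearson reliability is undefined for a constant series."""


@dataclass(frozen=True)
class PairedComparison:
    """Paired t-test summary: mean difference with 95% CI and p-value.

    ``degenerate`` flags zero-variance differences, where the CI collapses
    to a point and the t statistic is undefined (p is NaN, not an error).
    """

    mean_diff: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    degenerate: bool = False


def _as_array(x, min_n: int = 2) -> np.ndarray:
    a = np.asarray(x, dtype=np.float64).ravel()
    if len(a) < min_n:
        raise ValueError(f"need at least {min_n} values, got {len(a)}")
    if not np.isfinite(a).all():
        raise ValueError("values must be finite")
    return a


def paired_t(a, b) -> PairedComparison:
    """Two-sided paired t-test of series *a* vs *b* (equal length/order)."""
    a, b = _as_array(a), _as_array(b)
    if len(a) != len(b):
        raise ValueError("paired series must have equal length")
    d = a - b
    n = len(d)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        return PairedComparison(mean, mean, mean, float("nan"), n, degenerate=True)
    se = sd / math.sqrt(n)
    tq = float(_stats.t.ppf(0.975, n - 1))
    t = mean / se
    p = float(2 * _stats.t.sf(abs(t), n - 1))
    return PairedComparison(mean, mean - tq * se, mean + tq * se, p, n)


def pearson_reliability(a, b) -> float:
    """Product-moment correlation between two measurement series.

    May legitimately be negative (poor agreement); never clamped.  Raises
    :class:`ConstantSeriesError` when either series has zero variance.
    """
    a, b = _as_array(a, 3), _as_array(b, 3)
    if len(a) != len(b):
        raise ValueError("series must have equal length")
    if a.std() == 0 or b.std() == 0:
        raise ConstantSeriesError("reliability undefined for a constant series")
    return float(np.corrcoef(a, b)[0, 1])


def dme(a, b) -> float:
    """Duplicate measurement error: SD (n-1) of paired differences / sqrt(2)."""
    a, b = _as_array(a), _as_array(b)
    if len(a) != len(b):
        raise ValueError("paired series must have equal length")
    return float((a - b).std(ddof=1) / math.sqrt(2))


def mean_ci(series) -> tuple[float, tuple[float, float]]:
    """Mean with t-based 95% CI (n-1 degrees of freedom)."""
    a = _as_array(series)
    n = len(a)
    mean = float(a.mean())
    sd = float(a.std(ddof=1))
    if sd == 0.0:
        return mean, (mean, mean)
    half = float(_stats.t.ppf(0.975, n - 1)) * sd / math.sqrt(n)
    return mean, (mean - half, mean + half)


def clinical_bins(series) -> tuple[int, int, int]:
    """Counts in the clinical-acceptability bins (<=2, 2-3, >3 mm/deg).

    Boundaries are closed on the left bin's side: a value of exactly 2
    falls in the first bin, exactly 3 in the second.  Input must be
    absolutized (non-negative).
    """
    a = _as_array(series, 1)
    if (a < 0).any():
        raise ValueError("clinical bins expect absolutized (non-negative) values")
    b1 = int((a <= 2.0).sum())
    b2 = int(((a > 2.0) & (a <= 3.0)).sum())
    b3 = int((a > 3.0).sum())
    return b1, b2, b3


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------


def _deviation_table(cohort: CohortResult) -> pd.DataFrame:
    """Per-outcome summary: mean and CI for A-C and B-C, paired A-vs-B test."""
    rows = []
    for outcome in OUTCOMES:
        va = cohort.series("A-C", outcome)
        vb = cohort.series("B-C", outcome)
        ma, (la, ha) = mean_ci(va)
        mb, (lb, hb) = mean_ci(vb)
        cmp_ab = paired_t(va, vb)
        rows.append(
            {
                "outcome": outcome,
                "A_mean": ma,
                "A_ci_low": la,
                "A_ci_high": ha,
                "B_mean": mb,
                "B_ci_low": lb,
                "B_ci_high": hb,
                "AB_diff": cmp_ab.mean_diff,
                "AB_ci_low": cmp_ab.ci_low,
                "AB_ci_high": cmp_ab.ci_high,
                "AB_p": cmp_ab.p_value,
            }
        )
    return pd.DataFrame(rows)


def _bins_table(cohort: CohortResult) -> pd.DataFrame:
    rows = []
    for pair in ("A-C", "B-C"):
        for outcome in OUTCOMES:
            b1, b2, b3 = clinical_bins(cohort.series(pair, outcome))
            rows.append(
                {"pair": pair, "outcome": outcome, "le_2": b1, "gt2_le3": b2, "gt_3": b3}
            )
    return pd.DataFrame(rows)


def _agreement_table(cohort: CohortResult, replicate: CohortResult) -> pd.DataFrame:
    """Reliability / DME / paired-difference table between two fusion runs
    of the same subjects (an intra- or inter-observer analogue)."""
    if list(cohort.table["subject"].unique()) != list(replicate.table["subject"].unique()):
        raise ValueError("cohort and replicate must cover the same subjects")
    rows = []
    for pair in ("A-C", "B-C"):
        for outcome in OUTCOMES:
            v1 = cohort.series(pair, outcome)
            v2 = replicate.series(pair, outcome)
            try:
                r = pearson_reliability(v1, v2)
            except ConstantSeriesError:
                r = float("nan")
            cmp_ = paired_t(v1, v2)
            rows.append(
                {
                    "pair": pair,
                    "outcome": outcome,
                    "reliability": r,
                    "dme": dme(v1, v2),
                    "diff": cmp_.mean_diff,
                    "ci_low": cmp_.ci_low,
                    "ci_high": cmp_.ci_high,
                    "p": cmp_.p_value,
                }
            )
    return pd.DataFrame(rows)


def build_report(
    cohort: CohortResult, replicate: CohortResult | None = None
) -> dict[str, pd.DataFrame]:
    """Assemble the study's report tables from cohort results.

    Returns ``deviations`` (per-outcome means/CIs and the paired A-vs-B
    test), ``bins`` (clinical-acceptability counts), and — when a
    replicate run over the same subjects is supplied — ``agreement``
    (reliability, DME, and paired differences between the two runs).  All
    values operate on absolutized deviations; the ``diff`` columns of the
    agreement table are signed differences of those absolutized outcomes.
    """
    report = {"deviations": _deviation_table(cohort), "bins": _bins_table(cohort)}
    if replicate is not None:
        report["agreement"] = _agreement_table(cohort, replicate)
    return report
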