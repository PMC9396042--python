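"""Cohort-level analyses: group summaries, Welch tests, dose-coverage curves.

Per-sample profiles are aggregated the way the underlying study design
demands: tumour and normal groups are summarized as mean +/- sample
standard deviation, compared with Welch's unequal-variance t-test, and the
tumour GARD distribution defines a "GARD-high" threshold (cohort median by
default). Inverting the GARD formula at that threshold gives each patient's
minimum total dose, whose empirical CDF is the cohort's dose-coverage
curve.

Group GARD summaries are per-sample-then-averaged (mean of the per-sample
GARDs), not GARD evaluated at the mean RSI; the two differ by a Jensen gap
because GARD is nonlinear in RSI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DoseError, RadsensError
from .radiosensitivity import RadioProfile, optimal_total_dose

__all__ = [
    "GroupSummary",
    "WelchResult",
    "CohortReport",
    "summarize_group",
    "welch_test",
    "gard_high_threshold",
    "optimal_dose_ecdf",
    "coverage_at_dose",
    "loess_smooth",
    "build_report",
]


@dataclass(frozen=True)
class GroupSummary:
    label: str  # "tumor" | "normal"
    metric: str  # "rsi" | "gard"
    n_samples: int
    mean: float
    sd: float  # n-1 denominator


@dataclass(frozen=True)
class WelchResult:
    t_statistic: float
    degrees_of_freedom: float  # Welch-Satterthwaite, real-valued
    p_value: float  # two-sided


@dataclass(frozen=True)
class CohortReport:
    profiles: list[RadioProfile]
    summaries: list[GroupSummary]
    welch: dict[str, WelchResult]  # keyed by metric
    gard_high_threshold: float
    ecdf_x: np.ndarray  # sorted unique minimum doses (Gy)
    ecdf_y: np.ndarray  # cumulative patient fraction
    coverage: dict[float, float]  # dose -> fraction covered
    excluded_patients: list[str] = field(default_factory=list)


def summarize_group(
    values: Sequence[float], label: str, metric: str
) -> GroupSummary:
    """Arithmetic mean and n-1 standard deviation of a group's metric."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise RadsensError(f"empty group {label!r} for metric {metric!r}")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return GroupSummary(label, metric, int(arr.size), float(arr.mean()), sd)


def welch_test(a: Sequence[float], b: Sequence[float]) -> WelchResult:
    """Two-sided Welch unequal-variance t-test with Satterthwaite df."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise RadsensError("Welch test requires at least 2 values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise RadsensError("Welch test undefined: both group variances are zero")
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue))


def gard_high_threshold(
    tumor_gards: Sequence[float],
    mode: str = "median",
    fixed_value: float | None = None,
) -> float:
    """GARD-high threshold: tumour-cohort median, or a supplied fixed value."""
    if mode == "fixed":
        if fixed_value is None:
            raise RadsensError("fixed threshold mode requires a value")
        return float(fixed_value)
    if mode != "median":
        raise RadsensError(f"unknown threshold mode {mode!r}")
    arr = np.asarray(tumor_gards, dtype=float)
    if arr.size == 0:
        raise RadsensError("median threshold requires a non-empty tumour group")
    return float(np.median(arr))


def _min_doses(
    profiles: Sequence[RadioProfile], threshold: float
) -> tuple[np.ndarray, list[str]]:
    """Per-patient minimum continuous total dose; unattainable patients excluded."""
    doses, excluded = [], []
    for p in profiles:
        try:
            dose, _ = optimal_total_dose(p.alpha, threshold, p.regimen.d, p.regimen.beta)
        except DoseError:
            excluded.append(p.sample_id)
            continue
        doses.append(dose)
    return np.asarray(doses, dtype=float), excluded


def optimal_dose_ecdf(
    profiles: Sequence[RadioProfile], threshold: float
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Right-continuous ECDF of per-patient minimum dose reaching a GARD threshold.

    Returns (x, y, excluded): sorted unique doses, cumulative patient
    fractions, and samples for which the threshold is unattainable
    (alpha + beta*d <= 0), which are excluded and reported.
    """
    doses, excluded = _min_doses(profiles, threshold)
    if doses.size == 0:
        raise RadsensError("no patient has an attainable dose for the ECDF")
    x, counts = np.unique(doses, return_counts=True)
    y = np.cumsum(counts) / doses.size
    return x, y, excluded


def coverage_at_dose(
    profiles: Sequence[RadioProfile], threshold: float, dose: float
) -> float:
    """Fraction of patients whose minimum dose is at or below ``dose``.

    Equals the ECDF evaluated at ``dose``.
    """
    doses, _ = _min_doses(profiles, threshold)
    if doses.size == 0:
        raise RadsensError("no patient has an attainable dose")
    return float(np.mean(doses <= dose))


def loess_smooth(
    x: Sequence[float],
    y: Sequence[float],
    span: float = 0.75,
    xq: Sequence[float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Locally weighted (tricube) degree-1 regression, clipped to [0, 1].

    Presentation-only smoother for the dose-coverage curve. At each query
    point the span-fraction nearest neighbours get tricube weights by
    distance and a weighted straight line is fitted.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise RadsensError("LOESS needs at least 4 points")
    if not 0 < span <= 1:
        raise RadsensError("span must be in (0, 1]")
    k = max(int(np.ceil(span * x.size)), 2)
    xq = x if xq is None else np.asarray(xq, dtype=float)
    fitted = np.empty(xq.size)
    for i, x0 in enumerate(xq):
        dist = np.abs(x - x0)
        idx = np.argsort(dist, kind="stable")[:k]
        h = dist[idx].max()
        w = (1 - (dist[idx] / h) ** 3) ** 3 if h > 0 else np.ones(k)
        # weighted least squares for intercept + slope at x0
        sw = np.sqrt(np.maximum(w, 0))
        design = np.column_stack([np.ones(k), x[idx] - x0])
        coef, *_ = np.linalg.lstsq(design * sw[:, None], y[idx] * sw, rcond=None)
        fitted[i] = coef[0]
    return xq, np.clip(fitted, 0.0, 1.0)


def build_report(
    profiles: Sequence[RadioProfile],
    tissues: dict[str, str],
    threshold_mode: str = "median",
    threshold_value: float | None = None,
    coverage_doses: Sequence[float] = (),
) -> CohortReport:
    """Assemble the full cohort report from per-sample profiles.

    ``tissues`` maps sample_id -> "tumor"/"normal". The ECDF and coverage
    table are computed over the tumour profiles only (one per patient in a
    paired design).
    """
    tumor = [p for p in profiles if tissues[p.sample_id] == "tumor"]
    normal = [p for p in profiles if tissues[p.sample_id] == "normal"]
    if not tumor:
        raise RadsensError("cohort contains no tumour samples")

    summaries = []
    for metric in ("rsi", "gard"):
        for label, grp in (("tumor", tumor), ("normal", normal)):
            if grp:
                vals = [getattr(p, metric) for p in grp]
                summaries.append(summarize_group(vals, label, metric))

    welch = {}
    if len(tumor) >= 2 and len(normal) >= 2:
        for metric in ("rsi", "gard"):
            welch[metric] = welch_test(
                [getattr(p, metric) for p in tumor],
                [getattr(p, metric) for p in normal],
            )

    threshold = gard_high_threshold(
        [p.gard for p in tumor], threshold_mode, threshold_value
    )
    ecdf_x, ecdf_y, excluded = optimal_dose_ecdf(tumor, threshold)
    coverage = {
        float(d): coverage_at_dose(tumor, threshold, d) for d in coverage_doses
    }
    return CohortReport(
        profiles=list(profiles),
        summaries=summaries,
        welch=welch,
        gard_high_threshold=threshold,
        ecdf_x=ecdf_x,
        ecdf_y=ecdf_y,
        coverage=coverage,
        excluded_patients=excluded,
    )
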