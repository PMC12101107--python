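"""Day-night comparison statistics for pooled-interval biomarker series.

Each day interval (~08:00-20:00) is paired with the immediately following
night interval (~20:00-08:00) of the same 24-h period.  The paired t test
uses the difference ``night - day``, so a day-dominant excretion pattern
yields a negative t — the sign convention used throughout reporting.

An *inversion* is a 24-h period in which the night value strictly exceeds the
day value, contrary to the dominant pattern; ties count as non-inversions.

The coefficient-of-variation (CV) report quantifies how measurement
variability shrinks as the collection window widens: CVs of day-only and
night-only 12-h values, and of mass-pooled 24-h and 48-h windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .timeseries_io import (
    ChronuriaError,
    CorrectedSeries,
    RAW_UNIT,
    SeriesValidationError,
    UrineSeries,
    aggregate,
)

__all__ = [
    "DayNightPairs",
    "PairedTestResult",
    "CorrelationResult",
    "CvReport",
    "pair_day_night",
    "paired_t",
    "inversion_rate",
    "pearson",
    "cv_report",
]


@dataclass(frozen=True)
class DayNightPairs:
    """Matched (day, night) values from the same 24-h periods."""

    day_values: np.ndarray
    night_values: np.ndarray
    dropped: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "day_values", np.asarray(self.day_values, dtype=float))
        object.__setattr__(
            self, "night_values", np.asarray(self.night_values, dtype=float))
        if len(self.day_values) != len(self.night_values):
            raise SeriesValidationError("unbalanced day/night pair arrays")

    @property
    def n_pairs(self) -> int:
        return len(self.day_values)

    @property
    def differences(self) -> np.ndarray:
        """night - day, one per pair."""
        return self.night_values - self.day_values

    def swapped(self) -> "DayNightPairs":
        return DayNightPairs(self.night_values, self.day_values, self.dropped)


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    mean_diff: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class CvReport:
    """Percent CVs by phase and collection window, plus 12-h descriptives."""

    cv_12h_day: float
    cv_12h_night: float
    cv_24h: float
    cv_48h: float
    mean: float
    sd: float
    min: float
    max: float


def pair_day_night(series: CorrectedSeries) -> DayNightPairs:
    """Pair each day interval with the immediately following night interval.

    A leading night interval or a trailing day interval has no partner within
    its 24-h period and is counted in ``dropped``.  The rule is insensitive to
    whether the series starts with a day or a night interval.
    """
    if series.n < 2:
        raise SeriesValidationError("need at least 2 intervals to pair")
    phases = series.phases
    day_idx = [
        i for i in range(series.n - 1)
        if phases[i] == "day" and phases[i + 1] == "night"
    ]
    day_vals = series.values[day_idx]
    night_vals = series.values[[i + 1 for i in day_idx]]
    return DayNightPairs(day_vals, night_vals,
                         dropped=series.n - 2 * len(day_idx))


def paired_t(pairs: DayNightPairs) -> PairedTestResult:
    """Two-tailed paired t test on the night - day differences.

    ``t = mean(d) / (sd(d) / sqrt(n))`` with ``d = night - day`` and
    ``df = n - 1``; day > night levels therefore give t < 0.
    """
    n = pairs.n_pairs
    if n < 2:
        raise SeriesValidationError("paired t needs at least 2 pairs")
    d = pairs.differences
    if np.std(d, ddof=1) == 0:
        raise ChronuriaError(
            "paired t undefined: all night-day differences identical")
    res = stats.ttest_rel(pairs.night_values, pairs.day_values)
    return PairedTestResult(
        t=float(res.statistic),
        df=n - 1,
        p=float(res.pvalue),
        mean_diff=float(d.mean()),
    )


def inversion_rate(pairs: DayNightPairs) -> float:
    """Percent of 24-h periods whose night value exceeds the day value."""
    if pairs.n_pairs < 1:
        raise SeriesValidationError("no pairs to evaluate")
    inverted = np.count_nonzero(pairs.night_values > pairs.day_values)
    return 100.0 * inverted / pairs.n_pairs


def pearson(x: CorrectedSeries | np.ndarray,
            y: CorrectedSeries | np.ndarray) -> CorrelationResult:
    """Pearson product-moment correlation, two-tailed p with n-2 df.

    Used to check whether the two correction schemes rank the same intervals
    the same way.
    """
    xv = x.values if isinstance(x, CorrectedSeries) else np.asarray(x, float)
    yv = y.values if isinstance(y, CorrectedSeries) else np.asarray(y, float)
    if len(xv) != len(yv):
        raise SeriesValidationError("series lengths differ")
    if len(xv) < 3:
        raise SeriesValidationError("pearson needs n >= 3")
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ChronuriaError("pearson undefined for a constant input")
    res = stats.pearsonr(xv, yv)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue),
                             n=len(xv))


def _cv(values: np.ndarray) -> float:
    mean = values.mean()
    if mean == 0:
        raise ChronuriaError("CV undefined: mean is zero")
    return float(100.0 * values.std(ddof=1) / mean)


def cv_report(series: CorrectedSeries,
              raw: UrineSeries | None = None) -> CvReport:
    """Percent CVs at 12-h (by phase), 24-h and 48-h collection windows.

    ``CV = 100 * sd / mean`` with the n-1 sd.  When the underlying raw
    measurements are available, the 24-h and 48-h values are mass-pooled as
    if collected in a single canister; otherwise per-window means of the
    corrected values are used (the two coincide in the µg/h regime on a
    uniform grid).
    """
    if series.unit == RAW_UNIT:
        raise SeriesValidationError(
            "CV reporting requires a corrected unit regime")
    if series.n < 4:
        raise SeriesValidationError("cv_report needs n >= 4")
    day = series.values[series.phases == "day"]
    night = series.values[series.phases == "night"]
    if len(day) == 0 or len(night) == 0:
        raise SeriesValidationError("cv_report needs both phases present")

    def pooled(window: float) -> np.ndarray:
        if raw is not None:
            return aggregate(raw, window, unit=series.unit).values
        if not series.is_equidistant:
            raise SeriesValidationError(
                "window pooling of a corrected series requires an "
                "equidistant grid")
        k = int(round(window / series.sampling_interval))
        m = series.n // k
        return series.values[: m * k].reshape(m, k).mean(axis=1)

    return CvReport(
        cv_12h_day=_cv(day),
        cv_12h_night=_cv(night),
        cv_24h=_cv(pooled(24.0)),
        cv_48h=_cv(pooled(48.0)),
        mean=float(series.values.mean()),
        sd=float(series.values.std(ddof=1)),
        min=float(series.values.min()),
        max=float(series.values.max()),
    )
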