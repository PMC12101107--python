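"""Rhythm detection: autocorrelation, interval ANOVA, cosinor, LS spectrum.

Single-component cosinor rhythmometry fits, by ordinary least squares,

    y(t) = M + A cos(2*pi*t/tau + phi_rad)
         = M + beta*cos(omega*t) + gamma*sin(omega*t),   omega = 2*pi/tau,

for a fixed *trial period* tau.  M is the mesor (rhythm-adjusted mean),
A = sqrt(beta^2 + gamma^2) >= 0 the amplitude (half the peak-to-trough
extent), and the acrophase phi the timing of the fitted peak, reported in
degrees within (-360, 0]: 360 deg corresponds to one trial period, 0 deg is
the start of the time series, and the peak occurs at t = -phi*tau/360 hours.
The percent rhythm PR = SS_model / SS_total is the fraction of total variance
the cosine accounts for, and the zero-amplitude test

    F = (SS_model / 2) / (SS_resid / (n - 3))   on (2, n - 3) df

tests H0: A = 0.

The least-squares spectrum repeats the cosinor fit over the harmonic series
of trial periods tau_k = T/k of a fundamental period T (default 720 h, i.e.
30 days), down to the Nyquist limit of the sampling grid, and summarises PR
per trial period.  Because the fit is plain least squares, the spectrum is
equally valid on non-equidistant anchors (e.g. the day-only subset of an
alternating series), where FFT periodograms are not.

Values pooled over a window of length ``delta`` attenuate a tau-period cosine
by sin(omega*delta/2) / (omega*delta/2); :func:`pooling_attenuation` exposes
the factor so generator amplitudes can be compared with fitted ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.tsa.stattools import acf as _sm_acf

from .timeseries_io import (
    ChronuriaError,
    CorrectedSeries,
    DegenerateDesignError,
    SeriesValidationError,
)

__all__ = [
    "AcfResult",
    "IntervalAnovaResult",
    "CosinorFit",
    "PeakBand",
    "Spectrum",
    "acf",
    "interval_anova",
    "cosinor_fit",
    "ls_spectrum",
    "subset_by_phase",
    "pooling_attenuation",
]

#: condition-number threshold above which a cosinor design is rejected
_COND_LIMIT = 1e8


@dataclass(frozen=True)
class AcfResult:
    """Autocorrelation coefficients r_k with the +/- z_0.975/sqrt(n) band."""

    lags: np.ndarray
    coefficients: np.ndarray
    conf_limit: float

    def significant(self) -> np.ndarray:
        """Boolean mask of lags (excluding 0) beyond the confidence band."""
        out = np.abs(self.coefficients) >= self.conf_limit
        out[0] = False
        return out


@dataclass(frozen=True)
class IntervalAnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_means: np.ndarray
    group_sizes: np.ndarray


@dataclass(frozen=True)
class CosinorFit:
    trial_period: float
    mesor: float
    amplitude: float
    acrophase: float
    percent_rhythm: float
    p_zero_amplitude: float
    f_zero_amplitude: float
    n: int

    @property
    def peak_time(self) -> float:
        """Hours after series start at which the fitted cosine peaks."""
        return -self.acrophase * self.trial_period / 360.0

    def predict(self, t: np.ndarray | float) -> np.ndarray | float:
        omega = 2.0 * math.pi / self.trial_period
        return self.mesor + self.amplitude * np.cos(
            omega * (np.asarray(t, dtype=float) - self.peak_time))


@dataclass(frozen=True)
class PeakBand:
    """Contiguous harmonics around the PR maximum (PR > max PR / 2)."""

    harmonics: tuple[int, ...]
    periods: tuple[float, ...]
    total_pr: float
    best_harmonic: int
    best_period: float


@dataclass(frozen=True)
class Spectrum:
    fundamental: float
    harmonics: tuple[int, ...]
    fits: tuple[CosinorFit, ...]

    @property
    def periods(self) -> np.ndarray:
        return np.array([f.trial_period for f in self.fits])

    @property
    def percent_rhythm(self) -> np.ndarray:
        return np.array([f.percent_rhythm for f in self.fits])

    @property
    def peak(self) -> CosinorFit:
        return self.fits[int(np.argmax(self.percent_rhythm))]

    @property
    def peak_band(self) -> PeakBand:
        pr = self.percent_rhythm
        best = int(np.argmax(pr))
        half = pr[best] / 2.0
        lo = best
        while lo > 0 and pr[lo - 1] > half:
            lo -= 1
        hi = best
        while hi < len(pr) - 1 and pr[hi + 1] > half:
            hi += 1
        ks = self.harmonics[lo:hi + 1]
        return PeakBand(
            harmonics=ks,
            periods=tuple(self.fits[i].trial_period
                          for i in range(lo, hi + 1)),
            total_pr=float(pr[lo:hi + 1].sum()),
            best_harmonic=self.harmonics[best],
            best_period=self.fits[best].trial_period,
        )

    def fit_at(self, period: float) -> CosinorFit:
        """The fit whose trial period is closest to ``period`` (hours)."""
        return self.fits[int(np.argmin(np.abs(self.periods - period)))]


# ---------------------------------------------------------------------------


def _require_equidistant(series: CorrectedSeries, op: str) -> None:
    """Lag/block operations need the complete, gap-free pooled grid.

    A single-phase subset of an alternating 12-h series is equidistant at
    24-h spacing but has a gap (the missing phase) inside every step, so its
    lags are not comparable to the pooled sampling step; it is rejected here
    while the least-squares fits still accept it.
    """
    if not series.is_equidistant:
        raise SeriesValidationError(
            f"{op} requires an equidistant grid; this series is not")
    if series.durations is not None and series.n > 1:
        step = series.times[1] - series.times[0]
        if not np.allclose(series.durations, step, rtol=1e-9):
            raise SeriesValidationError(
                f"{op} requires a gap-free grid (spacing equal to the "
                "pooling duration); this series skips intervals, "
                "e.g. a single-phase subset")


def acf(series: CorrectedSeries, max_lag: int = 14) -> AcfResult:
    """Autocorrelation function up to ``max_lag`` sampling steps.

    Uses the standard biased estimator with the full-series mean,
    r_k = sum_t (x_t - xbar)(x_{t+k} - xbar) / sum_t (x_t - xbar)^2,
    under which the +/- z_0.975/sqrt(n) white-noise band applies.
    """
    _require_equidistant(series, "acf")
    if series.n < max_lag + 3:
        raise SeriesValidationError(
            f"need n >= max_lag + 3 (= {max_lag + 3}), got {series.n}")
    if np.std(series.values) == 0:
        raise ChronuriaError("acf undefined for a constant series")
    coeff = _sm_acf(series.values, nlags=max_lag, fft=False)
    return AcfResult(
        lags=np.arange(max_lag + 1),
        coefficients=coeff,
        conf_limit=float(stats.norm.ppf(0.975) / math.sqrt(series.n)),
    )


def interval_anova(
    series: CorrectedSeries,
    group_len: int = 8,
    partial_tail: str = "include",
) -> IntervalAnovaResult:
    """One-way ANOVA over consecutive non-overlapping blocks of the series.

    With 12-h sampling the default ``group_len=8`` groups the data into
    consecutive 4-day intervals; a significant F indicates systematic
    differences between the blocks, i.e. a multi-day pattern.  A trailing
    partial block is included when it has at least 2 values
    (``partial_tail="include"``, default) or dropped (``"drop"``).
    """
    _require_equidistant(series, "interval_anova")
    if partial_tail not in ("include", "drop"):
        raise ValueError("partial_tail must be 'include' or 'drop'")
    values = series.values
    groups = [values[i:i + group_len]
              for i in range(0, len(values), group_len)]
    if len(groups[-1]) < group_len:
        if partial_tail == "drop" or len(groups[-1]) < 2:
            groups = groups[:-1]
    if len(groups) < 2:
        raise SeriesValidationError(
            "interval_anova needs at least 2 complete groups")
    res = stats.f_oneway(*groups)
    n_total = sum(len(g) for g in groups)
    return IntervalAnovaResult(
        F=float(res.statistic),
        df_between=len(groups) - 1,
        df_within=n_total - len(groups),
        p=float(res.pvalue),
        group_means=np.array([g.mean() for g in groups]),
        group_sizes=np.array([len(g) for g in groups]),
    )


def _cosinor_design(t: np.ndarray, trial_period: float) -> np.ndarray:
    omega = 2.0 * math.pi / trial_period
    return np.column_stack(
        [np.ones_like(t), np.cos(omega * t), np.sin(omega * t)])


def cosinor_fit(series: CorrectedSeries, trial_period: float) -> CosinorFit:
    """Least-squares single-component cosinor fit at one trial period.

    Raises :class:`DegenerateDesignError` when the trial period resonates
    with the sampling grid so that the cosine/sine columns are collinear
    (condition number above 1e8), e.g. tau equal to the sampling interval.
    """
    if series.n < 4:
        raise SeriesValidationError("cosinor needs n >= 4")
    t = series.times
    y = series.values
    X = _cosinor_design(t, trial_period)
    if np.linalg.cond(X) > _COND_LIMIT:
        raise DegenerateDesignError(
            f"trial period {trial_period} h is degenerate on this "
            "sampling grid (collinear cosinor design)")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    mesor, beta, gamma = (float(c) for c in coef)
    amplitude = math.hypot(beta, gamma)
    # y = M + A cos(omega t - theta); peak at t = theta/omega
    theta = math.atan2(gamma, beta) % (2.0 * math.pi)
    if theta >= 2.0 * math.pi * (1.0 - 1e-15):  # -0.0 wrapped to 2*pi
        theta = 0.0
    acrophase = -math.degrees(theta)  # in (-360, 0]
    if acrophase == -0.0:
        acrophase = 0.0

    resid = y - X @ coef
    ss_total = float(np.sum((y - y.mean()) ** 2))
    ss_resid = float(np.sum(resid ** 2))
    ss_model = max(ss_total - ss_resid, 0.0)
    if ss_total == 0:
        raise ChronuriaError("cosinor undefined for a constant series")
    pr = ss_model / ss_total
    df_resid = series.n - 3
    if ss_resid <= 1e-14 * ss_total:  # numerically exact fit
        f_stat, p = math.inf, 0.0
    else:
        f_stat = (ss_model / 2.0) / (ss_resid / df_resid)
        p = float(stats.f.sf(f_stat, 2, df_resid))
    return CosinorFit(
        trial_period=float(trial_period),
        mesor=mesor,
        amplitude=amplitude,
        acrophase=acrophase,
        percent_rhythm=pr,
        p_zero_amplitude=p,
        f_zero_amplitude=f_stat,
        n=series.n,
    )


def ls_spectrum(series: CorrectedSeries,
                fundamental: float = 720.0) -> Spectrum:
    """Least-squares spectrum over the harmonic series of a fundamental.

    Fits a cosinor at every trial period tau_k = fundamental/k for
    k = 1..k_max, where k_max keeps tau_k at or above twice the sampling
    interval (Nyquist).  Harmonics whose design is degenerate on the grid
    (e.g. exactly the Nyquist period on equidistant midpoints) are omitted.
    """
    if series.n < 8:
        raise SeriesValidationError("ls_spectrum needs n >= 8")
    min_period = 2.0 * series.sampling_interval
    k_max = int(math.floor(fundamental / min_period + 1e-9))
    if k_max < 1:
        raise SeriesValidationError(
            "fundamental shorter than the Nyquist period")
    harmonics: list[int] = []
    fits: list[CosinorFit] = []
    for k in range(1, k_max + 1):
        try:
            fit = cosinor_fit(series, fundamental / k)
        except DegenerateDesignError:
            continue
        harmonics.append(k)
        fits.append(fit)
    if not fits:
        raise ChronuriaError("no admissible trial periods for this grid")
    return Spectrum(fundamental=float(fundamental),
                    harmonics=tuple(harmonics), fits=tuple(fits))


def subset_by_phase(series: CorrectedSeries, phase: str) -> CorrectedSeries:
    """Day-only or night-only subset, time axis preserved.

    The result is generally non-equidistant; cosinor fitting and the LS
    spectrum accept it, while :func:`acf` and :func:`interval_anova` reject
    it.
    """
    if phase not in ("day", "night"):
        raise ValueError("phase must be 'day' or 'night'")
    if len(set(series.phases)) < 2:
        raise SeriesValidationError("series must contain both phases")
    mask = series.phases == phase
    if not mask.any():
        raise SeriesValidationError(f"no {phase} intervals in series")
    return CorrectedSeries(
        subject_id=series.subject_id,
        unit=series.unit,
        times=series.times[mask],
        values=series.values[mask],
        phases=series.phases[mask],
        durations=None if series.durations is None
        else series.durations[mask],
    )


def pooling_attenuation(trial_period: float, pooling_window: float) -> float:
    """Amplitude attenuation of a cosine pooled over a finite window.

    Averaging a cosine of period tau over windows of length delta scales its
    amplitude by sin(omega*delta/2)/(omega*delta/2) with omega = 2*pi/tau
    (1 as delta -> 0).
    """
    x = math.pi * pooling_window / trial_period
    if x == 0:
        return 1.0
    return math.sin(x) / x
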