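"""Synthetic pooled-urine series with recorded ground truth.

The generator is phenomenological: a continuous excretion rate

    r(t) = baseline * phase_mult(t)
           * [1 + a_c * cos(2*pi*(t - t_peak)/24)]
           * [1 + a_s * cos(2*pi*t/tau_s + phi_s)]

(µg/h; ``phase_mult`` is ``day_multiplier`` during day windows and 1 at
night) is integrated *analytically* over each 12-h collection window to give
the excreted mass, so pooled values carry the exact
sin(omega*delta/2)/(omega*delta/2) amplitude attenuation of real pooled
sampling.  Volumes and creatinine concentrations are drawn per phase around
their own day/night means, and all noise is multiplicative, mean-preserving
lognormal — concentrations stay positive and the coefficient of variation is
scale-free.

Day/night excretion difference is modelled twice over: as the phase
multiplier and as the 24-h cosine.  Volume and creatinine get their own
day-night patterns, chosen so that the day/night signal is visible in the
corrected regimes but largely cancels in the raw concentration (mass and
volume rise together), where the slower ~90-h (circasemiseptan, about
half-weekly) component dominates instead.

Defaults emulate a month-long recording of one subject: ~63 alternating 12-h
intervals starting with a day collection at 08:00, day-dominant corrected
values with occasional inverted 24-h periods, higher night-sample
variability, and a 90-h periodic component.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
from scipy import stats

from .timeseries_io import PooledInterval, SeriesValidationError, UrineSeries

__all__ = ["SyntheticTruth", "generate", "make_fixture", "fixture_truth",
           "PROFILES"]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters of one simulated recording.

    Amplitude fractions are relative modulations in [0, 1); ``noise_cv`` is
    the lognormal CV of the excreted mass per (day, night) phase — night
    larger by default, reproducing the higher night-sample variability seen
    in 12-h pooled biomarker data.
    """

    baseline_rate: float = 17.0          # µg/h
    day_multiplier: float = 1.5          # excretion boost in day windows
    circadian: tuple[float, float] = (0.15, 14.0)   # (fraction, peak clock h)
    semiseptan: tuple[float, float, float] = (0.30, 90.0, -80.0)
    # (fraction, period h, phase deg in cos(2*pi*t/tau + phi))
    noise_cv: tuple[float, float] | float = (0.18, 0.30)   # (day, night)
    creatinine_day: float = 0.75         # mg/mL
    creatinine_night: float = 1.36       # overnight urine is more concentrated
    volume_day: float = 950.0            # mL per 12-h window
    volume_night: float = 525.0
    volume_cv: float = 0.12
    creatinine_cv: float = 0.10
    start_clock: float = 8.0             # clock time of the first day window
    inversion_target: float | None = None  # filled in by generate()
    seed: int = 0

    @property
    def noise_cv_pair(self) -> tuple[float, float]:
        cv = self.noise_cv
        return (cv, cv) if isinstance(cv, (int, float)) else tuple(cv)

    def validate(self) -> None:
        a_c, _ = self.circadian
        a_s, tau_s, _ = self.semiseptan
        if not (0 <= a_c < 1 and 0 <= a_s < 1):
            raise SeriesValidationError(
                "amplitude fractions must lie in [0, 1) or the excretion "
                "rate goes negative")
        if self.day_multiplier < 0:
            raise SeriesValidationError("day_multiplier must be >= 0")
        if tau_s <= 0:
            raise SeriesValidationError("semiseptan period must be > 0")
        for name in ("baseline_rate", "creatinine_day", "creatinine_night",
                     "volume_day", "volume_night"):
            if getattr(self, name) <= 0:
                raise SeriesValidationError(f"{name} must be > 0")
        if any(cv < 0 for cv in self.noise_cv_pair) or \
                self.volume_cv < 0 or self.creatinine_cv < 0:
            raise SeriesValidationError("CVs must be >= 0")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def _int_cos(a: float, b: float, t0: float, t1: float) -> float:
    """Integral of cos(a*t + b) over [t0, t1]."""
    if a == 0.0:
        return math.cos(b) * (t1 - t0)
    return (math.sin(a * t1 + b) - math.sin(a * t0 + b)) / a


def _window_integral(truth: SyntheticTruth, t0: float, t1: float) -> float:
    """Exact integral of the dimensionless rhythm modulation over a window.

    Integrand: (1 + a_c cos(w_c(t - tp))) (1 + a_s cos(w_s t + ps)).
    """
    a_c, peak_clock = truth.circadian
    a_s, tau_s, phi_deg = truth.semiseptan
    w_c = 2.0 * math.pi / 24.0
    w_s = 2.0 * math.pi / tau_s
    tp = (peak_clock - truth.start_clock) % 24.0
    ps = math.radians(phi_deg)
    total = (t1 - t0)
    total += a_c * _int_cos(w_c, -w_c * tp, t0, t1)
    total += a_s * _int_cos(w_s, ps, t0, t1)
    # product term: cos(x)cos(y) = [cos(x+y) + cos(x-y)] / 2
    total += 0.5 * a_c * a_s * (
        _int_cos(w_c + w_s, -w_c * tp + ps, t0, t1)
        + _int_cos(w_c - w_s, -w_c * tp - ps, t0, t1))
    return total


def _lognormal(rng: np.random.Generator, mean: float, cv: float,
               size: int) -> np.ndarray:
    """Mean-preserving lognormal draws with the given CV."""
    if cv == 0:
        return np.full(size, mean)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(math.log(mean) - sigma * sigma / 2.0, sigma, size)


def generate(
    truth: SyntheticTruth,
    n_intervals: int,
    subject_id: str = "synthetic",
    start_phase: str = "day",
    duration: float = 12.0,
) -> tuple[UrineSeries, SyntheticTruth]:
    """Simulate a pooled-interval recording; fully reproducible from seed.

    Returns the series together with a copy of ``truth`` whose
    ``inversion_target`` field holds the analytically expected fraction of
    inverted day-night pairs (volume-corrected regime) under the drawn
    parameters.
    """
    truth.validate()
    if n_intervals < 8:
        raise SeriesValidationError("generate needs n_intervals >= 8")
    if start_phase not in ("day", "night"):
        raise ValueError("start_phase must be 'day' or 'night'")
    rng = np.random.default_rng(truth.seed)

    starts = np.arange(n_intervals) * duration
    phases = np.array(
        [("day", "night")[(i + (start_phase == "night")) % 2]
         for i in range(n_intervals)], dtype=object)
    is_day = phases == "day"

    clean_mass = np.array([
        truth.baseline_rate
        * (truth.day_multiplier if is_day[i] else 1.0)
        * _window_integral(truth, starts[i], starts[i] + duration)
        for i in range(n_intervals)
    ])
    if np.any(clean_mass < 0):
        raise SeriesValidationError(
            "parameter combination produces a negative excretion rate")

    cv_day, cv_night = truth.noise_cv_pair
    noise = np.where(
        is_day,
        _lognormal(rng, 1.0, cv_day, n_intervals),
        _lognormal(rng, 1.0, cv_night, n_intervals),
    )
    mass = clean_mass * noise  # µg per window

    vol_mean = np.where(is_day, truth.volume_day, truth.volume_night)
    volumes = _lognormal(rng, 1.0, truth.volume_cv, n_intervals) * vol_mean
    creat_mean = np.where(is_day, truth.creatinine_day,
                          truth.creatinine_night)
    creat = _lognormal(rng, 1.0, truth.creatinine_cv,
                       n_intervals) * creat_mean

    ohdg_conc = mass * 1000.0 / volumes  # ng/mL
    intervals = tuple(
        PooledInterval(
            index=i,
            start_time=float(starts[i]),
            duration=duration,
            phase=str(phases[i]),
            volume=float(volumes[i]),
            ohdg_conc=float(ohdg_conc[i]),
            creatinine_conc=float(creat[i]),
        )
        for i in range(n_intervals)
    )
    series = UrineSeries(subject_id, intervals)
    return series, replace(
        truth,
        inversion_target=_expected_inversion(truth, clean_mass, is_day))


def _expected_inversion(truth: SyntheticTruth, clean_mass: np.ndarray,
                        is_day: np.ndarray) -> float:
    """P(night > day) per pair averaged over pairs, lognormal noise model.

    The log of the night/day mass ratio of a pair is normal with mean
    ln(m_night/m_day) and variance sigma_day^2 + sigma_night^2.
    """
    cv_day, cv_night = truth.noise_cv_pair
    var = math.log1p(cv_day ** 2) + math.log1p(cv_night ** 2)
    if var == 0:
        return float(np.mean([
            1.0 if clean_mass[i + 1] > clean_mass[i] else 0.0
            for i in range(len(clean_mass) - 1) if is_day[i]]))
    sd = math.sqrt(var)
    probs = [
        stats.norm.cdf(math.log(clean_mass[i + 1] / clean_mass[i]) / sd)
        for i in range(len(clean_mass) - 1)
        if is_day[i] and clean_mass[i] > 0 and clean_mass[i + 1] > 0
    ]
    return float(np.mean(probs))


# ---------------------------------------------------------------------------
# Packaged fixture profiles: two month-scale recordings with the structure
# the analysis pipeline assumes (day-dominant corrected values, inversions,
# ~90-h uncorrected component, noisier nights).

PROFILES: dict[str, tuple[SyntheticTruth, int]] = {
    "subject1_like": (
        SyntheticTruth(
            baseline_rate=17.0,
            day_multiplier=1.5,
            circadian=(0.15, 14.0),
            semiseptan=(0.30, 90.0, -80.0),
            noise_cv=(0.18, 0.30),
            seed=104729,
        ),
        63,
    ),
    "subject2_like": (
        SyntheticTruth(
            baseline_rate=10.0,
            day_multiplier=1.15,
            circadian=(0.10, 15.0),
            semiseptan=(0.18, 90.0, -60.0),
            noise_cv=(0.15, 0.25),
            creatinine_day=0.85,
            creatinine_night=1.11,
            volume_day=850.0,
            volume_night=650.0,
            seed=224737,
        ),
        55,
    ),
}


def fixture_truth(profile: str) -> SyntheticTruth:
    try:
        return PROFILES[profile][0]
    except KeyError:
        raise ValueError(
            f"unknown profile {profile!r}; choose from {list(PROFILES)}"
        ) from None


def make_fixture(profile: str) -> UrineSeries:
    """Deterministic packaged series (n = 63 or 55) for a named profile.

    The same series ship as CSV files under ``chronuria/data/``; this
    function regenerates them bit-identically from the recorded truth.
    """
    truth, n = PROFILES[profile][0], PROFILES[profile][1]
    series, _ = generate(truth, n, subject_id=profile)
    return series
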