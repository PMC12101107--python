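"""Data model and I/O for pooled-interval urine time series.

A *pooled interval* is a single urine collection accumulating all voids over a
fixed window (here nominally 12 h), yielding one averaged measurement per
window.  A subject's recording is an ordered, gap-free, equidistant sequence of
such intervals with strictly alternating day/night phase labels.

Two correction schemes convert raw analyte concentrations (ng/mL) into series
comparable across hydration states:

* creatinine correction — ng analyte per mg creatinine,
  ``value = ohdg_conc / creatinine_conc``;
* volume correction — average excretion rate in µg/h,
  ``value = ohdg_conc * volume / 1000 / duration``.

Corrected values are anchored at interval *midpoints*: a pooled value
estimates the window mean, and the midpoint is the unbiased time anchor for
phase estimation downstream.  The internal time axis is hours since the first
interval's start.

CSV dialects
------------
``raw`` dialect (one row per pooled interval)::

    subject,start_time_h,phase,volume_ml,ohdg_ng_per_ml,creatinine_mg_per_ml

``corrected`` dialect (pre-corrected values; ``duration_h`` optional, 12 h
default)::

    subject,start_time_h,phase,value,unit[,duration_h]

Unit strings are exactly ``raw_ng_per_ml``, ``ng_per_mg_creatinine`` and
``ug_per_h``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RAW_UNIT",
    "CREATININE_UNIT",
    "VOLUME_UNIT",
    "UNITS",
    "ChronuriaError",
    "SeriesFormatError",
    "SeriesValidationError",
    "DegenerateDesignError",
    "PooledInterval",
    "UrineSeries",
    "CorrectedSeries",
    "AggregatedSeries",
    "read_series",
    "write_series",
    "correct_creatinine",
    "correct_volume",
    "uncorrected",
    "aggregate",
]

RAW_UNIT = "raw_ng_per_ml"
CREATININE_UNIT = "ng_per_mg_creatinine"
VOLUME_UNIT = "ug_per_h"
UNITS = (RAW_UNIT, CREATININE_UNIT, VOLUME_UNIT)

PHASES = ("day", "night")

#: relative tolerance for "equidistant" grid checks (float time arithmetic)
_GRID_RTOL = 1e-9


class ChronuriaError(Exception):
    """Base class for all errors raised by this package."""


class SeriesFormatError(ChronuriaError):
    """A CSV file does not conform to a recognised dialect."""


class SeriesValidationError(ChronuriaError):
    """A series violates a structural invariant (grid, phases, signs)."""


class DegenerateDesignError(ChronuriaError):
    """A regression design is numerically rank-deficient."""


@dataclass(frozen=True)
class PooledInterval:
    """One 12-h pooled urine collection.

    Parameters
    ----------
    index : int
        0-based position within the series.
    start_time : float
        Hours since the start of the series.
    duration : float
        Collection window length in hours (nominally 12).
    phase : {"day", "night"}
        Whether the window covers the waking (~08:00-20:00) or sleeping
        (~20:00-08:00) half of the day.
    volume : float
        Total collected urine volume in mL.
    ohdg_conc : float
        8-OHdG concentration in ng/mL.
    creatinine_conc : float
        Creatinine concentration in mg/mL.
    """

    index: int
    start_time: float
    duration: float
    phase: str
    volume: float
    ohdg_conc: float
    creatinine_conc: float

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise SeriesValidationError(
                f"interval {self.index}: phase must be one of {PHASES}, "
                f"got {self.phase!r}"
            )
        if not self.duration > 0:
            raise SeriesValidationError(
                f"interval {self.index}: duration must be > 0"
            )
        if not self.volume > 0:
            raise SeriesValidationError(
                f"interval {self.index}: volume must be > 0, got {self.volume}"
            )
        if self.ohdg_conc < 0:
            raise SeriesValidationError(
                f"interval {self.index}: 8-OHdG concentration must be >= 0"
            )
        if not self.creatinine_conc > 0:
            raise SeriesValidationError(
                f"interval {self.index}: creatinine concentration must be > 0"
            )

    @property
    def midpoint(self) -> float:
        return self.start_time + self.duration / 2.0

    @property
    def ohdg_mass_ng(self) -> float:
        """Total excreted 8-OHdG in the window, ng."""
        return self.ohdg_conc * self.volume

    @property
    def creatinine_mass_mg(self) -> float:
        """Total excreted creatinine in the window, mg."""
        return self.creatinine_conc * self.volume


@dataclass(frozen=True)
class UrineSeries:
    """Ordered, equidistant, gap-free pooled-interval series for one subject."""

    subject_id: str
    intervals: tuple[PooledInterval, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals", tuple(self.intervals))
        iv = self.intervals
        for i in range(1, len(iv)):
            expected = iv[i - 1].start_time + iv[i - 1].duration
            if not np.isclose(iv[i].start_time, expected,
                              rtol=_GRID_RTOL, atol=1e-9):
                raise SeriesValidationError(
                    f"series {self.subject_id}: gap or overlap at interval {i} "
                    f"(start {iv[i].start_time}, expected {expected})"
                )
            if iv[i].phase == iv[i - 1].phase:
                raise SeriesValidationError(
                    f"series {self.subject_id}: phases do not alternate "
                    f"at interval {i} ({iv[i].phase!r} follows "
                    f"{iv[i - 1].phase!r})"
                )

    @property
    def n(self) -> int:
        return len(self.intervals)

    @property
    def start_times(self) -> np.ndarray:
        return np.array([iv.start_time for iv in self.intervals])

    @property
    def midpoints(self) -> np.ndarray:
        return np.array([iv.midpoint for iv in self.intervals])

    @property
    def phases(self) -> np.ndarray:
        return np.array([iv.phase for iv in self.intervals])

    @property
    def durations(self) -> np.ndarray:
        return np.array([iv.duration for iv in self.intervals])

    @property
    def volumes(self) -> np.ndarray:
        return np.array([iv.volume for iv in self.intervals])

    @property
    def ohdg_conc(self) -> np.ndarray:
        return np.array([iv.ohdg_conc for iv in self.intervals])

    @property
    def creatinine_conc(self) -> np.ndarray:
        return np.array([iv.creatinine_conc for iv in self.intervals])

    def slice(self, start: int, stop: int) -> "UrineSeries":
        """Contiguous sub-series with re-based indices (time axis kept)."""
        sub = [replace(iv, index=j) for j, iv in
               enumerate(self.intervals[start:stop])]
        return UrineSeries(self.subject_id, tuple(sub))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": self.subject_id,
                "start_time_h": self.start_times,
                "phase": self.phases,
                "volume_ml": self.volumes,
                "ohdg_ng_per_ml": self.ohdg_conc,
                "creatinine_mg_per_ml": self.creatinine_conc,
            }
        )


@dataclass(frozen=True)
class CorrectedSeries:
    """A numeric series in one unit regime, anchored at interval midpoints.

    ``unit`` determines admissible downstream operations: spectral analysis
    accepts any regime, while Table-1-style CV reporting requires a corrected
    (non-raw) regime.
    """

    subject_id: str
    unit: str
    times: np.ndarray
    values: np.ndarray
    phases: np.ndarray
    durations: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "phases", np.asarray(self.phases, dtype=object))
        if self.durations is not None:
            object.__setattr__(
                self, "durations", np.asarray(self.durations, dtype=float))
        if self.unit not in UNITS:
            raise SeriesValidationError(
                f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if not (len(self.times) == len(self.values) == len(self.phases)):
            raise SeriesValidationError(
                "times, values and phases must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise SeriesValidationError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise SeriesValidationError("corrected values must be >= 0")
        bad = set(self.phases) - set(PHASES)
        if bad:
            raise SeriesValidationError(f"unknown phase labels: {bad}")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def is_equidistant(self) -> bool:
        d = np.diff(self.times)
        return bool(len(d) == 0 or np.allclose(d, d[0], rtol=_GRID_RTOL))

    @property
    def sampling_interval(self) -> float:
        """Median spacing between consecutive anchors, hours."""
        return float(np.median(np.diff(self.times)))

    def slice(self, start: int, stop: int) -> "CorrectedSeries":
        return CorrectedSeries(
            self.subject_id, self.unit,
            self.times[start:stop], self.values[start:stop],
            self.phases[start:stop],
            None if self.durations is None else self.durations[start:stop],
        )

    def to_frame(self) -> pd.DataFrame:
        dur = (np.full(self.n, np.nan) if self.durations is None
               else self.durations)
        start = self.times - dur / 2.0
        return pd.DataFrame(
            {
                "subject": self.subject_id,
                "start_time_h": start,
                "phase": self.phases,
                "value": self.values,
                "unit": self.unit,
                "duration_h": dur,
            }
        )


@dataclass(frozen=True)
class AggregatedSeries:
    """Corrected values re-pooled over wider collection windows.

    One value per *complete* window; leftover tail intervals are dropped
    (a partial pool is not comparable to a complete one).
    """

    window: float
    unit: str
    values: np.ndarray
    times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))

    @property
    def n(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# CSV I/O

_RAW_COLS = ["subject", "start_time_h", "phase", "volume_ml",
             "ohdg_ng_per_ml", "creatinine_mg_per_ml"]
_CORR_COLS = ["subject", "start_time_h", "phase", "value", "unit"]


def _detect_dialect(columns: Iterable[str]) -> str:
    cols = set(columns)
    if set(_RAW_COLS) <= cols:
        return "raw"
    if set(_CORR_COLS) <= cols:
        return "corrected"
    for dialect, req in (("raw", _RAW_COLS), ("corrected", _CORR_COLS)):
        missing = [c for c in req if c not in cols]
        if len(missing) < len(req) - 1:
            raise SeriesFormatError(
                f"CSV close to {dialect!r} dialect but missing column(s) "
                f"{missing}")
    raise SeriesFormatError(
        f"CSV matches neither dialect; raw needs {_RAW_COLS}, "
        f"corrected needs {_CORR_COLS}")


def read_series(
    path: str | Path,
    dialect: Literal["auto", "raw", "corrected"] = "auto",
) -> UrineSeries | CorrectedSeries:
    """Read a pooled-interval series from CSV.

    The dialect is auto-detected from the header by default; pass
    ``dialect="raw"`` or ``"corrected"`` to override.  Returns a validated
    :class:`UrineSeries` (raw dialect) or :class:`CorrectedSeries`.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if dialect == "auto":
        dialect = _detect_dialect(df.columns)  # type: ignore[assignment]
    req = _RAW_COLS if dialect == "raw" else _CORR_COLS
    missing = [c for c in req if c not in df.columns]
    if missing:
        raise SeriesFormatError(
            f"{path}: missing required column(s) {missing} "
            f"for {dialect!r} dialect")
    subjects = df["subject"].unique()
    if len(subjects) != 1:
        raise SeriesFormatError(
            f"{path}: expected exactly one subject per file, got "
            f"{list(subjects)}")
    subject = str(subjects[0])

    if dialect == "raw":
        starts = df["start_time_h"].to_numpy(dtype=float)
        if len(starts) >= 2:
            durations = np.diff(starts)
            durations = np.append(durations, durations[-1])
        else:
            durations = np.full(len(starts), 12.0)
        if "duration_h" in df.columns:
            durations = df["duration_h"].to_numpy(dtype=float)
        intervals = tuple(
            PooledInterval(
                index=i,
                start_time=float(row.start_time_h),
                duration=float(durations[i]),
                phase=str(row.phase),
                volume=float(row.volume_ml),
                ohdg_conc=float(row.ohdg_ng_per_ml),
                creatinine_conc=float(row.creatinine_mg_per_ml),
            )
            for i, row in enumerate(df.itertuples(index=False))
        )
        return UrineSeries(subject, intervals)

    durations = (df["duration_h"].to_numpy(dtype=float)
                 if "duration_h" in df.columns
                 else np.full(len(df), 12.0))
    units = df["unit"].unique()
    if len(units) != 1:
        raise SeriesFormatError(f"{path}: mixed units {list(units)}")
    starts = df["start_time_h"].to_numpy(dtype=float)
    return CorrectedSeries(
        subject_id=subject,
        unit=str(units[0]),
        times=starts + durations / 2.0,
        values=df["value"].to_numpy(dtype=float),
        phases=df["phase"].to_numpy(dtype=object),
        durations=durations,
    )


def write_series(series: UrineSeries | CorrectedSeries,
                 path: str | Path) -> None:
    """Write a series in its natural CSV dialect (UTF-8, header row).

    Floats are written with ``repr`` round-trip precision, so
    write-then-read reproduces all fields bit-identically.
    """
    series.to_frame().to_csv(path, index=False,
                             float_format=lambda v: repr(float(v)))


# ---------------------------------------------------------------------------
# Correction schemes

def correct_creatinine(series: UrineSeries) -> CorrectedSeries:
    """Creatinine-corrected series: ng 8-OHdG per mg creatinine.

    Normalises for urinary flow and glomerular filtration rate by dividing
    the analyte concentration by the creatinine concentration from the same
    pooled sample.
    """
    return CorrectedSeries(
        subject_id=series.subject_id,
        unit=CREATININE_UNIT,
        times=series.midpoints,
        values=series.ohdg_conc / series.creatinine_conc,
        phases=series.phases,
        durations=series.durations,
    )


def correct_volume(series: UrineSeries) -> CorrectedSeries:
    """Volume-corrected series: µg 8-OHdG excreted per hour.

    ``value = conc[ng/mL] * volume[mL] / 1000 / duration[h]`` — total window
    mass (ng -> µg) divided by the collection duration; corrects for
    hydration status.
    """
    values = series.ohdg_conc * series.volumes / 1000.0 / series.durations
    return CorrectedSeries(
        subject_id=series.subject_id,
        unit=VOLUME_UNIT,
        times=series.midpoints,
        values=values,
        phases=series.phases,
        durations=series.durations,
    )


def uncorrected(series: UrineSeries) -> CorrectedSeries:
    """The raw concentration series (ng/mL) on the midpoint time axis."""
    return CorrectedSeries(
        subject_id=series.subject_id,
        unit=RAW_UNIT,
        times=series.midpoints,
        values=series.ohdg_conc,
        phases=series.phases,
        durations=series.durations,
    )


_CORRECTORS = {
    RAW_UNIT: uncorrected,
    CREATININE_UNIT: correct_creatinine,
    VOLUME_UNIT: correct_volume,
}


def correct(series: UrineSeries, unit: str) -> CorrectedSeries:
    """Dispatch to the correction scheme for ``unit``."""
    try:
        return _CORRECTORS[unit](series)
    except KeyError:
        raise SeriesValidationError(
            f"unknown unit {unit!r}; expected one of {UNITS}") from None


# ---------------------------------------------------------------------------
# Window aggregation

def aggregate(
    series: UrineSeries,
    window: float,
    unit: str = VOLUME_UNIT,
    method: Literal["mass", "mean"] = "mass",
) -> AggregatedSeries:
    """Re-pool consecutive intervals into wider collection windows.

    ``method="mass"`` (default) pools at the physical level, as if the urine
    of the window had been collected in one canister: summed 8-OHdG mass over
    summed creatinine mass (ng/mg regime), summed mass over window hours
    (µg/h regime), or summed mass over summed volume (raw regime).
    ``method="mean"`` averages the per-interval corrected values instead.
    Tail intervals that do not fill a complete window are dropped.
    """
    durations = series.durations
    step = durations[0]
    if not np.allclose(durations, step, rtol=_GRID_RTOL):
        raise SeriesValidationError(
            "aggregation requires uniform interval durations")
    ratio = window / step
    k = int(round(ratio))
    if k < 1 or not np.isclose(ratio, k, rtol=_GRID_RTOL):
        raise SeriesValidationError(
            f"window {window} h is not a multiple of the interval "
            f"duration {step} h")
    m = series.n // k
    if m == 0:
        raise SeriesValidationError(
            f"series too short for window {window} h")
    use = series.n - series.n % k

    ohdg_ng = (series.ohdg_conc * series.volumes)[:use].reshape(m, k)
    creat_mg = (series.creatinine_conc * series.volumes)[:use].reshape(m, k)
    vol = series.volumes[:use].reshape(m, k)
    starts = series.start_times[:use].reshape(m, k)[:, 0]
    times = starts + window / 2.0

    if method == "mean":
        per_interval = correct(series, unit).values[:use].reshape(m, k)
        values = per_interval.mean(axis=1)
    elif unit == CREATININE_UNIT:
        values = ohdg_ng.sum(axis=1) / creat_mg.sum(axis=1)
    elif unit == VOLUME_UNIT:
        values = ohdg_ng.sum(axis=1) / 1000.0 / window
    elif unit == RAW_UNIT:
        values = ohdg_ng.sum(axis=1) / vol.sum(axis=1)
    else:
        raise SeriesValidationError(f"unknown unit {unit!r}")
    return AggregatedSeries(window=window, unit=unit, values=values,
                            times=times)
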