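from pathlib import Path

import numpy as np
import pytest

from chronuria import (
    CorrectedSeries,
    PooledInterval,
    UrineSeries,
    VOLUME_UNIT,
    make_fixture,
)

DATA_DIR = Path(__file__).resolve().parents[1] / "src" / "chronuria" / "data"


def build_raw_series(
    n: int,
    start_phase: str = "day",
    volume: float = 600.0,
    ohdg: float | np.ndarray = 100.0,
    creatinine: float = 1.0,
    subject: str = "test",
) -> UrineSeries:
    ohdg = np.broadcast_to(np.asarray(ohdg, dtype=float), (n,))
    phases = ["day", "night"] if start_phase == "day" else ["night", "day"]
    return UrineSeries(subject, tuple(
        PooledInterval(i, 12.0 * i, 12.0, phases[i % 2],
                       volume, float(ohdg[i]), creatinine)
        for i in range(n)
    ))


def build_corrected(
    values,
    times=None,
    phases=None,
    unit: str = VOLUME_UNIT,
    subject: str = "test",
) -> CorrectedSeries:
    values = np.asarray(values, dtype=float)
    n = len(values)
    if times is None:
        times = 6.0 + 12.0 * np.arange(n)
    if phases is None:
        phases = np.array([("day", "night")[i % 2] for i in range(n)],
                          dtype=object)
    return CorrectedSeries(subject, unit, times, values, np.asarray(
        phases, dtype=object), durations=np.full(n, 12.0))


@pytest.fixture(scope="session")
def subject1():
    return make_fixture("subject1_like")


@pytest.fixture(scope="session")
def subject2():
    return make_fixture("subject2_like")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
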