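"""Shared fixtures: small synthetic series and CSV files, built at test time."""

from __future__ import annotations

from datetime import datetime, timedelta

import numpy as np
import pytest

from glucodiy.cgm_io import CGMSeries, GlucoseReading, series_from_arrays

T0 = datetime(2022, 1, 1, 0, 0, 0)


def make_series(values, start=T0, period_min=15.0, subject_id="test"):
    ts = [start + timedelta(minutes=period_min * i) for i in range(len(values))]
    return series_from_arrays(subject_id, ts, values)


def make_periodic_series(n_days=30, start=T0, period_min=15.0):
    """Noise-free strictly periodic trace with several daily harmonics.

    Deterministic day-over-day structure, so a forecaster that learns the
    pattern can beat persistence by a wide margin.
    """
    n = int(n_days * 24 * 60 / period_min)
    h = np.arange(n) * period_min / 60.0
    y = (140 + 35 * np.sin(2 * np.pi * h / 24)
         + 30 * np.sin(2 * np.pi * h / 6 + 1.0)
         + 15 * np.sin(2 * np.pi * h / 3 + 0.5))
    return make_series(y, start=start, period_min=period_min, subject_id="periodic")


@pytest.fixture(scope="session")
def periodic_series_30d():
    return make_periodic_series(30)


@pytest.fixture
def tiny_series():
    """12 readings over 3 h at 15-min spacing."""
    return make_series(np.linspace(100, 155, 12))


def insert_invalid(series: CGMSeries, index: int) -> CGMSeries:
    """Copy of series with the reading at ``index`` corrupted."""
    readings = list(series.readings)
    r = readings[index]
    readings[index] = GlucoseReading(r.timestamp, float("nan"), valid=False)
    return CGMSeries(subject_id=series.subject_id, readings=readings,
                     sampling_period=series.sampling_period)
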