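"""Reading, validating and writing CGM data in a LibreView-style CSV dialect.

The FreeStyle Libre export portal (LibreView) delivers interstitial glucose
histories as plain CSV with a device timestamp column and a glucose column in
mg/dl at a nominal 15-min sampling period.  The exact schema varies between
portal versions, so the column names, timestamp format and unit are carried
in a :class:`CSVDialect` and every field can be overridden.

Corrupted rows (unparseable timestamp, non-numeric or implausible glucose)
are *kept* as invalid readings rather than dropped: downstream block
segmentation treats them as sensor interruptions, which is what they almost
always are.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Plausibility window for a valid interstitial glucose reading, mg/dl.
#: FreeStyle-class sensors clip near 40-500; anything outside this wider
#: window is treated as a corrupted row.
GLUCOSE_MIN_MGDL = 20.0
GLUCOSE_MAX_MGDL = 600.0

MGDL_PER_MMOLL = 18.016


@dataclass(frozen=True)
class CSVDialect:
    """Column/format mapping for a CGM CSV export."""

    timestamp_col: str = "Device Timestamp"
    glucose_col: str = "Historic Glucose mg/dL"
    timestamp_format: str = "%d-%m-%Y %H:%M"
    skip_rows: int = 0          # extra preamble lines before the header row
    mmol: bool = False          # glucose column in mmol/L -> converted to mg/dl


@dataclass(frozen=True)
class GlucoseReading:
    """One timestamped interstitial glucose reading.

    ``valid`` is False for corrupted rows; such readings carry ``nan`` as
    value (and may carry an inferred timestamp) and force block breaks later.
    """

    timestamp: Optional[datetime]
    value: float
    valid: bool = True


@dataclass
class CGMSeries:
    """A subject's ordered interstitial glucose sequence.

    Readings are sorted by timestamp; among valid readings timestamps are
    unique (duplicates keep the first occurrence at read time).
    """

    subject_id: str
    readings: list[GlucoseReading] = field(default_factory=list)
    sampling_period: float = 15.0   # nominal, minutes
    unit: str = "mg/dl"

    def __post_init__(self) -> None:
        if self.sampling_period <= 0:
            raise ValueError("sampling_period must be positive")

    def __len__(self) -> int:
        return len(self.readings)

    @property
    def valid_readings(self) -> list[GlucoseReading]:
        return [r for r in self.readings if r.valid]

    def values(self) -> np.ndarray:
        """Valid glucose values, mg/dl, in time order."""
        return np.array([r.value for r in self.readings if r.valid], dtype=float)

    def timestamps(self) -> list[datetime]:
        """Timestamps of the valid readings, in time order."""
        return [r.timestamp for r in self.readings if r.valid]


@dataclass(frozen=True)
class SeriesValidationReport:
    """Eligibility of a series for personalized model generation.

    Inclusion requires at least one year of readings from a sensor with a
    15-min sampling period.
    """

    duration_days: float
    sampling_period_ok: bool
    duration_ok: bool
    n_valid_readings: int
    n_corrupted: int

    @property
    def eligible(self) -> bool:
        return self.sampling_period_ok and self.duration_ok


class EmptySeriesError(ValueError):
    """Raised when a file or series contains no parseable reading at all."""


def _parse_rows(df: pd.DataFrame, dialect: CSVDialect) -> list[GlucoseReading]:
    ts = pd.to_datetime(df[dialect.timestamp_col], format=dialect.timestamp_format, errors="coerce")
    val = pd.to_numeric(df[dialect.glucose_col], errors="coerce")
    if dialect.mmol:
        val = val * MGDL_PER_MMOLL
    readings: list[GlucoseReading] = []
    for t, v in zip(ts, val):
        t_ok = not pd.isna(t)
        v_ok = not np.isnan(v) and GLUCOSE_MIN_MGDL <= v <= GLUCOSE_MAX_MGDL
        readings.append(
            GlucoseReading(
                timestamp=t.to_pydatetime() if t_ok else None,
                value=float(v) if v_ok else float("nan"),
                valid=t_ok and v_ok,
            )
        )
    return readings


def read_cgm_csv(path: str | Path, dialect: CSVDialect | None = None, subject_id: str | None = None) -> CGMSeries:
    """Read a LibreView-style CSV into a sorted :class:`CGMSeries`.

    Rows with unparseable timestamps or non-numeric / implausible glucose are
    kept as invalid readings.  Duplicate timestamps keep the first occurrence.
    No row is silently dropped except exact timestamp duplicates, which are
    logged.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    EmptySeriesError
        If no row yields either a parseable timestamp or a numeric value.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dialect or CSVDialect()
    df = pd.read_csv(path, skiprows=dialect.skip_rows, dtype=str)
    for col in (dialect.timestamp_col, dialect.glucose_col):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path.name}; columns: {list(df.columns)}")
    readings = _parse_rows(df, dialect)
    if not any(r.valid for r in readings):
        raise EmptySeriesError(f"{path.name}: no parseable CGM rows")

    # Invalid rows without a timestamp inherit the last seen timestamp so that
    # a stable sort keeps them in their on-disk position relative to their
    # neighbours (they only matter as block breakers).
    sort_keys: list[datetime] = []
    last: Optional[datetime] = None
    for r in readings:
        if r.timestamp is not None:
            last = r.timestamp
        sort_keys.append(last if last is not None else datetime.min)
    order = sorted(range(len(readings)), key=lambda i: sort_keys[i])
    readings = [readings[i] for i in order]

    deduped: list[GlucoseReading] = []
    seen: set[datetime] = set()
    n_dup = 0
    for r in readings:
        if r.valid and r.timestamp in seen:
            n_dup += 1
            continue
        if r.valid:
            seen.add(r.timestamp)
        deduped.append(r)
    if n_dup:
        logger.info("%s: dropped %d duplicate-timestamp rows (kept first)", path.name, n_dup)

    return CGMSeries(subject_id=subject_id or path.stem, readings=deduped)


def validate_series(series: CGMSeries, required_period_min: float = 15.0, min_duration_days: float = 365.0) -> SeriesValidationReport:
    """Check the inclusion criteria: >= 1 year of data at a 15-min period.

    The sampling period is judged from the *median* gap between consecutive
    valid readings, rounded to the nearest minute, so occasional delays and
    interruptions do not disqualify an otherwise regular sensor.
    """
    valid = series.valid_readings
    if not valid:
        raise EmptySeriesError("series has no valid readings")
    t = series.timestamps()
    duration_days = (t[-1] - t[0]).total_seconds() / 86400.0
    if len(t) >= 2:
        gaps_min = np.array([(b - a).total_seconds() / 60.0 for a, b in zip(t[:-1], t[1:])])
        period_ok = round(float(np.median(gaps_min))) == round(required_period_min)
    else:
        period_ok = False
    return SeriesValidationReport(
        duration_days=duration_days,
        sampling_period_ok=period_ok,
        duration_ok=duration_days >= min_duration_days,
        n_valid_readings=len(valid),
        n_corrupted=len(series) - len(valid),
    )


def write_cgm_csv(series: CGMSeries, path: str | Path, dialect: CSVDialect | None = None) -> Path:
    """Write a series back to the LibreView-style dialect.

    Valid values are written to one decimal; invalid readings are written
    with an empty glucose field (re-read as invalid).  Reading the file back
    with the same dialect reproduces the series, timestamps to the precision
    of the dialect's format.
    """
    path = Path(path)
    dialect = dialect or CSVDialect()
    rows = []
    for r in series.readings:
        ts = r.timestamp.strftime(dialect.timestamp_format) if r.timestamp is not None else ""
        if r.valid:
            v = r.value / MGDL_PER_MMOLL if dialect.mmol else r.value
            rows.append((ts, f"{v:.1f}"))
        else:
            rows.append((ts, ""))
    df = pd.DataFrame(rows, columns=[dialect.timestamp_col, dialect.glucose_col])
    df.to_csv(path, index=False)
    return path


def series_from_arrays(subject_id: str, timestamps: Sequence[datetime], values: Sequence[float], sampling_period: float = 15.0) -> CGMSeries:
    """Build a series of valid readings from parallel arrays (helper)."""
    readings = [GlucoseReading(t, float(v)) for t, v in zip(timestamps, values)]
    return CGMSeries(subject_id=subject_id, readings=readings, sampling_period=sampling_period)


def drop_readings(series: CGMSeries, keep: Sequence[bool]) -> CGMSeries:
    """Return a copy of ``series`` keeping only readings where ``keep`` is True."""
    kept = [r for r, k in zip(series.readings, keep) if k]
    return replace(series, readings=kept)
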