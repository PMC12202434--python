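"""From a raw CGM series to normalized sequence-to-sequence instances.

Three stages:

1. **Block segmentation.**  The nominal sampling period is 15 min but real
   sensors drift; two readings are considered consecutive when the gap
   between them is *strictly below* twice the sampling period (a delay of up
   to 29:59 min is attributed to the next time slot; a gap of exactly 30:00
   starts a new block).  Corrupted readings always break blocks.  No
   interpolation is ever performed: blocks contain real readings only.

2. **Min–max normalization** with the subject's global minimum and maximum,
   mapping the personal glucose range onto [0, 1].  New readings outside the
   fitted range pass through the affine map unclamped.

3. **Sliding-window instance generation.**  Each block of length L yields
   ``max(0, L - (N + h) + 1)`` instances at step 1: an input window of N
   samples with two channels (normalized glucose and its first difference,
   zero-padded at the window head) and a target of the next h samples.
   Blocks shorter than N + h are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np

from glucodiy.cgm_io import CGMSeries, GlucoseReading


@dataclass(frozen=True)
class PreprocessConfig:
    """Windowing parameters.

    ``window_length`` of 96 samples is 24 h at a 15-min period — long enough
    to cover one full circadian cycle of basal regulation.
    ``prediction_steps`` is the prediction horizon divided by the sampling
    period: 2 for 30 min ahead, 4 for 60 min ahead.
    """

    window_length: int = 96
    prediction_steps: int = 2
    step: int = 1
    sampling_period: float = 15.0   # minutes

    def __post_init__(self) -> None:
        if self.window_length < 1 or self.prediction_steps < 1 or self.step < 1:
            raise ValueError("window_length, prediction_steps and step must be >= 1")

    @property
    def horizon_minutes(self) -> float:
        return self.prediction_steps * self.sampling_period


@dataclass
class DataBlock:
    """A maximal run of valid readings with no gap >= 2 x sampling period."""

    readings: list[GlucoseReading]

    @property
    def start_timestamp(self) -> datetime:
        return self.readings[0].timestamp

    @property
    def length(self) -> int:
        return len(self.readings)

    def values(self) -> np.ndarray:
        return np.array([r.value for r in self.readings], dtype=float)

    def timestamps(self) -> list[datetime]:
        return [r.timestamp for r in self.readings]


@dataclass(frozen=True)
class NormalizationParams:
    """Subject-wide min–max parameters, mg/dl."""

    s_min: float
    s_max: float

    def __post_init__(self) -> None:
        if not self.s_max > self.s_min:
            raise ValueError("degenerate range: s_max must exceed s_min")


@dataclass
class InstanceSet:
    """Sequence-to-sequence training instances.

    ``X`` has shape (n, N, 2): channel 0 is the normalized glucose window,
    channel 1 its first difference (leading element 0).  ``Y`` has shape
    (n, h) and is normalized.  Timestamps locate each instance in calendar
    time; ``source_block`` ties it back to its contiguous block.
    """

    X: np.ndarray
    Y: np.ndarray
    input_start: list[datetime] = field(default_factory=list)
    input_end: list[datetime] = field(default_factory=list)
    target_end: list[datetime] = field(default_factory=list)
    source_block: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    norm: NormalizationParams | None = None
    config: PreprocessConfig | None = None

    def __len__(self) -> int:
        return int(self.X.shape[0])

    def subset(self, idx) -> "InstanceSet":
        idx = np.asarray(idx, dtype=int)
        return InstanceSet(
            X=self.X[idx],
            Y=self.Y[idx],
            input_start=[self.input_start[i] for i in idx],
            input_end=[self.input_end[i] for i in idx],
            target_end=[self.target_end[i] for i in idx],
            source_block=self.source_block[idx],
            norm=self.norm,
            config=self.config,
        )


def segment_blocks(series: CGMSeries, config: PreprocessConfig | None = None) -> list[DataBlock]:
    """Partition the valid readings into maximal gap-free runs.

    A new block starts whenever the gap to the previous valid reading is
    >= 2 x sampling_period (i.e. a delay of 29:59 stays in the block, 30:00
    splits, at the default 15-min period), or whenever a corrupted reading
    interrupts the sequence.
    """
    config = config or PreprocessConfig()
    limit_s = 2.0 * config.sampling_period * 60.0
    blocks: list[DataBlock] = []
    current: list[GlucoseReading] = []
    prev: GlucoseReading | None = None
    for r in series.readings:
        if not r.valid:
            if current:
                blocks.append(DataBlock(current))
                current = []
            prev = None
            continue
        if prev is not None and (r.timestamp - prev.timestamp).total_seconds() >= limit_s:
            blocks.append(DataBlock(current))
            current = []
        current.append(r)
        prev = r
    if current:
        blocks.append(DataBlock(current))
    return blocks


def fit_normalization(series: CGMSeries) -> NormalizationParams:
    """Subject-wide min/max over all valid readings."""
    v = series.values()
    if v.size < 2 or float(v.min()) == float(v.max()):
        raise ValueError("need at least two distinct valid values to fit normalization")
    return NormalizationParams(s_min=float(v.min()), s_max=float(v.max()))


def normalize(value, params: NormalizationParams):
    """Affine map of mg/dl onto [0, 1] over the subject's range (unclamped)."""
    return (np.asarray(value, dtype=float) - params.s_min) / (params.s_max - params.s_min)


def denormalize(value, params: NormalizationParams):
    """Inverse of :func:`normalize`."""
    return np.asarray(value, dtype=float) * (params.s_max - params.s_min) + params.s_min


def instance_count(block_length: int, config: PreprocessConfig) -> int:
    """Closed-form instance count for one block."""
    usable = block_length - (config.window_length + config.prediction_steps) + 1
    if usable <= 0:
        return 0
    return (usable + config.step - 1) // config.step


def build_instances(blocks: list[DataBlock], params: NormalizationParams,
                    config: PreprocessConfig | None = None) -> InstanceSet:
    """Sweep each block into seq-to-seq instances.

    Instances never span block boundaries.  All blocks shorter than
    N + h yield nothing.
    """
    config = config or PreprocessConfig()
    N, h, step = config.window_length, config.prediction_steps, config.step
    xs, ys, blk = [], [], []
    t_in_start: list[datetime] = []
    t_in_end: list[datetime] = []
    t_tg_end: list[datetime] = []
    for b_id, block in enumerate(blocks):
        L = block.length
        if L < N + h:
            continue
        vn = normalize(block.values(), params)
        dn = np.diff(vn, prepend=vn[0])  # dn[0] = 0 by construction
        ts = block.timestamps()
        for i in range(0, L - (N + h) + 1, step):
            x = np.empty((N, 2))
            x[:, 0] = vn[i:i + N]
            x[:, 1] = dn[i:i + N]
            x[0, 1] = 0.0  # leading pad of the window's own first difference
            xs.append(x)
            ys.append(vn[i + N:i + N + h])
            blk.append(b_id)
            t_in_start.append(ts[i])
            t_in_end.append(ts[i + N - 1])
            t_tg_end.append(ts[i + N + h - 1])
    if xs:
        X = np.stack(xs)
        Y = np.stack(ys)
    else:
        X = np.empty((0, N, 2))
        Y = np.empty((0, h))
    return InstanceSet(X=X, Y=Y, input_start=t_in_start, input_end=t_in_end,
                       target_end=t_tg_end, source_block=np.array(blk, dtype=int),
                       norm=params, config=config)


def preprocess_series(series: CGMSeries, config: PreprocessConfig | None = None) -> InstanceSet:
    """Convenience pipeline: segment, fit normalization, build instances."""
    config = config or PreprocessConfig()
    blocks = segment_blocks(series, config)
    params = fit_normalization(series)
    return build_instances(blocks, params, config)
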