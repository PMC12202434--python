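"""Trimester-wise 4-fold cross-validation.

One year of a subject's data is split into four consecutive 3-month
(calendar-trimester) folds anchored at the oldest timestamp.  Each
cross-validation split trains on three trimesters and validates on the
held-out one, probing whether forecasting performance depends on the season
of the training data.  An instance belongs to a fold only if *all* of its
samples — input window and target — fall inside that trimester; instances
straddling a fold boundary are discarded.  Training folds are shuffled
(seeded) before feeding the models.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np

from glucodiy.preprocessing import InstanceSet

#: Fold label for instances that straddle a boundary (or fall past the year).
DISCARDED = 0

N_FOLDS = 4


def add_months(t: datetime, months: int) -> datetime:
    """Calendar-month addition with day-of-month clamping (Jan 31 + 1mo = Feb 28)."""
    month_index = t.month - 1 + months
    year = t.year + month_index // 12
    month = month_index % 12 + 1
    # clamp day to the target month's length
    for day in (t.day, 30, 29, 28):
        try:
            return t.replace(year=year, month=month, day=day)
        except ValueError:
            continue
    raise AssertionError("unreachable")


@dataclass
class FoldPartition:
    """Assignment of instances to trimester folds.

    ``fold_of_instance[i]`` is 1..4, or ``DISCARDED`` (0) for boundary
    instances.  ``fold_boundaries`` are the five timestamps
    t0, t0+3mo, ..., t0+12mo.
    """

    fold_boundaries: list[datetime]
    fold_of_instance: np.ndarray
    shuffle_seed: int | None = None

    def fold_ids(self, k: int) -> np.ndarray:
        """Instance indices of fold ``k`` (1..4)."""
        if not 1 <= k <= N_FOLDS:
            raise ValueError(f"fold index must be 1..{N_FOLDS}, got {k}")
        return np.flatnonzero(self.fold_of_instance == k)

    @property
    def discarded_ids(self) -> np.ndarray:
        return np.flatnonzero(self.fold_of_instance == DISCARDED)


def assign_folds(instances: InstanceSet, t0: datetime | None = None,
                 calendar_months: bool = True) -> FoldPartition:
    """Assign each instance to the trimester that contains its full span.

    ``t0`` defaults to the earliest instance input start (the oldest
    timestamp marks the beginning of the first fold).  With
    ``calendar_months=False`` trimesters are fixed 91.3125-day spans instead
    of calendar months.

    Raises if any instance starts before ``t0``.
    """
    if len(instances) == 0:
        raise ValueError("no instances to partition")
    if t0 is None:
        t0 = min(instances.input_start)
    if calendar_months:
        boundaries = [add_months(t0, 3 * k) for k in range(N_FOLDS + 1)]
    else:
        trimester = timedelta(days=365.25 / 4)
        boundaries = [t0 + k * trimester for k in range(N_FOLDS + 1)]

    fold = np.full(len(instances), DISCARDED, dtype=int)
    for i, (start, end) in enumerate(zip(instances.input_start, instances.target_end)):
        if start < t0:
            raise ValueError(f"instance {i} starts before t0 ({start} < {t0})")
        for k in range(1, N_FOLDS + 1):
            if boundaries[k - 1] <= start and end < boundaries[k]:
                fold[i] = k
                break
    return FoldPartition(fold_boundaries=boundaries, fold_of_instance=fold)


def make_split(partition: FoldPartition, validation_fold: int, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Train/validation instance ids for one cross-validation split.

    Train ids are the concatenation of the three other folds, shuffled with
    ``seed`` (deterministic); validation ids are the held-out fold in time
    order.
    """
    if not 1 <= validation_fold <= N_FOLDS:
        raise ValueError(f"validation_fold must be 1..{N_FOLDS}, got {validation_fold}")
    val_ids = partition.fold_ids(validation_fold)
    train_ids = np.concatenate([
        partition.fold_ids(k) for k in range(1, N_FOLDS + 1) if k != validation_fold
    ])
    rng = np.random.default_rng(seed)
    rng.shuffle(train_ids)
    partition.shuffle_seed = seed
    return train_ids, val_ids
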