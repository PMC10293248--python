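"""Outlier filtering, repetition averaging, and affected-arm selection.

Two complementary filters guard against pen-drop/lift artefacts:

* time-dependent series (velocity, force, coordinate sequences, the FFT
  input) drop the first and last 10% of datapoints;
* time-independent summaries (max/mean/std of the distance series) instead
  drop the 5% of values with the largest magnitude.

Both counts use floor(), which never over-removes.  The two feature values per
arm (repetitions) are combined by their arithmetic mean, and the arm whose
clipped distance series has the larger standard deviation — the stronger
affected side — supplies the motor features.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import DomainError, ValidationError
from .io import DrawingRecording
from .spiral import DistanceSeries

logger = logging.getLogger(__name__)

#: fixed processing order, applied by feature extraction and logged with runs
PIPELINE_ORDER = (
    "reversal check",
    "distance series",
    "clip 10% per end (time-dependent) / remove top 5% by magnitude (time-independent)",
    "per-repetition features",
    "repetition mean per arm",
    "affected-arm selection",
)

CLIP_FRACTION = 0.10
TOP_FRACTION = 0.05


def clip_time_series(series, fraction: float = CLIP_FRACTION):
    """Drop floor(fraction·n) samples from each end of an ordered series."""
    series = np.asarray(series)
    if series.size == 0:
        raise ValidationError("cannot clip an empty series")
    if not 0 <= fraction < 0.5:
        raise DomainError(f"clip fraction must be in [0, 0.5), got {fraction}")
    k = int(np.floor(fraction * len(series)))
    return series[k:len(series) - k] if k else series


def clip_recording(rec: DrawingRecording, fraction: float = CLIP_FRACTION) -> DrawingRecording:
    """Clip all four channels of a recording consistently."""
    return rec.replace_samples(
        t=clip_time_series(rec.t, fraction),
        x=clip_time_series(rec.x, fraction),
        y=clip_time_series(rec.y, fraction),
        force=clip_time_series(rec.force, fraction),
    )


def clip_distance_series(ds: DistanceSeries, fraction: float = CLIP_FRACTION) -> DistanceSeries:
    return DistanceSeries(t=clip_time_series(ds.t, fraction),
                          d=clip_time_series(ds.d, fraction))


def remove_top_values(values, fraction: float = TOP_FRACTION,
                      key: Callable | None = None):
    """Remove the floor(fraction·n) entries with the largest key as outliers.

    ``key`` defaults to the identity; pass ``np.abs`` to rank by magnitude
    (how the distance series is filtered before its time-independent
    summaries).  The surviving multiset is returned in original order.
    """
    values = np.asarray(values)
    if values.size == 0:
        raise ValidationError("cannot filter an empty collection")
    if not 0 <= fraction < 1:
        raise DomainError(f"outlier fraction must be in [0, 1), got {fraction}")
    k = int(np.floor(fraction * len(values)))
    if k == 0:
        return values
    ranks = values if key is None else key(values)
    # argpartition keeps ties deterministic enough: exactly k entries go
    drop = np.argpartition(ranks, len(values) - k)[len(values) - k:]
    keep = np.ones(len(values), dtype=bool)
    keep[drop] = False
    return values[keep]


def combine_repetitions(v1: float | None, v2: float | None) -> float:
    """Arithmetic mean of the two repetitions; pass-through if one is missing."""
    missing1 = v1 is None or (isinstance(v1, float) and np.isnan(v1))
    missing2 = v2 is None or (isinstance(v2, float) and np.isnan(v2))
    if missing1 and missing2:
        raise ValidationError("both repetition values are missing")
    if missing1:
        return float(v2)
    if missing2:
        return float(v1)
    return float((v1 + v2) / 2.0)


@dataclass(frozen=True)
class ArmSelection:
    """Outcome of affected-arm selection: the chosen side and both stds (cm)."""

    chosen: str
    left_std: float
    right_std: float


def _side_std(series_list: Sequence[DistanceSeries], fraction: float) -> float:
    """Repetition-averaged population std of the clipped distance series."""
    stds = [float(np.std(clip_time_series(ds.d, fraction))) for ds in series_list]
    if len(stds) == 1:
        return stds[0]
    return combine_repetitions(stds[0], stds[1])


def select_affected_arm(left: Sequence[DistanceSeries],
                        right: Sequence[DistanceSeries],
                        fraction: float = CLIP_FRACTION) -> ArmSelection:
    """Choose the stronger affected side: larger clipped distance-series std.

    Ties break to the right side (deterministic, logged).  A side with no
    repetitions loses by default with a warning.
    """
    if not left and not right:
        raise ValidationError("no distance series on either side")
    left_std = _side_std(left, fraction) if left else np.nan
    right_std = _side_std(right, fraction) if right else np.nan
    if not left:
        warnings.warn("left side has no repetitions; choosing right by default")
        chosen = "right"
    elif not right:
        warnings.warn("right side has no repetitions; choosing left by default")
        chosen = "left"
    elif left_std > right_std:
        chosen = "left"
    else:
        chosen = "right"  # ties go right
    logger.debug("arm selection: left_std=%.4g right_std=%.4g -> %s",
                 left_std, right_std, chosen)
    return ArmSelection(chosen=chosen, left_std=float(left_std), right_std=float(right_std))
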