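"""Missing-data handling and the non-overlapping temporal resolution ladder.

Minute-resolution series are reduced in a strictly non-overlapping manner
through a fixed ladder of resolutions from 1 min to 24 h. Before
reduction, missing values are treated with the short-gap rule: runs of
fewer than five consecutive missing minutes are linearly interpolated;
longer runs split the series into separate contiguous segments (temporal
adjacency across a long gap is never fabricated), and leading/trailing
missing runs are trimmed rather than extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RESOLUTION_LADDER",
    "fill_gaps",
    "segments_of",
    "downsample",
    "sufficiency_check",
    "longest_segment",
]

#: Allowed resolutions, in minutes: 1, 5, 10, 30 min; 1-6 h; 12 h; 24 h.
RESOLUTION_LADDER = (1, 5, 10, 30, 60, 120, 180, 240, 300, 360, 720, 1440)

#: Interior missing runs of at most this many points are interpolated;
#: longer runs (i.e. five or more) break the series into segments.
MAX_INTERP_RUN = 4

MIN_POINTS_TEST = 30   # stationarity tests
MIN_POINTS_FIT = 50    # ARIMA grid search


@dataclass(frozen=True)
class ResolutionSeries:
    """One patient x signal series at one rung of the ladder."""

    patient_id: str
    signal: str
    resolution: int               # minutes
    values: pd.Series             # indexed by timestamp, NaN allowed
    segment_id: np.ndarray        # per-value contiguous-block label

    def __post_init__(self) -> None:
        if self.resolution not in RESOLUTION_LADDER:
            raise ValueError(f"resolution {self.resolution} not on the ladder")


def _nan_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of each run of True in ``mask``."""
    runs = []
    i, n = 0, len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def fill_gaps(series: pd.Series, max_interp_run: int = MAX_INTERP_RUN) -> pd.DataFrame:
    """Apply the short-gap rule to a 1-min series.

    Interior missing runs of length <= ``max_interp_run`` are replaced by
    linear interpolation between the flanking observed values. Longer runs
    split the series into separate contiguous segments; leading and
    trailing missing runs are trimmed (no extrapolation). Observed values
    are never altered.

    Returns a frame with columns ``value`` and ``segment_id`` containing
    only the retained (observed or interpolated) points. An all-missing
    series yields an empty frame (zero segments).
    """
    values = series.to_numpy(dtype=float, copy=True)
    n = len(values)
    keep = np.ones(n, dtype=bool)
    mask = np.isnan(values)
    breaks = np.zeros(n, dtype=bool)   # True at first point after a long gap
    for start, length in _nan_runs(mask):
        interior = start > 0 and start + length < n
        if interior and length <= max_interp_run:
            left, right = values[start - 1], values[start + length]
            frac = np.arange(1, length + 1) / (length + 1)
            values[start:start + length] = left + frac * (right - left)
        else:
            keep[start:start + length] = False
            if start + length < n:
                breaks[start + length] = True
    segment_id = np.cumsum(breaks)[keep]
    if len(segment_id):
        segment_id = segment_id - segment_id[0]
    return pd.DataFrame(
        {"value": values[keep], "segment_id": segment_id},
        index=series.index[keep],
    )


def segments_of(filled: pd.DataFrame) -> list[pd.Series]:
    """Contiguous segments of a ``fill_gaps`` result, in temporal order."""
    return [seg["value"] for _, seg in filled.groupby("segment_id", sort=True)]


def downsample(series: pd.Series, target_resolution: int,
               source_resolution: int = 1, min_fraction: float = 0.5,
               allow_off_ladder: bool = False) -> pd.Series:
    """Non-overlapping block means at a coarser resolution.

    A block is emitted only when at least ``min_fraction`` of its expected
    points are present; otherwise it is NaN. The trailing partial block is
    dropped. The target must sit on the resolution ladder unless
    ``allow_off_ladder`` is set.
    """
    if target_resolution not in RESOLUTION_LADDER and not allow_off_ladder:
        raise ValueError(
            f"target resolution {target_resolution} not on the ladder "
            "(pass allow_off_ladder=True to override)")
    if target_resolution % source_resolution:
        raise ValueError("source resolution must divide target resolution")
    block = target_resolution // source_resolution
    vals = series.to_numpy(dtype=float)
    n_blocks = len(vals) // block
    if n_blocks == 0:
        return pd.Series(dtype=float)
    v = vals[: n_blocks * block].reshape(n_blocks, block)
    n_present = (~np.isnan(v)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        means = np.nanmean(v, axis=1)
    means[n_present < min_fraction * block] = np.nan
    index = series.index[: n_blocks * block : block]
    return pd.Series(means, index=index)


def sufficiency_check(series, min_points: int) -> bool:
    """Usable iff the non-NaN count reaches ``min_points`` (inclusive)."""
    vals = np.asarray(series, dtype=float)
    return int((~np.isnan(vals)).sum()) >= min_points


def longest_segment(series: pd.Series,
                    max_interp_run: int = MAX_INTERP_RUN) -> pd.Series:
    """Gap-rule preprocessing returning the longest contiguous segment.

    Convenience for downstream fits, which by default model the single
    longest uninterrupted stretch of data.
    """
    segs = segments_of(fill_gaps(series, max_interp_run))
    if not segs:
        return pd.Series(dtype=float)
    return max(segs, key=len)
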