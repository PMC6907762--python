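"""Gap-threshold sessionization of access-event streams into shifts.

A trainee's on-site event timestamps are split wherever the interval
between consecutive events is "long" (>= ``long_gap_threshold``); each
maximal run of events with strictly shorter internal gaps becomes one
candidate EHR-defined shift, spanning its first to its last event.
Refinement then merges candidates separated by less than ``merge_gap``
and discards candidates shorter than ``min_shift_duration``.

Because shift endpoints are observed events, the method can only
under-estimate, never over-estimate, time on duty; optional
``start_pad``/``end_pad`` allow a declared correction (default 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import SHIFT_COLUMNS, Source, empty_shift_frame, make_shift_frame

__all__ = [
    "SegmentationParams",
    "compute_intervals",
    "segment_shifts",
    "refine_shifts",
    "infer_all_shifts",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the sessionization heuristic (all minutes).

    long_gap_threshold
        An inter-event interval >= this value is a "long" gap and marks a
        shift boundary (strictly-less gaps stay within a shift).  Default
        300 min: longer than plausible on-shift idle time, shorter than any
        legal rest period.
    merge_gap
        Consecutive candidate shifts separated by a gap < this value are
        merged during refinement.  Must be < ``long_gap_threshold``.
    min_shift_duration
        Refined shifts shorter than this are discarded.
    start_pad / end_pad
        Minutes subtracted from each final start / added to each final end
        to compensate for pre-login and post-logout time (default 0).
    """

    long_gap_threshold: float = 300.0
    merge_gap: float = 60.0
    min_shift_duration: float = 60.0
    start_pad: float = 0.0
    end_pad: float = 0.0

    def __post_init__(self) -> None:
        if self.long_gap_threshold <= 0:
            raise ValueError("long_gap_threshold must be > 0")
        if not self.merge_gap < self.long_gap_threshold:
            raise ValueError("merge_gap must be < long_gap_threshold")
        if self.min_shift_duration < 0:
            raise ValueError("min_shift_duration must be >= 0")
        if self.start_pad < 0 or self.end_pad < 0:
            raise ValueError("pads must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentationParams":
        return cls(**d)

    def to_dict(self) -> dict:
        return {
            "long_gap_threshold": self.long_gap_threshold,
            "merge_gap": self.merge_gap,
            "min_shift_duration": self.min_shift_duration,
            "start_pad": self.start_pad,
            "end_pad": self.end_pad,
        }


def _as_times(events) -> pd.DatetimeIndex:
    if isinstance(events, pd.DataFrame):
        if events["trainee_id"].nunique() > 1:
            raise ValueError("expected events of a single trainee")
        return pd.DatetimeIndex(events["timestamp"])
    return pd.DatetimeIndex(events)


def compute_intervals(events) -> np.ndarray:
    """Minutes between subsequent timestamps of one trainee.

    Returns an array of length ``n_events - 1`` (empty for 0 or 1 events).
    Raises if the input is not sorted ascending — an upstream contract
    violation, not a condition to repair silently.
    """
    times = _as_times(events)
    if len(times) < 2:
        return np.empty(0, dtype=float)
    ns = times.asi8
    if (np.diff(ns) < 0).any():
        raise ValueError("events must be sorted ascending by timestamp")
    return np.diff(ns) / 60e9


def segment_shifts(events, params: SegmentationParams) -> pd.DataFrame:
    """Split one trainee's sorted events into candidate EHR-defined shifts.

    A boundary falls wherever the gap is >= ``params.long_gap_threshold``
    (a gap exactly equal to the threshold starts a new shift).  Each run's
    first event is the shift start and its last event the shift end, so a
    lone event yields a zero-length candidate, removed later by
    ``min_shift_duration``.
    """
    times = _as_times(events)
    if len(times) == 0:
        return empty_shift_frame()
    tid = events["trainee_id"].iloc[0] if isinstance(events, pd.DataFrame) else None
    gaps = compute_intervals(times)
    boundary = np.flatnonzero(gaps >= params.long_gap_threshold)
    starts = np.concatenate(([0], boundary + 1))
    ends = np.concatenate((boundary, [len(times) - 1]))
    return make_shift_frame(tid, times[starts], times[ends], Source.EHR_DEFINED)


def refine_shifts(candidates: pd.DataFrame, params: SegmentationParams) -> pd.DataFrame:
    """Merge close candidates, drop short ones, then apply pads.

    Consecutive candidates with an inter-shift gap < ``merge_gap`` are
    merged (applied before the duration filter, so short fragments can
    survive by merging); refined shifts with duration < ``min_shift_duration``
    are discarded.  With ``merge_gap = min_shift_duration = 0`` and zero
    pads this is the identity.
    """
    if candidates.empty:
        return candidates.copy()
    starts = candidates["start"].to_numpy()
    ends = candidates["end"].to_numpy()
    if len(candidates) > 1:
        if not (starts[1:] >= ends[:-1]).all():
            raise ValueError("candidate shifts must be sorted and non-overlapping")
        gap_min = (starts[1:] - ends[:-1]) / np.timedelta64(60, "s")
        group = np.concatenate(([0], np.cumsum(gap_min >= params.merge_gap)))
    else:
        group = np.zeros(1, dtype=int)
    first = np.flatnonzero(np.diff(group, prepend=-1))
    last = np.concatenate((first[1:] - 1, [len(group) - 1]))
    out = make_shift_frame(
        candidates["trainee_id"].to_numpy()[first],
        starts[first],
        ends[last],
        candidates["source"].iloc[0],
    )
    out = out[out["duration_min"] >= params.min_shift_duration]
    if params.start_pad or params.end_pad:
        out = make_shift_frame(
            out["trainee_id"].to_numpy(),
            out["start"] - pd.Timedelta(minutes=params.start_pad),
            out["end"] + pd.Timedelta(minutes=params.end_pad),
            Source.EHR_DEFINED,
        )
    return out.reset_index(drop=True)


def infer_all_shifts(events: pd.DataFrame, params: SegmentationParams) -> pd.DataFrame:
    """Run segment + refine per trainee over a multi-trainee event frame.

    Trainees are independent: the result equals concatenating per-trainee
    runs.  Deterministic for fixed input and parameters.
    """
    if events.empty:
        return empty_shift_frame()
    parts = []
    for _, grp in events.groupby("trainee_id", sort=True):
        parts.append(refine_shifts(segment_shifts(grp, params), params))
    out = pd.concat(parts, ignore_index=True)
    return out[SHIFT_COLUMNS]
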