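"""Shared vocabulary and frame schemas for the duty-hour pipeline.

The pipeline's canonical in-memory containers are :class:`pandas.DataFrame`
objects with fixed column sets.  The constants and validators here define
those contracts; every module reads and writes frames that satisfy them.

Frames
------
events
    ``trainee_id, timestamp, workstation_id, event_code`` — one EHR audit-log
    row per access event; ``timestamp`` is timezone-aware UTC.
shifts
    ``trainee_id, start, end, source, duration_min`` — one contiguous work
    interval; ``source`` distinguishes EHR-defined shifts (EDS) from
    self-reported shifts (SRS).
violations
    ``trainee_id, source, type, shift_start, shift_end, magnitude_min`` plus
    optional ``block_id, role`` — one duty-hour rule breach.
"""

from __future__ import annotations

import enum

import numpy as np
import pandas as pd

__all__ = [
    "Role",
    "Source",
    "ViolationType",
    "EVENT_COLUMNS",
    "SHIFT_COLUMNS",
    "VIOLATION_COLUMNS",
    "MINUTE",
    "make_shift_frame",
    "empty_shift_frame",
    "empty_violation_frame",
    "validate_shift_frame",
]


class Role(str, enum.Enum):
    """Trainee role within a scheduling block."""

    JR_FLC = "JR_FLC"  # junior front-line clinician (PGY-1 intern)
    SR_FLC = "SR_FLC"  # senior front-line clinician (PGY >= 2)
    SR_SUPRV = "SR_SUPRV"  # senior supervisory role (PGY >= 2)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Source(str, enum.Enum):
    """Provenance of a shift record."""

    EHR_DEFINED = "EHR_DEFINED"
    SELF_REPORTED = "SELF_REPORTED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class ViolationType(str, enum.Enum):
    DURATION = "DURATION"  # shift longer than the role's maximum
    INTERVAL = "INTERVAL"  # rest between consecutive shifts too short

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


EVENT_COLUMNS = ["trainee_id", "timestamp", "workstation_id", "event_code"]
SHIFT_COLUMNS = ["trainee_id", "start", "end", "source", "duration_min"]
VIOLATION_COLUMNS = [
    "trainee_id",
    "source",
    "type",
    "shift_start",
    "shift_end",
    "magnitude_min",
]

#: one minute as a numpy timedelta, for exact instant arithmetic
MINUTE = np.timedelta64(60, "s")


def make_shift_frame(
    trainee_id,
    start,
    end,
    source: str | Source,
) -> pd.DataFrame:
    """Assemble a shifts frame and fill in ``duration_min``.

    ``start``/``end`` must be timezone-aware (UTC) datetime-likes.
    """
    df = pd.DataFrame(
        {
            "trainee_id": trainee_id,
            "start": pd.DatetimeIndex(start),
            "end": pd.DatetimeIndex(end),
        }
    )
    df["source"] = str(source) if not isinstance(source, str) else source
    df["duration_min"] = (df["end"] - df["start"]).dt.total_seconds() / 60.0
    return df[SHIFT_COLUMNS]


def empty_shift_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trainee_id": pd.Series(dtype=object),
            "start": pd.Series(dtype="datetime64[ns, UTC]"),
            "end": pd.Series(dtype="datetime64[ns, UTC]"),
            "source": pd.Series(dtype=object),
            "duration_min": pd.Series(dtype=float),
        }
    )


def empty_violation_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trainee_id": pd.Series(dtype=object),
            "source": pd.Series(dtype=object),
            "type": pd.Series(dtype=object),
            "shift_start": pd.Series(dtype="datetime64[ns, UTC]"),
            "shift_end": pd.Series(dtype="datetime64[ns, UTC]"),
            "magnitude_min": pd.Series(dtype=float),
        }
    )


def validate_shift_frame(shifts: pd.DataFrame, *, context: str = "shifts") -> None:
    """Check the shift-frame invariants; raise ``ValueError`` on breach.

    Invariants: every shift has ``end > start``; within one
    ``(trainee_id, source)`` group shifts are sorted by ``start`` and
    pairwise non-overlapping.
    """
    missing = [c for c in SHIFT_COLUMNS if c not in shifts.columns]
    if missing:
        raise ValueError(f"{context}: missing columns {missing}")
    if shifts.empty:
        return
    bad = shifts["end"] <= shifts["start"]
    if bad.any():
        raise ValueError(
            f"{context}: {int(bad.sum())} shift(s) with end <= start "
            f"(first at index {shifts.index[bad][0]})"
        )
    for (tid, src), grp in shifts.groupby(["trainee_id", "source"], sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if len(grp) > 1:
            if not (starts[1:] >= starts[:-1]).all():
                raise ValueError(f"{context}: shifts of {tid}/{src} not sorted by start")
            if not (starts[1:] >= ends[:-1]).all():
                raise ValueError(f"{context}: overlapping shifts for {tid}/{src}")
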