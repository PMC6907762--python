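"""Duty-hour rule engine.

Evaluates the two duty-hour rules the study period's accreditation
standards imposed on every shift list, regardless of whether the shifts
came from EHR sessionization or from self-report:

DURATION — a shift strictly longer than the role's maximum (16 h for
    junior front-line clinicians; 24+4 h, applied as a single 28 h cap,
    for seniors) is a violation with magnitude = duration − maximum.
INTERVAL — rest between consecutive shifts below the requirement (8 h
    after shifts <= 16 h, 14 h after shifts > 16 h, boundaries per the
    printed rule: inclusive on the 16 h shift class, strict on the rest
    shortfall) is a violation attributed to the later shift, with
    magnitude = required rest − actual gap.

Weekly-hour and day-off rules are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .types import Role, ViolationType, empty_violation_frame

__all__ = [
    "DutyHourRules",
    "required_rest",
    "detect_duration_violations",
    "detect_interval_violations",
    "detect_violations",
    "excess_duration_stats",
]

_CARRY = ["block_id", "role", "rotation"]  # annotation columns passed through


def _default_max_duration() -> dict:
    return {
        Role.JR_FLC.value: 960.0,  # 16 h
        Role.SR_FLC.value: 1680.0,  # 24+4 h applied as one 28 h cap
        Role.SR_SUPRV.value: 1680.0,
    }


@dataclass(frozen=True)
class DutyHourRules:
    """Duty-hour rule parameters, all in minutes."""

    max_duration_by_role: Mapping[str, float] = field(default_factory=_default_max_duration)
    rest_short: float = 480.0  # required after shifts <= short_shift_cutoff
    rest_long: float = 840.0  # required after longer shifts
    short_shift_cutoff: float = 960.0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.max_duration_by_role.values()):
            raise ValueError("max durations must be > 0")
        if not (0 < self.rest_short < self.rest_long):
            raise ValueError("require 0 < rest_short < rest_long")
        if self.short_shift_cutoff <= 0:
            raise ValueError("short_shift_cutoff must be > 0")

    @classmethod
    def from_dict(cls, d: dict) -> "DutyHourRules":
        d = dict(d)
        if "max_duration_by_role" in d:
            d["max_duration_by_role"] = dict(d["max_duration_by_role"])
        return cls(**d)

    def to_dict(self) -> dict:
        return {
            "max_duration_by_role": dict(self.max_duration_by_role),
            "rest_short": self.rest_short,
            "rest_long": self.rest_long,
            "short_shift_cutoff": self.short_shift_cutoff,
        }


def required_rest(prior_shift_duration, rules: DutyHourRules):
    """Minutes of rest required after a shift of the given duration.

    Vectorized: accepts a scalar or array of durations.  The short class is
    inclusive (a shift of exactly the cutoff requires only the short rest).
    """
    d = np.asarray(prior_shift_duration, dtype=float)
    if (d <= 0).any():
        raise ValueError("shift duration must be > 0")
    out = np.where(d <= rules.short_shift_cutoff, rules.rest_short, rules.rest_long)
    return float(out) if np.isscalar(prior_shift_duration) else out


def _violation_rows(shifts: pd.DataFrame, mask: np.ndarray, vtype: ViolationType,
                    magnitude: np.ndarray) -> pd.DataFrame:
    sel = shifts[mask]
    out = pd.DataFrame(
        {
            "trainee_id": sel["trainee_id"].to_numpy(),
            "source": sel["source"].to_numpy(),
            "type": vtype.value,
            "shift_start": sel["start"].to_numpy(),
            "shift_end": sel["end"].to_numpy(),
            "magnitude_min": np.asarray(magnitude, dtype=float)[mask],
        }
    )
    for col in _CARRY:
        if col in shifts.columns:
            out[col] = sel[col].to_numpy()
    return out


def detect_duration_violations(
    shifts: pd.DataFrame, rules: DutyHourRules, role: str | Role | None = None
) -> pd.DataFrame:
    """One DURATION violation per shift strictly exceeding the role maximum.

    The role context comes either from the ``role`` argument (one role for
    the whole frame) or from a per-shift ``role`` column.  A shift of
    exactly the maximum is not a violation.
    """
    if shifts.empty:
        return empty_violation_frame()
    if role is not None:
        key = role.value if isinstance(role, Role) else str(role)
        if key not in rules.max_duration_by_role:
            raise KeyError(f"unknown role {key!r}")
        cap = np.full(len(shifts), rules.max_duration_by_role[key])
    else:
        if "role" not in shifts.columns:
            raise KeyError("no role argument and no 'role' column on shifts")
        unknown = set(shifts["role"]) - set(rules.max_duration_by_role)
        if unknown:
            raise KeyError(f"unknown role(s) {sorted(unknown)!r}")
        cap = shifts["role"].map(rules.max_duration_by_role).to_numpy(dtype=float)
    excess = shifts["duration_min"].to_numpy(dtype=float) - cap
    mask = excess > 0
    return _violation_rows(shifts, mask, ViolationType.DURATION, excess)


def detect_interval_violations(shifts: pd.DataFrame, rules: DutyHourRules) -> pd.DataFrame:
    """INTERVAL violations over consecutive shift pairs.

    Shifts are grouped by ``(trainee_id, source)``; within a group only
    adjacent pairs are examined (the input must be sorted and
    non-overlapping — overlap raises, as an upstream invariant breach).
    The violation is attached to the later shift of the pair, so any
    ``block_id`` annotation attributes it to that shift's block, including
    pairs that span a block boundary.
    """
    if shifts.empty:
        return empty_violation_frame()
    df = shifts
    keys = ["trainee_id", "source"] if "source" in df.columns else ["trainee_id"]
    grp = df.groupby(keys, sort=False)
    prev_end = grp["end"].shift(1)
    prev_dur = grp["duration_min"].shift(1)
    has_prev = prev_end.notna()
    gap = (df["start"] - prev_end).dt.total_seconds() / 60.0
    if (gap[has_prev] < 0).any():
        raise ValueError("overlapping or unsorted shifts within a trainee/source group")
    req = np.where(prev_dur.fillna(1.0) <= rules.short_shift_cutoff,
                   rules.rest_short, rules.rest_long)
    shortfall = req - gap.to_numpy()
    mask = (has_prev & (gap < req)).to_numpy()
    return _violation_rows(df, mask, ViolationType.INTERVAL, shortfall)


def detect_violations(shifts: pd.DataFrame, rules: DutyHourRules) -> pd.DataFrame:
    """Both rule checks over an annotated shift frame (needs a role column)."""
    parts = [detect_duration_violations(shifts, rules),
             detect_interval_violations(shifts, rules)]
    nonempty = [p for p in parts if not p.empty]
    if not nonempty:
        return empty_violation_frame()
    out = pd.concat(nonempty, ignore_index=True)
    return out.sort_values(
        ["trainee_id", "source", "shift_start", "type"], kind="mergesort"
    ).reset_index(drop=True)


def excess_duration_stats(duration_violations) -> dict:
    """Median and quartiles (linear-interpolation, type-7) of DURATION excess.

    Accepts a violation frame or a magnitude sequence; an empty input yields
    NaN statistics with ``n = 0`` rather than an exception.
    """
    if isinstance(duration_violations, pd.DataFrame):
        mags = duration_violations["magnitude_min"].to_numpy(dtype=float)
    else:
        mags = np.asarray(duration_violations, dtype=float)
    if mags.size == 0:
        return {"median": float("nan"), "q1": float("nan"), "q3": float("nan"), "n": 0}
    q1, med, q3 = np.percentile(mags, [25, 50, 75])
    return {"median": float(med), "q1": float(q1), "q3": float(q3), "n": int(mags.size)}
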