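"""Read, validate, and normalize the five pipeline input tables.

All readers return pandas frames satisfying the schemas in
:mod:`shiftaudit.types`.  Instants are normalized to UTC at ingest; local
wall-clock time is used only later, for block-date assignment.  Every
row-level rejection names the file and the (1-based, header-inclusive)
line number.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import EVENT_COLUMNS, SHIFT_COLUMNS, Role, Source, make_shift_frame

log = logging.getLogger(__name__)

__all__ = [
    "IngestError",
    "read_access_log",
    "read_workstations",
    "filter_onsite",
    "read_roster",
    "read_block_calendar",
    "read_self_reports",
    "write_table",
]


class IngestError(ValueError):
    """A validation failure in an input table, with file/line context."""


def _lines(idx) -> str:
    # +2: one for the header row, one for 0-based indexing
    shown = [str(i + 2) for i in list(idx)[:10]]
    more = "" if len(idx) <= 10 else f" (+{len(idx) - 10} more)"
    return ", ".join(shown) + more


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise IngestError(f"{path}: missing required column(s) {missing}")


def _parse_utc(series: pd.Series, path, column: str) -> pd.Series:
    parsed = pd.to_datetime(series, utc=True, format="ISO8601", errors="coerce")
    bad = parsed.isna() & series.notna()
    if bad.any():
        raise IngestError(
            f"{path}: unparseable {column} at line(s) {_lines(series.index[bad])}"
        )
    if parsed.isna().any():
        raise IngestError(
            f"{path}: empty {column} at line(s) {_lines(series.index[parsed.isna()])}"
        )
    # audit logs are second-resolution; normalize so downstream equality is exact
    return parsed.dt.floor("s")


def read_access_log(path) -> pd.DataFrame:
    """Read an EHR access-log export into a validated event frame.

    The returned frame is UTC-normalized, sorted ascending by
    ``(trainee_id, timestamp)``, and exact-duplicate rows are collapsed to
    one.  Near-duplicates (same second, different ``event_code``) are kept:
    the shift algorithm only consumes timestamps, and audit logs routinely
    repeat an instant across event classes.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        log.warning("%s: empty access log", path)
        return df.reindex(columns=EVENT_COLUMNS)
    _require_columns(df, EVENT_COLUMNS, path)
    df = df[EVENT_COLUMNS]
    df["timestamp"] = _parse_utc(df["timestamp"], path, "timestamp")
    n_raw = len(df)
    df = df.drop_duplicates()
    n_dedup = len(df)
    log.info("%s: %d rows, %d after de-duplication", path, n_raw, n_dedup)
    df = df.sort_values(["trainee_id", "timestamp"], kind="mergesort")
    return df.reset_index(drop=True)


def read_workstations(path) -> pd.DataFrame:
    """Read the workstation directory: ``workstation_id,onsite`` (0/1)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"workstation_id": str})
    _require_columns(df, ["workstation_id", "onsite"], path)
    onsite = pd.to_numeric(df["onsite"], errors="coerce")
    bad = ~onsite.isin([0, 1])
    if bad.any():
        raise IngestError(f"{path}: onsite must be 0/1 at line(s) {_lines(df.index[bad])}")
    dup = df["workstation_id"].duplicated()
    if dup.any():
        raise IngestError(
            f"{path}: duplicate workstation_id at line(s) {_lines(df.index[dup])}"
        )
    return pd.DataFrame(
        {"workstation_id": df["workstation_id"], "onsite": onsite.astype(bool)}
    )


def filter_onsite(events: pd.DataFrame, directory: pd.DataFrame) -> pd.DataFrame:
    """Drop events from known off-site workstations.

    Unknown workstation ids are retained (exclusion is evidence-based: only
    stations known to sit outside the hospital are removed); the count of
    unknown-station events is logged.  The filter is total and idempotent.
    """
    if events.empty:
        return events.copy()
    lookup = directory.set_index("workstation_id")["onsite"]
    onsite = events["workstation_id"].map(lookup)
    n_unknown = int(onsite.isna().sum())
    if n_unknown:
        log.warning("%d event(s) on workstations absent from the directory; retained",
                    n_unknown)
    keep = onsite.to_numpy(dtype=object) != False  # noqa: E712 - NaN (unknown) kept
    return events[keep].reset_index(drop=True)


_VALID_ROLES = {r.value for r in Role}


def read_roster(path) -> pd.DataFrame:
    """Read the trainee roster: one row per (trainee, block) assignment.

    Enforced invariants: role is one of JR_FLC/SR_FLC/SR_SUPRV; JR_FLC
    implies PGY 1 and SR_* implies PGY >= 2; at most one assignment per
    trainee per block.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"trainee_id": str, "block_id": str, "role": str,
                                  "rotation": str})
    _require_columns(df, ["trainee_id", "pgy", "block_id", "role", "rotation"], path)
    pgy = pd.to_numeric(df["pgy"], errors="coerce")
    if pgy.isna().any() or (pgy < 1).any() or (pgy != pgy.astype("Int64")).any():
        raise IngestError(
            f"{path}: pgy must be a positive integer at line(s) "
            f"{_lines(df.index[pgy.isna() | (pgy < 1)])}"
        )
    df["pgy"] = pgy.astype(int)
    bad_role = ~df["role"].isin(_VALID_ROLES)
    if bad_role.any():
        raise IngestError(f"{path}: unknown role at line(s) {_lines(df.index[bad_role])}")
    jr_bad = (df["role"] == Role.JR_FLC.value) & (df["pgy"] != 1)
    sr_bad = df["role"].isin([Role.SR_FLC.value, Role.SR_SUPRV.value]) & (df["pgy"] < 2)
    if jr_bad.any() or sr_bad.any():
        raise IngestError(
            f"{path}: role/pgy mismatch (JR_FLC requires pgy=1, SR_* requires pgy>=2) "
            f"at line(s) {_lines(df.index[jr_bad | sr_bad])}"
        )
    dup = df.duplicated(["trainee_id", "block_id"])
    if dup.any():
        raise IngestError(
            f"{path}: more than one assignment for a trainee-block at line(s) "
            f"{_lines(df.index[dup])}"
        )
    per_trainee_pgy = df.groupby("trainee_id")["pgy"].nunique()
    if (per_trainee_pgy > 1).any():
        bad = per_trainee_pgy[per_trainee_pgy > 1].index.tolist()
        raise IngestError(f"{path}: inconsistent pgy within trainee(s) {bad[:5]}")
    return df.reset_index(drop=True)


def read_block_calendar(path) -> pd.DataFrame:
    """Read the block calendar and verify it tiles the study interval.

    Blocks must be contiguous and non-overlapping:
    ``start[i+1] == start[i] + length_days[i]``.  The returned frame adds an
    exclusive ``end_date``.  Lengths other than the usual 28-day block (29
    for the year's first and last) are allowed but logged, since the engine
    itself is calendar-agnostic.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"block_id": str})
    _require_columns(df, ["block_id", "start_date", "length_days"], path)
    start = pd.to_datetime(df["start_date"], format="%Y-%m-%d", errors="coerce")
    if start.isna().any():
        raise IngestError(
            f"{path}: unparseable start_date at line(s) {_lines(df.index[start.isna()])}"
        )
    length = pd.to_numeric(df["length_days"], errors="coerce")
    if length.isna().any() or (length < 1).any():
        raise IngestError(f"{path}: length_days must be a positive integer")
    df = df.assign(start_date=start, length_days=length.astype(int))
    df = df.sort_values("start_date", kind="mergesort").reset_index(drop=True)
    df["end_date"] = df["start_date"] + pd.to_timedelta(df["length_days"], unit="D")
    gaps = df["start_date"].iloc[1:].to_numpy() != df["end_date"].iloc[:-1].to_numpy()
    if gaps.any():
        first = df["block_id"].iloc[1:][gaps].iloc[0]
        raise IngestError(f"{path}: calendar not contiguous at block {first}")
    interior = df["length_days"].iloc[1:-1]
    if len(df) > 2 and ((interior != 28).any() or
                        df["length_days"].iloc[[0, -1]].isin([28, 29]).sum() < 2):
        log.info("%s: calendar deviates from the usual 28-day (29 first/last) pattern",
                 path)
    return df


def _merge_overlaps(grp: pd.DataFrame) -> pd.DataFrame:
    rows = []
    cur_start, cur_end = None, None
    for start, end in zip(grp["start"], grp["end"]):
        if cur_start is None:
            cur_start, cur_end = start, end
        elif start < cur_end:  # overlap: extend
            cur_end = max(cur_end, end)
        else:
            rows.append((cur_start, cur_end))
            cur_start, cur_end = start, end
    rows.append((cur_start, cur_end))
    return pd.DataFrame(rows, columns=["start", "end"])


def read_self_reports(path, overlap_policy: str = "reject") -> pd.DataFrame:
    """Read the self-reported shift export into a SELF_REPORTED shift frame.

    Rows with ``end <= start`` are rejected row-wise (logged with line
    numbers).  Overlapping reports for one trainee follow ``overlap_policy``:
    ``"reject"`` (default) raises; ``"merge"`` unions the intervals.
    """
    if overlap_policy not in {"reject", "merge"}:
        raise ValueError(f"unknown overlap_policy {overlap_policy!r}")
    path = Path(path)
    df = pd.read_csv(path, dtype={"trainee_id": str})
    if df.empty:
        log.warning("%s: empty self-report export", path)
        from .types import empty_shift_frame

        return empty_shift_frame()
    _require_columns(df, ["trainee_id", "start", "end"], path)
    df["start"] = _parse_utc(df["start"], path, "start")
    df["end"] = _parse_utc(df["end"], path, "end")
    nonpos = df["end"] <= df["start"]
    if nonpos.any():
        log.warning("%s: rejected %d row(s) with end <= start at line(s) %s",
                    path, int(nonpos.sum()), _lines(df.index[nonpos]))
        df = df[~nonpos]
    df = df.sort_values(["trainee_id", "start"], kind="mergesort")
    overlap = (df.groupby("trainee_id")["start"].shift(-1) < df["end"]) & (
        df["trainee_id"] == df.groupby("trainee_id")["trainee_id"].shift(-1)
    )
    if overlap.any():
        if overlap_policy == "reject":
            raise IngestError(
                f"{path}: overlapping self-reported shifts at line(s) "
                f"{_lines(df.index[overlap])}"
            )
        df = (
            df.groupby("trainee_id", group_keys=True)
            .apply(_merge_overlaps, include_groups=False)
            .reset_index(level=0)
            .reset_index(drop=True)
        )
        log.warning("%s: merged overlapping self-reported shifts", path)
    out = make_shift_frame(
        df["trainee_id"].to_numpy(), df["start"], df["end"], Source.SELF_REPORTED
    )
    return out.reset_index(drop=True)


def write_table(df: pd.DataFrame, path) -> None:
    """Write a frame as CSV with ISO-8601 instants; round-trips via the readers."""
    out = df.copy()
    for col in out.columns:
        if isinstance(out[col].dtype, pd.DatetimeTZDtype):
            out[col] = out[col].dt.strftime("%Y-%m-%dT%H:%M:%S%z")
        elif out[col].dtype == "datetime64[ns]":
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
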