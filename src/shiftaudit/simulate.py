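"""Synthetic study generator with known ground truth.

Emulates a pediatric residency year: a block calendar (13 blocks, 28 days
each with 29-day first and last blocks), a trainee roster mixing junior
front-line, senior front-line, and senior supervisory roles, true shift
schedules from two templates (every-fourth-night call with ~17 shifts per
block; day-night with ~23), an EHR access-event process inside each true
shift, and a mechanistic biased self-reporting model (whole blocks left
unlogged, shifts omitted, over-long shifts truncated at the legal maximum,
plus rounding and jitter).

Every stage is deterministic for a fixed seed and emits ground-truth
labels, so pipeline recovery and the under-reporting analysis can be
tested without any real data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .compare import _block_boundaries_utc
from .types import Role, Source
from .violations import DutyHourRules, detect_violations

log = logging.getLogger(__name__)

__all__ = [
    "ScheduleTemplate",
    "Q4_CALL",
    "DAY_NIGHT",
    "RotationSpec",
    "EventProcessParams",
    "ReportingBehaviorModel",
    "SimulationProfile",
    "SimulationResult",
    "make_block_calendar",
    "make_workstations",
    "generate_cohort",
    "generate_true_shifts",
    "generate_events",
    "generate_self_reports",
    "true_shifts_as_eds",
    "ground_truth_violations",
    "simulate_study",
    "write_simulation",
]

_EVENT_CODES = np.array(["LOGIN", "CHART_REVIEW", "ORDER_ENTRY", "NOTE_EDIT"])
_DAY_MIN = 1440

#: minimum true rest between consecutive shifts (minutes).  Keeping this
#: above the default 300-min sessionization threshold guarantees the
#: separation condition, so gap-based inference can recover true shifts.
MIN_TRUE_GAP_MIN = 360


@dataclass(frozen=True)
class ScheduleTemplate:
    """A deterministic within-block shift pattern.

    ``slots(length_days)`` yields ``(day, start_min_of_day, base_duration_min,
    extendable)`` tuples; ``base_duration_min`` is ``None`` for call slots
    whose duration is referenced to the role's legal maximum at generation
    time.  ``extendable`` marks slots eligible for a duration overage.
    """

    name: str

    def slots(self, length_days: int) -> list[tuple[int, int, int | None, bool]]:
        out: list[tuple[int, int, int | None, bool]] = []
        if self.name == "Q4_CALL":
            horizon = min(length_days, 28)  # day 28 of a 29-day block stays free
            for d in range(0, horizon, 4):  # overnight call every 4th day, 07:00
                out.append((d, 420, None, True))
            for d in range(2, horizon, 4):  # 10 h day shifts
                out.append((d, 420, 600, False))
            for d in (3, 11, 19):
                if d < horizon:
                    out.append((d, 420, 600, False))
        elif self.name == "DAY_NIGHT":
            for d in range(length_days):
                if d % 6 == 5 or d >= 27:  # one day off per 6, none at block end
                    continue
                if d < 14:
                    out.append((d, 420, 840, True))  # 14 h days, 07:00
                else:
                    out.append((d, 1140, 840, True))  # 14 h nights, 19:00
        else:
            raise ValueError(f"unknown template {self.name!r}")
        return sorted(out)

    def expected_count(self, length_days: int) -> int:
        return len(self.slots(length_days))


Q4_CALL = ScheduleTemplate("Q4_CALL")
DAY_NIGHT = ScheduleTemplate("DAY_NIGHT")


@dataclass(frozen=True)
class RotationSpec:
    """A rotation: its role, schedule template, and violation seeding.

    p_overage
        Per extendable slot, the probability the true duration exceeds the
        role maximum; the excess is Exponential(``overage_mean_min``),
        rounded to whole minutes (min 1).
    p_early_start
        Per shift, the probability the shift begins early enough to leave
        only ``required rest − shortfall`` after the previous shift, with
        the shortfall uniform over ``early_shortfall_min``.
    """

    name: str
    role: str
    template: ScheduleTemplate
    p_overage: float = 0.0
    overage_mean_min: float = 52.4
    p_early_start: float = 0.0
    early_shortfall_min: tuple[float, float] = (30.0, 120.0)


@dataclass(frozen=True)
class EventProcessParams:
    """Within-shift EHR access-event process (homogeneous Poisson, capped).

    Intra-shift inter-event gaps are exponential with ``mean_gap_min``,
    clipped strictly below ``max_idle_gap_min`` (which must stay below the
    segmentation threshold for recovery experiments).  The first event lags
    the true start and the last leads the true end by independent
    exponential amounts (means in minutes; 0 means exactly at the
    boundary), so EHR-defined shifts can only under-estimate true ones.
    ``offsite_events_per_day`` adds off-duty noise events on off-site
    workstations, which the on-site filter should remove.
    """

    mean_gap_min: float = 30.0
    max_idle_gap_min: float = 240.0
    first_lag_mean_min: float = 5.0
    last_lead_mean_min: float = 5.0
    offsite_events_per_day: float = 0.3

    def __post_init__(self) -> None:
        if self.mean_gap_min <= 0 or self.max_idle_gap_min <= self.mean_gap_min:
            raise ValueError("require 0 < mean_gap_min < max_idle_gap_min")
        if min(self.first_lag_mean_min, self.last_lead_mean_min,
               self.offsite_events_per_day) < 0:
            raise ValueError("lag/lead/noise parameters must be >= 0")


@dataclass(frozen=True)
class ReportingBehaviorModel:
    """Mechanistic biased self-reporting.

    Each mechanism is independently switchable; the all-zero model
    reproduces the true shifts exactly.  Defaults emulate the observed
    reporting landscape: 22% of resident-blocks never logged, occasional
    omitted shifts, and a tendency to report over-long shifts exactly at
    the legal maximum, with quarter-hour rounding and small timing jitter.
    """

    p_block_unlogged: float = 0.22
    p_shift_omit: float = 0.03
    p_truncate_at_limit: float = 0.40
    rounding_min: float = 15.0
    jitter_sd_min: float = 8.0

    def __post_init__(self) -> None:
        for p in (self.p_block_unlogged, self.p_shift_omit, self.p_truncate_at_limit):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.rounding_min < 0 or self.jitter_sd_min < 0:
            raise ValueError("rounding/jitter must be >= 0")

    @classmethod
    def all_zero(cls) -> "ReportingBehaviorModel":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


def make_block_calendar(
    first_block_start: str = "2015-06-29",
    n_blocks: int = 13,
    interior_days: int = 28,
    cap_days: int = 29,
) -> pd.DataFrame:
    """Contiguous block calendar; first and last blocks carry the extra day."""
    lengths = [interior_days] * n_blocks
    if n_blocks >= 2:
        lengths[0] = lengths[-1] = cap_days
    starts, cur = [], pd.Timestamp(first_block_start)
    for ln in lengths:
        starts.append(cur)
        cur = cur + pd.Timedelta(days=ln)
    df = pd.DataFrame(
        {
            "block_id": [f"B{i + 1:02d}" for i in range(n_blocks)],
            "start_date": starts,
            "length_days": lengths,
        }
    )
    df["end_date"] = df["start_date"] + pd.to_timedelta(df["length_days"], unit="D")
    return df


def make_workstations(n_onsite: int = 40, n_offsite: int = 10) -> pd.DataFrame:
    ids = [f"WS_ON_{i:03d}" for i in range(n_onsite)] + [
        f"WS_OFF_{i:03d}" for i in range(n_offsite)
    ]
    return pd.DataFrame(
        {"workstation_id": ids, "onsite": [True] * n_onsite + [False] * n_offsite}
    )


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_cohort(
    n_trainees: int,
    role_mix: tuple[float, float, float],
    calendar: pd.DataFrame,
    seed,
    rotations: tuple[RotationSpec, ...],
    p_block_assigned: float = 1.0,
) -> pd.DataFrame:
    """Sample a roster: per-trainee PGY track, per-block role and rotation.

    ``role_mix`` gives the target (JR_FLC, SR_FLC, SR_SUPRV) proportions of
    resident-blocks; a trainee is an intern with probability ``role_mix[0]``
    and fills both senior roles block-by-block otherwise.  Each (trainee,
    block) pair is staffed on an inpatient rotation with probability
    ``p_block_assigned``.
    """
    mix = np.asarray(role_mix, dtype=float)
    if mix.min() < 0 or not np.isclose(mix.sum(), 1.0, atol=1e-6):
        raise ValueError("role_mix must be non-negative and sum to 1")
    by_role: dict[str, list[RotationSpec]] = {}
    for spec in rotations:
        by_role.setdefault(spec.role, []).append(spec)
    for r, p in zip((Role.JR_FLC, Role.SR_FLC, Role.SR_SUPRV), mix):
        if p > 0 and r.value not in by_role:
            raise ValueError(f"role_mix includes {r.value} but no rotation offers it")
    rng = _rng(seed)
    sr_flc_share = mix[1] / (mix[1] + mix[2]) if (mix[1] + mix[2]) > 0 else 0.0
    rows = []
    for i in range(n_trainees):
        tid = f"T{i + 1:04d}"
        is_jr = rng.random() < mix[0]
        pgy = 1 if is_jr else int(rng.choice([2, 3], p=[0.75, 0.25]))
        for blk in calendar["block_id"]:
            if rng.random() >= p_block_assigned:
                continue
            if is_jr:
                role = Role.JR_FLC.value
            else:
                role = (Role.SR_FLC.value if rng.random() < sr_flc_share
                        else Role.SR_SUPRV.value)
            choices = by_role[role]
            spec = choices[int(rng.integers(len(choices)))]
            rows.append((tid, pgy, blk, role, spec.name))
    return pd.DataFrame(rows, columns=["trainee_id", "pgy", "block_id", "role", "rotation"])


def generate_true_shifts(
    roster: pd.DataFrame,
    calendar: pd.DataFrame,
    rotations: tuple[RotationSpec, ...],
    rules: DutyHourRules,
    seed,
    tz: str = "America/New_York",
) -> pd.DataFrame:
    """Expand the roster into ground-truth shifts, seeding violations.

    Per block the shift count equals the template's deterministic count.
    Call slots draw a true duration of (role max − U{15..90}) minutes, or
    (role max + overage) with the rotation's overage probability; day-night
    slots extend the same way from their 14 h base.  Early starts shorten
    the preceding rest to seed interval violations.  Consecutive true
    shifts of one trainee always stay >= ``MIN_TRUE_GAP_MIN`` apart
    (overage is clipped and early-start shortfalls are bounded
    accordingly; a template whose base slots overlap raises), keeping
    every true rest period above the default sessionization threshold.
    """
    rng = _rng(seed)
    spec_by_name = {s.name: s for s in rotations}
    edges = _block_boundaries_utc(calendar, tz)
    edge_s = {b: int(t) // 10**9 for b, t in zip(calendar["block_id"], edges[:-1].asi8)}
    length_by_block = dict(zip(calendar["block_id"], calendar["length_days"]))
    order = {b: i for i, b in enumerate(calendar["block_id"])}

    out_rows = []
    roster_sorted = roster.assign(_ord=roster["block_id"].map(order)).sort_values(
        ["trainee_id", "_ord"]
    )
    for tid, tgrp in roster_sorted.groupby("trainee_id", sort=True):
        starts, durs, caps, specs, blocks, roles, rots = [], [], [], [], [], [], []
        for row in tgrp.itertuples(index=False):
            spec = spec_by_name[row.rotation]
            cap = rules.max_duration_by_role[row.role]
            base = edge_s[row.block_id]
            for day, smin, dmin, ext in spec.template.slots(length_by_block[row.block_id]):
                start_s = base + (day * _DAY_MIN + smin) * 60
                if dmin is None:  # call slot referenced to the legal cap
                    dur = cap - float(rng.integers(15, 91))
                else:
                    dur = float(dmin)
                if ext and rng.random() < spec.p_overage:
                    dur = cap + max(1.0, np.round(rng.exponential(spec.overage_mean_min)))
                starts.append(start_s)
                durs.append(dur)
                caps.append(cap)
                specs.append(spec)
                blocks.append(row.block_id)
                roles.append(row.role)
                rots.append(row.rotation)
        if not starts:
            continue
        starts = np.asarray(starts, dtype=np.int64)
        if (np.diff(starts) <= 0).any():
            raise ValueError(f"template slots overlap for trainee {tid}")
        durs = np.asarray(durs, dtype=float)
        # clip overage against the next start, preserving the separation gap
        for i in range(len(starts) - 1):
            max_dur = (starts[i + 1] - starts[i]) / 60.0 - MIN_TRUE_GAP_MIN
            if durs[i] > max_dur:
                durs[i] = float(np.floor(max_dur))
        # early starts: shorten the preceding rest below the requirement
        ends = starts + (durs * 60).astype(np.int64)
        for i in range(1, len(starts)):
            sp = specs[i]
            if sp.p_early_start and rng.random() < sp.p_early_start:
                req = rules.rest_short if durs[i - 1] <= rules.short_shift_cutoff \
                    else rules.rest_long
                lo, hi = sp.early_shortfall_min
                shortfall = float(rng.integers(int(lo), int(hi) + 1))
                new_start = ends[i - 1] + int((req - shortfall) * 60)
                if new_start < starts[i]:
                    starts[i] = new_start
                    ends[i] = new_start + int(durs[i] * 60)
        # block labels follow the attribution rule (block containing the
        # start instant); an early start can pull a shift into the block
        # before its scheduled one
        all_edges = edges.asi8 // 10**9
        block_ids = calendar["block_id"].to_numpy()
        idx = np.searchsorted(all_edges, starts, side="right") - 1
        blocks = block_ids[np.clip(idx, 0, len(block_ids) - 1)]
        out_rows.append(
            pd.DataFrame(
                {
                    "trainee_id": tid,
                    "block_id": blocks,
                    "role": roles,
                    "rotation": rots,
                    "start": pd.to_datetime(starts, unit="s", utc=True),
                    "end": pd.to_datetime(ends, unit="s", utc=True),
                    "duration_min": durs,
                }
            )
        )
    if not out_rows:
        return pd.DataFrame(
            columns=["trainee_id", "block_id", "role", "rotation", "start", "end",
                     "duration_min"]
        )
    return pd.concat(out_rows, ignore_index=True)


def _capped_exp_seconds(rng, mean_min: float, cap_s: int) -> int:
    if mean_min <= 0:
        return 0
    return min(int(round(rng.exponential(mean_min) * 60)), cap_s)


def generate_events(
    true_shifts: pd.DataFrame,
    event_params: EventProcessParams,
    workstations: pd.DataFrame,
    seed,
    study_start=None,
    study_end=None,
) -> pd.DataFrame:
    """Simulate the access log implied by the true shifts.

    Every true shift yields >= 2 events: the first within the lag of its
    start, the last within the lead of its end, intermediate gaps strictly
    below the idle cap.  Off-duty noise events land on off-site
    workstations only, so the on-site filter removes them.
    """
    rng = _rng(seed)
    onsite_ids = workstations.loc[workstations["onsite"], "workstation_id"].to_numpy()
    offsite_ids = workstations.loc[~workstations["onsite"], "workstation_id"].to_numpy()
    p = event_params
    cap_s = int(p.max_idle_gap_min * 60)
    tid_col, ts_col = [], []
    for row in true_shifts.itertuples(index=False):
        start_s = int(row.start.timestamp())
        end_s = int(row.end.timestamp())
        dur_s = end_s - start_s
        lag = _capped_exp_seconds(rng, p.first_lag_mean_min, dur_s // 4)
        lead = _capped_exp_seconds(rng, p.last_lead_mean_min, dur_s // 4)
        t0, t1 = start_s + lag, end_s - lead
        span = t1 - t0
        n_draw = int(span / (p.mean_gap_min * 60) * 1.6) + 8
        gaps = np.minimum(rng.exponential(p.mean_gap_min, n_draw),
                          p.max_idle_gap_min - 1.0 / 30.0)
        gaps_s = np.maximum((gaps * 60).round().astype(np.int64), 1)
        cum = np.cumsum(gaps_s)
        while cum[-1] < span:  # rare under-draw
            extra = np.maximum(
                (np.minimum(rng.exponential(p.mean_gap_min, n_draw),
                            p.max_idle_gap_min - 1.0 / 30.0) * 60).round().astype(np.int64),
                1,
            )
            cum = np.concatenate([cum, cum[-1] + np.cumsum(extra)])
        inner = t0 + cum[cum < span]
        times = np.concatenate(([t0], inner, [t1]))
        tid_col.append(np.repeat(row.trainee_id, len(times)))
        ts_col.append(times)
    # off-duty noise on off-site workstations
    if p.offsite_events_per_day > 0 and len(offsite_ids) and len(true_shifts):
        lo = int(pd.Timestamp(study_start).timestamp()) if study_start is not None \
            else int(true_shifts["start"].min().timestamp())
        hi = int(pd.Timestamp(study_end).timestamp()) if study_end is not None \
            else int(true_shifts["end"].max().timestamp())
        days = max((hi - lo) / 86400.0, 0.0)
        for tid, grp in true_shifts.groupby("trainee_id", sort=True):
            n_noise = rng.poisson(p.offsite_events_per_day * days)
            if n_noise == 0:
                continue
            ts = rng.integers(lo, hi, size=n_noise)
            s = grp["start"].astype("int64").to_numpy() // 10**9
            e = grp["end"].astype("int64").to_numpy() // 10**9
            idx = np.searchsorted(s, ts, side="right") - 1
            inside = (idx >= 0) & (ts < e[np.clip(idx, 0, None)])
            ts = ts[~inside]
            if len(ts):
                tid_col.append(np.repeat(tid, len(ts)))
                ts_col.append(np.sort(ts))
    if not tid_col:
        return pd.DataFrame(columns=["trainee_id", "timestamp", "workstation_id",
                                     "event_code"])
    tid_all = np.concatenate(tid_col)
    ts_all = np.concatenate(ts_col)
    n = len(ts_all)
    ws = np.empty(n, dtype=object)
    # noise rows were appended after shift rows; recover which are which by
    # membership in offsite blocks appended above
    n_shift_rows = sum(len(a) for a in ts_col[: len(true_shifts)])
    ws[:n_shift_rows] = rng.choice(onsite_ids, size=n_shift_rows)
    if n > n_shift_rows:
        ws[n_shift_rows:] = rng.choice(offsite_ids, size=n - n_shift_rows)
    codes = rng.choice(_EVENT_CODES, size=n)
    df = pd.DataFrame(
        {
            "trainee_id": tid_all,
            "timestamp": pd.to_datetime(ts_all, unit="s", utc=True),
            "workstation_id": ws,
            "event_code": codes,
        }
    )
    return df.sort_values(["trainee_id", "timestamp"], kind="mergesort").reset_index(drop=True)


def generate_self_reports(
    true_shifts: pd.DataFrame,
    behavior: ReportingBehaviorModel,
    rules: DutyHourRules,
    seed,
):
    """Apply the reporting-behavior model to the true shifts.

    Returns ``(self_reports, provenance)``: the report frame matches the
    self-report ingest schema; provenance records, per true shift, every
    transformation applied (block unlogged, omitted, truncated, and the
    reported interval), for use as a test oracle.  Mechanisms apply in
    order: block-level non-logging, per-shift omission, truncation at the
    role maximum, then jitter and rounding.
    """
    rng = _rng(seed)
    df = true_shifts.reset_index(drop=True)
    n = len(df)
    block_keys = df[["trainee_id", "block_id"]].drop_duplicates().sort_values(
        ["trainee_id", "block_id"]
    )
    unlogged_flags = {
        tuple(k): rng.random() < behavior.p_block_unlogged
        for k in block_keys.itertuples(index=False)
    }
    unlogged = np.array(
        [unlogged_flags[(t, b)] for t, b in zip(df["trainee_id"], df["block_id"])]
    )
    omitted = rng.random(n) < behavior.p_shift_omit
    cap = df["role"].map(rules.max_duration_by_role).to_numpy(dtype=float)
    over = df["duration_min"].to_numpy(dtype=float) > cap
    truncated = over & (rng.random(n) < behavior.p_truncate_at_limit)

    start_s = df["start"].astype("int64").to_numpy() // 10**9
    end_s = df["end"].astype("int64").to_numpy() // 10**9
    rep_start = start_s.astype(float)
    rep_end = np.where(truncated, start_s + cap * 60.0, end_s.astype(float))
    if behavior.jitter_sd_min > 0:
        rep_start = rep_start + rng.normal(0, behavior.jitter_sd_min * 60.0, n)
        rep_end = rep_end + rng.normal(0, behavior.jitter_sd_min * 60.0, n)
    if behavior.rounding_min > 0:
        r = behavior.rounding_min * 60.0
        rep_start = np.round(rep_start / r) * r
        rep_end = np.round(rep_end / r) * r
    rep_start = rep_start.round().astype(np.int64)
    rep_end = np.maximum(rep_end.round().astype(np.int64), rep_start + 60)
    reported = ~(unlogged | omitted)
    # repair any jitter-induced overlap within a trainee (true gaps are hours,
    # so this only fires at extreme jitter settings)
    rep_df = df[["trainee_id"]].assign(rs=rep_start, re=rep_end, keep=reported)
    for _, grp in rep_df[rep_df["keep"]].groupby("trainee_id", sort=False):
        rs, re_, idx = grp["rs"].to_numpy(), grp["re"].to_numpy(), grp.index.to_numpy()
        prev_end = np.maximum.accumulate(np.concatenate(([np.iinfo(np.int64).min], re_[:-1])))
        clip = rs < prev_end
        if clip.any():
            rep_df.loc[idx[clip], "rs"] = prev_end[clip]
    rep_start = rep_df["rs"].to_numpy()
    provenance = pd.DataFrame(
        {
            "trainee_id": df["trainee_id"],
            "block_id": df["block_id"],
            "role": df["role"],
            "rotation": df["rotation"],
            "true_start": df["start"],
            "true_end": df["end"],
            "block_unlogged": unlogged,
            "omitted": omitted & ~unlogged,
            "truncated": truncated,
            "reported": reported,
            "reported_start": pd.to_datetime(
                np.where(reported, rep_start, np.iinfo(np.int64).min), unit="s", utc=True
            ).where(pd.Series(reported)),
            "reported_end": pd.to_datetime(
                np.where(reported, rep_end, np.iinfo(np.int64).min), unit="s", utc=True
            ).where(pd.Series(reported)),
        }
    )
    from .types import make_shift_frame

    reports = make_shift_frame(
        df.loc[reported, "trainee_id"].to_numpy(),
        pd.to_datetime(rep_start[reported], unit="s", utc=True),
        pd.to_datetime(rep_end[reported], unit="s", utc=True),
        Source.SELF_REPORTED,
    ).sort_values(["trainee_id", "start"], kind="mergesort").reset_index(drop=True)
    return reports, provenance


def true_shifts_as_eds(true_shifts: pd.DataFrame) -> pd.DataFrame:
    """Ground-truth shifts relabelled as EHR-defined, for oracle analyses."""
    out = true_shifts[["trainee_id", "start", "end", "duration_min"]].copy()
    out["source"] = Source.EHR_DEFINED.value
    from .types import SHIFT_COLUMNS

    return out[SHIFT_COLUMNS].sort_values(
        ["trainee_id", "start"], kind="mergesort"
    ).reset_index(drop=True)


def ground_truth_violations(true_shifts: pd.DataFrame, rules: DutyHourRules) -> pd.DataFrame:
    """Duty-hour violations over the true shifts — the recovery oracle.

    Simply the rule engine applied to ground truth, tagged EHR_DEFINED so
    counts are directly comparable with EDV.
    """
    shifts = true_shifts.sort_values(["trainee_id", "start"], kind="mergesort").copy()
    shifts["source"] = Source.EHR_DEFINED.value
    return detect_violations(shifts, rules)


# --------------------------------------------------------------------------
# profiles and one-call orchestration
# --------------------------------------------------------------------------


def _study_scale_rotations() -> tuple[RotationSpec, ...]:
    # Overage probabilities are calibrated so the *EHR-measured* per-block
    # violation means by role land near 0.6 / 2.4 / 1.4 once the event
    # process (5 min mean first-lag/last-lead) trims small excesses; the
    # exponential overage mean 52.4 min puts the median excess near 36 min.
    return (
        RotationSpec("gen_wards", Role.JR_FLC.value, DAY_NIGHT,
                     p_overage=0.013, p_early_start=0.001),
        RotationSpec("icu_jr", Role.JR_FLC.value, DAY_NIGHT,
                     p_overage=0.024, p_early_start=0.003),
        RotationSpec("picu_call", Role.SR_FLC.value, Q4_CALL,
                     p_overage=0.50, p_early_start=0.0065),
        RotationSpec("nicu_call", Role.SR_FLC.value, Q4_CALL,
                     p_overage=0.30, p_early_start=0.0065),
        RotationSpec("wards_suprv", Role.SR_SUPRV.value, Q4_CALL,
                     p_overage=0.227, p_early_start=0.0065),
    )


@dataclass(frozen=True)
class SimulationProfile:
    """Bundle of generator settings for one simulated study."""

    n_trainees: int
    role_mix: tuple[float, float, float]
    p_block_assigned: float
    n_blocks: int
    first_block_start: str
    rotations: tuple[RotationSpec, ...]
    event_params: EventProcessParams = field(default_factory=EventProcessParams)
    behavior: ReportingBehaviorModel = field(default_factory=ReportingBehaviorModel)
    rules: DutyHourRules = field(default_factory=DutyHourRules)
    tz: str = "America/New_York"
    n_onsite_ws: int = 40
    n_offsite_ws: int = 10

    @classmethod
    def study_scale(cls, **overrides) -> "SimulationProfile":
        """The study-scale profile: 139 trainees over a 13-block year.

        Each trainee staffs an inpatient rotation in ~43% of blocks, giving
        ~771 resident-blocks with role shares near 44/40/16% and ~22% of
        blocks never logged.
        """
        base = cls(
            n_trainees=139,
            role_mix=(0.44, 0.3956, 0.1644),
            p_block_assigned=0.4267,
            n_blocks=13,
            first_block_start="2015-06-29",
            rotations=_study_scale_rotations(),
        )
        return replace(base, **overrides) if overrides else base

    @classmethod
    def minimal(cls, **overrides) -> "SimulationProfile":
        """A seconds-scale profile for tests: 12 trainees, 3 blocks."""
        base = cls(
            n_trainees=12,
            role_mix=(0.5, 0.3, 0.2),
            p_block_assigned=1.0,
            n_blocks=3,
            first_block_start="2015-06-29",
            rotations=_study_scale_rotations(),
            event_params=EventProcessParams(offsite_events_per_day=0.1),
        )
        return replace(base, **overrides) if overrides else base

    def calendar(self) -> pd.DataFrame:
        return make_block_calendar(self.first_block_start, self.n_blocks)


@dataclass
class SimulationResult:
    profile: SimulationProfile
    seed: int
    calendar: pd.DataFrame
    workstations: pd.DataFrame
    roster: pd.DataFrame
    true_shifts: pd.DataFrame
    events: pd.DataFrame
    self_reports: pd.DataFrame
    provenance: pd.DataFrame
    true_violations: pd.DataFrame


def simulate_study(
    profile: SimulationProfile, seed: int, with_events: bool = True
) -> SimulationResult:
    """Run every generator stage with independent child streams of ``seed``."""
    ss = np.random.SeedSequence(seed)
    s_cohort, s_shifts, s_events, s_reports = [np.random.default_rng(c)
                                               for c in ss.spawn(4)]
    calendar = profile.calendar()
    workstations = make_workstations(profile.n_onsite_ws, profile.n_offsite_ws)
    roster = generate_cohort(
        profile.n_trainees, profile.role_mix, calendar, s_cohort,
        profile.rotations, profile.p_block_assigned,
    )
    true_shifts = generate_true_shifts(
        roster, calendar, profile.rotations, profile.rules, s_shifts, profile.tz
    )
    if with_events:
        events = generate_events(
            true_shifts, profile.event_params, workstations, s_events,
            study_start=calendar["start_date"].iloc[0],
            study_end=calendar["end_date"].iloc[-1],
        )
    else:
        events = pd.DataFrame(columns=["trainee_id", "timestamp", "workstation_id",
                                       "event_code"])
    reports, provenance = generate_self_reports(
        true_shifts, profile.behavior, profile.rules, s_reports
    )
    truth_v = ground_truth_violations(true_shifts, profile.rules)
    return SimulationResult(
        profile, seed, calendar, workstations, roster, true_shifts, events,
        reports, provenance, truth_v,
    )


def write_simulation(result: SimulationResult, outdir) -> dict:
    """Write the five ingest CSVs plus ground-truth labels under ``truth/``."""
    from .ingest import write_table

    outdir = Path(outdir)
    truth = outdir / "truth"
    truth.mkdir(parents=True, exist_ok=True)
    paths = {
        "access_log": outdir / "access_log.csv",
        "workstations": outdir / "workstations.csv",
        "roster": outdir / "roster.csv",
        "blocks": outdir / "blocks.csv",
        "self_reports": outdir / "self_reports.csv",
        "true_shifts": truth / "true_shifts.csv",
        "true_violations": truth / "true_violations.csv",
        "report_provenance": truth / "report_provenance.csv",
    }
    write_table(result.events, paths["access_log"])
    ws = result.workstations.assign(onsite=result.workstations["onsite"].astype(int))
    write_table(ws, paths["workstations"])
    write_table(result.roster, paths["roster"])
    cal = result.calendar[["block_id", "start_date", "length_days"]]
    write_table(cal, paths["blocks"])
    write_table(result.self_reports, paths["self_reports"])
    write_table(result.true_shifts, paths["true_shifts"])
    write_table(result.true_violations, paths["true_violations"])
    write_table(result.provenance, paths["report_provenance"])
    return {k: str(v) for k, v in paths.items()}
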