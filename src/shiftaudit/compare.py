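"""Resident-block aggregation and EHR-vs-self-report comparison statistics.

A *resident-block* is one trainee on one rotation during one scheduling
block.  This module assigns shifts to blocks, tallies violations per
resident-block and source (EDV from EHR-defined shifts, SRV from
self-reported shifts), excludes blocks with no self-reported shifts from
paired analyses, and computes:

* the paired SRV − EDV distribution and its under/equal/over proportions,
* per-role means ± SEM with one-way ANOVA and Tukey-Kramer post-hoc tests,
* an OLS model of total violations on report source and role.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

from .violations import DutyHourRules
from .types import Role, Source, ViolationType

log = logging.getLogger(__name__)

__all__ = [
    "BlockAssignmentError",
    "AssignedShifts",
    "assign_blocks",
    "tally",
    "exclude_unlogged_blocks",
    "paired_difference",
    "RoleSummaryResult",
    "role_summary",
    "tukey_pairwise",
    "ModelFit",
    "fit_violation_model",
]

TALLY_COLUMNS = [
    "trainee_id", "block_id", "role", "rotation",
    "n_eds", "n_srs",
    "edv_duration", "edv_interval", "edv_total",
    "srv_duration", "srv_interval", "srv_total",
]


class BlockAssignmentError(ValueError):
    """A shift starts outside the block calendar."""


class AssignedShifts(NamedTuple):
    shifts: pd.DataFrame  # annotated with block_id, role, rotation
    excluded: pd.DataFrame  # shifts in trainee-blocks absent from the roster


def _block_boundaries_utc(calendar: pd.DataFrame, tz: str) -> pd.DatetimeIndex:
    """Local-midnight block boundaries as UTC instants (length n_blocks + 1)."""
    edges = pd.DatetimeIndex(
        list(calendar["start_date"]) + [calendar["end_date"].iloc[-1]]
    )
    return edges.tz_localize(tz, nonexistent="shift_forward", ambiguous=True).tz_convert("UTC")


def assign_blocks(
    shifts: pd.DataFrame,
    calendar: pd.DataFrame,
    roster: pd.DataFrame,
    tz: str = "America/New_York",
) -> AssignedShifts:
    """Annotate shifts with block_id, role, and rotation.

    A shift belongs to the block containing its *start* instant (blocks are
    half-open ``[start, next_start)`` in local wall-clock time), so a call
    shift starting on a block's last day counts in that block even though it
    ends in the next.  A start outside the calendar raises; a shift whose
    trainee has no roster assignment for that block is moved to the
    ``excluded`` frame with a warning.
    """
    if shifts.empty:
        ann = shifts.copy()
        for col in ("block_id", "role", "rotation"):
            ann[col] = pd.Series(dtype=object)
        return AssignedShifts(ann, ann.iloc[0:0].copy())
    edges = _block_boundaries_utc(calendar, tz)
    idx = np.searchsorted(edges.asi8, pd.DatetimeIndex(shifts["start"]).asi8, side="right") - 1
    bad = (idx < 0) | (idx >= len(calendar))
    if bad.any():
        offenders = shifts.loc[bad, ["trainee_id", "start"]].head(10)
        raise BlockAssignmentError(
            f"{int(bad.sum())} shift(s) start outside the block calendar; first:\n"
            f"{offenders.to_string(index=False)}"
        )
    ann = shifts.copy()
    ann["block_id"] = calendar["block_id"].to_numpy()[idx]
    ann = ann.merge(
        roster[["trainee_id", "block_id", "role", "rotation"]],
        on=["trainee_id", "block_id"],
        how="left",
    )
    missing = ann["role"].isna()
    excluded = ann[missing].reset_index(drop=True)
    if missing.any():
        nb = excluded.groupby(["trainee_id", "block_id"]).ngroups
        log.warning(
            "%d shift(s) in %d trainee-block(s) without a roster assignment; excluded",
            int(missing.sum()), nb,
        )
    return AssignedShifts(ann[~missing].reset_index(drop=True), excluded)


def tally(
    shifts: pd.DataFrame, violations: pd.DataFrame, roster: pd.DataFrame
) -> pd.DataFrame:
    """Per resident-block counts of shifts and violations, by source and type.

    One row per roster assignment, so blocks with zero shifts of a source
    carry zero counts (and ``n_srs = 0`` marks unlogged blocks).  Conservation
    holds: the column sums equal the shift/violation list lengths per
    source and type.
    """
    base = roster[["trainee_id", "block_id", "role", "rotation"]].copy()
    keys = ["trainee_id", "block_id"]

    def _counts(df, col_by, names):
        if df.empty:
            return pd.DataFrame(columns=keys + names)
        piv = (
            df.groupby(keys + [col_by], sort=False).size().unstack(col_by, fill_value=0)
        )
        piv = piv.reindex(columns=list(names.keys()), fill_value=0).rename(columns=names)
        return piv.reset_index()

    shift_counts = _counts(
        shifts, "source",
        {Source.EHR_DEFINED.value: "n_eds", Source.SELF_REPORTED.value: "n_srs"},
    )
    out = base.merge(shift_counts, on=keys, how="left")
    if not violations.empty:
        vio = violations.copy()
        vio["kind"] = (
            vio["source"].map({Source.EHR_DEFINED.value: "edv",
                               Source.SELF_REPORTED.value: "srv"})
            + "_" + vio["type"].str.lower()
        )
        unknown = vio["kind"].isna()
        if unknown.any():
            raise ValueError("violation with unknown source cannot be tallied")
        if "block_id" not in vio.columns or vio["block_id"].isna().any():
            raise ValueError("violations must carry block_id (run assign_blocks first)")
        vc = (
            vio.groupby(keys + ["kind"], sort=False).size().unstack("kind", fill_value=0)
        ).reset_index()
        out = out.merge(vc, on=keys, how="left")
    for col in ["n_eds", "n_srs", "edv_duration", "edv_interval",
                "srv_duration", "srv_interval"]:
        if col not in out.columns:
            out[col] = 0
        out[col] = out[col].fillna(0).astype(int)
    if not violations.empty:
        # a violation in a trainee-block absent from the roster has no row to land in
        vkeys = violations.groupby(keys).size()
        tkeys = set(map(tuple, base[keys].itertuples(index=False)))
        orphans = [k for k in vkeys.index if tuple(k) not in tkeys]
        if orphans:
            raise ValueError(f"violations reference unrostered trainee-blocks: {orphans[:5]}")
    out["edv_total"] = out["edv_duration"] + out["edv_interval"]
    out["srv_total"] = out["srv_duration"] + out["srv_interval"]
    return out[TALLY_COLUMNS].sort_values(["trainee_id", "block_id"]).reset_index(drop=True)


def exclude_unlogged_blocks(tallies: pd.DataFrame):
    """Drop resident-blocks with zero self-reported shifts.

    Returns ``(eligible, report)`` where the report counts excluded blocks
    and trainees (a trainee is "excluded" when none of their blocks remain)
    with percentages to one decimal.
    """
    unlogged = tallies["n_srs"] == 0
    eligible = tallies[~unlogged].reset_index(drop=True)
    all_tr = tallies["trainee_id"].nunique()
    kept_tr = eligible["trainee_id"].nunique()
    n_total = len(tallies)
    n_excl = int(unlogged.sum())
    report = {
        "n_blocks_total": n_total,
        "n_blocks_excluded": n_excl,
        "n_blocks_eligible": n_total - n_excl,
        "pct_blocks_excluded": round(100.0 * n_excl / n_total, 1) if n_total else 0.0,
        "n_trainees_total": all_tr,
        "n_trainees_excluded": all_tr - kept_tr,
        "pct_trainees_excluded": round(100.0 * (all_tr - kept_tr) / all_tr, 1)
        if all_tr else 0.0,
    }
    return eligible, report


def paired_difference(eligible_tallies: pd.DataFrame):
    """Block-by-block SRV − EDV differences and their sign proportions.

    Returns ``(paired, summary)``: the paired frame adds ``diff`` and a
    class column (UNDER for diff < 0 — the trainee reported fewer
    violations than the EHR shows — EQUAL, OVER for diff > 0); the summary
    carries counts and percentages (one decimal) that sum to 100.
    """
    paired = eligible_tallies.copy()
    paired["diff"] = paired["srv_total"] - paired["edv_total"]
    paired["cls"] = np.select(
        [paired["diff"] < 0, paired["diff"] > 0], ["UNDER", "OVER"], default="EQUAL"
    )
    n = len(paired)
    n_under = int((paired["cls"] == "UNDER").sum())
    n_over = int((paired["cls"] == "OVER").sum())
    n_equal = n - n_under - n_over
    summary = {
        "n_blocks": n,
        "n_under": n_under,
        "n_equal": n_equal,
        "n_over": n_over,
        "pct_under": round(100.0 * n_under / n, 1) if n else float("nan"),
        "pct_equal": round(100.0 * n_equal / n, 1) if n else float("nan"),
        "pct_over": round(100.0 * n_over / n, 1) if n else float("nan"),
    }
    return paired, summary


def diff_histogram(paired: pd.DataFrame) -> pd.DataFrame:
    """Integer-bin histogram of SRV − EDV, ready for CSV export."""
    counts = paired["diff"].value_counts().sort_index()
    return pd.DataFrame({"diff": counts.index.astype(int), "n_blocks": counts.to_numpy()})


# --------------------------------------------------------------------------
# role summaries: ANOVA + Tukey-Kramer
# --------------------------------------------------------------------------


@dataclass
class RoleSummaryResult:
    summary: pd.DataFrame  # role, n_blocks, mean, sem
    anova: dict | None  # F, p, df_between, df_within (None if inference skipped)
    tukey: pd.DataFrame | None  # pairwise Tukey-Kramer table
    warnings: list


def _anova_oneway(groups: list[np.ndarray]) -> dict:
    """One-way fixed-effects ANOVA from the sum-of-squares decomposition."""
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    n = ns.sum()
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    df_b, df_w = k - 1, int(n - k)
    ms_w = ss_within / df_w
    F = (ss_between / df_b) / ms_w if ms_w > 0 else (np.inf if ss_between > 0 else 0.0)
    p = float(sps.f.sf(F, df_b, df_w)) if np.isfinite(F) else 0.0
    return {"F": float(F), "p": p, "df_between": df_b, "df_within": df_w, "mse": ms_w}


def tukey_pairwise(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Tukey-Kramer pairwise comparisons with studentized-range p-values.

    Uses the exact studentized-range distribution (not a table
    approximation): for groups i, j with pooled within-group mean square
    MSE on nu degrees of freedom,
    ``q = |mean_i - mean_j| / sqrt(MSE/2 * (1/n_i + 1/n_j))`` and
    ``p_adj = P(Q_{k,nu} > q)``.
    """
    names = list(groups)
    arrays = [np.asarray(groups[nm], dtype=float) for nm in names]
    an = _anova_oneway(arrays)
    k, nu, mse = len(names), an["df_within"], an["mse"]
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = arrays[j].mean() - arrays[i].mean()
            se = np.sqrt(mse / 2.0 * (1.0 / len(arrays[i]) + 1.0 / len(arrays[j])))
            q = abs(diff) / se if se > 0 else np.inf
            p = float(sps.studentized_range.sf(q, k, nu)) if np.isfinite(q) else 0.0
            qcrit = sps.studentized_range.ppf(0.95, k, nu)
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "mean_diff": diff,
                    "se": se,
                    "q": q,
                    "p_adj": min(p, 1.0),
                    "ci_low": diff - qcrit * se,
                    "ci_high": diff + qcrit * se,
                }
            )
    return pd.DataFrame(rows)


def role_summary(
    tallies: pd.DataFrame, source: str | Source, metric: str = "total"
) -> RoleSummaryResult:
    """Mean ± SEM violations per resident-block by role, with inference.

    ``source`` selects the EDV or SRV columns; ``metric`` is ``"total"``,
    ``"duration"`` or ``"interval"``.  SEM uses the sample SD (n−1).  ANOVA
    and Tukey-Kramer run only when at least two roles have at least two
    blocks each; otherwise descriptives are returned with a warning.
    """
    src = source.value if isinstance(source, Source) else str(source)
    prefix = {"EHR_DEFINED": "edv", "SELF_REPORTED": "srv"}[src]
    col = f"{prefix}_{metric}"
    if col not in tallies.columns:
        raise KeyError(f"no tally column {col!r}")
    warnings: list[str] = []
    rows = []
    groups: dict[str, np.ndarray] = {}
    for role, grp in tallies.groupby("role", sort=True):
        vals = grp[col].to_numpy(dtype=float)
        n = len(vals)
        sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        rows.append({"role": role, "n_blocks": n, "mean": float(vals.mean()), "sem": sem})
        groups[role] = vals
    summary = pd.DataFrame(rows)
    usable = {r: v for r, v in groups.items() if len(v) >= 2}
    dropped = sorted(set(groups) - set(usable))
    if dropped:
        warnings.append(f"role(s) with <2 blocks skipped in inference: {dropped}")
    if len(usable) < 2:
        warnings.append("fewer than two roles with >=2 blocks; inference skipped")
        for w in warnings:
            log.warning(w)
        return RoleSummaryResult(summary, None, None, warnings)
    an = _anova_oneway(list(usable.values()))
    tk = tukey_pairwise(usable)
    for w in warnings:
        log.warning(w)
    return RoleSummaryResult(
        summary, {k: an[k] for k in ("F", "p", "df_between", "df_within")}, tk, warnings
    )


def rotation_summary(tallies: pd.DataFrame, source: str | Source,
                     metric: str = "total") -> pd.DataFrame:
    """Descriptive mean ± SEM per rotation (no inference)."""
    src = source.value if isinstance(source, Source) else str(source)
    col = {"EHR_DEFINED": "edv", "SELF_REPORTED": "srv"}[src] + f"_{metric}"
    grp = tallies.groupby(["rotation", "role"])[col]
    out = grp.agg(n_blocks="size", mean="mean",
                  sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan)
    return out.reset_index().sort_values("mean", ascending=False).reset_index(drop=True)


# --------------------------------------------------------------------------
# multivariable model
# --------------------------------------------------------------------------

MODEL_TERMS = ["intercept", "source_SRV", "role_SR_FLC", "role_SR_SUPRV"]


@dataclass
class ModelFit:
    """OLS fit of total violations on report source and role.

    ``table`` has one row per term (intercept; SRV-vs-EDV indicator; senior
    role indicators against the junior front-line reference) with the
    estimate, standard error, and two-sided t-based p-value.
    """

    table: pd.DataFrame
    nobs: int
    r_squared: float

    def coef(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "estimate"])

    def se(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "se"])

    def pvalue(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "p"])

    def to_dict(self) -> dict:
        return {
            "nobs": self.nobs,
            "r_squared": self.r_squared,
            "terms": {
                r["term"]: {"estimate": r["estimate"], "se": r["se"], "p": r["p"]}
                for r in self.table.to_dict("records")
            },
        }


def tallies_to_long(eligible_tallies: pd.DataFrame) -> pd.DataFrame:
    """Reshape tallies to one row per resident-block × source."""
    base = eligible_tallies[["trainee_id", "block_id", "role"]]
    long = pd.concat(
        [
            base.assign(source=Source.EHR_DEFINED.value,
                        total=eligible_tallies["edv_total"].to_numpy()),
            base.assign(source=Source.SELF_REPORTED.value,
                        total=eligible_tallies["srv_total"].to_numpy()),
        ],
        ignore_index=True,
    )
    return long


def fit_violation_model(eligible_tallies: pd.DataFrame) -> ModelFit:
    """OLS: total violations ~ intercept + source_SRV + role dummies.

    The paired tallies are stacked long (one row per block × source); the
    source coefficient is the adjusted mean SRV − EDV difference per
    resident-block, so systematic under-reporting shows up as a negative
    estimate.  Raises on a rank-deficient design (e.g. a single role
    present), naming the collinear column.
    """
    long = tallies_to_long(eligible_tallies)
    X = pd.DataFrame(
        {
            "intercept": 1.0,
            "source_SRV": (long["source"] == Source.SELF_REPORTED.value).astype(float),
            "role_SR_FLC": (long["role"] == Role.SR_FLC.value).astype(float),
            "role_SR_SUPRV": (long["role"] == Role.SR_SUPRV.value).astype(float),
        }
    )
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the offender: a column with no variation, or one linearly
        # dependent on the others
        for col in X.columns[1:]:
            if X[col].nunique() == 1:
                raise ValueError(f"design matrix rank-deficient: column {col!r} is constant")
        raise ValueError("design matrix rank-deficient: role columns are collinear")
    res = sm.OLS(long["total"].to_numpy(dtype=float), X).fit()
    table = pd.DataFrame(
        {
            "term": MODEL_TERMS,
            "estimate": [res.params[t] for t in MODEL_TERMS],
            "se": [res.bse[t] for t in MODEL_TERMS],
            "p": [res.pvalues[t] for t in MODEL_TERMS],
        }
    )
    return ModelFit(table=table, nobs=int(res.nobs), r_squared=float(res.rsquared))
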