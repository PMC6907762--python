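"""Block assignment, tallies, paired differences, and inference."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from shiftaudit.compare import (
    BlockAssignmentError,
    assign_blocks,
    diff_histogram,
    exclude_unlogged_blocks,
    fit_violation_model,
    paired_difference,
    role_summary,
    tallies_to_long,
    tally,
    tukey_pairwise,
)
from shiftaudit.simulate import make_block_calendar
from shiftaudit.types import Source, make_shift_frame
from shiftaudit.violations import DutyHourRules, detect_violations


def roster_frame(rows):
    return pd.DataFrame(rows, columns=["trainee_id", "pgy", "block_id", "role", "rotation"])


@pytest.fixture(scope="module")
def calendar():
    return make_block_calendar("2015-06-29", 13)


@pytest.fixture(scope="module")
def roster(calendar):
    rows = []
    for tid, pgy, role in (("T1", 1, "JR_FLC"), ("T2", 2, "SR_FLC"), ("T3", 3, "SR_SUPRV")):
        for blk in calendar["block_id"]:
            rows.append((tid, pgy, blk, role, "wards"))
    return roster_frame(rows)


def shift(trainee, start_utc, hours, source=Source.EHR_DEFINED):
    start = pd.DatetimeIndex([pd.Timestamp(start_utc)])
    return make_shift_frame(trainee, start, start + pd.Timedelta(hours=hours), source)


class TestAssignBlocks:
    def test_late_start_counts_in_earlier_block(self, calendar, roster):
        # 23:00 local on B01's last day (2015-07-27) -> 03:00 UTC next day
        s = shift("T1", "2015-07-28T03:00:00Z", 28)
        out, _ = assign_blocks(s, calendar, roster)
        assert out["block_id"].tolist() == ["B01"]

    def test_block_first_midnight_belongs_to_block(self, calendar, roster):
        # B02 starts 2015-07-28 local midnight = 04:00 UTC (EDT)
        s = shift("T1", "2015-07-28T04:00:00Z", 12)
        out, _ = assign_blocks(s, calendar, roster)
        assert out["block_id"].tolist() == ["B02"]

    def test_matches_linear_scan_oracle(self, calendar, roster):
        rng = np.random.default_rng(3)
        days = rng.integers(0, 366, size=80)
        starts = pd.DatetimeIndex(
            [pd.Timestamp("2015-06-29T12:00:00").tz_localize("America/New_York")
             + pd.Timedelta(days=int(d)) for d in days]
        ).tz_convert("UTC")
        shifts = make_shift_frame(
            "T1", starts, starts + pd.Timedelta(hours=8), Source.EHR_DEFINED
        ).sort_values("start").reset_index(drop=True)
        shifts = shifts.drop_duplicates("start").reset_index(drop=True)
        out, _ = assign_blocks(shifts, calendar, roster)
        for s, got in zip(out["start"], out["block_id"]):
            local_date = s.tz_convert("America/New_York").normalize().tz_localize(None)
            expect = None
            for row in calendar.itertuples(index=False):
                if row.start_date <= local_date < row.end_date:
                    expect = row.block_id
            assert got == expect

    def test_start_outside_calendar_raises(self, calendar, roster):
        with pytest.raises(BlockAssignmentError, match="outside the block calendar"):
            assign_blocks(shift("T1", "2017-01-01T12:00:00Z", 8), calendar, roster)

    def test_unrostered_trainee_block_excluded_with_warning(self, calendar, roster, caplog):
        s = shift("T9", "2015-07-01T12:00:00Z", 8)
        with caplog.at_level("WARNING"):
            kept, excluded = assign_blocks(s, calendar, roster)
        assert kept.empty and len(excluded) == 1
        assert "without a roster assignment" in caplog.text


class TestTally:
    def test_hand_tallied_fixture(self, calendar, roster, rules):
        # T2 (senior): one 30h call (duration violation) then 7h rest (interval)
        eds = pd.concat(
            [
                shift("T2", "2015-07-01T11:00:00Z", 30),
                shift("T2", "2015-07-03T00:00:00Z", 10),
                shift("T1", "2015-07-01T11:00:00Z", 12),
            ],
            ignore_index=True,
        )
        srs = shift("T2", "2015-07-01T11:00:00Z", 24, Source.SELF_REPORTED)
        assigned, _ = assign_blocks(pd.concat([eds, srs], ignore_index=True),
                                    calendar, roster)
        vio = detect_violations(assigned, rules)
        t = tally(assigned, vio, roster)
        t2 = t[(t["trainee_id"] == "T2") & (t["block_id"] == "B01")].iloc[0]
        assert (t2["n_eds"], t2["n_srs"]) == (2, 1)
        assert (t2["edv_duration"], t2["edv_interval"], t2["edv_total"]) == (1, 1, 2)
        assert t2["srv_total"] == 0
        t1 = t[(t["trainee_id"] == "T1") & (t["block_id"] == "B01")].iloc[0]
        assert t1["n_eds"] == 1 and t1["edv_total"] == 0 and t1["n_srs"] == 0
        # conservation over the whole table
        assert t["edv_total"].sum() == (vio["source"] == "EHR_DEFINED").sum()
        assert t["srv_total"].sum() == (vio["source"] == "SELF_REPORTED").sum()
        assert len(t) == len(roster)

    def test_totals_are_sums_of_types(self, minimal_sim, rules):
        from shiftaudit.pipeline import analyze
        from shiftaudit.simulate import true_shifts_as_eds

        res = analyze(
            true_shifts_as_eds(minimal_sim.true_shifts),
            minimal_sim.self_reports,
            minimal_sim.roster,
            minimal_sim.calendar,
            rules,
        )
        t = res.tallies
        assert (t["edv_total"] == t["edv_duration"] + t["edv_interval"]).all()
        assert (t["srv_total"] == t["srv_duration"] + t["srv_interval"]).all()
        assert (t[["edv_total", "srv_total", "n_eds", "n_srs"]] >= 0).all().all()


class TestExclusion:
    def _tallies(self, n_srs):
        n = len(n_srs)
        return pd.DataFrame(
            {
                "trainee_id": [f"T{i % 2}" for i in range(n)],
                "block_id": [f"B{i:02d}" for i in range(n)],
                "role": "JR_FLC",
                "rotation": "wards",
                "n_eds": 5,
                "n_srs": n_srs,
                "edv_duration": 0, "edv_interval": 0, "edv_total": 0,
                "srv_duration": 0, "srv_interval": 0, "srv_total": 0,
            }
        )

    def test_unlogged_blocks_removed(self):
        eligible, report = exclude_unlogged_blocks(self._tallies([0, 3, 0, 2, 1]))
        assert len(eligible) == 3
        assert report["n_blocks_excluded"] == 2
        assert report["pct_blocks_excluded"] == 40.0

    def test_fully_logged_is_identity(self):
        t = self._tallies([1, 2, 3])
        eligible, report = exclude_unlogged_blocks(t)
        pd.testing.assert_frame_equal(eligible, t)
        assert report["n_blocks_excluded"] == 0

    def test_trainee_exclusion_means_no_remaining_blocks(self):
        t = self._tallies([0, 1, 0, 2])  # T0 has blocks 0,2 (both unlogged)
        eligible, report = exclude_unlogged_blocks(t)
        assert report["n_trainees_excluded"] == 1
        assert report["pct_trainees_excluded"] == 50.0


class TestPairedDifference:
    def _tally_row(self, i, srv, edv):
        return {
            "trainee_id": f"T{i}", "block_id": "B01", "role": "JR_FLC",
            "rotation": "w", "n_eds": 1, "n_srs": 1,
            "edv_duration": edv, "edv_interval": 0, "edv_total": edv,
            "srv_duration": srv, "srv_interval": 0, "srv_total": srv,
        }

    def test_classes_follow_sign(self):
        t = pd.DataFrame([self._tally_row(0, 1, 3), self._tally_row(1, 2, 2),
                          self._tally_row(2, 4, 1)])
        paired, summary = paired_difference(t)
        assert paired["diff"].tolist() == [-2, 0, 3]
        assert paired["cls"].tolist() == ["UNDER", "EQUAL", "OVER"]
        total = summary["pct_under"] + summary["pct_equal"] + summary["pct_over"]
        assert total == pytest.approx(100.0, abs=0.15)  # one-decimal rounding

    def test_study_scale_proportions(self):
        rows = (
            [self._tally_row(i, 0, 1) for i in range(222)]
            + [self._tally_row(i + 300, 1, 0) for i in range(108)]
            + [self._tally_row(i + 600, 1, 1) for i in range(273)]
        )
        _, summary = paired_difference(pd.DataFrame(rows))
        assert summary["n_blocks"] == 603
        assert summary["pct_under"] == 36.8
        assert summary["pct_over"] == 17.9
        assert summary["pct_equal"] == 45.3

    def test_histogram_counts_every_block(self):
        t = pd.DataFrame([self._tally_row(i, srv, edv)
                          for i, (srv, edv) in enumerate([(0, 2), (0, 2), (1, 0), (2, 2)])])
        paired, _ = paired_difference(t)
        hist = diff_histogram(paired)
        assert hist["n_blocks"].sum() == 4
        assert hist.set_index("diff")["n_blocks"].to_dict() == {-2: 2, 0: 1, 1: 1}


def _role_tallies(values_by_role):
    rows = []
    for role, vals in values_by_role.items():
        for i, v in enumerate(vals):
            rows.append(
                {
                    "trainee_id": f"{role}_{i}", "block_id": "B01", "role": role,
                    "rotation": "w", "n_eds": 1, "n_srs": 1,
                    "edv_duration": v, "edv_interval": 0, "edv_total": v,
                    "srv_duration": 0, "srv_interval": 0, "srv_total": 0,
                }
            )
    return pd.DataFrame(rows)


class TestRoleSummary:
    def test_identical_groups_give_zero_F(self):
        t = _role_tallies({r: [1, 2, 3] for r in ("JR_FLC", "SR_FLC", "SR_SUPRV")})
        res = role_summary(t, Source.EHR_DEFINED)
        assert res.anova["F"] == pytest.approx(0.0)

    def test_two_group_F_equals_t_squared(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 15)
        t = _role_tallies({"JR_FLC": a, "SR_FLC": b})
        res = role_summary(t, Source.EHR_DEFINED)
        tstat, _ = sps.ttest_ind(a, b, equal_var=True)
        assert res.anova["F"] == pytest.approx(tstat**2, rel=1e-12)

    def test_sem_uses_sample_sd(self):
        vals = [1.0, 2.0, 6.0]
        t = _role_tallies({"JR_FLC": vals, "SR_FLC": [0, 0, 0]})
        res = role_summary(t, Source.EHR_DEFINED)
        row = res.summary[res.summary["role"] == "JR_FLC"].iloc[0]
        assert row["sem"] == pytest.approx(np.std(vals, ddof=1) / np.sqrt(3))

    def test_small_group_skips_inference(self, caplog):
        t = _role_tallies({"JR_FLC": [1, 2, 3], "SR_FLC": [5]})
        with caplog.at_level("WARNING"):
            res = role_summary(t, Source.EHR_DEFINED)
        assert res.anova is None and res.tukey is None
        assert len(res.summary) == 2

    def test_invariant_to_ordering_and_ids(self):
        t = _role_tallies({"JR_FLC": [1, 2, 3, 4], "SR_FLC": [2, 2, 5, 1]})
        shuffled = t.sample(frac=1.0, random_state=5).reset_index(drop=True)
        shuffled["trainee_id"] = [f"X{i}" for i in range(len(shuffled))]
        a = role_summary(t, Source.EHR_DEFINED)
        b = role_summary(shuffled, Source.EHR_DEFINED)
        pd.testing.assert_frame_equal(a.summary, b.summary)
        assert a.anova == b.anova


class TestViolationModel:
    def _eligible(self, rows):
        return pd.DataFrame(
            [
                {
                    "trainee_id": f"T{i}", "block_id": "B01", "role": role,
                    "rotation": "w", "n_eds": 1, "n_srs": 1,
                    "edv_duration": edv, "edv_interval": 0, "edv_total": edv,
                    "srv_duration": srv, "srv_interval": 0, "srv_total": srv,
                }
                for i, (role, edv, srv) in enumerate(rows)
            ]
        )

    def test_matches_normal_equations_on_hand_table(self):
        t = self._eligible(
            [("JR_FLC", 2, 1), ("JR_FLC", 0, 0), ("SR_FLC", 3, 2), ("SR_SUPRV", 2, 2)]
        )
        fit = fit_violation_model(t)
        long = tallies_to_long(t)
        X = np.column_stack(
            [
                np.ones(len(long)),
                (long["source"] == "SELF_REPORTED").astype(float),
                (long["role"] == "SR_FLC").astype(float),
                (long["role"] == "SR_SUPRV").astype(float),
            ]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ long["total"].to_numpy(dtype=float))
        got = fit.table["estimate"].to_numpy()
        np.testing.assert_allclose(got, beta, atol=1e-10)
        assert fit.nobs == 8

    def test_long_reshape_doubles_rows(self):
        t = self._eligible([("JR_FLC", 2, 1), ("SR_FLC", 3, 2)])
        long = tallies_to_long(t)
        assert len(long) == 4
        assert set(long["source"]) == {"EHR_DEFINED", "SELF_REPORTED"}

    def test_single_role_is_rank_deficient(self):
        t = self._eligible([("SR_FLC", 2, 1), ("SR_FLC", 1, 1), ("SR_FLC", 3, 2)])
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_violation_model(t)

    def test_known_source_effect_recovered_exactly_without_noise(self):
        # srv = edv - 1 everywhere => source coefficient is exactly -1
        t = self._eligible(
            [("JR_FLC", 2, 1), ("JR_FLC", 3, 2), ("SR_FLC", 4, 3), ("SR_SUPRV", 2, 1)]
        )
        fit = fit_violation_model(t)
        assert fit.coef("source_SRV") == pytest.approx(-1.0)
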