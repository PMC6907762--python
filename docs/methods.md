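# Methods

## Problem and approach

Accredited residency programs must monitor trainee duty hours, but the
standard instrument — trainee self-report — is onerous and subject to bias.
EHR access logs offer an objective alternative: every chart open, order, or
note edit leaves a timestamp, and a trainee's stream of on-site timestamps
traces their physical presence at work. `shiftaudit` implements the full
analysis chain from raw access-log rows to a block-level comparison of
EHR-defined and self-reported duty-hour violations, together with a
synthetic-data generator that makes the whole chain testable without any
protected health data.

The pipeline has four computational stages:

1. **Sessionization** (`sessionize`). For each trainee, the sorted on-site
   event stream is split wherever the interval between consecutive events
   reaches `long_gap_threshold`. Each maximal run of events with strictly
   shorter internal gaps becomes a candidate EHR-defined shift (EDS),
   spanning its first to its last event. Refinement merges candidates
   separated by less than `merge_gap` and drops candidates shorter than
   `min_shift_duration`. Because endpoints are observed events, the method
   under-estimates and never over-estimates time on duty.
2. **Rule engine** (`violations`). Two rules, evaluated identically over
   EDS and self-reported shifts (SRS):
   *duration* — a shift strictly longer than the role cap (16 h for junior
   front-line clinicians, 24+4 h applied as a single 28 h cap for seniors)
   with magnitude = duration − cap; *interval* — rest before a shift below
   the requirement (8 h after shifts ≤ 16 h, 14 h after longer shifts)
   with magnitude = required − actual rest. Weekly-hour and day-off rules
   are out of scope.
3. **Block aggregation and comparison** (`compare`). Shifts are attributed
   to the scheduling block containing their start instant (half-open
   blocks in local wall-clock time, reference timezone configurable,
   default America/New_York). Violations are tallied per resident-block
   (one trainee × one block × one rotation) and source, giving EDV and SRV
   counts. Blocks with zero SRS are excluded from any analysis involving
   self-report, with a bookkeeping report. Outputs: the paired SRV − EDV
   distribution with under/equal/over proportions; per-role means ± SEM
   with one-way ANOVA and Tukey-Kramer post-hoc tests; and an OLS model
   `total ~ intercept + source_SRV + role_SR_FLC + role_SR_SUPRV` on the
   long (block × source) table, whose source coefficient is the adjusted
   mean reporting gap per block.
4. **Simulation** (`simulate`), described below.

## Rule-boundary conventions

The printed rules fix most boundaries; the rest are declared here and
enforced by an exhaustive ±1-minute truth-table test:

* duration violation: strict `>` cap (a 16:00:00 intern shift is legal);
* rest-class boundary: inclusive — a shift of exactly 16 h takes the 8 h
  requirement;
* inadequate rest: strict `<` requirement (exactly 8 h off is legal);
* sessionization: a gap exactly equal to `long_gap_threshold` starts a new
  shift (strict `<` keeps events in one shift); a candidate gap exactly
  equal to `merge_gap` is *not* merged;
* interval checks cross block boundaries and attribute the violation to
  the later shift's block.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `long_gap_threshold` | 300 min | inter-event gap that ends a shift; longer than plausible on-shift idle, shorter than any legal rest |
| `merge_gap` | 60 min | refinement: merge candidate shifts closer than this |
| `min_shift_duration` | 60 min | refinement: discard shorter candidates |
| `start_pad` / `end_pad` | 0 | optional correction for pre-login / post-logout time |
| duration caps | 960 / 1680 min | junior / senior role maxima |
| rest requirement | 480 / 840 min | after shifts ≤ / > 960 min |

The validated sessionization heuristic behind the published analysis is
not restated in full anywhere public, so the threshold and the
merge-then-filter refinement here are declared, documented stand-ins,
exposed as named configuration (`segmentation:` YAML block) rather than
constants.

## The synthetic study

The generator emulates one academic year of a large pediatric program:

* **Calendar**: 13 contiguous blocks from 2015-06-29; 28 days each, 29 for
  the first and last (366 days total).
* **Cohort**: 139 trainees; each staffs an inpatient rotation in ~43% of
  blocks, yielding ≈ 771 resident-blocks with role shares ≈ 44/40/16%
  (junior front-line / senior front-line / senior supervisory).
* **Schedules**: every-fourth-night call (7 overnight calls + 10 day
  shifts = 17 shifts per 28-day block) for senior rotations; day-night
  (23 × 14 h shifts) for junior rotations. Counts are deterministic per
  template and block length.
* **Violation seeding**: call durations are (cap − U{15..90}) min, or
  (cap + Exponential(52.4 min)) with a per-rotation overage probability;
  day-night shifts extend the same way past the junior cap. Overage
  probabilities (0.013–0.50 by rotation) were calibrated analytically so
  the *EHR-measured* per-block EDV means land near 0.6 / 2.4 / 1.4 by
  role after the event process trims small excesses; the exponential mean
  puts the median measured excess near 36 min. Occasional early starts
  (probability ≤ 0.0065 per shift) shorten a rest period by 30–120 min to
  seed interval violations. Consecutive true shifts always remain ≥ 6 h
  apart (`MIN_TRUE_GAP_MIN`), which keeps every true rest above the
  sessionization threshold — the separation condition that makes exact
  shift recovery possible.
* **Event process**: homogeneous Poisson within shifts (mean gap 30 min)
  with gaps clipped strictly below a 240-min idle cap; the first event
  lags the true start and the last leads the true end by Exponential(5
  min) amounts (capped at a quarter of the shift), so EDS under-estimate
  truth; off-duty noise events occur only on off-site workstations and
  are removed by the on-site filter.
* **Reporting behavior**: mechanistic and independently switchable —
  22% of resident-blocks unlogged, 3% of shifts omitted, 40% of over-cap
  shifts reported exactly at the cap (truncation), then ±8 min Gaussian
  jitter and rounding to 15 min. The all-zero model reproduces the true
  shifts exactly. Truncating an over-long shift also restores the
  following rest interval, so truncation hides the coupled interval
  violation as well — matching the intuition that a sanitized report
  looks legal in every respect.

### What the simulation does and does not show

Passing recovery tests show the *algorithmic* chain is correct: with
separable streams the sessionizer returns the true shifts exactly, and
with realistic lag/lead it never over-counts violations. They do not
validate the heuristic against real clinician behavior — real EHR usage
is burstier than Poisson, real schedules are messier than two templates,
off-site EHR work exists, and real under-reporting need not be a
mixture of block non-logging, omission, and truncation. Two known gaps:
the generator produces a smaller over-reported share (~7% of blocks)
than observed in practice, because the behavior model contains no
deliberate over-reporting mechanism (over-reports arise only from EHR
under-capture and report-timing noise); and block non-logging is
independent across blocks, whereas real non-loggers cluster by trainee.

## Numerical and design choices

* All instants are normalized to UTC at ingest and rounded to whole
  seconds (audit logs are second-resolution); local wall-clock enters
  only through block-boundary placement. Durations are exact in UTC, so
  DST transitions cannot double-count or drop an hour. Simulated shift
  start instants are computed as block-start instant + minute offsets, so
  nominal wall-clock start hours drift by one hour across a DST change.
* Unknown workstations are treated as on-site with a logged tally:
  exclusion is evidence-based, only stations known to be off-site drop
  events.
* Exact-duplicate audit rows collapse to one; same-second rows with
  different event codes are kept.
* Quantiles of the excess-duration distribution use linear interpolation
  (numpy default, type 7); SEM uses the sample SD (n − 1).
* Tukey-Kramer p-values use the exact studentized-range distribution
  (`scipy.stats.studentized_range`) rather than a lookup-table
  approximation; the ANOVA F comes from the closed-form sum-of-squares
  decomposition. Both are cross-checked against R's `aov`/`TukeyHSD`
  to 1e-8 on a frozen fixture.
* The regression is plain OLS, mirroring a mean-difference-with-SE
  reporting style; it ignores trainee-level clustering. A
  negative-binomial or mixed model would be the natural extension for
  count outcomes and is deliberately not the default.
* Degenerate inputs are defined, not exceptional: empty event streams
  yield empty shift lists, empty violation sets yield NaN quantile
  summaries with `n = 0`, roles with fewer than two blocks get
  descriptives with inference skipped, and a single-role cohort raises a
  named rank-deficiency error from the model.

## Problem sizes in the test suite

The oracle-equivalence suite checks 1,000 random streams of up to 200
events; exact recovery runs 50 seeded studies of 20 trainees × 13 blocks
with full event simulation; the under-reporting power check runs 100
seeded studies at full cohort scale (~771 resident-blocks, ~620 eligible)
on the truth-based route without event simulation. These sizes keep the
default suite in the minutes range on one CPU while leaving the binomial
and regression checks well-powered.
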