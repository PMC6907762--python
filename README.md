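# shiftaudit

Objective duty-hour auditing for residency programs: infer clinician
shifts from EHR access-log timestamps, evaluate duty-hour rules over both
EHR-defined and self-reported shifts, and quantify systematic
under-reporting at the resident-block level.

Accredited training programs must monitor duty hours, but the usual
instrument — trainee self-report — is onerous and biased. Every EHR
action leaves an audit-log timestamp, and a trainee's stream of on-site
timestamps traces their presence at work. `shiftaudit` turns those
timestamps into **EHR-defined shifts (EDS)** by gap-threshold
sessionization: a shift is a maximal run of events whose inter-event
gaps are all below a threshold (default 5 h), refined by merging
near-adjacent runs and dropping slivers. A rule engine then flags

* **duration violations** — shift length strictly above the role cap
  (16 h for interns, 24+4 = 28 h for seniors), magnitude = excess;
* **interval violations** — rest below the requirement (8 h after shifts
  ≤ 16 h, 14 h after longer shifts), magnitude = shortfall;

over both EDS and self-reported shifts (SRS), tallies **EDV** and
**SRV** per resident-block (trainee × rotation × 4-week block), and
compares them: the paired SRV − EDV distribution, per-role means ± SEM
with ANOVA/Tukey, and the OLS model

```
total_violations ~ intercept + source_SRV + role_SR_FLC + role_SR_SUPRV
```

whose `source_SRV` coefficient is the adjusted per-block reporting gap —
negative when trainees report fewer violations than the EHR shows.

Because access logs are protected data, the package ships a first-class
synthetic-data generator (`shiftaudit.simulate`) that emulates a full
academic year — q4-call and day-night schedules, a Poisson within-shift
event process, off-site noise, and a mechanistic biased-reporting model
(unlogged blocks, omitted shifts, truncation at the legal cap, jitter,
rounding) — with ground-truth labels for every stage.

## Worked example

Simulate a study year and run the whole pipeline:

```sh
shiftaudit all --seed 1 --outdir out
```

or in Python:

```python
from shiftaudit.ingest import filter_onsite
from shiftaudit.pipeline import analyze
from shiftaudit.sessionize import SegmentationParams, infer_all_shifts
from shiftaudit.simulate import SimulationProfile, simulate_study
from shiftaudit.violations import DutyHourRules

sim = simulate_study(SimulationProfile.study_scale(), seed=1)
events = filter_onsite(sim.events, sim.workstations)       # drop off-site
eds = infer_all_shifts(events, SegmentationParams())       # sessionize
res = analyze(eds, sim.self_reports, sim.roster, sim.calendar, DutyHourRules())

print(res.edv_by_role.summary.round(2))
print(res.paired_summary)
print(res.model.table.round(3))
```

which prints (seed 1):

```
       role  n_blocks  mean   sem
0    JR_FLC       395  0.68  0.06
1    SR_FLC       279  2.37  0.08
2  SR_SUPRV       116  1.27  0.10
{'n_blocks': 619, 'n_under': 181, 'n_equal': 393, 'n_over': 45,
 'pct_under': 29.2, 'pct_equal': 63.5, 'pct_over': 7.3}
            term  estimate     se    p
0      intercept     0.770  0.056  0.0
1     source_SRV    -0.355  0.065  0.0
2    role_SR_FLC     1.489  0.072  0.0
3  role_SR_SUPRV     0.473  0.096  0.0
```

Read: EHR-defined violations average 0.68 per junior front-line block,
2.37 per senior front-line block, and 1.27 per supervisory block; 171 of
790 resident-blocks (21.6%) had no self-reported shifts and were excluded
from paired analysis; among eligible blocks 29.2% show fewer self-reported
than EHR-defined violations versus 7.3% the other way; adjusted for role,
self-report misses 0.36 ± 0.07 violations per block (p < 0.001) — the
under-reporting signal the pipeline is built to expose.

The CLI stages (`simulate`, `infer`, `violations`, `compare`, `report`,
`all`) read a YAML config (paths, `segmentation:` and `rules:` blocks,
reference timezone, seed), write CSV/JSON artifacts plus a Markdown
report, and record a manifest with input checksums, package version,
config hash, and seed.

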