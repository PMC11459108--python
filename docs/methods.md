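# Methods

This note records the modelling choices behind `wardpath`: what each
component assumes, which parameters matter, what the synthetic generator
does and does not emulate, and where the design was genuinely open.

## Pathway model

A stay is a trace of stages; a stage is the pairing of one `start` and one
`complete` event of the same unit, with no intervening event of that unit.
When start/complete events of one unit interleave pathologically, the
pairing is ambiguous; we take the unique *non-crossing* pairing (each start
matches the next free complete) and reject logs where even that fails.
Timestamps are absolute date-times; durations are computed exactly, with no
day rounding, because bed-management phenomena (boarding, observation-unit
waits) live at hour scale.

Gaps between stages are legal — they represent inter-site transfer travel —
and a patient occupies no unit during a gap. Traces must begin at an
ED-category unit; the validator reports (never raises on) violations.
A permissive mode accepts truncated extracts whose final stage has no
complete event; it is off by default.

## Rules and labeling

Each rule emits verdicts: sub-intervals of stages judged level 1 (wrong
unit) or level 0 (hospitalization no longer justified). The labeler tiles
every stage with phases: per instant the *minimum* (worst) level across
covering verdicts wins and rule ids accumulate; maximal constant-level runs
become phases, and zero-length split artifacts are dropped. This
interval-wise minimum generalizes the event-wise worst-label priority to
overlapping verdicts, which no single rule produces on its own but
combinations do (e.g. an excess-stay verdict overlapping a delayed-discharge
verdict).

Parameter defaults, with rationale:

* `ed_los_max` = 10 h. Clinicians bound an acceptable ED stay at 5–10 h; we
  ship the permissive end so only unambiguous boarding is flagged. Strict
  inequality: exactly 10 h is compliant.
* `buffer_window` = 7.5 d. A buffer stay is a short polyvalent /
  post-emergency / observation stage followed by a transfer; one week is the
  clinical rule of thumb and the extra half day absorbs transfer timing. The
  trigger is `duration ≤ window` (a boundary stay is still a buffer — the
  violation here is shortness, unlike the duration rules where the boundary
  is compliant).
* `awaiting_bed_label` = "awaiting bed"; the other observation-unit labels
  ("observation", "back home within 24 h") are legitimate uses.
* `los_excess_factor` = 1.0, applied to the per-stay reference length of
  stay (the national per-DRG mean). Setting it to infinity disables the
  rule for any trace.
* `require_specialized_successor` = true. Whether a buffer verdict should
  require the successor to be a specialized ward (specialized medicine,
  surgery, ICU, CCU) or any different unit is genuinely open; requiring it
  avoids flagging legitimate polyvalent-to-polyvalent transfers, at the cost
  of missing buffers that feed non-specialized wards. The flag exposes both
  readings.

The ED stage is exempt from rules 4–7 (it is the entry point, not a
destination ward). Rules 1 and 2 ship disabled in the `validated` profile
because their thresholds could not be expert-validated; rules 2 and 7 are
reconstructions from described patterns rather than published algorithms
and should be read as such.

Correction targets: an overflow verdict carries the medically responsible
unit; buffer / awaiting-bed / week-before-full verdicts carry the successor
unit. The ED-boarding rule deliberately carries **no** target: the boarded
time is resolved at correction time to the next *relevant* (level-2) phase,
which coincides with the next stage when it is clean and skips it when that
stage is itself flagged — attaching the immediate successor would resurrect
an irrelevant unit.

## Correction

Level-1 phases keep their time but change activity (rule target, else next
level-2 phase's activity, else deletion); level-0 phases are deleted; then
consecutive same-activity phases merge by extending the first phase's end.

Two conventions were open:

* **Interior level-0 deletions leave a timestamp gap**; shifting later
  admissions earlier would fabricate admission times that never happened.
  Trailing deletions genuinely shorten the stay (the patient leaves at the
  presumed discharge instant). With the shipped rules, level-0 time is
  always trailing, so gaps arise only from hand-written rules.
* **The merge is unconditional on contiguity.** A relabeled wait followed by
  the destination stage across a 30-minute transfer gap must fuse into one
  stay — that is precisely what the canonical worked example requires — so
  same-activity adjacency, not timestamp contiguity, drives the merge; an
  absorbed gap is tallied in the diff report.

Corrections never add hospital time. Note that the variant count of a
corrected log is below its source's on every log the generator can produce,
but it is not a theorem for adversarial labelings (one historical variant
can split into two corrected ones when identical sequences carry different
labels); the test suite asserts it under the generator's conditions.

## Evaluation

The confusion matrix takes *relevant* (level 2) as the positive class, rows
as predictions. A stage's level is the minimum over its phases; the first
ED stage is excluded at both stage and pathway granularity — the entry
point is out of the evaluated rules' scope — and a pathway is positive only
when every assessed stage is level 2. Zero denominators yield NaN rather
than exceptions.

## Process graphs

Cohorts (all traces containing a given unit) are mined into directly-follows
graphs with artificial START/END nodes; arcs below `noise_threshold` times
the most-traversed arc are pruned. The complexity metrics are computed **on
the DFG, not on a mined Petri net**: density = |E|/(|V|·(|V|−1)), extended
cyclomatic = |E| − |V| + #strongly-connected-components, and the extended
Cardoso metric simplified to the sum of out-degrees over split nodes. The
original Cardoso taxonomy penalizes XOR/OR/AND gateway constructs, which a
DFG does not have; our figures therefore support before/after comparisons
on the same cohort but are not comparable in absolute value to Petri-net
tool output.

## Occupancy simulation

Capacities are infinite — the question is how many beds would have been
needed, not who is blocked — so each unit is an infinite-server queue and
no event calendar is required: occupancy is computed exactly as interval
overlap, vectorized. Patients arrive at their logged arrival instants
(arrivals are *not* resampled), visit their trace's units in order with
instantaneous transfers, and draw each visit's LoS from the unit's
distribution.

* Inclusion criteria: at most 3 stages, no day/week-mode unit, variant
  coverage ≥ 0.1%, optionally one site.
* LoS fitting: maximum likelihood over six families (normal, gamma,
  log-normal, Weibull, exponentiated Weibull, beta), ranked by AIC; units
  with under 30 positive durations fall back to a pooled fit with a logged
  warning; constant samples are a degeneracy error.
* Caps: 28 d per ward visit, 24 h in the ED, enforced by **resampling**
  above the cap rather than clipping, to avoid a probability atom at the
  cap (configurable).
* Replications differ only in LoS draws; reports carry t-based 95% CIs and
  both the maximum and mean relative half-width across units (the
  replication-precision criterion can be read either way). Occupancy is the
  continuous time-weighted average after a 60-day warm-up; a
  midnight-census option exists but is not the default.
* Scenario comparisons share the replication seeds and draw each unit's
  samples in a fixed visit order (common random numbers), tightening paired
  deltas.

Because arrivals are fixed, replication CIs quantify LoS uncertainty only.
The infinite-server sanity check (Poisson arrivals λ, mean stay m ⇒ mean
occupancy λ·m) therefore redraws the arrival process independently per
replication in the test, so that the CI covers the analytic value with its
nominal probability.

## Synthetic generator

The generator emulates, with planted ground truth, the mechanisms the rules
target: ED boarding (excess beyond 10 h), overflow beds (responsible unit ≠
location), buffer stays (short polyvalent/post-emergency stage before a
specialized ward), observation-unit bed waits (including terminal waits
that correct to a bare ED variant), week-unit stays before the same
specialty's full unit, and delayed discharges (fit-for-discharge before the
actual end). Defaults are one simulated year of 13,366 stays across an
18-unit registry with per-unit log-normal LoS, a Monday-peaked weekday
profile and a daytime-peaked hour profile (cosmetic, not calibrated);
mechanism probabilities (0.03/0.03/0.04/0.01 insertion, 0.04 delay, 0.04
boarding) put the share of pathways with a rules-3-to-7-detectable
irrelevance near 14%, the order observed in practice for unscheduled
pathways. Insertion mechanisms are mutually exclusive per pathway and
boarding is not combined with a terminal bed wait (boarding implies an
inpatient destination).

Three aligned artifacts come out of one run: the historical log, the truth
labeling, and the ideal log — the pathway under unlimited beds, constructed
per mechanism with the same timestamps the correction semantics preserve
(inserted stages are absorbed by the stage they fed, boarded ED time by the
first destination, delayed ends truncate to the fit instant). *Mechanism*
and *signature* are separable: the attribute-dropout rate removes the
detectable signature (responsible unit, transfer label, fit timestamp)
while leaving the planted truth, emulating detector-invisible bias — the
kind of gap an expert panel finds behind an automatic labeler. Structural
mechanisms (buffers, week-unit stays, and bed waits followed by a
specialized ward, which the buffer rule still catches) remain detectable
under dropout, so detection degrades smoothly rather than linearly.

What passing tests do and do not show: perfect recovery on dropout-free
synthetic logs validates the *internal consistency* of rules, labeler,
corrector and generator — every planted signature is found, nothing else is
flagged, and correction inverts the planted bias exactly. It does not show
that the rules capture real clinical practice: real extracts carry noisy
attributes, undocumented mechanisms (e.g. specialty mismatches between two
specialized wards) and genuine medical ambiguity, which is why rule
engines of this kind show double-digit disagreement with expert panels.

## Numerical choices and degenerate inputs

Thresholds compare with strict inequality except the buffer window (see
above). Instantaneous stages are kept as zero-length phases so labeling
conserves stage counts. Empty corrected traces (everything irrelevant,
nothing to relabel to) are kept in the log, flagged per case. Metrics with
empty denominators are NaN. Seeds: every stochastic component takes an
explicit integer seed; replications derive child seeds via seed sequences,
so identical configurations are bit-identical.

## Known limitations

* Rules 2 and 7 are reconstructions; sites deploying them should validate
  thresholds locally.
* The DFG metrics are not Petri-net metrics (no structuredness measure is
  provided).
* The simulator has no finite capacities, blocking, bed-assignment policy
  or seasonal ward calendars; it answers demand questions, not congestion
  questions.
* The generator does not calibrate to any real hospital's marginals; its
  defaults are plausible, not fitted.
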