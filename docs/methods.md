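# Methods

This note documents the models, conventions and numerical choices
behind `oxiburden`: what each pipeline stage assumes, which parameters
matter, what the synthetic-data generator does and does not emulate,
and where the design was genuinely open.

## Data model

Traces are per-neonate time series at 0.5 Hz: one *cell* every 2 s with
integer SpO2 (%), pulse rate (bpm), perfusion index (%), a binary
signal-quality flag (SIQ ok/low) and a set of event annotations.
Timestamps are normalised to seconds from trace start; gaps in the 2 s
grid are preserved, never imputed. Invalid measurements are represented
by sentinel tokens ("Invalid functional SpO2", "Invalid PR") with an
empty value cell; in memory the value is NaN and the token is kept as a
label, so the null↔token mapping is a bijection and file round-trips
are lossless. Vendor exports vary, so the reader takes a column-mapping
config (`TraceDialect`); the shipped event-token table (four clinical
threshold streams, system events, "other" for unknown tokens) is a
documented assumption, not a vendor schema.

## Quality filtering

A cell is **excluded** when it carries a system event (sensor off, low
perfusion index, cable disconnect) or an invalid SpO2/PR sentinel; the
excluded set is the union of the rules, so overlapping causes are
counted once. Exclusion is row-wise: both values are nulled on an
excluded row and nothing downstream consumes it. Low SIQ is treated
differently: it discredits the *alarm annotation*, which is removed
from the clinical alarm stream and counted, but not the sample value
itself. Alarm annotations inside excluded segments are artifact alarms
and are likewise removed (and reported separately).

Per-hour burden metrics use **quality-passing hours** as denominator.
Whether per-hour densities should be normalised by total or by
quality-passing monitoring time is a genuinely open convention; the
quality report carries both totals so either reading can be recovered.

## Alarm-event segmentation

An alarm event is a maximal group of same-type alarm cells in which no
silent separation exceeds `gap_s` (default 30 s). With 2 s cells the
silence between two active cells at times `t1 < t2` is `t2 − t1 − 2`;
a separation of exactly 30 s still merges, strictly more splits. Event
duration counts **active cells only** (2 s each); silent gap cells
inside a merged event add no duration. Each clinical category
(spo2_low, spo2_high, pr_low, pr_high) is segmented as its own stream,
so SpO2 and PR alarms overlapping in time are distinct simultaneous
events, and the gap rule is applied within category. An event announced
on both channels (audio_visual) contributes to both the audible and the
visual density. Events are never merged across trace files; daily
device reassignment makes cross-file continuity meaningless.

Cohort statistics are medians/IQRs over per-neonate values — never over
pooled cells — so long recordings do not dominate. IQR is reported as a
single width (Q3 − Q1), quartiles by linear interpolation. Threshold
comparisons are strict (`value < low`, `value > high`): a reading equal
to a limit is in range. Hourly/daily maxima use windows aligned to each
neonate's first sample, which is reproducible without wall-clock
metadata.

## Monitor alarm logic

The simulator reproduces three stages of the bedside device:

1. **Averaging** — trailing boxcar over `averaging_s / 2` samples
   (default 8 s = 4 samples). Null samples are excluded from the
   window; a fully-null window yields null. Partial windows at trace
   start average what is available, avoiding dead time.
2. **Threshold check** — strict inequalities on the averaged value.
   An upper threshold may be `None` (disabled).
3. **Delay** — the alarm asserts at the first cell where the violation
   has been continuously true for at least `delay_s`, measured in whole
   cells: a 15 s delay asserts at the 8th consecutive violating cell
   (16 s). A null average or a gap in the time grid breaks continuity.
   The delay applies to upper- and lower-limit alarms alike (the
   device's behaviour for upper limits is unpublished; this is the
   symmetric interpretation).
4. **Rapid desaturation** — when the averaged SpO2 is at or below
   `spo2_low − rapid_desat_pct` (default 85 − 10 = 75), the low-SpO2
   alarm asserts immediately, bypassing the delay. The vendor's exact
   semantics are unpublished; this is a documented interpretation of
   the "rapid desaturation 10%" setting. "Sensitivity" and "fast sat"
   are carried as metadata with no computational effect (fast sat is
   off in the modelled configuration).

Simulated alarm-active cells are segmented with the same 30 s grouping
rule as recorded annotations, so simulated and recorded streams are
directly comparable.

**A boundary effect worth knowing.** Alarm *annunciation* counts are
provably non-increasing in `delay_s` (a violation run either reaches
the delay horizon or it does not). After 30 s gap-merging this can fail
marginally: a longer delay starts the second of two nearby alarm runs
later, which can widen their silent gap past 30 s and split a
previously merged event. The monotonicity property is therefore exact
at the annunciation level (`gap_s = 0`) and holds only up to such rare
re-splits in the merged stream; the tests assert it where it is exact.

## Synthetic cohort generator

The generator stands in for raw unit exports. Signals are built from
interpretable episode processes, and the device annotations are written
by running the monitor logic above over the generated values — so
annotations are self-consistent with the simulator by construction, and
every planted episode has a known implied alarm stream (the ground
truth against which recovery is tested exactly).

**SpO2** is an integer-valued regime process:

* an in-range band (85–96%) modelled as a sticky resampling chain whose
  stationary distribution concentrates at 94–96%, with a point mass at
  exactly 96% — necessary for a pooled median of 96% to coexist with
  half the readings out of range;
* long hyperoxic stretches at 97–100% (stationary mass 36/20/22/22% at
  100/99/98/97), with dwell times a short/long lognormal mixture: many
  brief flickers above the limit plus rare stretches of tens of
  minutes. In a cohort on supplemental oxygen these stretches carry
  ~44% of monitored time and dominate the high-alarm burden;
* desaturation episodes: frequent **shallow dips** (81–84%, capped at
  8 cells — deliberately below the 15 s delay horizon, so they add
  below-85% tail mass without ever alarming) and rarer **deep events**
  (62–78%, again a short/long dwell mixture) that trigger the low
  alarm, mostly through the rapid-desaturation override.

**PR** is a clipped AR(1) baseline (mean-reverting, confined to the
90–200 bpm band) with bradycardia (< 90 bpm) and tachycardia
(> 200 bpm) episode overlays; bradycardia is weakly coupled to deep
desaturations (each deep event has a 15% chance of a concurrent
bradycardic response), reflecting the physiology of hypoxemia.

**Artifacts** are renewal segments of three kinds (sensor off, low
perfusion, cable disconnect) totalling ~10% of monitoring time; inside
them ~75% of SpO2 and ~74% of PR entries are invalid, the rest are junk
readings, and SIQ is low. Junk readings trigger artifact alarms that
the quality filter later removes — as on a real unit.

**Heterogeneity and durations.** Each neonate draws unit-mean lognormal
multipliers on its episode odds (desaturation, hyperoxia dwell,
brady/tachy mix) and a small shift of its PR baseline. Monitoring
durations are lognormal with the spread of a multi-week unit stay;
the shipped desk-scale default scales the median to 2 days (clipped to
0.35–6 days) so the 49-neonate cohort generates in ~15 s and the whole
acceptance run stays under a minute, while `default_calibration(
full_scale=True)` restores the multi-week model (median 11.2 days,
16 h–41 days).

**Calibration.** The default parameters were tuned once so that the
cohort's *emergent* pooled statistics — nothing is set directly — land
on the published summary profile the generator emulates: SpO2 median
96%, 5.78% of readings below 85%, 50% outside 85–96%, 3.4% below
80.2%; PR mean 158 bpm, SD 19.87, 2% outside 90–200, 0.92% below 90;
57.4% of simulated SpO2 alarm events high, median event duration 20 s.
Across independent seeds the cohort values scatter around these points
with cluster-level Monte-Carlo standard errors of roughly 0.2
percentage points on the SpO2 tail masses, 1 point on the out-of-range
and high-share percentages, and 0.03 points on the PR tails; the
acceptance tests check each statistic within 3 such standard errors
(neonate-level bootstrap), floored at the statistic's printed
precision.

**What the generator does not emulate.** No photoplethysmogram
waveforms, no oxygen-therapy state or circadian structure, no
covariates (sex, weight, outcomes), and only mild, unstructured
between-neonate heterogeneity: the published pooled marginals do not
constrain, for example, a subgroup with chronic hypoxemia. Passing
calibration therefore shows that the pipeline reproduces the pooled
statistics of a realistic signal mix — not that the generator is a
clinical model of any particular unit.

## Numerical conventions

* Sampling interval fixed at 2 s; all dwell parameters are in cells.
* Random generation uses NumPy's PCG64 with per-neonate spawned seed
  sequences: same spec + seed gives byte-identical cohorts across
  platforms.
* Medians of pooled integer readings follow the usual
  average-of-central-order-statistics rule; population (not sample)
  standard deviation is reported for pooled PR.
* Degenerate inputs are contracts, not silent defaults: zero monitored
  hours, an empty event list for a duration distribution, or a trace
  with no valid readings raise errors; an empty trace filter returns an
  all-zero report.

## Known limitations

* The gap-merge/delay interaction described above means merged-event
  counts are not a strictly monotone function of the delay.
* The simulator models the device's *documented* controls; proprietary
  sensitivity modes and motion-rejection algorithms are out of scope.
* Shallow-dip and artifact processes are stationary within a neonate;
  real units show care-event clustering (handling, feeds, kangaroo
  care) that the generator smooths over.
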