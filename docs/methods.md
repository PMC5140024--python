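# Methods

## Data model

A PIR recording is a uniform grid of 10 s epochs (configurable), each holding
% sensor activation in [0, 100] per cage plus one raw light-sensor reading.
Epochs are labelled by their start time; all intervals are half-open
`[start, start + epoch_s)`, which makes aggregation unambiguous. Timestamps
are ISO8601 UTC throughout. Missing epochs (logger restarts, transfer
dropouts) are kept as explicit NaN rows on the grid, never dropped: each
downstream operation declares its gap policy (scoring breaks immobility runs
at gaps by default; binned resampling propagates NaN into the affected bin;
the periodogram refuses gapped input).

The CSV dialect is configurable (delimiter, column names, timestamp format)
because logger variants differ; the canonical dialect written by the package
is `timestamp,cage_<id>,...,light`. Hypnograms are one vigilance-state token
per 10 s epoch; the token→{WAKE, NREM, REM} map must be total — an unmapped
token is an error, never silently scored as wake.

## Sleep from immobility

Sleep is scored as extended immobility: ≥ 4 consecutive zero-activity 10 s
bins (≥ 40 s). Two conventions are implemented:

* **run** (default): every epoch of a qualifying immobile run is asleep.
  This matches the video-validation convention in which the entire immobile
  period counts as sleep.
* **window**: epoch *i* is asleep iff the 4 bins ending at *i* are all zero —
  the literal spreadsheet rolling-sum formula. It misses the first 3 epochs
  (30 s) of every bout, so run-mode totals exceed window-mode totals by
  exactly `(threshold − 1) × #qualifying runs` epochs; the test suite checks
  this identity against a brute-force run-enumeration oracle.

Any nonzero activation breaks immobility (the noise floor defaults to 0 and
is configurable). The threshold is expressed in bins (`threshold_bins=4`);
"> 40 s" is implemented as "≥ 40 s", consistent with the 4-bin rolling-sum
formulation.

## Chi-squared periodogram

For each candidate period P (an integer number of bins), the binned series is
folded into K complete rows of P columns and

    Qp = K · N · Σ_h (M_h − M̄)² / Σ_i (x_i − M̄)²,   N = K·P,

with column means M_h and grand mean M̄. Under the no-rhythm null Qp ≈
χ²(P − 1), giving a per-period significance line at the (1 − α) quantile;
α defaults to 0.001 (field convention). The peak is the period with the
largest exceedance Qp − threshold; when nothing exceeds the line the peak is
reported as absent rather than as the global maximum. The candidate grid
defaults to 20–28 h in one-bin (10 min) steps, so period estimates are
quantised to the grid: a simulated 23.7 h rhythm resolves to 23.667 h or
23.833 h (≤ 8 min error). Constant input raises an explicit "no rhythm
detectable" error instead of returning NaN; at least two complete cycles of
the longest candidate are required. Qp is invariant to affine rescaling of
the input, which the suite tests.

## Light schedule, onsets, stability

The LIGHT/DARK threshold on the raw light channel is, by default, the
midpoint of the two 2-means centres of the value distribution; if the two
centres are not separated by at least twice the pooled within-cluster spread
the histogram is considered unimodal and an explicit threshold is required
(a uniformly zero channel is unambiguous darkness). Phase runs shorter than
10 min are treated as sensor glitches and absorbed into the surrounding
phase. The regime is LD when both phases alternate with cycle-length CV
≤ 5 %, DD/LL when uniformly dark/light, otherwise irregular.

Activity onset has no universal definition; the convention here is the first
bin exceeding mean + k·sd of the preceding quiescent window (default 6 h,
k = 2, circular) and staying above it for ≥ 30 min. Days with no qualifying
bin report a missing onset, not an error. All three constants are exposed.

Interdaily stability and intradaily variability use the standard
nonparametric forms

    IS = n Σ_h (x̄_h − x̄)² / (p Σ_i (x_i − x̄)²),
    IV = n Σ (x_i − x_{i−1})² / ((n−1) Σ (x_i − x̄)²),

with p period-bins and n total bins. IS = 1 for a perfectly repeating day;
IV ≈ 2 for white noise (checked by Monte-Carlo against the closed-form
expectation).

## Agreement analysis

PIR and EEG sleep are summarised as minutes per 30 min bin, paired on the
intersection of their time grids, and compared with Pearson r (per animal)
and Bland–Altman statistics on pooled per-bin differences d = PIR − EEG:
bias = mean(d), limits of agreement = bias ± 1.96·sd(d) with the sample
(n−1) standard deviation. The interval bias ± 1.96·sd is sometimes loosely
called a 95 % confidence interval in the actigraphy literature; it is a
limits-of-agreement interval (the expected span of individual differences),
not a CI of the mean bias, and the report names it accordingly. Pooling
across animals is the default; per-animal statistics are obtained by passing
one animal. With a light schedule the analysis is repeated per phase, bins
assigned by their start time.

## Simulator

The behavioural model is deliberately minimal: a semi-Markov chain over
ACTIVE, QUIET_WAKE and SLEEP with exponential dwell times, chosen as the
simplest process that reproduces the phenomena the analyses must detect —
nocturnality, entrainment, free-running periods, the quiet-wakefulness
confound, and optional ultradian bouts.

* **Phase.** Under LD the behavioural phase follows the light cycle (12 h:12 h
  default); under DD/LL it free-runs at an intrinsic period τ (defaults
  23.7 h in DD, 24.6 h in LL — the classic shortening/lengthening pattern in
  C57BL/6J mice). `phase_shift_s` offsets the behavioural phase from the
  light cycle, modelling chronotypes.
* **States.** At each bout boundary the next state is drawn from
  phase-dependent entry weights (defaults: light 0.25/0.10/0.65,
  dark 0.75/0.10/0.15 for active/quiet/sleep), never repeating the current
  state. Dwell means default to 180 s (ACTIVE; ×3 in the dark), 60 s
  (QUIET_WAKE) and 240 s (SLEEP), giving realistic bout-scale structure and
  roughly two-thirds of sleep in the light phase. `sleep_min_s` floors the
  sleep-bout length (0 by default; 40 s in the sensor-fidelity scenarios).
* **Emissions.** ACTIVE epochs emit clipped Normal(60, 20) % activation;
  QUIET_WAKE epochs move with probability `quiet_move_prob` (default 0.2,
  emitting clipped Normal(5, 2)) and are otherwise motionless; SLEEP epochs
  are 0 except for movement artifacts with probability `artifact_prob`
  (default 0).

Two distinct parameters govern quiet wakefulness: its *rate* (the
phase-dependent entry weights) and its *detectability* (`quiet_move_prob`).
Raising the light-phase rate of motionless quiet wake inflates PIR-scored
sleep in the light phase only — the mechanism behind the light/dark bias
asymmetry of immobility-based scoring — while raising detectability removes
it. The perfect-sensor scenario (no quiet wake, no artifacts, all sleep
bouts ≥ 40 s, active emission Normal(60, 10) so clamping to 0 % is
negligible, ≈ Φ(−6)) makes run-mode PIR sleep equal hypnogram sleep exactly.
In per-bin comparisons the final bin is excluded because the end of a
recording can truncate a sleep bout below the 40 s criterion, which the
scorer then (correctly) rejects while the hypnogram still contains it.

The hypnogram emits NREM for all simulated sleep: REM is not modelled
separately because the PIR comparison concerns total sleep only.

What the simulator does *not* emulate: sensor geometry and cross-talk
between cages, dwell-time autocorrelation of real PIR hardware, seasonal
light drift, REM/NREM architecture, and inter-individual variability beyond
parameter jitter. Passing tests therefore demonstrate correctness of the
analysis pipeline under the stated behavioural model, not hardware-level
fidelity.

## Problem sizes and numerical choices

Validation runs use sizes at which the checked properties are already
unambiguous: 10-day simulations for period recovery (≥ 8 cycles of every
candidate period), 2-day simulations for scoring-fidelity and bias scenarios
(≈ 96 paired 30 min bins each, 50 seeds), and 24-animal 2-day cohorts for
phenotype-recovery clustering (100 seeds in the test, 50 in the acceptance
script). The scoring oracle is exercised on 1,000 random vectors up to
10,000 epochs. Periodogram oracle equivalence is asserted at 1e-9 relative
tolerance (pure floating-point agreement); Monte-Carlo assertions use fixed
seed sets and tolerances stated in each test (e.g. dark-phase bias within
3 SEM of zero).

Hierarchical clustering uses average linkage on Euclidean distances of
per-animal z-scored profiles (clustering shape, not level; both raw and
normalised input are supported). Rows are sorted by animal label before
linkage so leaf order is deterministic and invariant to input permutation.

## Known limitations

* Period estimates are quantised to the candidate grid (one bin).
* The chi-square null is approximate; with ~50 correlated candidates the
  familywise false-positive rate at α = 0.001 is measured at ~2 % on white
  noise, not α itself.
* Immobility-defined sleep cannot separate motionless quiet wakefulness from
  sleep — that is a property of the measurement principle, quantified (not
  removed) by the agreement analysis.
* Light-schedule inference assumes an approximately bimodal light
  distribution; dawn/dusk ramps need an explicit threshold.
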