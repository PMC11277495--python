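# Methods

`flysleep` analyzes per-fly locomotor time series — distance traveled (mm)
per 30-s bin from a video-tracked multiwell arena, or counts per bin from
an infrared beam-crossing monitor — recorded under 2 days of LD12:12
(lights-on 07:00 = ZT00) followed by 8 days of constant darkness. This
note records the models, conventions and numerical choices, and what the
synthetic benchmark does and does not establish.

## Sleep scoring

A **sleep bout** is a maximal run of bins with activity ≤ `move_threshold`
lasting at least `min_sleep_min` minutes. Defaults: threshold 0 mm — any
recorded displacement, including sub-body-length micromovement, counts as
wake — and a 5-min minimum, the standard behavioral sleep criterion in
adult flies. A 3-mm threshold option exists for excluding micromovements
below roughly one body length. A run still open at the end of the
recording is kept if already long enough (symmetric with runs that begin
at bin 0). Bin indexing is 0-based with half-open intervals; ZT is decimal
hours; all of this exists to make the DT/NT split exact to the bin.

Per day and phase (DT = [ZT00, ZT12), NT = [ZT12, ZT24); DD days are
analyzed whole, since "lights-on" does not exist there) the panel reports:

* **n_bouts, mean bout length, TST** — a bout overlapping a phase boundary
  is *clipped* for TST and bout length but *counted once in each* phase it
  overlaps. Clipping is what makes DT TST + NT TST equal whole-day TST
  exactly, an invariant the tests assert. Mean bout length is NaN (not 0)
  when a phase has no bout, and NaN values are excluded from group
  summaries — a fly that never slept has no bout length, rather than a
  zero-length one.
* **latency** — minutes from the phase start (ZT00 or ZT12) to the onset
  of the first bout overlapping or starting after it; a bout already in
  progress at the phase start gives latency 0 (the fly *is* asleep there —
  this convention is what makes WASO vanish for a fly that sleeps through
  the whole night). The search crosses the phase end and is capped at
  1440 min; the cap is the value a fly receives when no qualifying bout
  occurs within 24 h.
* **WASO** (NT only) — the fixed identity 720 − (NT TST − night latency).
  It can exceed 720 min when latency is large; that is a property of the
  formula, not a bug.
* **SFI** — n_bouts / TST, defined as 0 when TST = 0. The 5-min floor
  bounds SFI by 0.2 min⁻¹ whenever any sleep exists.

A fly's reported LD value for each parameter is the mean of its two LD
days; group statistics operate on these per-fly values. Flies whose
terminal silence spans ≥ 24 h (configurable lookback) are excluded as dead
before any scoring; an all-zero trailing day cannot be distinguished from
consolidated sleep, so the lookback errs conservative. In arena CSVs a
single missing bin is imputed as 0 with a warning; two or more consecutive
missing bins exclude the fly, because zero-filling long gaps manufactures
sleep.

## Chi-square periodogram

Rhythmicity is assessed on DD days 3–10 only, resampled to 5-min bins
(sums, total activity conserved). For a candidate period of P analysis
bins, with K = ⌊N/P⌋ complete cycles (trailing partial cycle discarded),
column means M_h over the K×P fold and grand mean M:

    Qp = K · KP · Σ_h (M_h − M)² / Σ_i (X_i − M)²

compared to the χ²(1−α) quantile with P − 1 degrees of freedom, α = 0.05.
Candidates run 16–32 h in steps of one analysis bin (1/12 h ≈ 0.083 h —
resolution comparable to the dispersion of fly free-running periods). Qp
is scale-invariant (a ratio), so mm and counts give identical results.

Conventions chosen where the ecosystem varies, all surfaced as arguments:

* **Rhythmic** ⇔ some candidate's Qp exceeds its significance line.
* **Peak period** = the candidate maximizing Qp − line among those above
  it; **power** = that excess at the peak (not raw Qp). Power is therefore
  positive exactly for rhythmic flies and 0 at the boundary.
* A constant or all-zero series is arrhythmic with undefined period —
  there is nothing to fold.

**Calibration, measured.** At a *single* candidate period the test is
approximately calibrated: on iid noise with K = 20 cycles the measured
type-I rate is ≈ 0.047 at α = 0.05; with few cycles and large P it runs
conservative (≈ 0.03 at P = 288, K = 8), a known small-sample property of
the χ² approximation. The *full scan* applies no multiple-testing
correction across its ~190 candidates — this mirrors the peak-above-line
rule as practiced — and is therefore strongly anticonservative: the
measured family-wise false-positive rate on iid noise, and on arrhythmic
two-state bout data, approaches 1.0. Consequences we document rather than
hide: simulated arrhythmic flies are almost always *classified* rhythmic
(their fitted "periods" scatter widely and their powers sit near the
line), so classification frequencies cannot recover a generative rhythmic
fraction, and the pipeline's rhythmicity chi-square is skipped whenever a
cohort has no classified-arrhythmic flies at all. Detection claims in the
tests are accordingly made with the single-candidate test; the scan is
validated on period *location* (noiseless 24-h square wave recovers
24.0 h exactly; strong simulated rhythms at 23.7 h recover the group
median within one to a few grid steps) and on its documented invariants.

Actograms are raster matrices (rows = days, default 30-min plotting bins,
modulo 24 h), double-plotted by concatenating consecutive days; values are
raw binned activity, never normalized.

## Group statistics

Summaries report n, mean, sample SD, median, min, max. Rhythmicity counts
are compared by the chi-square test without continuity correction (the
default of common biostatistics software; a Yates toggle exists).
Multi-group comparisons use Kruskal–Wallis (midranks, scipy) with Dunn's
(1964) pairwise z-tests on the pooled midranks, tie-corrected variance,
and a Bonferroni-type family-wise adjustment over the k(k−1)/2 pairwise
contrasts of one parameter — the named procedure does not pin down the
adjustment variant, so this explicit choice is part of the package
contract. Sex contrasts within genotype use two-sided Mann–Whitney: exact
enumeration when the smaller sample has ≤ 8 values and no cross-sample
ties, else the midrank normal approximation with tie correction — a fixed,
reproducible switch rather than a library default that may drift. The
normality screen (Shapiro–Wilk; Kolmogorov–Smirnov with Lilliefors
correction, since plain KS against a fitted normal is badly miscalibrated)
is advisory only: downstream tests are nonparametric regardless. Constant
samples are degenerate for normality and returned flagged, not tested.

## Synthetic cohorts

The generator is a two-state (wake/sleep) semi-Markov process per 30-s
bin with geometric dwells — the simplest process giving the right
bout-count/TST trade-offs. A drive d(t) ∈ [−1, 1] is the light square
wave (+1 DT, −1 NT) on LD days for every fly (light masking), and
s·cos(2π(t − 6 h)/τ) on DD days, where τ is the fly's free-running period
(default 23.7 h) and s its rhythm strength — so s = 0 means genuinely
constant rates in DD. Mean dwells interpolate geometrically between their
day and night values as a function of d(t). Awake bins emit a distance of
~one body length (floor 3.2 mm; a fly scored as moving traveled at least
its own length) plus an exponential tail, mean 20 mm per 30-s bin at
d = 0, modulated by (1 + 0.5·d(t)); asleep bins emit exactly 0, so the
scorer's bout list equals the scheduled episodes of ≥ 5 min exactly — the
pipeline-recovery tests are exact, not approximate. A jitter option puts
sub-threshold micromovement (< 3 mm) into sleep bins to exercise the 3-mm
threshold path. Randomness: `default_rng([master_seed, fly_index])`, so
cohorts are reproducible fly-by-fly.

Cohort presets encode the qualitative contrasts of the study design the
generator stands in for, with n = 50 per genotype × sex: `wildtype-like`
(fraction rhythmic 0.90, s = 0.6; ~120 min DT / ~400 min NT sleep),
`clockless-like` (0.62, s = 0.25; little day sleep), `fxs-like` (0.86,
s = 0.35; more sleep in both phases, weaker rhythm). Dwell means were set
once from the target TST levels via the stationary occupancy
sleep/(sleep+wake) per phase.

What the generator does **not** emulate: inter-fly parameter
heterogeneity beyond the rhythmic/arrhythmic mixture, activity
autocorrelation within wake (bursts, grooming), period dispersion across
individuals (all rhythmic flies share τ), masking transients at the LD→DD
transition, and death. Passing recovery tests therefore show the
pipeline's operations are correct on data satisfying its assumptions, not
that the biological effect sizes of any real experiment will reproduce.

## Problem sizes and runtimes

The analysis scripts run the full design (6 × 50 flies × 10 days at 30-s
bins; ~1 min total). The test suite uses smaller cohorts chosen for
coverage rather than power — 8–40 flies, occasionally shortened
protocols — and seeds every stochastic fixture; calibration assertions
use binomial bands at their stated replicate counts (400–1000).

## Known limitations

* The periodogram scan's anticonservatism (above) is faithful to field
  practice but means "percent rhythmic" from this classifier is an upper
  bound heavily inflated for weakly rhythmic cohorts; a corrected or
  permutation-based threshold would change classification substantially.
* DD sleep is computed per whole day; subjective DT/NT splits are
  available (`subjective=True`) but no output table uses them by default.
* The Dunn adjustment variant and the Mann–Whitney exact/asymptotic
  switch are declared conventions; other software may differ in the third
  decimal of adjusted p-values.
* The beam-monitor writer rounds distances half-to-even to integer
  counts; round-tripping mm data through that dialect is lossy by design.
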