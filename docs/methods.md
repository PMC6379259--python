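# Methods

This note documents the models and numerical choices behind `sqvfs`: what
each stage computes, which parameters matter, what the synthetic cohort
does and does not emulate, and where the design was genuinely open.

## Study design assumed by the pipeline

A practice session is 20 trials of a violin bowing exercise (eight up/down
strokes on the open A string), grouped into four five-trial blocks:
baseline (trials 1–5), early (6–10), middle (11–15), late (16–20).
Subjects belong to one of three groups: EG (experienced violinists), BF
(beginners practising with offline sound-quality feedback) and BNF
(beginners without it).  Trials 1–5 are the shared reference interval for
both the sound-quality percent change and ERD/ERS; nothing from the
baseline block enters any post-baseline aggregate.

## Audio descriptors

### Yin frame analysis

`frame_metrics` implements the Yin fundamental-frequency estimator
directly: per frame, the difference function

    d(tau) = sum_{j<W} (x_j - x_{j+tau})^2,   tau = 0..W

is evaluated (via FFT cross-correlation plus cumulative energy sums, in
chunks to bound memory), normalised to the cumulative-mean-normalised
difference d'(tau) = d(tau)·tau / sum_{1..tau} d, and the first dip of d'
below an absolute threshold is refined by parabolic interpolation.  A
frame with no dip below the threshold is unvoiced (f0 = NaN).

Parameters and defaults:

* window 33 ms, hop 0.7 ms (both configurable).  The 0.7 ms hop produces
  ~1430 frames/s; per-trial descriptors are standard deviations over
  frames, which are insensitive to frame density, so cohort-scale runs
  and long simulations may use a coarser hop (7 ms is used in the
  package's own cohort-scale checks) with no measurable effect on the
  descriptors.
* absolute threshold 0.15 on d' — mid-range of published practice for
  this estimator family.
* search range 80–1200 Hz, comfortably bracketing the violin's open
  strings (G3 196 Hz to E5 660 Hz and above).

Per-frame outputs: f0 in cents re 440 Hz (1200·log2(f/440)); power as
the window's mean squared amplitude (linear, not dB — a z-scored
composite is scale-free, so the choice only affects the unit of the
dynamic descriptor); aperiodicity as d(tau*) divided by the total energy
of the two windows compared, i.e. the fraction of power the best periodic
model leaves unexplained, clipped to [0, 1].  A clean tone gives ~0;
white noise ~1.

### Per-trial descriptors

* `dynamic_instability`: population SD (1/N inside the root) of frame
  power over **all** frames.
* `pitch_instability`: population SD of f0 cents over **voiced** frames
  only — unvoiced frames carry no pitch.  (The all-frames variant is
  available via `voiced_only=False`, which zero-fills unvoiced f0.)
* `aperiodicity`: mean frame aperiodicity over all frames, unvoiced
  included — a scratchy unvoiced frame is precisely the bad-sound signal
  this descriptor exists to capture.

The "stability" orientation of these quantities is inverted: larger
values mean a less stable sound, which keeps all three descriptors and
the composite pointing the same way.

### Sound instability composite

Each included descriptor is standardized across the analysis cohort (all
trials of all subjects in the run, so cross-group comparisons share one
scale) and the per-trial composite is the mean of the standardized
components — three with aperiodicity, two without.  Default
standardization is a full z-score (population SD): the components live in
different physical units (power², cents, a ratio), and averaging them is
only meaningful after variance normalization.  Mean-centering without
scaling is available as `scale="center_only"` for sensitivity analysis.
Either way, the cohort mean of the composite is zero by construction.

### Block percent change

Per group and block b: `100·(mean(baseline) − mean(b)) / |mean(baseline)|`,
so positive = the instability score fell = improvement.  The sign
convention is written into the output (`convention` field) so no consumer
has to guess.  A zero baseline mean is an error, not a silent NaN.

## EEG band power and ERD/ERS

Per trial and electrode, the one-sided PSD is estimated with Welch's
method: 2 s Hann segments, 50% overlap (the classic defaults of that
estimator family; both configurable).  Band values are the **mean**
density over bins with low ≤ f < high for theta 4–8, alpha 8–13, beta
13–24 and gamma 30–50 Hz, so bands of different widths stay comparable in
µV²/Hz (`aggregate="integral"` switches to total band power).  Cluster
values are the arithmetic mean over member electrodes of the 13 named
clusters on the 14-channel consumer montage.

ERD/ERS per subject, cluster, band and post-baseline block:

    ERD/ERS(%) = 100 · (baseline_power − test_power) / test_power

with baseline power the mean over unmasked trials 1–5 and test power the
mean over the block's unmasked trials.  Positive = desynchronization.
Note the denominator is the *test-interval* power; the classical
baseline-denominator form is available (`denominator="baseline"`) but is
not the default, because the test-denominator form is the convention the
rest of the outputs assume.  Under a programmed density multiplier m on a
block, the expected readback is 100·(1−m)/m (e.g. m = 0.7 → +42.86%).

### Outlier masking

Trial band-power values are screened with the modified Z-score
M = 0.6745·(x − median)/MAD; |M| > 3.5 flags a value, and flagged values
are excluded from block averages.  The default masking **scope is
within-block**: each value is scored against the other trials of the same
block for that subject/cluster/band.  Scoring against all 20 trials of
the session (available as `scope="session"`) turns a genuine
between-block power shift — the very signal ERD measures — into a cluster
of "outliers": with a strong block effect the five baseline trials sit
far from the session median and are all masked, deleting the baseline.
The within-block scope detects aberrant single trials (artifacts) while
being blind to block-level structure by construction.  With five values
per scope group, the MAD rule flags a few percent of clean Gaussian
values (small-sample MAD is noisy); this costs a little data but never a
whole block.  No other artifact rejection is performed; an optional 1–60
Hz zero-phase pre-filter exists but is off by default.

## Statistics

* **Information gain.**  IG = H(labels) − Σ_bins P(bin)·H(labels|bin) in
  bits, after supervised Fayyad–Irani MDL discretization of the numeric
  feature (recursive best-entropy binary cuts, each accepted only if the
  gain clears the MDL coding cost); an unsupervised equal-width fallback
  (`equal_width_k`, default k = 10) exists mainly so tests can pin IG to
  brute-force entropy oracles over stated bins.  Features are ranked by
  descending IG with name-order tie-breaks for determinism.  Rankings in
  the pipeline use first-block rows only (before any external feedback)
  with a beginner/expert class label.
* **Normality gate.**  Shapiro–Wilk per group at α = 0.05; any rejection
  routes downstream contrasts to the nonparametric battery.  Constant
  samples are degenerate and routed nonparametric.
* **Battery.**  Wilcoxon rank-sum (= Mann–Whitney U), Wilcoxon
  signed-rank (zero differences excluded and counted in the result note),
  Friedman over ≥3 related blocks, and a paired t for the one behavioral
  contrast that warrants it.  All two-sided.  Rank tests use exact
  enumeration when both samples have n ≤ 10 and no ties — every group in
  the target design has n ≤ 9 — and mid-rank normal approximation
  otherwise.
* **Multiplicity.**  Bonferroni: per-test α = family α / m, with m the
  number of tests the pipeline actually performs in each family (audio
  descriptors; top-8 EEG features; per-group block tests; all ERD
  cluster×band×block cells; the 4 correlation bands; behavioral material
  types).  Every result row carries its adjusted α, and `significant` is
  `p < adjusted_alpha` by construction.  For reference,
  `bonferroni_alpha(0.05, 156) ≈ 0.00032`.
* **Trialwise correlation.**  Pearson r of the 20-point trial-averaged
  frontal band-power series against the trial-averaged sound-instability
  series of the beginner groups, per band, reporting R², p and a
  Bonferroni flag over the four bands.

## Synthetic cohort

The generator's job is to produce data whose *programmed* structure the
analysis stages must recover; its defaults mirror the target study design
(EG 7, BF 9, BNF 9 subjects; 20 trials; 30 s trials).

* **Audio.**  Eight harmonics with 1/k rolloff; an 8-stroke raised-sine
  amplitude envelope that dips at bow changes; pitch follows a
  mean-reverting Ornstein–Uhlenbeck walk (correlation time 0.5 s) with
  stationary SD = `pitch_jitter_sd` cents — mean reversion keeps pitch
  locally coherent so a 33 ms window reads it as pitch instability rather
  than aperiodicity, which i.i.d. per-sample jitter would become; a slow
  multiplicative gain (OU, 1 s) with amplitude SD set to half the
  requested relative power SD; white noise at `noise_snr` dB.  Group
  defaults: experts 3 cents / 0.05 / 35 dB throughout; beginners 15 cents
  / 0.25 / 18 dB at baseline with block multipliers < 1 expressing
  improvement (BF improves through all blocks, BNF plateaus after the
  early block).  Within a trial of length T the sample SD of an OU track
  underestimates its stationary SD by roughly √(1 − 2τ/T); recovery
  tolerances in the tests account for this.
* **EEG.**  Per channel, Gaussian noise synthesized in the frequency
  domain: rFFT coefficients drawn with variance S·N·fs/4 per quadrature
  so the one-sided density inside each band equals the target for the
  channel's scalp region (frontal 8, posterior 4, temporal 2 — a disjoint
  partition of which every analysis cluster is a subset).  Each band's
  density is extended ~0.75 Hz into adjacent spectral gaps so the Welch
  taper's leakage does not bias band-edge bins toward the background
  level (a flat 0.25 µV²/Hz fills the spectrum outside bands, clear of
  all band measurements).  Frequency-domain synthesis was chosen over
  filtered noise because it needs no per-band gain calibration to hit
  Welch-measured targets.  Group defaults: beginners carry 2.9× frontal
  beta and 1.16× frontal gamma relative to experts at baseline; beginner
  gamma drops to 0.7× everywhere after the baseline block; experts get a
  0.75× posterior/temporal gamma decrease and a 1.3× temporal beta
  increase.
* **Behavior.**  Poisson request counts; the feedback group's
  reference-video mean exceeds the no-feedback group's, and only the
  feedback group has score requests.
* **Determinism.**  All randomness flows from one `SeedSequence`; a fixed
  spec + seed reproduces every file bit-for-bit.

What the generator does **not** emulate — and therefore what passing
tests do not show about real data: physically modeled bowed-string sound
(no stick-slip transients, no room acoustics), EEG artifacts (blinks,
EMG, electrode drift), the 1/f background spectrum, or any coupling
between a subject's audio quality and their EEG beyond the programmed
group/block schedules.

## Problem sizes and numerical choices

* Cohort-scale checks and the reproduction script use scaled-down
  cohorts — 2 subjects per group, 1.5 s audio trials, 8–12 s EEG trials,
  7 ms analysis hop — sizes chosen so that every programmed effect is
  still recovered well inside its tolerance (e.g. ~60 s of EEG per block
  puts the ERD readback within ±5 points of the 42.86% closed form).
* Singleton electrode clusters are the noisiest readback (no averaging):
  a single channel's band-mean density has ~8% sampling SD at 60 s, which
  is why the generator's calibration test runs 240 s.
* Yin parabolic refinement is clamped to ±0.5 samples; frames at the
  search-range boundary skip refinement.  FFT work is chunked (~2^24
  floats per chunk).
* All floating-point table outputs use 6 significant digits; tests
  compare numerically with stated tolerances, never by string equality.
* Degenerate inputs fail loudly and specifically: all-unvoiced trials,
  zero-variance components under z-scoring, zero baseline means, MAD = 0
  (warns, flags nothing), bands without frequency bins, missing
  electrodes and manifest gaps are all named in the error.

## Known limitations

* The composite is defined only relative to a cohort; scores from
  different runs are not comparable unless standardized together.
* The ERD formula's test-power denominator makes large desynchronizations
  read larger than the classical convention would; comparisons with
  ERD values computed under the classical form require the
  `denominator="baseline"` switch.
* EEG ingestion is CSV-only; no EDF/BDF, no re-referencing (the consumer
  headset applies its P3/P4 reference on-device), no source-space or
  time–frequency analysis.
* MDL discretization follows Fayyad–Irani; other discretizers would give
  somewhat different IG magnitudes (rank order is typically stable for
  well-separated features).
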