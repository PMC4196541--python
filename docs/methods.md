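# Methods

This note documents the models and procedures implemented in `adaptbci`,
the parameter choices that matter, what the synthetic generator does and
does not emulate, and the design decisions taken where the design was
genuinely open.

## Signal model and feature extraction

Trials follow a cue-guided paradigm: relax from 0–3 s, a visual cue at 3 s,
sustained mental-task performance until 10 s, sampled at 256 Hz
(`TrialTiming`). The decoder consumes *bipolar derivations* — differences
between two electrodes on a common sagittal or coronal line of a sparse
rectangular grid, with at most one skipped intermediate position. Canonical
polarity is anterior-minus-posterior / left-minus-right; polarity does not
affect band power and is fixed only for reproducibility. The "scalp area
covered" by a derivation, used by the non-overlap constraint during channel
selection, is the inclusive set of grid positions between its electrodes;
skipped positions need not hold an electrode (10/20 layouts are not full
grids). The packaged default montage has 30 electrodes and yields 63
derivations; it approximates, but does not claim to reproduce, a specific
laboratory montage, and is fully configurable via YAML.

Features are logarithmic band power in five bands (8–10, 10–13, 13–16,
16–24, 24–30 Hz — bands known to respond to motor imagery and to the
non-motor tasks used here): causal 4th-order Butterworth band-pass, squaring,
a trailing 1-s moving average, then the natural log. Everything is strictly
causal so a simulated online run never uses future samples; the first second
of every trial is a warm-up region excluded from classification and
accuracy summaries. Averaged power is floored at 10⁻¹⁰ μV² before the log so
silent inputs stay finite. Filters are Butterworth because the procedure
only requires a causal band-pass with flat passband; the filter family is
otherwise immaterial to the method.

Separability of a scalar feature between two classes is the Fisher
criterion (μ₁−μ₂)²/(σ₁²+σ₂²+ε), with unbiased variances and ε = 10⁻¹² as a
numerical stabilizer. Per derivation, the band with the highest Fisher
score of trial-wise features averaged over the 4–8 s analysis window is
selected (ties go to the lower band). A `feature_selection="global_single"`
switch instead keeps the single best (derivation, band) feature overall;
per-derivation selection is the default, giving the classifier one feature
per derivation (1 for Mini, 3 for SMR/Auto).

## Calibration

`train_lda` is a two-class linear discriminant with pooled within-class
covariance and the decision boundary at the midpoint of the class means.
The pooled covariance receives a ridge of 10⁻⁶·trace/dim on its diagonal:
leave-one-out folds with as few as 6 trials per class are otherwise
near-singular. The implementation is deliberately minimal and deterministic;
scikit-learn's LDA serves as an independent cross-check in the test suite,
not as the implementation.

Window search: the 4–8 s analysis window is split into eight adjacent 0.5-s
windows. For each, leave-one-out cross-validation trains an LDA on
window-averaged features of the held-in trials and applies it to the
held-out trial's full feature time course; per-timepoint correctness is
pooled across folds and the median of the resulting accuracy curve inside
4–8 s is the window's score. The best window (ties: earliest) trains the
final classifier on all trials. The within-window statistic is the plain
mean of the feature time course — the simplest choice consistent with
"averaging over the window". Warm-up samples never enter the median.

Four-class auto-calibration runs this procedure for all six class pairs and
keeps the pair with the highest LooCV median accuracy; exact ties fall back
to the higher Fisher score of the best selected feature, and any remaining
tie to lexicographic pair order (determinism).

## Adaptive loop

`run_session` processes trials strictly in arrival order. Each arriving
trial is screened by a *prequential* version of the outlier pipeline
(statistics over the artifact-free trials collected so far plus the new
trial; only the new trial can be flagged). Once every in-scope class has 7
artifact-free trials, initial calibration runs; in Auto mode this includes
the one-off pair selection, after which trials of the two dropped classes
are ignored entirely — the pair is frozen for the rest of the session.
Subsequent artifact-free trials are classified at every valid timepoint
with the most recent model, and the system recalibrates on **all** collected
artifact-free trials whenever every in-scope class has 7 *new*
artifact-free trials since the last calibration (`update_counting="total"`
switches to a total-count trigger). The model applied to trial *i* is
always trained on trials with arrival index < *i*; results are bit-for-bit
deterministic. A stream that ends before initial calibration yields a
result flagged "never calibrated", not an exception.

## Outlier rejection

Three phases, in order, applied separately to the relax segment (0–3 s,
pooled over classes) and the analysed imagery segment (3–8 s, per class):

1. **Amplitude**: any sample beyond ±100 μV (strict inequality; the
   boundary convention is unspecified in the procedure's usual statement).
2. **Statistical**: per channel, trial kurtosis and mean log empirical
   probability; the density behind the probability measure is a per-channel
   histogram (100 bins) over the pooled samples of the group. A trial
   beyond 3.5 SD of the across-trial mean on any channel and either measure
   is rejected. Groups with fewer than 3 trials skip this phase.
3. **Band power**: per-trial mean log band power for every (channel, band)
   cell, iteratively trimmed at 3.5 SD of the surviving set until a pass
   rejects nothing (at most 20 iterations — a guard against
   non-convergence).

Rejection sets flags and writes a per-trial log; signal values are never
modified. Channels can be excluded by name (`excluded_channels`), mirroring
the manual removal of artifact-congested lateral channels that real
recordings sometimes require.

Two implementation decisions deserve emphasis:

- **Which channels are screened.** The pipeline operates on the channels
  the decoder consumes — the configured bipolar derivations — not on all
  monopolar electrodes. The any-channel 3.5-SD rule is extremely
  sensitive to the number of channels tested: sample kurtosis and the log
  probability measure are heavy-tailed across 200 trials, and applying the
  rule to 30 monopolar channels flags an implausibly large fraction of
  clean data (~40 % on synthetic sessions), while on the 1–3 derivations a
  decoder actually uses the false-positive rate is ~4–5 %, consistent with
  the overall ~12–16 % rejection observed when ~12 % of trials carry real
  artifacts. Since the rejection is part of the (few-channel) BCI system,
  derivation-level screening is the faithful operationalization.
- **Prequential bookkeeping.** The batch procedure defines rejection over a
  complete session; online operation recomputes the same statistics over
  the trials collected so far at each arrival. For efficiency the
  prequential rejector caches per-trial histogram counts on fixed bins
  spanning ±amplitude_limit (so group densities are sums of cached counts);
  batch mode bins over the pooled min–max range. The two estimators differ
  only in bin placement.

## Evaluation

The prequential accuracy time course is the fraction of evaluated trials
(artifact-free trials classified after initial calibration; calibration
buffers are not retro-scored) whose prediction at a timepoint matches the
true label. Its **median** in 4–8 s is the robust measure used for model
selection and for channel/class ranking; its **peak** in the same window is
the headline per-session figure, reflecting that a deployed system would
use a shorter, per-user-optimized decision window.

Better-than-chance bounds use the exact one-sided binomial tail: the
smallest k/n with P(X ≥ k | n, 1/classes) ≤ α, no normal approximation.
For 60 binary trials at α = 0.01 this is 40/60 ≈ 66.7 %. One calibration
note: the bound is valid for a *single* accuracy summary. The peak of an
accuracy curve is a maximum over several effectively independent timepoints
(the 1-s smoothing leaves roughly 4–8 in a 4-s window), so on null data the
peak exceeds the single-test bound far more often than α; null-control
checks in this package therefore compare the *median* accuracy against the
bound, while the peak is used in the effect-present direction where it is
the stricter requirement.

The screening sweep simulates the Mini configuration on every (derivation,
class-pair) cell; cells whose run never calibrates are recorded as missing.
Derivations are ranked by the median of their cells over class pairs
(mean available via option), then traversed best-first, keeping each
derivation only if it overlaps no previously kept one; the top three
survivors are the selected channels. Class ranking averages each class's
cells over all pairs containing it and over the selected derivations, and
keeps the top four of five; ties break lexicographically. Separability maps
average the Fisher score of imagery-window features over all class pairs
passing a filter (motor-vs-motor, motor-vs-non-motor,
non-motor-vs-non-motor, or all), per derivation × band, after outlier
rejection; the numeric table is the artifact, topographic rendering is
cosmetic and not part of the core.

## Synthetic generator

Each trial of each electrode is a sum of

- 1/f background noise (white noise shaped by a standard 3-pole pink
  filter, scaled to 5 μV RMS),
- white sensor noise (2 μV),
- narrowband rhythm carriers: band-pass-filtered Gaussian noise (so band
  power estimates have the variance of real rhythms rather than the zero
  variance of a sinusoid), at configurable RMS amplitudes per (electrode,
  band), with a 1-s pre-roll absorbing the filter transient.

During imagery ([cue, trial end)) a carrier's amplitude is scaled by
√(1 + effect) — band *power* changes by the effect fraction, negative
values being ERD — with a 250-ms raised-cosine ramp at cue onset to avoid
spectral splatter; the ramp sits well before the 4-s start of the analysis
window. Sessions comprise 8 runs × 25 trials, five per class in random
order per run. Artifact trials receive four ±150 μV spikes per channel at
independent random times (independent times prevent cancellation in any
bipolar derivation), so they violate the ±100 μV rule by construction;
clean trials stay below 100 μV with high probability under the default
noise budget.

The default effect template concentrates motor ERD near the vertex
(FCz, C3; 10–13 Hz) and gives the non-motor tasks parietal effects in
13–16/16–24 Hz, echoing the spatio-spectral structure reported for
motor/non-motor task contrasts in impaired users. *Hand* and *Word* each
carry one strong unique effect (FCz −0.85 at 10–13 Hz; P1 −0.78 at
16–24 Hz) while *Feet* and *Math* carry diluted versions of both, making
(*Hand*, *Word*) the designed most-separable pair by a clear margin — large
enough that the 7-trial-per-class LooCV of initial auto-calibration
identifies it reliably, which is the regime the auto-selection heuristic is
meant for. *Nav* carries no effect and is the natural drop in five-to-four
class selection. All template values are free generator parameters, not
empirical claims.

Cohorts jitter each effect multiplicatively with unit-mean lognormal
factors (`exp(N(−σ²/2, σ))`, default σ = 0.3), clipped so no effect falls
below −0.95, and give each subject a fresh session seed.

**What the generator does not emulate**: volume conduction and realistic
source geometry (effects are placed directly at electrodes), ocular/EMG
artifact waveforms (artifacts are amplitude spikes only; fixtures for
kurtosis/probability-triggered rejection are built in unit tests),
non-stationarity within a session (fatigue, drifting rhythms), and user
learning. Passing tests therefore demonstrate the correctness and internal
consistency of the decoding machinery under its stated assumptions, not
clinical-grade performance on real EEG — real sessions have weaker, less
stationary effects and more diverse artifacts.

## Problem sizes used in the packaged studies

The recovery study uses 20 independently seeded default sessions (200
trials each) plus 20 label-shuffled twins; the configuration comparison
uses a 9-subject jittered cohort with a 12 % injected artifact rate, each
subject simulated under both the four-task (Auto) and the motor-only (SMR)
configuration. These sizes keep a full reproduction in the range of a few
minutes on one CPU while leaving the binomial comparisons meaningful.

## Known limitations

- The batch outlier pipeline applied to a full 200-trial session has a
  clean-trial false-positive rate of roughly 5 % on the default generator
  (heavy-tailed measures under the pooled-relax grouping); the prequential
  screen used by the adaptive loop is what the rejection-rate figures refer
  to.
- The per-channel/pooled ambiguity of the statistical rejection is resolved
  as per-channel with any-channel rejection; a channel-pooled mode is not
  implemented.
- EDF files are read (via the optional `mne` dependency) but not written;
  the native session container is NPZ.
- LooCV fold predictions are pooled before the median over time; pooling
  after a per-fold median is a defensible alternative not implemented.
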