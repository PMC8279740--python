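# Methods

This note documents the models, parameter choices and numerical conventions
behind `aonpop`, and what the synthetic-data tests do and do not establish
about real recordings.

## Synthetic sessions

The generator emulates a Go/No-Go visuomotor grasping task run in an
execution (EXE) and an observation (OBS) block.  Event times per trial:
fixation onset after a 1–1.5 s intertrial period; cue 0.3 s later; object
presentation exactly 0.8 s after the cue; Go/No-Go signal 0.8–1.2 s after
the object (uniform); on Go trials, movement onset 0.25–0.45 s after the
Go signal and pulling 0.3–0.5 s later.  No-Go trials have no movement
events.  Trial order is randomized per block and all randomness flows from
one session seed through per-unit/per-trial child streams, so identical
configurations are bit-identical.

**Spike trains** are inhomogeneous Poisson processes sampled exactly by
thinning against a global rate bound.  Each unit's rate is a baseline
(gamma-distributed across units, shape 4, scale 2.5 spk/s → mean 10) plus
an epoch-locked plateau modulation: half-Gaussian rise (SD 50 ms) to the
plateau at `onset_event + latency`, sustained 0.8 s by default, signed per
task (+1 facilitated, −1 suppressed, 0 unmodulated) and scaled by a
per-object gain (Dirichlet-distributed for object-selective units).  Rates
are clipped at zero; the thinning bound makes the sampling exact, and a
rate-conservation test checks the realized counts against the numerically
integrated profile.  The profile shape is a modelling convenience — nothing
is claimed about true firing dynamics.

**Waveform snippets** are a difference of two Gaussian lobes (negative
trough, later positive peak at half the trough amplitude; trough width
0.35 × trough-to-peak, clipped to 0.03–0.08 ms).  The lobe separation and
peak width are calibrated by damped fixed-point iteration on the template's
*analytic* landmarks (extrema and inflection located by root-finding on the
closed-form derivatives) so that the template's trough-to-peak and
peak-to-inflection intervals equal the requested features to 10⁻⁶ ms.  The
three cell classes have feature means (0.20, 0.050), (0.35, 0.160),
(0.50, 0.310) ms with SDs of ~0.02 ms, separated by ≥ 4 within-class SDs
and spanning the observed ranges (trough-to-peak 0.13–0.58 ms,
repolarization 0.0025–0.43 ms); draws are clipped to those ranges (the
repolarization floor is 0.01 ms, the narrowest peak lobe the smooth
template resolves at 40 kHz).  Snippet noise is Gaussian smoothed along
time (kernel SD 2.5 samples at 40 kHz, rescaled to unit pointwise
variance): band-limited noise is the realistic model for filtered
extracellular snippets, and this correlation length makes the pointwise
±3 SD rejection remove ≈ 10% of snippets, the documented behaviour of that
rule.

What the generator does **not** emulate: noise correlations between units
(pseudo-populations assume independence by construction anyway), reaction-
time variability coupled to neural state, drifting baselines, bursty or
refractory spike-train structure, eye movements, LFPs.  Tests passing on
this generator therefore establish the *correctness of the analysis
chain* — recovery of planted structure under the stated noise model — not
the robustness of the analyses to real-data pathologies.

## Waveform processing

Up to 1000 snippets are selected at random without replacement and windowed
to 2.5 ms centered on each snippet's absolute minimum (symmetric crop;
shifted, with a warning, when the minimum is too close to an edge).
Outlier rejection is single-pass: pointwise mean and SD are computed once
and snippets exceeding ±3 SD at any sample are dropped (zero-SD samples
count as no exceedance).  It is applied to aligned raw-resolution snippets,
before interpolation.  Each retained snippet is cubic-spline interpolated
to 1000 points over 2.5 ms with its minimum at sample 500, averaged
pointwise, and the average normalized to unit trough depth.  Re-running the
interpolation on its own output is a no-op (the grid reproduces itself).

Unit exclusion applies three rules in order: < 1000 total spikes; multipeak
(more than one local maximum strictly between the main trough and the
largest post-trough peak); amplitude ratios typical of axon fibers (main
trough smaller than the subsequent peak, or a pre-trough peak above 20% of
the trough depth).  Local maxima use strict three-point comparison with
plateaus resolved to the earliest sample.

Features: trough-to-peak is the interval from the global minimum to the
next local maximum; repolarization time runs from that maximum to the next
zero of the second derivative, computed by central second differences on
the 1000-point grid with the sign change localized by linear
interpolation — no smoothing, matching the "second derivative equals zero"
definition directly.  An analytic oracle (a Gaussian lobe's inflection sits
exactly one SD past its peak) validates the numerical inflection.

## Cell-class clustering

`sklearn.mixture.GaussianMixture` with diagonal covariances, k-means++
initialization, 500 replicates (best log-likelihood kept), at most 100 EM
iterations per replicate, and `reg_covar = 10⁻⁶ ms²` as the variance floor.
BIC uses 5K−1 free parameters (2 means + 2 variances per component plus
K−1 weights), which is sklearn's count for this model; K = 1..10 is scanned
and the minimum taken (ties resolve to the smallest K).  Classes are
numbered by ascending mean trough-to-peak, so class 1 is narrow-spiking and
class 3 broad-spiking; the mixture itself is label-invariant.  Separation
is quantified by drawing 10⁴ labelled points from the fitted mixture and
reassigning them by maximum posterior (row-normalized confusion matrix;
accuracy = mean diagonal).  68% ellipses use semi-axes
√(variance · χ²₂(0.68)); floored components are flagged degenerate.  The
additional outlier-removal step some clustering protocols apply is
deliberately not part of the default chain — otherwise valid physiological
data are kept.

## Response classification

Binning: 200-ms windows advanced by 20 ms, values at window centers, only
windows fully inside the analysis span (so −0.3..+0.9 s around the Go
signal yields 51 bins centered −0.2..+0.8 s).  Baseline: per-trial rate in
the 500 ms before cue onset, computed separately per task.  Soft
normalization divides net activity by (max |net| across conditions +
5 spk/s), which damps low-rate units and bounds traces strictly inside
(−1, 1).

The sliding test is a *paired* t test (per-trial baseline vs per-trial bin
rate), one-tailed with the tail set by the sign of the unit's mean net
modulation over the window; bins with zero-variance differences are
nonsignificant.  A unit is facilitated/suppressed with ≥ 5 consecutive
significant bins at p < 0.05.  The paired choice (the published description
does not say paired or two-sample) matches the paired test used for MMD
significance and shares trials correctly; simulations show the unpaired
variant behaves identically at these trial counts.

A caveat this package measures explicitly: with a post-hoc tail and ~6
quasi-independent 200-ms windows inside the 1.2-s test interval, the
*null* false-label rate of this criterion is ≈ 25% (≈ 1 − 0.95⁶), not the
nominal 5% — the criterion is deliberately permissive.  The type-I property
test records this bound honestly rather than tuning around it.

Burst fraction uses a declared surrogate (proportion of ISIs < 10 ms); peak
times are the maxima of condition-averaged net traces in 0.1–0.5 s after
object presentation and 0–0.6 s after the Go signal, earliest bin on ties.

## Decoding

Pseudo-populations deal each unit's within-condition trials independently
into `n_splits` splits (the number of trials per condition), one data point
per condition per split.  Leave-one-split-out cross-validation; per fold
and per time bin, features (units) are preselected on training data only
(one-way F test across conditions, p < 0.5) — training-fold-only selection
avoids test-set leakage where the published description is ambiguous.  The
Poisson naive Bayes score of counts x under class c is
Σ_units (x·log λ − λ) with class-conditional mean counts λ floored at 10⁻³
and uniform priors; ties break uniformly at random.  The classifier is
checked bin-for-bin against a brute-force Bayes oracle built from explicit
Poisson pmfs.

Mutual information is the plug-in MI of the pooled (actual, predicted)
confusion counts, in bits, clipped at 0 against round-off; it is normalized
by log₂K (1 for Go/No-Go, 1.585 for three objects).  Number matching draws
65 units with replacement (3/4 of the smallest area, rounded half up) per
iteration, 50 iterations each averaged over 10 cross-validation runs; the
"40 ms Gaussian kernel" is interpreted as SD = 40 ms (truncated ±4 SD,
nearest-edge padding), and the interpretation is recorded in the result
metadata.  Onset = first bin where the smoothed MI exceeds log₂K/3,
averaged over iterations (undefined if fewer than half cross); SE =
SD(onsets) × 65/N_area, applied exactly as published even though its
statistical justification is not derived anywhere.  Onset and
epoch-averaged MI comparisons use two-tailed two-sample z tests.  Class-wise
decoding draws 20 units per class per area (population 60).  Note that the
plug-in MI is positively biased at small sample counts (~0.02–0.05 bits at
60 data points); the ⅓·log₂K onset threshold sits far above this bias.

## MMD

MMD_n(t) = EXE_n(t) · OBS_n(t) on the −0.5..+0.7 s movement-aligned grid
(51 bins centered −0.4..+0.6 s, same binning conventions as above), with
the *Go-signal-referenced* 500-ms baseline.  The index is symmetric in the
two tasks and bounded by |EXE|·|OBS| ≤ 1; with the +5 soft constant and
finite rates the bound is strict on real traces.  Group significance:
per-unit reference = mean of the first five bins (280 ms of the grid; the
published "300 ms" does not land on the bin grid, and the literal first
five bins are used), one-tailed paired t across units per bin, p < 0.01 by
default with a documented switch to 0.05 (the two thresholds both appear in
the published description), masked to runs of ≥ 5 consecutive bins.  Units
are the pairing dimension — the only reading consistent with a paired test.
The 3×3 class-by-area factorial comparison is exported as a tidy per-unit
table for standard ANOVA routines rather than re-implemented.

## Problem sizes in tests and drivers

The test suite and analysis drivers run on deliberately compact problems
chosen to exercise every code path at interactive speed: sessions of 8–60
units, 6–10 trials per condition-object cell, decoding with 5–25 iterations
and 2–5 runs, and clustering studies with 10–500 replicates depending on
what the check needs (stochastic-recovery assertions use reduced replicate
counts, since EM on well-separated 2-D data converges identically from a
handful of k-means++ starts; the committed BIC result is verified with the
full 500-replicate, K = 1..10 procedure over 25 independent draws of 355
points).  These sizes are the package's own choices for its reference
studies; all published-analysis defaults remain available and are the
library defaults.
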