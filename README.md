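# aonpop

Single-unit analysis pipeline for action execution/observation
electrophysiology in the primate grasping network (anterior intraparietal
area AIP, ventral premotor F5, pre-supplementary motor F6).  It is written
for researchers who record extracellular single units while a subject
performs a Go/No-Go grasping task (EXE) and watches an experimenter perform
it (OBS), and who want to characterize *what kind of cell* responds, *how*
it responds, and *when* task information becomes decodable.

The pipeline implements four analysis stages, plus a synthetic-session
generator with planted ground truth so that every stage is testable without
access to recordings:

1. **Waveform cell classes.**  Each unit's average spike shape (1000 points
   over 2.5 ms, spline-interpolated, realigned on the trough, with ±3 SD
   snippet rejection and three unit-exclusion rules) yields two features:
   trough-to-peak duration and repolarization time.  Units are clustered in
   this 2-D space with a diagonal-covariance Gaussian mixture (500
   k-means++ EM replicates per fit), the number of classes chosen by
   minimizing the BIC over K = 1..10, and class separation quantified by a
   10⁴-draw confusion matrix.
2. **Response classification.**  Firing in 200-ms bins stepped by 20 ms is
   referenced to the 500-ms pre-cue baseline; a unit is *facilitated* or
   *suppressed* when a one-tailed sliding t test (p < 0.05, tail set by the
   sign of its mean net modulation) is significant in ≥ 5 consecutive bins
   within −0.3..+0.9 s around the Go signal.  Net activity is
   soft-normalized: (rate − baseline) / (max |net| + 5 spk/s).
3. **Pseudo-population decoding.**  Units recorded separately are combined
   by dealing within-condition trials into splits (one data point per
   condition per split) and decoded leave-one-split-out with a Poisson
   naive Bayes classifier, with per-fold feature preselection (one-way F
   test, p < 0.5).  Performance is the plug-in mutual information of the
   confusion matrix, normalized by its theoretical maximum log₂K (1 bit for
   Go/No-Go, 1.585 for the three objects), averaged over number-matched
   subsamples (65 units with replacement, 50 iterations × 10 runs) and
   smoothed with a 40-ms-SD Gaussian.  The information onset is the first
   crossing of ⅓·log₂K, with SE = SD(onsets) × 65/N_area, compared across
   populations by two-sample z tests.
4. **Mutual Modulation Depth (MMD).**  For each unit, MMD(t) =
   EXE(t)·OBS(t), the per-bin product of the net soft-normalized activities
   of the two tasks in −0.5..+0.7 s around movement onset (baseline: 500 ms
   before the Go signal).  MMD is bounded in [−1, 1]: positive for
   congruent (mirror-like) modulation, negative for opposite modulation,
   near 0 when either task is unmodulated.  Group increases are tested
   bin-by-bin against the mean of the first five bins (one-tailed paired t,
   p < 0.01, ≥ 5 consecutive bins).

## Worked example

The numbered drivers under `analysis/` run the full chain on a synthetic
session (60 units, 10 trials per condition × object cell, seed 0):

```sh
cd analysis
python 01_simulate_session.py
python 02_waveform_features.py
python 03_cluster_cell_classes.py
...
```

`02` prints the waveform QC outcome:

```
QC outcome: {'retained': 58, 'excluded_min_spikes': 2}
trough-to-peak range: 0.163-0.533 ms; repolarization range: 0.0259-0.376 ms
mean snippet removal by the +-3 SD rule: 9.4%
```

— two units fall below the 1000-spike minimum, the features lie in the
physiological range, and the ±3 SD rule removes ≈ 10% of snippets.  `03`
recovers the planted class structure:

```
BIC selects K = 3
class means (trough-to-peak, repolarization) ms:
  class 1: (0.200, 0.050)  class 2: (0.346, 0.156)  class 3: (0.497, 0.313)
mixture separation accuracy (10^4 draws): 1.000
agreement with planted classes: 100.0%
```

`05` decodes Go vs No-Go from the pseudo-population
(`peak MI 1.00 bits`, `information onset: 246 +- 32 ms` after the Go
signal — the planted movement-locked modulation begins at the movement
onset, ~250–450 ms after Go), and `06` shows the MMD rising from ≈ 0.02 in
the pre-movement reference bins to ≈ 0.14 during movement, positive in all
three cell classes, as expected for a session dominated by congruently
modulated units.

The same operations are available as a CLI (`aonpop simulate`, `aonpop
features`, ..., `aonpop run`) over a YAML config, and as plain library
calls (`aonpop.clustering.select_K_by_bic`,
`aonpop.decoding.decode_timecourse`, `aonpop.mmd.mmd_timecourse`, ...).

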