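"""Average-waveform construction, unit quality control, and feature extraction.

Per unit: randomly select up to 1000 spike snippets, window each to 2.5 ms
centered on its absolute minimum, reject snippets exceeding +-3 SD from the
pointwise mean anywhere, spline-interpolate to 1000 points, realign on the
minimum, and average.  Units are excluded when they have fewer than 1000
spikes, a multipeak average waveform, or trough/peak amplitude ratios
typical of axon fibers.  Retained units yield two scalar features:
trough-to-peak duration (global minimum to next local maximum) and
repolarization time (that maximum to the next inflection point).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import (DegenerateInputError, FormatError, MeasurementError,
                     ParameterError)

WINDOW_MS = 2.5
N_POINTS = 1000
DT_MS = WINDOW_MS / (N_POINTS - 1)
QC_RETAINED = "retained"
QC_MIN_SPIKES = "excluded_min_spikes"
QC_MULTIPEAK = "excluded_multipeak"
QC_AMPLITUDE = "excluded_amplitude_ratio"
MIN_SPIKES = 1000


@dataclass
class AverageWaveform:
    """Normalized 1000-point average spike shape spanning 2.5 ms."""

    samples: np.ndarray
    dt_ms: float = DT_MS

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape != (N_POINTS,):
            raise FormatError(
                f"average waveform must have {N_POINTS} samples, "
                f"got {self.samples.shape}")
        if not np.all(np.isfinite(self.samples)):
            raise FormatError("average waveform contains non-finite values")

    @property
    def align_index(self):
        return int(np.argmin(self.samples))

    @property
    def time_ms(self):
        return (np.arange(N_POINTS) - self.align_index) * self.dt_ms


@dataclass
class WaveformFeatures:
    trough_to_peak_ms: float | None
    repolarization_ms: float | None
    qc_status: str


def select_and_align_snippets(snippets, sampling_rate, n_select=1000, seed=0):
    """Randomly select snippets and window each to 2.5 ms around its minimum.

    Selection is without replacement; when fewer than `n_select` snippets
    exist, all are returned (the min-spike exclusion is applied downstream
    on the unit's total spike count).  The crop is symmetric about the
    absolute minimum; when the minimum sits too close to an edge the window
    is shifted to fit and a warning is issued.
    """
    snippets = np.atleast_2d(np.asarray(snippets, dtype=float))
    if snippets.shape[0] < 1:
        raise ParameterError("need at least one snippet")
    half = int(round(WINDOW_MS / 2 * 1e-3 * sampling_rate))
    width = 2 * half + 1
    if snippets.shape[1] < width:
        raise FormatError(
            f"snippets must span >= {WINDOW_MS} ms "
            f"({width} samples at {sampling_rate:g} Hz), "
            f"got {snippets.shape[1]} samples")
    rng = np.random.default_rng(seed)
    if snippets.shape[0] > n_select:
        idx = rng.choice(snippets.shape[0], size=n_select, replace=False)
        snippets = snippets[idx]
    out = np.empty((snippets.shape[0], width))
    shifted = 0
    for i, s in enumerate(snippets):
        c = int(np.argmin(s))
        lo = c - half
        if lo < 0 or lo + width > s.size:
            shifted += 1
            lo = min(max(lo, 0), s.size - width)
        out[i] = s[lo:lo + width]
    if shifted:
        warnings.warn(f"{shifted} snippet(s) had their 2.5-ms window shifted "
                      "to fit inside the recorded span")
    return out


def reject_outlier_waveforms(aligned):
    """Drop snippets exceeding +-3 SD from the pointwise mean at any sample.

    Single pass: the mean and SD are computed once over all snippets.
    Samples with zero SD are treated as no exceedance.  Returns the retained
    subset and the removal fraction.
    """
    aligned = np.asarray(aligned, dtype=float)
    if aligned.shape[0] < 2:
        raise ParameterError("outlier rejection needs >= 2 snippets")
    mean = aligned.mean(axis=0)
    sd = aligned.std(axis=0)
    dev = np.abs(aligned - mean)
    ok = np.all((dev <= 3 * sd) | (sd == 0), axis=1)
    if not ok.any():
        raise DegenerateInputError("all snippets rejected by the +-3 SD rule")
    removed_fraction = 1.0 - ok.mean()
    return aligned[ok], removed_fraction


def average_and_interpolate(retained, sampling_rate):
    """Cubic-spline each snippet to 1000 points over 2.5 ms, realign, average.

    Each snippet is interpolated onto a 1000-point grid whose sample 500
    coincides with the snippet's absolute minimum, then the pointwise mean is
    taken and normalized to unit trough depth.
    """
    retained = np.atleast_2d(np.asarray(retained, dtype=float))
    if retained.shape[0] < 1:
        raise ParameterError("need at least one retained snippet")
    if not np.all(np.isfinite(retained)):
        raise FormatError("snippets contain non-finite values")
    dt_s = DT_MS * 1e-3
    offsets = (np.arange(N_POINTS) - N_POINTS // 2) * dt_s
    acc = np.zeros(N_POINTS)
    for s in retained:
        t = np.arange(s.size) / sampling_rate
        spline = CubicSpline(t, s)
        t_min = t[int(np.argmin(s))]
        acc += spline(t_min + offsets)
    avg = acc / retained.shape[0]
    depth = np.abs(avg.min())
    if depth == 0:
        raise DegenerateInputError("average waveform has no trough")
    return AverageWaveform(avg / depth)


def _local_maxima(x):
    """Indices of strict three-point local maxima; plateaus -> earliest sample."""
    idx = []
    i = 1
    n = x.size
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j < n - 1 and x[j + 1] == x[j]:
                j += 1
            if j < n - 1 and x[j + 1] < x[j]:
                idx.append(i)
                i = j + 1
                continue
        i += 1
    return np.array(idx, dtype=int)


def qc_exclude_unit(avg, n_spikes_total):
    """Apply the three unit-exclusion criteria in order; return the qc status.

    1. fewer than 1000 spikes in total;
    2. multipeak average waveform (more than one local maximum strictly
       between the main trough and the largest post-trough peak);
    3. main trough smaller than the subsequent peak, or a pre-trough peak
       exceeding 20% of the trough depth (axon-fiber-like shapes).
    """
    if n_spikes_total < MIN_SPIKES:
        return QC_MIN_SPIKES
    x = avg.samples
    trough = avg.align_index
    depth = np.abs(x[trough])
    maxima = _local_maxima(x)
    post = maxima[maxima > trough]
    if post.size == 0:
        return QC_MULTIPEAK
    largest_peak = post[np.argmax(x[post])]
    between = post[(post > trough) & (post < largest_peak)]
    if between.size > 1:
        return QC_MULTIPEAK
    if x[largest_peak] > depth:
        return QC_AMPLITUDE
    pre = maxima[maxima < trough]
    if pre.size and np.max(x[pre]) > 0.2 * depth:
        return QC_AMPLITUDE
    return QC_RETAINED


def compute_features(avg):
    """Trough-to-peak duration and repolarization time of a retained waveform.

    Trough-to-peak: global minimum to the next local maximum.
    Repolarization: that maximum to the first subsequent zero of the second
    derivative (central second differences, sign change located by linear
    interpolation).
    """
    x = avg.samples
    trough = avg.align_index
    maxima = _local_maxima(x)
    post = maxima[maxima > trough]
    if post.size == 0:
        raise MeasurementError("no local maximum after the trough")
    peak = int(post[0])
    t2p = (peak - trough) * avg.dt_ms
    d2 = np.diff(x, 2)  # d2[i] ~ second derivative at sample i+1
    j = None
    for i in range(peak, d2.size - 1):
        a, b = d2[i], d2[i + 1]
        if a == 0:
            j = float(i)
            break
        if a * b < 0:
            j = i + a / (a - b)
            break
    if j is None:
        raise MeasurementError("no inflection point after the peak")
    t_infl = (j + 1) * avg.dt_ms  # +1: diff offset
    rep = t_infl - peak * avg.dt_ms
    if rep < 0:
        raise MeasurementError("inflection located before the peak")
    return WaveformFeatures(t2p, rep, QC_RETAINED)


def exclusion_percentage(n_total, n_excluded_by_rule):
    """Percentage of units excluded by the QC rules, to one decimal.

    E.g. 436 recorded units with 15 + 35 + 31 exclusions -> 18.6.
    """
    if n_total < 1:
        raise ParameterError("n_total must be >= 1")
    excluded = int(np.sum(n_excluded_by_rule))
    if excluded > n_total:
        raise ParameterError("more exclusions than units")
    return round(100.0 * excluded / n_total, 1)


def process_unit(snippets, sampling_rate, n_spikes_total=None, n_select=1000,
                 seed=0):
    """Full per-unit chain: select/align, reject, average, QC, features.

    `n_spikes_total` defaults to the number of snippets provided; pass the
    unit's true spike count when snippets are a subsample.
    Returns (AverageWaveform or None, WaveformFeatures, removal_fraction).
    """
    if n_spikes_total is None:
        n_spikes_total = np.atleast_2d(snippets).shape[0]
    aligned = select_and_align_snippets(snippets, sampling_rate,
                                        n_select=n_select, seed=seed)
    if aligned.shape[0] >= 2:
        retained, removed = reject_outlier_waveforms(aligned)
    else:
        retained, removed = aligned, 0.0
    avg = average_and_interpolate(retained, sampling_rate)
    status = qc_exclude_unit(avg, n_spikes_total)
    if status != QC_RETAINED:
        return avg, WaveformFeatures(None, None, status), removed
    try:
        feats = compute_features(avg)
    except MeasurementError:
        feats = WaveformFeatures(None, None, QC_MULTIPEAK)
    return avg, feats, removed
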