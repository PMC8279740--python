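"""Binned activity, baseline normalization, and response classification.

Activity is binned in 200-ms windows advanced in 20-ms steps, with each
value assigned to the window center and only windows falling fully inside
the analysis span retained.  Baseline is the firing rate in the 500 ms
preceding cue onset, computed per task.  Net activity (rate minus baseline)
is soft-normalized by the absolute maximum across conditions plus 5 spk/s,
bounding traces strictly inside (-1, 1).

A unit is labelled facilitated or suppressed around the Go signal
(-300/+900 ms) when a one-tailed sliding t test (window 200 ms, step 20 ms,
p < 0.05, uncorrected, tail set by the sign of its mean net modulation) is
significant in at least five consecutive bins; otherwise nonsignificant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ParameterError

BIN_WIDTH = 0.2
BIN_STEP = 0.02
SOFT_NORM_CONSTANT = 5.0          # spk/s
CLASSIFY_WINDOW = (-0.3, 0.9)     # s around the Go signal
BASELINE_EPOCH = (-0.5, 0.0)      # s around cue onset
MIN_CONSECUTIVE_BINS = 5
SLIDING_P = 0.05
PEAK_WINDOWS = {"object": (0.1, 0.5), "go": (0.0, 0.6)}
BURST_ISI_THRESHOLD = 0.010       # s; declared surrogate burst criterion

FACILITATED = "facilitated"
SUPPRESSED = "suppressed"
NONSIGNIFICANT = "nonsignificant"


def bin_centers_for_window(window, bin_width=BIN_WIDTH, step=BIN_STEP):
    """Centers of all bins whose full width lies inside `window`."""
    t0, t1 = window
    first = t0 + bin_width / 2
    n = int(np.floor((t1 - bin_width / 2 - first) / step + 1e-9)) + 1
    if n < 1:
        raise ParameterError(f"window {window} holds no full {bin_width}-s bin")
    return first + step * np.arange(n)


@dataclass
class BinnedActivity:
    """Per-trial binned activity of one unit, aligned to a trial event."""

    rates: np.ndarray        # (n_trials, n_bins) spk/s
    counts: np.ndarray       # (n_trials, n_bins) spike counts
    bin_centers: np.ndarray  # s relative to the alignment event
    trial_ids: np.ndarray
    alignment: str
    bin_width: float = BIN_WIDTH
    step: float = BIN_STEP


def bin_activity(spikes_by_trial, trials, alignment, window,
                 bin_width=BIN_WIDTH, step=BIN_STEP):
    """Bin one unit's spike times around `alignment` for the given trials.

    Parameters
    ----------
    spikes_by_trial : mapping trial_id -> array of spike times (s, trial clock)
    trials : TrialTable rows to include
    alignment : event column name (e.g. ``"t_go_signal"``)
    window : (t0, t1) seconds relative to the event; only bins fully inside
        are produced.

    Trials missing the alignment event are excluded with a warning.
    """
    if len(trials) == 0:
        raise ParameterError("empty trial set")
    centers = bin_centers_for_window(window, bin_width, step)
    edges_lo = centers - bin_width / 2
    kept_ids, rows = [], []
    for _, trial in trials.iterrows():
        t_ev = trial[alignment]
        if not np.isfinite(t_ev):
            continue
        st = np.asarray(spikes_by_trial.get(trial["trial_id"], ()), dtype=float)
        rel = np.sort(st - t_ev)
        lo = np.searchsorted(rel, edges_lo, side="left")
        hi = np.searchsorted(rel, edges_lo + bin_width, side="left")
        rows.append(hi - lo)
        kept_ids.append(trial["trial_id"])
    if len(kept_ids) < len(trials):
        warnings.warn(f"{len(trials) - len(kept_ids)} trial(s) missing "
                      f"{alignment}; excluded from binning")
    if not rows:
        raise ParameterError(f"no trial has the alignment event {alignment}")
    counts = np.asarray(rows, dtype=float)
    return BinnedActivity(rates=counts / bin_width, counts=counts,
                          bin_centers=centers,
                          trial_ids=np.asarray(kept_ids),
                          alignment=alignment, bin_width=bin_width, step=step)


def compute_baseline(spikes_by_trial, trials, alignment="t_cue_onset",
                     epoch=BASELINE_EPOCH):
    """Per-trial baseline rates in `epoch` around `alignment`, plus the mean.

    Returns (per_trial_rates, trial_ids, mean_rate).  Callers wanting
    task-specific baselines pass task-filtered trials.
    """
    if len(trials) == 0:
        raise ParameterError("empty trial set")
    t0, t1 = epoch
    rates, ids = [], []
    for _, trial in trials.iterrows():
        t_ev = trial[alignment]
        if not np.isfinite(t_ev):
            warnings.warn(f"trial {trial['trial_id']} missing {alignment}; dropped")
            continue
        if t_ev + t0 < 0:
            warnings.warn(f"trial {trial['trial_id']}: baseline epoch precedes "
                          "the recorded span; dropped")
            continue
        st = np.asarray(spikes_by_trial.get(trial["trial_id"], ()), dtype=float)
        n = np.count_nonzero((st >= t_ev + t0) & (st < t_ev + t1))
        rates.append(n / (t1 - t0))
        ids.append(trial["trial_id"])
    if not rates:
        raise ParameterError("no trial provides a baseline epoch")
    rates = np.asarray(rates)
    return rates, np.asarray(ids), float(rates.mean())


def net_soft_normalize(condition_traces, baseline,
                       soft_constant=SOFT_NORM_CONSTANT):
    """Soft-normalized net activity: (trace - baseline) / (max |net| + 5).

    `condition_traces` maps condition name -> mean-rate trace; the
    normalizer (absolute maximum of the net traces plus the 5-spk/s
    constant) is shared across all conditions, so outputs lie strictly
    inside (-1, 1).
    """
    net = {c: np.asarray(t, dtype=float) - baseline
           for c, t in condition_traces.items()}
    max_abs = max((np.max(np.abs(t)) if t.size else 0.0) for t in net.values())
    denom = max_abs + soft_constant
    return {c: t / denom for c, t in net.items()}


@dataclass
class ResponseLabel:
    label: str
    sign: int
    significant_bin_mask: np.ndarray
    p_values: np.ndarray
    peak_time_object: float | None = None
    peak_time_go: float | None = None


def _runs_of_true(mask, min_len):
    """Boolean mask keeping only runs of >= min_len consecutive True bins."""
    out = np.zeros_like(mask)
    i = 0
    n = mask.size
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i >= min_len:
                out[i:j] = True
            i = j
        else:
            i += 1
    return out


def classify_response(binned, baseline_rates, baseline_trial_ids=None,
                      p_threshold=SLIDING_P,
                      min_consecutive=MIN_CONSECUTIVE_BINS):
    """Facilitated/suppressed/nonsignificant label from the sliding t test.

    The test is paired per trial: each trial's baseline rate against its
    rate in each bin, one-tailed with the tail set by the sign of the unit's
    mean net modulation over the whole window.  Bins with zero-variance
    differences are nonsignificant.
    """
    rates = binned.rates
    base = np.asarray(baseline_rates, dtype=float)
    if baseline_trial_ids is not None:
        order = {tid: i for i, tid in enumerate(baseline_trial_ids)}
        keep = [i for i, tid in enumerate(binned.trial_ids) if tid in order]
        rates = rates[keep]
        base = base[[order[binned.trial_ids[i]] for i in keep]]
    if rates.shape[0] < 2:
        raise ParameterError("classification needs >= 2 trials")
    if rates.shape[0] != base.size:
        raise ParameterError("baseline and binned trial counts differ")
    mean_net = float((rates - base[:, None]).mean())
    sign = 0 if mean_net == 0 else int(np.sign(mean_net))
    tail = "greater" if sign >= 0 else "less"
    pvals = np.ones(rates.shape[1])
    for b in range(rates.shape[1]):
        diff = rates[:, b] - base
        if np.allclose(diff, diff[0]):
            continue  # t undefined; bin stays nonsignificant
        pvals[b] = stats.ttest_rel(rates[:, b], base, alternative=tail).pvalue
    mask = _runs_of_true(pvals < p_threshold, min_consecutive)
    if mask.any():
        label = FACILITATED if sign > 0 else SUPPRESSED
    else:
        label, sign = NONSIGNIFICANT, 0
    return ResponseLabel(label=label, sign=sign, significant_bin_mask=mask,
                         p_values=pvals)


def peak_time(trace, bin_centers, window):
    """Time of the maximum of a net trace within `window` (earliest on ties)."""
    if isinstance(window, str):
        window = PEAK_WINDOWS[window]
    t0, t1 = window
    sel = (bin_centers >= t0 - 1e-9) & (bin_centers <= t1 + 1e-9)
    if not sel.any():
        raise ParameterError(f"no bins inside the peak window {window}")
    sub = np.asarray(trace)[sel]
    return float(bin_centers[sel][int(np.argmax(sub))])


def firing_statistics(spikes_by_trial, trials=None):
    """Baseline-free firing statistics over concatenated within-trial ISIs.

    Returns dict with mean rate, mean ISI, ISI CV, and the burst fraction
    (proportion of ISIs below 10 ms, a surrogate burst-propensity measure).
    ISI fields are None with fewer than 2 spikes in every trial.
    """
    isis = []
    n_spikes = 0
    t_total = 0.0
    for tid, st in spikes_by_trial.items():
        st = np.sort(np.asarray(st, dtype=float))
        n_spikes += st.size
        if st.size:
            t_total += st[-1] - st[0]
        if st.size >= 2:
            isis.append(np.diff(st))
    rate = n_spikes / t_total if t_total > 0 else 0.0
    if not isis:
        return {"rate": rate, "mean_isi": None, "isi_cv": None,
                "burst_fraction": None}
    isis = np.concatenate(isis)
    return {
        "rate": rate,
        "mean_isi": float(isis.mean()),
        "isi_cv": float(isis.std(ddof=1) / isis.mean()) if isis.size > 1 else None,
        "burst_fraction": float(np.mean(isis < BURST_ISI_THRESHOLD)),
    }


def order_heatmap(normalized_traces, bin_centers, window=CLASSIFY_WINDOW):
    """Descending ordering of units by mean net normalized activity in `window`.

    Stable sort, so identical traces keep their input order.  Orderings for
    different tasks are computed by separate calls.
    """
    traces = np.atleast_2d(np.asarray(normalized_traces, dtype=float))
    sel = (bin_centers >= window[0] - 1e-9) & (bin_centers <= window[1] + 1e-9)
    scores = traces[:, sel].mean(axis=1)
    return np.argsort(-scores, kind="stable")
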