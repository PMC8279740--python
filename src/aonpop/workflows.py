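"""Bridging helpers: from a session's spikes to analysis-ready structures.

These functions wire the primitive operations together for the common
cases: per-unit waveform features, condition-wise count matrices for
decoding, normalized traces for heatmaps, and movement-aligned EXE/OBS
traces for the mutual-modulation-depth index.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import responses, waveforms
from .mmd import MMD_BASELINE_EPOCH, MMD_WINDOW, mmd_timecourse


def unit_features_table(snippets, unit_meta, seed=0, n_spikes_total=None):
    """Waveform features for every unit.

    Parameters
    ----------
    snippets : mapping unit_id -> (snippet array, sampling_rate)
    unit_meta : mapping unit_id -> area (or DataFrame with unit_id/area)
    n_spikes_total : optional mapping unit_id -> total spike count; defaults
        to the number of snippets provided per unit.
    """
    if isinstance(unit_meta, pd.DataFrame):
        unit_meta = dict(zip(unit_meta["unit_id"], unit_meta["area"]))
    rows = []
    rng = np.random.default_rng(seed)
    for uid, (arr, fs) in snippets.items():
        total = (n_spikes_total or {}).get(uid, np.atleast_2d(arr).shape[0])
        _, feats, removed = waveforms.process_unit(
            arr, fs, n_spikes_total=total, seed=rng.integers(2**31))
        rows.append({"unit_id": uid, "area": unit_meta.get(uid, "NA"),
                     "trough_to_peak_ms": feats.trough_to_peak_ms,
                     "repolarization_ms": feats.repolarization_ms,
                     "qc_status": feats.qc_status,
                     "removed_fraction": removed})
    return pd.DataFrame(rows)


def task_trials(trials, task, condition=None):
    sel = trials["task"] == task
    if condition is not None:
        sel &= trials["condition"] == condition
    return trials[sel]


def condition_counts(session, unit_id, task, variable, alignment, window):
    """Condition -> (n_trials, n_bins) count matrices for one unit.

    `variable` is ``"go_nogo"`` (conditions Go/NoGo) or ``"object"``
    (the three objects, Go trials only, since No-Go trials lack the
    movement-period structure object decoding relies on).
    """
    spikes = session.unit_spikes(unit_id)
    trials = task_trials(session.trials, task)
    out = {}
    if variable == "go_nogo":
        groups = [("Go", trials[trials["condition"] == "Go"]),
                  ("NoGo", trials[trials["condition"] == "NoGo"])]
    elif variable == "object":
        go = trials[trials["condition"] == "Go"]
        groups = [(obj, go[go["object"] == obj])
                  for obj in sorted(go["object"].unique())]
    else:
        raise ValueError(f"unknown variable {variable!r}")
    for name, grp in groups:
        binned = responses.bin_activity(spikes, grp, alignment, window)
        out[name] = binned.counts
    centers = responses.bin_centers_for_window(window)
    return out, centers


def population_condition_counts(session, task, variable, alignment, window,
                                unit_ids=None):
    """List (one entry per unit) of condition->counts maps, plus bin centers."""
    unit_ids = unit_ids or [u.unit_id for u in session.units]
    per_unit = []
    centers = None
    for uid in unit_ids:
        counts, centers = condition_counts(session, uid, task, variable,
                                           alignment, window)
        per_unit.append(counts)
    return per_unit, centers


def normalized_task_trace(session, unit_id, task, alignment="t_go_signal",
                          window=responses.CLASSIFY_WINDOW,
                          baseline_alignment="t_cue_onset",
                          baseline_epoch=responses.BASELINE_EPOCH,
                          condition="Go"):
    """Condition-averaged net soft-normalized trace for one unit and task."""
    spikes = session.unit_spikes(unit_id)
    trials = task_trials(session.trials, task)
    _, _, baseline = responses.compute_baseline(
        spikes, trials, alignment=baseline_alignment, epoch=baseline_epoch)
    sel = task_trials(session.trials, task, condition)
    binned = responses.bin_activity(spikes, sel, alignment, window)
    traces = {condition: binned.rates.mean(axis=0)}
    return responses.net_soft_normalize(traces, baseline)[condition], binned


def classify_unit(session, unit_id, task):
    """Facilitated/suppressed label of one unit around the Go signal."""
    spikes = session.unit_spikes(unit_id)
    trials = task_trials(session.trials, task)
    base_rates, base_ids, _ = responses.compute_baseline(spikes, trials)
    binned = responses.bin_activity(spikes, trials, "t_go_signal",
                                    responses.CLASSIFY_WINDOW)
    return responses.classify_response(binned, base_rates,
                                       baseline_trial_ids=base_ids)


def movement_aligned_mmd_trace(session, unit_id, task):
    """Net soft-normalized Go-trial activity around movement onset.

    Baseline for this analysis is the 500 ms preceding the Go signal.
    """
    spikes = session.unit_spikes(unit_id)
    go = task_trials(session.trials, task, "Go")
    _, _, baseline = responses.compute_baseline(
        spikes, go, alignment="t_go_signal", epoch=MMD_BASELINE_EPOCH)
    binned = responses.bin_activity(spikes, go, "t_movement_onset", MMD_WINDOW)
    traces = {"Go": binned.rates.mean(axis=0)}
    return responses.net_soft_normalize(traces, baseline)["Go"]


def session_mmd(session, unit_ids=None):
    """MMD time courses of all units: (matrix units x bins, bin centers)."""
    unit_ids = unit_ids or [u.unit_id for u in session.units]
    rows = []
    for uid in unit_ids:
        exe = movement_aligned_mmd_trace(session, uid, "EXE")
        obs = movement_aligned_mmd_trace(session, uid, "OBS")
        rows.append(mmd_timecourse(exe, obs))
    centers = responses.bin_centers_for_window(MMD_WINDOW)
    return np.asarray(rows), centers
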