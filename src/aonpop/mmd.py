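"""Mutual Modulation Depth (MMD): coupling of execution and observation activity.

For each unit, the net soft-normalized activity is computed separately for
the execution (EXE) and observation (OBS) tasks in the window -500/+700 ms
around movement onset, in 200-ms bins advanced by 20 ms (values at bin
centers, windows fully inside the span -> 51 bins centered -0.4..0.6 s).
The baseline for this analysis is the 500 ms preceding the Go signal.  The
index is the per-bin product

    MMD_n(t) = EXE_n(t) * OBS_n(t)

bounded in [-1, 1]: positive when the unit is congruently modulated in the
two tasks (jointly facilitated or jointly suppressed), negative for
opposite modulation, and near zero whenever either task shows no
modulation.  Group-level increases during movement are tested bin-by-bin
against the per-unit mean of the first five bins (one-tailed paired t test,
p < 0.01 by default; the looser 0.05 threshold is available as a switch),
keeping only runs of at least five consecutive significant bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ParameterError
from .responses import _runs_of_true, bin_centers_for_window

MMD_WINDOW = (-0.5, 0.7)          # s around movement onset
MMD_BASELINE_EPOCH = (-0.5, 0.0)  # s around the Go signal (task-specific)
MMD_P = 0.01                      # primary threshold; 0.05 available
N_REFERENCE_BINS = 5
MIN_CONSECUTIVE_BINS = 5


def mmd_bin_centers():
    return bin_centers_for_window(MMD_WINDOW)


def mmd_timecourse(exe_trace, obs_trace, bin_centers=None):
    """Per-bin product of the two tasks' net soft-normalized activities.

    Both traces must lie on the identical bin grid.  The result inherits the
    sign structure of the inputs (positive for congruent modulation) and is
    bounded by |EXE|*|OBS| <= 1.
    """
    exe = np.asarray(exe_trace, dtype=float)
    obs = np.asarray(obs_trace, dtype=float)
    if exe.shape != obs.shape:
        raise ParameterError(
            f"EXE and OBS traces are on different grids: "
            f"{exe.shape} vs {obs.shape}")
    if bin_centers is not None and np.asarray(bin_centers).shape[-1] != exe.shape[-1]:
        raise ParameterError("bin grid does not match the traces")
    return exe * obs


def mmd_significance(mmd_matrix, p_threshold=MMD_P,
                     n_reference_bins=N_REFERENCE_BINS,
                     min_consecutive=MIN_CONSECUTIVE_BINS):
    """Bin-wise one-tailed increase of group MMD over its early reference.

    The reference is each unit's mean over the first `n_reference_bins`
    bins; each bin's MMD values are compared against it across units with a
    one-tailed paired t test, and only runs of at least `min_consecutive`
    significant bins are kept in the mask.
    """
    m = np.atleast_2d(np.asarray(mmd_matrix, dtype=float))
    if m.shape[0] < 2:
        raise ParameterError("group significance needs >= 2 units")
    ref = m[:, :n_reference_bins].mean(axis=1)
    pvals = np.ones(m.shape[1])
    for b in range(m.shape[1]):
        diff = m[:, b] - ref
        if np.allclose(diff, diff[0]):
            continue
        pvals[b] = stats.ttest_rel(m[:, b], ref, alternative="greater").pvalue
    return _runs_of_true(pvals < p_threshold, min_consecutive), pvals


@dataclass
class MMDSummary:
    class_means: dict            # class -> (mean curve, SE curve, n)
    area_means: dict
    grand_mean: np.ndarray
    class_scalar: dict = field(default_factory=dict)  # class -> (mean, SE)


def mmd_summary(mmd_matrix, classes, areas=None):
    """Class- and area-level mean MMD curves with standard errors.

    Empty classes are omitted with a warning.  Also returns per-class scalar
    means (curve averaged over bins, then over units) for histogram-style
    comparisons; the factorial class-by-area testing is left to standard
    ANOVA routines on the exported per-unit values.
    """
    m = np.atleast_2d(np.asarray(mmd_matrix, dtype=float))
    classes = np.asarray(classes)
    out_class, scalar = {}, {}
    for cls in sorted(set(classes.tolist())):
        sel = classes == cls
        if not sel.any():
            import warnings
            warnings.warn(f"class {cls} empty; omitted")
            continue
        sub = m[sel]
        n = sub.shape[0]
        se = sub.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(m.shape[1])
        out_class[cls] = (sub.mean(axis=0), se, n)
        per_unit = sub.mean(axis=1)
        scalar[cls] = (float(per_unit.mean()),
                       float(per_unit.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0)
    out_area = {}
    if areas is not None:
        areas = np.asarray(areas)
        for area in sorted(set(areas.tolist())):
            sel = areas == area
            sub = m[sel]
            n = sub.shape[0]
            se = sub.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(m.shape[1])
            out_area[area] = (sub.mean(axis=0), se, n)
    return MMDSummary(class_means=out_class, area_means=out_area,
                      grand_mean=m.mean(axis=0), class_scalar=scalar)


def mmd_export_table(mmd_matrix, classes, areas):
    """Tidy per-unit table (unit, class, area, movement-epoch mean MMD) for
    downstream factorial ANOVA."""
    import pandas as pd
    m = np.atleast_2d(np.asarray(mmd_matrix, dtype=float))
    return pd.DataFrame({
        "unit_index": np.arange(m.shape[0]),
        "cell_class": np.asarray(classes),
        "area": np.asarray(areas),
        "mean_mmd": m.mean(axis=1),
    })
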