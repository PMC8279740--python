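"""Pseudo-population decoding with a Poisson naive Bayes classifier.

Independently recorded units are combined into pseudo-populations: each
unit's trials are shuffled within condition and dealt into as many splits as
there are trials per condition, every split holding one data point per
condition.  Decoding is leave-one-split-out: per time bin, units whose
training-fold activity differs between conditions at p < 0.5 (one-way F
test) are retained, class-conditional mean counts are estimated (floored at
1e-3), and the held-out split is classified by the Poisson log-likelihood

    score(class c) = sum_units [ x_u * log(lambda_uc) - lambda_uc ]

with uniform priors.  Performance is summarized as the plug-in mutual
information of the (actual, predicted) confusion matrix, normalized against
its theoretical maximum log2 K.  The full procedure is repeated over
number-matched unit subsamples (65 units drawn with replacement, 50
iterations, each averaged over 10 cross-validation runs) and smoothed with a
40-ms-SD Gaussian kernel; information onset is the first time the MI curve
exceeds one third of log2 K, with the across-iteration SD scaled by
65/N_area as the standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from .errors import ParameterError

RATE_FLOOR = 1e-3                 # counts; Poisson parameter floor
PRESELECT_P = 0.5
N_SUBSAMPLE = 65
N_ITERATIONS = 50
N_RUNS = 10
SMOOTHING_SD_S = 0.040
ONSET_FRACTION = 1.0 / 3.0
N_PER_CLASS_PER_AREA = 20
OBJECT_EPOCH = (0.2, 0.7)         # s after object presentation
REFERENCE_N = 65                  # reference population size for SE scaling


def number_matched_subsample_size(area_counts, fraction=0.75):
    """Number-matched population size: `fraction` of the smallest area,
    rounded half up (e.g. areas of 86/106/163 units -> 65)."""
    smallest = min(area_counts)
    if smallest < 1:
        raise ParameterError("every area must contain at least one unit")
    return int(np.floor(fraction * smallest + 0.5))


@dataclass
class PseudoPopulation:
    """Split-structured pseudo-population of spike counts.

    ``counts`` has shape (n_splits, n_conditions, n_units, n_bins); every
    split holds exactly one data point per condition and the unit order is
    identical across splits.
    """

    counts: np.ndarray
    conditions: list
    bin_centers: np.ndarray

    @property
    def n_splits(self):
        return self.counts.shape[0]


def make_pseudopopulation(unit_counts, bin_centers, seed=0, n_splits=None):
    """Deal each unit's within-condition trials into splits, independently.

    Parameters
    ----------
    unit_counts : list, one entry per unit, of mappings
        condition -> (n_trials, n_bins) spike-count arrays.
    n_splits : int, optional
        Defaults to the number of trials per condition (every unit must have
        at least that many trials in every condition).
    """
    if not unit_counts:
        raise ParameterError("no units supplied")
    conditions = sorted(unit_counts[0])
    rng = np.random.default_rng(seed)
    if n_splits is None:
        n_splits = min(min(np.asarray(u[c]).shape[0] for c in conditions)
                       for u in unit_counts)
    if n_splits < 2:
        raise ParameterError(
            "at least 2 trials per condition are required for "
            "leave-one-split-out decoding")
    n_bins = np.asarray(unit_counts[0][conditions[0]]).shape[1]
    X = np.empty((n_splits, len(conditions), len(unit_counts), n_bins))
    for ui, u in enumerate(unit_counts):
        for ci, c in enumerate(conditions):
            arr = np.asarray(u[c], dtype=float)
            if arr.shape[0] < n_splits:
                raise ParameterError(
                    f"unit {ui} has {arr.shape[0]} trials in condition {c!r}, "
                    f"fewer than the {n_splits} splits")
            sel = rng.permutation(arr.shape[0])[:n_splits]
            X[:, ci, ui, :] = arr[sel]
    return PseudoPopulation(counts=X, conditions=conditions,
                            bin_centers=np.asarray(bin_centers))


def preselect_features(train_counts, p_threshold=PRESELECT_P):
    """Per-unit, per-bin condition-difference mask from training data only.

    `train_counts` has shape (n_train_splits, K, n_units, n_bins).  A one-way
    F test across the K condition groups retains units with p < `p_threshold`.
    Units with identical data in all groups get p = 1 (dropped); units with
    zero within-group variance but distinct group means get p = 0 (kept).
    """
    X = np.asarray(train_counts, dtype=float)
    if X.shape[0] < 2:
        raise ParameterError("feature preselection needs >= 2 training splits")
    n, K = X.shape[0], X.shape[1]
    m_c = X.mean(axis=0)                       # (K, U, B)
    grand = m_c.mean(axis=0)                   # (U, B)
    ssb = n * ((m_c - grand) ** 2).sum(axis=0)
    ssw = ((X - m_c[None]) ** 2).sum(axis=(0, 1))
    df1, df2 = K - 1, n * K - K
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df1) / (ssw / df2)
    p = np.where(ssw > 0, stats.f.sf(F, df1, df2),
                 np.where(ssb > 0, 0.0, 1.0))
    mask = p < p_threshold
    if not mask.any():
        raise ParameterError(
            "all units were filtered out; review the preselection threshold")
    return mask


def train_poisson_nb(train_counts, floor=RATE_FLOOR):
    """Class-conditional mean counts per unit per bin, floored at `floor`."""
    lam = np.asarray(train_counts, dtype=float).mean(axis=0)
    return np.maximum(lam, floor)


def poisson_nb_scores(x, lam, mask=None):
    """Poisson naive Bayes log-likelihood of counts `x` under each class.

    ``x``: (U, B) counts; ``lam``: (K, U, B) class-conditional means;
    ``mask``: optional (U, B) feature mask.  Uniform priors (a constant)
    are omitted.  Returns (K, B) scores.
    """
    ll = x[None] * np.log(lam) - lam
    if mask is not None:
        ll = ll * mask[None]
    return ll.sum(axis=1)


def _cv_confusions(pop, rng, p_threshold=PRESELECT_P, floor=RATE_FLOOR):
    """Leave-one-split-out CV; returns per-bin confusion counts (B, K, K)."""
    X = pop.counts                              # (S, K, U, B)
    S, K, U, B = X.shape
    tot = X.sum(axis=0)                         # (K, U, B)
    lam = (tot[None] - X) / (S - 1)             # (S, K, U, B): per-fold means
    lam_f = np.maximum(lam, floor)
    # per-fold F-test preselection on the training folds
    n = S - 1
    grand = lam.mean(axis=1)                    # (S, U, B)
    ssb = n * ((lam - grand[:, None]) ** 2).sum(axis=1)
    sq_tot = (X ** 2).sum(axis=0)               # (K, U, B)
    ssw = (sq_tot[None] - X ** 2 - n * lam ** 2).sum(axis=1)
    ssw = np.maximum(ssw, 0.0)                  # numerical guard
    df1, df2 = K - 1, n * K - K
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df1) / (ssw / df2)
    p = np.where(ssw > 0, stats.f.sf(F, df1, df2),
                 np.where(ssb > 0, 0.0, 1.0))
    mask = (p < p_threshold).astype(float)      # (S, U, B)
    loglam = np.log(lam_f)
    scores = np.einsum("sub,skub,scub->skcb", mask, X, loglam) \
        - np.einsum("sub,scub->scb", mask, lam_f)[:, None]
    scores = scores + rng.uniform(0.0, 1e-9, scores.shape)  # uniform tie-break
    pred = scores.argmax(axis=2)                # (S, K, B)
    conf = np.zeros((B, K, K))
    true = np.broadcast_to(np.arange(K)[None, :, None], pred.shape)
    for b in range(B):
        np.add.at(conf[b], (true[..., b].ravel(), pred[..., b].ravel()), 1.0)
    return conf


def mi_from_confusion(confusion, base=2.0):
    """Plug-in mutual information (bits) of a confusion-count matrix."""
    c = np.asarray(confusion, dtype=float)
    if c.min() < 0 or c.sum() == 0:
        raise ParameterError("confusion matrix must be nonnegative, nonzero")
    pxy = c / c.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pxy * (np.log(pxy) - np.log(px) - np.log(py))
    return max(0.0, float(np.nansum(terms) / np.log(base)))


@dataclass
class DecodingResult:
    """Across-iteration MI time courses of one decoded variable."""

    bin_centers: np.ndarray
    mi_curves: np.ndarray          # (n_iterations, n_bins), smoothed, bits
    max_mi: float                  # log2 K
    config: dict = field(default_factory=dict)

    @property
    def mi_mean(self):
        return self.mi_curves.mean(axis=0)

    @property
    def mi_sd(self):
        if self.mi_curves.shape[0] < 2:
            return np.zeros(self.mi_curves.shape[1])
        return self.mi_curves.std(axis=0, ddof=1)

    @property
    def significance_mask(self):
        return self.mi_mean > self.max_mi * ONSET_FRACTION

    def normalized(self):
        return self.mi_curves / self.max_mi


def _decode_once(unit_counts, bin_centers, unit_idx, rng, n_runs,
                 p_threshold=PRESELECT_P):
    curves = []
    selected = [unit_counts[i] for i in unit_idx]
    for _ in range(n_runs):
        pop = make_pseudopopulation(selected, bin_centers,
                                    seed=rng.integers(2**31))
        conf = _cv_confusions(pop, rng, p_threshold=p_threshold)
        curves.append([mi_from_confusion(conf[b])
                       for b in range(conf.shape[0])])
    return np.mean(curves, axis=0)


def decode_timecourse(unit_counts, bin_centers, n_subsample=N_SUBSAMPLE,
                      n_iterations=N_ITERATIONS, n_runs=N_RUNS,
                      smoothing_sd_s=SMOOTHING_SD_S, seed=0,
                      p_threshold=PRESELECT_P):
    """Number-matched MI time course of one decoded variable.

    Per iteration: draw `n_subsample` units with replacement, run `n_runs`
    full leave-one-split-out cross-validations with fresh splits, average
    the MI curves, and smooth with a Gaussian kernel (SD `smoothing_sd_s`).
    """
    if not unit_counts:
        raise ParameterError("no units supplied")
    K = len(unit_counts[0])
    if K < 2:
        raise ParameterError("decoding needs >= 2 conditions")
    bin_centers = np.asarray(bin_centers)
    step = float(np.median(np.diff(bin_centers))) if bin_centers.size > 1 else BIN_STEP_FALLBACK
    rng = np.random.default_rng(seed)
    curves = np.empty((n_iterations, bin_centers.size))
    for it in range(n_iterations):
        idx = rng.integers(0, len(unit_counts), size=n_subsample) \
            if n_subsample else np.arange(len(unit_counts))
        raw = _decode_once(unit_counts, bin_centers, idx, rng, n_runs,
                           p_threshold=p_threshold)
        curves[it] = gaussian_filter1d(raw, smoothing_sd_s / step,
                                       mode="nearest")
    return DecodingResult(
        bin_centers=bin_centers, mi_curves=curves, max_mi=float(np.log2(K)),
        config={"n_subsample": n_subsample, "n_iterations": n_iterations,
                "n_runs": n_runs, "smoothing_sd_s": smoothing_sd_s,
                "smoothing": "Gaussian kernel, SD interpretation",
                "p_preselect": p_threshold, "seed": seed})


BIN_STEP_FALLBACK = 0.02


@dataclass
class OnsetEstimate:
    defined: bool
    mean: float | None = None
    se: float | None = None
    n_crossing: int = 0
    n_iterations: int = 0


def onset_time(result, n_area=None, fraction=ONSET_FRACTION,
               reference_n=REFERENCE_N):
    """Information onset: first crossing of MI above `fraction` * log2 K.

    Per-iteration first-crossing times are averaged; their SD, scaled by
    ``reference_n / n_area`` to account for the number-matched subsample
    size, is the standard error.  The onset is undefined when fewer than
    half of the iterations cross the threshold.
    """
    thr = result.max_mi * fraction
    onsets = []
    for curve in result.mi_curves:
        above = np.nonzero(curve > thr)[0]
        if above.size:
            onsets.append(result.bin_centers[above[0]])
    n_iter = result.mi_curves.shape[0]
    if len(onsets) < 0.5 * n_iter:
        return OnsetEstimate(defined=False, n_crossing=len(onsets),
                             n_iterations=n_iter)
    onsets = np.asarray(onsets)
    if n_area is None:
        n_area = result.config.get("n_subsample") or reference_n
    sd = float(onsets.std(ddof=1)) if onsets.size > 1 else 0.0
    se = sd * reference_n / n_area
    return OnsetEstimate(defined=True, mean=float(onsets.mean()), se=se,
                         n_crossing=len(onsets), n_iterations=n_iter)


def compare_onsets(a, b):
    """Two-tailed two-sample z test between two onset estimates."""
    if not (a.defined and b.defined):
        return {"defined": False, "z": None, "p": None}
    denom = np.hypot(a.se, b.se)
    z = 0.0 if denom == 0 and a.mean == b.mean else (a.mean - b.mean) / denom
    return {"defined": True, "z": float(z),
            "p": float(2 * stats.norm.sf(abs(z)))}


def classwise_decode(unit_counts, classes, areas, bin_centers,
                     n_per_class_per_area=N_PER_CLASS_PER_AREA,
                     n_iterations=N_ITERATIONS, n_runs=N_RUNS,
                     smoothing_sd_s=SMOOTHING_SD_S, seed=0):
    """Per-class decoding from area-balanced pseudo-populations.

    For each class, every iteration draws `n_per_class_per_area` units of
    that class with replacement from each area (a class absent from an area
    is an error naming both), decodes the pooled population, and the
    iteration curves are summarized as in `decode_timecourse`.
    """
    classes = np.asarray(classes)
    areas = np.asarray(areas)
    bin_centers = np.asarray(bin_centers)
    step = float(np.median(np.diff(bin_centers)))
    rng = np.random.default_rng(seed)
    results = {}
    for cls in sorted(set(classes.tolist())):
        pools = {}
        for area in sorted(set(areas.tolist())):
            pool = np.nonzero((classes == cls) & (areas == area))[0]
            if pool.size == 0:
                raise ParameterError(
                    f"class {cls} has no units in area {area}")
            pools[area] = pool
        K = len(unit_counts[0])
        curves = np.empty((n_iterations, bin_centers.size))
        for it in range(n_iterations):
            idx = np.concatenate([
                rng.choice(pool, size=n_per_class_per_area, replace=True)
                for pool in pools.values()])
            raw = _decode_once(unit_counts, bin_centers, idx, rng, n_runs)
            curves[it] = gaussian_filter1d(raw, smoothing_sd_s / step,
                                           mode="nearest")
        results[cls] = DecodingResult(
            bin_centers=bin_centers, mi_curves=curves,
            max_mi=float(np.log2(K)),
            config={"n_per_class_per_area": n_per_class_per_area,
                    "population_size": n_per_class_per_area * len(pools),
                    "n_iterations": n_iterations, "n_runs": n_runs,
                    "seed": seed})
    return results


def epoch_average_mi(result, window=OBJECT_EPOCH):
    """Per-iteration mean MI inside `window` (bin centers, seconds)."""
    t0, t1 = window
    bc = result.bin_centers
    if t0 < bc[0] - 1e-9 or t1 > bc[-1] + 1e-9:
        raise ParameterError(
            f"epoch window {window} extends outside the decoded span "
            f"[{bc[0]:.3f}, {bc[-1]:.3f}]")
    sel = (bc >= t0 - 1e-9) & (bc <= t1 + 1e-9)
    return result.mi_curves[:, sel].mean(axis=1)


def compare_epoch_mi(vals_a, vals_b, n_area_a=None, n_area_b=None,
                     n_subsample=N_SUBSAMPLE, reference_n=REFERENCE_N):
    """Two-sample z test on per-iteration epoch-averaged MI values.

    The SE of each group is the across-iteration SD, scaled by
    reference_n/n_area when the population sizes are given (the same
    number-matching correction used for onsets).
    """
    a, b = np.asarray(vals_a), np.asarray(vals_b)
    se_a = a.std(ddof=1) * (reference_n / n_area_a if n_area_a else 1.0)
    se_b = b.std(ddof=1) * (reference_n / n_area_b if n_area_b else 1.0)
    z = (a.mean() - b.mean()) / np.hypot(se_a, se_b)
    return {"z": float(z), "p": float(2 * stats.norm.sf(abs(z))),
            "mean_a": float(a.mean()), "mean_b": float(b.mean())}
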