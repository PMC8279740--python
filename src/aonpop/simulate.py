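"""Synthetic sessions for the execution/observation grasping task.

This module generates everything the downstream analyses consume — trial
tables with the task's event sequence, spike-waveform snippets drawn from
three distinct cell-class templates, and condition-dependent spike trains —
together with a ground-truth record per unit, so that clustering, response
classification, decoding and the mutual-modulation-depth analysis can all be
validated against planted structure.

The task emulated is a Go/No-Go visuomotor grasping paradigm run in two
blocks: the subject performs the action (EXE) or watches an experimenter
perform it (OBS).  Each trial unfolds as fixation onset -> auditory cue ->
object presentation (0.8 s after the cue) -> Go/No-Go signal (0.8-1.2 s
after the object) -> movement and pulling (Go trials only).

Spike trains are inhomogeneous Poisson processes sampled exactly by
thinning; modulation is an epoch-locked plateau with half-Gaussian rise and
decay, signed per task, scaled per object.  Waveform templates are a
difference of two Gaussian lobes (negative trough, later positive peak)
calibrated numerically so that the template's analytic trough-to-peak and
inflection-based repolarization time equal the requested parameters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import AonpopError, ParameterError

TASKS = ("EXE", "OBS")
CONDITIONS = ("Go", "NoGo")
OBJECTS = ("ring", "small_cone", "big_cone")
AREAS = ("AIP", "F5", "F6")

#: per-class (mean, SD) of the two waveform features, in ms.  Means are
#: separated by >= 4 within-class SDs per feature and the +-3 SD spans stay
#: inside the observed ranges (trough-to-peak 0.13-0.58 ms, repolarization
#: 0.0025-0.43 ms), so the three classes are recoverable by clustering.
CLASS_FEATURE_PARAMS = {
    1: {"trough_to_peak_ms": (0.20, 0.022), "repolarization_ms": (0.050, 0.012)},
    2: {"trough_to_peak_ms": (0.35, 0.022), "repolarization_ms": (0.160, 0.022)},
    3: {"trough_to_peak_ms": (0.50, 0.020), "repolarization_ms": (0.310, 0.028)},
}
#: class mixing proportions used when sampling units (narrow -> broad).
CLASS_WEIGHTS = (0.25, 0.35, 0.40)
TROUGH_TO_PEAK_RANGE_MS = (0.13, 0.58)
REPOLARIZATION_RANGE_MS = (0.0025, 0.43)
#: sampling clip for repolarization draws; the lower edge stays inside the
#: observed range but above the narrowest peak lobe the smooth two-lobe
#: template can realize at the default sampling rate.
_REP_SAMPLING_CLIP = (0.01, REPOLARIZATION_RANGE_MS[1])

#: temporal correlation of snippet noise, in samples (Gaussian kernel SD).
#: Filtered extracellular noise is band-limited; this correlation length
#: makes the pointwise +-3 SD snippet rejection remove roughly 10% of
#: snippets, matching the reported behaviour of that rule on real data.
NOISE_SMOOTHING_SAMPLES = 2.5

TRIAL_COLUMNS = [
    "trial_id", "task", "condition", "object",
    "t_fixation_onset", "t_cue_onset", "t_object_presentation", "t_go_signal",
    "t_movement_onset", "t_pulling_onset", "correct",
]


# ---------------------------------------------------------------------------
# trial tables
# ---------------------------------------------------------------------------

def generate_trials(n_per_condition, task="EXE", seed=0, objects=OBJECTS,
                    trial_id_start=0):
    """Generate a randomized trial table for one task block.

    Parameters
    ----------
    n_per_condition : int
        Trials per (condition x object) cell; with the default three objects
        this yields ``6 * n_per_condition`` trials (e.g. 10 -> 30 Go + 30
        NoGo, the trial counts used for Go/No-Go decoding).
    task : {"EXE", "OBS"}
    seed : int
        Seeds both the event-time jitter and the trial-order shuffle.
    objects : sequence of str
        Pass a single object to generate a table collapsed over objects.
    trial_id_start : int
        First trial id; lets EXE and OBS share a globally unique id space.
    """
    if n_per_condition < 1:
        raise ParameterError(f"n_per_condition must be >= 1, got {n_per_condition}")
    if task not in TASKS:
        raise ParameterError(f"task must be one of {TASKS}, got {task!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for condition in CONDITIONS:
        for obj in objects:
            for _ in range(int(n_per_condition)):
                t_fix = rng.uniform(1.0, 1.5)          # intertrial period
                t_cue = t_fix + 0.3                    # fixation triggers the cue
                t_obj = t_cue + 0.8                    # fixed cue-to-object delay
                t_go = t_obj + rng.uniform(0.8, 1.2)   # variable delay, then Go/No-Go
                if condition == "Go":
                    t_move = t_go + rng.uniform(0.25, 0.45)
                    t_pull = t_move + rng.uniform(0.30, 0.50)
                else:
                    t_move = np.nan
                    t_pull = np.nan
                rows.append((task, condition, obj, t_fix, t_cue, t_obj, t_go,
                             t_move, t_pull, True))
    order = rng.permutation(len(rows))
    rows = [rows[i] for i in order]
    table = pd.DataFrame(rows, columns=TRIAL_COLUMNS[1:])
    table.insert(0, "trial_id", np.arange(trial_id_start,
                                          trial_id_start + len(rows)))
    return table


def validate_trials(trials):
    """Check TrialTable invariants; raise ParameterError on violation."""
    event_order = ["t_fixation_onset", "t_cue_onset", "t_object_presentation",
                   "t_go_signal", "t_movement_onset", "t_pulling_onset"]
    for _, row in trials.iterrows():
        times = [row[c] for c in event_order]
        finite = [t for t in times if np.isfinite(t)]
        if any(b <= a for a, b in zip(finite, finite[1:])):
            raise ParameterError(
                f"trial {row['trial_id']}: event times not strictly increasing")
        if row["condition"] == "NoGo" and np.isfinite(row["t_movement_onset"]):
            raise ParameterError(
                f"trial {row['trial_id']}: NoGo trial has a movement onset")
        if row["condition"] == "Go" and not np.isfinite(row["t_movement_onset"]):
            raise ParameterError(
                f"trial {row['trial_id']}: Go trial lacks a movement onset")
    return trials


# ---------------------------------------------------------------------------
# waveform templates and snippets
# ---------------------------------------------------------------------------

_PEAK_FRACTION = 0.5     # positive-lobe amplitude relative to the trough


def _trough_sd(trough_to_peak_ms):
    """Negative-lobe width, scaled with spike narrowness (narrow spikes have
    narrow troughs); keeps the lobes resolvable at small separations."""
    return float(np.clip(0.35 * trough_to_peak_ms, 0.03, 0.08))


def _template_value(t, d, sp, st, a=_PEAK_FRACTION):
    return -np.exp(-t**2 / (2 * st**2)) + a * np.exp(-(t - d)**2 / (2 * sp**2))


def _template_d1(t, d, sp, st, a=_PEAK_FRACTION):
    return (t / st**2) * np.exp(-t**2 / (2 * st**2)) \
        - a * ((t - d) / sp**2) * np.exp(-(t - d)**2 / (2 * sp**2))


def _template_d2(t, d, sp, st, a=_PEAK_FRACTION):
    g1 = np.exp(-t**2 / (2 * st**2))
    g2 = np.exp(-(t - d)**2 / (2 * sp**2))
    return (1.0 / st**2 - t**2 / st**4) * g1 \
        + a * ((t - d)**2 / sp**4 - 1.0 / sp**2) * g2


def _root_after(fun, t_start, t_stop, args, n_grid=2000):
    """First sign change of `fun` in (t_start, t_stop], located by brentq."""
    ts = np.linspace(t_start, t_stop, n_grid)
    vals = fun(ts, *args)
    sign = np.sign(vals)
    for i in range(len(ts) - 1):
        if sign[i] != 0 and sign[i + 1] != 0 and sign[i] != sign[i + 1]:
            return brentq(lambda t: fun(t, *args), ts[i], ts[i + 1])
    return None


def _template_landmarks(d, sp, st):
    """Analytic trough, peak and post-peak inflection times (ms)."""
    t_trough = _root_after(_template_d1, -3 * st, d / 2.0, (d, sp, st))
    if t_trough is None:
        raise AonpopError("template trough not found")
    t_peak = _root_after(_template_d1, t_trough + 1e-4, d + 4 * sp, (d, sp, st))
    if t_peak is None:
        raise AonpopError("template peak not found")
    t_infl = _root_after(_template_d2, t_peak + 1e-5, t_peak + 6 * sp,
                         (d, sp, st))
    if t_infl is None:
        raise AonpopError("template inflection not found")
    return t_trough, t_peak, t_infl


def calibrate_template(trough_to_peak_ms, repolarization_ms, tol_ms=1e-6,
                       max_iter=200):
    """Solve for the lobe separation and width that realize the two features.

    Returns ``(d, sp, st)`` such that the analytic template's trough-to-peak
    and peak-to-inflection intervals equal the targets within `tol_ms`.
    """
    if trough_to_peak_ms <= 0 or repolarization_ms <= 0:
        raise ParameterError("waveform features must be positive")
    st = _trough_sd(trough_to_peak_ms)
    d = float(trough_to_peak_ms)
    sp = max(float(repolarization_ms), 0.008)
    step = 0.8  # damping against lobe-interference overshoot
    for _ in range(max_iter):
        t_trough, t_peak, t_infl = _template_landmarks(d, sp, st)
        err_t2p = trough_to_peak_ms - (t_peak - t_trough)
        err_rep = repolarization_ms - (t_infl - t_peak)
        if abs(err_t2p) < tol_ms and abs(err_rep) < tol_ms:
            return d, sp, st
        d = max(d + step * err_t2p, 0.02)
        sp = max(sp + step * err_rep, 0.005)
    raise AonpopError(
        f"template calibration did not converge for "
        f"({trough_to_peak_ms}, {repolarization_ms}) ms")


def waveform_template(trough_to_peak_ms, repolarization_ms, amplitude=1.0,
                      sampling_rate=40_000.0, duration_ms=4.0):
    """Sampled noiseless template with its trough exactly on the center sample."""
    d, sp, st = calibrate_template(trough_to_peak_ms, repolarization_ms)
    t_trough, _, _ = _template_landmarks(d, sp, st)
    n = int(round(duration_ms * 1e-3 * sampling_rate)) + 1
    center = n // 2
    t_ms = t_trough + (np.arange(n) - center) * 1e3 / sampling_rate
    w = _template_value(t_ms, d, sp, st)
    return amplitude * w / np.abs(w.min())


def generate_waveform_snippets(params, n_spikes, noise_sd, seed=0,
                               sampling_rate=40_000.0, duration_ms=4.0):
    """Spike-shaped snippets: calibrated template plus band-limited noise.

    Parameters
    ----------
    params : (trough_to_peak_ms, repolarization_ms, amplitude)
    n_spikes : int
    noise_sd : float
        Pointwise noise SD, same units as the amplitude.

    Returns
    -------
    snippets : ndarray, shape (n_spikes, n_samples)
    sampling_rate : float
    """
    if n_spikes < 1:
        raise ParameterError(f"n_spikes must be >= 1, got {n_spikes}")
    if noise_sd < 0:
        raise ParameterError(f"noise_sd must be >= 0, got {noise_sd}")
    if duration_ms < 2.5:
        raise ParameterError("snippet duration must be >= 2.5 ms")
    t2p, rep, amplitude = params
    template = waveform_template(t2p, rep, amplitude, sampling_rate, duration_ms)
    rng = np.random.default_rng(seed)
    snippets = np.tile(template, (int(n_spikes), 1))
    if noise_sd > 0:
        noise = rng.standard_normal(snippets.shape)
        noise = _smooth_rows(noise, NOISE_SMOOTHING_SAMPLES)
        snippets = snippets + noise_sd * noise
    return snippets, float(sampling_rate)


def _smooth_rows(x, sigma_samples):
    """Gaussian-smooth each row and rescale back to unit pointwise variance."""
    from scipy.ndimage import gaussian_filter1d
    y = gaussian_filter1d(x, sigma_samples, axis=-1, mode="constant")
    kernel_norm = gaussian_filter1d(
        np.eye(1, x.shape[-1], x.shape[-1] // 2)[0], sigma_samples,
        mode="constant")
    return y / np.sqrt(np.sum(kernel_norm**2))


# ---------------------------------------------------------------------------
# ground truth and spike trains
# ---------------------------------------------------------------------------

@dataclass
class UnitGroundTruth:
    """Planted parameters of one synthetic unit."""

    unit_id: str
    area: str
    true_class: int
    trough_to_peak_ms: float
    repolarization_ms: float
    amplitude: float
    baseline_rate: float                      # spk/s
    mod_sign_exe: int                         # {+1, -1, 0}
    mod_sign_obs: int
    modulation_depth: float                   # spk/s
    onset_latency: float                      # s, relative to onset_event
    onset_event: str = "t_movement_onset"
    object_gain: tuple = (1.0, 1.0, 1.0)
    duration: float = 0.8                     # s of sustained modulation
    rise_sd: float = 0.05                     # s; half-Gaussian ramp SD
    n_snippets: int = 1400

    def __post_init__(self):
        if self.baseline_rate < 0:
            raise ParameterError("baseline_rate must be >= 0")
        if self.modulation_depth < 0:
            raise ParameterError("modulation_depth must be >= 0")
        for s in (self.mod_sign_exe, self.mod_sign_obs):
            if s not in (-1, 0, 1):
                raise ParameterError("modulation signs must be in {-1, 0, +1}")


def rate_profile(t, gt, trial, task):
    """Instantaneous firing rate (spk/s) of `gt` at times `t` in one trial.

    Baseline plus an epoch-locked plateau modulation: half-Gaussian rise to
    the plateau at ``onset_event + onset_latency``, sustained for
    ``duration``, half-Gaussian decay after; signed per task and scaled by
    the object gain.  Rates are clipped at zero.
    """
    t = np.asarray(t, dtype=float)
    r = np.full(t.shape, gt.baseline_rate)
    sign = gt.mod_sign_exe if task == "EXE" else gt.mod_sign_obs
    if sign == 0 or gt.modulation_depth == 0:
        return r
    ev = trial[gt.onset_event]
    if not np.isfinite(ev):
        return r
    gain = gt.object_gain[OBJECTS.index(trial["object"])]
    t_on = ev + gt.onset_latency
    t_off = t_on + gt.duration
    env = np.where(
        t < t_on, np.exp(-((t - t_on) ** 2) / (2 * gt.rise_sd ** 2)),
        np.where(t <= t_off, 1.0,
                 np.exp(-((t - t_off) ** 2) / (2 * gt.rise_sd ** 2))))
    return np.clip(r + sign * gt.modulation_depth * gain * env, 0.0, None)


def rate_bound(gt, trial, task):
    sign = gt.mod_sign_exe if task == "EXE" else gt.mod_sign_obs
    if sign > 0 and np.isfinite(trial[gt.onset_event]):
        return gt.baseline_rate + gt.modulation_depth * max(gt.object_gain)
    return gt.baseline_rate


def generate_spike_train(gt, trial, task, t_stop, seed=0, t_start=0.0):
    """Sample one trial's spike train by thinning an inhomogeneous Poisson process."""
    lam_max = rate_bound(gt, trial, task)
    if lam_max < 0 or not np.isfinite(lam_max):
        raise AonpopError("rate bound invalid; generator bug")
    if lam_max == 0:
        return np.empty(0)
    rng = np.random.default_rng(seed)
    n = rng.poisson(lam_max * (t_stop - t_start))
    cand = np.sort(rng.uniform(t_start, t_stop, n))
    rates = rate_profile(cand, gt, trial, task)
    if np.any(rates < 0):
        raise AonpopError("negative rate after clipping; generator bug")
    keep = rng.uniform(0, lam_max, n) < rates
    return cand[keep]


# ---------------------------------------------------------------------------
# whole sessions
# ---------------------------------------------------------------------------

@dataclass
class Session:
    """One synthetic recording session (both task blocks)."""

    trials: pd.DataFrame                       # EXE and OBS trials, unique ids
    units: list                                # list of UnitGroundTruth
    spikes: dict                               # (unit_id, trial_id) -> spike times
    snippets: dict = field(default_factory=dict)   # unit_id -> (array, fs)
    seed: int = 0

    @property
    def ground_truth(self):
        return pd.DataFrame([dataclasses.asdict(u) for u in self.units])

    def unit_spikes(self, unit_id):
        return {tid: st for (uid, tid), st in self.spikes.items() if uid == unit_id}


def sample_unit_ground_truth(rng, unit_id, area, profile=None):
    """Draw one unit's planted parameters from the session defaults."""
    true_class = int(rng.choice([1, 2, 3], p=CLASS_WEIGHTS))
    fp = CLASS_FEATURE_PARAMS[true_class]
    t2p = float(np.clip(rng.normal(*fp["trough_to_peak_ms"]),
                        *TROUGH_TO_PEAK_RANGE_MS))
    rep = float(np.clip(rng.normal(*fp["repolarization_ms"]),
                        *_REP_SAMPLING_CLIP))
    baseline = float(rng.gamma(4.0, 2.5))      # mean 10 spk/s, right-skewed
    # response profiles: mirror-like (joint facilitation), joint suppression,
    # opposite modulation, EXE-only, unmodulated
    if profile is None:
        profile = rng.choice(
            ["joint_fac", "joint_sup", "opposite", "exe_only", "none"],
            p=[0.35, 0.15, 0.15, 0.20, 0.15])
    signs = {"joint_fac": (1, 1), "joint_sup": (-1, -1), "opposite": (1, -1),
             "exe_only": (1, 0), "none": (0, 0)}[profile]
    depth = float(rng.uniform(8.0, 20.0))
    if -1 in signs:
        depth = min(depth, max(0.8 * baseline, 1.0))
    onset_event = rng.choice(["t_movement_onset", "t_object_presentation"],
                             p=[0.6, 0.4])
    latency = float(rng.uniform(-0.1, 0.3)) if onset_event == "t_movement_onset" \
        else float(rng.uniform(0.05, 0.25))
    if rng.uniform() < 0.5:                    # object-selective half
        gains = rng.dirichlet(np.ones(3)) * 3.0
    else:
        gains = np.ones(3)
    return UnitGroundTruth(
        unit_id=unit_id, area=area, true_class=true_class,
        trough_to_peak_ms=t2p, repolarization_ms=rep,
        amplitude=float(rng.uniform(60.0, 120.0)),
        baseline_rate=baseline, mod_sign_exe=signs[0], mod_sign_obs=signs[1],
        modulation_depth=depth, onset_latency=latency, onset_event=onset_event,
        object_gain=tuple(float(g) for g in np.round(gains, 6)),
        n_snippets=int(rng.integers(600, 1000)) if rng.uniform() < 0.05
        else int(rng.integers(1100, 1700)))


def generate_session(n_units=60, n_per_condition=10, seed=0, areas=AREAS,
                     with_snippets=True, noise_sd=0.05, snippet_fs=40_000.0):
    """Generate a full synthetic session: trials, units, spikes, snippets.

    All randomness flows from `seed` through per-unit/per-trial child
    streams, so identical arguments give bit-identical sessions.
    """
    if n_units < 1 or n_per_condition < 1:
        raise ParameterError("n_units and n_per_condition must be >= 1")
    root = np.random.SeedSequence(seed)
    s_trials, s_units, s_spikes, s_snip = root.spawn(4)
    rng_units = np.random.default_rng(s_units)

    exe = generate_trials(n_per_condition, "EXE",
                          seed=np.random.default_rng(s_trials).integers(2**31))
    obs = generate_trials(n_per_condition, "OBS",
                          seed=np.random.default_rng(s_trials).integers(2**31),
                          trial_id_start=len(exe))
    trials = pd.concat([exe, obs], ignore_index=True)

    units = [sample_unit_ground_truth(rng_units, f"u{i:04d}",
                                      areas[i % len(areas)])
             for i in range(int(n_units))]

    spike_seeds = np.random.default_rng(s_spikes).integers(
        2**31, size=(len(units), len(trials)))
    spikes = {}
    for ui, gt in enumerate(units):
        for ti, trial in trials.iterrows():
            t_stop = (trial["t_pulling_onset"]
                      if np.isfinite(trial["t_pulling_onset"])
                      else trial["t_go_signal"]) + 1.5
            spikes[(gt.unit_id, trial["trial_id"])] = generate_spike_train(
                gt, trial, trial["task"], t_stop, seed=spike_seeds[ui, ti])

    snippets = {}
    if with_snippets:
        snip_seeds = np.random.default_rng(s_snip).integers(2**31,
                                                            size=len(units))
        for ui, gt in enumerate(units):
            snippets[gt.unit_id] = generate_waveform_snippets(
                (gt.trough_to_peak_ms, gt.repolarization_ms, gt.amplitude),
                gt.n_snippets, noise_sd * gt.amplitude, seed=snip_seeds[ui],
                sampling_rate=snippet_fs)
    return Session(trials=trials, units=units, spikes=spikes,
                   snippets=snippets, seed=seed)


def sample_feature_points(n=355, seed=0, class_weights=CLASS_WEIGHTS,
                          class_params=CLASS_FEATURE_PARAMS):
    """Draw (trough-to-peak, repolarization) points from the 3-class mixture.

    Convenience for clustering studies that do not need full waveforms;
    returns an (n, 2) array in ms and the true class labels (1-based).
    """
    rng = np.random.default_rng(seed)
    classes = rng.choice(sorted(class_params), size=n, p=class_weights)
    pts = np.empty((n, 2))
    for i, c in enumerate(classes):
        fp = class_params[c]
        pts[i, 0] = np.clip(rng.normal(*fp["trough_to_peak_ms"]),
                            *TROUGH_TO_PEAK_RANGE_MS)
        pts[i, 1] = np.clip(rng.normal(*fp["repolarization_ms"]),
                            *_REP_SAMPLING_CLIP)
    return pts, classes
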