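"""Session configuration and stage orchestration.

The pipeline runs simulate -> features -> cluster -> classify -> decode ->
mmd -> report in dependency order, reading and writing the TSV/JSON
artifacts defined in :mod:`aonpop.io`.  Every artifact directory carries a
run log stamping the configuration hash and seed; any parameter overridden
away from its default is echoed there exactly once.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, decoding, io, mmd as mmd_mod, responses, simulate, \
    workflows
from .errors import DependencyError

log = logging.getLogger("aonpop")

STAGES = ["simulate", "features", "cluster", "classify", "decode", "mmd",
          "report"]


@dataclass
class SessionConfig:
    """All pipeline parameters; defaults are the published analysis values."""

    out_dir: str = "aonpop_out"
    seed: int = 0
    # synthetic session
    n_units: int = 60
    n_per_condition: int = 10
    snippet_noise_sd: float = 0.05
    # binning / baseline / sliding test
    bin_width: float = responses.BIN_WIDTH
    bin_step: float = responses.BIN_STEP
    baseline_epoch: tuple = responses.BASELINE_EPOCH
    classify_window: tuple = responses.CLASSIFY_WINDOW
    sliding_p: float = responses.SLIDING_P
    min_consecutive_bins: int = responses.MIN_CONSECUTIVE_BINS
    # clustering
    k_max: int = clustering.K_MAX
    n_replicates: int = clustering.N_REPLICATES
    # decoding
    n_subsample: int = decoding.N_SUBSAMPLE
    n_iterations: int = decoding.N_ITERATIONS
    n_runs: int = decoding.N_RUNS
    smoothing_sd_s: float = decoding.SMOOTHING_SD_S
    preselect_p: float = decoding.PRESELECT_P
    decode_window: tuple = (-0.5, 1.0)      # s around the Go signal
    # mmd
    mmd_window: tuple = mmd_mod.MMD_WINDOW
    mmd_p: float = mmd_mod.MMD_P

    def config_hash(self):
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def log_overrides(self):
        defaults = SessionConfig(out_dir=self.out_dir, seed=self.seed)
        for f in dataclasses.fields(self):
            if f.name in ("out_dir", "seed"):
                continue
            if getattr(self, f.name) != getattr(defaults, f.name):
                log.info("override: %s = %r (default %r)", f.name,
                         getattr(self, f.name), getattr(defaults, f.name))


def _out(config):
    p = Path(config.out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _stamp(config, path, extra=None):
    meta = {"config_hash": config.config_hash(), "seed": config.seed}
    meta.update(extra or {})
    Path(path).write_text(json.dumps(meta, indent=1))


def _require(path, stage, needed_by):
    if not Path(path).exists():
        raise DependencyError(
            f"stage '{needed_by}' needs {path}; run stage '{stage}' first")


def stage_simulate(config):
    out = _out(config)
    session = simulate.generate_session(
        n_units=config.n_units, n_per_condition=config.n_per_condition,
        seed=config.seed, noise_sd=config.snippet_noise_sd)
    io.write_trials(session.trials, out / "trials.tsv")
    io.write_spikes(session.spikes, session.units, out / "spikes.tsv")
    io.write_snippets(session.snippets, out / "snippets.bin")
    session.ground_truth.to_csv(out / "ground_truth.tsv", sep="\t",
                                index=False)
    _stamp(config, out / "run_meta.json", {"stage": "simulate"})
    return session


def _load_session(config):
    out = _out(config)
    _require(out / "trials.tsv", "simulate", "load")
    trials = io.read_trials(out / "trials.tsv")
    spikes = io.spikes_frame_to_dict(io.read_spikes(out / "spikes.tsv"))
    gt = pd.read_csv(out / "ground_truth.tsv", sep="\t")
    units = []
    for _, r in gt.iterrows():
        d = r.to_dict()
        d["object_gain"] = tuple(
            float(x) for x in str(d["object_gain"]).strip("()").split(","))
        units.append(simulate.UnitGroundTruth(**d))
    snippets = {}
    if (out / "snippets.bin").exists():
        snippets = io.read_snippets(out / "snippets.bin")
    return simulate.Session(trials=trials, units=units, spikes=spikes,
                            snippets=snippets, seed=config.seed)


def stage_features(config, session=None):
    out = _out(config)
    session = session or _load_session(config)
    totals = {u.unit_id: u.n_snippets for u in session.units}
    feats = workflows.unit_features_table(
        session.snippets, {u.unit_id: u.area for u in session.units},
        seed=config.seed, n_spikes_total=totals)
    io.write_features(feats, out / "features.tsv")
    return feats


def stage_cluster(config):
    out = _out(config)
    _require(out / "features.tsv", "features", "cluster")
    feats = io.read_features(out / "features.tsv")
    kept = feats[feats["qc_status"] == "retained"]
    X = kept[["trough_to_peak_ms", "repolarization_ms"]].to_numpy()
    model = clustering.select_K_by_bic(
        X, k_max=config.k_max, n_replicates=config.n_replicates,
        seed=config.seed)
    classes = kept.copy()
    classes["cell_class"] = model.assignments
    for k in range(model.K):
        classes[f"posterior_{k + 1}"] = model.posteriors[:, k]
    classes.to_csv(out / "classes.tsv", sep="\t", index=False)
    (out / "model.json").write_text(json.dumps({
        "K": model.K, "means": model.means.tolist(),
        "variances": model.variances.tolist(),
        "weights": model.weights.tolist(),
        "bic_by_k": {str(k): v for k, v in model.bic_by_k.items()},
    }, indent=1))
    return model, classes


def stage_classify(config):
    out = _out(config)
    session = _load_session(config)
    rows = []
    for u in session.units:
        for task in simulate.TASKS:
            lab = workflows.classify_unit(session, u.unit_id, task)
            trace, binned = workflows.normalized_task_trace(
                session, u.unit_id, task)
            pk_go = responses.peak_time(trace, binned.bin_centers, "go") \
                if lab.label == responses.FACILITATED else None
            rows.append({"unit_id": u.unit_id, "task": task,
                         "label": lab.label, "sign": lab.sign,
                         "peak_time_go": pk_go})
    labels = pd.DataFrame(rows)
    labels.to_csv(out / "labels.tsv", sep="\t", index=False)
    return labels


def stage_decode(config):
    out = _out(config)
    session = _load_session(config)
    counts, centers = workflows.population_condition_counts(
        session, "EXE", "go_nogo", "t_go_signal", config.decode_window)
    result = decoding.decode_timecourse(
        counts, centers, n_subsample=min(config.n_subsample, len(counts)),
        n_iterations=config.n_iterations, n_runs=config.n_runs,
        smoothing_sd_s=config.smoothing_sd_s, seed=config.seed,
        p_threshold=config.preselect_p)
    pd.DataFrame({
        "bin_center_s": result.bin_centers,
        "mi_mean": result.mi_mean, "mi_sd": result.mi_sd,
        "significant": result.significance_mask,
    }).to_csv(out / "mi_curves.tsv", sep="\t", index=False)
    onset = decoding.onset_time(result, n_area=len(counts))
    (out / "onsets.json").write_text(json.dumps({
        "variable": "go_nogo", "defined": onset.defined,
        "mean": onset.mean, "se": onset.se,
        "n_iterations": onset.n_iterations,
        "smoothing": result.config.get("smoothing"),
    }, indent=1))
    return result, onset


def stage_mmd(config):
    out = _out(config)
    session = _load_session(config)
    matrix, centers = workflows.session_mmd(session)
    classes_path = out / "classes.tsv"
    _require(classes_path, "cluster", "mmd")
    classes = pd.read_csv(classes_path, sep="\t")
    cls_map = dict(zip(classes["unit_id"], classes["cell_class"]))
    unit_ids = [u.unit_id for u in session.units]
    keep = [i for i, uid in enumerate(unit_ids) if uid in cls_map]
    matrix_k = matrix[keep]
    cls = np.array([cls_map[unit_ids[i]] for i in keep])
    areas = np.array([session.units[i].area for i in keep])
    df = pd.DataFrame(matrix_k, columns=[f"{c:.2f}" for c in centers])
    df.insert(0, "unit_id", [unit_ids[i] for i in keep])
    df.to_csv(out / "mmd.tsv", sep="\t", index=False)
    summary = mmd_mod.mmd_summary(matrix_k, cls, areas)
    mask, _ = mmd_mod.mmd_significance(matrix_k, p_threshold=config.mmd_p) \
        if matrix_k.shape[0] >= 2 else (None, None)
    (out / "summary.json").write_text(json.dumps({
        "class_mean_mmd": {str(k): v for k, v in summary.class_scalar.items()},
        "significant_bins": mask.tolist() if mask is not None else None,
        "bin_centers_s": centers.tolist(),
    }, indent=1))
    return summary


def run_pipeline(config, stages=None):
    """Execute the requested stages (default: all) in dependency order."""
    stages = [s for s in STAGES if stages is None or s in stages]
    config.log_overrides()
    artifacts = {}
    for stage in stages:
        log.info("running stage %s (config %s, seed %d)", stage,
                 config.config_hash(), config.seed)
        if stage == "simulate":
            artifacts[stage] = stage_simulate(config)
        elif stage == "features":
            artifacts[stage] = stage_features(config)
        elif stage == "cluster":
            artifacts[stage] = stage_cluster(config)
        elif stage == "classify":
            artifacts[stage] = stage_classify(config)
        elif stage == "decode":
            artifacts[stage] = stage_decode(config)
        elif stage == "mmd":
            artifacts[stage] = stage_mmd(config)
        elif stage == "report":
            artifacts[stage] = _report(config)
    return artifacts


def _report(config):
    out = _out(config)
    report = {"config_hash": config.config_hash(), "seed": config.seed,
              "artifacts": sorted(p.name for p in out.iterdir())}
    (out / "report.json").write_text(json.dumps(report, indent=1))
    return report
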