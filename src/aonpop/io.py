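"""On-disk formats: TSV tables and the snippet array container.

Trials and spikes are UTF-8 TSV with '.' decimals, times in seconds.
Waveform snippets live in a flat little-endian float32 binary file with a
JSON sidecar describing sampling rate and the per-unit layout.  Readers
validate schemas and the trial-table invariants, raising `SchemaError`
naming the offending file and column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .simulate import TRIAL_COLUMNS, validate_trials

SPIKE_COLUMNS = ["unit_id", "area", "trial_id", "spike_time_s"]
FEATURE_COLUMNS = ["unit_id", "area", "trough_to_peak_ms",
                   "repolarization_ms", "qc_status"]


def _require_columns(df, columns, path):
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def write_trials(trials, path):
    trials.to_csv(path, sep="\t", index=False)


def read_trials(path):
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(df, TRIAL_COLUMNS, path)
    try:
        validate_trials(df)
    except Exception as e:
        raise SchemaError(f"{path}: {e}") from e
    return df


def write_spikes(spikes, units, path):
    """`spikes`: mapping (unit_id, trial_id) -> spike times; `units`: ground
    truth list providing the area of each unit."""
    area = {u.unit_id: u.area for u in units}
    rows = []
    for (uid, tid), st in spikes.items():
        for t in np.asarray(st):
            rows.append((uid, area[uid], tid, t))
    df = pd.DataFrame(rows, columns=SPIKE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return df


def read_spikes(path):
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(df, SPIKE_COLUMNS, path)
    if df["spike_time_s"].lt(0).any():
        bad = df.index[df["spike_time_s"] < 0][0]
        raise SchemaError(f"{path}: negative spike_time_s at line {bad + 2}")
    return df


def spikes_frame_to_dict(df):
    """(unit_id, trial_id) -> sorted spike-time array, from a spikes table."""
    out = {}
    for (uid, tid), grp in df.groupby(["unit_id", "trial_id"], sort=False):
        out[(uid, tid)] = np.sort(grp["spike_time_s"].to_numpy())
    return out


def write_snippets(snippets, path_bin, path_json=None):
    """Write per-unit snippet arrays to one float32 container plus sidecar.

    `snippets`: mapping unit_id -> (array (n_snippets, n_samples), fs).
    """
    path_bin = Path(path_bin)
    path_json = Path(path_json) if path_json else path_bin.with_suffix(".json")
    layout = []
    offset = 0
    with open(path_bin, "wb") as fh:
        for uid, (arr, fs) in snippets.items():
            arr = np.asarray(arr, dtype="<f4")
            arr.tofile(fh)
            layout.append({"unit_id": str(uid), "offset": offset,
                           "n_snippets": int(arr.shape[0]),
                           "n_samples": int(arr.shape[1]),
                           "sampling_rate_hz": float(fs)})
            offset += arr.size
    path_json.write_text(json.dumps({"dtype": "<f4", "units": layout}, indent=1))


def read_snippets(path_bin, path_json=None):
    path_bin = Path(path_bin)
    path_json = Path(path_json) if path_json else path_bin.with_suffix(".json")
    try:
        meta = json.loads(path_json.read_text())
    except FileNotFoundError:
        raise SchemaError(f"{path_json}: snippet sidecar not found")
    data = np.fromfile(path_bin, dtype=meta["dtype"])
    out = {}
    for u in meta["units"]:
        n = u["n_snippets"] * u["n_samples"]
        arr = data[u["offset"]:u["offset"] + n].reshape(u["n_snippets"],
                                                        u["n_samples"])
        out[u["unit_id"]] = (arr.astype(float), u["sampling_rate_hz"])
    return out


def write_features(features_df, path):
    _require_columns(features_df, FEATURE_COLUMNS, path)
    features_df.to_csv(path, sep="\t", index=False)


def read_features(path):
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, FEATURE_COLUMNS, path)
    return df
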