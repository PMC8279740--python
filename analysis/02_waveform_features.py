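"""Average waveforms, QC exclusion, and the two spike-shape features.

Reads the simulated session, runs the per-unit waveform chain (snippet
selection, +-3 SD rejection, spline interpolation, QC, feature extraction)
and writes features.tsv.  Reports the exclusion bookkeeping and the range
of the retained features.
"""

from common import session_config

from aonpop.pipeline import run_pipeline
from aonpop.waveforms import exclusion_percentage


def main():
    cfg = session_config()
    feats = run_pipeline(cfg, stages=["features"])["features"]
    counts = feats["qc_status"].value_counts().to_dict()
    n_excl = sum(v for k, v in counts.items() if k != "retained")
    print("QC outcome:", counts)
    print(f"excluded {n_excl}/{len(feats)} units "
          f"({exclusion_percentage(len(feats), [n_excl])}%)")
    kept = feats[feats["qc_status"] == "retained"]
    print(f"trough-to-peak range: {kept['trough_to_peak_ms'].min():.3f}"
          f"-{kept['trough_to_peak_ms'].max():.3f} ms; "
          f"repolarization range: {kept['repolarization_ms'].min():.4f}"
          f"-{kept['repolarization_ms'].max():.3f} ms")
    print(f"mean snippet removal by the +-3 SD rule: "
          f"{feats['removed_fraction'].mean():.1%}")


if __name__ == "__main__":
    main()
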