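"""Generate the synthetic execution/observation session all drivers analyze.

Writes trials.tsv, spikes.tsv, snippets.bin(+json) and ground_truth.tsv
under results/session/ and reports the session's composition.
"""

from common import session_config

from aonpop.pipeline import run_pipeline


def main():
    cfg = session_config()
    session = run_pipeline(cfg, stages=["simulate"])["simulate"]
    gt = session.ground_truth
    print(f"session seed {cfg.seed}: {len(gt)} units, "
          f"{len(session.trials)} trials "
          f"({session.trials['task'].value_counts().to_dict()})")
    print("planted cell classes:",
          gt["true_class"].value_counts().sort_index().to_dict())
    print("planted response profiles (EXE sign):",
          gt["mod_sign_exe"].value_counts().sort_index().to_dict())
    print(f"artifacts in {cfg.out_dir}")


if __name__ == "__main__":
    main()
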