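"""Shared configuration for the numbered analysis drivers.

One synthetic session stands in for the unreleased recordings; its scale
(60 units across three areas, 10 trials per condition-object cell) keeps
every driver interactive while preserving the structure the analyses rely
on.  Decoding iteration counts are reduced from the 50x10 defaults to 20x5
for the same reason; the library defaults remain the published values.
"""

from pathlib import Path

from aonpop.pipeline import SessionConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"


def session_config(seed=0):
    return SessionConfig(
        out_dir=str(RESULTS / "session"),
        seed=seed,
        n_units=60,
        n_per_condition=10,
        n_iterations=20,
        n_runs=5,
    )
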