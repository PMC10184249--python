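"""Shared configuration for the numbered analysis drivers.

Every driver runs the pipeline deterministically (seed 7) into
``results/analysis``; later drivers extend the stage list, so artifacts are
always mutually consistent.  Re-running any driver reproduces its outputs
byte-for-byte.
"""

import os

from mandiblescape.pipeline import RunConfig, run_pipeline

SEED = 7
OUT_DIR = os.path.join(os.path.dirname(__file__), "..", "results", "analysis")


def run_stages(*stages: str) -> dict:
    cfg = RunConfig(
        seed=SEED,
        out_dir=OUT_DIR,
        stages=list(stages),
        n_taxa=(40, 40),
        k=300,
        grid=(10, 10),
        n_sets=100,
        n_draws=300,
        n_boot=100,
        n_perm=499,
        write_svg=True,
    )
    return run_pipeline(cfg)
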