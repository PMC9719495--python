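"""Shared configuration for the numbered analysis drivers.

All drivers operate on one pipeline directory under results/ and must be run
in order (each stage consumes the previous stage's artifacts).
"""

from pathlib import Path

from firecomm.io import RunConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
PIPELINE_DIR = RESULTS / "pipeline"
SEED = 1


def config(stages) -> RunConfig:
    RESULTS.mkdir(exist_ok=True)
    return RunConfig(outdir=str(PIPELINE_DIR), seed=SEED, stages=tuple(stages), n_perm=999)
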