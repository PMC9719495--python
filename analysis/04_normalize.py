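"""Tame within-cell overdispersed counts (Pearson-residual cap 4) and scale
each sample by the geometric mean of its positive counts, so 1 marks a
family at its sample's typical abundance."""

import pandas as pd

from firecomm.io import run_pipeline

from _common import PIPELINE_DIR, config

if __name__ == "__main__":
    run_pipeline(config(["normalize"]))
    log = pd.read_csv(PIPELINE_DIR / "shrink_log.tsv", sep="\t")
    factors = pd.read_csv(PIPELINE_DIR / "scale_factors.tsv", sep="\t", index_col=0)
    print(f"{len(log)} counts shrunk toward their cell mean")
    print(f"scale factors: median {factors['scale_factor'].median():.1f}, "
          f"range {factors['scale_factor'].min():.1f}-{factors['scale_factor'].max():.1f}")
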