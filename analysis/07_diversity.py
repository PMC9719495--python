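"""Family-level richness/evenness with paired Poisson and beta GLMMs,
geometric-mean summaries per treatment, and beta-diversity tests (PERMANOVA
and multivariate dispersion homogeneity) on the Hellinger matrix."""

import pandas as pd

from firecomm.diversity import gm_summary
from firecomm.io import read_metadata, run_pipeline

from _common import PIPELINE_DIR, RESULTS, config

if __name__ == "__main__":
    run_pipeline(config(["diversity"]))
    div = pd.read_csv(PIPELINE_DIR / "diversity.tsv", sep="\t", index_col=0)
    meta = read_metadata(PIPELINE_DIR / "metadata.tsv").set_index("sample_id")
    meta = meta.loc[div.index]

    rows = [{"group": "all", "metric": "richness",
             **gm_summary(div["richness"]).__dict__}]
    for (sub, fire), idx in div.groupby([meta["substrate"], meta["fire"]]).groups.items():
        g = gm_summary(div.loc[idx, "evenness"])
        rows.append({"group": f"{fire}-{sub}", "metric": "evenness", **g.__dict__})
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "diversity_gm_summaries.tsv", sep="\t", index=False)
    print(summary.round(3).to_string(index=False))
    print(pd.read_csv(PIPELINE_DIR / "diversity_glmm_tests.tsv", sep="\t").round(4).to_string(index=False))
    print(pd.read_csv(PIPELINE_DIR / "beta_diversity_tests.tsv", sep="\t").round(3).to_string(index=False))
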