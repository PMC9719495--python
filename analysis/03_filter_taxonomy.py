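"""Remove rare ESVs at the 1-in-1e5 rule, build dual-database consensus
lineages (genus agreement, else the 0.80 bootstrap fallback), aggregate to
family, and audit that family is the rank whose ordination explains the most
variance."""

import pandas as pd

from firecomm import ordination as ordn
from firecomm import taxonomy as tax
from firecomm.io import read_count_table, read_metadata, run_pipeline

from _common import PIPELINE_DIR, RESULTS, config

if __name__ == "__main__":
    run_pipeline(config(["filter", "taxonomy"]))

    filtered = read_count_table(PIPELINE_DIR / "esv_counts_filtered.tsv")
    consensus = pd.read_csv(PIPELINE_DIR / "taxonomy_consensus.tsv", sep="\t").fillna("")
    meta = read_metadata(PIPELINE_DIR / "metadata.tsv")
    meta = meta.set_index("sample_id").loc[filtered.index].reset_index()

    tables = {}
    for rank in ("order", "family", "genus"):
        tab, _ = tax.aggregate_by_rank(filtered, consensus, rank)
        tables[rank] = tab
    best, audit = ordn.select_taxonomic_level(
        tables, ordn.treatment_terms(meta), ordn.condition_matrix(meta)
    )
    audit.to_csv(RESULTS / "rank_selection_audit.tsv", sep="\t")
    print(audit)
    print(f"rank with most explained variance: {best}")
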