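"""Generate the synthetic study: 30 burnt/unburnt pairs (half near pines),
litter + soil per plot (119 samples after the dropped library), 83 bacterial
families (10 planted specialists at fold 3), ~28k reads per sample, plus
simulated index reads for the demultiplexing stage."""

from firecomm.io import run_pipeline

from _common import config

if __name__ == "__main__":
    out = run_pipeline(config(["simulate"]))
    print(f"synthetic study written to {out}")
    print("tables: metadata.tsv, esv_counts.tsv, taxonomy_{primary,secondary}.tsv, "
          "barcodes.tsv, index_I1.fastq, truth_labels.tsv")
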