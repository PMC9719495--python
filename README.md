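# firecomm

Bacterial communities at the ground level of frequently burnt pine savannas
live in a shifting mosaic of burnt and unburnt patches, and of litter versus
the soil directly beneath it. `firecomm` is a tested re-implementation of the
16S amplicon analysis used to study such communities in a paired
burnt/unburnt, litter/soil field design: it takes raw index reads and
ESV-by-sample count tables through demultiplexing, filtering, taxonomy,
normalization, constrained ordination, influential-taxon statistics and
diversity models, and it ships a synthetic-study generator so the entire
pipeline is exercisable and testable without any sequencing download.

## What the pipeline computes

1. **Maximum-likelihood demultiplexing** (`firecomm.demux`). Each index read
   is scored against every candidate barcode from per-base Phred error
   probabilities (match: 1−e<sub>i</sub>; mismatch: e<sub>i</sub>/3; N: 1/4) and accepted or
   rejected on a decibel statistic built from geometric means of the matched
   and mismatched positions, `Z = −10·log₁₀(GM_unmatched) + 10·log₁₀(GM_matched)`,
   with threshold Z ≤ 6 for removal, a perfect-match shortcut, ties never
   broken arbitrarily, and a calibration routine that sets the threshold from
   known-spurious control reads.
2. **Rare-ESV filtering and consensus taxonomy** (`firecomm.taxonomy`). ESVs
   below `floor(total_reads × 10⁻⁵)` reads are removed (at a 7,084,243-read
   experiment this is a minimum count of 70). Lineages come from two
   independent per-rank classifications: agreeing genus calls adopt the
   primary database's full lineage; disagreements fall back to the deepest
   rank with bootstrap confidence ≥ 0.80. Counts aggregate to any rank with
   dropped reads reported, so reads are conserved.
3. **Normalization** (`firecomm.normalize`). Within-cell overdispersed counts
   are shrunk to a Pearson-residual cap under a leave-one-out negative
   binomial fit; every sample is then divided by the geometric mean of its
   positive counts, so a value of 1 marks a taxon at its sample's typical
   abundance.
4. **Partial constrained ordination** (`firecomm.ordination`). The table is
   Hellinger-transformed (`y = sqrt(x/rowsum)`), conditioned on plot pairing
   (and optional soil covariates), and constrained on substrate, fire and
   their interaction — transformation-based RDA, identical to a partial PCoA
   with Euclidean distances on the Hellinger matrix. Variance partitions
   exactly into conditional + constrained (per term, per axis) + residual,
   with seeded marginal permutation tests.
5. **Influential families** (`firecomm.influential`). A family is influential
   when its taxon score lies farther from the origin than the mean distance
   from the origin to the four substrate×fire centroids (both sets in the
   taxon-focused scaling, first two constrained axes). Selected families are
   modelled jointly with a log-link Tweedie GLM (power profiled on a grid in
   (1,2)) of family×fire×substrate on within-family standardized abundances;
   pairwise treatment ratios carry simultaneous max-|z| confidence intervals
   and each family is classified as a litter/soil/fire/single-cell specialist.
6. **Diversity and dispersion** (`firecomm.diversity`). Richness, Shannon H,
   Pielou J = H/ln S per sample; geometric-mean summaries with multiplicative
   ×/÷ error factors; paired Poisson (log) and beta (logit) GLMMs fitted by
   PQL with a pair random intercept; Euclidean PERMANOVA and a multivariate
   dispersion-homogeneity test with seeded permutations.
7. **Synthetic study generator** (`firecomm.simulate`). 30 burnt/unburnt
   pairs split near/away from pines, litter + soil per plot (120 samples, or
   119 with the drop-one option), negative-binomial family counts carrying
   multiplicative substrate/fire/interaction effects, multinomial ESV splits,
   simulated index reads with truth labels, and ground-truth specialist
   labels — the test bed for every stage.

## Worked example

Run the numbered drivers in order (each consumes the previous stage's
artifacts under `results/pipeline/`):

```bash
cd analysis
python 01_simulate.py && python 02_demultiplex.py && python 03_filter_taxonomy.py
python 04_normalize.py && python 05_ordinate.py && python 06_influential.py
python 07_diversity.py
```

On the default synthetic study (seed 1) the ordination driver prints

```
          component  fraction  percent
        conditional     0.109   10.922
  constrained_total     0.574   57.388
           residual     0.317   31.690
          term      F  df1  df2     p
     substrate 57.066    1   86 0.001
          fire 23.017    1   86 0.001
substrate:fire  8.229    1   86 0.001
```

i.e. the planted substrate/fire structure explains 57% of community variance
(marginal permutation tests all at the minimal attainable p), and the
influential driver prints

```
10/83 families selected (threshold 0.161)
vs planted truth: sensitivity 1.00, specificity 1.00
specialist labels: {'litter': 3, 'soil': 3, 'fire': 2, 'burnt-litter': 1, 'unburnt-soil': 1}
```

— the selection statistic recovers exactly the ten planted specialist
families and the Tweedie contrasts classify each one correctly. The
diversity driver closes with `permanova F=51.9 (df 3,115, p=0.001)` and a
homogeneous dispersion (p ≫ 0.05), mirroring the structure-without-
dispersion-difference pattern the design is meant to detect.

The same stages are scriptable via the `firecomm` CLI
(`firecomm simulate|demux|taxonomy|normalize|ordinate|run-all ...`).

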