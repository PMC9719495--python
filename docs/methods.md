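# Methods

This note records the models implemented in `firecomm`, the defaults and why
they were chosen, what the synthetic generator does and does not emulate, and
the numerical decisions a maintainer would want written down.

## Study design and the synthetic generator

The pipeline is keyed to a paired 2×2×2 field layout: `n_pairs` burnt/unburnt
plot pairs (default 30), each pair sharing pine proximity (half near, half
away), with one litter and one soil sample per plot — 120 samples, or 119
with `drop_one=True` (emulating a failed library). `generate_design` draws
the near/away pair assignment from a seeded substream; all other structure is
deterministic.

Family-level counts are negative binomial: the expected count of family *f*
in a sample is

    mu = library_size_mean * baseline_f * substrate_fold^[litter] *
         fire_fold^[burnt] * interaction_fold^[cell match]

with gamma–Poisson sampling at dispersion *k* (variance `mu + mu²/k`). ESV
counts split each family total multinomially with fixed, skewed
(Dirichlet-0.3) within-family weights, so the family-level generative means
are exactly the stated model (`aggregate → family` recovers them without
bias). Ground-truth specialist labels use a 1.5-fold cell-mean ratio rule:
large enough to clear sampling noise at the default sizes, well below the
planted fold of 3.

Defaults (chosen once, as study conditions):

| parameter | default | rationale |
|---|---|---|
| `n_pairs` | 30 | the field design (60 plots, 120 samples) |
| `library_size_mean` | 28,000 | the per-sample mean of a ~3.3M-read, 119-sample experiment |
| families | 83, with 10 planted specialists (3 litter, 3 soil, 2 fire, 2 single-cell) at fold 3 | the family count and selection problem the statistic targets |
| baselines | rank-abundance `r^-0.3` | a gentle power law; effect families sit at spread ranks so recovery is not a dominance artifact |
| dispersion `k` | 30 | calibrated so treatments explain roughly 60% of community variance, the magnitude regime the selection statistic was designed around |
| `esvs_per_family` | 12 | keeps ESV tables light while exercising the filter/aggregation path |

What the generator does **not** emulate: lineage-correlated residual
variation (each family's noise is independent), absent/rare families (every
family is present in every sample at the defaults, so richness is constant
and the richness model degenerates to an all-zero fit on default runs — the
GLMM machinery is exercised with variable richness in tests), chimeras, PCR
bias, compositional coupling between families, and biological read content
(only index reads are synthesized). Two consequences worth knowing:
passing recovery tests show the statistics work *under the stated generative
model*, not that real litter/soil data meet that model; and because family
noise is independent, aggregating *above* family averages noise away faster
than it dilutes the planted signal, so the explained-variance rank-selection
criterion favours coarser ranks on synthetic data. The rank-selection test
therefore compares family against genus (where the planted signal genuinely
splits and dilutes); on real data, where residual variation is
lineage-correlated, the comparison across all ranks is meaningful.

## Demultiplexing statistic

Per position, a matched base contributes probability `1 − e_i`
(`e_i = 10^(−Q_i/10)`), a mismatched base `e_i/3`, and an `N` in either
sequence a flat 1/4 (excluded from both geometric means). The acceptance
statistic is

    Z = −10·log10(GM over mismatched positions of e_i/3)
        + 10·log10(GM over matched positions of (1 − e_i))

with empty-set geometric means defined as 1. Reads are routed to the
maximum-likelihood barcode; a read is left unassigned on a top-two
log-likelihood tie (never broken arbitrarily, to avoid silent sample bleed)
or when Z ≤ threshold (default 6). Exact matches with no N bypass the
threshold (perfect-match shortcut) — without it, the Z of a perfect read is
`10·log10(GM_matched) ≤ 0` and every clean read would be rejected.

Properties of this closed form worth stating plainly: Z depends on the
mismatch *qualities*, not the mismatch *count* (geometric means are
count-free), so it is monotone non-increasing — not strictly decreasing — in
mismatches at fixed quality, and it is *low-quality* mismatch evidence that
drives Z toward the threshold. That matches the calibration procedure: the
threshold is set as the smallest integer excluding all of a set of
known-spurious control reads (2–3 substituted positions at uniformly high
per-base error), emulating how a removal rule of Z ≤ 6 is derived from ~500
flagged high-error reads. Dual-index reads pool both indices' positions
(log-likelihoods sum); whether to pool or score indices separately is a
genuinely open choice, recorded in the output metadata.

## Rare-ESV filter and consensus taxonomy

The cutoff is `floor(grand_total × rel_threshold)` with *strict less-than*
removal: at 7,084,243 reads and 10⁻⁵ this gives 70 (70.8 floored), and ESVs
exactly at the cutoff survive. Consensus assignment: case-insensitive genus
agreement adopts the primary database's lineage through genus regardless of
confidence (agreement dominates); otherwise the primary lineage truncates at
the deepest rank with bootstrap confidence ≥ 0.80; nothing qualifying means
unassigned. ESVs unassigned at the aggregation rank are dropped — not pooled
into a pseudo-taxon — and their read total is reported, so
`rank total + dropped = input total` always holds. No genus-synonym
resolution is attempted (deterministic, database-version independent).

## Normalization

Two separable operations:

* **Geometric-mean scaling**: each sample's counts divided by the geometric
  mean of its *positive* counts. Zeros stay zero (never imputed — the
  downstream Tweedie model handles exact zeros), and the positive outputs of
  each sample have geometric mean exactly 1.
* **Within-cell overdispersion taming**: per taxon per substrate×fire cell, a
  leave-one-out method-of-moments NB fit (LOO so a lone outlier cannot mask
  itself); observations with Pearson residual above the cap (default 4) are
  shrunk to exactly the cap (rounded), with a Poisson floor on the fitted
  standard deviation. Counts are never increased, and a taxon whose
  within-cell variance does not exceed its mean is never touched. The cap is
  an explicit, configurable stand-in for an "adjust toward the mean"
  magnitude that has no canonical value.

The pipeline applies the count-domain shrink *before* scaling (the shrink
rounds to integer counts, which is only meaningful pre-scaling).

## Partial constrained ordination

Euclidean distances on Hellinger-transformed data make constrained PCoA
identical to redundancy analysis of the transformed matrix, so the
implementation works directly on the centered Hellinger matrix: project onto
the conditioning space (pair indicators; covariates standardized), then
project the residual onto the condition-residualized constraint space, and
SVD the fitted matrix. Total variance splits exactly (to 1e-9) into
conditional + constrained + residual; per-term *marginal* fractions are
full-minus-reduced differences. Eigenvalues come from an SVD so they are
nonnegative by construction; axis signs are fixed by making each axis's
first nonzero taxon loading positive. Both biplot scalings are returned with
vegan-compatible constants (`const = ((n−1)·total_variance)^¼`): the
site-focused scaling weights site scores by `sqrt(λ/tot)`, the taxon-focused
scaling weights taxon scores instead.

Marginal permutation tests permute rows of the condition-residualized
community matrix freely (conditioning has already absorbed the pair
structure; a restricted scheme would be a config extension), recomputing
`F = (SS_term/df_term)/(SS_resid/df_resid)` each time;
`p = (1 + #{F* ≥ F})/(1 + n_perm)` from a seeded stream. Degenerate
separable data (zero residual) returns F = ∞ with exchangeable handling
under permutation.

## Influential families

Interaction centroids are arithmetic means of site scores per substrate×fire
cell on the first two constrained axes; the selection threshold is the mean
Euclidean norm of those centroids, and a family is influential when its
taxon score exceeds it. Two conventions are fixed and documented: both sets
use the **taxon-focused scaling** (the rule compares the two point sets, so
one common scaling is mandatory), and distances use the **displayed plane**
(first two axes) by default, with a per-axis |score| variant behind a flag.
The selection is invariant to any common rescaling of scores and centroids.

The Tweedie GLM models within-family standardized abundances (each family
divided by its grand mean, so only treatment-versus-treatment contrasts
within a family are interpretable) with the full family×fire×substrate
interaction, log link. The power index p ∈ (1,2) is profiled over the grid
{1.1, …, 1.9} by the series (compound Poisson–gamma) log-likelihood — raw
deviance is not comparable across p because its units change with the
variance power — and the profile recovers the true p in simulation.
Families absent from any treatment cell are excluded with a warning. The
model is a fixed-effects GLM: the pair structure is absorbed upstream by the
ordination conditioning, and stable Tweedie mixed solvers are not available;
pair indicators can be added as covariates. Type-III Wald tests use
sum-to-zero contrasts.

Pairwise treatment ratios per family get single-step simultaneous intervals:
the critical value is the 1−α quantile of max-|z| over the whole contrast
family, simulated (seeded, 20k draws) from the joint normal of the contrast
estimates. Specialist classification then follows the sign-and-significance
pattern of the four standardized cell means: a substrate (or fire)
specialist needs both its cells above 1, the other two below, and all four
cross-factor contrasts significant; a single-cell specialist needs its one
cell above 1 and significantly above the other three; anything else is
"none".

## Diversity and dispersion

Richness counts positive families, Shannon H uses natural logs, evenness is
Pielou J = H/ln S (undefined at S = 1; boundary values squeezed by
`(J(n−1)+0.5)/n` only when present, logged). Geometric-mean summaries report
the multiplicative standard-error factor `f = exp(SE of mean log)` — the
"×/÷" error bar natural to ratio-scale data.

The richness (Poisson, log) and evenness (beta, logit) models are GLMMs with
a pair random intercept, fitted by classic PQL: iterate the GLM working
response and weights around a weighted REML linear mixed model whose single
variance ratio is profiled with a closed-form (Woodbury) per-pair inverse.
The beta precision is moment-updated each outer iteration. A constant
response returns an all-zero fit (richness) or a degenerate-fit error
(evenness); non-convergence falls back to pair-as-fixed-effects GLMs,
flagged in the result. Per-effect type-I error at α = 0.05 is verified by
simulation in the test suite.

PERMANOVA partitions Euclidean sums of squares among/within groups (any
factor coding: a 4-level substrate×fire grouping on 119 samples gives df
3, 115). The dispersion test is a one-way F on distances to own-group
centroids; its permutation **recomputes centroids and distances under every
relabelling** rather than shuffling precomputed distances — with small cells
the shortcut's null p is visibly non-uniform, while the exchangeable
recomputation is calibrated (verified by KS over 200 seeds). Both use the
same seeded permutation stream conventions as the ordination tests.

## Reproducibility and problem sizes

One global seed expands into named per-stage substreams (fixed offsets), so
any stage can be rerun in isolation with identical output; pipeline stages
write JSON manifests with output checksums and are resumable. Simulation
sizes in the test suite are package choices balancing statistical resolution
against runtime: null-calibration of the three permutation tests uses 200
seeds at n = 16 with 199 permutations; Tweedie recovery uses 200 replicates
at 25 pairs (100 samples); GLMM type-I checks use 200 replicates at the full
30-pair design; planted-effect recovery runs 20 seeds of the complete
83-family study; the demultiplexing contract uses 20 seeds of 10⁴ reads
against 119 barcodes.

## Known limitations

* The demultiplexing statistic is a reconstruction from a qualitative
  description: count-free by construction, it tolerates any number of
  high-confidence mismatches at high Z. It is used for *threshold-based
  rejection of low-quality evidence*, which is the contract it was built
  for, not as a general aligner score.
* PQL is biased for variance components with small cluster sizes (pairs of
  4); fixed-effect estimates and Wald tests are accurate at the study's
  scale, which is what the pipeline reports.
* The simultaneous-CI critical value is simulation-based; with 162 contrasts
  and 20k draws its Monte-Carlo error is ≈0.01 on the critical value.
* Synthetic-data caveats listed above (independent family noise, constant
  richness at defaults, no read-content simulation).
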