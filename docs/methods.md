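# Methods

`gwasim` simulates complete GWAS datasets — genotypes, traits, and per-variant
association summary statistics — in which the causal architecture is known and
can be anchored to named biological pathways. This note describes the models,
the parameters that matter, the synthetic-data generator, and the numerical
choices, together with what the validation experiments do and do not show.

## Genotype model: haplotype-mosaic resampling

A phased reference panel of H haplotypes over M biallelic SNPs is expanded to
N diploid individuals by mosaic resampling. Each of the 2N simulated
haplotypes starts as a copy of a uniformly chosen panel haplotype; between
consecutive variants it switches, with constant probability `switch_rate`
(default 0.002 per variant interval), to a new uniformly chosen panel
haplotype. Switching resets at chromosome boundaries; two independent mosaic
haplotypes are summed to an unphased dosage in {0, 1, 2}.

Properties of this model:

* the expected allele frequency at every variant equals the panel frequency;
* local LD is preserved (at `switch_rate = 0` the simulated haplotypes are
  exact panel copies, and adjacent-variant r² decays monotonically as the
  switch rate grows);
* the simulated sample is more homogeneous than the panel, since mosaics
  average over any population structure present in the reference — the
  expected behaviour for this class of resampling generators.

The switch rate is deliberately not recombination-map aware: a constant
per-interval rate is fully specifiable, seedable, and sufficient for
clumping- and pruning-dependent logic. Panels are filtered before expansion by
an inclusive minor-allele-frequency cutoff (`maf >= min_maf`, default 0.05,
matching the usual reading of a `--maf` flag) and an optional sample
keep-list; this panel-level filter is independent of the causal-candidate
window below.

## Causal-variant selection

Every variant is annotated with its nearest gene: distance 0 inside the
(1-based, inclusive) gene interval, otherwise the base-pair gap to the nearer
boundary; equidistant ties go to the gene with the smaller start coordinate,
then the lexicographically smaller id. The tie rule is a deterministic
artifact decision — interval annotation tools do not document one. Strand is
ignored. BED input (0-based half-open) is converted on read.

The causal-candidate pool is the set of variants whose *sample* MAF lies
strictly inside (`causal_maf_min`, `causal_maf_max`), default (0.05, 0.5) —
the bounds are exclusive, so neither rare variants nor perfectly balanced
ones can be causal.

In pathway mode, K causal variants are selected, k of them anchored in a
chosen gene set:

1. among the set's genes, those with at least one pool variant mapped are
   eligible (n′ genes);
2. if k ≤ n′, k genes are sampled uniformly without replacement and one
   mapped pool variant is drawn uniformly per gene; if k > n′, remaining
   picks are assigned round-robin over fresh uniform permutations of the
   genes, so per-gene counts differ by at most one ("uniform coverage");
3. the other K − k variants are drawn uniformly from pool variants whose
   nearest gene is *not* in the set.

No MAF weighting is applied within a gene. Explicit mode instead intersects a
user-supplied id list with the genotype data, warning about absent ids.

## Phenotype model: exact variance partition

Effect sizes are drawn i.i.d. from Normal(`m_beta`, `sd_beta`²); defaults
`m_beta = 0.05`, `sd_beta = 0.001`. With this ratio (mean fifty times the
standard deviation) effects are all positive, and that is the package's
default: `random_sign=False`. An optional sign flip (`random_sign=True`) is
available for users who want direction-symmetric architectures; note that in
LD-structured genotypes the *sign of LD* between nearby causal variants is
random anyway, so direction symmetry is not required for realism.

The trait is assembled from empirically standardized components:

    g_causal = standardize( standardize_cols(X_causal) @ beta )
    g        = sqrt(hs2) * g_causal + sqrt(1 - hs2) * g_background
    y        = sqrt(h2) * g + sqrt(1 - h2) * e

where `standardize` means zero mean and unit variance in the realized sample,
`X_causal` is the N×K causal dosage matrix, and `e` is standard Gaussian
noise. Both the background score and the noise are *residualized against the
genetic score before standardization*. Consequence: the realized variance
fraction of the genetic component equals `h2` exactly (to floating error,
asserted at 1e-9), rather than in expectation only. This mirrors what
rescaling-based phenotype simulators achieve and is what the
parameter-selection experiments optimize against. A side effect worth
knowing: at `h2 = 0` the trait is exactly orthogonal to the causal score in
the realized sample, not merely independent.

The background score (`hs2 < 1`) is a polygenic score over B background
variants (default intent: non-causal candidates) with i.i.d. Normal(0, 1/B)
effects — the minimal construction honouring the `hs2` semantics; the
validated default is `hs2 = 1`, which makes the background inert. The four
multi-trait parameters `theta`, `p_indep`, `phi`, `alpha` are accepted and
validated but must hold their single-trait inert values (0, 1, 1, 0); any
other value raises immediately rather than being silently approximated.

Binary traits are produced by liability thresholding: cases are the
`round(prevalence * N)` individuals with the largest trait values (ties by
sample order). The threshold on the *empirical* quantile gives an exact case
count. Prevalence is a documented package parameter with no hidden default in
the pipeline (0.1 when unspecified on the CLI).

## Association, clumping, evaluation

Quantitative association is per-SNP simple linear regression (intercept +
dosage): Wald t with N−2 degrees of freedom, two-sided t-tail p-value —
`qassoc` semantics, no covariates. Monomorphic variants keep their row with
p = 1, beta = 0 and undefined se/stat, so row order stays aligned with the
genotype matrix. Binary association is the allelic 1-df chi-square on the 2×2
case/control × ref/alt allele table; the effect column is the log odds ratio
with the Haldane–Anscombe 0.5 correction when a cell is zero. The genomic
inflation factor is the median observed chi-square divided by the 1-df null
median (0.45493642...).

Clumping is the classic greedy scheme: candidates with p < p1 are processed
best-first (ties by chromosome order, then position); each index absorbs
unassigned same-chromosome variants with p < p2, within `kb` of the index,
and r² ≥ `r2` with the index (genotypic r², i.e. squared Pearson correlation
of dosages). Defaults p1 = 1e-4, p2 = 1e-2, r2 = 0.5, kb = 250 mirror the
standard clump defaults. The *evaluation* path overrides p1 to the
genome-wide 5e-8 so "significant loci" means genome-wide-significant clumps;
both thresholds are exposed.

Evaluation metrics: precision is the fraction of clumps containing at least
one predefined causal variant, recall the fraction of the K causal variants
captured by any clump, F1 their harmonic mean. A causal variant counts in
either the index or member role (the index-only variant is computable via a
flag). Enrichment-benchmark rates consume a tidy per-simulation result table
(sim, set, p, design): TPR is the fraction of causal-design simulations where
the target set is significant after multiple-testing correction (default
Bonferroni over the tested sets; none and Benjamini–Hochberg available), FPR
the fraction of null-design simulations with any significant set, each with
Wilson score intervals.

## The synthetic-data generator

The fixture generator stands in for a reference panel, a gene annotation, and
a gene-set database, so the whole pipeline runs offline. Panels are built
from `n_blocks` LD blocks. Each block carries one deep two-lineage split:
every haplotype joins lineage 1 with a per-block frequency q ~ Uniform(0.05,
0.95), a fraction (default 0.75) of the block's sites are divergent between
the lineages (the alt-carrying lineage randomized per site), and independent
per-site mutation noise (default rate 0.005 per haplotype per site) is
overlaid. Monomorphic sites are dropped.

This yields: strong within-block LD among common variants (they all tag the
same lineage partition), near-zero between-block LD, a frequency spectrum
mixing common partition-tagging variants with rare mutation-derived ones, and
at least 30% of variants inside the (0.05, 0.5) causal window. Gene intervals
tile the variant span (every gene covers ≥ 1 variant); gene sets always
include three calibrated sets of 17, 69, and 199 genes — small, medium, and
big pathways — plus random sets.

What the fixture does *not* emulate: realistic recombination maps, allele
frequency spectra under demography, population stratification, genotyping
error or missingness. Tests passing on fixtures therefore demonstrate the
mechanics (LD-aware clumping, pruning, selection, variance bookkeeping), not
population-genetic realism of any particular organism.

## Validation experiments and problem sizes

The headline validation (also recomputed by `scripts/acceptance.py`) uses a
panel of 200 haplotypes over 20,000 SNPs in 2,000 LD blocks, expanded to
N = 10,000 individuals — a deliberately scaled-down stand-in for a
genome-scale reference panel, sized so the full experiment runs in minutes on
one CPU. Block granularity (~10 SNPs per block) was chosen to emulate many
independent loci: with few large blocks, two causal variants frequently land
in the same block and, when their LD is negative, their marginal effects
cancel — an artifact of compressing a genome into few loci that a
genome-scale panel does not exhibit at K ≤ 30.

* Default-parameter recovery: 20 replicates at K = 10, k = 5 from the
  69-gene fixture set, default phenotype parameters, genome-wide clumping —
  mean F1 ≥ 0.95 expected (each causal variant tags h2/K = 0.01 of trait
  variance, non-centrality ≈ 101 at this N, so power at 5e-8 is essentially
  1 and false loci are rare).
* Strong-effect recall: 20 replicates at K = 20, h2 = 0.2 (same per-variant
  variance share) — mean recall ≥ 0.99 expected.
* Null calibration: at h2 = 0, the p < 0.05 fraction and the inflation
  factor are evaluated on an LD-pruned (pairwise r² < 0.1), approximately
  independent variant subset, because the binomial reference band assumes
  independent tests — within an LD block, p-values move together and the raw
  per-variant fraction has super-binomial variance by construction.

Replicates share one genotype dataset and redraw causal sets, effect sizes,
and noise, mirroring the usual practice of simulating genotypes once and
repeating the phenotype stage. All per-stage and per-replicate seeds are
derived from one master seed by SHA-256 hashing of (seed, stage, replicate),
keeping stages independently reproducible and collision-free.

## Numerical choices and degenerate inputs

* Standardization uses population variance (ddof = 0) consistently; variance
  ratios are therefore exact identities, not estimates.
* p-values are floored at the smallest positive normal double, so a perfect
  fit reports a positive p rather than zero.
* Zero-variance causal columns, empty candidate pools, disjoint keep-lists,
  empty case/control classes and unmapped gene sets are all loud, early
  errors with diagnostic content; monomorphic variants in association keep
  their rows by convention (p = 1).
* Q-Q expected quantiles use i/(M+1); PCA standardizes dosage columns by
  their sample moments and takes components from an SVD (equal to the
  covariance eigendecomposition up to per-component sign).
* Chromosome labels are opaque strings; within one input file their order is
  first appearance, while merging per-chromosome datasets sorts labels
  naturally (numeric first) so the merge is invariant to part order.

## Known limitations

* The genotype generator does not model case-control ascertainment at
  disease loci, missingness, or sex chromosomes.
* One causal pathway per simulated trait; multi-trait simulation (shared
  genetic effects, shared noise) is out of scope, and its parameters are
  accepted only at their inert values.
* LD for clumping is always computed from the analyzed genotypes themselves,
  never from an external reference.
* Enrichment tools themselves are not implemented; only their result tables
  are consumed through the adapter format.
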