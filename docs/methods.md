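# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of `rilgp`.

## Genetic model of the panel

Three fully homozygous parental inbreds are crossed pairwise; each cross is
advanced by single-seed descent for six selfing generations (F7). Meiosis
follows the Haldane model: the number of crossovers per chromosome per
meiosis is Poisson with mean equal to the map length in Morgans, positions
uniform, no interference. Residual heterozygosity therefore halves each
selfing generation, E[het] = (1/2)^6 ≈ 1.6 % at F7, which is why the
cleaning stage may treat heterozygous calls in RILs as predominantly
technical errors. Genotypes are coded as alternate-allele dosage {0, 1, 2};
after cleaning only {0, 2, missing} remain, and after imputation {0, 2}.

Default panel structure (the study conditions the generator emulates):
populations of 65/92/80 RILs, randomized incomplete blocks of 24 samples
each containing 21 RILs plus all three parents as checks, eight traits
scored in 4–7 environments with broad-sense heritabilities between 0.74 and
0.89. The genome/transcriptome scale defaults to a desk-size 3 chromosomes ×
1 Morgan with 5,000 variants and 2,000 transcripts so that the full chain
runs in seconds; all scales are plain config fields.

## Synthetic observation models

**Expression.** Transcript baseline abundances are log-normal (σ = 1.2 on
the log scale). A configurable fraction (default 0.3) of transcripts carries
a cis-eQTL: a variant located inside the transcript shifts the log-mean by
±log(2) per allele (default 2-fold between homozygotes). Blocks contribute
per-transcript multiplicative log-normal effects (σ = 0.1 on the log scale
— modest, consistent with a controlled growth-chamber setting). Counts are
negative-binomial with dispersion 0.05 (a typical bulk-RNA-seq value for
genetically identical replicates) around library-size-scaled relative
abundances; dispersion 0 degenerates to Poisson. The default mean library
size of 300,000 reads keeps per-transcript counts in a realistic range at
the desk-scale transcriptome (the real assay's much larger depth and
transcriptome scale proportionally).

**Variant observation.** Per-sample read depth at a variant is Poisson with
mean proportional to the host transcript's count in that sample
(`depth_per_count`, default 0.1), coupling callability to expression as in
real RNA-seq. Calls are missing when DP = 0 or with probability 0.05;
genotyping errors occur at rate 0.02, half becoming spurious heterozygotes
and half the opposite homozygote. Site QUAL is 10·log(1 + total DP) plus
Gaussian noise — only its ordering matters for the relative-strength filter
grid. NS is the per-variant count of samples without a call; MAF is computed
from observed calls. Parental WGS covers every simulated variant error-free
(a strict superset of what RNA observation can call); the array subset is a
random fixed set of variants typed on all lines with 1 % missingness.

**Phenotypes.** y_ijk = μ + G_i + E_j + (G×E)_ij + ε_ijk with G_i the sum of
additive effects of n_qtl (default 25) randomly placed QTL with N(0,1)
effects. Given a target H², the noise components are set from the balanced
entry-mean relation H² = σ²_G / (σ²_G + (σ²_GE + σ²_ε)/n_env), split equally
between interaction and residual; environment main-effect variance equals
σ²_G. RILs get one replicate per environment, parents three (checks).

What the generator does **not** emulate: read-level artifacts (mapping
bias, strandedness), splice isoforms, indels/multiallelic sites, linkage
disequilibrium with unobserved causal loci outside the simulated map,
spatial field trends, and trait-specific genetic architectures. Passing
tests therefore demonstrate correctness of the statistical machinery and
the qualitative behavior of the designs under the assumed structure, not
performance guarantees on any real panel.

## Variant cleaning and imputation

Repeated observations of one line (the parental checks) are united by the
major allele; ties resolve to missing (deterministic and conservative).
Cleaning then removes variants with any missing parental call, masks
heterozygous calls, and masks RIL calls inconsistent with the line's own two
parents. A raw-mode toggle skips the strict steps to emulate an uncleaned
call set. Median imputation is per population per variant; an even-count
median tie on {0,2} data resolves to the lower value (deterministic; the
choice is arbitrary but fixed). Monomorphic variants are dropped after
imputation.

The WGS consensus set intersects RNA-called variants with parental WGS
positions (matching chromosome, position and alleles; ref/alt swaps
harmonized by dosage flip, other mismatches excluded and logged) and then
fills missing RIL calls by **nearest-flank parental-haplotype imputation**:
at parent-discordant sites, the closest informative flanking markers on each
side vote for a parent; agreeing flanks impute that parent's allele,
conflicting or absent flanks fall back to the population median. This
replaces a general phased-haplotype imputation model: a RIL has exactly two
known founder haplotypes, so the mosaic structure makes full
haplotype-frequency modeling unnecessary; the simplification is exact away
from recombination breakpoints and deliberately conservative inside them.

The empirical quality filter interpolates a threshold linearly between the
observed minimum and maximum of a criterion at a relative strength in
[0, 1]: DP/MAF/QUAL keep values ≥ threshold (low end up), NS keeps values ≤
threshold (high end down); strength 0 keeps everything. "Combining" filters
means *set intersection* of the retained markers — a marker must pass every
member filter, which matches the observed shrinking variant counts under
combination; a union variant is available behind a flag since the
alternative reading is not excluded by the workflow's description. Whether
DP should be mean or minimum per-site depth is equally open; mean is
implemented.

Nei's G_st uses per-variant G_st = (H_T − H_S)/H_T with H_S the mean
within-population expected heterozygosity and H_T the expected
heterozygosity at the pooled mean allele frequency; the multilocus summary
is the ratio of locus-averaged components, with H_T = 0 sites undefined and
excluded.

## Expression processing

The detection filter keeps transcripts with nonzero counts in at least 2 %
of samples (boundary inclusive). TMM uses 30 % two-sided trimming on
M-values, 5 % on average log abundance, inverse-asymptotic-variance weights,
reference = sample whose upper-quartile cpm is closest to the mean, and
factors rescaled to geometric mean 1 — conventional defaults for the
method. EMM normalization fits, per transcript, genotype (fixed) + block
(random) by profiled REML and returns generalized-least-squares genotype
means.

DEG calling is a likelihood-ratio test between a full NB model (one mean
per genotype) and a reduced model (grand mean) at fixed dispersion, with
2ΔlogL ~ χ² on (n_genotypes − 1) degrees of freedom and BH adjustment
(significance at FDR < 0.05; the cutoff is a config value). Because nearly
all genotypes are unreplicated, the dispersion comes from the replicated
parental check groups by method of moments. Two numerical points matter:

* The **common dispersion** is the mean of per-transcript pooled ratios
  Σ_g(s²_g − m̄_g)/Σ_g m̄_g² over transcripts whose every check group
  averages ≥ 10 counts. Tag-wise estimates from a handful of replicates are
  far too noisy (badly underestimated tags inflate the LRT), the *median*
  of the right-skewed ratio distribution is biased low, and the
  ratio-of-sums across all transcripts is dominated by a few high-abundance
  transcripts; the trimmed mean-of-ratios is near-unbiased and stable.
  Tag-wise estimates remain available (`per_transcript=True`), floored at
  10⁻⁴.
* Genotype means are fit on the raw count scale, where the group sample
  mean is the exact fixed-dispersion maximum-likelihood estimate. This is
  justified because every sample targets the same library size by design;
  between-sample normalization is handled separately (TMM/EMM) and the
  genomic-prediction features default to un-normalized cpm, with TMM, EMM
  and log2(cpm+1) selectable (log scaling improves homoscedasticity of
  expression features).

The cpm-threshold scan evaluates ~40 evenly spaced quantiles of
per-transcript mean cpm between 0 and the 90th percentile (grid size is a
parameter; the procedure's grid is not otherwise pinned down), re-runs the
LRT with BH *within* each filtered set, and returns the threshold with the
maximum significant count, ties to the smallest threshold.

## Entry means and heritability

Adjusted entry means fit genotype (fixed, cell-means coding) with
environment random; the interaction is pooled into the residual unless at
least 10 % of genotype×environment cells are replicated, because with
check-only replication (three replicated parents among hundreds of
singleton lines) a separate σ²_GE is not estimable in practice — with
single-replicate cells the interaction is formally confounded with error.
ν̄ is the mean over line pairs of Var(m̂_i − m̂_j) from the GLS covariance;
σ²_G comes from a companion fit with genotype random (two-stage
entry-mean-heritability convention). All REML fits profile the residual
variance and search variance ratios on the log scale in [−12, 12]
(tolerance 10⁻⁸, bounded scalar search for one ratio, Nelder–Mead from
three starts for two), with all solves through the Woodbury identity so
cost scales with the number of random-effect levels. Row–column field
design effects are not modeled, matching the stated phenotype model.

## GBLUP

Features are column z-scored with the population (n) denominator, which
makes mean(diag(G)) = 1 exactly for G = W*W*ᵀ/m; constant columns are
dropped with a count. REML for y = μ + u + ε with u ~ N(0, G σ²_u) uses one
eigendecomposition of the training kernel and a bounded scalar search on
log λ ∈ [−12, 12], λ = σ²_e/σ²_u; kernels failing PSD by more than 10⁻⁸ are
ridge-stabilized with 10⁻⁸ on the diagonal (logged). Prediction uses the
conditional-mean form û_test = G_te,tr (G_tr,tr + λI)⁻¹(y_tr − μ̂), which
equals the joint Henderson mixed-model-equation solve with masked test
phenotypes — that equivalence is itself a test. Prediction ability is the
Pearson correlation of predictions with observed adjusted entry means (the
field-standard metric); zero-variance cases return missing with a warning.
Kernel combination is an elementwise weighted average with non-negative
weights summing to 1, equal by default; convexity preserves positive
semidefiniteness.

## Validation designs

All schemes draw without replacement, keep training and validation sets
disjoint in every repetition, store per-repetition abilities (never only
aggregates), and are seed-reproducible. Defaults mirror the study designs:
fivefold CV with 50 repetitions; fixed-size sampling with 200 repetitions,
training size 50 for intra/inter, validation 15 (intra) or 65
(cross/inter); training sizes 20–170 in steps of 15 for the learning curve.
An inter-population validation population smaller than the requested size
is capped at its size (logged). Cross-validation folds are shared across
datasets (paired evaluation), which reduces comparison variance and is what
justifies pairwise t-tests between datasets. Variance components are re-fit
within each training fold rather than reused globally — the conservative
choice, since a validation fold must not influence the fit.

The filter-grid search evaluates each criterion at 21 strengths and then
the 11 intersections (6 pairs, 4 triples, 1 quadruple) of the four
per-criterion best subsets, with a common fold seed throughout; subsets
below 10 variants are skipped and logged. The depth sweep binomially thins
counts, re-derives the variant observations from the thinned expression,
rebuilds the SNP (total / standard / quality-filtered) and expression
(total / cpm-filtered / DEG) datasets per depth, and enforces one retained
sample set across all depths so comparisons are like-for-like; the
quality-filter criteria/strengths for the depth sweep are fixed inputs
(default MAF and QUAL at strength 0.25) rather than re-optimized per depth.

## Problem sizes used by the test suite and acceptance script

Tests run the generator at a desk scale chosen once: 800–5,000 variants,
400–2,000 transcripts, populations 30/30/30 for unit tests and the full
65/92/80 where the design requires 237 lines (training sets of 170, the
heritability panel). Recovery checks average 20 replicate seeds; the DEG
null calibration uses three 2,000-transcript studies with eQTL and block
effects switched off so the type-I rate isolates the χ² approximation; the
REML null check uses n = 200 lines with m = 500 markers, where the kernel's
eigenvalue spread keeps the variance ratio identifiable (with m ≫ n the
kernel approaches the identity and σ²_u/σ²_e is barely identified — a
property of the model, not the implementation). The acceptance script runs
the full pipeline at 2,000 variants × 800 transcripts × 237 RILs.

## Known limitations

* The nearest-flank imputation ignores double recombinants between adjacent
  informative markers and falls back to the median inside breakpoint
  intervals.
* The DEG test's χ² reference is asymptotic; at very low counts the
  near-saturated NB deviance is mildly inflated, which is one reason the
  cpm filter before DEG calling helps.
* The entry-mean model cannot separate G×E from error for single-replicate
  lines; reported σ²_G and H² interpret the pooled component accordingly.
* The empirical filter grid optimizes mean CV ability on the same panel it
  reports; as in any empirical tuning, the selected subset's advantage is
  an in-sample quantity unless validated on an independent design.
* Multiallelic sites, indels, phasing beyond the two-founder model and
  Bayesian whole-genome regressions are out of scope.
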