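"""Synthetic multi-parent RIL data with the structure the pipeline assumes.

The generator emulates a three-parent crossing design: three fully homozygous
inbred parents crossed pairwise, each cross advanced by repeated selfing
(single-seed descent) to near-homozygous recombinant inbred lines (RILs).
Downstream it produces, per line:

* RNA-seq-like negative-binomial transcript counts with cis-eQTL effects,
  multiplicative block effects, and parental check replication inside
  randomized incomplete blocks;
* noisy, expression-coupled variant-call observations (per-sample read depth
  DP, site quality QUAL, missingness NS, observed MAF) written back as a
  VCF-shaped table;
* multi-environment phenotypes for several traits, with variance components
  scaled so the broad-sense heritability of entry means hits a target;
* error-free parental whole-genome variants and a sparse array genotype set.

Everything is driven by a single :class:`SimConfig`; a fixed seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import EFFECT_CLASSES, ExpressionMatrix, GenotypeMatrix, PopulationMap

PARENT_NAMES = ("P1", "P2", "P3")
POP_NAMES = ("POP1", "POP2", "POP3")

# Trait panel: 8 quantitative traits scored in 4-7 environments with
# broad-sense heritabilities between 0.74 and 0.89.
DEFAULT_TRAITS = (
    ("spike_length", 5, 0.88),
    ("awn_length", 5, 0.74),
    ("flowering_time", 7, 0.86),
    ("plant_height", 5, 0.76),
    ("grain_length", 4, 0.84),
    ("grain_width", 4, 0.85),
    ("grain_area", 4, 0.89),
    ("grain_weight", 4, 0.84),
)


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Population sizes, selfing depth, block layout and the trait panel default
    to the study conditions (65/92/80 F7 lines, blocks of 24 with three
    parental checks, 8 traits in 4-7 environments at H2 0.74-0.89); the
    genome/transcriptome scale defaults to a desk-size 3 x 1-Morgan genome
    with 5,000 variants and 2,000 transcripts.
    """

    n_chromosomes: int = 3
    map_length_per_chrom: float = 1.0  # Morgans
    chrom_length_bp: int = 50_000_000
    n_variants: int = 5000
    n_transcripts: int = 2000
    pop_sizes: tuple[int, ...] = (65, 92, 80)
    selfing_generations: int = 6  # F1 selfed 6x -> F7
    traits: tuple[tuple[str, int, float], ...] = DEFAULT_TRAITS
    n_qtl_per_trait: int = 25
    sigma_env_rel: float = 1.0  # var(env main effect) / var(genetic)
    parent_reps_per_env: int = 3
    # expression
    nb_dispersion: float = 0.05
    mean_library_size: float = 300_000.0
    block_size: int = 24
    eqtl_fraction: float = 0.3
    eqtl_log2_fold: float = 1.0
    block_log_sd: float = 0.10
    # variant observation
    depth_per_count: float = 0.1
    genotyping_error_rate: float = 0.02
    het_error_share: float = 0.5
    missing_rate: float = 0.05
    qual_noise_sd: float = 1.0
    # auxiliary datasets
    array_size: int = 500
    array_missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.genotyping_error_rate,
            self.het_error_share,
            self.missing_rate,
            self.eqtl_fraction,
            self.array_missing_rate,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if any(s <= 0 for s in self.pop_sizes):
            raise ValueError("pop_sizes must be positive")
        for _, n_env, h2 in self.traits:
            if not 0.0 < h2 <= 1.0:
                raise ValueError(f"target H2 {h2} outside (0, 1]")
            if n_env < 1:
                raise ValueError("each trait needs >= 1 environment")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")

    @property
    def trait_names(self) -> list[str]:
        return [t[0] for t in self.traits]


@dataclass
class GeneticMap:
    """Variant ids grouped by chromosome with genetic (M) and bp positions."""

    chrom: np.ndarray  # int chromosome index per variant
    pos_morgan: np.ndarray
    pos_bp: np.ndarray
    variant_ids: list[str]
    map_length: float

    def by_chrom(self):
        for c in np.unique(self.chrom):
            yield c, np.flatnonzero(self.chrom == c)


@dataclass
class Parents:
    """Three homozygous parental genomes: haplotype alleles in {0, 1}."""

    haplotypes: pd.DataFrame  # parents x variants, alt-allele indicator
    gmap: GeneticMap
    variants: pd.DataFrame  # variant metadata skeleton

    def dosage(self) -> pd.DataFrame:
        return self.haplotypes * 2.0


@dataclass
class TruthRecord:
    """Ground truth retained for recovery tests."""

    breeding_values: pd.DataFrame  # lines x traits
    qtl: dict[str, pd.Series]  # trait -> effects indexed by variant id
    eqtl: pd.Series  # transcript -> variant id (subset of transcripts)
    variance_components: dict[str, dict[str, float]]
    excluded_traits: list[str] = field(default_factory=list)


def simulate_parents(config: SimConfig, rng: np.random.Generator) -> Parents:
    """Place variants on a genetic map and draw 3 homozygous parental genomes.

    Every variant is polymorphic between at least one parent pair: the joint
    parental allele pattern is drawn uniformly from the six non-monomorphic
    patterns over three haploid alleles.
    """
    if config.n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    m = config.n_variants
    chrom = np.sort(rng.integers(0, config.n_chromosomes, size=m))
    pos = rng.uniform(0.0, config.map_length_per_chrom, size=m)
    # sort within chromosome
    order = np.lexsort((pos, chrom))
    chrom, pos = chrom[order], pos[order]
    pos_bp = np.rint(
        pos / config.map_length_per_chrom * config.chrom_length_bp
    ).astype(int) + 1
    ids = [f"var{i:06d}" for i in range(m)]
    gmap = GeneticMap(chrom, pos, pos_bp, ids, config.map_length_per_chrom)

    patterns = np.array(
        [[0, 0, 1], [0, 1, 0], [1, 0, 0], [0, 1, 1], [1, 0, 1], [1, 1, 0]]
    )
    hap = patterns[rng.integers(0, 6, size=m)].T  # 3 x m
    haplotypes = pd.DataFrame(hap, index=list(PARENT_NAMES), columns=ids, dtype=float)

    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, size=m)]
    shift = rng.integers(1, 4, size=m)
    alt = bases[(np.searchsorted(bases, ref) + shift) % 4]
    # host transcript: transcripts tile the chromosomes; a variant belongs to
    # the transcript whose window covers it
    per_chrom = config.n_transcripts // config.n_chromosomes
    t_index = np.minimum(
        (pos / config.map_length_per_chrom * per_chrom).astype(int), per_chrom - 1
    )
    transcript = np.array(
        [f"tr{c * per_chrom + t:05d}" for c, t in zip(chrom, t_index)]
    )
    effect = rng.choice(EFFECT_CLASSES, size=m, p=[0.2, 0.25, 0.3, 0.25])
    distance = np.where(
        np.isin(effect, ["upstream_gene_variant", "downstream_gene_variant"]),
        rng.integers(1, 8001, size=m),
        0,
    )
    variants = pd.DataFrame(
        {
            "chrom": [f"chr{c + 1}" for c in chrom],
            "pos": pos_bp,
            "ref": ref,
            "alt": alt,
            "transcript": transcript,
            "effect_class": effect,
            "distance_bp": distance,
        },
        index=ids,
    )
    return Parents(haplotypes, gmap, variants)


def _gamete(hap_a: np.ndarray, hap_b: np.ndarray, gmap: GeneticMap,
            rng: np.random.Generator) -> np.ndarray:
    """One meiotic product: Haldane crossovers (Poisson, no interference)."""
    out = np.empty_like(hap_a)
    for _, idx in gmap.by_chrom():
        pos = gmap.pos_morgan[idx]
        n_x = rng.poisson(gmap.map_length)
        start = rng.integers(0, 2)
        if n_x == 0:
            src = np.full(idx.size, start)
        else:
            xpos = np.sort(rng.uniform(0.0, gmap.map_length, size=n_x))
            src = (start + np.searchsorted(xpos, pos)) % 2
        out[idx] = np.where(src == 0, hap_a[idx], hap_b[idx])
    return out


def simulate_ril_population(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    n_rils: int,
    selfing_generations: int,
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> np.ndarray:
    """Advance a biparental cross by single-seed descent to F(1+g).

    Returns an (n_rils x n_variants) dosage matrix in {0, 1, 2}; residual
    heterozygosity halves each selfing generation, E[het] = (1/2)^g at F(1+g).
    """
    for hap in (parent_a, parent_b):
        if not np.isin(hap, [0, 1]).all():
            raise ValueError("parents must be homozygous haploid patterns in {0,1}")
    out = np.empty((n_rils, parent_a.size))
    for i in range(n_rils):
        h1, h2 = parent_a.copy(), parent_b.copy()
        for _ in range(selfing_generations):
            h1, h2 = _gamete(h1, h2, gmap, rng), _gamete(h1, h2, gmap, rng)
        out[i] = h1 + h2
    return out


def simulate_genotypes(
    config: SimConfig, rng: np.random.Generator, parents: Parents
) -> tuple[GenotypeMatrix, PopulationMap]:
    """All three RIL populations plus the parents, as a line-level matrix."""
    pairs = [(0, 1), (0, 2), (1, 2)]
    rows, names, line_to_pop = [], [], {}
    pop_parents = {}
    for (ia, ib), pop, n in zip(pairs, POP_NAMES, config.pop_sizes):
        pa = parents.haplotypes.iloc[ia].to_numpy()
        pb = parents.haplotypes.iloc[ib].to_numpy()
        rows.append(
            simulate_ril_population(
                pa, pb, n, config.selfing_generations, parents.gmap, rng
            )
        )
        names += [f"{pop}_{i + 1:03d}" for i in range(n)]
        for nm in names[-n:]:
            line_to_pop[nm] = pop
        pop_parents[pop] = (PARENT_NAMES[ia], PARENT_NAMES[ib])
    data = pd.DataFrame(
        np.vstack(rows), index=names, columns=parents.haplotypes.columns
    )
    data = pd.concat([parents.dosage(), data])
    return GenotypeMatrix(data, provenance="truth"), PopulationMap(
        line_to_pop, pop_parents
    )


def build_block_design(
    popmap: PopulationMap, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Randomized incomplete blocks: block_size samples = RILs + 3 checks.

    Every block contains all three parents once; RILs are randomly assigned,
    one sample each.  A final partial block holds any remainder (still with
    all checks).  Returns a sample table (sample, line, block).
    """
    rils = list(popmap.ril_lines)
    perm = rng.permutation(len(rils))
    rils = [rils[i] for i in perm]
    per_block = config.block_size - len(popmap.parents)
    if per_block < 1:
        raise ValueError("block_size too small for the parental checks")
    records = []
    n_blocks = int(np.ceil(len(rils) / per_block))
    s = 0
    for b in range(n_blocks):
        block = f"B{b + 1:02d}"
        members = rils[b * per_block : (b + 1) * per_block] + list(popmap.parents)
        for line in members:
            records.append({"sample": f"S{s + 1:03d}", "line": line, "block": block})
            s += 1
    return pd.DataFrame(records)


def simulate_phenotypes(
    genotypes: GenotypeMatrix, config: SimConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, TruthRecord]:
    """Multi-environment phenotypes with H2 calibrated variance components.

    Model: y_ijk = mu + G_i + E_j + (GxE)_ij + eps_ijk with G_i the sum of
    additive QTL effects.  Interaction and residual variances are set from
    the target H2 via the balanced-case entry-mean relation
    H2 = s2_G / (s2_G + (s2_GE + s2_e) / n_env), split equally between the
    two noise components.  RILs carry one replicate per environment, parents
    ``parent_reps_per_env`` replicates (checks).
    """
    dosage = genotypes.data.to_numpy()
    lines = genotypes.lines
    n_lines = len(lines)
    records = []
    bvs, qtl_map, vcs, excluded = {}, {}, {}, []
    for name, n_env, h2 in config.traits:
        if config.n_qtl_per_trait == 0:
            excluded.append(name)
            continue
        poly = np.flatnonzero(np.nanstd(dosage, axis=0) > 0)
        qtl_idx = rng.choice(poly, size=min(config.n_qtl_per_trait, poly.size),
                             replace=False)
        effects = rng.normal(0.0, 1.0, size=qtl_idx.size)
        g = (dosage[:, qtl_idx] - dosage[:, qtl_idx].mean(axis=0)) @ effects
        s2_g = float(g.var())
        if s2_g == 0:
            excluded.append(name)
            continue
        noise = n_env * s2_g * (1.0 - h2) / h2
        s2_ge = s2_e = noise / 2.0
        s2_env = config.sigma_env_rel * s2_g
        env_eff = rng.normal(0.0, np.sqrt(s2_env), size=n_env)
        ge = rng.normal(0.0, np.sqrt(s2_ge), size=(n_lines, n_env))
        mu = 10.0 * np.sqrt(s2_g)
        for j in range(n_env):
            env = f"{name}_env{j + 1}"
            for i, line in enumerate(lines):
                reps = (
                    config.parent_reps_per_env
                    if line in PARENT_NAMES
                    else 1
                )
                eps = rng.normal(0.0, np.sqrt(s2_e), size=reps)
                for r in range(reps):
                    records.append(
                        {
                            "line": line,
                            "environment": env,
                            "trait": name,
                            "replicate": r + 1,
                            "value": mu + g[i] + env_eff[j] + ge[i, j] + eps[r],
                        }
                    )
        bvs[name] = g
        qtl_map[name] = pd.Series(
            effects, index=[genotypes.variant_ids[k] for k in qtl_idx]
        )
        vcs[name] = {
            "sigma2_g": s2_g,
            "sigma2_env": s2_env,
            "sigma2_ge": s2_ge,
            "sigma2_e": s2_e,
            "target_h2": h2,
        }
    truth = TruthRecord(
        breeding_values=pd.DataFrame(bvs, index=lines),
        qtl=qtl_map,
        eqtl=pd.Series(dtype=object),
        variance_components=vcs,
        excluded_traits=excluded,
    )
    return pd.DataFrame(records), truth


def simulate_expression(
    genotypes: GenotypeMatrix,
    design: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    variants: pd.DataFrame | None = None,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Negative-binomial transcript counts with cis-eQTL and block effects.

    Each transcript gets a log-normal baseline abundance; a random fraction
    carries a cis-eQTL (a variant inside the transcript) shifting the mean
    multiplicatively with dosage; blocks add per-transcript multiplicative
    log-normal effects.  Counts ~ NB(mean = library_size x relative
    abundance, dispersion = nb_dispersion); dispersion 0 degenerates to
    Poisson.  Returns the matrix and the transcript -> eQTL-variant map.
    """
    n_t = config.n_transcripts
    tr_ids = [f"tr{t:05d}" for t in range(n_t)]
    base = np.exp(rng.normal(0.0, 1.2, size=n_t))
    samples = design["sample"].tolist()
    n_s = len(samples)

    eqtl = pd.Series(dtype=object)
    beta = np.zeros(n_t)
    if variants is not None and config.eqtl_fraction > 0:
        hosts = variants.groupby("transcript").groups
        candidates = [t for t in tr_ids if t in hosts]
        k = int(round(config.eqtl_fraction * n_t))
        chosen = rng.choice(candidates, size=min(k, len(candidates)), replace=False)
        pick = {t: rng.choice(list(hosts[t])) for t in chosen}
        eqtl = pd.Series(pick, dtype=object)
        beta_map = {t: config.eqtl_log2_fold * np.log(2.0) for t in chosen}
        beta = np.array([beta_map.get(t, 0.0) for t in tr_ids])

    dos = np.zeros((n_t, n_s))
    if len(eqtl):
        tr_pos = {t: i for i, t in enumerate(tr_ids)}
        line_of = design.set_index("sample")["line"]
        for t, v in eqtl.items():
            d = genotypes.data[v].loc[line_of.loc[samples]].to_numpy()
            dos[tr_pos[t]] = d - 1.0  # centered dosage in [-1, 1]

    blocks = design.set_index("sample")["block"]
    block_ids = blocks.unique()
    block_eff = {
        b: rng.normal(0.0, config.block_log_sd, size=n_t) for b in block_ids
    }
    log_mu = np.log(base)[:, None] + beta[:, None] * dos
    for j, s in enumerate(samples):
        log_mu[:, j] += block_eff[blocks.loc[s]]
    rel = np.exp(log_mu)
    rel /= rel.sum(axis=0, keepdims=True)
    mean = rel * config.mean_library_size
    if config.nb_dispersion < 1e-8:
        counts = rng.poisson(mean)
    else:
        r = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mean))
    cdf = pd.DataFrame(counts, index=tr_ids, columns=samples)
    expr = ExpressionMatrix(
        cdf, blocks, design.set_index("sample")["line"]
    )
    return expr, eqtl


def simulate_variant_observation(
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
    variants: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Noisy RNA-seq variant calls per *sample* (parents appear repeatedly).

    Per-sample read depth is Poisson with mean proportional to the host
    transcript's count in that sample, so callability tracks expression.
    Calls are missing when DP = 0 or with ``missing_rate``; with
    ``genotyping_error_rate`` a call is corrupted (a ``het_error_share``
    fraction becomes a spurious heterozygote, the rest the opposite
    homozygote).  Site QUAL increases with total DP; NS counts samples
    without a call; MAF comes from the observed calls.

    Returns (observed sample x variant dosage matrix, variant table with
    DP/QUAL/NS/MAF filled in).
    """
    samples = expression.samples
    line_of = expression.genotype
    var_ids = list(variants.index)
    host = variants["transcript"].to_numpy()
    counts = expression.counts
    host_counts = counts.reindex(host).to_numpy()  # variants x samples
    host_counts = np.nan_to_num(host_counts)
    dp = rng.poisson(config.depth_per_count * host_counts)

    true_line = genotypes.data.loc[line_of.loc[samples], var_ids].to_numpy()
    obs = true_line.astype(float).copy()

    miss = (dp == 0).T | (
        rng.random((len(samples), len(var_ids))) < config.missing_rate
    )
    err = rng.random((len(samples), len(var_ids))) < config.genotyping_error_rate
    as_het = rng.random((len(samples), len(var_ids))) < config.het_error_share
    flipped = np.where(obs == 0, 2.0, 0.0)
    obs = np.where(err & as_het, 1.0, np.where(err, flipped, obs))
    obs = np.where(miss, np.nan, obs)

    obs_df = pd.DataFrame(obs, index=samples, columns=var_ids)
    total_dp = dp.sum(axis=1)
    vt = variants.copy()
    vt["DP"] = dp.mean(axis=1)
    vt["QUAL"] = 10.0 * np.log1p(total_dp) + rng.normal(
        0.0, config.qual_noise_sd, size=len(var_ids)
    )
    vt["NS"] = np.isnan(obs).sum(axis=0)
    vt["MAF"] = observed_maf(obs_df)
    return obs_df, vt


def observed_maf(obs: pd.DataFrame) -> pd.Series:
    """Minor-allele frequency per variant from non-missing dosage calls."""
    arr = obs.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(arr, axis=0) / 2.0
    p = np.nan_to_num(p)
    return pd.Series(np.minimum(p, 1.0 - p), index=obs.columns)


def derive_wgs_and_array(
    parents: Parents,
    genotypes: GenotypeMatrix,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Error-free parental WGS genotypes and a sparse array genotype subset.

    WGS covers every simulated variant position for the parents only (a
    superset of whatever the RNA observation managed to call).  The array is
    a random fixed subset of ``array_size`` variants typed on all lines with
    low missingness.
    """
    wgs = GenotypeMatrix(parents.dosage().copy(), provenance="wgs_consensus")
    if config.array_size > len(genotypes.variant_ids):
        raise ValueError("requested array size exceeds available variants")
    chosen = rng.choice(
        genotypes.variant_ids, size=config.array_size, replace=False
    )
    chosen = [v for v in genotypes.variant_ids if v in set(chosen)]
    arr = genotypes.data[chosen].astype(float).copy()
    mask = rng.random(arr.shape) < config.array_missing_rate
    arr = arr.mask(mask)
    return wgs, GenotypeMatrix(arr, provenance="array")


def thin_reads(
    expression: ExpressionMatrix,
    fraction: float,
    rng: np.random.Generator,
    min_reads: float = 0.0,
) -> ExpressionMatrix:
    """Binomially thin counts to a fraction of the original sequencing depth.

    Samples whose thinned totals fall below ``min_reads`` are excluded; the
    caller is responsible for enforcing the same retained sample set across
    datasets being compared.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        thinned = expression.counts.copy()
    else:
        thinned = pd.DataFrame(
            rng.binomial(expression.counts.to_numpy().astype(int), fraction),
            index=expression.counts.index,
            columns=expression.counts.columns,
        )
    keep = thinned.sum(axis=0) >= min_reads
    kept = [s for s, k in zip(thinned.columns, keep) if k]
    return ExpressionMatrix(
        thinned[kept],
        expression.blocks.loc[kept],
        expression.genotype.loc[kept],
        None,
    )


@dataclass
class SimResult:
    """Bundle of one full synthetic study."""

    config: SimConfig
    parents: Parents
    genotypes: GenotypeMatrix  # line-level truth (parents + RILs)
    popmap: PopulationMap
    design: pd.DataFrame
    expression: ExpressionMatrix
    observed: pd.DataFrame  # sample x variant noisy calls
    variants: pd.DataFrame  # with DP/QUAL/NS/MAF
    phenotypes: pd.DataFrame
    truth: TruthRecord
    wgs: GenotypeMatrix
    array: GenotypeMatrix


def simulate_study(config: SimConfig) -> SimResult:
    """Run the whole generator under one seed."""
    rng = np.random.default_rng(config.seed)
    parents = simulate_parents(config, rng)
    genotypes, popmap = simulate_genotypes(config, rng, parents)
    design = build_block_design(popmap, config, rng)
    phenos, truth = simulate_phenotypes(genotypes, config, rng)
    expr, eqtl = simulate_expression(
        genotypes, design, config, rng, variants=parents.variants
    )
    truth.eqtl = eqtl
    observed, variants = simulate_variant_observation(
        genotypes, expr, parents.variants, config, rng
    )
    wgs, array = derive_wgs_and_array(parents, genotypes, config, rng)
    return SimResult(
        config=config,
        parents=parents,
        genotypes=genotypes,
        popmap=popmap,
        design=design,
        expression=expr,
        observed=observed,
        variants=variants,
        phenotypes=phenos,
        truth=truth,
        wgs=wgs,
        array=array,
    )
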