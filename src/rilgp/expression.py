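"""Read-count processing: detection filter, cpm, TMM, block adjustment, DEG.

The differential-expression test is a negative-binomial likelihood-ratio
test per transcript: the full model fits one mean per genotype, the reduced
model a single grand mean, with a fixed dispersion estimated from the
replicated parental check groups by a pooled method-of-moments.  Because
most genotypes are unreplicated, the full model is near-saturated; the test
statistic is 2 * (logL_full - logL_reduced) on (n_genotypes - 1) degrees of
freedom.  Library sizes are near-identical by design (all samples target the
same depth), so genotype means are fit on the raw count scale where the
group sample mean is the exact fixed-dispersion maximum-likelihood estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .mixedlm import fit_reml, indicator
from .types import ExpressionMatrix

DISPERSION_FLOOR = 1e-4
DEG_ALPHA = 0.05


def detection_filter(expr: ExpressionMatrix, fraction: float = 0.02) -> ExpressionMatrix:
    """Keep transcripts detected (nonzero) in at least ``fraction`` of samples."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    share = (expr.counts > 0).mean(axis=1)
    return expr.subset_transcripts(expr.counts.index[share >= fraction])


def cpm(expr: ExpressionMatrix) -> pd.DataFrame:
    """Counts per million of the library size; columns sum to 1e6."""
    libs = expr.library_sizes
    zero = libs[libs <= 0].index
    if len(zero):
        warnings.warn(f"excluding zero-library samples: {list(zero)}", stacklevel=2)
    keep = [s for s in expr.samples if s not in set(zero)]
    return expr.counts[keep] / libs[keep] * 1e6


def tmm_factors(
    expr: ExpressionMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    reference: str | None = None,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors (geometric mean 1).

    M-values (log2 count ratios to a reference sample, library-size scaled)
    are two-sided trimmed by ``trim_m`` and the average log abundance by
    ``trim_a``; the factor is 2 to the inverse-variance-weighted mean of the
    surviving M-values.  The reference is the sample whose upper-quartile
    cpm is closest to the mean upper quartile.
    """
    counts = expr.counts.to_numpy(dtype=float)
    libs = expr.library_sizes.to_numpy(dtype=float)
    samples = expr.samples
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    if reference is None:
        cp = counts / libs * 1e6
        q75 = np.nanquantile(np.where(cp > 0, cp, np.nan), 0.75, axis=0)
        reference = samples[int(np.argmin(np.abs(q75 - q75.mean())))]
    r = samples.index(reference)
    yr, lr = counts[:, r], libs[r]

    factors = np.ones(len(samples))
    for j, s in enumerate(samples):
        if s == reference:
            continue
        yj, lj = counts[:, j], libs[j]
        use = (yj > 0) & (yr > 0)
        if not use.any():
            warnings.warn(
                f"sample {s} shares no expressed transcripts with reference",
                stacklevel=2,
            )
            continue
        pj, pr = yj[use] / lj, yr[use] / lr
        m = np.log2(pj / pr)
        a = 0.5 * np.log2(pj * pr)
        w = (lj - yj[use]) / (lj * yj[use]) + (lr - yr[use]) / (lr * yr[use])
        keep = _double_trim(m, a, trim_m, trim_a)
        if not keep.any():
            factors[j] = 1.0
            continue
        factors[j] = 2.0 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=samples)


def _double_trim(m, a, trim_m, trim_a):
    """Joint two-sided trim on M and A ranks (kept = inside both windows)."""
    n = m.size
    rm = stats.rankdata(m)
    ra = stats.rankdata(a)
    keep_m = (rm > n * trim_m) & (rm <= n * (1.0 - trim_m))
    keep_a = (ra > n * trim_a) & (ra <= n * (1.0 - trim_a))
    return keep_m & keep_a


def emm_adjust(
    expr: ExpressionMatrix,
    response: pd.DataFrame | None = None,
    transcripts=None,
) -> pd.DataFrame:
    """Block-adjusted genotype means per transcript (EMM normalization).

    For each transcript, fits y = mu + genotype (fixed) + block (random) +
    error, the block-variance ratio by restricted likelihood, and returns the
    generalized-least-squares genotype means (transcripts x genotypes).
    Falls back to raw genotype means when fewer than 2 blocks exist.
    """
    if response is None:
        response = cpm(expr)
    samples = list(response.columns)
    geno = expr.genotype.loc[samples]
    blocks = expr.blocks.loc[samples]
    X, geno_levels = indicator(geno)
    if transcripts is None:
        transcripts = list(response.index)
    if blocks.nunique() < 2:
        warnings.warn("fewer than 2 blocks: returning raw genotype means",
                      stacklevel=2)
        means = response.T.groupby(geno).mean().T
        return means.loc[transcripts, geno_levels]
    Zb, _ = indicator(blocks)
    out = np.empty((len(transcripts), len(geno_levels)))
    for i, t in enumerate(transcripts):
        y = response.loc[t].to_numpy(dtype=float)
        fit = fit_reml(y, X, [Zb])
        out[i] = fit.beta
    return pd.DataFrame(out, index=transcripts, columns=geno_levels)


@dataclass
class DEGResult:
    """Per-transcript likelihood-ratio test results."""

    table: pd.DataFrame  # columns: stat, df, pvalue, fdr, significant
    dispersion: pd.Series
    alpha: float = DEG_ALPHA

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    @property
    def significant_transcripts(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def estimate_dispersion(
    expr: ExpressionMatrix,
    per_transcript: bool = False,
    min_group_mean: float = 10.0,
) -> pd.Series:
    """Method-of-moments NB dispersion from the replicated check groups.

    Per transcript, alpha_t = sum_g (s2_g - m_g) / sum_g m_g^2 over the
    genotype groups with >= 2 samples.  The default is a *common* dispersion
    — the mean of the per-transcript ratios over transcripts whose every
    replicate group averages at least ``min_group_mean`` counts — because
    the handful of check replicates makes tag-wise moments far too noisy for
    a likelihood-ratio test (badly underestimated tags would inflate it),
    and the low-count ratios are dominated by 1/mean^2 noise.  Set
    ``per_transcript=True`` for the raw tag-wise estimates.  Values are
    floored at a small positive constant.
    """
    geno = expr.genotype
    counts = expr.counts
    groups = [idx for _, idx in geno.groupby(geno).groups.items() if len(idx) > 1]
    if not groups:
        raise ValueError("no replicated genotype groups to estimate dispersion")
    num = np.zeros(len(counts))
    den = np.zeros(len(counts))
    den_sel = np.zeros(len(counts))
    for idx in groups:
        block = counts[list(idx)].to_numpy(dtype=float)
        m = block.mean(axis=1)
        v = block.var(axis=1, ddof=1)
        num += v - m
        den += m**2
        den_sel += np.where(m >= min_group_mean, m**2, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / den, np.nan)
    if not per_transcript:
        with np.errstate(invalid="ignore"):
            ratios = num / den_sel
        if np.isfinite(ratios).any():
            common = float(np.nanmean(ratios))
        elif den.sum() > 0:  # nothing well expressed: fall back to pooled ratio
            common = float(num.sum() / den.sum())
        else:
            common = DISPERSION_FLOOR
        alpha = np.full(len(counts), common)
    alpha = np.maximum(np.nan_to_num(alpha, nan=DISPERSION_FLOOR), DISPERSION_FLOOR)
    return pd.Series(alpha, index=counts.index)


def _nb_loglik(y, mu, r):
    """NB2 log-likelihood with mean mu and size r = 1/dispersion."""
    mu = np.maximum(mu, 1e-12)
    return (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )


def deg_lrt(
    expr: ExpressionMatrix,
    alpha: float = DEG_ALPHA,
    dispersion: pd.Series | None = None,
) -> DEGResult:
    """Genotype-effect LRT per transcript under a fixed-dispersion NB model.

    Full model: one mean per genotype group; reduced model: grand mean.
    All-zero transcripts get p = 1 by convention.  P-values are BH-adjusted;
    significance is fdr < ``alpha``.
    """
    counts = expr.counts.to_numpy(dtype=float)
    geno = expr.genotype
    if dispersion is None:
        dispersion = estimate_dispersion(expr)
    r = 1.0 / dispersion.loc[expr.counts.index].to_numpy()

    groups = list(geno.groupby(geno).groups.values())
    n_geno = len(groups)
    grand = counts.mean(axis=1)
    ll_red = np.zeros(len(counts))
    ll_full = np.zeros(len(counts))
    for idx in groups:
        cols = [expr.samples.index(s) for s in idx]
        block = counts[:, cols]
        gm = block.mean(axis=1)
        ll_full += _nb_loglik(block, gm[:, None], r[:, None]).sum(axis=1)
        ll_red += _nb_loglik(block, grand[:, None], r[:, None]).sum(axis=1)
    stat = np.maximum(2.0 * (ll_full - ll_red), 0.0)
    df = n_geno - 1
    pvals = stats.chi2.sf(stat, df)
    allzero = counts.sum(axis=1) == 0
    pvals = np.where(allzero, 1.0, pvals)
    stat = np.where(allzero, 0.0, stat)
    fdr = bh_adjust(pvals)
    table = pd.DataFrame(
        {
            "stat": stat,
            "df": df,
            "pvalue": pvals,
            "fdr": fdr,
            "significant": fdr < alpha,
        },
        index=expr.counts.index,
    )
    return DEGResult(table, dispersion, alpha)


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return stats.false_discovery_control(np.asarray(pvals, dtype=float),
                                         method="bh")


@dataclass
class ThresholdScan:
    threshold: float
    counts: pd.Series  # DEG count per candidate threshold
    results: dict


def cpm_threshold_scan(
    expr: ExpressionMatrix,
    n_candidates: int = 40,
    alpha: float = DEG_ALPHA,
    dispersion: pd.Series | None = None,
) -> ThresholdScan:
    """Choose the mean-cpm filter threshold maximizing the DEG count.

    Candidates are evenly spaced quantiles of per-transcript mean cpm between
    0 and the 90th percentile (always including 0); for each, transcripts
    with mean cpm > threshold are kept, the LRT re-run, and BH applied within
    the filtered set.  Ties break toward the smallest threshold.
    """
    if n_candidates < 1:
        raise ValueError("empty candidate grid")
    mean_cpm = cpm(expr).mean(axis=1)
    qs = np.linspace(0.0, 0.90, n_candidates)
    grid = np.unique(np.concatenate([[0.0], np.quantile(mean_cpm, qs)]))
    if dispersion is None:
        dispersion = estimate_dispersion(expr)
    counts, results = {}, {}
    for thr in grid:
        keep = mean_cpm.index[mean_cpm > thr] if thr > 0 else mean_cpm.index
        sub = expr.subset_transcripts(keep)
        if sub.counts.shape[0] == 0:
            counts[thr] = 0
            continue
        res = deg_lrt(sub, alpha=alpha, dispersion=dispersion)
        counts[thr] = res.n_significant
        results[thr] = res
    series = pd.Series(counts).sort_index()
    best = float(series.index[np.argmax(series.to_numpy())])  # first max = smallest
    return ThresholdScan(best, series, results)


def aggregate_per_gene(
    expr: ExpressionMatrix, transcript_to_gene: pd.Series
) -> ExpressionMatrix:
    """Sum transcript counts within genes (count-conserving aggregation)."""
    genes = transcript_to_gene.reindex(expr.counts.index)
    summed = expr.counts.groupby(genes).sum()
    return ExpressionMatrix(summed, expr.blocks, expr.genotype, expr.library_sizes)
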