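"""Variant-call cleaning, imputation, consensus and filtering for RIL panels.

The cleaning chain exploits three pieces of prior knowledge about a RIL
panel: lines are (near) fully homozygous, every line descends from a known
parent pair, and the parents are genotyped.  Heterozygous calls and calls
inconsistent with the parental alleles are therefore treated as errors and
masked; remaining gaps are median-imputed per population or filled from the
parental haplotype mosaic.

Empirical quality filtering thresholds each of four per-variant criteria
(DP, MAF, QUAL, NS) at a relative strength between 0 (keep everything) and 1
(keep only the extreme), interpolated linearly between the observed minimum
and maximum of the criterion.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .types import GenotypeMatrix, PopulationMap

log = logging.getLogger(__name__)

QUALITY_CRITERIA = ("DP", "MAF", "QUAL", "NS")


def consensus_duplicates(calls) -> float:
    """Unite repeated observations of one line at one variant.

    Returns the most frequent non-missing call (major allele); ties and
    all-missing inputs return missing.
    """
    arr = np.asarray(list(calls), dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one observation")
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        return np.nan
    vals, counts = np.unique(arr, return_counts=True)
    top = counts.max()
    winners = vals[counts == top]
    return float(winners[0]) if winners.size == 1 else np.nan


def consensus_by_line(
    observed: pd.DataFrame, sample_to_line: pd.Series
) -> GenotypeMatrix:
    """Collapse a sample-level call matrix to line level.

    Lines with a single sample pass through; replicated lines (parental
    checks) are united by :func:`consensus_duplicates` per variant.
    """
    groups = sample_to_line.loc[observed.index]
    out = {}
    for line, idx in observed.groupby(groups).groups.items():
        block = observed.loc[idx]
        if len(block) == 1:
            out[line] = block.iloc[0]
        else:
            arr = block.to_numpy(dtype=float)
            n0 = (arr == 0).sum(axis=0)
            n1 = (arr == 1).sum(axis=0)
            n2 = (arr == 2).sum(axis=0)
            stack = np.stack([n0, n1, n2])
            top = stack.max(axis=0)
            n_top = (stack == top).sum(axis=0)
            winner = stack.argmax(axis=0).astype(float)
            winner[(top == 0) | (n_top > 1)] = np.nan
            out[line] = pd.Series(winner, index=observed.columns)
    data = pd.DataFrame(out).T
    data.index.name = None
    return GenotypeMatrix(data, provenance="rnaseq")


def clean_calls(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    raw: bool = False,
) -> GenotypeMatrix:
    """Homozygosity/parent-consistency cleaning of RIL variant calls.

    * variants with any missing parental call are removed;
    * heterozygous calls (dosage 1) are set to missing;
    * RIL calls not matching either parent's allele at a site are set to
      missing; parent calls are left untouched.

    With ``raw=True`` the strict steps are skipped entirely (the matrix is
    returned as-is), emulating an uncleaned call set for comparison.
    """
    missing_lines = [
        l
        for l in list(popmap.ril_lines) + popmap.parents
        if l not in matrix.data.index
    ]
    if missing_lines:
        raise ValueError(f"lines absent from matrix: {missing_lines}")
    if raw:
        return GenotypeMatrix(matrix.data.copy(), provenance=matrix.provenance)

    data = matrix.data.copy()
    parents = popmap.parents
    parent_block = data.loc[parents]
    keep = parent_block.notna().all(axis=0)
    data = data.loc[:, keep]
    # parents are inbreds too: a heterozygous parent call is an error and
    # is masked (after the missing-parent exclusion above, per the chain's
    # stated order), which in turn masks unconfirmable RIL calls below
    parent_arr = data.loc[parents].to_numpy(dtype=float)
    parent_arr[parent_arr == 1.0] = np.nan
    data.loc[parents] = parent_arr
    parent_block = data.loc[parents]

    ril_lines = [l for l in data.index if l not in parents]
    rils = data.loc[ril_lines].to_numpy(dtype=float)
    rils[rils == 1.0] = np.nan

    # per-population parental consistency: a RIL call must equal one of its
    # own two parents' dosages at that site
    for pop in popmap.populations:
        pa, pb = popmap.pop_parents[pop]
        members = [l for l in popmap.lines_of(pop) if l in data.index]
        rows = [ril_lines.index(l) for l in members]
        a = parent_block.loc[pa].to_numpy(dtype=float)
        b = parent_block.loc[pb].to_numpy(dtype=float)
        block = rils[rows]
        ok = (block == a) | (block == b)
        block[~ok & ~np.isnan(block)] = np.nan
        rils[rows] = block
    data.loc[ril_lines] = rils
    return GenotypeMatrix(data, provenance=matrix.provenance)


def _column_median(col: np.ndarray) -> float:
    """Median of observed dosages; even-count ties resolve to the lower value."""
    obs = col[~np.isnan(col)]
    if obs.size == 0:
        return np.nan
    obs = np.sort(obs)
    mid = obs.size // 2
    if obs.size % 2 == 1:
        return float(obs[mid])
    return float(obs[mid - 1])  # even count: lower of the two middle values


def median_impute(
    matrix: GenotypeMatrix, popmap: PopulationMap, drop_monomorphic: bool = True
) -> GenotypeMatrix:
    """Fill missing calls with the per-population, per-variant median.

    A population with no observed call at a variant falls back to the
    cross-population median; variants with no observed call anywhere are
    dropped, as are variants monomorphic after imputation (across the RIL
    analysis set) when ``drop_monomorphic`` is set.
    """
    data = matrix.data.copy()
    arr = data.to_numpy(dtype=float)
    lines = list(data.index)
    global_median = np.apply_along_axis(_column_median, 0, arr)

    for pop in popmap.populations:
        members = [l for l in popmap.lines_of(pop) if l in data.index]
        rows = [lines.index(l) for l in members]
        block = arr[rows]
        med = np.apply_along_axis(_column_median, 0, block)
        med = np.where(np.isnan(med), global_median, med)
        nn = np.isnan(block)
        block[nn] = np.broadcast_to(med, block.shape)[nn]
        arr[rows] = block
    # parents (or any line outside the populations): global median
    other_rows = [
        i for i, l in enumerate(lines) if popmap.line_to_pop.get(l) is None
    ]
    if other_rows:
        block = arr[other_rows]
        nn = np.isnan(block)
        block[nn] = np.broadcast_to(global_median, block.shape)[nn]
        arr[other_rows] = block

    out = pd.DataFrame(arr, index=lines, columns=data.columns)
    out = out.dropna(axis=1, how="any")
    if drop_monomorphic:
        ril_rows = [l for l in lines if l in popmap.line_to_pop]
        std = out.loc[ril_rows].std(axis=0, ddof=0)
        out = out.loc[:, std > 0]
    return GenotypeMatrix(out, provenance=matrix.provenance)


def intersect_wgs(
    matrix: GenotypeMatrix,
    variants: pd.DataFrame,
    wgs: GenotypeMatrix,
    wgs_variants: pd.DataFrame,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Keep variants present (chrom, pos, alleles) in both RNA and WGS sets.

    Parental genotypes are taken from the (error-free) WGS calls.  Ref/alt
    swaps at a shared position are harmonized by flipping dosages; other
    allele mismatches exclude the variant (logged).
    """
    variants = variants.loc[[v for v in matrix.variant_ids if v in variants.index]]
    rna_key = variants[["chrom", "pos"]].apply(tuple, axis=1)
    wgs_key = wgs_variants[["chrom", "pos"]].apply(tuple, axis=1)
    wgs_by_key = dict(zip(wgs_key, wgs_variants.index))

    keep, flipped, mismatched = [], [], 0
    for vid, key in rna_key.items():
        wid = wgs_by_key.get(key)
        if wid is None:
            continue
        r = variants.loc[vid]
        w = wgs_variants.loc[wid]
        if (r["ref"], r["alt"]) == (w["ref"], w["alt"]):
            keep.append((vid, wid, False))
        elif (r["ref"], r["alt"]) == (w["alt"], w["ref"]):
            keep.append((vid, wid, True))
            flipped.append(vid)
        else:
            mismatched += 1
    if mismatched:
        log.warning("excluded %d variants with allele mismatch", mismatched)
    if not keep:
        warnings.warn("empty RNA/WGS intersection", stacklevel=2)
        empty = matrix.data.iloc[:, :0]
        return GenotypeMatrix(empty, provenance="wgs_consensus"), variants.iloc[:0]

    vids = [k[0] for k in keep]
    data = matrix.data[vids].copy()
    for vid, wid, flip in keep:
        col = wgs.data[wid]
        if flip:
            col = 2.0 - col
        for p in wgs.data.index:
            if p in data.index:
                data.loc[p, vid] = col.loc[p]
    return (
        GenotypeMatrix(data, provenance="wgs_consensus"),
        variants.loc[vids],
    )


def impute_from_parents(
    matrix: GenotypeMatrix,
    variants: pd.DataFrame,
    popmap: PopulationMap,
) -> GenotypeMatrix:
    """Fill missing RIL calls from the parental haplotype mosaic.

    RILs are mosaics of their two founder haplotypes, so a missing call is
    determined by which parent contributed the surrounding segment.  At sites
    where the parents agree, the shared allele is filled directly.  At
    informative (parent-discordant) sites, the nearest informative flanking
    markers on each side vote for a parent; agreeing flanks impute that
    parent's allele, while conflicting or absent flanks fall back to the
    per-population median.
    """
    data = matrix.data.copy()
    order = variants.sort_values(["chrom", "pos"]).index
    order = [v for v in order if v in data.columns]
    data = data[order]
    chroms = variants.loc[order, "chrom"].to_numpy()
    cols = np.arange(len(order))

    parents_all = popmap.parents
    fallback_needed = False
    for pop in popmap.populations:
        pa, pb = popmap.pop_parents[pop]
        a = data.loc[pa].to_numpy(dtype=float)
        b = data.loc[pb].to_numpy(dtype=float)
        informative = a != b
        for line in popmap.lines_of(pop):
            if line not in data.index:
                continue
            row = data.loc[line].to_numpy(dtype=float)
            nn = np.isnan(row)
            if not nn.any():
                continue
            # sites where parents agree: deterministic fill
            agree_fill = nn & ~informative
            row[agree_fill] = a[agree_fill]
            nn = np.isnan(row)
            if nn.any():
                # vote: +1 parent A, -1 parent B at observed informative sites
                support = np.zeros(len(order))
                obs_inf = informative & ~np.isnan(row)
                support[obs_inf] = np.where(row[obs_inf] == a[obs_inf], 1.0, -1.0)
                for c in np.flatnonzero(nn):
                    ch = chroms[c]
                    same = (chroms == ch) & (support != 0)
                    left = cols[same & (cols < c)]
                    right = cols[same & (cols > c)]
                    if left.size and right.size:
                        sl, sr = support[left[-1]], support[right[0]]
                        if sl == sr:
                            row[c] = a[c] if sl > 0 else b[c]
                            continue
                    fallback_needed = True
            data.loc[line] = row
    if fallback_needed:
        log.info("conflicting/absent flanks present; median fallback applied")
    out = median_impute(
        GenotypeMatrix(data, provenance=matrix.provenance), popmap,
        drop_monomorphic=False,
    )
    # restrict to lines of interest untouched; drop still-missing columns
    return GenotypeMatrix(
        out.data.loc[[l for l in matrix.data.index]],
        provenance=matrix.provenance,
    )


def functional_filter(
    matrix: GenotypeMatrix,
    variants: pd.DataFrame,
    klass: str,
    max_distance_bp: int = 5000,
    drop_monomorphic: bool = True,
) -> GenotypeMatrix:
    """Annotation-based subsets: regulatory (Reg) or coding missense (CDS).

    Reg keeps upstream/downstream gene variants within ``max_distance_bp``
    of the coding region; CDS keeps only missense variants (synonymous
    excluded).
    """
    vt = variants.loc[[v for v in matrix.variant_ids if v in variants.index]]
    if klass == "CDS":
        keep = vt.index[vt["effect_class"] == "missense_variant"]
    elif klass == "Reg":
        is_reg = vt["effect_class"].isin(
            ["upstream_gene_variant", "downstream_gene_variant"]
        )
        keep = vt.index[is_reg & (vt["distance_bp"] <= max_distance_bp)]
    else:
        raise ValueError(f"unknown functional class {klass!r}; use 'Reg' or 'CDS'")
    out = matrix.subset_variants(keep)
    if drop_monomorphic:
        std = out.data.std(axis=0, ddof=0)
        out = GenotypeMatrix(
            out.data.loc[:, (std > 0) | out.data.isna().any(axis=0)],
            provenance=matrix.provenance,
        )
    return out


def quality_threshold(values: pd.Series, criterion: str, strength: float) -> float:
    """Linear threshold between a criterion's observed min and max.

    DP/MAF/QUAL filter from the low end up (keep >= threshold); NS filters
    from the high end down (keep <= threshold).  Strength 0 keeps everything.
    """
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        warnings.warn(
            f"criterion {criterion}: all values identical, strength has no effect",
            stacklevel=2,
        )
    if criterion == "NS":
        return hi - strength * (hi - lo)
    return lo + strength * (hi - lo)


def quality_filter(
    matrix: GenotypeMatrix,
    variants: pd.DataFrame,
    criterion: str,
    strength: float,
) -> GenotypeMatrix:
    """Keep variants passing one criterion at a relative strength in [0, 1]."""
    if criterion not in QUALITY_CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}")
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must be in [0, 1]")
    vals = variants.loc[
        [v for v in matrix.variant_ids if v in variants.index], criterion
    ].astype(float)
    if not np.isfinite(vals).all():
        raise ValueError(f"non-finite {criterion} values")
    thr = quality_threshold(vals, criterion, strength)
    if criterion == "NS":
        keep = vals.index[vals <= thr]
    else:
        keep = vals.index[vals >= thr]
    return matrix.subset_variants(keep)


def combine_filters(matrix: GenotypeMatrix, *subsets) -> GenotypeMatrix:
    """Inclusive intersection: keep variants present in every member subset."""
    if len(subsets) < 2:
        raise ValueError("need at least 2 subsets to combine")
    sets = [set(s) for s in subsets]
    keep = set.intersection(*sets)
    if not keep:
        warnings.warn("empty filter intersection", stacklevel=2)
    return matrix.subset_variants(keep)


def union_filters(matrix: GenotypeMatrix, *subsets) -> GenotypeMatrix:
    """Alternative reading of filter combination: union of retained markers."""
    if len(subsets) < 2:
        raise ValueError("need at least 2 subsets to combine")
    keep = set.union(*(set(s) for s in subsets))
    return matrix.subset_variants(keep)


def standard_filter(
    matrix: GenotypeMatrix,
    max_missing_rate: float = 0.20,
    min_maf: float = 0.05,
) -> GenotypeMatrix:
    """Conventional marker filter: missing rate < 20% and MAF > 0.05.

    Both bounds are strict, and both statistics are computed from the matrix
    itself (pre-imputation missingness, observed-call MAF).
    """
    arr = matrix.data.to_numpy(dtype=float)
    miss_rate = np.isnan(arr).mean(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(arr, axis=0) / 2.0
    p = np.nan_to_num(p)
    maf = np.minimum(p, 1.0 - p)
    keep = matrix.data.columns[(miss_rate < max_missing_rate) & (maf > min_maf)]
    return matrix.subset_variants(keep)


def gst(
    matrix: GenotypeMatrix, popmap: PopulationMap
) -> tuple[pd.Series, float]:
    """Nei's coefficient of genetic differentiation, per variant + multilocus.

    Per variant, G_st = (H_T - H_S) / H_T with H_S the mean within-population
    expected heterozygosity 2p(1-p) and H_T the expected heterozygosity at
    the pooled (mean) allele frequency.  The multilocus summary is the ratio
    of locus-averaged (H_T - H_S) to locus-averaged H_T; variants with
    H_T = 0 are undefined and excluded from the summary.
    """
    pops = popmap.populations
    freqs = []
    for pop in pops:
        members = [l for l in popmap.lines_of(pop) if l in matrix.data.index]
        if not members:
            continue
        block = matrix.data.loc[members].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            freqs.append(np.nanmean(block, axis=0) / 2.0)
    if len(freqs) < 2:
        raise ValueError("need >= 2 populations with typed lines")
    p = np.vstack(freqs)  # populations x variants
    hs = np.nanmean(2.0 * p * (1.0 - p), axis=0)
    pbar = np.nanmean(p, axis=0)
    ht = 2.0 * pbar * (1.0 - pbar)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_variant = np.where(ht > 0, (ht - hs) / ht, np.nan)
    defined = ht > 0
    multilocus = float(
        (ht[defined] - hs[defined]).mean() / ht[defined].mean()
    ) if defined.any() else float("nan")
    return pd.Series(per_variant, index=matrix.data.columns), multilocus
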