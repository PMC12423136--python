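"""Validation designs for genomic prediction on connected RIL populations.

Four designs are supported: repeated fivefold cross-validation over the
pooled panel; fixed-size random training/validation (TS/VS) sampling either
across populations (cross), within one population (intra), or between two
populations (inter); a training-set-size sweep; and sweeps over kernel
weights, empirical filter strengths, and sequencing depth.  Every scheme
stores per-repetition prediction abilities, never only aggregates, and all
sampling is seed-reproducible.  Dataset comparisons reuse identical fold or
subset assignments (paired evaluation), which is what justifies pairwise
t-tests between datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import expression as xpr
from . import genotypes as gt
from . import simdata
from .gp import (
    combine_kernels,
    gblup_predict,
    kernel_from_features,
    prediction_ability,
    reml_fit,
)
from .types import EvalResult, GenotypeMatrix, Kernel, PopulationMap

log = logging.getLogger(__name__)


@dataclass
class Scheme:
    """A fixed-size random TS/VS sampling design."""

    kind: str  # cross | intra | inter
    repetitions: int = 200
    ts_size: int = 50
    vs_size: int = 65
    ts_population: str | None = None
    vs_population: str | None = None
    seed: int = 0


def _ability_once(kernel: Kernel, y: pd.Series, train, test) -> float:
    sub = kernel.reorder(train)
    fit = reml_fit(y, sub)
    pred = gblup_predict(fit, kernel, train, test)
    return prediction_ability(pred, y)


def cv_fivefold(
    kernel: Kernel,
    y: pd.Series,
    reps: int = 50,
    n_folds: int = 5,
    seed: int = 0,
    dataset: str = "dataset",
    trait: str = "trait",
) -> EvalResult:
    """Repeated k-fold cross-validation; stores one ability per fold x rep."""
    lines = [l for l in kernel.lines if l in y.index]
    if len(lines) < 10:
        raise ValueError("need at least 10 lines")
    kernel = kernel.reorder(lines)
    rng = np.random.default_rng(seed)
    abilities = []
    for rep in range(reps):
        perm = rng.permutation(len(lines))
        folds = np.array_split(perm, n_folds)
        if min(len(f) for f in folds) < 3:
            raise ValueError("fold with fewer than 3 lines")
        for f in folds:
            test = [lines[i] for i in f]
            train = [l for l in lines if l not in set(test)]
            abilities.append(_ability_once(kernel, y, train, test))
    return EvalResult(
        scheme="fivefold",
        dataset=dataset,
        trait=trait,
        abilities=np.array(abilities),
        meta={"reps": reps, "n_folds": n_folds, "seed": seed},
    )


def _draw_sets(scheme: Scheme, popmap: PopulationMap, lines,
               rng: np.random.Generator):
    pool = list(lines)
    if scheme.kind == "cross":
        if scheme.ts_size + scheme.vs_size > len(pool):
            raise ValueError("pooled panel too small for ts + vs")
        pick = rng.choice(len(pool), scheme.ts_size + scheme.vs_size, replace=False)
        ts = [pool[i] for i in pick[: scheme.ts_size]]
        vs = [pool[i] for i in pick[scheme.ts_size :]]
    elif scheme.kind == "intra":
        members = [l for l in popmap.lines_of(scheme.ts_population) if l in pool]
        if scheme.ts_size + scheme.vs_size > len(members):
            raise ValueError(
                f"population {scheme.ts_population} too small "
                f"({len(members)}) for ts {scheme.ts_size} + vs {scheme.vs_size}"
            )
        pick = rng.choice(
            len(members), scheme.ts_size + scheme.vs_size, replace=False
        )
        ts = [members[i] for i in pick[: scheme.ts_size]]
        vs = [members[i] for i in pick[scheme.ts_size :]]
    elif scheme.kind == "inter":
        ts_pool = [l for l in popmap.lines_of(scheme.ts_population) if l in pool]
        vs_pool = [l for l in popmap.lines_of(scheme.vs_population) if l in pool]
        if scheme.ts_size > len(ts_pool):
            raise ValueError(f"population {scheme.ts_population} too small for ts")
        vs_size = min(scheme.vs_size, len(vs_pool))  # capped, without replacement
        ts = [ts_pool[i] for i in rng.choice(len(ts_pool), scheme.ts_size,
                                             replace=False)]
        vs = [vs_pool[i] for i in rng.choice(len(vs_pool), vs_size, replace=False)]
    else:
        raise ValueError(f"unknown scheme kind {scheme.kind!r}")
    return ts, vs


def subset_validation(
    kernel: Kernel,
    y: pd.Series,
    scheme: Scheme,
    popmap: PopulationMap,
    dataset: str = "dataset",
    trait: str = "trait",
) -> EvalResult:
    """Fixed-size random TS/VS validation under a cross/intra/inter scheme."""
    lines = [l for l in kernel.lines if l in y.index]
    kernel = kernel.reorder(lines)
    rng = np.random.default_rng(scheme.seed)
    abilities = []
    for _ in range(scheme.repetitions):
        ts, vs = _draw_sets(scheme, popmap, lines, rng)
        abilities.append(_ability_once(kernel, y, ts, vs))
    return EvalResult(
        scheme=scheme.kind,
        dataset=dataset,
        trait=trait,
        abilities=np.array(abilities),
        meta={
            "ts_size": scheme.ts_size,
            "vs_size": scheme.vs_size,
            "ts_population": scheme.ts_population,
            "vs_population": scheme.vs_population,
            "seed": scheme.seed,
        },
    )


def ts_size_sweep(
    kernel: Kernel,
    y: pd.Series,
    popmap: PopulationMap,
    sizes=tuple(range(20, 171, 15)),
    vs_size: int = 65,
    reps: int = 200,
    seed: int = 0,
    dataset: str = "dataset",
    trait: str = "trait",
) -> dict[int, EvalResult]:
    """Cross-population validation at a ladder of training-set sizes."""
    out = {}
    for size in sizes:
        scheme = Scheme(
            kind="cross", repetitions=reps, ts_size=size, vs_size=vs_size,
            seed=seed,
        )
        out[size] = subset_validation(kernel, y, scheme, popmap, dataset, trait)
    return out


def weight_sweep(
    kernel_a: Kernel,
    kernel_b: Kernel,
    y: pd.Series,
    step: float = 0.10,
    reps: int = 10,
    seed: int = 0,
    trait: str = "trait",
) -> dict[float, EvalResult]:
    """CV ability of the weighted kernel average at weights 0, step, ..., 1.

    Weight w is the share of ``kernel_b``; endpoints reproduce the
    single-dataset results exactly.
    """
    ws = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    out = {}
    for w in ws:
        k = combine_kernels([kernel_a, kernel_b], [1.0 - w, w])
        out[float(w)] = cv_fivefold(
            k, y, reps=reps, seed=seed, dataset=f"w={w:.2f}", trait=trait
        )
    return out


def mean_ability_objective(
    kernel: Kernel, entry_means: pd.DataFrame, reps: int = 2, seed: int = 0
) -> float:
    """Mean CV prediction ability across all traits (paired fold seed)."""
    vals = []
    for trait in entry_means.columns:
        res = cv_fivefold(
            kernel, entry_means[trait].dropna(), reps=reps, seed=seed,
            trait=trait,
        )
        vals.append(res.mean)
    return float(np.mean(vals))


@dataclass
class FilterGridResult:
    per_criterion: pd.DataFrame  # criterion, strength, n_variants, ability
    best_single: dict[str, float]  # criterion -> best strength
    combinations: pd.DataFrame  # members, n_variants, ability
    best_combination: tuple[str, ...]
    best_matrix: GenotypeMatrix


def filter_grid_search(
    matrix: GenotypeMatrix,
    variants: pd.DataFrame,
    entry_means: pd.DataFrame,
    criteria=gt.QUALITY_CRITERIA,
    steps: int = 21,
    objective_reps: int = 2,
    seed: int = 0,
    min_variants: int = 10,
) -> FilterGridResult:
    """Empirical quality-filter optimization against CV prediction ability.

    Each criterion is filtered at ``steps`` relative strengths (0-100%); the
    per-criterion best subset (argmax mean ability) is kept and all
    multi-criterion intersections of the single-best subsets (pairs, triples,
    the full set) are then evaluated.  All evaluations share one fold seed
    so subset rankings are paired.
    """
    ril_lines = matrix.lines
    strengths = np.linspace(0.0, 1.0, steps)

    def objective(sub: GenotypeMatrix) -> float:
        return mean_ability_objective(
            kernel_from_features(sub.data.loc[ril_lines]),
            entry_means,
            reps=objective_reps,
            seed=seed,
        )

    rows, best_single, best_ids = [], {}, {}
    for crit in criteria:
        best_val, best_s = -np.inf, 0.0
        for s in strengths:
            sub = gt.quality_filter(matrix, variants, crit, float(s))
            n = len(sub.variant_ids)
            if n < min_variants:
                log.info("skipping %s@%.2f: only %d variants", crit, s, n)
                rows.append(
                    {"criterion": crit, "strength": float(s), "n_variants": n,
                     "ability": np.nan}
                )
                continue
            val = objective(sub)
            rows.append(
                {"criterion": crit, "strength": float(s), "n_variants": n,
                 "ability": val}
            )
            if val > best_val:
                best_val, best_s = val, float(s)
        best_single[crit] = best_s
        best_ids[crit] = set(
            gt.quality_filter(matrix, variants, crit, best_s).variant_ids
        )
    per_criterion = pd.DataFrame(rows)

    from itertools import combinations as iter_combos

    combo_rows = []
    best_combo, best_combo_val, best_matrix = None, -np.inf, None
    names = list(criteria)
    for k in range(2, len(names) + 1):
        for members in iter_combos(names, k):
            sub = gt.combine_filters(matrix, *(best_ids[m] for m in members))
            n = len(sub.variant_ids)
            if n < min_variants:
                combo_rows.append(
                    {"members": "+".join(members), "n_variants": n,
                     "ability": np.nan}
                )
                continue
            val = objective(sub)
            combo_rows.append(
                {"members": "+".join(members), "n_variants": n, "ability": val}
            )
            if val > best_combo_val:
                best_combo, best_combo_val, best_matrix = members, val, sub
    combinations = pd.DataFrame(combo_rows)
    return FilterGridResult(
        per_criterion=per_criterion,
        best_single=best_single,
        combinations=combinations,
        best_combination=tuple(best_combo) if best_combo else (),
        best_matrix=best_matrix if best_matrix is not None else matrix,
    )


def paired_ttest(a, b) -> tuple[float, float]:
    """Two-sided paired t-test between two matched ability series."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# sequencing-depth sweep


@dataclass
class DepthSweepResult:
    table: pd.DataFrame  # fraction, dataset, n_features, ability


def _snp_pipeline(sim: simdata.SimResult, expr, rng) -> dict[str, GenotypeMatrix]:
    """Observation -> consensus -> clean -> impute at one sequencing depth."""
    observed, vt = simdata.simulate_variant_observation(
        sim.genotypes, expr, sim.parents.variants, sim.config, rng
    )
    line_calls = gt.consensus_by_line(observed, expr.genotype)
    cleaned = gt.clean_calls(line_calls, sim.popmap)
    total = gt.median_impute(cleaned, sim.popmap)
    std = gt.median_impute(gt.standard_filter(cleaned), sim.popmap)
    return {"snp_total": total, "snp_std": std, "_cleaned": cleaned,
            "_variants": vt}


def depth_sweep(
    sim: simdata.SimResult,
    entry_means: pd.DataFrame,
    fractions=(0.02, 0.05, 0.1, 0.25, 0.5, 1.0),
    qc_spec=(("MAF", 0.25), ("QUAL", 0.25)),
    min_reads: float = 0.0,
    objective_reps: int = 2,
    seed: int = 0,
    min_features: int = 10,
    datasets=("snp_total", "snp_std", "snp_qc", "ge_total", "ge_filtered",
              "ge_deg"),
) -> DepthSweepResult:
    """Rebuild SNP and expression datasets at reduced depths and score them.

    Counts are binomially thinned per fraction; the retained sample set is
    the intersection across all fractions so every depth is scored on the
    same samples.  ``qc_spec`` fixes the quality-filter criteria/strengths
    used for the quality-filtered SNP dataset at every depth.
    """
    rng = np.random.default_rng(seed)
    thinned = {
        f: simdata.thin_reads(sim.expression, f, np.random.default_rng(
            rng.integers(2**31)), min_reads=min_reads)
        for f in fractions
    }
    common = set(sim.expression.samples)
    for t in thinned.values():
        common &= set(t.samples)
    common_samples = [s for s in sim.expression.samples if s in common]
    ril_lines = sim.popmap.ril_lines
    rows = []
    for f in fractions:
        expr = thinned[f].subset_samples(common_samples)
        built: dict[str, object] = {}
        if any(d.startswith("snp") for d in datasets):
            snp = _snp_pipeline(sim, expr, np.random.default_rng(
                rng.integers(2**31)))
            built["snp_total"] = snp["snp_total"]
            built["snp_std"] = snp["snp_std"]
            if "snp_qc" in datasets:
                sub_ids = [
                    set(
                        gt.quality_filter(
                            snp["_cleaned"], snp["_variants"], c, s
                        ).variant_ids
                    )
                    for c, s in qc_spec
                ]
                qc = gt.combine_filters(snp["_cleaned"], *sub_ids) \
                    if len(sub_ids) > 1 else snp["_cleaned"].subset_variants(
                        sub_ids[0])
                built["snp_qc"] = gt.median_impute(qc, sim.popmap)
        if any(d.startswith("ge") for d in datasets):
            total = xpr.detection_filter(expr)
            built["ge_total"] = total
            if {"ge_filtered", "ge_deg"} & set(datasets):
                try:
                    scan = xpr.cpm_threshold_scan(total)
                    mean_cpm = xpr.cpm(total).mean(axis=1)
                    built["ge_filtered"] = total.subset_transcripts(
                        mean_cpm.index[mean_cpm > scan.threshold]
                        if scan.threshold > 0 else mean_cpm.index
                    )
                    deg = scan.results.get(scan.threshold)
                    if deg is None:
                        deg = xpr.deg_lrt(total)
                    built["ge_deg"] = total.subset_transcripts(
                        deg.significant_transcripts
                    )
                except ValueError:
                    pass
        for name in datasets:
            obj = built.get(name)
            if obj is None:
                continue
            if isinstance(obj, GenotypeMatrix):
                feats = obj.data.loc[
                    [l for l in ril_lines if l in obj.data.index]
                ]
            else:  # expression: features = cpm per transcript, lines = RILs
                cp = xpr.cpm(obj)
                by_line = cp.T.groupby(obj.genotype.loc[cp.columns]).mean()
                feats = by_line.loc[[l for l in ril_lines if l in by_line.index]]
            n_feat = feats.shape[1]
            if n_feat < min_features or feats.shape[0] < 10:
                rows.append({"fraction": f, "dataset": name,
                             "n_features": n_feat, "ability": np.nan})
                continue
            ability = mean_ability_objective(
                kernel_from_features(feats), entry_means,
                reps=objective_reps, seed=seed,
            )
            rows.append({"fraction": f, "dataset": name,
                         "n_features": n_feat, "ability": ability})
    return DepthSweepResult(pd.DataFrame(rows))
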