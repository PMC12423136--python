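"""End-to-end pipeline: simulate -> clean -> normalize -> kernels -> evaluate.

``run_pipeline`` chains the stages for a configurable list of predictor
dataset recipes and writes per-dataset cross-validation summaries plus a
manifest (config hash, seeds, shapes, file hashes).  The twelve recipe names
mirror the predictor families the analysis compares:

    ge_total, ge_filtered, ge_deg            transcript expression
    snp_total, snp_reg, snp_cds,             RNA-seq variants (cleaned,
    snp_std, snp_qc                            annotation-/quality-filtered)
    wgs_total, wgs_reg, wgs_cds              RNA/WGS consensus variants
    array                                    array genotypes
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import expression as xpr
from . import genotypes as gt
from . import io as rio
from . import simdata
from .evaluation import cv_fivefold
from .gp import kernel_from_features
from .phenotypes import entry_means_all_traits
from .types import GenotypeMatrix, Kernel

log = logging.getLogger(__name__)

ALL_RECIPES = (
    "ge_total", "ge_filtered", "ge_deg",
    "snp_total", "snp_reg", "snp_cds", "snp_std", "snp_qc",
    "wgs_total", "wgs_reg", "wgs_cds",
    "array",
)


@dataclass
class PipelineConfig:
    sim: simdata.SimConfig = field(default_factory=simdata.SimConfig)
    recipes: tuple[str, ...] = ALL_RECIPES
    cv_reps: int = 5
    cv_seed: int = 0
    qc_spec: tuple = (("MAF", 0.25), ("QUAL", 0.25))
    expression_normalization: str = "cpm"  # cpm | tmm | log2cpm | emm
    out_dir: str | None = None

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "sim": vars(self.sim) | {"traits": list(self.sim.traits)},
                "recipes": list(self.recipes),
                "cv_reps": self.cv_reps,
                "cv_seed": self.cv_seed,
                "qc_spec": [list(q) for q in self.qc_spec],
                "expression_normalization": self.expression_normalization,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def expression_features(
    expr, ril_lines, normalization: str = "cpm"
) -> pd.DataFrame:
    """Per-line expression feature matrix for genomic prediction.

    ``normalization`` selects the response: un-normalized cpm (default),
    TMM-scaled cpm, log2(cpm + 1), or EMM (mixed-model block-adjusted
    genotype means).  Replicated samples of a line (parental checks) are
    averaged.
    """
    if normalization == "emm":
        means = xpr.emm_adjust(expr)  # transcripts x genotypes
        by_line = means.T
    else:
        cp = xpr.cpm(expr)
        if normalization == "tmm":
            cp = cp.div(xpr.tmm_factors(expr), axis=1)
        elif normalization == "log2cpm":
            cp = np.log2(cp + 1.0)
        elif normalization != "cpm":
            raise ValueError(f"unknown normalization {normalization!r}")
        by_line = cp.T.groupby(expr.genotype.loc[cp.columns]).mean()
    return by_line.loc[[l for l in ril_lines if l in by_line.index]]


def build_datasets(sim: simdata.SimResult, config: PipelineConfig) -> dict:
    """Construct every requested predictor dataset as a per-line feature table."""
    recipes = set(config.recipes)
    popmap = sim.popmap
    rils = popmap.ril_lines
    out: dict[str, pd.DataFrame] = {}
    info: dict[str, dict] = {}

    line_calls = gt.consensus_by_line(sim.observed, sim.expression.genotype)
    cleaned = gt.clean_calls(line_calls, popmap)

    def snp_features(m: GenotypeMatrix) -> pd.DataFrame:
        return m.data.loc[[l for l in rils if l in m.data.index]]

    if recipes & {"snp_total", "snp_reg", "snp_cds"}:
        total = gt.median_impute(cleaned, popmap)
        if "snp_total" in recipes:
            out["snp_total"] = snp_features(total)
        for name, klass in (("snp_reg", "Reg"), ("snp_cds", "CDS")):
            if name in recipes:
                sub = gt.functional_filter(cleaned, sim.variants, klass)
                out[name] = snp_features(gt.median_impute(sub, popmap))
    if "snp_std" in recipes:
        out["snp_std"] = snp_features(
            gt.median_impute(gt.standard_filter(cleaned), popmap)
        )
    if "snp_qc" in recipes:
        ids = [
            set(gt.quality_filter(cleaned, sim.variants, c, s).variant_ids)
            for c, s in config.qc_spec
        ]
        qc = (
            gt.combine_filters(cleaned, *ids)
            if len(ids) > 1
            else cleaned.subset_variants(ids[0])
        )
        out["snp_qc"] = snp_features(gt.median_impute(qc, popmap))

    if recipes & {"wgs_total", "wgs_reg", "wgs_cds"}:
        consensus, cons_variants = gt.intersect_wgs(
            cleaned, sim.variants, sim.wgs, sim.parents.variants
        )
        imputed = gt.impute_from_parents(consensus, cons_variants, popmap)
        # drop monomorphic across the RIL analysis set
        feats = snp_features(imputed)
        poly = feats.columns[feats.std(axis=0, ddof=0) > 0]
        if "wgs_total" in recipes:
            out["wgs_total"] = feats[poly]
        for name, klass in (("wgs_reg", "Reg"), ("wgs_cds", "CDS")):
            if name in recipes:
                sub = gt.functional_filter(
                    GenotypeMatrix(feats[poly]), cons_variants, klass
                )
                out[name] = sub.data
    if "array" in recipes:
        arr = gt.median_impute(sim.array, popmap)
        out["array"] = snp_features(arr)

    if recipes & {"ge_total", "ge_filtered", "ge_deg"}:
        norm = config.expression_normalization
        total = xpr.detection_filter(sim.expression)
        if "ge_total" in recipes:
            out["ge_total"] = expression_features(total, rils, norm)
        if recipes & {"ge_filtered", "ge_deg"}:
            scan = xpr.cpm_threshold_scan(total)
            info["cpm_threshold"] = {
                "threshold": scan.threshold,
                "deg_counts": {f"{k:.4g}": int(v) for k, v in
                               scan.counts.items()},
            }
            mean_cpm = xpr.cpm(total).mean(axis=1)
            if "ge_filtered" in recipes:
                keep = (
                    mean_cpm.index[mean_cpm > scan.threshold]
                    if scan.threshold > 0
                    else mean_cpm.index
                )
                out["ge_filtered"] = expression_features(
                    total.subset_transcripts(keep), rils, norm
                )
            if "ge_deg" in recipes:
                deg = scan.results.get(scan.threshold) or xpr.deg_lrt(total)
                out["ge_deg"] = expression_features(
                    total.subset_transcripts(deg.significant_transcripts),
                    rils, norm,
                )
    for name, feats in out.items():
        info.setdefault(name, {})["n_features"] = int(feats.shape[1])
    return {"features": out, "info": info}


@dataclass
class PipelineResult:
    datasets: dict[str, pd.DataFrame]
    kernels: dict[str, Kernel]
    entry_means: pd.DataFrame
    trait_summary: pd.DataFrame
    cv_summary: pd.DataFrame
    info: dict
    manifest: dict


def run_pipeline(config: PipelineConfig, sim: simdata.SimResult | None = None
                 ) -> PipelineResult:
    """Execute the full chain and (optionally) write results to out_dir."""
    if sim is None:
        sim = simdata.simulate_study(config.sim)
    built = build_datasets(sim, config)
    features, info = built["features"], built["info"]

    entry_means, trait_summary = entry_means_all_traits(
        sim.phenotypes, lines=sim.popmap.ril_lines
    )
    kernels = {
        name: kernel_from_features(f, provenance=name)
        for name, f in features.items()
        if f.shape[1] > 0
    }
    rows = []
    for name, kernel in kernels.items():
        for trait in entry_means.columns:
            res = cv_fivefold(
                kernel,
                entry_means[trait].dropna(),
                reps=config.cv_reps,
                seed=config.cv_seed,
                dataset=name,
                trait=trait,
            )
            rows.append(
                {
                    "dataset": name,
                    "trait": trait,
                    "mean_ability": res.mean,
                    "sd_ability": res.std,
                    "n_features": info[name]["n_features"],
                }
            )
    cv_summary = pd.DataFrame(rows)

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.sim.seed,
        "n_lines": len(sim.popmap.ril_lines),
        "datasets": {k: v.shape for k, v in features.items()},
        "files": {},
    }
    if config.out_dir:
        outdir = Path(config.out_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        cv_summary.to_csv(outdir / "cv_summary.csv", index=False)
        trait_summary.to_csv(outdir / "trait_summary.csv")
        entry_means.to_csv(outdir / "entry_means.csv", na_rep="NA")
        rio.write_json(outdir / "dataset_info.json", info)
        for f in ("cv_summary.csv", "trait_summary.csv", "entry_means.csv",
                  "dataset_info.json"):
            digest = hashlib.sha256((outdir / f).read_bytes()).hexdigest()
            manifest["files"][f] = digest
        rio.write_json(outdir / "manifest.json", manifest)
    return PipelineResult(
        datasets=features,
        kernels=kernels,
        entry_means=entry_means,
        trait_summary=trait_summary,
        cv_summary=cv_summary,
        info=info,
        manifest=manifest,
    )
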