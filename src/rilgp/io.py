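"""Readers and writers for the pipeline's on-disk formats.

Formats: VCFv4.2 (biallelic SNPs; per-sample GT and DP; site QUAL; INFO NS),
transcript-count TSV (transcripts x samples), long-format phenotype CSV,
population-map CSV, variant-annotation TSV, kernel TSV, and JSON reports.
Internally positions are kept 1-based as in the VCF; missing genotype calls
serialize as "./." in VCF and "NA" in CSV/TSV.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, GenotypeMatrix, Kernel, PopulationMap

log = logging.getLogger(__name__)

_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(
    path,
    matrix: pd.DataFrame,
    variants: pd.DataFrame,
    dp: pd.DataFrame | None = None,
) -> None:
    """Write a biallelic-SNP VCFv4.2 with GT (and DP) per sample.

    ``matrix`` is samples x variants dosage; ``variants`` carries chrom, pos,
    ref, alt and optionally QUAL/NS; ``dp`` (samples x variants) adds
    per-sample depth.
    """
    samples = list(matrix.index)
    fmt = "GT:DP" if dp is not None else "GT"
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=NS,Number=1,Type=Integer,Description='
        '"Number of samples without data">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    if dp is not None:
        lines.append(
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">'
        )
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
    )
    arr = matrix.to_numpy(dtype=float)
    dp_arr = None if dp is None else dp.to_numpy()
    for j, vid in enumerate(matrix.columns):
        v = variants.loc[vid]
        qual = f"{float(v['QUAL']):.2f}" if "QUAL" in v and pd.notna(v.get("QUAL")) else "."
        ns = int(v["NS"]) if "NS" in v and pd.notna(v.get("NS")) else int(
            np.isnan(arr[:, j]).sum()
        )
        cells = []
        for i in range(len(samples)):
            g = arr[i, j]
            gt = _GT_CODE.get(g, "./.") if not np.isnan(g) else "./."
            if dp_arr is not None:
                cells.append(f"{gt}:{int(dp_arr[i, j])}")
            else:
                cells.append(gt)
        lines.append(
            f"{v['chrom']}\t{int(v['pos'])}\t{vid}\t{v['ref']}\t{v['alt']}\t"
            f"{qual}\tPASS\tNS={ns}\t{fmt}\t" + "\t".join(cells)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a biallelic-SNP VCF into (samples x variants dosage, variant table).

    GT maps to dosage {0, 1, 2} with "./." missing; per-sample DP (if
    present) is averaged into the variant table; multiallelic records are
    skipped with a count.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    cols, meta, skipped = {}, [], 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            skipped += 1
            continue
        gts = rec.gt_types.astype(float)  # 0,1,2 dosage; 3 unknown
        gts[gts == 3] = np.nan
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        cols[vid] = gts
        try:
            dp = rec.format("DP")
            mean_dp = float(np.nanmean(dp)) if dp is not None else np.nan
        except Exception:
            mean_dp = np.nan
        ns = rec.INFO.get("NS")
        meta.append(
            {
                "variant": vid,
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": rec.ALT[0],
                "QUAL": rec.QUAL,
                "DP": mean_dp,
                "NS": int(ns) if ns is not None else int(np.isnan(gts).sum()),
            }
        )
    if skipped:
        log.warning("skipped %d multiallelic records", skipped)
    matrix = pd.DataFrame(cols, index=samples)
    vt = pd.DataFrame(meta).set_index("variant") if meta else pd.DataFrame()
    if len(vt):
        with np.errstate(invalid="ignore"):
            p = np.nanmean(matrix.to_numpy(), axis=0) / 2.0
        vt["MAF"] = np.minimum(np.nan_to_num(p), 1.0 - np.nan_to_num(p))
    return matrix, vt


def write_counts_tsv(path, expr: ExpressionMatrix) -> None:
    expr.counts.to_csv(path, sep="\t", index_label="transcript")


def read_counts_tsv(path, blocks: pd.Series, genotype: pd.Series) -> ExpressionMatrix:
    counts = pd.read_csv(path, sep="\t", index_col="transcript")
    counts.index.name = None
    return ExpressionMatrix(counts, blocks, genotype)


def write_phenotypes_csv(path, records: pd.DataFrame) -> None:
    records.to_csv(path, index=False, na_rep="NA")


def read_phenotypes_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_popmap_csv(path, popmap: PopulationMap) -> None:
    rows = [
        {"line": l, "population": p,
         "parent_a": popmap.pop_parents[p][0],
         "parent_b": popmap.pop_parents[p][1]}
        for l, p in popmap.line_to_pop.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_popmap_csv(path) -> PopulationMap:
    df = pd.read_csv(path)
    line_to_pop = dict(zip(df["line"], df["population"]))
    pop_parents = {
        p: (g["parent_a"].iloc[0], g["parent_b"].iloc[0])
        for p, g in df.groupby("population")
    }
    return PopulationMap(line_to_pop, pop_parents)


def write_annotation_tsv(path, variants: pd.DataFrame) -> None:
    variants[["effect_class", "distance_bp"]].to_csv(
        path, sep="\t", index_label="variant_id"
    )


def write_matrix_tsv(path, matrix: GenotypeMatrix) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="line", na_rep="NA")


def read_matrix_tsv(path, provenance: str = "rnaseq") -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="line", na_values=["NA"])
    df.index.name = None
    return GenotypeMatrix(df, provenance=provenance)


def write_kernel_tsv(path, kernel: Kernel) -> None:
    kernel.to_frame().to_csv(path, sep="\t", index_label="line")


def read_kernel_tsv(path) -> Kernel:
    df = pd.read_csv(path, sep="\t", index_col="line")
    return Kernel(df.to_numpy(), list(df.index))


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
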