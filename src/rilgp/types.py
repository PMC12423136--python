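"""Shared in-memory containers for the RIL genomic-prediction pipeline.

Conventions
-----------
* Genotypes are coded as alternate-allele dosage in {0, 1, 2}; missing calls are
  ``NaN``.  After cleaning, only {0, 2, NaN} remain (homozygous RILs), and after
  imputation only {0, 2}.
* Variant metadata lives in a :class:`pandas.DataFrame` indexed by variant id
  with columns ``chrom, pos, ref, alt, DP, QUAL, NS, MAF, effect_class,
  distance_bp`` (``pos`` is 1-based, VCF convention).
* Expression counts are a transcripts x samples DataFrame of non-negative
  integers; each sample carries a block label and a genotype (line) label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.nan

EFFECT_CLASSES = (
    "missense_variant",
    "synonymous_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
)


@dataclass
class PopulationMap:
    """Line -> sub-population assignment plus each population's parent pair."""

    line_to_pop: dict[str, str]
    pop_parents: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        for pop, pair in self.pop_parents.items():
            if len(pair) != 2:
                raise ValueError(f"population {pop!r} needs exactly 2 parents")

    @property
    def parents(self) -> list[str]:
        seen: dict[str, None] = {}
        for pair in self.pop_parents.values():
            for p in pair:
                seen.setdefault(p)
        return list(seen)

    @property
    def populations(self) -> list[str]:
        return list(self.pop_parents)

    def lines_of(self, pop: str) -> list[str]:
        return [l for l, p in self.line_to_pop.items() if p == pop]

    @property
    def ril_lines(self) -> list[str]:
        return list(self.line_to_pop)


@dataclass
class GenotypeMatrix:
    """Lines x variants allele-dosage matrix (rows = lines)."""

    data: pd.DataFrame
    provenance: str = "rnaseq"

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate line ids")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate variant ids")

    @property
    def lines(self) -> list[str]:
        return list(self.data.index)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def subset_variants(self, variant_ids) -> "GenotypeMatrix":
        keep = [v for v in self.data.columns if v in set(variant_ids)]
        return GenotypeMatrix(self.data[keep], provenance=self.provenance)

    def subset_lines(self, lines) -> "GenotypeMatrix":
        return GenotypeMatrix(self.data.loc[list(lines)], provenance=self.provenance)


@dataclass
class ExpressionMatrix:
    """Transcripts x samples raw counts with sample-level design metadata."""

    counts: pd.DataFrame
    blocks: pd.Series  # sample id -> block label
    genotype: pd.Series  # sample id -> line id (parents appear repeatedly)
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        samples = list(self.counts.columns)
        self.blocks = self.blocks.reindex(samples)
        self.genotype = self.genotype.reindex(samples)
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.library_sizes = self.library_sizes.reindex(samples).astype(float)
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("negative counts")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def transcripts(self) -> list[str]:
        return list(self.counts.index)

    def subset_transcripts(self, ids) -> "ExpressionMatrix":
        keep = self.counts.index.intersection(pd.Index(ids))
        return ExpressionMatrix(
            self.counts.loc[keep],
            self.blocks,
            self.genotype,
            self.library_sizes,
        )

    def subset_samples(self, samples) -> "ExpressionMatrix":
        samples = list(samples)
        return ExpressionMatrix(
            self.counts[samples],
            self.blocks.loc[samples],
            self.genotype.loc[samples],
            None,  # library sizes re-derived from retained counts
        )


@dataclass
class Kernel:
    """Symmetric line x line relationship matrix with provenance weights."""

    values: np.ndarray
    lines: list[str]
    provenance: dict[str, float] = field(default_factory=dict)

    SYM_TOL = 1e-10
    PSD_TOL = -1e-8

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.lines)
        if self.values.shape != (n, n):
            raise ValueError("kernel shape does not match line count")
        if not np.allclose(self.values, self.values.T, atol=self.SYM_TOL):
            raise ValueError("kernel is not symmetric")

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.lines, columns=self.lines)

    def reorder(self, lines) -> "Kernel":
        lines = list(lines)
        idx = [self.lines.index(l) for l in lines]
        return Kernel(self.values[np.ix_(idx, idx)], lines, dict(self.provenance))


@dataclass
class EvalResult:
    """Per-repetition prediction abilities for one validation scheme."""

    scheme: str
    dataset: str
    trait: str
    abilities: np.ndarray  # one entry per repetition (or per fold x repetition)
    meta: dict = field(default_factory=dict)

    @property
    def mean(self) -> float:
        a = self.abilities[~np.isnan(self.abilities)]
        return float(a.mean()) if a.size else float("nan")

    @property
    def std(self) -> float:
        a = self.abilities[~np.isnan(self.abilities)]
        return float(a.std(ddof=1)) if a.size > 1 else float("nan")
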