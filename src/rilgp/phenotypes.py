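"""Adjusted entry means across environments and broad-sense heritability.

Entry means come from the mixed model

    y_ijk = mu + G_i + E_j + (GxE)_ij + eps_ijk

with genotype fixed and environment and interaction random.  When no
genotype has within-environment replication the interaction is completely
confounded with the residual and the two are pooled into one component.
Heritability follows the entry-mean definition

    H2 = s2_G / (s2_G + vbar / 2)

where vbar is the mean variance of a difference between two adjusted entry
means and s2_G comes from a companion fit with genotype random.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixedlm import fit_reml, indicator


@dataclass
class EntryMeans:
    """Per-line adjusted means and the trait-level variance summary."""

    trait: str
    means: pd.Series  # line -> adjusted entry mean
    vbar: float  # mean variance of a difference of two adjusted means
    sigma2_g: float  # genetic variance (genotype-random companion fit)
    h2: float
    components: dict


def _pairwise_diff_var_mean(cov: np.ndarray) -> float:
    """Mean over line pairs i<j of Var(m_i - m_j) from the GLS covariance."""
    g = cov.shape[0]
    if g < 2:
        return float("nan")
    d = np.diag(cov)
    total = g * d.sum() + g * d.sum() - 2.0 * cov.sum()  # sum over all i,j
    return float((total - 0.0) / (g * (g - 1)))  # i=j terms vanish


def adjusted_entry_means(
    records: pd.DataFrame, trait: str | None = None
) -> EntryMeans:
    """Fit the entry-means mixed model for one trait.

    ``records`` is long-format with columns line, environment, value (and
    optionally trait to select on).  Returns adjusted means, vbar, the
    genotype-random genetic variance, and the Piepho-Moehring H2.
    """
    df = records
    if trait is not None and "trait" in df.columns:
        df = df[df["trait"] == trait]
    elif trait is None:
        trait = str(df["trait"].iloc[0]) if "trait" in df.columns else "trait"
        if "trait" in df.columns:
            df = df[df["trait"] == trait]
    y = df["value"].to_numpy(dtype=float)
    X, lines = indicator(df["line"])
    Ze, _ = indicator(df["environment"])
    n_env = Ze.shape[1]

    if n_env < 2:
        warnings.warn(
            f"trait {trait}: single environment; raw means reported", stacklevel=2
        )
        means = df.groupby("line")["value"].mean().reindex(lines)
        resid = df["value"] - means.loc[df["line"]].to_numpy()
        s2_e = float(resid.var(ddof=len(lines)))
        counts = df.groupby("line").size().reindex(lines).to_numpy(dtype=float)
        var_mean = s2_e / counts
        g = len(lines)
        vbar = float(
            (g * var_mean.sum() * 2 - 2 * var_mean.sum()) / (g * (g - 1))
        ) if g > 1 else float("nan")
        s2_g = max(float(means.var(ddof=1)) - float(np.mean(var_mean)), 0.0)
        h2 = heritability(s2_g, vbar) if s2_g + vbar > 0 else float("nan")
        return EntryMeans(trait, means, vbar, s2_g, h2,
                          {"sigma2_e": s2_e, "pooled": True, "n_env": 1})

    # Interaction is only separable from error through within-environment
    # replication.  With check-only replication (a few replicated parents
    # among hundreds of singleton lines) the interaction variance is not
    # estimable in practice, so it is pooled into the residual unless a
    # substantial share of cells is replicated.
    cell = df.groupby(["line", "environment"]).size()
    replicated = (cell > 1).mean() >= 0.10
    Zs = [Ze]
    if replicated:
        Zge, _ = indicator(
            df["line"].astype(str) + "::" + df["environment"].astype(str)
        )
        Zs.append(Zge)

    fit = fit_reml(y, X, Zs)
    means = pd.Series(fit.beta, index=lines)
    vbar = _pairwise_diff_var_mean(fit.cov_beta)

    # companion fit: genotype random, for sigma2_g
    Zg, _ = indicator(df["line"])
    Xmu = np.ones((len(y), 1))
    rfit = fit_reml(y, Xmu, [Zg] + Zs)
    s2_g = float(rfit.lambdas[0] * rfit.sigma2)

    comps = {
        "sigma2_e": fit.sigma2,
        "sigma2_env": float(fit.lambdas[0] * fit.sigma2),
        "pooled": not replicated,
        "n_env": int(n_env),
    }
    if replicated:
        comps["sigma2_ge"] = float(fit.lambdas[1] * fit.sigma2)
    h2 = heritability(s2_g, vbar)
    return EntryMeans(trait, means, vbar, s2_g, h2, comps)


def heritability(sigma2_g: float, vbar: float) -> float:
    """Entry-mean broad-sense heritability s2_G / (s2_G + vbar / 2)."""
    if sigma2_g < 0 or vbar < 0:
        raise ValueError("variance inputs must be non-negative")
    if sigma2_g == 0 and vbar == 0:
        raise ValueError("H2 undefined when both components are zero")
    return sigma2_g / (sigma2_g + vbar / 2.0)


def entry_means_all_traits(
    records: pd.DataFrame, lines=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Adjusted means for every trait; returns (means table, trait summary).

    ``lines`` optionally restricts/reorders the output rows (e.g. RILs only).
    """
    means, rows = {}, []
    for trait in records["trait"].unique():
        em = adjusted_entry_means(records, trait)
        means[trait] = em.means
        rows.append(
            {
                "trait": trait,
                "H2": em.h2,
                "sigma2_g": em.sigma2_g,
                "vbar": em.vbar,
            }
        )
    table = pd.DataFrame(means)
    if lines is not None:
        table = table.loc[[l for l in lines if l in table.index]]
    return table, pd.DataFrame(rows).set_index("trait")
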