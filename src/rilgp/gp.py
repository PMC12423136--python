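"""Kernels, REML variance components, GBLUP prediction, prediction ability.

A predictor dataset (marker dosages or expression values) is column
z-scored and turned into an additive relationship matrix G = W* W*^T / m
(VanRaden-style, with m the feature count).  Several datasets enter one
model through an elementwise weighted average of their kernels.  The GBLUP
model

    y = mu + u + e,   u ~ N(0, G s2_u),   e ~ N(0, I s2_e)

is fit by REML through a single eigendecomposition of the training kernel
and a bounded scalar search over log(lambda), lambda = s2_e / s2_u; test
lines are predicted by the conditional mean

    u_test = G_test,train (G_train,train + lambda I)^-1 (y_train - mu).

Prediction ability is the Pearson correlation between predictions and the
observed adjusted entry means of the validation set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .types import Kernel

LOG_LAMBDA_BOUNDS = (-12.0, 12.0)
RIDGE = 1e-8


def zscore(features: pd.DataFrame) -> pd.DataFrame:
    """Column-standardize (mean 0, population-SD 1); constant columns dropped."""
    if len(features) < 2:
        raise ValueError("need at least 2 lines")
    arr = features.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("features contain missing values; impute upstream")
    mu = arr.mean(axis=0)
    sd = arr.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all feature columns are constant")
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} constant feature columns", stacklevel=2)
    out = (arr[:, keep] - mu[keep]) / sd[keep]
    return pd.DataFrame(out, index=features.index, columns=features.columns[keep])


def vanraden_kernel(zscores: pd.DataFrame, provenance: str = "features") -> Kernel:
    """G = W* W*^T / m.  With population-SD z-scores, mean(diag(G)) = 1."""
    m = zscores.shape[1]
    if m == 0:
        raise ValueError("no features left")
    W = zscores.to_numpy(dtype=float)
    G = W @ W.T / m
    G = (G + G.T) / 2.0
    return Kernel(G, list(zscores.index), {provenance: 1.0})


def kernel_from_features(features: pd.DataFrame, provenance: str = "features") -> Kernel:
    """Convenience: z-score then build the relationship matrix."""
    return vanraden_kernel(zscore(features), provenance)


def combine_kernels(kernels: list[Kernel], weights=None) -> Kernel:
    """Elementwise weighted average of kernels on identical line sets."""
    if weights is None:
        weights = np.full(len(kernels), 1.0 / len(kernels))
    weights = np.asarray(weights, dtype=float)
    if weights.size != len(kernels):
        raise ValueError("one weight per kernel required")
    if (weights < 0).any() or not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must be non-negative and sum to 1")
    ref = kernels[0].lines
    for k in kernels[1:]:
        if k.lines != ref:
            diff = set(k.lines) ^ set(ref)
            raise ValueError(f"kernel line sets differ: {sorted(diff)[:10]}")
    values = sum(w * k.values for w, k in zip(weights, kernels))
    prov = {}
    for w, k in zip(weights, kernels):
        for src, wsrc in k.provenance.items():
            prov[src] = prov.get(src, 0.0) + w * wsrc
    return Kernel(values, list(ref), prov)


@dataclass
class GBLUPFit:
    """REML solution of the single-kernel GBLUP model on a training set."""

    mu: float
    sigma2_u: float
    sigma2_e: float
    u: pd.Series  # BLUPs of training-line genotypic effects
    reml_loglik: float
    lines: list
    y_resid: np.ndarray  # training-set y - mu, in line order

    @property
    def h2(self) -> float:
        return self.sigma2_u / (self.sigma2_u + self.sigma2_e)

    @property
    def lam(self) -> float:
        """Shrinkage ratio s2_e / s2_u (inf when s2_u = 0)."""
        return self.sigma2_e / self.sigma2_u if self.sigma2_u > 0 else np.inf


def reml_fit(y: pd.Series, kernel: Kernel) -> GBLUPFit:
    """REML variance components by spectral decomposition + scalar search."""
    y = y.loc[kernel.lines]
    yv = y.to_numpy(dtype=float)
    if not np.isfinite(yv).all():
        raise ValueError("non-finite phenotypes")
    n = yv.size
    if n < 5:
        raise ValueError("need at least 5 training lines")
    K = kernel.values
    d, U = np.linalg.eigh(K)
    if d[0] < Kernel.PSD_TOL:
        warnings.warn("kernel not PSD; ridge-stabilized", stacklevel=2)
        K = K + RIDGE * np.eye(n)
        d, U = np.linalg.eigh(K)
    d = np.maximum(d, 0.0)
    yt = U.T @ yv
    xt = U.T @ np.ones(n)

    def profile(log_delta):
        """Profiled restricted log-likelihood at delta = s2_e / s2_u."""
        delta = np.exp(log_delta)
        r = d + delta
        xr = xt / r
        sxx = xr @ xt
        mu = (xr @ yt) / sxx
        e = yt - mu * xt
        s2u = (e**2 / r).sum() / (n - 1)
        ll = -0.5 * (
            (n - 1) * (np.log(2.0 * np.pi * s2u) + 1.0)
            + np.log(r).sum()
            + np.log(sxx)
        )
        return ll, mu, s2u, delta

    res = optimize.minimize_scalar(
        lambda x: -profile(x)[0],
        bounds=LOG_LAMBDA_BOUNDS,
        method="bounded",
        options={"xatol": 1e-8},
    )
    ll, mu, s2u, delta = profile(res.x)
    s2e = delta * s2u
    # BLUP of u on the training lines: u = K (K + delta I)^-1 (y - mu)
    resid = yv - mu
    u = (U * (d / (d + delta))) @ (U.T @ resid)
    return GBLUPFit(
        mu=float(mu),
        sigma2_u=float(s2u),
        sigma2_e=float(s2e),
        u=pd.Series(u, index=kernel.lines),
        reml_loglik=float(ll),
        lines=list(kernel.lines),
        y_resid=resid,
    )


def gblup_predict(
    fit: GBLUPFit, kernel_full: Kernel, train_lines, test_lines
) -> pd.Series:
    """Conditional-mean prediction of test-line genotypic values.

    Requires ``fit`` to have been obtained on ``train_lines`` of the same
    kernel.  With s2_u = 0 every prediction collapses to mu.
    """
    train_lines, test_lines = list(train_lines), list(test_lines)
    pos = {l: i for i, l in enumerate(kernel_full.lines)}
    tr = [pos[l] for l in train_lines]
    te = [pos[l] for l in test_lines]
    if fit.sigma2_u <= 0 or not np.isfinite(fit.lam):
        warnings.warn("sigma2_u = 0: predictions equal mu", stacklevel=2)
        return pd.Series(fit.mu, index=test_lines)
    if list(fit.lines) != train_lines:
        raise ValueError("fit was not obtained on the given training lines")
    K = kernel_full.values
    Ktt = K[np.ix_(tr, tr)] + fit.lam * np.eye(len(tr))
    alpha = np.linalg.solve(Ktt, fit.y_resid)
    pred = fit.mu + K[np.ix_(te, tr)] @ alpha
    return pd.Series(pred, index=test_lines)


def prediction_ability(predicted: pd.Series, observed: pd.Series) -> float:
    """Pearson correlation of predictions with observed entry means.

    Returns NaN (with a warning) when either vector has zero variance.
    """
    common = predicted.index.intersection(observed.index)
    if len(common) < 3:
        raise ValueError("need at least 3 prediction/observation pairs")
    a = predicted.loc[common].to_numpy(dtype=float)
    b = observed.loc[common].to_numpy(dtype=float)
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero variance: prediction ability undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
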