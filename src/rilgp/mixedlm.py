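"""Small dense REML machinery for models with a few random-effect factors.

Covers the two designs the pipeline needs: per-transcript block adjustment
(genotype fixed, block random) and multi-environment entry means (genotype
fixed; environment and optionally genotype-by-environment random).  The
scaled covariance is R = I + sum_k lambda_k Z_k Z_k'; the residual variance
is profiled out and each variance ratio lambda_k is found by bounded search
on the restricted likelihood.  All solves go through the Woodbury identity,
so cost scales with the number of random-effect levels, not observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

LOG_LAMBDA_BOUNDS = (-12.0, 12.0)
REML_TOL = 1e-8


@dataclass
class GLSFit:
    beta: np.ndarray
    cov_beta: np.ndarray  # sampling covariance of beta
    sigma2: float  # residual variance
    lambdas: np.ndarray  # variance ratios sigma2_k / sigma2
    reml_loglik: float


def _profiled_reml(y, X, Zs, lambdas):
    """Restricted log-likelihood with sigma2 profiled out, plus GLS pieces."""
    n, p = X.shape
    parts = [np.sqrt(lam) * Z for lam, Z in zip(lambdas, Zs) if lam > 0]
    if parts:
        Zs_ = np.hstack(parts)
        q = Zs_.shape[1]
        M = np.eye(q) + Zs_.T @ Zs_
        cM = linalg.cho_factor(M, lower=True)
        logdet_R = 2.0 * np.log(np.diag(cM[0])).sum()

        def rinv(v):
            return v - Zs_ @ linalg.cho_solve(cM, Zs_.T @ v)
    else:
        logdet_R = 0.0

        def rinv(v):
            return v

    RiX = rinv(X)
    Riy = rinv(y)
    XtRiX = X.T @ RiX
    XtRiy = X.T @ Riy
    beta = linalg.solve(XtRiX, XtRiy, assume_a="pos")
    rss = float(y @ Riy - beta @ XtRiy)
    rss = max(rss, 1e-300)
    sigma2 = rss / (n - p)
    sign, logdet_XtRiX = np.linalg.slogdet(XtRiX)
    ll = -0.5 * (
        (n - p) * (np.log(2.0 * np.pi * sigma2) + 1.0)
        + logdet_R
        + logdet_XtRiX
    )
    cov_beta = sigma2 * linalg.inv(XtRiX)
    return ll, beta, cov_beta, sigma2


def fit_reml(y, X, Zs, fixed_lambdas=None) -> GLSFit:
    """REML fit of y = X beta + sum_k u_k + e over the variance ratios.

    ``Zs`` is a list of incidence matrices (one per random factor); pass
    ``fixed_lambdas`` to skip the optimization (used by oracles/tests).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Zs = [np.asarray(Z, dtype=float) for Z in Zs]
    k = len(Zs)
    if fixed_lambdas is not None:
        lam = np.asarray(fixed_lambdas, dtype=float)
        ll, beta, cov, s2 = _profiled_reml(y, X, Zs, lam)
        return GLSFit(beta, cov, s2, lam, ll)
    if k == 0:
        ll, beta, cov, s2 = _profiled_reml(y, X, [], np.array([]))
        return GLSFit(beta, cov, s2, np.array([]), ll)

    lo, hi = LOG_LAMBDA_BOUNDS

    if k == 1:
        def neg(loglam):
            return -_profiled_reml(y, X, Zs, np.array([np.exp(loglam)]))[0]

        res = optimize.minimize_scalar(
            neg, bounds=(lo, hi), method="bounded",
            options={"xatol": REML_TOL},
        )
        # allow the boundary solution lambda -> 0
        if neg(lo) <= res.fun:
            lam = np.array([0.0])
        else:
            lam = np.array([np.exp(res.x)])
    else:
        def neg(loglam):
            return -_profiled_reml(y, X, Zs, np.exp(np.clip(loglam, lo, hi)))[0]

        best = None
        for start in ([0.0] * k, [-3.0] * k, [2.0] * k):
            res = optimize.minimize(
                neg, np.array(start), method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 400},
            )
            if best is None or res.fun < best.fun:
                best = res
        lam = np.exp(np.clip(best.x, lo, hi))
        lam[lam < 1.5 * np.exp(lo)] = 0.0
    ll, beta, cov, s2 = _profiled_reml(y, X, Zs, lam)
    return GLSFit(beta, cov, s2, lam, ll)


def indicator(labels) -> tuple[np.ndarray, list]:
    """0/1 incidence matrix for a categorical vector, plus level order."""
    labels = np.asarray(labels)
    levels = list(dict.fromkeys(labels))
    Z = np.zeros((labels.size, len(levels)))
    for j, lev in enumerate(levels):
        Z[labels == lev, j] = 1.0
    return Z, levels
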