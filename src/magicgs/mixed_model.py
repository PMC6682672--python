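"""REML/BLUP engine for the single-random-effect linear mixed model.

The model is y = X beta + g + e with g ~ N(0, sigma2_u K) and
e ~ N(0, sigma2_e I). In the ridge-regression (RRBLUP) form the random
term is marker effects, g = Z u with u ~ N(0, sigma2_u I), which is the
same model with K = Z Z'. The restricted likelihood is profiled down to a
one-dimensional search over the variance ratio lambda = sigma2_e/sigma2_u
after a single spectral decomposition of K, so refits at different fixed
effects (as in stepwise GWAS) are cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .gio import GenotypeMatrix, kinship


@dataclass
class VarianceComponents:
    sigma2_u: float
    sigma2_e: float

    @property
    def lambda_(self) -> float:
        """Ridge parameter lambda = sigma2_e / sigma2_u (inf if no signal)."""
        if self.sigma2_u <= 0:
            return np.inf
        return self.sigma2_e / self.sigma2_u


@dataclass
class MixedModelFit:
    beta: np.ndarray
    varcomp: VarianceComponents
    g: np.ndarray              # BLUP genetic values (n,)
    u: np.ndarray | None       # BLUP marker effects (p,), RRBLUP form only
    fitted: np.ndarray
    loglik: float
    lambda_: float

    def to_dict(self) -> dict:
        return {
            "sigma2_u": self.varcomp.sigma2_u,
            "sigma2_e": self.varcomp.sigma2_e,
            "lambda": self.lambda_,
            "beta": np.asarray(self.beta).tolist(),
        }


def _prepare_K(K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecompose K, jittering once if it is not PSD."""
    K = np.asarray(K, dtype=float)
    d, U = np.linalg.eigh((K + K.T) / 2.0)
    tol = -1e-8 * max(1.0, abs(d[-1]))
    if d[0] < tol:
        K = K + np.eye(K.shape[0]) * (1e-6 * np.mean(np.diag(K)))
        d, U = np.linalg.eigh((K + K.T) / 2.0)
        if d[0] < tol:
            raise ValueError("K is not positive semi-definite even after jitter")
    return np.clip(d, 0.0, None), U


def reml_fit(
    y: np.ndarray,
    X: np.ndarray | None = None,
    K: np.ndarray | None = None,
    Z: np.ndarray | None = None,
    lambda_: float | None = None,
    log_lambda_bounds: tuple = (-10.0, 10.0),
    tol: float = 1e-8,
) -> MixedModelFit:
    """Fit the mixed model by REML (or at a user-fixed variance ratio).

    Exactly one of ``K`` (kinship/GBLUP form) or ``Z`` (marker/RRBLUP form)
    must be given. ``lambda_`` fixes sigma2_e/sigma2_u instead of
    estimating it, which recovers plain ridge regression.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(y) == 0:
        raise ValueError("y is constant")
    if (K is None) == (Z is None):
        raise ValueError("give exactly one of K or Z")
    X = np.ones((n, 1)) if X is None else np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != n:
        raise ValueError("X rows must match y")
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("X is not full column rank")
    if Z is not None:
        Z = np.asarray(Z, dtype=float)
        Kmat = Z @ Z.T
    else:
        Kmat = K
    d, U = _prepare_K(Kmat)
    ys = U.T @ y
    Xs = U.T @ X

    def profile(log_lam):
        lam = np.exp(log_lam)
        dinv = 1.0 / (d + lam)
        XtDX = (Xs * dinv[:, None]).T @ Xs
        beta = np.linalg.solve(XtDX, (Xs * dinv[:, None]).T @ ys)
        r = ys - Xs @ beta
        rss = float(r @ (dinv * r))
        sigma2_u = max(rss / (n - p), 1e-300)
        _, logdet_XtDX = np.linalg.slogdet(XtDX)
        ll = -0.5 * ((n - p) * (np.log(2 * np.pi * sigma2_u) + 1.0)
                     + np.sum(np.log(d + lam)) + logdet_XtDX)
        return lam, dinv, beta, r, sigma2_u, ll

    if lambda_ is not None:
        if lambda_ < 0:
            raise ValueError("lambda_ must be non-negative")
        log_lam = np.log(max(lambda_, 1e-300))
    else:
        res = minimize_scalar(
            lambda ll_: -profile(ll_)[5], bounds=log_lambda_bounds,
            method="bounded", options={"xatol": tol},
        )
        log_lam = float(res.x)
    lam, dinv, beta, r, sigma2_u, ll = profile(log_lam)
    if lambda_ is not None:
        lam = float(lambda_)
        # keep the user's exact ratio in the downstream shrinkage weights
        dinv = 1.0 / (d + lam)
        XtDX = (Xs * dinv[:, None]).T @ Xs
        beta = np.linalg.solve(XtDX, (Xs * dinv[:, None]).T @ ys)
        r = ys - Xs @ beta
        sigma2_u = max(float(r @ (dinv * r)) / (n - p), 1e-300)
    g = U @ (d * dinv * r)
    u = Z.T @ (U @ (dinv * r)) if Z is not None else None
    vc = VarianceComponents(sigma2_u=float(sigma2_u),
                            sigma2_e=float(lam * sigma2_u))
    return MixedModelFit(beta=beta, varcomp=vc, g=g, u=u,
                         fitted=X @ beta + g, loglik=float(ll),
                         lambda_=float(lam))


def marker_h2(geno: GenotypeMatrix, pheno: np.ndarray) -> float:
    """Narrow-sense genomic heritability from the kinship-form REML fit.

    h2 = sigma2_g / (sigma2_g + sigma2_e), where the genetic variance on
    the observation scale is sigma2_u times the mean diagonal of the
    VanRaden K (which is ~2 for fully inbred lines rather than 1).
    """
    y = np.asarray(pheno, dtype=float).ravel()
    if len(y) != geno.n_rils:
        raise ValueError("phenotype length must match the number of RILs")
    Km = kinship(geno).values
    fit = reml_fit(y, K=Km)
    scale = float(np.mean(np.diag(Km)))
    sg = fit.varcomp.sigma2_u * scale
    h2 = sg / (sg + fit.varcomp.sigma2_e)
    return float(np.clip(h2, 0.0, 1.0))
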