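"""Genomic prediction models: RRBLUP, FxRRBLUP, Bayesian RKHS, and SVR.

* RRBLUP fits all markers as random effects with a common variance via the
  REML engine; FxRRBLUP additionally moves a short list of known QTNs into
  the fixed-effects design (and out of the random term).
* RKHS is a Bayesian kernel regression y = 1 mu + u + eps with
  u ~ N(0, K_h sigma2_u), K_h a Gaussian kernel of marker distances; the
  posterior is explored by a Gibbs sampler in the kernel eigenbasis with
  scaled-inverse-chi-square priors on both variances.
* SVR is epsilon-insensitive support vector regression with an RBF kernel
  (scikit-learn), bandwidth set by the median heuristic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.svm import SVR

from .gio import GenotypeMatrix
from .mixed_model import reml_fit

MODEL_KINDS = ("rrblup", "fx_rrblup", "rkhs", "svr")


@dataclass
class GsFit:
    """A trained genotype -> phenotype prediction model."""

    kind: str
    snp_ids: np.ndarray
    train_ril_ids: np.ndarray
    params: dict

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")


def _codes(geno: GenotypeMatrix) -> np.ndarray:
    return geno.float_codes(impute=True)


def _check_snps(fit: GsFit, geno: GenotypeMatrix) -> None:
    if list(geno.snp_ids) != list(fit.snp_ids):
        missing = sorted(set(fit.snp_ids) - set(geno.snp_ids))
        raise ValueError(
            "SNP set does not match training panel"
            + (f"; missing {missing[:5]}..." if missing else " (order differs)")
        )


def fit_rrblup(
    geno_train: GenotypeMatrix,
    pheno_train: np.ndarray,
    fixed_qtns: list | None = None,
) -> GsFit:
    """(Fx)RRBLUP: markers random, optional named QTNs as fixed effects.

    With ``fixed_qtns`` empty this is plain RRBLUP. Fixed QTNs are removed
    from the random-marker design; collinear fixed QTNs are dropped with a
    warning rather than failing the fit.
    """
    y = np.asarray(pheno_train, dtype=float).ravel()
    X_all = _codes(geno_train)
    snp_index = {s: j for j, s in enumerate(geno_train.snp_ids)}
    fixed_qtns = list(fixed_qtns or [])
    for s in fixed_qtns:
        if s not in snp_index:
            raise ValueError(f"fixed QTN {s!r} not in the panel")
    fixed_idx = [snp_index[s] for s in fixed_qtns]
    # drop collinear fixed QTNs (keep earlier = more significant ones)
    keep: list[int] = []
    n = len(y)
    for j in fixed_idx:
        cand = np.column_stack([np.ones(n)] + [X_all[:, t] for t in keep]
                               + [X_all[:, j]])
        if np.linalg.matrix_rank(cand) == cand.shape[1]:
            keep.append(j)
        else:
            warnings.warn(
                f"fixed QTN {geno_train.snp_ids[j]!r} is collinear; dropped",
                stacklevel=2)
    fixed_idx = keep
    rand_mask = np.ones(X_all.shape[1], dtype=bool)
    rand_mask[fixed_idx] = False
    z_means = X_all[:, rand_mask].mean(axis=0)
    Z = X_all[:, rand_mask] - z_means
    X = np.column_stack([np.ones(n), X_all[:, fixed_idx]])
    fit = reml_fit(y, X=X, Z=Z)
    kind = "fx_rrblup" if fixed_idx else "rrblup"
    return GsFit(
        kind=kind, snp_ids=geno_train.snp_ids,
        train_ril_ids=geno_train.ril_ids,
        params={
            "beta": fit.beta, "u": fit.u, "fixed_idx": np.array(fixed_idx, int),
            "fixed_qtns": [geno_train.snp_ids[j] for j in fixed_idx],
            "rand_mask": rand_mask, "z_means": z_means,
            "varcomp": fit.varcomp, "lambda": fit.lambda_,
            "fitted": fit.fitted,
        },
    )


def _predict_rrblup(fit: GsFit, geno: GenotypeMatrix) -> np.ndarray:
    X_all = _codes(geno)
    p = fit.params
    X = np.column_stack([np.ones(geno.n_rils), X_all[:, p["fixed_idx"]]])
    Z = X_all[:, p["rand_mask"]] - p["z_means"]
    return X @ p["beta"] + Z @ p["u"]


def gaussian_kernel(
    geno_a: np.ndarray | GenotypeMatrix,
    geno_b: np.ndarray | GenotypeMatrix | None = None,
    h: float = 0.5,
    mean_sq_dist: float | None = None,
) -> np.ndarray:
    """K_ij = exp(-h d2_ij / mean(d2)) on squared Euclidean marker distance.

    ``mean_sq_dist`` is the scaling constant from the *training* panel
    (mean off-diagonal squared distance); pass it when computing
    train x new cross-kernels so train and test share one scale.
    """
    if h <= 0:
        raise ValueError("smoothing parameter h must be > 0")
    A = _codes(geno_a) if isinstance(geno_a, GenotypeMatrix) else np.asarray(
        geno_a, float)
    B = A if geno_b is None else (
        _codes(geno_b) if isinstance(geno_b, GenotypeMatrix)
        else np.asarray(geno_b, float))
    d2 = cdist(A, B, metric="sqeuclidean")
    if mean_sq_dist is None:
        if geno_b is not None and not np.array_equal(A, B):
            raise ValueError("mean_sq_dist is required for cross-kernels")
        off = d2[~np.eye(len(A), dtype=bool)]
        mean_sq_dist = float(off.mean()) if off.size else 0.0
        if mean_sq_dist <= 0:
            raise ValueError("zero mean squared distance (identical rows)")
    return np.exp(-h * d2 / mean_sq_dist)


@dataclass
class RkhsConfig:
    """Gibbs-sampler settings for the Bayesian RKHS model."""

    h: float = 0.5
    burn_in: int = 1000
    iterations: int = 2500
    prior_df: float = 5.0

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("h must be > 0")
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")


def fit_rkhs(
    geno_train: GenotypeMatrix,
    pheno_train: np.ndarray,
    config: RkhsConfig | None = None,
    seed: int | None = None,
) -> GsFit:
    """Bayesian RKHS regression by Gibbs sampling in the kernel eigenbasis.

    Scaled-inverse-chi-square priors on sigma2_u and sigma2_e have
    ``config.prior_df`` degrees of freedom and scales chosen so each prior
    mode is half of Var(y). The GEBV is the posterior mean of u.
    """
    cfg = config or RkhsConfig()
    y = np.asarray(pheno_train, dtype=float).ravel()
    n = len(y)
    Xtr = _codes(geno_train)
    d2 = cdist(Xtr, Xtr, metric="sqeuclidean")
    off = d2[~np.eye(n, dtype=bool)]
    mean_sq_dist = float(off.mean())
    if mean_sq_dist <= 0:
        raise ValueError("zero mean squared distance among training lines")
    K = np.exp(-cfg.h * d2 / mean_sq_dist)
    d, U = np.linalg.eigh((K + K.T) / 2.0)
    d = np.clip(d, 0.0, None)
    pos = d > 1e-10 * d.max()
    ys = U.T @ y
    ones_s = U.T @ np.ones(n)
    rng = np.random.default_rng(seed)
    vy = float(np.var(y))
    nu = cfg.prior_df
    s2_scale = 0.5 * vy * (nu + 2.0) / nu  # prior mode at Var(y)/2
    sigma2_u = sigma2_e = max(vy / 2.0, 1e-12)
    mu = float(y.mean())
    a = np.zeros(n)
    keep = cfg.iterations - cfg.burn_in
    a_sum = np.zeros(n)
    mu_sum = 0.0
    su_sum = se_sum = vu_sum = 0.0
    for it in range(cfg.iterations):
        # a | rest: independent normals in the eigenbasis
        prec = 1.0 / sigma2_e + np.where(pos, 1.0 / (d * sigma2_u + 1e-300),
                                         np.inf)
        var_a = 1.0 / prec
        mean_a = var_a * (ys - ones_s * mu) / sigma2_e
        a = mean_a + rng.normal(size=n) * np.sqrt(var_a)
        a[~pos] = 0.0
        # mu | rest
        r = ys - a
        denom = float(ones_s @ ones_s)
        mu = float(rng.normal((ones_s @ r) / denom,
                              np.sqrt(sigma2_e / denom)))
        # sigma2_e | rest
        sse = float(np.sum((ys - ones_s * mu - a)**2))
        sigma2_e = (nu * s2_scale + sse) / rng.chisquare(nu + n)
        # sigma2_u | rest
        ssu = float(np.sum(a[pos]**2 / d[pos]))
        n_pos = int(pos.sum())
        sigma2_u = (nu * s2_scale + ssu) / rng.chisquare(nu + n_pos)
        if not (np.isfinite(sigma2_u) and np.isfinite(sigma2_e)):
            raise FloatingPointError(
                f"divergent variance draw at iteration {it}: "
                f"sigma2_u={sigma2_u}, sigma2_e={sigma2_e}")
        if it >= cfg.burn_in:
            a_sum += a
            mu_sum += mu
            su_sum += sigma2_u
            se_sum += sigma2_e
            vu_sum += float(np.var(U @ a))
    a_mean = a_sum / keep
    u_hat = U @ a_mean
    # kernel-regression weights for out-of-sample prediction
    coef = np.zeros(n)
    coef[pos] = a_mean[pos] / d[pos]
    alpha = U @ coef
    return GsFit(
        kind="rkhs", snp_ids=geno_train.snp_ids,
        train_ril_ids=geno_train.ril_ids,
        params={
            "mu": mu_sum / keep, "u": u_hat, "alpha": alpha,
            "train_codes": Xtr, "h": cfg.h, "mean_sq_dist": mean_sq_dist,
            "sigma2_u": su_sum / keep, "sigma2_e": se_sum / keep,
            # realised genetic variance across lines (the kernel's scale
            # parameter sigma2_u overlaps the intercept via the leading
            # near-constant eigencomponent, so it is not directly the
            # observation-scale genetic variance)
            "genetic_variance": vu_sum / keep,
            "config": cfg,
        },
    )


def _predict_rkhs(fit: GsFit, geno: GenotypeMatrix) -> np.ndarray:
    p = fit.params
    Kc = gaussian_kernel(_codes(geno), p["train_codes"], h=p["h"],
                         mean_sq_dist=p["mean_sq_dist"])
    return p["mu"] + Kc @ p["alpha"]


def fit_svr(
    geno_train: GenotypeMatrix,
    pheno_train: np.ndarray,
    C: float = 1.0,
    epsilon: float = 0.1,
    seed: int | None = None,
) -> GsFit:
    """Epsilon-insensitive SVR with RBF kernel, median-heuristic bandwidth.

    The solver is deterministic; ``seed`` is accepted for interface
    uniformity with the other models.
    """
    y = np.asarray(pheno_train, dtype=float).ravel()
    if len(y) < 5:
        raise ValueError("SVR needs at least 5 training lines")
    Xtr = _codes(geno_train)
    if np.all(np.ptp(Xtr, axis=0) == 0):
        raise ValueError("all marker features are constant")
    d2 = cdist(Xtr, Xtr, metric="sqeuclidean")
    med = float(np.median(d2[~np.eye(len(y), dtype=bool)]))
    gamma = 1.0 / med if med > 0 else "scale"
    model = SVR(kernel="rbf", C=C, epsilon=epsilon, gamma=gamma)
    model.fit(Xtr, y)
    return GsFit(
        kind="svr", snp_ids=geno_train.snp_ids,
        train_ril_ids=geno_train.ril_ids,
        params={"model": model, "gamma": gamma, "C": C, "epsilon": epsilon},
    )


def predict(fit: GsFit, geno_new: GenotypeMatrix) -> np.ndarray:
    """Predict phenotypes for new genotypes with any fitted model."""
    _check_snps(fit, geno_new)
    if fit.kind in ("rrblup", "fx_rrblup"):
        out = _predict_rrblup(fit, geno_new)
    elif fit.kind == "rkhs":
        out = _predict_rkhs(fit, geno_new)
    else:
        out = fit.params["model"].predict(_codes(geno_new))
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite predictions")
    return out
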