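"""Multi-locus mixed-model (MLMM) GWAS with stepwise cofactor selection.

Each forward step refits the K-only mixed model (kinship random term, no
population-structure covariates) with the currently selected cofactor SNPs
as fixed effects, re-estimating the variance components, then scores every
remaining SNP with a Wald/F test in the whitened (spectrally rotated)
coordinates and promotes the most significant one. After the forward
passes, cofactors whose conditional p-value exceeds the retention
threshold are backward-eliminated. Reporting significance uses a
Bonferroni cutoff alpha / n_markers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gio import GenotypeMatrix, KinshipMatrix, kinship
from .mixed_model import reml_fit

log = logging.getLogger(__name__)


def bonferroni_threshold(alpha: float, n_markers: int) -> float:
    """Family-wise significance cutoff alpha / n_markers."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    return alpha / n_markers


@dataclass
class GwasResult:
    """Per-step scan p-values and the selected cofactor trail."""

    snp_ids: np.ndarray
    chrom: np.ndarray
    pos_cm: np.ndarray
    step_pvalues: list = field(default_factory=list)   # one (p,) array per step
    step_effects: list = field(default_factory=list)
    cofactors: list = field(default_factory=list)      # final ids, entry order
    alpha: float = 0.05
    threshold: float = np.nan

    def best_pvalues(self) -> np.ndarray:
        """Smallest p-value per SNP across all scan steps."""
        if not self.step_pvalues:
            raise ValueError("empty scan result")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmin(np.vstack(self.step_pvalues), axis=0)

    def best_effects(self) -> np.ndarray:
        stacked_p = np.vstack(self.step_pvalues)
        stacked_b = np.vstack(self.step_effects)
        filled = np.where(np.isnan(stacked_p), np.inf, stacked_p)
        idx = np.argmin(filled, axis=0)
        return stacked_b[idx, np.arange(stacked_b.shape[1])]


def _whitened_scores(yw, Xw, Gw, skip_mask):
    """F-test p-value/effect for adding each column of Gw to the design Xw."""
    n = len(yw)
    q, _ = np.linalg.qr(Xw)
    ry = yw - q @ (q.T @ yw)
    Gp = Gw - q @ (q.T @ Gw)
    ss = np.einsum("ij,ij->j", Gp, Gp)
    dof = n - Xw.shape[1] - 1
    collinear = ss <= 1e-10 * np.maximum(np.einsum("ij,ij->j", Gw, Gw), 1e-30)
    with np.errstate(divide="ignore", invalid="ignore"):
        b = (Gp.T @ ry) / ss
        rss0 = float(ry @ ry)
        rss1 = np.maximum(rss0 - b**2 * ss, 0.0)
        fstat = np.where(rss1 > 0, (rss0 - rss1) / (rss1 / dof), np.inf)
        pvals = stats.f.sf(fstat, 1, dof)
    pvals = np.where(collinear | skip_mask, np.nan, pvals)
    b = np.where(collinear | skip_mask, np.nan, b)
    return pvals, b, collinear


def mlmm_scan(
    geno: GenotypeMatrix,
    pheno: np.ndarray,
    K: KinshipMatrix | np.ndarray | None = None,
    max_steps: int = 10,
    alpha: float = 0.05,
    forward_stop_p: float = 0.01,
    backward_exit_p: float | None = None,
) -> GwasResult:
    """Forward/backward stepwise MLMM scan under the K-only model."""
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    y = np.asarray(pheno, dtype=float).ravel()
    if len(y) != geno.n_rils:
        raise ValueError("phenotype length must match the number of RILs")
    if backward_exit_p is None:
        backward_exit_p = forward_stop_p
    G = geno.float_codes(impute=True)
    n, m = G.shape
    if K is None:
        Kmat = kinship(geno).values
    else:
        Kmat = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, float)
    d, U = np.linalg.eigh((Kmat + Kmat.T) / 2.0)
    d = np.clip(d, 0.0, None)
    ys = U.T @ y
    Gs = U.T @ G
    ones_s = U.T @ np.ones((n, 1))
    result = GwasResult(
        snp_ids=geno.snp_ids, chrom=geno.chrom, pos_cm=geno.pos_cm,
        alpha=alpha, threshold=bonferroni_threshold(alpha, m),
    )
    cof: list[int] = []

    def whiten(cof_idx):
        X = np.concatenate([np.ones((n, 1)), G[:, cof_idx]], axis=1) \
            if cof_idx else np.ones((n, 1))
        fit = reml_fit(y, X=X, K=Kmat)
        w = 1.0 / np.sqrt(d + fit.lambda_)
        Xs = np.concatenate([ones_s, Gs[:, cof_idx]], axis=1) \
            if cof_idx else ones_s
        return ys * w, Xs * w[:, None], Gs * w[:, None]

    for _ in range(max_steps):
        yw, Xw, Gw = whiten(cof)
        skip = np.zeros(m, dtype=bool)
        skip[cof] = True
        pvals, effs, collinear = _whitened_scores(yw, Xw, Gw, skip)
        n_coll = int(collinear.sum()) - len(cof)
        if n_coll > 0:
            log.info("skipped %d SNPs collinear with current cofactors", n_coll)
        result.step_pvalues.append(pvals)
        result.step_effects.append(effs)
        if np.all(np.isnan(pvals)):
            break
        j = int(np.nanargmin(pvals))
        if pvals[j] > forward_stop_p:
            break
        cof.append(j)
    # backward elimination on conditional p-values
    while cof:
        yw, Xw, _ = whiten(cof)
        XtX = Xw.T @ Xw
        XtXinv = np.linalg.pinv(XtX)
        beta = XtXinv @ (Xw.T @ yw)
        resid = yw - Xw @ beta
        dof = n - Xw.shape[1]
        s2 = float(resid @ resid) / dof
        se = np.sqrt(np.clip(np.diag(XtXinv) * s2, 1e-300, None))
        tstat = beta / se
        pcond = 2.0 * stats.t.sf(np.abs(tstat), dof)
        pc = pcond[1:]  # skip intercept
        worst = int(np.argmax(pc))
        if pc[worst] > backward_exit_p:
            dropped = cof.pop(worst)
            log.info("backward-eliminated cofactor %s (p=%.3g)",
                     geno.snp_ids[dropped], pc[worst])
        else:
            break
    result.cofactors = [geno.snp_ids[j] for j in cof]
    return result


def top_k_associations(result: GwasResult, k: int) -> pd.DataFrame:
    """The k most significant distinct SNPs at their best scan step.

    Ties are broken deterministically by (p, chrom, pos_cm, snp_id).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    p = result.best_pvalues()
    eff = result.best_effects()
    df = pd.DataFrame({
        "snp_id": result.snp_ids, "chrom": result.chrom,
        "pos_cm": result.pos_cm, "p": p, "effect": eff,
    })
    df = df[np.isfinite(df["p"])]
    df = df.sort_values(["p", "chrom", "pos_cm", "snp_id"],
                        kind="mergesort").reset_index(drop=True)
    if len(df) < k:
        warnings.warn(f"only {len(df)} scoreable SNPs available for top-{k}",
                      stacklevel=2)
    return df.head(k)
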