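"""Marker-assisted selection surrogate: GWAS-top-k regression.

The MAS model runs the MLMM scan on the training split only, takes the
top-k (default 3) most significant associations, and fits ordinary least
squares of the phenotype on those SNP codes. Validation individuals are
then scored with the fitted regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .gio import GenotypeMatrix
from .gwas import GwasResult, mlmm_scan, top_k_associations


@dataclass
class MasFit:
    snp_ids: list            # selected SNPs, most significant first
    coef: np.ndarray         # intercept followed by per-SNP coefficients
    train_ril_ids: np.ndarray
    panel_snp_ids: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("selected SNPs must be distinct")
        if not np.all(np.isfinite(self.coef)):
            raise ValueError("non-finite MAS coefficients")


def mas_train(
    geno_train: GenotypeMatrix,
    pheno_train: np.ndarray,
    k: int = 3,
    scan: GwasResult | None = None,
    **scan_kwargs,
) -> MasFit:
    """Select the top-k GWAS hits on the training split and fit OLS.

    ``scan`` may carry a precomputed MLMM result for this same training
    split (the harness shares one scan between MAS and FxRRBLUP); when
    absent the scan is run here, so selection never sees validation data.
    """
    y = np.asarray(pheno_train, dtype=float).ravel()
    if scan is None:
        scan = mlmm_scan(geno_train, y, **scan_kwargs)
    top = top_k_associations(scan, k)
    if len(top) < k:
        warnings.warn(f"only {len(top)} SNPs available for MAS (k={k})",
                      stacklevel=2)
    snp_index = {s: j for j, s in enumerate(geno_train.snp_ids)}
    idx = [snp_index[s] for s in top["snp_id"]]
    X = np.column_stack([np.ones(len(y)),
                         geno_train.float_codes(impute=True)[:, idx]])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return MasFit(snp_ids=list(top["snp_id"]), coef=coef,
                  train_ril_ids=geno_train.ril_ids,
                  panel_snp_ids=geno_train.snp_ids)


def mas_predict(fit: MasFit, geno_new: GenotypeMatrix) -> np.ndarray:
    snp_index = {s: j for j, s in enumerate(geno_new.snp_ids)}
    missing = [s for s in fit.snp_ids if s not in snp_index]
    if missing:
        raise ValueError(f"panel is missing MAS SNPs {missing}")
    idx = [snp_index[s] for s in fit.snp_ids]
    X = np.column_stack([np.ones(geno_new.n_rils),
                         geno_new.float_codes(impute=True)[:, idx]])
    return X @ fit.coef
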