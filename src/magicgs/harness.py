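"""Subbagging comparison of the five prediction methods and its metrics.

Every cycle draws one 80/20 train/validation split (without replacement)
from a per-cycle seed shared by all methods, runs the MLMM scan once on
the training split, and trains FxRRBLUP (top-3 scan hits fixed), RRBLUP,
RKHS, SVR and MAS on identical data. Validation predictions are scored by

* accuracy — Pearson correlation between observed and predicted values;
* coincidence index — overlap of the observed and predicted top 20%;
* bias — intercept and slope of observed regressed on predicted
  (0 and 1 for an unbiased predictor).

Cross-environment prediction trains on one environment's phenotypes over
the full panel and correlates the fitted genetic values with every other
environment's phenotypes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gio import GenotypeMatrix
from .gs_models import RkhsConfig, fit_rkhs, fit_rrblup, fit_svr, predict
from .gwas import mlmm_scan, top_k_associations
from .mas import mas_predict, mas_train

log = logging.getLogger(__name__)

ALL_MODELS = ("fx_rrblup", "rrblup", "rkhs", "svr", "mas")


@dataclass
class HarnessConfig:
    """Study design for the seeded subbagging comparison."""

    train_fraction: float = 0.8
    n_cycles: int = 100
    top_fraction: float = 0.2
    fixed_qtn_count: int = 3
    models: tuple = ALL_MODELS
    seeds: list | None = None    # one seed per cycle, shared across models
    seed: int | None = None      # master seed used when seeds is None
    rkhs: RkhsConfig = field(default_factory=RkhsConfig)
    scan_kwargs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if not (0.0 < self.top_fraction < 1.0):
            raise ValueError("top_fraction must be in (0, 1)")
        if self.seeds is None:
            ss = np.random.SeedSequence(self.seed)
            self.seeds = [int(c.generate_state(1)[0] % (2**31))
                          for c in ss.spawn(self.n_cycles)]
        if len(self.seeds) != self.n_cycles:
            raise ValueError("seed list length must equal n_cycles")
        unknown = set(self.models) - set(ALL_MODELS)
        if unknown:
            raise ValueError(f"unknown models {sorted(unknown)}")


def subbag_split(ril_ids, train_fraction: float = 0.8,
                 seed: int | None = None):
    """Deterministic disjoint train/validation partition of the RIL ids."""
    ids = np.asarray(ril_ids, dtype=object)
    n = len(ids)
    n_train = int(math.floor(train_fraction * n))
    if n_train < 2 or n_train >= n:
        raise ValueError("train fraction leaves an empty split")
    perm = np.random.default_rng(seed).permutation(n)
    return ids[perm[:n_train]], ids[perm[n_train:]]


def coincidence_index(observed, predicted, top_fraction: float = 0.2) -> float:
    """Overlap of observed and predicted top fractions (size ceil(f n))."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    n = len(obs)
    if n < 5 or len(pred) != n:
        raise ValueError("need two equal-length vectors with n >= 5")
    if np.ptp(pred) == 0:
        raise ValueError("constant predictions: top set undefined")
    k = int(math.ceil(top_fraction * n))
    ids = np.arange(n)
    top_obs = set(ids[np.lexsort((ids, -obs))][:k])
    top_pred = set(ids[np.lexsort((ids, -pred))][:k])
    return len(top_obs & top_pred) / k


def bias_regression(observed, predicted) -> tuple[float, float]:
    """(intercept, slope) of OLS observed ~ predicted."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if np.ptp(pred) == 0:
        raise ValueError("constant predictions: bias regression undefined")
    slope, intercept = np.polyfit(pred, obs, 1)
    return float(intercept), float(slope)


def accuracy(observed, predicted) -> float:
    """Pearson correlation between observed and predicted values."""
    return float(np.corrcoef(np.asarray(observed, float),
                             np.asarray(predicted, float))[0, 1])


def _metrics(y_val, pred, top_fraction):
    intercept, slope = bias_regression(y_val, pred)
    return {
        "accuracy": accuracy(y_val, pred),
        "coincidence": coincidence_index(y_val, pred, top_fraction),
        "slope": slope,
        "intercept": intercept,
    }


def run_comparison(geno: GenotypeMatrix, pheno: np.ndarray,
                   config: HarnessConfig | None = None) -> pd.DataFrame:
    """Run the full multi-model subbagging study; one row per model x cycle.

    A model failure in a cycle is recorded (metrics NaN, error message
    kept) and never silently dropped; the harness continues.
    """
    cfg = config or HarnessConfig()
    y = np.asarray(pheno, dtype=float).ravel()
    if len(y) != geno.n_rils:
        raise ValueError("phenotype length must match the panel")
    id_pos = {r: i for i, r in enumerate(geno.ril_ids)}
    rows = []
    for cycle, seed in enumerate(cfg.seeds):
        train_ids, val_ids = subbag_split(geno.ril_ids, cfg.train_fraction,
                                          seed)
        tr = np.array([id_pos[r] for r in train_ids])
        va = np.array([id_pos[r] for r in val_ids])
        g_tr, g_va = geno.subset(rils=tr), geno.subset(rils=va)
        y_tr, y_va = y[tr], y[va]
        scan = None
        if "fx_rrblup" in cfg.models or "mas" in cfg.models:
            scan = mlmm_scan(g_tr, y_tr, **cfg.scan_kwargs)
        for model in cfg.models:
            row = {"cycle": cycle, "seed": seed, "model": model,
                   "n_train": len(tr), "n_validation": len(va),
                   "accuracy": np.nan, "coincidence": np.nan,
                   "slope": np.nan, "intercept": np.nan, "error": ""}
            try:
                if model == "rrblup":
                    pred = predict(fit_rrblup(g_tr, y_tr), g_va)
                elif model == "fx_rrblup":
                    top = top_k_associations(scan, cfg.fixed_qtn_count)
                    pred = predict(
                        fit_rrblup(g_tr, y_tr,
                                   fixed_qtns=list(top["snp_id"])), g_va)
                elif model == "rkhs":
                    pred = predict(fit_rkhs(g_tr, y_tr, cfg.rkhs, seed=seed),
                                   g_va)
                elif model == "svr":
                    pred = predict(fit_svr(g_tr, y_tr, seed=seed), g_va)
                else:  # mas
                    fit = mas_train(g_tr, y_tr, k=cfg.fixed_qtn_count,
                                    scan=scan)
                    pred = mas_predict(fit, g_va)
                row.update(_metrics(y_va, pred, cfg.top_fraction))
            except Exception as exc:  # recorded, not raised
                row["error"] = f"{type(exc).__name__}: {exc}"
                log.warning("cycle %d model %s failed: %s", cycle, model, exc)
            rows.append(row)
    return pd.DataFrame(rows)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Per-model mean/SD of each metric plus the count of completed cycles."""
    ok = results[results["error"] == ""]
    agg = ok.groupby("model").agg(
        n_ok=("accuracy", "size"),
        accuracy_mean=("accuracy", "mean"), accuracy_sd=("accuracy", "std"),
        coincidence_mean=("coincidence", "mean"),
        coincidence_sd=("coincidence", "std"),
        slope_mean=("slope", "mean"), intercept_mean=("intercept", "mean"),
    )
    n_total = results.groupby("model")["cycle"].size().rename("n_cycles")
    return agg.join(n_total)


def cross_environment_predict(
    geno: GenotypeMatrix,
    pheno_by_env: dict,
    model_kind: str = "rrblup",
    within_env_cycles: int = 10,
    config: HarnessConfig | None = None,
) -> pd.DataFrame:
    """Environment x environment prediction-accuracy matrix.

    Off-diagonal (train, test): the model is trained on the training
    environment's phenotypes over all pairwise-complete RILs and its
    predictions are correlated with the test environment's phenotypes.
    The diagonal holds the within-environment subbagged accuracy.
    """
    envs = list(pheno_by_env)
    if len(envs) < 2:
        raise ValueError("need at least two environments")
    cfg = config or HarnessConfig(n_cycles=within_env_cycles,
                                  models=(model_kind,))
    out = pd.DataFrame(np.nan, index=envs, columns=envs, dtype=float)
    for etr in envs:
        y_tr_full = np.asarray(pheno_by_env[etr], dtype=float)
        for ete in envs:
            if ete == etr:
                res = run_comparison(geno, y_tr_full, cfg)
                out.loc[etr, ete] = summarize(res)["accuracy_mean"].iloc[0]
                continue
            y_te = np.asarray(pheno_by_env[ete], dtype=float)
            mask = np.isfinite(y_tr_full) & np.isfinite(y_te)
            if mask.sum() < len(mask):
                log.info("using %d pairwise-complete RILs for %s -> %s",
                         int(mask.sum()), etr, ete)
            sub = geno.subset(rils=np.flatnonzero(mask))
            if model_kind == "rkhs":
                fit = fit_rkhs(sub, y_tr_full[mask], cfg.rkhs, seed=cfg.seeds[0])
            elif model_kind == "svr":
                fit = fit_svr(sub, y_tr_full[mask])
            else:
                fit = fit_rrblup(sub, y_tr_full[mask])
            out.loc[etr, ete] = accuracy(y_te[mask], predict(fit, sub))
    return out


def environment_blups(pheno_table, trait: str) -> pd.Series:
    """Across-environment genotype BLUPs from a two-way mixed model.

    y_ij = env_j + g_i + e_ij with environments fixed and genotypes
    random; variance components come from the balanced-ANOVA method-of-
    moments estimator and the BLUP is the shrunken genotype mean of the
    environment-centred records.
    """
    d = pheno_table.data
    d = d[d["trait"] == trait]
    wide = d.pivot_table(index="ril_id", columns="environment", values="value")
    centred = wide - wide.mean(axis=0)
    n_env = wide.shape[1]
    g_means = centred.mean(axis=1)
    ms_g = float(g_means.var(ddof=1)) * n_env
    ms_e = float(((centred.sub(g_means, axis=0))**2).sum().sum()
                 / (len(wide) - 1) / max(n_env - 1, 1))
    sigma2_g = max((ms_g - ms_e) / n_env, 0.0)
    shrink = sigma2_g / (sigma2_g + ms_e / n_env) if sigma2_g > 0 else 0.0
    return g_means * shrink + float(wide.mean().mean())
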