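"""Stepwise main-effect QTL mapping and additive + epistatic model building.

Two mappers share the same forward/backward machinery:

* :func:`stepwise_main_qtl` — additive-only stepwise regression whose entry
  threshold is calibrated by permutation: at each step the current model's
  residuals are permuted and rescanned, and the 5th percentile of the
  genome-wide minimum p-value is the bar a new SNP must clear.
* :func:`spaeml_fit` — a stepwise search over additive terms and two-way
  additive x additive interaction terms (elementwise products of -1/0/1
  codes), selecting by an extended BIC and classifying each retained locus
  as additive, epistatic, or both.

Per-term summaries follow the single-regressor conventions: PVE is
100 x R^2 of the trait on that term alone, and the additive effect of a
marker is half the difference between its homozygous class means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .gio import GenotypeMatrix


def pve(regressor: np.ndarray, pheno: np.ndarray) -> float:
    """Percent of phenotypic variance explained: 100 x R^2, single term."""
    x = np.asarray(regressor, dtype=float).ravel()
    y = np.asarray(pheno, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("regressor and phenotype lengths differ")
    if np.ptp(x) == 0:
        raise ValueError("constant regressor has undefined PVE")
    r = np.corrcoef(x, y)[0, 1]
    return float(100.0 * r * r)


def additive_effect(geno_column: np.ndarray, pheno: np.ndarray) -> float:
    """(mean of +1 homozygotes - mean of -1 homozygotes) / 2, in trait units.

    Heterozygotes (code 0) are excluded, matching the two-class estimator.
    """
    x = np.asarray(geno_column).ravel()
    y = np.asarray(pheno, dtype=float).ravel()
    hi = y[x == 1]
    lo = y[x == -1]
    if len(hi) == 0 or len(lo) == 0:
        raise ValueError("both homozygous classes must be present")
    return float((hi.mean() - lo.mean()) / 2.0)


@dataclass
class QtlModel:
    """Selected additive and two-way epistatic terms with summaries."""

    additive_terms: pd.DataFrame   # snp_id, chrom, pos_cm, effect, p, pve
    epistatic_terms: pd.DataFrame  # snp_i, snp_j, effect, p, pve
    trace: list = field(default_factory=list)
    permutation_threshold: float | None = None
    criterion: str | None = None

    def snp_classification(self) -> dict:
        """Map snp_id -> 'additive' | 'epistatic' | 'both'."""
        add = set(self.additive_terms["snp_id"])
        epi = set(self.epistatic_terms["snp_i"]) | set(self.epistatic_terms["snp_j"])
        out = {}
        for s in add | epi:
            out[s] = "both" if (s in add and s in epi) else \
                ("additive" if s in add else "epistatic")
        return out

    def to_frame(self) -> pd.DataFrame:
        a = self.additive_terms.assign(term_type="additive",
                                       snp_i=lambda d: d["snp_id"], snp_j=None)
        e = self.epistatic_terms.assign(term_type="epistatic")
        cols = ["term_type", "snp_i", "snp_j", "effect", "p", "pve"]
        parts = [f[cols] for f in (a, e) if len(f)]
        if not parts:
            return pd.DataFrame(columns=cols)
        return pd.concat(parts, ignore_index=True)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _scan_add(y, Q, C, ss=None):
    """Partial F p-values for adding each column of C to design with basis Q."""
    n = len(y)
    ry = y - Q @ (Q.T @ y)
    Cp = C - Q @ (Q.T @ C)
    ssc = np.einsum("ij,ij->j", Cp, Cp)
    dof = n - Q.shape[1] - 1
    ok = ssc > 1e-10 * np.maximum(np.einsum("ij,ij->j", C, C), 1e-30)
    with np.errstate(divide="ignore", invalid="ignore"):
        b = (Cp.T @ ry) / ssc
        rss0 = float(ry @ ry)
        rss1 = np.maximum(rss0 - b**2 * ssc, 0.0)
        f = np.where(rss1 > 0, (rss0 - rss1) / (rss1 / dof), np.inf)
        p = stats.f.sf(f, 1, dof)
    p = np.where(ok, p, np.nan)
    return p, b, rss0, rss1, Cp, ssc, dof


def _perm_min_p(rng, n_perm, resid, Q, Cp, ssc, dof):
    """Null distribution of the genome-wide minimum p under permutation.

    Residuals of the current model are shuffled and rescanned with the
    same partial-F statistic.
    """
    n = len(resid)
    idx = np.argsort(rng.random((n_perm, n)), axis=1)
    E = resid[idx]                      # (B, n) permuted residuals
    E = E - (E @ Q) @ Q.T               # re-project against the design
    ok = ssc > 0
    num = (E @ Cp[:, ok])**2 / ssc[ok]
    rss0 = np.einsum("ij,ij->i", E, E)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = num / ((rss0[:, None] - num) / dof)
    fmax = np.nanmax(f, axis=1)
    return stats.f.sf(fmax, 1, dof)


def stepwise_main_qtl(
    geno: GenotypeMatrix,
    pheno: np.ndarray,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    max_terms: int = 20,
    seed: int | None = None,
) -> QtlModel:
    """Forward/backward additive QTL model with permutation entry threshold."""
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    y = np.asarray(pheno, dtype=float).ravel()
    G = geno.float_codes(impute=True)
    n = len(y)
    rng = np.random.default_rng(seed)
    terms: list[int] = []
    trace = []
    first_threshold = None
    while len(terms) < max_terms:
        X = np.concatenate([np.ones((n, 1)), G[:, terms]], axis=1) \
            if terms else np.ones((n, 1))
        Q, _ = np.linalg.qr(X)
        p, b, rss0, rss1, Cp, ssc, dof = _scan_add(y, Q, G)
        p[terms] = np.nan
        resid = y - Q @ (Q.T @ y)
        null_min_p = _perm_min_p(rng, n_permutations, resid, Q, Cp, ssc, dof)
        threshold = float(np.percentile(null_min_p, 100.0 * alpha))
        if first_threshold is None:
            first_threshold = threshold
        if np.all(np.isnan(p)):
            break
        j = int(np.nanargmin(p))
        trace.append({"step": len(trace), "snp_id": geno.snp_ids[j],
                      "p": float(p[j]), "threshold": threshold})
        if p[j] >= threshold:
            break
        terms.append(j)
        # backward pruning at the same (current) exit threshold
        changed = True
        while changed and len(terms) > 1:
            changed = False
            Xf = np.concatenate([np.ones((n, 1)), G[:, terms]], axis=1)
            pc = _conditional_p(y, Xf)[1:]
            worst = int(np.argmax(pc))
            if pc[worst] >= threshold:
                terms.pop(worst)
                changed = True
    return _build_model(geno, y, [("add", j) for j in terms],
                        trace=trace, permutation_threshold=first_threshold,
                        criterion="permutation-F")


def _conditional_p(y, X):
    """Two-sided t-test p-values for each coefficient of an OLS fit."""
    n, k = X.shape
    XtXinv = np.linalg.pinv(X.T @ X)
    beta = XtXinv @ (X.T @ y)
    resid = y - X @ beta
    dof = max(n - k, 1)
    s2 = float(resid @ resid) / dof
    se = np.sqrt(np.clip(np.diag(XtXinv) * s2, 1e-300, None))
    return 2.0 * stats.t.sf(np.abs(beta / se), dof)


def _build_model(geno, y, term_keys, trace, permutation_threshold=None,
                 criterion=None) -> QtlModel:
    """Joint-fit summaries (effect, conditional p, single-term PVE)."""
    G = geno.float_codes(impute=True)
    n = len(y)
    cols, labels = [], []
    for key in term_keys:
        if key[0] == "add":
            cols.append(G[:, key[1]])
        else:
            cols.append(G[:, key[1]] * G[:, key[2]])
        labels.append(key)
    if cols:
        X = np.column_stack([np.ones(n)] + cols)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        pcond = _conditional_p(y, X)
    add_rows, epi_rows = [], []
    for t, key in enumerate(labels):
        eff = float(beta[t + 1])
        p = float(pcond[t + 1])
        term_pve = pve(cols[t], y) if np.ptp(cols[t]) > 0 else 0.0
        if key[0] == "add":
            j = key[1]
            add_rows.append({
                "snp_id": geno.snp_ids[j], "chrom": geno.chrom[j],
                "pos_cm": geno.pos_cm[j], "effect": eff, "p": p,
                "pve": term_pve,
            })
        else:
            i, j = key[1], key[2]
            epi_rows.append({
                "snp_i": geno.snp_ids[i], "snp_j": geno.snp_ids[j],
                "effect": eff, "p": p, "pve": term_pve,
            })
    add_df = pd.DataFrame(add_rows, columns=["snp_id", "chrom", "pos_cm",
                                             "effect", "p", "pve"])
    epi_df = pd.DataFrame(epi_rows, columns=["snp_i", "snp_j", "effect",
                                             "p", "pve"])
    return QtlModel(additive_terms=add_df, epistatic_terms=epi_df, trace=trace,
                    permutation_threshold=permutation_threshold,
                    criterion=criterion)


def _marginal_assoc_order(y, C):
    """Columns of C ranked by single-term association (strongest first)."""
    yc = y - y.mean()
    Cc = C - C.mean(axis=0)
    ss = np.einsum("ij,ij->j", Cc, Cc)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = (Cc.T @ yc)**2 / (ss * float(yc @ yc))
    r2 = np.where(ss > 1e-12, r2, -np.inf)
    return np.argsort(-r2), r2


def _screen_product_pairs(y, G, cap):
    """Top product terms x_i * x_j by marginal association, via matmuls.

    cov(y, x_i x_j) and var(x_i x_j) are assembled from G' diag(y) G,
    G'G and (G^2)'(G^2) without materialising all p(p-1)/2 products.
    """
    n, m = G.shape
    yc = y - y.mean()
    S = (G * yc[:, None]).T @ G / n          # cov with product (mean(y)=0 part)
    M = G.T @ G / n                          # mean of products
    Q = (G**2).T @ (G**2) / n
    varp = np.maximum(Q - M**2, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = S**2 / varp
    score[varp <= 1e-12] = -np.inf
    iu = np.triu_indices(m, k=1)
    flat = score[iu]
    k = min(cap, np.sum(np.isfinite(flat)))
    top = np.argpartition(-flat, k - 1)[:k] if k > 0 else np.array([], int)
    return [(int(iu[0][t]), int(iu[1][t])) for t in top]


def spaeml_fit(
    geno: GenotypeMatrix,
    pheno: np.ndarray,
    candidate_cap: int = 50,
    max_terms: int = 15,
    ebic_gamma: float = 1.0,
) -> QtlModel:
    """Stepwise additive + two-way epistatic model selection.

    The candidate pool holds the top ``candidate_cap`` single SNPs by
    marginal association, all pairwise products among them, and the top
    ``candidate_cap`` product terms from a genome-wide marginal screen of
    products (so pure interactions with no marginal signal are reachable).
    Terms enter/leave by extended BIC:
    EBIC = n log(RSS/n) + k log n + 2 gamma k log P, with P the pool size.
    """
    if candidate_cap < 2:
        raise ValueError("candidate_cap must be >= 2")
    y = np.asarray(pheno, dtype=float).ravel()
    G = geno.float_codes(impute=True)
    n, m = G.shape
    if candidate_cap > m:
        warnings.warn("candidate_cap exceeds SNP count; clamped", stacklevel=2)
        candidate_cap = m
    order, _ = _marginal_assoc_order(y, G)
    singles = [int(j) for j in order[:candidate_cap]]
    pool_keys = [("add", j) for j in singles]
    pool_keys += [("epi", i, j) for i, j in combinations(sorted(singles), 2)]
    for i, j in _screen_product_pairs(y, G, candidate_cap):
        key = ("epi", min(i, j), max(i, j))
        if key not in pool_keys:
            pool_keys.append(key)
    cols = []
    keys = []
    for key in pool_keys:
        c = G[:, key[1]] if key[0] == "add" else G[:, key[1]] * G[:, key[2]]
        if np.ptp(c) > 0:
            cols.append(c)
            keys.append(key)
    C = np.column_stack(cols) if cols else np.empty((n, 0))
    P = max(C.shape[1], 1)
    logn = np.log(n)
    logP = np.log(P)

    def ebic(rss, k):
        return n * np.log(max(rss, 1e-300) / n) + k * logn \
            + 2.0 * ebic_gamma * k * logP

    model: list[int] = []   # indices into keys/C
    trace = []
    X = np.ones((n, 1))
    Q, _ = np.linalg.qr(X)
    resid = y - Q @ (Q.T @ y)
    rss = float(resid @ resid)
    cur = ebic(rss, 1)
    while len(model) < max_terms:
        Cp = C - Q @ (Q.T @ C)
        ssc = np.einsum("ij,ij->j", Cp, Cp)
        ry = y - Q @ (Q.T @ y)
        with np.errstate(divide="ignore", invalid="ignore"):
            gain = (Cp.T @ ry)**2 / ssc
        gain = np.where(ssc > 1e-10 * np.maximum(
            np.einsum("ij,ij->j", C, C), 1e-30), gain, -np.inf)
        gain[model] = -np.inf
        j = int(np.argmax(gain))
        if not np.isfinite(gain[j]):
            break
        new_rss = max(float(ry @ ry) - gain[j], 0.0)
        new_score = ebic(new_rss, len(model) + 2)
        trace.append({"step": len(trace), "action": "try-add",
                      "term": keys[j], "score": float(new_score),
                      "current": float(cur)})
        if new_score >= cur - 1e-9:
            break
        model.append(j)
        X = np.column_stack([np.ones(n), C[:, model]])
        Q, _ = np.linalg.qr(X)
        cur = new_score
        # backward: drop any term whose removal improves the criterion
        improved = True
        while improved and len(model) > 1:
            improved = False
            best_drop, best_score = None, cur
            for t in range(len(model)):
                sub = model[:t] + model[t + 1:]
                Xs = np.column_stack([np.ones(n), C[:, sub]])
                beta, *_ = np.linalg.lstsq(Xs, y, rcond=None)
                rss_s = float(np.sum((y - Xs @ beta)**2))
                sc = ebic(rss_s, len(sub) + 1)
                if sc < best_score - 1e-9:
                    best_drop, best_score = t, sc
            if best_drop is not None:
                dropped = model.pop(best_drop)
                trace.append({"step": len(trace), "action": "drop",
                              "term": keys[dropped], "score": float(best_score)})
                X = np.column_stack([np.ones(n), C[:, model]])
                Q, _ = np.linalg.qr(X)
                cur = best_score
                improved = True
    return _build_model(geno, y, [keys[t] for t in model], trace=trace,
                        criterion=f"ebic(gamma={ebic_gamma})")
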