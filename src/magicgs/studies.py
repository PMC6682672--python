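"""Self-contained simulation studies over the full pipeline.

Each study regenerates its inputs from a seed, runs the relevant method,
and returns summary numbers. They are shared by the test suite, the
acceptance script and the analysis drivers so every report comes from the
same computation. Default problem sizes are the package's standard study
conditions: 305 RILs genotyped on 11 chromosomes x 100 SNPs (100 cM each),
traits at narrow-sense heritability 0.45 on a days-like scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import simulate
from .gio import GenotypeMatrix, minor_allele_freq
from .gs_models import RkhsConfig
from .gwas import bonferroni_threshold, mlmm_scan
from .harness import HarnessConfig, coincidence_index, run_comparison, \
    cross_environment_predict, summarize
from .mixed_model import marker_h2, reml_fit
from .epistasis import spaeml_fit
from .simulate import TraitArchitecture, simulate_magic_panel, \
    simulate_phenotypes

# shortened Gibbs chain used inside repeated comparison studies; single
# model fits default to the full RkhsConfig chain (1,000 / 2,500)
STUDY_RKHS = RkhsConfig(burn_in=500, iterations=1500)


def _spawn(seed: int | None, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def _panel(seed, n_rils=305, n_snps_per_chr=100, n_chr=11) -> GenotypeMatrix:
    return simulate_magic_panel(n_rils=n_rils, n_snps_per_chr=n_snps_per_chr,
                                n_chr=n_chr, seed=seed)


def solver_oracle(seed: int | None = None) -> dict:
    """BLUP identities on a 50 x 200 simulated panel.

    Returns the maximum deviation of (a) fixed-ridge BLUP marker effects
    from the closed-form ridge solution and (b) RRBLUP-form versus
    GBLUP-form genomic values at the same variance ratio.
    """
    s1, s2 = _spawn(seed, 2)
    geno = _panel(s1, n_rils=50, n_snps_per_chr=50, n_chr=4)
    z = geno.float_codes(impute=True)[:, :200]
    z = z - z.mean(axis=0)
    rng = np.random.default_rng(s2)
    y = z @ rng.normal(0, 0.2, z.shape[1]) + rng.normal(0, 1, 50)
    lam = 2.5
    fit = reml_fit(y, Z=z, lambda_=lam)
    n = len(y)
    x = np.ones((n, 1))
    vinv = np.linalg.inv(z @ z.T + lam * np.eye(n))
    beta = np.linalg.solve(x.T @ vinv @ x, x.T @ vinv @ y)
    u_ref = z.T @ vinv @ (y - x @ beta)
    blup_diff = float(np.max(np.abs(fit.u - u_ref)))
    fit_rr = reml_fit(y, Z=z)
    fit_gb = reml_fit(y, K=z @ z.T, lambda_=fit_rr.lambda_)
    gebv_diff = float(np.max(np.abs(z @ fit_rr.u - fit_gb.g)))
    return {"ridge_blup_max_diff": blup_diff, "gblup_gebv_max_diff": gebv_diff}


def h2_recovery(seed: int | None = None, n_reps: int = 30,
                target_h2: float = 0.45) -> dict:
    """Genomic-heritability recovery on 305 RILs x 1,000 SNPs."""
    seeds = _spawn(seed, 3 * n_reps)
    vals = []
    for rep in range(n_reps):
        geno = _panel(seeds[3 * rep], n_snps_per_chr=100, n_chr=10)
        arch = simulate.polygenic_architecture(
            geno, seed=seeds[3 * rep + 1], n_qtl=100, target_h2=target_h2)
        pt = simulate_phenotypes(geno, arch, seed=seeds[3 * rep + 2])
        y = pt.values_for(geno.ril_ids, environment="env1")
        vals.append(marker_h2(geno, y))
    return {"mean_h2": float(np.mean(vals)), "values": vals,
            "target": target_h2, "n_reps": n_reps}


def mlmm_power(seed: int | None = None, n_reps: int = 50,
               qtn_pve: float = 0.25, window_cm: float = 5.0) -> dict:
    """Recovery rate of a single planted QTN as the first MLMM cofactor."""
    seeds = _spawn(seed, 3 * n_reps)
    hits = 0
    for rep in range(n_reps):
        geno = _panel(seeds[3 * rep])
        maf = minor_allele_freq(geno)
        rng = np.random.default_rng(seeds[3 * rep + 1])
        j = int(rng.choice(np.flatnonzero(maf >= 0.2)))
        arch = TraitArchitecture(additive_qtl=[(j, 5.0)], target_h2=qtn_pve)
        pt = simulate_phenotypes(geno, arch, seed=seeds[3 * rep + 2])
        y = pt.values_for(geno.ril_ids, environment="env1")
        res = mlmm_scan(geno, y, max_steps=3)
        if res.cofactors:
            first = list(geno.snp_ids).index(res.cofactors[0])
            if (geno.chrom[first] == geno.chrom[j]
                    and abs(geno.pos_cm[first] - geno.pos_cm[j]) <= window_cm):
                hits += 1
    return {"power": hits / n_reps, "n_reps": n_reps}


def mlmm_type1(seed: int | None = None, n_reps: int = 50,
               alpha: float = 0.05) -> dict:
    """Family-wise rate of any SNP passing Bonferroni on null traits."""
    seeds = _spawn(seed, 2 * n_reps)
    exceed = 0
    for rep in range(n_reps):
        geno = _panel(seeds[2 * rep])
        y = np.random.default_rng(seeds[2 * rep + 1]).normal(size=geno.n_rils)
        res = mlmm_scan(geno, y, max_steps=1)
        thr = bonferroni_threshold(alpha, geno.n_snps)
        exceed += bool(np.nanmin(res.step_pvalues[0]) < thr)
    return {"familywise_rate": exceed / n_reps, "n_reps": n_reps}


def _near(geno, a, b, window_cm):
    return (geno.chrom[a] == geno.chrom[b]
            and abs(geno.pos_cm[a] - geno.pos_cm[b]) <= window_cm)


def spaeml_classification(seed: int | None = None, n_reps: int = 30,
                          pve: float = 0.25, candidate_cap: int = 50,
                          window_cm: float = 5.0) -> dict:
    """Sensitivity to pure epistasis / specificity on pure-additive traits.

    Sensitivity: a trait driven by one interaction pair with no marginal
    effects; recovery means some selected epistatic term matches both
    members within ``window_cm``. Specificity: a trait driven by one
    additive QTL; success means no epistatic term is reported.
    """
    seeds = _spawn(seed, 2 * n_reps)
    sens = spec = 0
    for rep in range(n_reps):
        geno = _panel(seeds[2 * rep])
        x = geno.float_codes(impute=True)
        rng = np.random.default_rng(seeds[2 * rep + 1])
        ok = np.flatnonzero(minor_allele_freq(geno) >= 0.2)
        while True:
            i, j = rng.choice(ok, 2, replace=False)
            if geno.chrom[i] != geno.chrom[j]:
                break
        prod = x[:, i] * x[:, j]
        noise_sd = np.sqrt(np.var(prod) * (1 - pve) / pve)
        y_epi = prod + rng.normal(0, noise_sd, geno.n_rils)
        model = spaeml_fit(geno, y_epi, candidate_cap=candidate_cap)
        snp_pos = {s: t for t, s in enumerate(geno.snp_ids)}
        hit = False
        for _, row in model.epistatic_terms.iterrows():
            a, b = snp_pos[row["snp_i"]], snp_pos[row["snp_j"]]
            if (_near(geno, a, i, window_cm) and _near(geno, b, j, window_cm)) \
               or (_near(geno, a, j, window_cm) and _near(geno, b, i, window_cm)):
                hit = True
        sens += hit
        q = int(rng.choice(ok))
        xa = x[:, q]
        y_add = xa + rng.normal(
            0, np.sqrt(np.var(xa) * (1 - pve) / pve), geno.n_rils)
        model_a = spaeml_fit(geno, y_add, candidate_cap=candidate_cap)
        spec += len(model_a.epistatic_terms) == 0
    return {"sensitivity": sens / n_reps, "specificity": spec / n_reps,
            "n_reps": n_reps}


def model_comparison(seed: int | None = None, regime: str = "large",
                     n_replicates: int | None = None,
                     n_cycles: int | None = None) -> pd.DataFrame:
    """Five-method subbagging comparison over replicate simulated traits.

    Returns per-model mean accuracy/coincidence pooled over replicates
    (each replicate = fresh panel + architecture, shared-seed cycles).
    The moderate regime uses more replicates because the FxRRBLUP-vs-
    RRBLUP contrast there is a small difference between noisy means.
    """
    if regime == "large":
        factory = simulate.large_effect_architecture
        n_replicates = 3 if n_replicates is None else n_replicates
        n_cycles = 100 if n_cycles is None else n_cycles
    elif regime == "moderate":
        factory = simulate.moderate_effect_architecture
        n_replicates = 8 if n_replicates is None else n_replicates
        n_cycles = 50 if n_cycles is None else n_cycles
    else:
        raise ValueError(f"unknown regime {regime!r}")
    seeds = _spawn(seed, 4 * n_replicates)
    frames = []
    for rep in range(n_replicates):
        geno = _panel(seeds[4 * rep])
        arch = factory(geno, seed=seeds[4 * rep + 1])
        pt = simulate_phenotypes(geno, arch, seed=seeds[4 * rep + 2])
        y = pt.values_for(geno.ril_ids, environment="env1")
        cfg = HarnessConfig(n_cycles=n_cycles, seed=seeds[4 * rep + 3],
                            rkhs=STUDY_RKHS)
        res = run_comparison(geno, y, cfg)
        s = summarize(res).reset_index()
        s["replicate"] = rep
        frames.append(s)
    per_rep = pd.concat(frames, ignore_index=True)
    pooled = per_rep.groupby("model")[
        ["accuracy_mean", "coincidence_mean", "slope_mean"]].mean()
    pooled["n_replicates"] = n_replicates
    pooled["n_cycles"] = n_cycles
    return pooled


def coincidence_null(seed: int | None = None, n: int = 61,
                     n_reps: int = 1000, top_fraction: float = 0.2) -> dict:
    """Mean coincidence index of random predictions against a fixed trait."""
    rng = np.random.default_rng(_spawn(seed, 1)[0])
    y = rng.normal(size=n)
    vals = [coincidence_index(y, rng.normal(size=n), top_fraction)
            for _ in range(n_reps)]
    return {"mean": float(np.mean(vals)), "n": n, "n_reps": n_reps}


def photoperiod_cross_env(seed: int | None = None,
                          n_snps_per_chr: int = 50) -> dict:
    """Cross-environment prediction across two photoperiod blocks.

    Four environments (two long-day, two short-day) share a common QTL set
    but carry block-specific loci; returns the mean off-diagonal accuracy
    within and across photoperiod blocks for RRBLUP.
    """
    s1, s2, s3 = _spawn(seed, 3)
    geno = _panel(s1, n_snps_per_chr=n_snps_per_chr)
    arch = simulate.photoperiod_block_architecture(geno, seed=s2)
    envs = ["LD_FI", "LD_RI", "SD_FI", "SD_RI"]
    pt = simulate_phenotypes(geno, arch, seed=s3, env_names=envs)
    by_env = {e: pt.values_for(geno.ril_ids, environment=e) for e in envs}
    mat = cross_environment_predict(geno, by_env, within_env_cycles=5)
    blocks = {"LD_FI": "LD", "LD_RI": "LD", "SD_FI": "SD", "SD_RI": "SD"}
    within, across = [], []
    for a in envs:
        for b in envs:
            if a == b:
                continue
            (within if blocks[a] == blocks[b] else across).append(
                mat.loc[a, b])
    return {"within_photoperiod": float(np.mean(within)),
            "cross_photoperiod": float(np.mean(across)),
            "matrix": mat}
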