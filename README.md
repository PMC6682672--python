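# magicgs

Epistasis-aware QTL mapping and genomic-selection benchmarking for
multi-parent (MAGIC) recombinant-inbred populations, with a built-in
population simulator so every stage of the pipeline can be validated
against known truth.

## The problem

Breeders working with multi-parent advanced generation inter-cross (MAGIC)
panels — such as the eight-founder cowpea population of 305 F8 RILs — want
to know two things about a trait like flowering time: *what is its genetic
architecture* (how many loci, how large, and do they interact), and *which
selection strategy exploits that architecture best* (marker-assisted
selection on a few hits versus genome-wide prediction). `magicgs`
implements that whole workflow:

* **Simulator** — an 8-founder balanced-funnel intercross followed by
  single-seed-descent selfing, with meiosis under Haldane's map function
  (no interference). Traits combine additive QTL and two-way
  additive×additive epistatic QTL (products of −1/0/1 codes) at a target
  narrow-sense heritability, and true genetic values are emitted.
* **Mixed-model engine** — REML for y = Xβ + Zu + e (marker form) or
  y = Xβ + g + e with g ~ N(0, σ²ᵤK) (kinship form), by spectral
  decomposition and a 1-D profile search over λ = σ²ₑ/σ²ᵤ. Gives genomic
  heritability ĥ² = σ²_g/(σ²_g + σ²ₑ) and BLUPs.
* **MLMM GWAS** — forward/backward stepwise scan under a K-only model
  (VanRaden kinship, no structure covariates), variance components
  re-estimated each step, Bonferroni reporting threshold α/m.
* **QTL/epistasis mapping** — permutation-thresholded stepwise main-effect
  mapping, and a stepwise additive + two-way epistatic model search that
  classifies each locus as additive, epistatic or both.
* **Four GS models + MAS** — RRBLUP; FxRRBLUP (top GWAS hits moved into
  the fixed effects); Bayesian RKHS with a Gaussian kernel
  K_h = exp(−h·d²/mean d²) sampled by Gibbs (default h = 0.5, 1,000
  burn-in, 2,500 iterations); ε-insensitive SVR with an RBF kernel; and a
  MAS surrogate (OLS on the top-3 GWAS hits).
* **Evaluation harness** — 100 seeded 80/20 subbagging cycles with the
  split shared across methods; metrics are prediction accuracy (Pearson
  r), the coincidence index (overlap of observed and predicted top 20%)
  and prediction bias (intercept/slope of observed on predicted);
  plus environment-to-environment prediction matrices.

## Worked example

```python
import magicgs as mg

# 1. simulate a MAGIC panel: 8 founders, balanced funnel, F8 SSD
geno = mg.simulate_magic_panel(n_rils=305, n_snps_per_chr=100, n_chr=11, seed=42)

# 2. a flowering-time-like trait: 3 large QTL + polygenic tail + epistasis
arch = mg.simulate.large_effect_architecture(geno, seed=43)
pheno = mg.simulate_phenotypes(geno, arch, seed=44)
y = pheno.values_for(geno.ril_ids, environment="env1")
print(f"genomic h2 = {mg.marker_h2(geno, y):.2f}")

# 3. multi-locus mixed-model GWAS and the top associations
scan = mg.mlmm_scan(geno, y)
print(mg.top_k_associations(scan, 3).round(3).to_string(index=False))

# 4. five-method comparison on 20 shared-seed 80/20 subbagging cycles
cfg = mg.HarnessConfig(n_cycles=20, seed=45,
                       rkhs=mg.RkhsConfig(burn_in=500, iterations=1500))
res = mg.run_comparison(geno, y, cfg)
print(mg.summarize(res)[["accuracy_mean", "coincidence_mean"]].round(3))
```

Output:

```
genomic h2 = 0.32
      snp_id chrom  pos_cm   p  effect
chr5_031.781  chr5  31.781 0.0   5.668
chr8_018.933  chr8  18.933 0.0  -3.386
chr8_014.533  chr8  14.533 0.0   3.369
           accuracy_mean  coincidence_mean
model
fx_rrblup          0.568             0.308
mas                0.570             0.254
rkhs               0.280             0.358
rrblup             0.276             0.362
svr                0.283             0.327
```

The scan's top association is the planted large QTL (effect ≈ 5.7 days);
because a handful of large loci dominate this trait, the two methods that
model them explicitly as fixed effects — FxRRBLUP and MAS — clearly beat
the genome-wide shrinkage models, exactly the regime dependence the
harness is built to expose.

The numbered drivers under `analysis/` walk the full study: population
simulation, architecture mapping, GWAS + heritability, the five-method
comparison, and cross-photoperiod prediction. Each prints what it found
and writes tables under `results/`.

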