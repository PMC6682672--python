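# Methods

This note documents the models, algorithms and design choices behind
`magicgs`, in the order the pipeline runs them.

## Population simulator

**Breeding scheme.** Founders are fully homozygous inbreds. The default
eight founders are crossed in a balanced three-level funnel — four two-way
F1s from consecutive pairs, two four-way hybrids, one eight-way hybrid —
and each RIL descends from an independent realisation of that funnel
followed by `selfing_generations` rounds of single-seed descent (default
8, i.e. F8). The funnel order is a configuration parameter
(`MagicDesign.funnel_order`); the default pairs founders consecutively.
Residual heterozygosity halves per selfing generation, so F8 lines retain
about (1/2)⁸ ≈ 0.4% of the eight-way hybrid's heterozygosity — matching
what the tests assert empirically.

**Meiosis.** Crossovers follow Haldane's map function with no
interference. For marker data this Poisson model is exactly equivalent to
a Markov chain along each chromosome whose phase switches between
adjacent markers at probability r = (1 − e^(−2d/100))/2 for a gap of d cM;
the simulator samples that chain directly (vectorised over individuals),
with phase at the first marker of each chromosome uniform. Haldane was
chosen over Kosambi for its exact Markov factorisation; positive
interference would slightly reduce double-crossover rates but does not
affect any quantity the pipeline estimates from a single panel.

**Founder alleles.** Each SNP's minor-founder count is a uniform draw
from `maf_range` (default 0.1–0.5) rounded to the founder grid and
clipped so every SNP segregates; the minor-allele label is randomised.
SNP positions are uniform on 100 cM chromosomes; the default panel is 11
chromosomes × 100 SNPs = 1,100 markers on 305 RILs. This is a
down-scaled stand-in for an array of tens of thousands of markers: LD
between adjacent simulated markers (~1–2 cM apart) is comparable to a
dense array's local LD, while keeping a full multi-study run in minutes.

**Traits.** A trait is y = Σ aⱼxⱼ + Σ w_ij·(x_i·x_j) + env_shift + e with
x the −1/0/1 codes, i.e. additive QTL plus two-way additive×additive
epistasis. Noise is Gaussian with variance set per environment so the
realised genetic:total variance ratio equals `target_h2` (default 0.45,
inside the 0.2–0.5 band typical of field-measured phenology traits in
RIL panels); `target_h2 = 1` means zero noise. True genetic values are
returned alongside phenotypes for oracle checks. Environment masks
(`env_active_additive` / `env_active_epistatic`) let loci act in a subset
of environments, which the photoperiod-block architecture uses to give
long-day and short-day environments distinct plus shared loci.

**Canonical architectures.** Four factories define the study regimes; all
scale effects so the genetic SD is 5 "days" (a realistic flowering-time
scale — this matters for SVR, see below):

* *large-effect*: three large QTL at ~55/15/10% of genetic variance (the
  top one ≈ a quarter of phenotypic variance at h² = 0.45), a 40-QTL tail
  (15%) and two epistatic pairs (5%);
* *moderate-effect*: 18 QTL spread across chromosomes (≥20 cM apart,
  MAF ≥ 0.15) with shares 9/8/7% for the top three and the rest equal,
  plus three epistatic pairs (~3%). Spreading matters: unconstrained
  random placement frequently co-locates QTL, creating de-facto
  large-effect loci and contaminating the moderate regime;
* *polygenic*: 100–200 tiny additive QTL, no epistasis;
* *photoperiod-block*: four environments in two blocks sharing a common
  QTL set (~30% of genetic variance) with block-specific sets (~70%), and
  a +15-day shift for the long-day block.

## Genotype layer

Codes are −1/1 for homozygotes and 0 for heterozygotes (kept, not
dropped; they are <1% of calls in an F8 panel). Missing calls are
mean-imputed per SNP for kinship and all model matrices; the mapping
estimators that need discrete classes (the homozygous-class additive
effect) exclude them. MAF is min(p, 1−p) with p counted over allele
copies (hets contribute one of each). The relationship matrix is
VanRaden's K = WW′/(2Σp(1−p)) with W the codes centred by 2p−1.

For fully inbred lines this normalisation gives mean diag(K) ≈ 2 (there
are no heterozygotes to pull it to 1), so the genomic heritability is
reported on the observation scale as
ĥ² = σ̂²ᵤ·mean(diag K) / (σ̂²ᵤ·mean(diag K) + σ̂²ₑ). Without that factor
h² would be biased down by ~2× on RIL panels.

## REML engine

One eigendecomposition of K (or ZZ′) rotates the model to independent
coordinates; the restricted likelihood is then profiled to a function of
λ = σ²ₑ/σ²ᵤ alone and maximised by bounded Brent search on
log λ ∈ [−10, 10] (tolerance 1e−8). Non-PSD K gets one jitter of
1e−6·mean(diag). BLUPs come from the mixed-model equations at the
optimum; with a user-fixed λ the fit is exactly closed-form ridge
regression, which the tests verify to machine precision, and the marker
(RRBLUP) and kinship (GBLUP) forms give identical genomic values when
K = ZZ′.

## MLMM GWAS

The scan is a full multi-locus mixed model, not P3D: at every forward
step the K-only model is refit by REML with the current cofactors as
fixed effects, the data are whitened by (K + λ̂I)^(−1/2) via the stored
eigenbasis, and every remaining SNP is scored by a partial-F (Wald) test.
The most significant SNP joins the cofactors; the forward pass stops at
`max_steps` (default 10) or when the best new p exceeds 0.01
(pre-Bonferroni). Backward elimination then drops cofactors whose
conditional p exceeds the same retention threshold. Reporting
significance uses α/m (0.05/32,130 = 1.6e−06 for the reference
array-panel size). SNPs collinear with current cofactors are skipped with
a log notice. The 0.01 stop/retention rule is a design choice — the
original stepwise formulation specifies only the reporting threshold —
and the per-SNP, per-step p-value trail is kept so any other rule can be
applied post hoc.

## QTL and epistasis mapping

**PVE and additive effects.** PVE of a term is 100·R² from a
single-regressor OLS; the additive effect of a marker is half the
difference of its homozygous class means. Single-term PVEs of correlated
loci can sum past the joint-model R²; they are reported as-is.

**Stepwise main-QTL mapping.** Forward steps add the SNP with the
smallest partial-F p-value; the entry bar is the 5th percentile of the
null distribution of the genome-wide minimum p, obtained by permuting the
*current model's residuals* `n_permutations` times (default 1,000) and
rescanning. Backward pruning applies the same threshold to conditional
p-values. Residual-based permutation was chosen over raw-phenotype
shuffles so the null is conditional on already-selected loci.

**Additive + epistatic model search.** Candidate terms are (a) the top
`candidate_cap` (default 50) SNPs by marginal association, (b) all
pairwise code-products among them, and (c) the top `candidate_cap`
product terms from a *genome-wide* marginal screen of all p(p−1)/2
products — computed with three matrix products (G′diag(y)G, G′G,
(G²)′(G²)) so nothing is materialised. Screen (c) is what makes pure
interactions with no marginal effects reachable. Selection is stepwise by
extended BIC, EBIC = n·log(RSS/n) + k·log n + 2γ·k·log P with P the pool
size and γ = 1: with ~1,300 candidates and n ≈ 300, plain BIC's bar
(partial R² ≈ 1.9%) sits below the maximum of ~1,300 null scores
(R² ≈ 4–5%), so it admits spurious interactions at a high rate — the
known false-positive weakness of this model class at n ≈ 300. EBIC
restores specificity (~80% of pure-additive traits yield no interaction
term) while a 25%-PVE interaction is still found essentially always.
Retained SNPs are classified additive / epistatic / both. Two-way terms
only; three-way epistasis is out of scope.

## Prediction models

* **RRBLUP / FxRRBLUP** — marker-random-effect REML fit; FxRRBLUP moves
  k = 3 named QTNs (the top GWAS hits of the *training split*) into the
  fixed design and out of the random term. Three, not more, because
  unshrunk fixed effects add estimation variance; collinear fixed QTNs
  are dropped with a warning.
* **RKHS** — Bayesian kernel regression with K_h = exp(−h·d²/mean(d²)),
  h = 0.5. Scaling by the mean training squared distance makes h
  transferable across panels; cross-kernels for prediction reuse the
  training scale. The Gibbs sampler works in the kernel eigenbasis (the
  conditional of the random effect factorises into independent normals),
  with scaled-inverse-χ² priors, df = 5, scales putting each prior mode
  at Var(y)/2; defaults 1,000 burn-in / 2,500 iterations. GEBVs are
  posterior means. The kernel's scale parameter σ²ᵤ overlaps the
  intercept through the leading near-constant eigencomponent, so the
  realised genetic variance var(u) is tracked separately
  (`params["genetic_variance"]`); it, plus σ²ₑ, reconstructs Var(y)
  within ~20%.
* **SVR** — ε-insensitive support-vector regression, RBF kernel, with
  C = 1, ε = 0.1 and the median heuristic for the bandwidth
  (γ = 1/median d²). These common defaults are part of the study design:
  on day-scale traits they underfit relative to the mixed models, which
  is the regime in which the non-parametric model ranks last.
* **MAS** — OLS of the phenotype on the top-3 GWAS hits of the training
  split. The GWAS is re-run inside every cycle on the training split only
  (no validation leakage), enforced by the harness rather than left to
  callers.

## Evaluation harness

Each cycle draws one 80/20 split without replacement from a per-cycle
seed; the seed list is shared by all five methods, and the MLMM scan of
the training split is computed once and shared by FxRRBLUP and MAS.
Metrics per cycle: Pearson accuracy, coincidence index (top set size
⌈0.2n⌉, ties broken by line id; a constant prediction vector is an
error), and the intercept/slope of observed on predicted. Failed cycles
are recorded with their error, never dropped silently. The default study
is 100 cycles.

Cross-environment prediction trains on one environment's phenotypes over
all pairwise-complete lines and correlates predictions with each other
environment's phenotypes; the matrix diagonal holds within-environment
subbagged accuracy. Across-environment BLUPs (`environment_blups`) use a
two-way model with environments fixed and genotypes random, variance
components by balanced-ANOVA moments.

## Study sizes and what the simulations do (not) show

The formal studies (`magicgs.studies`, also driven by
`scripts/acceptance.py` and `tests/test_acceptance.py`) use panels of 305
RILs × 1,100 SNPs (1,000 for the heritability study), 30–50 replicates
for recovery/power/classification rates, and replicate traits for the
five-method comparison: 3 replicates × 100 cycles in the large-effect
regime and 8 replicates × 50 cycles in the moderate regime. The
moderate-regime contrast (FxRRBLUP vs RRBLUP) is a small difference
between noisy means — its replicate-to-replicate SD is ≈0.05 at n = 305 —
so it is assessed on the pooled mean over replicate architectures;
single traits can and do swing either way, which is itself a finding
about MAS/fixed-effect strategies at this sample size. Repeated
comparison studies shorten the RKHS chain to 500/1,500 (posterior-mean
GEBVs from independent chains correlate >0.99 on these panels, so the
shorter chain does not move mean accuracies at the reported precision).

The simulator emulates the design of a real MAGIC panel but not all of
its texture: no genotyping error or missingness by default, no selection
during population development, founder alleles exchangeable rather than
reflecting real ascertainment, and map positions uniform. Passing tests
therefore certify the estimators and the relative behaviour of the
methods under known architectures — not absolute accuracy values on any
particular real dataset.

## Numerical conventions

Ties in ranked outputs break deterministically (p, chromosome, position,
id; line id for top-20% sets). Collinearity is detected at relative
scale 1e−10 and collinear candidates are skipped (scans) or dropped with
a warning (fixed designs). All stochastic entry points take seeds;
studies derive child seeds from one master seed via `SeedSequence`.
Degenerate inputs (constant phenotype, monomorphic panels, all-missing
SNPs, empty splits, zero-distance kernels) raise `ValueError` with the
offending object named.
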