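"""MAGIC RIL population and trait simulator.

Emulates an eight-founder multi-parent advanced generation inter-cross
(MAGIC): fully homozygous founders are crossed through a balanced funnel
(four two-way F1s, two four-way hybrids, one eight-way hybrid), then each
line is selfed by single-seed descent (default eight generations, F8).

Meiosis follows Haldane's map function with no crossover interference: a
gamete's parental phase switches between adjacent markers at distance d cM
with probability r = (1 - exp(-2d/100)) / 2, which is the exact
marker-level consequence of a Poisson crossover process (one crossover per
Morgan on average). Phase at the first marker of each chromosome is
uniform, so a plain cumulative phase works across chromosome boundaries.

Traits are built from known additive QTL and two-way additive x additive
epistatic QTL (products of -1/0/1 codes), with Gaussian noise scaled to hit
a target narrow-sense heritability; true genetic values are emitted
alongside phenotypes so downstream estimators can be checked against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gio import GenotypeMatrix, PhenotypeTable


@dataclass
class FounderSet:
    """Fully homozygous founder haplotypes with their genetic map."""

    haplotypes: np.ndarray  # (n_founders, n_snps) alleles in {0, 1}
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos_cm: np.ndarray

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be 2-D (founders x SNPs)")
        nf = self.haplotypes.shape[0]
        if nf < 2 or (nf & (nf - 1)) != 0:
            raise ValueError("n_founders must be a power of 2 and >= 2")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("founder alleles must be 0/1 (homozygous lines)")
        self.pos_cm = np.asarray(self.pos_cm, dtype=float)
        self.chrom = np.asarray(self.chrom, dtype=object)

    @property
    def n_founders(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]


@dataclass
class MagicDesign:
    """Population design: funnel order, inbreeding depth, panel size."""

    n_rils: int = 305
    selfing_generations: int = 8
    funnel_order: tuple | None = None  # founder indices, paired consecutively
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_rils < 2:
            raise ValueError("n_rils must be >= 2")
        if self.selfing_generations < 1:
            raise ValueError("selfing_generations must be >= 1")


@dataclass
class TraitArchitecture:
    """True genetic architecture of a simulated trait.

    ``additive_qtl`` is a list of (snp_index, effect) pairs; the effect is
    half the difference between homozygous class means, in trait units.
    ``epistatic_pairs`` is a list of (snp_i, snp_j, effect) with the effect
    applied to the elementwise product of the two -1/0/1 codes.
    ``env_shift`` gives one additive offset per environment (e.g. the
    long-day vs short-day flowering delay); ``env_active_additive`` /
    ``env_active_epistatic`` optionally restrict which QTL (by list index)
    act in each environment, emulating photoperiod-specific loci.
    """

    additive_qtl: list = field(default_factory=list)
    epistatic_pairs: list = field(default_factory=list)
    target_h2: float = 0.45
    env_shift: tuple = (0.0,)
    env_active_additive: list | None = None
    env_active_epistatic: list | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.target_h2 <= 1.0):
            raise ValueError("target_h2 must be in (0, 1]")
        for _, eff in self.additive_qtl:
            if not np.isfinite(eff):
                raise ValueError("additive effects must be finite")
        for _, _, eff in self.epistatic_pairs:
            if not np.isfinite(eff):
                raise ValueError("epistatic effects must be finite")
        n_env = len(self.env_shift)
        for masks in (self.env_active_additive, self.env_active_epistatic):
            if masks is not None and len(masks) != n_env:
                raise ValueError("per-environment QTL masks must match env_shift")


def simulate_founders(
    n_founders: int = 8,
    n_snps_per_chr: int = 100,
    n_chr: int = 11,
    maf_range: tuple = (0.1, 0.5),
    seed: int | None = None,
    chrom_length_cm: float = 100.0,
) -> FounderSet:
    """Draw homozygous founder haplotypes with segregating SNPs.

    Each SNP's founder minor-allele count is the target frequency (uniform
    in ``maf_range``) rounded to the founder grid and clipped so every SNP
    segregates (at least one founder carries each allele).
    """
    if n_founders < 2:
        raise ValueError("n_founders must be >= 2")
    if n_snps_per_chr < 2:
        raise ValueError("n_snps_per_chr must be >= 2")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    rng = np.random.default_rng(seed)
    m = n_snps_per_chr * n_chr
    chrom = np.repeat([f"chr{i + 1}" for i in range(n_chr)], n_snps_per_chr)
    pos = np.concatenate(
        [np.sort(rng.uniform(0.0, chrom_length_cm, n_snps_per_chr))
         for _ in range(n_chr)]
    )
    u = rng.uniform(lo, hi, size=m)
    k = np.clip(np.rint(u * n_founders).astype(int), 1, n_founders // 2)
    hap = np.zeros((n_founders, m), dtype=np.int8)
    for j in range(m):
        carriers = rng.choice(n_founders, size=k[j], replace=False)
        hap[carriers, j] = 1
    # randomly swap which allele is minor so neither label is privileged
    flip = rng.random(m) < 0.5
    hap[:, flip] = 1 - hap[:, flip]
    snp_ids = np.array(
        [f"{c}_{p:07.3f}" for c, p in zip(chrom, pos)], dtype=object
    )
    # guarantee unique ids even for coincident positions
    if len(set(snp_ids)) != m:
        snp_ids = np.array([f"{s}_{j}" for j, s in enumerate(snp_ids)],
                           dtype=object)
    return FounderSet(haplotypes=hap, snp_ids=snp_ids, chrom=chrom, pos_cm=pos)


def _switch_probs(chrom: np.ndarray, pos_cm: np.ndarray) -> np.ndarray:
    """Per-marker phase-switch probabilities under Haldane's map function."""
    m = len(pos_cm)
    p = np.empty(m)
    p[0] = 0.5
    if m > 1:
        same = chrom[1:] == chrom[:-1]
        d = np.diff(pos_cm)
        if np.any(d[same] < 0):
            raise ValueError("negative cM gaps within a chromosome")
        r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
        p[1:] = np.where(same, r, 0.5)
    return p


def _gametes(h1: np.ndarray, h2: np.ndarray, p_switch: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """One meiotic gamete per individual (rows of h1/h2), vectorised."""
    s = rng.random(h1.shape) < p_switch
    phase = np.bitwise_and(np.cumsum(s, axis=1), 1)
    return np.where(phase == 0, h1, h2)


def intercross_and_ssd(founders: FounderSet, design: MagicDesign) -> GenotypeMatrix:
    """Run the funnel intercross and single-seed-descent selfing.

    Every RIL descends from an independent realisation of the balanced
    funnel, so recombination events are independent across lines. Returns
    -1/0/1 codes (residual heterozygosity decays as (1/2)^g during the g
    selfing generations).
    """
    nf = founders.n_founders
    order = tuple(design.funnel_order) if design.funnel_order is not None \
        else tuple(range(nf))
    if sorted(order) != list(range(nf)):
        raise ValueError("funnel_order must be a permutation of all founders")
    p_switch = _switch_probs(founders.chrom, founders.pos_cm)
    rng = np.random.default_rng(design.seed)
    n = design.n_rils
    f = founders.haplotypes
    # two-way F1s are deterministic for homozygous founders
    pops = [
        (np.broadcast_to(f[order[2 * i]], (n, founders.n_snps)).copy(),
         np.broadcast_to(f[order[2 * i + 1]], (n, founders.n_snps)).copy())
        for i in range(nf // 2)
    ]
    while len(pops) > 1:
        pops = [
            (_gametes(*pops[2 * i], p_switch, rng),
             _gametes(*pops[2 * i + 1], p_switch, rng))
            for i in range(len(pops) // 2)
        ]
    h1, h2 = pops[0]
    for _ in range(design.selfing_generations):
        h1, h2 = (_gametes(h1, h2, p_switch, rng),
                  _gametes(h1, h2, p_switch, rng))
    codes = (h1.astype(np.int8) + h2.astype(np.int8) - 1)
    width = len(str(n))
    ril_ids = np.array([f"RIL{i + 1:0{width}d}" for i in range(n)], dtype=object)
    return GenotypeMatrix(
        codes=codes, snp_ids=founders.snp_ids, ril_ids=ril_ids,
        chrom=founders.chrom, pos_cm=founders.pos_cm,
    )


def simulate_magic_panel(
    n_rils: int = 305,
    n_snps_per_chr: int = 100,
    n_chr: int = 11,
    n_founders: int = 8,
    maf_range: tuple = (0.1, 0.5),
    selfing_generations: int = 8,
    seed: int | None = None,
) -> GenotypeMatrix:
    """Convenience wrapper: founders + funnel + SSD in one call."""
    ss = np.random.SeedSequence(seed)
    s_found, s_cross = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    founders = simulate_founders(
        n_founders=n_founders, n_snps_per_chr=n_snps_per_chr, n_chr=n_chr,
        maf_range=maf_range, seed=s_found,
    )
    design = MagicDesign(n_rils=n_rils, selfing_generations=selfing_generations,
                         seed=s_cross)
    return intercross_and_ssd(founders, design)


def genetic_values(geno: GenotypeMatrix, arch: TraitArchitecture) -> np.ndarray:
    """True genetic values per environment, shape (n_rils, n_envs)."""
    x = geno.float_codes(impute=True)
    n_env = len(arch.env_shift)
    g = np.zeros((geno.n_rils, n_env))
    for e in range(n_env):
        add_idx = (range(len(arch.additive_qtl))
                   if arch.env_active_additive is None
                   else arch.env_active_additive[e])
        epi_idx = (range(len(arch.epistatic_pairs))
                   if arch.env_active_epistatic is None
                   else arch.env_active_epistatic[e])
        for t in add_idx:
            j, eff = arch.additive_qtl[t]
            g[:, e] += eff * x[:, j]
        for t in epi_idx:
            i, j, eff = arch.epistatic_pairs[t]
            g[:, e] += eff * x[:, i] * x[:, j]
    return g


def simulate_phenotypes(
    geno: GenotypeMatrix,
    arch: TraitArchitecture,
    seed: int | None = None,
    trait: str = "trait",
    env_names: list | None = None,
) -> PhenotypeTable:
    """Phenotypes = genetic value + environment shift + Gaussian noise.

    Noise variance is set per environment so that the realised genetic
    variance over total variance matches ``arch.target_h2``; with
    target_h2 = 1 the phenotype equals the genetic value plus the shift.
    """
    rng = np.random.default_rng(seed)
    g = genetic_values(geno, arch)
    n_env = g.shape[1]
    if env_names is None:
        env_names = [f"env{e + 1}" for e in range(n_env)]
    if len(env_names) != n_env:
        raise ValueError("env_names must match the number of environments")
    rows = []
    truth = []
    for e in range(n_env):
        ge = g[:, e]
        var_g = float(np.var(ge))
        if var_g <= 0:
            raise ValueError(
                f"zero genetic variance in environment {env_names[e]!r} "
                "(all QTL monomorphic?)"
            )
        h2 = arch.target_h2
        sigma_e = 0.0 if h2 >= 1.0 else np.sqrt(var_g * (1.0 - h2) / h2)
        y = ge + arch.env_shift[e] + rng.normal(0.0, sigma_e, size=len(ge))
        rows.append(pd.DataFrame({
            "ril_id": geno.ril_ids, "trait": trait,
            "environment": env_names[e], "value": y,
        }))
        truth.append(pd.DataFrame({
            "ril_id": geno.ril_ids, "environment": env_names[e],
            "genetic_value": ge,
        }))
    return PhenotypeTable(data=pd.concat(rows, ignore_index=True),
                          genetic_values=pd.concat(truth, ignore_index=True))


# ---------------------------------------------------------------------------
# canonical trait architectures used across the simulation studies


def _scaled_group(x: np.ndarray, idx: np.ndarray, raw: np.ndarray,
                  share: float) -> list:
    """Scale a group's raw effects so its genetic variance equals ``share``."""
    gv = x[:, idx] @ raw
    v = float(np.var(gv))
    if v <= 0:
        raise ValueError("degenerate QTL group (no variance)")
    s = np.sqrt(share / v)
    return [(int(j), float(b * s)) for j, b in zip(idx, raw)]


def _pick_qtl(geno: GenotypeMatrix, rng: np.random.Generator, k: int,
              exclude=()) -> np.ndarray:
    """Pick k well-segregating SNPs spread over the genome."""
    from .gio import minor_allele_freq

    maf = minor_allele_freq(geno)
    ok = np.flatnonzero(maf >= 0.1)
    ok = ok[~np.isin(ok, list(exclude))]
    return rng.choice(ok, size=k, replace=False)


def _rescale_architecture(arch: TraitArchitecture, geno: GenotypeMatrix,
                          genetic_sd: float) -> TraitArchitecture:
    """Scale all effects so the total genetic standard deviation (env 0) is
    ``genetic_sd`` trait units (days, for a flowering-time-like trait)."""
    gv = genetic_values(geno, arch)[:, 0]
    s = genetic_sd / float(np.std(gv))
    arch.additive_qtl = [(j, e * s) for j, e in arch.additive_qtl]
    arch.epistatic_pairs = [(i, j, e * s) for i, j, e in arch.epistatic_pairs]
    return arch


def _spread_qtl(geno: GenotypeMatrix, rng: np.random.Generator, k: int,
                min_maf: float = 0.15, min_gap_cm: float = 20.0) -> list:
    """Pick k QTL cycling over chromosomes, keeping them well separated."""
    from .gio import minor_allele_freq

    maf = minor_allele_freq(geno)
    chroms = list(dict.fromkeys(geno.chrom))
    qtl: list[int] = []
    ci = 0
    attempts = 0
    while len(qtl) < k and attempts < 10 * k:
        c = chroms[ci % len(chroms)]
        ci += 1
        attempts += 1
        on = np.flatnonzero((geno.chrom == c) & (maf >= min_maf))
        on = [j for j in on
              if all(geno.chrom[q] != c
                     or abs(geno.pos_cm[q] - geno.pos_cm[j]) > min_gap_cm
                     for q in qtl)]
        if on:
            qtl.append(int(rng.choice(on)))
    if len(qtl) < k:
        raise ValueError("panel too small to place the requested QTL")
    return qtl


def large_effect_architecture(geno: GenotypeMatrix, seed: int | None = None,
                              target_h2: float = 0.45,
                              genetic_sd: float = 5.0) -> TraitArchitecture:
    """Oligogenic trait: three large QTL over a small polygenic tail.

    Genetic-variance shares: the three large QTL carry ~55/15/10% (the top
    locus alone approaches a quarter of the phenotypic variance at
    h2 = 0.45, like the strongest long-day flowering QTL), a 40-QTL tail
    carries ~15%, and two epistatic pairs add ~5%. Effects are scaled so
    the genetic standard deviation is ``genetic_sd`` trait units.
    """
    rng = np.random.default_rng(seed)
    x = geno.float_codes(impute=True)
    big = _pick_qtl(geno, rng, 3)
    tail = _pick_qtl(geno, rng, 40, exclude=big)
    epi = _pick_qtl(geno, rng, 4, exclude=np.concatenate([big, tail]))
    additive = []
    for j, share in zip(big, (0.55, 0.15, 0.10)):
        additive += _scaled_group(x, np.array([j]), np.array([1.0]), share)
    additive += _scaled_group(x, tail, rng.normal(size=len(tail)), 0.15)
    pairs = []
    for (i, j), share in zip((epi[:2], epi[2:]), (0.025, 0.025)):
        prod = x[:, i] * x[:, j]
        v = float(np.var(prod))
        if v > 0:
            pairs.append((int(i), int(j), float(np.sqrt(share / v))))
    arch = TraitArchitecture(additive_qtl=additive, epistatic_pairs=pairs,
                             target_h2=target_h2)
    return _rescale_architecture(arch, geno, genetic_sd)


def moderate_effect_architecture(geno: GenotypeMatrix, seed: int | None = None,
                                 target_h2: float = 0.45,
                                 genetic_sd: float = 5.0) -> TraitArchitecture:
    """Trait controlled by moderate-effect loci only.

    Eighteen QTL spread across chromosomes (>=20 cM apart) share the
    genetic variance with a gently decaying profile (9/8/7% for the top
    three, the rest equal), so every locus sits in the "moderate" band of
    a few percent of phenotypic variance; three epistatic pairs add ~3%.
    This is the regime where moving top GWAS hits into the fixed effects
    should neither help nor hurt genome-wide prediction much.
    """
    rng = np.random.default_rng(seed)
    x = geno.float_codes(impute=True)
    n_qtl = 18
    qtl = _spread_qtl(geno, rng, n_qtl)
    rest = (1.0 - 0.24) / (n_qtl - 3)
    shares = [0.09, 0.08, 0.07] + [rest] * (n_qtl - 3)
    additive = []
    for j, share in zip(qtl, shares):
        sign = float(rng.choice([-1.0, 1.0]))
        additive += _scaled_group(x, np.array([j]), np.array([sign]), share)
    epi = _pick_qtl(geno, rng, 6, exclude=np.array(qtl))
    pairs = []
    for i, j in zip(epi[::2], epi[1::2]):
        prod = x[:, i] * x[:, j]
        v = float(np.var(prod))
        if v > 0:
            pairs.append((int(i), int(j), float(np.sqrt(0.033 / v))))
    arch = TraitArchitecture(additive_qtl=additive, epistatic_pairs=pairs,
                             target_h2=target_h2)
    return _rescale_architecture(arch, geno, genetic_sd)


def polygenic_architecture(geno: GenotypeMatrix, seed: int | None = None,
                           n_qtl: int = 200, target_h2: float = 0.45,
                           genetic_sd: float = 5.0) -> TraitArchitecture:
    """Many tiny additive QTL and no epistasis (the MAS-unfriendly regime)."""
    rng = np.random.default_rng(seed)
    x = geno.float_codes(impute=True)
    n_qtl = min(n_qtl, geno.n_snps)
    qtl = _pick_qtl(geno, rng, n_qtl)
    additive = _scaled_group(x, qtl, rng.normal(size=len(qtl)), 1.0)
    arch = TraitArchitecture(additive_qtl=additive, target_h2=target_h2)
    return _rescale_architecture(arch, geno, genetic_sd)


def photoperiod_block_architecture(geno: GenotypeMatrix,
                                   seed: int | None = None,
                                   target_h2: float = 0.45,
                                   genetic_sd: float = 5.0
                                   ) -> TraitArchitecture:
    """Four environments in two photoperiod blocks with block-specific QTL.

    Environments 1-2 (long day) share one QTL set, environments 3-4 (short
    day) another; a common set (~30% of genetic variance) acts everywhere,
    so genetic correlation is high within a block and modest across blocks.
    Long-day environments get a +15-day shift (later flowering).
    """
    rng = np.random.default_rng(seed)
    x = geno.float_codes(impute=True)
    common = _pick_qtl(geno, rng, 8)
    block_a = _pick_qtl(geno, rng, 8, exclude=common)
    block_b = _pick_qtl(geno, rng, 8,
                        exclude=np.concatenate([common, block_a]))
    additive = (_scaled_group(x, common, rng.normal(size=8), 0.30)
                + _scaled_group(x, block_a, rng.normal(size=8), 0.70)
                + _scaled_group(x, block_b, rng.normal(size=8), 0.70))
    idx_common = list(range(8))
    idx_a = list(range(8, 16))
    idx_b = list(range(16, 24))
    arch = TraitArchitecture(
        additive_qtl=additive,
        target_h2=target_h2,
        env_shift=(15.0, 14.0, 0.0, 0.0),
        env_active_additive=[idx_common + idx_a, idx_common + idx_a,
                             idx_common + idx_b, idx_common + idx_b],
    )
    return _rescale_architecture(arch, geno, genetic_sd)
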