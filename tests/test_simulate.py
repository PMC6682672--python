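"""Tests of the MAGIC population and trait simulator."""

import numpy as np
import pytest

import magicgs as mg
from magicgs.simulate import (
    MagicDesign,
    TraitArchitecture,
    intercross_and_ssd,
    simulate_founders,
    simulate_phenotypes,
)


class TestFounders:
    def test_founders_are_homozygous_and_segregating(self):
        f = simulate_founders(8, 100, 11, (0.1, 0.5), seed=1)
        assert f.haplotypes.shape == (8, 1100)
        assert set(np.unique(f.haplotypes)) <= {0, 1}
        counts = f.haplotypes.sum(axis=0)
        assert np.all((counts >= 1) & (counts <= 7))

    def test_two_founders_at_maf_half_always_split(self):
        f = simulate_founders(2, 10, 1, (0.5, 0.5), seed=7)
        assert np.all(f.haplotypes.sum(axis=0) == 1)

    def test_empirical_founder_maf_within_range_plus_discretisation(self):
        f = simulate_founders(8, 50, 2, (0.05, 0.5), seed=3)
        counts = f.haplotypes.sum(axis=0)
        maf = np.minimum(counts, 8 - counts) / 8.0
        assert np.all(maf >= 0.05 - 1 / 16)
        assert np.all(maf <= 0.5 + 1 / 16)

    @pytest.mark.parametrize("kwargs", [
        {"n_founders": 1},
        {"maf_range": (0.0, 0.5)},
        {"maf_range": (0.4, 0.2)},
        {"maf_range": (0.1, 0.6)},
        {"n_snps_per_chr": 1},
    ])
    def test_degenerate_inputs_error(self, kwargs):
        base = dict(n_founders=8, n_snps_per_chr=10, n_chr=1,
                    maf_range=(0.1, 0.5), seed=0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            simulate_founders(**base)


class TestIntercross:
    def test_codes_and_residual_heterozygosity_f8(self, panel305):
        assert set(np.unique(panel305.codes)) <= {-1, 0, 1}
        het = float((panel305.codes == 0).mean())
        assert het <= 0.01  # (1/2)^8 of the fully heterozygous hybrid

    def test_heterozygosity_halves_per_selfing_generation(self):
        f = simulate_founders(8, 40, 3, seed=5)
        hets = []
        for g in (2, 4, 6):
            het = np.mean([
                (intercross_and_ssd(
                    f, MagicDesign(n_rils=400, selfing_generations=g,
                                   seed=100 + g + rep)).codes == 0).mean()
                for rep in range(3)
            ])
            hets.append(het)
        # two extra selfing generations -> roughly a factor 4 decay
        assert hets[0] / hets[1] == pytest.approx(4.0, rel=0.5)
        assert hets[1] / hets[2] == pytest.approx(4.0, rel=0.6)

    def test_monomorphic_founder_snp_stays_monomorphic(self):
        f = simulate_founders(8, 20, 1, seed=6)
        f.haplotypes[:, 3] = 1
        geno = intercross_and_ssd(f, MagicDesign(n_rils=100, seed=7))
        assert np.all(geno.codes[:, 3] == 1)

    def test_recombinant_fraction_matches_gene_dropping_oracle(self):
        """Two loci 100 cM apart: the full simulator's recombinant fraction
        must match a minimal two-locus gene-dropping simulator of the same
        breeding scheme (funnel + SSD, Haldane r per meiosis)."""
        r = 0.5 * (1 - np.exp(-2.0))  # Haldane r for 100 cM

        def drop_gamete(rng, h1, h2):
            start = rng.integers(0, 2)
            swap = rng.random() < r
            a = h1[0] if start == 0 else h2[0]
            b_src = start ^ swap
            b = h1[1] if b_src == 0 else h2[1]
            return np.array([a, b])

        def oracle_ril(rng):
            # founders: locus pair haplotypes distinguishing all 8 founders
            founders = [(i, i) for i in range(8)]
            pops = [(np.array(founders[2 * i]), np.array(founders[2 * i + 1]))
                    for i in range(4)]
            while len(pops) > 1:
                pops = [(drop_gamete(rng, *pops[2 * i]),
                         drop_gamete(rng, *pops[2 * i + 1]))
                        for i in range(len(pops) // 2)]
            h1, h2 = pops[0]
            for _ in range(8):
                h1, h2 = drop_gamete(rng, h1, h2), drop_gamete(rng, h1, h2)
            return h1  # near homozygous; one haplotype suffices
        rng = np.random.default_rng(99)
        oracle = np.array([oracle_ril(rng) for _ in range(3000)])
        # alleles = founder parity at both loci (the funnel pairs an even
        # with an odd founder, so parity mixing measures recombination)
        frac_oracle = float(np.mean(oracle[:, 0] % 2 != oracle[:, 1] % 2))

        f = mg.FounderSet(
            haplotypes=np.array([[i % 2, i % 2] for i in range(8)],
                                dtype=np.int8),
            snp_ids=np.array(["a", "b"], dtype=object),
            chrom=np.array(["chr1", "chr1"], dtype=object),
            pos_cm=np.array([0.0, 100.0]),
        )
        geno = intercross_and_ssd(f, MagicDesign(n_rils=3000, seed=17))
        hom = np.all(geno.codes != 0, axis=1)
        codes = geno.codes[hom]
        frac_sim = float(np.mean(codes[:, 0] != codes[:, 1]))
        assert frac_sim == pytest.approx(frac_oracle, abs=0.04)
        assert frac_oracle > r  # funnel+SSD adds meioses beyond one

    def test_negative_map_gap_errors(self):
        f = simulate_founders(4, 5, 1, seed=2)
        f.pos_cm[2] = f.pos_cm[1] - 1.0
        with pytest.raises(ValueError, match="negative"):
            intercross_and_ssd(f, MagicDesign(n_rils=10, seed=0))

    def test_ld_decays_with_map_distance(self, panel305):
        x = panel305.float_codes(impute=True)
        chrom = panel305.chrom
        on_chr1 = np.flatnonzero(chrom == "chr1")
        c = np.corrcoef(x[:, on_chr1].T) ** 2
        d = np.abs(panel305.pos_cm[on_chr1][:, None]
                   - panel305.pos_cm[on_chr1][None, :])
        iu = np.triu_indices(len(on_chr1), k=1)
        near = c[iu][d[iu] < 10]
        far = c[iu][d[iu] > 50]
        assert near.mean() > far.mean()


class TestPhenotypes:
    def test_h2_one_is_noiseless(self, panel305):
        arch = TraitArchitecture(additive_qtl=[(0, 2.0), (60, -1.0)],
                                 target_h2=1.0, env_shift=(5.0,))
        pt = simulate_phenotypes(panel305, arch, seed=1)
        y = pt.values_for(panel305.ril_ids, environment="env1")
        g = pt.genetic_values["genetic_value"].to_numpy()
        np.testing.assert_allclose(y, g + 5.0)

    def test_additive_effect_seven_days_recovered(self, panel305):
        maf = mg.minor_allele_freq(panel305)
        j = int(np.argmax(maf))
        ests = []
        for rep in range(10):
            arch = TraitArchitecture(additive_qtl=[(j, 7.0)], target_h2=0.5)
            pt = simulate_phenotypes(panel305, arch, seed=50 + rep)
            y = pt.values_for(panel305.ril_ids, environment="env1")
            ests.append(mg.additive_effect(panel305.codes[:, j], y))
        assert np.mean(ests) == pytest.approx(7.0, abs=0.8)

    def test_realized_h2_tracks_target(self, panel305):
        ratios = []
        for rep in range(30):
            arch = mg.simulate.polygenic_architecture(
                panel305, seed=rep, n_qtl=80, target_h2=0.45)
            pt = simulate_phenotypes(panel305, arch, seed=1000 + rep)
            y = pt.values_for(panel305.ril_ids, environment="env1")
            g = pt.genetic_values["genetic_value"].to_numpy()
            ratios.append(np.var(g) / np.var(y))
        assert 0.40 <= np.mean(ratios) <= 0.50

    def test_no_epistasis_means_linear_in_codes(self, panel305):
        arch = mg.simulate.polygenic_architecture(panel305, seed=3, n_qtl=20,
                                                  target_h2=1.0)
        pt = simulate_phenotypes(panel305, arch, seed=4)
        y = pt.values_for(panel305.ril_ids, environment="env1")
        idx = [j for j, _ in arch.additive_qtl]
        X = np.column_stack([np.ones(panel305.n_rils),
                             panel305.float_codes(impute=True)[:, idx]])
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.max(np.abs(resid)) < 1e-8

    def test_monomorphic_qtl_errors(self, tiny_panel):
        geno = tiny_panel.subset()
        geno.codes[:, 0] = 1
        arch = TraitArchitecture(additive_qtl=[(0, 3.0)], target_h2=0.5)
        with pytest.raises(ValueError, match="genetic variance"):
            simulate_phenotypes(geno, arch, seed=0)

    def test_environment_masks_give_block_structure(self, panel305):
        arch = mg.simulate.photoperiod_block_architecture(panel305, seed=8,
                                                          target_h2=1.0)
        pt = simulate_phenotypes(panel305, arch, seed=9)
        g = pt.genetic_values.pivot(index="ril_id", columns="environment",
                                    values="genetic_value")
        within = g["env1"].corr(g["env2"])
        across = g["env1"].corr(g["env3"])
        assert within > 0.99  # identical active QTL within a block
        assert across < 0.8
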