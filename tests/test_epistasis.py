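"""Tests for PVE/additive-effect estimators and the two QTL mappers."""

import numpy as np
import pytest

import magicgs as mg
from magicgs.epistasis import additive_effect, pve, spaeml_fit, stepwise_main_qtl

from conftest import make_genotype


class TestPve:
    def test_perfect_fit_is_100(self, tiny_panel):
        x = tiny_panel.float_codes()[:, 0]
        assert pve(x, 3.0 * x + 1.0) == pytest.approx(100.0)

    def test_null_is_near_zero(self, panel305):
        x = panel305.float_codes()[:, 0]
        vals = [pve(x, np.random.default_rng(s).normal(size=305))
                for s in range(20)]
        assert np.mean(vals) <= 3.0

    def test_planted_28_percent_recovered(self, panel305):
        maf = mg.minor_allele_freq(panel305)
        j = int(np.argmax(maf))
        vals = []
        for rep in range(15):
            arch = mg.TraitArchitecture(additive_qtl=[(j, 1.0)],
                                        target_h2=0.28)
            pt = mg.simulate_phenotypes(panel305, arch, seed=900 + rep)
            y = pt.values_for(panel305.ril_ids, environment="env1")
            vals.append(pve(panel305.float_codes()[:, j], y))
        assert 22.0 <= np.mean(vals) <= 34.0

    def test_constant_regressor_errors(self):
        with pytest.raises(ValueError, match="constant"):
            pve(np.ones(10), np.arange(10.0))


class TestAdditiveEffect:
    def test_class_mean_arithmetic(self):
        x = np.array([1, 1, -1, -1, 0])
        y = np.array([10.0, 10.0, 4.0, 4.0, 99.0])  # het excluded
        assert additive_effect(x, y) == pytest.approx(3.0)

    def test_balanced_symmetric_phenotype_gives_zero(self):
        x = np.array([1, -1, 1, -1])
        y = np.array([2.0, 2.0, -2.0, -2.0])
        assert additive_effect(x, y) == pytest.approx(0.0)

    def test_missing_class_errors(self):
        with pytest.raises(ValueError, match="homozygous classes"):
            additive_effect(np.array([1, 1, 0]), np.arange(3.0))


class TestStepwiseMainQtl:
    def test_exact_linear_function_is_saturated(self, panel305):
        x = panel305.float_codes(impute=True)
        j = 37
        y = 2.5 * x[:, j]
        model = stepwise_main_qtl(panel305, y, n_permutations=100, seed=1)
        assert panel305.snp_ids[j] in set(model.additive_terms["snp_id"])
        assert model.additive_terms["pve"].max() == pytest.approx(100.0)

    def test_three_planted_qtl_mostly_recovered(self, panel305):
        maf = mg.minor_allele_freq(panel305)
        ok = np.flatnonzero(maf > 0.3)
        picks = [ok[10], ok[len(ok) // 2], ok[-10]]
        n_found = []
        for rep in range(5):
            # variance shares ~20/10/5% of phenotypic variance
            x = panel305.float_codes(impute=True)
            g = sum(np.sqrt(s / np.var(x[:, j])) * x[:, j]
                    for j, s in zip(picks, (0.20, 0.10, 0.05)))
            rng = np.random.default_rng(40 + rep)
            y = g + rng.normal(0, np.sqrt(0.65), panel305.n_rils)
            model = stepwise_main_qtl(panel305, y, n_permutations=200,
                                      seed=rep)
            found = 0
            for j in picks:
                d = np.abs(model.additive_terms["pos_cm"] - panel305.pos_cm[j])
                same = model.additive_terms["chrom"] == panel305.chrom[j]
                found += int((same & (d <= 5.0)).any())
            n_found.append(found)
        assert np.mean([f >= 2 for f in n_found]) >= 0.6

    def test_null_rarely_selects_anything(self, panel305):
        n_nonempty = 0
        for rep in range(8):
            y = np.random.default_rng(70 + rep).normal(size=305)
            model = stepwise_main_qtl(panel305, y, n_permutations=100,
                                      seed=rep)
            n_nonempty += len(model.additive_terms) > 0
        assert n_nonempty <= 3

    def test_more_permutations_tighten_entry_threshold(self, panel305):
        """The 5th-percentile null threshold is more stringent (smaller) in
        expectation when estimated from more permutations."""
        from magicgs.epistasis import _perm_min_p
        G = panel305.float_codes(impute=True)
        n = panel305.n_rils
        Q, _ = np.linalg.qr(np.ones((n, 1)))
        t_small, t_large = [], []
        for rep in range(10):
            y = np.random.default_rng(rep).normal(size=n)
            resid = y - Q @ (Q.T @ y)
            Cp = G - Q @ (Q.T @ G)
            ssc = np.einsum("ij,ij->j", Cp, Cp)
            for n_perm, store in ((100, t_small), (600, t_large)):
                rng = np.random.default_rng(1000 + rep)
                null = _perm_min_p(rng, n_perm, resid, Q, Cp, ssc, n - 2)
                store.append(np.percentile(null, 5))
        assert np.mean(t_large) < np.mean(t_small)

    def test_too_few_permutations_error(self, tiny_panel):
        with pytest.raises(ValueError, match="n_permutations"):
            stepwise_main_qtl(tiny_panel, np.arange(60.0), n_permutations=50)


class TestSpaeml:
    def test_pure_additive_classified_additive(self, panel305):
        x = panel305.float_codes(impute=True)
        j = 211
        rng = np.random.default_rng(3)
        y = x[:, j] + rng.normal(0, np.sqrt(np.var(x[:, j]) * 3), 305)
        model = spaeml_fit(panel305, y, candidate_cap=50)
        cls = model.snp_classification()
        assert cls.get(panel305.snp_ids[j]) == "additive"

    def test_pure_interaction_classified_epistatic(self, panel305):
        x = panel305.float_codes(impute=True)
        i, j = 30, 330  # different chromosomes
        prod = x[:, i] * x[:, j]
        rng = np.random.default_rng(4)
        y = prod + rng.normal(0, np.sqrt(np.var(prod) * 3), 305)
        model = spaeml_fit(panel305, y, candidate_cap=50)
        pairs = set(map(frozenset, zip(model.epistatic_terms["snp_i"],
                                       model.epistatic_terms["snp_j"])))
        assert frozenset((panel305.snp_ids[i], panel305.snp_ids[j])) in pairs

    def test_cap_clamped_with_warning(self, tiny_panel):
        y = np.random.default_rng(5).normal(size=60)
        with pytest.warns(UserWarning, match="clamped"):
            spaeml_fit(tiny_panel, y, candidate_cap=10_000)

    def test_interaction_free_data_matches_stepwise_support(self, panel305):
        """On additive-only traits the additive+epistatic search should find
        an additive model covering the stepwise mapper's support."""
        agree = 0
        for rep in range(5):
            arch = mg.simulate.polygenic_architecture(panel305, seed=rep,
                                                      n_qtl=3, target_h2=0.4)
            pt = mg.simulate_phenotypes(panel305, arch, seed=rep + 50)
            y = pt.values_for(panel305.ril_ids, environment="env1")
            sp = spaeml_fit(panel305, y, candidate_cap=50)
            st_ = stepwise_main_qtl(panel305, y, n_permutations=100, seed=rep)
            sp_add = set(sp.additive_terms["snp_id"])
            st_add = set(st_.additive_terms["snp_id"])
            share = len(sp_add & st_add) / max(len(st_add), 1)
            agree += share >= 0.5 and len(sp.epistatic_terms) == 0
        assert agree >= 4

    def test_model_csv_roundtrip(self, tmp_path, panel305):
        x = panel305.float_codes(impute=True)
        y = x[:, 5] + x[:, 200] * x[:, 400]
        model = spaeml_fit(panel305, y, candidate_cap=30)
        model.write_csv(tmp_path / "qtl.csv")
        import pandas as pd
        back = pd.read_csv(tmp_path / "qtl.csv")
        assert set(back["term_type"]) <= {"additive", "epistatic"}
        assert (back["pve"] <= 100).all()
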