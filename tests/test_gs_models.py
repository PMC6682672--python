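"""Tests for the four genomic-prediction models."""

import numpy as np
import pytest

import magicgs as mg
from magicgs.gs_models import (
    RkhsConfig,
    fit_rkhs,
    fit_rrblup,
    fit_svr,
    gaussian_kernel,
    predict,
)
from magicgs.mixed_model import reml_fit


@pytest.fixture(scope="module")
def split_data(panel305, oligogenic_trait):
    _, _, y = oligogenic_trait
    tr, va = mg.subbag_split(panel305.ril_ids, 0.8, seed=42)
    pos = {r: i for i, r in enumerate(panel305.ril_ids)}
    tr_i = np.array([pos[r] for r in tr])
    va_i = np.array([pos[r] for r in va])
    return (panel305.subset(rils=tr_i), y[tr_i],
            panel305.subset(rils=va_i), y[va_i])


class TestRrblup:
    def test_no_fixed_qtns_nests_plain_rrblup(self, split_data):
        g_tr, y_tr, g_va, _ = split_data
        f0 = fit_rrblup(g_tr, y_tr)
        f1 = fit_rrblup(g_tr, y_tr, fixed_qtns=[])
        np.testing.assert_allclose(predict(f0, g_va), predict(f1, g_va),
                                   atol=1e-10)

    def test_gblup_refit_gives_identical_gebvs(self, split_data):
        g_tr, y_tr, _, _ = split_data
        fit = fit_rrblup(g_tr, y_tr)
        z = g_tr.float_codes(impute=True) - fit.params["z_means"]
        gb = reml_fit(y_tr, K=z @ z.T, lambda_=fit.params["lambda"])
        np.testing.assert_allclose(z @ fit.params["u"], gb.g, atol=1e-6)

    def test_predict_on_train_equals_fitted_values(self, split_data):
        g_tr, y_tr, _, _ = split_data
        fit = fit_rrblup(g_tr, y_tr)
        pred = predict(fit, g_tr)
        np.testing.assert_allclose(pred, fit.params["fitted"], atol=1e-8)

    def test_collinear_fixed_qtn_dropped_with_warning(self, split_data):
        g_tr, y_tr, g_va, _ = split_data
        geno = g_tr.subset()
        geno.codes[:, 1] = geno.codes[:, 0]
        with pytest.warns(UserWarning, match="collinear"):
            fit = fit_rrblup(geno, y_tr, fixed_qtns=[geno.snp_ids[0],
                                                     geno.snp_ids[1]])
        assert len(fit.params["fixed_qtns"]) == 1

    def test_fixed_qtns_help_under_large_effect_architecture(
            self, panel305, oligogenic_trait):
        arch, _, y = oligogenic_trait
        big = panel305.snp_ids[arch.additive_qtl[0][0]]
        accs = {"fx": [], "rr": []}
        for seed in range(8):
            tr, va = mg.subbag_split(panel305.ril_ids, 0.8, seed=seed)
            pos = {r: i for i, r in enumerate(panel305.ril_ids)}
            ti = np.array([pos[r] for r in tr])
            vi = np.array([pos[r] for r in va])
            g_tr, g_va = panel305.subset(rils=ti), panel305.subset(rils=vi)
            fx = predict(fit_rrblup(g_tr, y[ti], fixed_qtns=[big]), g_va)
            rr = predict(fit_rrblup(g_tr, y[ti]), g_va)
            accs["fx"].append(np.corrcoef(fx, y[vi])[0, 1])
            accs["rr"].append(np.corrcoef(rr, y[vi])[0, 1])
        assert np.mean(accs["fx"]) > np.mean(accs["rr"])

    def test_unknown_fixed_qtn_errors(self, split_data):
        g_tr, y_tr, _, _ = split_data
        with pytest.raises(ValueError, match="not in the panel"):
            fit_rrblup(g_tr, y_tr, fixed_qtns=["no_such_snp"])


class TestGaussianKernel:
    def test_identical_individuals_have_unit_kernel(self):
        a = np.array([[1.0, -1.0, 0.0], [1.0, -1.0, 0.0], [-1.0, 1.0, 1.0]])
        k = gaussian_kernel(a, h=0.5)
        assert k[0, 1] == pytest.approx(1.0)
        assert np.all(np.diag(k) == 1.0)

    def test_h_to_zero_limit_is_all_ones(self):
        rng = np.random.default_rng(0)
        a = rng.choice([-1.0, 1.0], size=(6, 10))
        k = gaussian_kernel(a, h=1e-9)
        np.testing.assert_allclose(k, 1.0, atol=1e-6)

    def test_matches_brute_force_toy_oracle(self):
        rng = np.random.default_rng(1)
        a = rng.choice([-1.0, 0.0, 1.0], size=(4, 6))
        h = 0.7
        k = gaussian_kernel(a, h=h)
        d2 = np.array([[np.sum((a[i] - a[j]) ** 2) for j in range(4)]
                       for i in range(4)])
        scale = d2[~np.eye(4, dtype=bool)].mean()
        np.testing.assert_allclose(k, np.exp(-h * d2 / scale), atol=1e-12)

    def test_identical_rows_everywhere_error(self):
        a = np.ones((4, 5))
        with pytest.raises(ValueError, match="zero mean"):
            gaussian_kernel(a)

    def test_cross_kernel_requires_training_scale(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(5, 4)), rng.normal(size=(3, 4))
        with pytest.raises(ValueError, match="mean_sq_dist"):
            gaussian_kernel(a, b)


class TestRkhs:
    CFG = RkhsConfig(h=0.5, burn_in=200, iterations=700)

    def test_resubstitution_on_noiseless_trait(self, panel305):
        arch = mg.simulate.polygenic_architecture(panel305, seed=9, n_qtl=40,
                                                  target_h2=1.0)
        pt = mg.simulate_phenotypes(panel305, arch, seed=10)
        y = pt.values_for(panel305.ril_ids, environment="env1")
        fit = fit_rkhs(panel305, y, self.CFG, seed=0)
        assert np.corrcoef(fit.params["mu"] + fit.params["u"], y)[0, 1] > 0.9

    def test_posterior_variances_conserve_total_variance(self, split_data):
        g_tr, y_tr, _, _ = split_data
        fit = fit_rkhs(g_tr, y_tr, self.CFG, seed=1)
        total = fit.params["genetic_variance"] + fit.params["sigma2_e"]
        assert total == pytest.approx(np.var(y_tr), rel=0.2)

    def test_prediction_for_duplicated_training_line(self, split_data):
        g_tr, y_tr, _, _ = split_data
        fit = fit_rkhs(g_tr, y_tr, self.CFG, seed=2)
        pred = predict(fit, g_tr)
        gebv = fit.params["mu"] + fit.params["u"]
        assert np.corrcoef(pred, gebv)[0, 1] > 0.99

    def test_seed_swap_changes_draws_not_gebvs(self, split_data):
        g_tr, y_tr, _, _ = split_data
        cfg = RkhsConfig(burn_in=500, iterations=1500)
        u1 = fit_rkhs(g_tr, y_tr, cfg, seed=3).params["u"]
        u2 = fit_rkhs(g_tr, y_tr, cfg, seed=4).params["u"]
        assert not np.array_equal(u1, u2)
        assert np.corrcoef(u1, u2)[0, 1] > 0.99

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            RkhsConfig(h=0.0)
        with pytest.raises(ValueError):
            RkhsConfig(burn_in=100, iterations=100)


class TestSvr:
    def test_noiseless_single_snp_trait_learned(self, panel305):
        x = panel305.float_codes(impute=True)
        y = 4.0 * x[:, 12]
        fit = fit_svr(panel305, y)
        pred = predict(fit, panel305)
        assert np.corrcoef(pred, y)[0, 1] >= 0.95

    def test_deterministic_across_runs(self, split_data):
        g_tr, y_tr, g_va, _ = split_data
        p1 = predict(fit_svr(g_tr, y_tr, seed=5), g_va)
        p2 = predict(fit_svr(g_tr, y_tr, seed=6), g_va)
        np.testing.assert_array_equal(p1, p2)

    def test_needs_minimum_lines(self, panel305):
        small = panel305.subset(rils=np.arange(3))
        with pytest.raises(ValueError, match="at least 5"):
            fit_svr(small, np.arange(3.0))


class TestPredictContract:
    def test_all_four_models_produce_finite_validation_vectors(self,
                                                               split_data):
        g_tr, y_tr, g_va, _ = split_data
        fits = [
            fit_rrblup(g_tr, y_tr),
            fit_rrblup(g_tr, y_tr, fixed_qtns=[g_tr.snp_ids[0]]),
            fit_rkhs(g_tr, y_tr, RkhsConfig(burn_in=50, iterations=150),
                     seed=7),
            fit_svr(g_tr, y_tr),
        ]
        for fit in fits:
            pred = predict(fit, g_va)
            assert pred.shape == (g_va.n_rils,)
            assert np.all(np.isfinite(pred))

    def test_snp_mismatch_errors(self, split_data):
        g_tr, y_tr, g_va, _ = split_data
        fit = fit_rrblup(g_tr, y_tr)
        with pytest.raises(ValueError, match="SNP set"):
            predict(fit, g_va.subset(snps=np.arange(10)))
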