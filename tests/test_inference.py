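"""Gaussian latent-model inference against dense brute-force oracles."""

import numpy as np
import pytest
import scipy.stats as st
from scipy.integrate import quad

from fieldspatial.inference import (
    _Evaluator,
    fit,
    joint_precision,
    latent_posterior,
    log_marginal_post,
    predict_lines,
)
from fieldspatial.model import ModelSpec, assemble
from fieldspatial.priors import (
    FisherZGaussianPrior,
    InverseGammaVariancePrior,
    rho_to_z,
    z_to_rho,
)
from fieldspatial.spatial import FieldLayout

from conftest import make_phenotypes

THETA_BY_KIND = {"variance": 0.7, "rho": 0.3, "log_kappa": 0.5, "log_tau": 0.8}


def theta_for(model):
    return {h.name: THETA_BY_KIND[h.kind] for h in model.hypers}


def toy_model(rng, spatial="none", genetic="iid", n_lines=10):
    lay = FieldLayout.lattice(4, 5, trial_id="t1")
    phen = make_phenotypes(lay, n_lines, rng)
    return assemble(ModelSpec(spatial=spatial, genetic=genetic), phen, {"t1": lay})


class TestLatentPosteriorOracle:
    @pytest.mark.parametrize("spatial", ["none", "rowcol", "ar1xar1", "matern"])
    def test_matches_dense_bayesian_linear_model(self, rng, spatial):
        m = toy_model(rng, spatial=spatial)
        theta = theta_for(m)
        mu, sd = latent_posterior(m, m.y_default, theta)
        q, _, a = joint_precision(m, theta)
        a = a.toarray()
        q_post = q + a.T @ a / theta["var_e"]
        cov = np.linalg.inv(q_post)
        mu_oracle = cov @ a.T @ m.y_default / theta["var_e"]
        np.testing.assert_allclose(mu, mu_oracle, atol=1e-8)
        np.testing.assert_allclose(sd, np.sqrt(np.diag(cov)), atol=1e-8)

    def test_interpolation_limit_zero_noise(self, rng):
        # saturated matern model with vanishing noise reproduces the data
        m = toy_model(rng, spatial="matern")
        theta = theta_for(m) | {"var_e": 1e-12}
        mu, _ = latent_posterior(m, m.y_default, theta)
        a = joint_precision(m, theta)[2].toarray()
        np.testing.assert_allclose(a @ mu, m.y_default, atol=1e-4)

    def test_intercept_only_posterior_mean_near_ybar(self, rng):
        lay = FieldLayout.lattice(4, 5, trial_id="t1")
        phen = make_phenotypes(lay, 10, rng)
        m = assemble(ModelSpec(spatial="none", genetic="none"), phen, {"t1": lay})
        mu, _ = latent_posterior(m, m.y_default, {"var_e": 1.0})
        assert mu[0] == pytest.approx(m.y_default.mean(), abs=0.01)

    def test_missing_theta_rejected(self, rng):
        m = toy_model(rng)
        with pytest.raises(ValueError, match="missing"):
            latent_posterior(m, m.y_default, {"var_e": 1.0})


class TestLogMarginalPosteriorOracle:
    @pytest.mark.parametrize("spatial", ["none", "ar1xar1", "matern"])
    def test_differences_match_integrated_latent_field(self, rng, spatial):
        """Differences of log p(theta | y) equal the brute-force Gaussian
        marginal (latent field integrated out analytically)."""
        m = toy_model(rng, spatial=spatial)
        theta1 = theta_for(m)
        theta2 = {k: (v * 1.6 if k == "var_e" else v) for k, v in theta1.items()}

        def brute(theta):
            q, _, a = joint_precision(m, theta)
            a = a.toarray()
            v = a @ np.linalg.inv(q) @ a.T + theta["var_e"] * np.eye(m.n_obs)
            ll = st.multivariate_normal.logpdf(m.y_default, cov=v)
            lp = sum(
                h.logpdf(h.from_natural(theta[h.name])) for h in m.hypers
            )
            return ll + lp

        d_pkg = log_marginal_post(m, m.y_default, theta1) - log_marginal_post(
            m, m.y_default, theta2
        )
        d_oracle = brute(theta1) - brute(theta2)
        assert d_pkg == pytest.approx(d_oracle, abs=1e-6)

    def test_nonfinite_theta_raises_with_context(self, rng):
        m = toy_model(rng)
        with pytest.raises(Exception, match="positive"):
            log_marginal_post(m, m.y_default, {"var_e": -1.0, "var_n": 0.5})


class TestPriors:
    def test_inverse_gamma_density_integrates_to_one(self):
        prior = InverseGammaVariancePrior()
        val, err = quad(
            lambda v: np.exp(prior.logpdf_natural(v)), 0, np.inf, limit=200
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_rho_transform_round_trip(self):
        for rho in (-0.95, -0.3, 0.0, 0.5, 0.99):
            assert z_to_rho(rho_to_z(rho)) == pytest.approx(rho, abs=1e-12)
        assert rho_to_z(0.0) == 0.0

    @pytest.mark.parametrize("rho", [1.0, -1.0, 2.0])
    def test_rho_transform_domain(self, rho):
        with pytest.raises(ValueError):
            rho_to_z(rho)

    def test_rho_prior_percentiles_near_015(self):
        prior = FisherZGaussianPrior(sd=0.15)
        assert prior.rho_quantile(0.975) == pytest.approx(0.15, abs=0.005)
        assert prior.rho_quantile(0.025) == pytest.approx(-0.15, abs=0.005)

    def test_rho_prior_pushforward_matches_sampling(self, rng):
        z = rng.normal(0.0, 0.15, size=100_000)
        rho = np.tanh(z / 2.0)
        # CDF of rho = tanh(Z/2): P(rho <= r) = Phi(2 atanh(r) / 0.15)
        stat = st.kstest(rho, lambda r: st.norm.cdf(2.0 * np.arctanh(r) / 0.15)).statistic
        assert stat < 0.02


class TestFit:
    def test_grid_and_eb_agree_on_toy_model(self, rng):
        m = toy_model(rng, spatial="none")
        f_eb = fit(m, strategy="eb")
        f_grid = fit(m, strategy="grid")
        diff = np.abs(f_eb.latent_mean - f_grid.latent_mean)
        assert (diff / np.maximum(f_grid.latent_sd, 1e-9)).max() < 0.02

    def test_ccd_runs_above_four_dims(self, rng):
        m = toy_model(rng, spatial="ar1xar1")  # 5 hyperparameters
        f = fit(m)
        assert f.strategy == "ccd"
        assert len(f.weights) == 2 * 5 + 1
        assert f.weights.sum() == pytest.approx(1.0)

    def test_residual_variance_interval_calibration(self, rng):
        """95% intervals for sigma2_e cover the truth at a frequency
        consistent with nominal coverage (iid Gaussian data, 20 seeds)."""
        lay = FieldLayout.lattice(25, 40, row_spacing=1.0, col_spacing=1.0, trial_id="t1")
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            phen = make_phenotypes(lay, n_lines=1000, rng=r)
            phen["phenotype"] = r.normal(0.3, 1.0, size=1000)
            m = assemble(ModelSpec(spatial="none", genetic="none"), phen, {"t1": lay})
            f = fit(m, strategy="eb")
            lo, hi = f.hyper_interval("var_e")
            hits += lo <= 1.0 <= hi
        assert 0.85 * 20 <= hits <= 20

    def test_shrinkage_on_pure_noise(self, rng):
        m = toy_model(rng, spatial="none")  # phenotype is pure noise
        f = fit(m, strategy="eb")
        assert f.theta_mode["var_n"] < 0.1
        assert np.abs(f.block_mean("genetic_iid")).max() < 0.2

    def test_nonconvergence_raises(self, rng):
        m = toy_model(rng, spatial="none")
        with pytest.raises(RuntimeError, match="converge"):
            fit(m, strategy="eb", max_iter=1)

    def test_deterministic_given_inputs(self, rng):
        m = toy_model(rng, spatial="rowcol")
        f1 = fit(m, strategy="eb")
        f2 = fit(m, strategy="eb")
        np.testing.assert_array_equal(f1.latent_mean, f2.latent_mean)
        np.testing.assert_array_equal(f1.theta_mode_unc, f2.theta_mode_unc)


class TestPrediction:
    @pytest.fixture
    def marker_fit(self, rng):
        from fieldspatial.genomics import polymorphic_mask, vanraden_grm

        n_lines, p = 15, 40
        q = rng.uniform(0.2, 0.8, p)
        z_raw = rng.binomial(2, q, size=(n_lines, p)).astype(float)
        z_raw = z_raw[:, polymorphic_mask(z_raw)]
        ids = np.array([f"L{i}" for i in range(n_lines)])
        geno = vanraden_grm(z_raw, ids).compressed(8)
        lay = FieldLayout.lattice(5, 6, trial_id="t1")
        phen = make_phenotypes(lay, n_lines, rng)
        m = assemble(ModelSpec(spatial="none", genetic="markers"), phen, {"t1": lay}, geno)
        return fit(m, strategy="eb"), geno, ids

    def test_zero_row_predicts_zero(self, marker_fit):
        f, geno, _ = marker_fit
        mean, sd = predict_lines(f, np.zeros((1, geno.p_star)))
        assert mean[0] == pytest.approx(0.0)
        assert sd[0] == pytest.approx(0.0, abs=1e-8)

    def test_training_row_matches_fitted_effect(self, marker_fit):
        f, geno, ids = marker_fit
        mean, _ = predict_lines(f, geno.z_star[3:4])
        bv_mean, _ = f.breeding_values(ids[3:4])
        assert mean[0] == pytest.approx(bv_mean[0], abs=1e-10)

    def test_column_mismatch_rejected(self, marker_fit):
        f, geno, _ = marker_fit
        with pytest.raises(ValueError, match="width"):
            predict_lines(f, np.zeros((1, geno.p_star + 2)))

    def test_prediction_positively_correlated_with_truth(self, rng):
        """Marker predictions of unphenotyped lines track true breeding
        values when the trait is marker-determined."""
        from fieldspatial.genomics import polymorphic_mask, vanraden_grm

        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            q = r.uniform(0.2, 0.8, 80)
            z_all = r.binomial(2, q, size=(60, 80)).astype(float)
            keep = polymorphic_mask(z_all[:40])
            effects = r.normal(size=keep.sum()) * 0.2
            g_all = (z_all[:, keep] - z_all[:40, keep].mean(axis=0)) @ effects
            ids = np.array([f"L{i}" for i in range(40)])
            geno = vanraden_grm(z_all[:40, keep], ids).compressed(20)
            lay = FieldLayout.lattice(8, 5, trial_id="t1")
            phen = make_phenotypes(lay, 40, r)
            lookup = {f"L{i}": g_all[i] for i in range(40)}
            phen["phenotype"] = phen["line_id"].map(lookup) + r.normal(0, 0.5, 40)
            m = assemble(
                ModelSpec(spatial="none", genetic="markers"), phen, {"t1": lay}, geno
            )
            f = fit(m, strategy="eb")
            pred, _ = predict_lines(f, geno.project(z_all[40:, keep]))
            hits += np.corrcoef(pred, g_all[40:])[0, 1] > 0
        assert hits >= 9
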