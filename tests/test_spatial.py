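"""Spatial covariance builders: Matern, AR1 x AR1, Nelder geometry."""

import numpy as np
import pytest
from scipy.linalg import cholesky

from fieldspatial.spatial import (
    AR1Params,
    FieldLayout,
    MaternParams,
    NelderDesign,
    ar1_cov,
    ar1_corr_precision,
    ar1_precision,
    ar1_range,
    ar1xar1_cov,
    ar1xar1_precision,
    chol_psd,
    kappa_from_range,
    matern_correlation,
    matern_cov,
    nelder_layout,
    range_from_kappa,
    sample_field,
    sigma2_from_spde,
    tau_from_sigma2,
)


class TestMaternParameters:
    @pytest.mark.parametrize(
        "range_, nu, expected",
        [(2.0, 0.5, 1.0), (10.0, 1.0, np.sqrt(8.0) / 10.0)],
    )
    def test_kappa_from_range(self, range_, nu, expected):
        assert kappa_from_range(range_, nu) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("range_, nu", [(3.7, 1.0), (0.4, 0.5), (25.0, 2.0)])
    def test_range_kappa_round_trip(self, range_, nu):
        assert range_from_kappa(kappa_from_range(range_, nu), nu) == pytest.approx(range_)

    def test_spde_variance_link_unit_case(self):
        # Gamma(1) / (Gamma(2) * 4 pi) = 1 / (4 pi)
        assert sigma2_from_spde(1.0, 1.0, nu=1.0) == pytest.approx(1.0 / (4.0 * np.pi))

    def test_spde_variance_quarters_when_tau_doubles(self):
        assert sigma2_from_spde(0.7, 2.0) == pytest.approx(sigma2_from_spde(0.7, 1.0) / 4.0)

    @pytest.mark.parametrize("kappa, tau", [(0.3, 1.0), (2.0, 0.05)])
    def test_tau_sigma2_round_trip(self, kappa, tau):
        assert tau_from_sigma2(sigma2_from_spde(kappa, tau), kappa) == pytest.approx(tau)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            kappa_from_range(bad)
        with pytest.raises(ValueError):
            sigma2_from_spde(bad, 1.0)


class TestMaternCovariance:
    def test_zero_distance_gives_marginal_variance(self):
        c = matern_cov(np.array([[0.0, 0.0], [3.0, 4.0]]), MaternParams(sigma2=2.5))
        assert c[0, 0] == pytest.approx(2.5)
        assert c[1, 1] == pytest.approx(2.5)

    def test_correlation_near_point_one_at_the_range(self):
        # the range convention: correlation ~0.1 at distance rho (0.14 for nu=1)
        corr = matern_correlation(np.array([10.0]), kappa_from_range(10.0, 1.0), 1.0)
        assert corr[0] == pytest.approx(0.13966747, abs=1e-6)
        assert 0.05 < corr[0] < 0.2

    def test_nu_half_equals_exponential_covariance(self):
        d = np.linspace(0.0, 30.0, 200)
        kappa = 2.0 / 7.0  # range 7, nu = 1/2
        got = matern_correlation(d, kappa, nu=0.5)
        np.testing.assert_allclose(got, np.exp(-kappa * d), atol=1e-10)

    def test_symmetric_positive_definite(self, rng):
        coords = rng.uniform(0, 20, size=(40, 2))
        c = matern_cov(coords, MaternParams(sigma2=1.3, range_=6.0))
        np.testing.assert_allclose(c, c.T)
        chol_psd(c)  # must not raise

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            matern_cov(np.array([[0.0, np.inf]]), MaternParams())


class TestAR1:
    def test_rho_zero_is_scaled_identity(self):
        q = ar1_precision(4, 0.0, sigma2_innov=2.0).toarray()
        np.testing.assert_allclose(q, np.eye(4) / 2.0)

    def test_stationary_marginal_variance(self):
        # innovation variance 0.36, rho 0.8 -> marginal 0.36 / (1 - 0.64) = 1
        q = ar1_precision(3, 0.8, sigma2_innov=0.36).toarray()
        cov = np.linalg.inv(q)
        assert cov[0, 0] == pytest.approx(1.0)

    @pytest.mark.parametrize("n, rho", [(5, 0.5), (7, -0.3), (4, 0.9)])
    def test_precision_inverts_dense_covariance(self, n, rho):
        q = ar1_precision(n, rho, sigma2_innov=1.7).toarray()
        np.testing.assert_allclose(q @ ar1_cov(n, rho, 1.7), np.eye(n), atol=1e-10)

    def test_corr_precision_inverts_correlation_matrix(self):
        n, rho = 6, 0.65
        corr = rho ** np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        np.testing.assert_allclose(
            ar1_corr_precision(n, rho).toarray() @ corr, np.eye(n), atol=1e-10
        )

    @pytest.mark.parametrize("rho", [1.0, -1.0, 1.5])
    def test_invalid_rho_rejected(self, rho):
        with pytest.raises(ValueError):
            ar1_precision(3, rho)


class TestAR1xAR1:
    def test_rho_zero_gives_identity_correlation(self):
        c = ar1xar1_cov(3, 4, AR1Params(0.0, 0.0, 2.0))
        np.testing.assert_allclose(c, 2.0 * np.eye(12), atol=1e-12)

    def test_separable_lag_correlation(self):
        params = AR1Params(0.8, 0.8, 1.0)
        c = ar1xar1_cov(4, 3, params)
        # row-major: plot (r, c) at index r * 3 + c; lag (1, 1) between 0 and 4
        assert c[0, 4] == pytest.approx(0.64)
        # general separability at lag (a, b)
        assert c[0, 7] == pytest.approx(0.8**2 * 0.8)  # lag (2, 1)

    @pytest.mark.parametrize("shape", [(4, 3), (6, 6), (2, 5)])
    def test_precision_covariance_inverse_pair(self, shape):
        params = AR1Params(0.7, -0.4, 0.9)
        q, logdet = ar1xar1_precision(*shape, params)
        c = ar1xar1_cov(*shape, params)
        np.testing.assert_allclose(q.toarray() @ c, np.eye(c.shape[0]), atol=1e-10)
        sign, ld = np.linalg.slogdet(q.toarray())
        assert sign == 1.0
        assert logdet == pytest.approx(ld)

    def test_ar1_range_anchor_values(self):
        assert ar1_range(0.1) == pytest.approx(1.0)
        # rho = 0.8 corresponds to a range of (about) 10 lattice units
        assert ar1_range(0.8) == pytest.approx(10.32, abs=0.01)
        assert ar1_range(0.9) > ar1_range(0.8) > ar1_range(0.5)

    @pytest.mark.parametrize("rho", [0.0, 1.0, -0.2])
    def test_ar1_range_domain(self, rho):
        with pytest.raises(ValueError):
            ar1_range(rho)


class TestSampling:
    def test_fixed_seed_reproducible(self):
        c = matern_cov(np.random.default_rng(0).uniform(0, 5, (10, 2)), MaternParams())
        a = sample_field(cov=c, n_samples=3, rng=123)
        b = sample_field(cov=c, n_samples=3, rng=123)
        np.testing.assert_array_equal(a, b)

    def test_tiny_variance_fields_near_zero(self):
        c = matern_cov(np.arange(10.0).reshape(5, 2), MaternParams(sigma2=1e-14))
        x = sample_field(cov=c, rng=0)
        assert np.abs(x).max() < 1e-5

    def test_marginal_variance_matches_model(self, rng):
        params = AR1Params(0.6, 0.6, 2.0)
        c = ar1xar1_cov(6, 6, params)
        draws = sample_field(cov=c, n_samples=1000, rng=rng)
        # avg over coordinates of empirical/target variance, within 3 MC SE
        ratio = draws.var(axis=0, ddof=1).mean() / 2.0
        assert abs(ratio - 1.0) < 3.0 * np.sqrt(2.0 / 999)

    def test_precision_route_matches_covariance_route(self):
        params = AR1Params(0.5, 0.2, 1.5)
        c = ar1xar1_cov(4, 4, params)
        q, _ = ar1xar1_precision(4, 4, params)
        draws = sample_field(precision=q, n_samples=4000, rng=7)
        emp = np.cov(draws.T)
        assert np.abs(emp - c).max() < 0.15

    def test_non_spd_input_reports_eigenvalue(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        with pytest.raises(np.linalg.LinAlgError, match="eigenvalue"):
            sample_field(cov=bad, rng=0)

    def test_exactly_one_source_required(self):
        with pytest.raises(ValueError):
            sample_field(cov=np.eye(2), precision=np.eye(2))


class TestNelderWheel:
    def test_design_counts_and_densities(self):
        lay = nelder_layout(NelderDesign())
        assert lay.n_plots == 300
        dens = lay.extra["density"]
        assert dens.nunique() == 10
        assert (dens.value_counts() == 30).all()

    def test_growing_area_formula_ring1(self):
        d = NelderDesign()
        # theta r^2 (k - 1/k) / 2 at r = 10, k = 1.15, theta = 2 pi / 30
        assert d.growing_areas[0] == pytest.approx(2.937, abs=1e-3)
        assert d.densities[0] == pytest.approx(0.3405, abs=1e-4)
        np.testing.assert_allclose(d.densities, 1.0 / d.growing_areas)

    def test_ring_radii_geometric(self):
        d = NelderDesign()
        assert d.radii[-1] == pytest.approx(10.0 * 1.15**9)
        assert d.radii[-1] == pytest.approx(35.18, abs=0.01)

    def test_rings_must_expand(self):
        with pytest.raises(ValueError, match="expand"):
            NelderDesign(k=1.0)


class TestFieldLayout:
    def test_lattice_column_spacing_doubles_row_spacing(self):
        lay = FieldLayout.lattice(3, 4, trial_id="t")
        # same row, adjacent columns: 2 units; same column, adjacent rows: 1
        assert lay.coords[1, 1] - lay.coords[0, 1] == pytest.approx(2.0)
        r0c0 = lay.coords[lay.col == 1][:2]
        assert r0c0[1, 0] - r0c0[0, 0] == pytest.approx(1.0)

    def test_duplicate_coordinates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            FieldLayout(
                trial_id="t",
                row=np.array([1, 1]),
                col=np.array([1, 2]),
                coords=np.zeros((2, 2)),
            )
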