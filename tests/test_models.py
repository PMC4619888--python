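import numpy as np
import pytest

from givh import (
    DesignSpec,
    Grid,
    MCMCConfig,
    adjacency_matrix,
    expand_design,
    fit_gam,
    fit_glm_bayes,
    fit_strm_rsr,
    moran_basis,
    posterior_total_abundance,
    predict_mean_response,
    prediction_set,
    simulate_covariate_field,
)
from givh.models import AbundanceDraws, BayesPoissonGLM, BayesSTRM, QuasiPoissonGAM
from givh.simulate import CountData

FAST = dict(iterations=1500, burn_in=300)


def _degenerate_glm(beta, X_grid, cells, n_draws=200, sigma2=0.0):
    """A 'fitted' GLM whose posterior is a point mass at beta."""
    from givh.lattice import DesignMatrix

    model = BayesPoissonGLM()
    beta = np.asarray(beta, float)
    model.coef_draws_ = np.tile(beta, (n_draws, 1))
    model.sigma2_draws_ = np.full(n_draws, sigma2)
    model.coef_ = beta
    model.coef_cov_ = np.zeros((beta.size, beta.size))
    model.n_features_in_ = beta.size
    model.design_grid_ = DesignMatrix(
        X_grid, ["intercept"] + [f"x{j}" for j in range(1, beta.size)],
        np.arange(X_grid.shape[0]),
    )
    model.cells_ = np.asarray(cells, int)
    return model


class TestMCMCConfig:
    def test_defaults_match_field_analysis_chain(self):
        config = MCMCConfig()
        assert config.iterations == 60_000
        assert config.burn_in == 10_000

    def test_burn_in_must_precede_iterations(self):
        with pytest.raises(ValueError):
            MCMCConfig(iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            BayesPoissonGLM(iterations=100, burn_in=200).fit(
                np.ones((5, 1)), np.ones(5)
            )


class TestBayesPoissonGLM:
    def test_intercept_only_posterior_concentrates_at_mean_count(self):
        y = np.full(80, 7)
        X = np.ones((80, 1))
        model = BayesPoissonGLM(seed=1, **FAST).fit(X, y)
        assert np.exp(model.coef_draws_[:, 0].mean()) == pytest.approx(7.0, rel=0.15)

    def test_chains_reproducible_under_fixed_seed(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(40), rng.normal(size=40)])
        y = rng.poisson(np.exp(1.0 + 0.5 * X[:, 1]))
        a = BayesPoissonGLM(seed=5, iterations=500, burn_in=100).fit(X, y)
        b = BayesPoissonGLM(seed=5, iterations=500, burn_in=100).fit(X, y)
        np.testing.assert_array_equal(a.coef_draws_, b.coef_draws_)
        c = BayesPoissonGLM(seed=6, iterations=500, burn_in=100).fit(X, y)
        assert not np.array_equal(a.coef_draws_, c.coef_draws_)

    def test_coefficient_covariance_psd(self, sim_counts, design10):
        _, _, counts = sim_counts
        model = fit_glm_bayes(counts, design10, MCMCConfig(seed=2, **FAST))
        eig = np.linalg.eigvalsh(model.coef_cov_)
        assert eig.min() >= -1e-8 * max(eig.max(), 1.0)

    def test_parameter_recovery_within_three_posterior_sd(self):
        rng = np.random.default_rng(3)
        n = 200
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        beta = np.array([1.2, 0.5, -0.3])
        eps = rng.normal(0, 0.2, n)
        y = rng.poisson(np.exp(X @ beta + eps))
        model = BayesPoissonGLM(seed=4, iterations=4000, burn_in=800).fit(X, y)
        sd = model.coef_draws_.std(axis=0)
        assert np.all(np.abs(model.coef_ - beta) < 3 * sd)

    def test_non_finite_offset_rejected(self):
        X = np.ones((3, 1))
        with pytest.raises(ValueError, match="offset"):
            BayesPoissonGLM(iterations=10, burn_in=1).fit(
                X, np.ones(3), offset=np.array([0.0, -np.inf, 0.0])
            )


class TestDegeneratePosteriorPredictions:
    def test_point_mass_posterior_predicts_exp_mu_exactly(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(10), rng.normal(size=10)])
        beta = np.array([0.4, -0.7])
        model = _degenerate_glm(beta, X, cells=[0, 1, 2])
        np.testing.assert_allclose(model.predict(X), np.exp(X @ beta), rtol=1e-12)

    def test_posterior_mean_equals_brute_force_average_of_draws(self, sim_counts, design10):
        _, _, counts = sim_counts
        model = fit_glm_bayes(counts, design10, MCMCConfig(seed=2, **FAST))
        lam = model.predict(design10)
        brute = np.exp(model.coef_draws_ @ design10.matrix.T).mean(axis=0)
        np.testing.assert_allclose(lam, brute, rtol=1e-12)

    def test_prediction_at_fitted_cell_matches_fitted_mean(self, sim_counts, design10):
        _, _, counts = sim_counts
        model = fit_glm_bayes(counts, design10, MCMCConfig(seed=2, **FAST))
        full = predict_mean_response(model)
        np.testing.assert_allclose(
            full[counts.cells], model.predict(design10.rows_for(counts.cells)), rtol=1e-12
        )

    def test_column_mismatch_rejected(self):
        model = _degenerate_glm([0.1, 0.2], np.ones((4, 2)), cells=[0])
        with pytest.raises(ValueError, match="columns"):
            model.predict(np.ones((3, 5)))


class TestMoranBasis:
    def test_basis_orthogonal_to_fixed_effects(self, design10, grid10):
        A = adjacency_matrix(grid10, "rook")
        K, Q = moran_basis(design10, A, 0.5)
        assert K.shape[1] > 0
        assert np.abs(K.T @ design10.matrix).max() < 1e-10
        # reduced precision is symmetric positive definite
        eig = np.linalg.eigvalsh(Q)
        assert eig.min() > 0

    def test_threshold_above_spectrum_warns_and_empties_basis(self, design10, grid10):
        A = adjacency_matrix(grid10, "rook")
        with pytest.warns(UserWarning, match="empty"):
            K, Q = moran_basis(design10, A, 1e6)
        assert K.shape == (grid10.n_cells, 0)


class TestBayesSTRM:
    def test_empty_basis_fit_coincides_with_glm(self, sim_counts, design10, grid10):
        _, _, counts = sim_counts
        A = adjacency_matrix(grid10, "rook")
        with pytest.warns(UserWarning):
            strm = fit_strm_rsr(counts, design10, A, 1e6, MCMCConfig(seed=9, **FAST))
        glm = fit_glm_bayes(counts, design10, MCMCConfig(seed=9, **FAST))
        np.testing.assert_allclose(strm.coef_draws_, glm.coef_draws_)

    def test_fit_and_hull(self, sim_counts, design10, grid10):
        _, _, counts = sim_counts
        A = adjacency_matrix(grid10, "rook")
        model = fit_strm_rsr(counts, design10, A, 0.5, MCMCConfig(seed=9, **FAST))
        assert model.n_spatial_ > 0
        eig = np.linalg.eigvalsh(model.coef_cov_)
        assert eig.min() >= -1e-8 * max(eig.max(), 1.0)
        preds = prediction_set(model)
        assert preds.in_givh[counts.cells].all()


class TestPosteriorTotalAbundance:
    def test_zero_habitat_gives_zero_abundance(self, sim_counts, design10):
        _, _, counts = sim_counts
        model = fit_glm_bayes(counts, design10, MCMCConfig(seed=2, **FAST))
        draws, q = posterior_total_abundance(
            model, habitat_fraction=np.zeros(design10.n_rows), seed=0
        )
        assert draws.totals().max() == 0
        assert q == {"q05": 0.0, "q50": 0.0, "q95": 0.0}

    def test_quantiles_ordered(self, sim_counts, design10):
        _, _, counts = sim_counts
        model = fit_glm_bayes(counts, design10, MCMCConfig(seed=2, **FAST))
        _, q = posterior_total_abundance(model, seed=1)
        assert q["q05"] <= q["q50"] <= q["q95"]

    def test_totals_match_analytic_mean_for_point_posterior(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(50), rng.normal(size=50)])
        beta = np.array([2.0, 0.3])
        model = _degenerate_glm(beta, X, cells=[0], n_draws=3000)
        draws, _ = posterior_total_abundance(model, seed=3)
        expected = np.exp(X @ beta).sum()
        se = np.sqrt(expected / 3000)
        assert abs(draws.totals().mean() - expected) < 5 * se

    def test_empty_subset_rejected(self, sim_counts, design10):
        _, _, counts = sim_counts
        model = fit_glm_bayes(counts, design10, MCMCConfig(seed=2, **FAST))
        with pytest.raises(ValueError, match="empty"):
            posterior_total_abundance(model, subset=np.array([], dtype=int))

    def test_abundance_draws_validation(self):
        with pytest.raises(ValueError):
            AbundanceDraws(np.arange(3), -np.ones((5, 3), dtype=int))


class TestQuasiPoissonGAM:
    def test_recovers_quadratic_log_intensity(self):
        rng = np.random.default_rng(1)
        z = rng.uniform(-2, 2, 300)
        mu = 1.0 + 0.8 * z - 0.5 * z**2
        y = rng.poisson(np.exp(mu))
        model = QuasiPoissonGAM(basis_size=8).fit(z, y)
        zg = np.linspace(-1.8, 1.8, 50)
        fitted = np.log(model.predict(zg))
        truth = 1.0 + 0.8 * zg - 0.5 * zg**2
        rmse = np.sqrt(np.mean((fitted - truth) ** 2))
        # noise floor: the fit's own delta-method pointwise uncertainty
        from givh.hull import prediction_variance_linear

        se = np.sqrt(
            prediction_variance_linear(model.design_rows(zg), model.coef_cov_)
        )
        assert rmse < 2.5 * se.mean() + 0.05

    def test_constant_covariate_reported_degenerate(self, grid10, fields10):
        from givh.simulate import observe_counts, simulate_abundance, draw_spatially_balanced
        from givh.lattice import CovariateField

        surf = simulate_abundance(fields10[:1], [np.log(10.0), 0.5], seed=1)
        survey = draw_spatially_balanced(grid10, 25, seed=2)
        counts = observe_counts(surf, survey, 0.5, seed=3)
        flat = CovariateField(grid10, "flat", np.full(grid10.n_cells, 2.0))
        model = fit_gam(counts, [fields10[0], flat], basis_size=5)
        assert model.degenerate_smooths_ == [1]
        assert np.all(np.isfinite(model.predict(model.covariates_grid_)))

    def test_minimum_basis_size_enforced(self, sim_counts, fields10):
        _, _, counts = sim_counts
        with pytest.raises(ValueError, match="basis_size"):
            fit_gam(counts, fields10[:2], basis_size=2)

    def test_unpenalized_limit_matches_statsmodels_glm(self, sim_counts, fields10):
        statsmodels = pytest.importorskip("statsmodels.api")
        _, _, counts = sim_counts
        Z = np.column_stack([f.values for f in fields10[:2]])[counts.cells]
        model = QuasiPoissonGAM(basis_size=5, lambda_grid=[1e-10]).fit(
            Z, counts.y, offset=counts.offset
        )
        X = model.design_rows(Z)
        sm_fit = statsmodels.GLM(
            counts.y, X, family=statsmodels.families.Poisson(), offset=counts.offset
        ).fit()
        np.testing.assert_allclose(model.coef_, sm_fit.params, rtol=1e-5, atol=1e-6)
        np.testing.assert_allclose(
            model.predict(Z, offset=counts.offset), sm_fit.mu, rtol=1e-5
        )

    def test_gam_default_variance_is_delta_with_bootstrap_option(self, sim_counts, fields10):
        _, _, counts = sim_counts
        model = fit_gam(counts, fields10[:2], basis_size=5)
        delta = prediction_set(model)
        assert delta.variance_method == "delta"
        boot = prediction_set(model, method="bootstrap", seed=1, n_boot=4000)
        assert boot.variance_method == "bootstrap"
        # both routes agree on the bulk of cells
        ratio = (boot.var_lambda + 1e-12) / (delta.var_lambda + 1e-12)
        assert np.median(np.abs(np.log(ratio))) < 0.5


class TestSerialization:
    @pytest.mark.parametrize("kind", ["glm", "strm", "gam"])
    def test_dump_roundtrip_preserves_predictions(
        self, kind, tmp_path, sim_counts, design10, fields10, grid10
    ):
        from givh.serialize import load_model, save_model

        _, _, counts = sim_counts
        spec = DesignSpec(covariates=("z1", "z2"))
        if kind == "glm":
            model = fit_glm_bayes(counts, design10, MCMCConfig(seed=2, **FAST))
        elif kind == "strm":
            model = fit_strm_rsr(
                counts, design10, adjacency_matrix(grid10, "rook"), 0.5,
                MCMCConfig(seed=2, **FAST),
            )
        else:
            model = fit_gam(counts, fields10[:2], basis_size=5)
        save_model(model, tmp_path / "dump", design_spec=spec)
        back = load_model(tmp_path / "dump", fields10)
        p0 = prediction_set(model, seed=0)
        p1 = prediction_set(back, seed=0)
        np.testing.assert_allclose(p1.lambda_mean, p0.lambda_mean, rtol=1e-8)
        np.testing.assert_array_equal(p1.in_givh, p0.in_givh)
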