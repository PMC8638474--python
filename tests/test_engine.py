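import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.stats import norm

from qintreg import GeneratorConfig, generate_dataset
from qintreg.engine import (MCMCSettings, ModelSpec, al_logdensity,
                            check_loss, fit_quantile_model,
                            laplace_hyper_posterior, posterior_summaries)
from qintreg.experiments import empirical_check_loss_minimiser
from qintreg.gmrf import LatentSpec

from conftest import make_plain_dataset


class TestCheckLoss:
    @pytest.mark.parametrize("u,tau,expected", [
        (1.0, 0.92, 0.92),      # positive branch
        (-1.0, 0.92, 0.08),     # negative branch
        (2.0, 0.5, 1.0),        # symmetric case |u|/2
        (-2.0, 0.5, 1.0),
        (0.0, 0.3, 0.0),
    ])
    def test_values(self, u, tau, expected):
        assert check_loss(u, tau) == pytest.approx(expected)

    @given(st.floats(-1e6, 1e6, allow_nan=False),
           st.floats(0.01, 0.99))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_nonnegative_and_zero_only_at_origin(self, u, tau):
        val = check_loss(u, tau)
        assert val >= 0
        assert (val == 0) == (u == 0)

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            check_loss(1.0, 1.0)


class TestAlLogDensity:
    def test_density_at_mode_is_tau_times_one_minus_tau(self):
        assert al_logdensity(0.0, 0.0, 1.0, 0.92) == pytest.approx(
            np.log(0.92 * 0.08))

    def test_unit_offset(self):
        got = al_logdensity(1.0, 0.0, 1.0, 0.92)
        assert got == pytest.approx(np.log(0.92 * 0.08) - 0.92)

    def test_integrates_to_one(self):
        val, err = quad(lambda y: np.exp(al_logdensity(y, 0.0, 1.0, 0.85)),
                        -200, 50, limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            al_logdensity(0.0, 0.0, 0.0, 0.5)


class TestFitQuantileModel:
    def test_intercept_matches_check_loss_minimiser(self, quick_mcmc):
        rng = np.random.default_rng(8)
        y = rng.standard_normal(200)
        data = make_plain_dataset(y)
        fit = fit_quantile_model(data, ModelSpec(tau=0.9),
                                 MCMCSettings(iterations=2000, burn_in=500),
                                 seed=1)
        draws = fit.fixed_draws[:, 0]
        oracle = empirical_check_loss_minimiser(y, 0.9)
        assert abs(draws.mean() - oracle) < 3 * draws.std()

    def test_median_fit_matches_sample_median(self):
        rng = np.random.default_rng(3)
        y = rng.standard_normal(800)
        data = make_plain_dataset(y)
        fit = fit_quantile_model(data, ModelSpec(tau=0.5),
                                 MCMCSettings(iterations=2000, burn_in=500),
                                 seed=5)
        med = float(np.median(y))
        mcse = 1.2533 / np.sqrt(len(y))  # asymptotic SE of the normal median
        assert abs(fit.fixed_draws[:, 0].mean() - med) < 3 * mcse

    def test_posterior_mode_approaches_empirical_quantile(self):
        # check-loss coherence at n = 5000
        tau = 0.85
        rng = np.random.default_rng(12)
        y = rng.standard_normal(5000)
        fit = fit_quantile_model(make_plain_dataset(y), ModelSpec(tau=tau),
                                 MCMCSettings(iterations=1500, burn_in=500),
                                 seed=2)
        q_emp = empirical_check_loss_minimiser(y, tau)
        mcse = np.sqrt(tau * (1 - tau) / y.size) / norm.pdf(norm.ppf(tau))
        assert abs(fit.fixed_draws[:, 0].mean() - q_emp) < 3 * mcse

    def test_fixed_effects_match_frequentist_quantile_regression(self):
        # independent oracle: statsmodels QuantReg point estimates
        import statsmodels.api as sm

        from qintreg import GeneratorConfig, build_region_graph, generate_dataset
        from qintreg.experiments import RECOVERY_EFFECTS, recovery_config

        cfg = recovery_config(n_per_year=1000, seed=19)
        data = generate_dataset(cfg, build_region_graph("namibia13"))
        tau = 0.92
        fit = fit_quantile_model(
            data, ModelSpec(tau=tau, fixed_covariates=tuple(RECOVERY_EFFECTS)),
            MCMCSettings(iterations=1500, burn_in=500), seed=6)
        X = np.column_stack(
            [np.ones(len(data.df))]
            + [data.df[c].to_numpy(float) for c in RECOVERY_EFFECTS])
        freq = sm.QuantReg(data.df["bmiaz"].to_numpy(), X).fit(q=tau)
        bayes = fit.fixed_draws.mean(axis=0)
        se = freq.bse
        assert np.all(np.abs(bayes - freq.params) < 3 * se)

    def test_seeded_determinism(self, small_dataset, quick_mcmc):
        spec = ModelSpec(tau=0.9, fixed_covariates=("urban",),
                         temporal_term="RW1")
        a = fit_quantile_model(small_dataset, spec, quick_mcmc, seed=9)
        b = fit_quantile_model(small_dataset, spec, quick_mcmc, seed=9)
        assert np.array_equal(a.fixed_draws, b.fixed_draws)
        assert np.array_equal(a.loglik, b.loglik)

    def test_likelihood_bookkeeping_exact(self, small_dataset, quick_mcmc):
        spec = ModelSpec(tau=0.92, fixed_covariates=("urban", "television"))
        fit = fit_quantile_model(small_dataset, spec, quick_mcmc, seed=4)
        recomputed = al_logdensity(fit.y[None, :], fit.eta_draws,
                                   fit.sigma_draws[:, None], fit.tau)
        assert np.array_equal(recomputed, fit.loglik)

    def test_wholly_missing_covariate_dropped(self, small_dataset,
                                              quick_mcmc):
        # wealth is entirely missing in 2000; restricting the data to 2000
        # must drop it from the design and record that
        df2000 = small_dataset.df[small_dataset.df.year == 2000]
        from qintreg.synthetic import AnalysisDataset
        sub = AnalysisDataset(df2000.reset_index(drop=True))
        spec = ModelSpec(tau=0.9, fixed_covariates=("urban", "wealth"))
        fit = fit_quantile_model(sub, spec, quick_mcmc, seed=0)
        assert fit.dropped_covariates == ["wealth"]
        assert not any(lab.startswith("wealth") for lab in fit.fixed_labels)

    def test_unknown_covariate_rejected(self, small_dataset, quick_mcmc):
        with pytest.raises(ValueError, match="unknown covariate"):
            fit_quantile_model(small_dataset,
                               ModelSpec(tau=0.5, fixed_covariates=("zz",)),
                               quick_mcmc, seed=0)

    def test_structured_terms_sum_to_zero(self, small_dataset, quick_mcmc,
                                          namibia):
        spec = ModelSpec(tau=0.9,
                         smooth_terms={"child_age_months": "RW2"},
                         spatial_term=LatentSpec("ICAR", graph=namibia),
                         temporal_term="RW1")
        fit = fit_quantile_model(small_dataset, spec, quick_mcmc, seed=1)
        age = fit.smooth["child_age_months"]["draws"]
        assert np.max(np.abs(age.sum(axis=1))) < 1e-8
        assert np.max(np.abs(fit.spatial["draws"].sum(axis=1))) < 1e-8
        assert np.max(np.abs(fit.temporal["draws"].sum(axis=1))) < 1e-8

    def test_pcar_rho_sampled_inside_unit_interval(self, small_dataset,
                                                   quick_mcmc, namibia):
        spec = ModelSpec(tau=0.9,
                         spatial_term=LatentSpec("PCAR", graph=namibia,
                                                 rho=0.5))
        fit = fit_quantile_model(small_dataset, spec, quick_mcmc, seed=2)
        assert fit.rho_draws is not None
        assert np.all((fit.rho_draws > 0) & (fit.rho_draws < 1))
        assert 0 < fit.diagnostics["rho_acceptance"] <= 1


def test_save_fit_writes_draw_tables(tmp_path, small_dataset, quick_mcmc,
                                     namibia):
    from qintreg.engine import save_fit

    spec = ModelSpec(tau=0.9, fixed_covariates=("urban",),
                     spatial_term=LatentSpec("PCAR", graph=namibia, rho=0.5),
                     temporal_term="RW1")
    fit = fit_quantile_model(small_dataset, spec, quick_mcmc, seed=1)
    save_fit(fit, tmp_path)
    fixed = pd.read_csv(tmp_path / "fixed_draws.csv")
    assert list(fixed.columns) == fit.fixed_labels
    assert np.allclose(fixed.to_numpy(), fit.fixed_draws)
    hyper = pd.read_csv(tmp_path / "hyperparameter_draws.csv")
    assert {"sigma", "rho", "precision_spatial"} <= set(hyper.columns)
    assert (tmp_path / "fit.yaml").exists()
    assert (tmp_path / "diagnostics.log").exists()


class TestLaplaceHyperPosterior:
    def test_gaussian_case_exact_vs_conjugate(self):
        from qintreg.experiments import laplace_gaussian_study
        res = laplace_gaussian_study(n=40, seed=3)
        assert res["mass_sum"] == pytest.approx(1.0, abs=1e-12)
        assert res["tv_distance"] < 1e-4

    def test_al_grid_normalised_and_converged(self):
        rng = np.random.default_rng(5)
        data = make_plain_dataset(rng.standard_normal(60))
        grid = [{"sigma": s} for s in np.geomspace(0.2, 2.0, 9)]
        table = laplace_hyper_posterior(data, ModelSpec(tau=0.85), grid)
        assert table["mass"].sum() == pytest.approx(1.0)
        assert table["converged"].all()


class TestPosteriorSummaries:
    def _fit_like(self, draws):
        from qintreg.engine import QuantileFitResult
        s = draws.shape[0]
        return QuantileFitResult(
            tau=0.9, fixed_labels=["a"], fixed_draws=draws, smooth={},
            spatial=None, temporal=None, sigma_draws=np.ones(s),
            precision_draws={}, rho_draws=None,
            eta_draws=np.zeros((s, 1)), loglik=np.zeros((s, 1)),
            diagnostics={}, dropped_covariates=[], y=np.zeros(1))

    def test_constant_draws_collapse_interval(self):
        out = posterior_summaries(self._fit_like(np.full((50, 1), 3.25)))
        row = out[out.quantity == "a"].iloc[0]
        assert row["mean"] == row["lower"] == row["upper"] == 3.25

    def test_interval_endpoints_are_empirical_quantiles(self):
        draws = np.arange(1.0, 101.0)[:, None]
        out = posterior_summaries(self._fit_like(draws), level=0.95)
        row = out.iloc[0]
        assert row["mean"] == pytest.approx(draws.mean())
        assert row["lower"] == pytest.approx(np.quantile(draws, 0.025))
        assert row["upper"] == pytest.approx(np.quantile(draws, 0.975))

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            posterior_summaries(self._fit_like(np.zeros((1, 1))))
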