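"""Likelihood, posterior density, summaries and the inference engines."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import binom, multivariate_normal, norm

import geocoverage as gc
from geocoverage.data_io import ClusterRecord
from geocoverage.matern import MaternParams, covariance_matrix
from geocoverage.model import (
    FitResult,
    HyperPrior,
    ModelData,
    ModelSpec,
    binomial_loglik,
    default_hyperprior,
    fit,
    log_posterior,
    summarize,
)
from geocoverage.synthetic import CovariateSpec, SimulationConfig, simulate_dataset


def _rec(i, x, y, n, yv):
    return ClusterRecord(cluster_id=str(i), x=x, y=y, lon=x, lat=y, year=2000,
                         n_children=n, n_vaccinated=yv)


class TestBinomialLoglik:
    def test_hand_computation(self):
        total, pw = binomial_loglik(np.array([0.0]), ([1], [2]))
        # log C(2,1) + 2 log 0.5 = log 2 - 2 log 2 = -log 2
        assert total == pytest.approx(-np.log(2.0), abs=1e-12)

    def test_saturated_limit_goes_to_zero_from_below(self):
        etas = [5.0, 15.0, 30.0]
        vals = [binomial_loglik(np.array([e]), ([10], [10]))[0] for e in etas]
        assert all(v < 0 for v in vals)
        assert vals[0] < vals[1] < vals[2]
        assert vals[2] == pytest.approx(0.0, abs=1e-12)

    def test_matches_scipy_pmf_oracle(self):
        rng = np.random.default_rng(1)
        n = rng.integers(1, 50, size=5)
        y = np.array([rng.integers(0, k + 1) for k in n])
        eta = rng.normal(scale=2, size=5)
        total, pw = binomial_loglik(eta, (y, n))
        oracle = binom.logpmf(y, n, expit(eta))
        np.testing.assert_allclose(pw, oracle, atol=1e-12)
        assert total == pytest.approx(oracle.sum(), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            binomial_loglik(np.zeros(3), ([1, 2], [2, 3]))


class TestLogPosterior:
    def _small_instance(self):
        recs = [_rec(0, 0.0, 0.0, 10, 4), _rec(1, 30.0, 10.0, 12, 9),
                _rec(2, 10.0, 40.0, 8, 2)]
        X = np.array([[-1.0], [0.2], [0.8]])
        data = ModelData(
            y=np.array([4.0, 9.0, 2.0]), n_trials=np.array([10.0, 12.0, 8.0]),
            X=X, locations=np.array([[0.0, 0.0], [30.0, 10.0], [10.0, 40.0]]),
        )
        hp = HyperPrior(log_sigma_mean=0.0, log_sigma_sd=1.0,
                        log_rho_mean=3.0, log_rho_sd=1.0)
        spec = ModelSpec(covariate_names=["c"], include_spatial_field=True,
                         nu=1.0, hyperprior=hp)
        return data, spec, hp

    def test_matches_term_by_term_oracle(self):
        data, spec, hp = self._small_instance()
        theta = np.array([0.3, -0.5, np.log(0.9), np.log(20.0), 0.1, -0.2, 0.05])
        got = log_posterior(theta, data, spec)
        # independent oracle: scipy densities term by term
        alpha, beta, ls, lr = theta[0], theta[1], theta[2], theta[3]
        zeta = theta[4:]
        eta = alpha + data.X[:, 0] * beta + zeta
        ll = binom.logpmf(data.y, data.n_trials, expit(eta)).sum()
        lp_beta = norm.logpdf(beta, 0.0, np.sqrt(1e4))
        cov = covariance_matrix(data.locations, MaternParams(np.exp(ls), np.exp(lr), 1.0))
        lp_zeta = multivariate_normal.logpdf(zeta, mean=np.zeros(3), cov=cov)
        lp_hyp = (norm.logpdf(ls, 0.0, 1.0) + norm.logpdf(lr, 3.0, 1.0))
        assert got == pytest.approx(ll + lp_beta + lp_zeta + lp_hyp, abs=1e-10)

    def test_beta_prior_maximal_at_zero(self):
        data, spec, _ = self._small_instance()
        base = np.array([0.0, 0.0, 0.0, 3.0, 0.0, 0.0, 0.0])
        # isolate the beta prior by cancelling the likelihood change:
        # compare posterior differences against likelihood differences
        for b in (0.5, -1.0, 2.0):
            t = base.copy()
            t[1] = b
            diff = log_posterior(t, data, spec) - log_posterior(base, data, spec)
            eta_b = t[0] + data.X[:, 0] * b
            eta_0 = np.full(3, base[0])
            ll_diff = (binomial_loglik(eta_b, (data.y, data.n_trials))[0]
                       - binomial_loglik(eta_0, (data.y, data.n_trials))[0])
            prior_diff = diff - ll_diff
            assert prior_diff == pytest.approx(-0.5 * 1e-4 * b**2, abs=1e-10)

    def test_changing_beta_leaves_field_and_hyper_terms_unchanged(self):
        data, spec, _ = self._small_instance()
        t1 = np.array([0.1, 0.4, np.log(0.8), np.log(15.0), 0.2, -0.1, 0.3])
        t2 = t1.copy()
        t2[1] = -0.9
        diff = log_posterior(t2, data, spec) - log_posterior(t1, data, spec)
        ll1 = binomial_loglik(t1[0] + data.X[:, 0] * t1[1] + t1[4:], (data.y, data.n_trials))[0]
        ll2 = binomial_loglik(t2[0] + data.X[:, 0] * t2[1] + t2[4:], (data.y, data.n_trials))[0]
        beta_prior_diff = -0.5 * 1e-4 * (t2[1] ** 2 - t1[1] ** 2)
        assert diff == pytest.approx((ll2 - ll1) + beta_prior_diff, abs=1e-10)

    def test_wrong_length_rejected(self):
        data, spec, _ = self._small_instance()
        with pytest.raises(ValueError):
            log_posterior(np.zeros(5), data, spec)


class TestSummarize:
    def _fit_from_draws(self, draws, names):
        n_draws = draws.shape[0]
        return FitResult(
            param_names=names, draws=draws, zeta_draws=np.empty((n_draws, 0)),
            pointwise_loglik=np.zeros((n_draws, 1)), spec=ModelSpec(),
            data_hash="x", locations=np.zeros((1, 2)), cov_columns=[],
            cov_means=np.zeros(0), cov_sds=np.ones(0), hyperprior=None,
        )

    def test_constant_draws(self):
        f = self._fit_from_draws(np.full((200, 1), 1.3), ["alpha"])
        row = summarize(f).table.iloc[0]
        assert row["mean"] == pytest.approx(1.3)
        assert row["cri_low"] == row["cri_high"] == pytest.approx(1.3)
        assert row["significant"]
        f0 = self._fit_from_draws(np.zeros((200, 1)), ["alpha"])
        assert not summarize(f0).table.iloc[0]["significant"]

    def test_significance_follows_cri_excludes_zero_rule(self):
        rng = np.random.default_rng(0)
        # a clearly negative coefficient (like a travel-time effect of -0.27
        # with CrI (-0.40, -0.15)) is significant; one straddling zero is not
        neg = rng.normal(-0.27, 0.06, size=4000)
        strad = rng.normal(0.36, 0.25, size=4000)
        f = self._fit_from_draws(np.column_stack([neg, strad]), ["b1", "b2"])
        t = summarize(f).table.set_index("name")
        assert t.loc["b1", "significant"]
        assert t.loc["b1", "cri_high"] < 0
        assert not t.loc["b2", "significant"]
        assert t.loc["b2", "cri_low"] < 0 < t.loc["b2", "cri_high"]

    def test_odds_ratio_is_exp_of_draws(self):
        rng = np.random.default_rng(1)
        d = rng.normal(0.5, 0.1, size=1000)[:, None]
        row = summarize(self._fit_from_draws(d, ["b"])).table.iloc[0]
        assert row["odds_ratio"] == pytest.approx(np.exp(d).mean(), rel=1e-12)
        assert row["or_cri_low"] == pytest.approx(np.quantile(np.exp(d), 0.025), rel=1e-9)

    def test_symmetric_draws_mean_near_zero(self):
        rng = np.random.default_rng(2)
        half = rng.normal(0, 1, size=2000)
        d = np.concatenate([half, -half])[:, None]  # exactly symmetric
        row = summarize(self._fit_from_draws(d, ["b"])).table.iloc[0]
        se = d.std() / np.sqrt(len(d))
        assert abs(row["mean"]) < 3 * se + 1e-12

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            summarize(self._fit_from_draws(np.zeros((50, 1)), ["a"]))


class TestFit:
    def test_intercept_only_matches_numerical_integration(self):
        """Posterior mean of α (no field, no covariates) vs a dense
        quadrature posterior over α alone."""
        rng = np.random.default_rng(0)
        n = np.full(50, 20)
        y = rng.binomial(n, 0.7)
        recs = [_rec(i, float(i), 0.0, int(n[i]), int(y[i])) for i in range(50)]
        spec = ModelSpec(include_spatial_field=False)
        fr = fit(recs, None, spec, engine="laplace", seed=1, n_draws=4000)
        a = fr.param_draws("alpha")
        # quadrature oracle: flat prior on alpha
        grid = np.linspace(-2, 4, 4001)
        logpost = np.array([binom.logpmf(y, n, expit(g)).sum() for g in grid])
        w = np.exp(logpost - logpost.max())
        w /= w.sum()
        post_mean = float(grid @ w)
        post_sd = float(np.sqrt(((grid - post_mean) ** 2) @ w))
        assert abs(a.mean() - post_mean) < 3 * post_sd / np.sqrt(50)
        assert abs(a.mean() - np.log(0.7 / 0.3)) < 3 * post_sd
        assert a.std() == pytest.approx(post_sd, rel=0.15)

    def test_same_seed_identical_draws(self):
        ds = simulate_dataset(SimulationConfig(
            seed=4, n_clusters=40, true_sigma=0.6, true_range=40.0,
            region_extent=(200.0, 200.0), n_children_range=(20, 20)))
        spec = ModelSpec(include_spatial_field=True, nu=1.0)
        for engine in ("laplace", "mcmc"):
            a = fit(ds.records, None, spec, engine=engine, seed=11, n_draws=300)
            b = fit(ds.records, None, spec, engine=engine, seed=11, n_draws=300)
            np.testing.assert_array_equal(a.draws, b.draws)
            np.testing.assert_array_equal(a.pointwise_loglik, b.pointwise_loglik)

    def test_draws_are_finite_and_shapes_consistent(self):
        ds = simulate_dataset(SimulationConfig(
            seed=8, n_clusters=30, true_sigma=0.5, true_range=30.0,
            region_extent=(150.0, 150.0)))
        fr = fit(ds.records, None, ModelSpec(include_spatial_field=True),
                 engine="laplace", seed=2, n_draws=500)
        assert np.all(np.isfinite(fr.draws))
        assert np.all(np.isfinite(fr.pointwise_loglik))
        assert fr.zeta_draws.shape == (500, 30)
        assert fr.pointwise_loglik.shape == (500, 30)

    def test_rank_deficient_design_names_columns(self):
        ds = simulate_dataset(SimulationConfig(
            seed=3, n_clusters=25, true_sigma=0.4, true_range=30.0,
            region_extent=(150.0, 150.0)))
        from geocoverage.data_io import CovariateMatrix

        X = np.ones((25, 1))  # collinear with the intercept
        cov = CovariateMatrix(columns=["dup"], X=X, means=np.zeros(1), sds=np.ones(1))
        with pytest.raises(ValueError, match="collinear"):
            fit(ds.records, cov, ModelSpec(covariate_names=["dup"]), seed=0, n_draws=200)

    def test_default_draw_count_honours_large_default(self):
        from geocoverage.model import DEFAULT_N_DRAWS

        assert DEFAULT_N_DRAWS == 150_000

    def test_fit_serialization_round_trip(self, tmp_path):
        ds = simulate_dataset(SimulationConfig(
            seed=6, n_clusters=20, true_sigma=0.5, true_range=30.0,
            region_extent=(150.0, 150.0)))
        fr = fit(ds.records, None, ModelSpec(include_spatial_field=True),
                 engine="laplace", seed=3, n_draws=200)
        fr.save(tmp_path / "f")
        back = FitResult.load(tmp_path / "f")
        np.testing.assert_array_equal(back.draws, fr.draws)
        assert back.data_hash == fr.data_hash
        assert back.param_names == fr.param_names


def test_engine_cross_check_cri_endpoints():
    """Laplace 95% CrI endpoints for α and β sit within 0.1 of a
    three-chain MCMC estimate on a 50-cluster survey.  Tail quantiles of
    a single 5,000-draw chain are noisy (the α tail follows the heavy ρ
    tail), so the MCMC side averages endpoint estimates over chains."""
    cfg = SimulationConfig(
        seed=11, region_extent=(300.0, 300.0), n_clusters=50,
        n_children_range=(30, 30), true_alpha=0.3, true_betas=(0.6,),
        true_sigma=0.8, true_range=50.0, nu=1.0,
        covariate_spec=[CovariateSpec("grad", "linear-gradient",
                                      {"start": -2.0, "stop": 2.0, "axis": "x"})])
    ds = simulate_dataset(cfg)
    import geocoverage as gc

    cov = gc.build_design_matrix(ds.records, ds.rasters)
    spec = ModelSpec(covariate_names=cov.columns, include_spatial_field=True, nu=1.0)
    fl = fit(ds.records, cov, spec, engine="laplace", seed=12, n_draws=5000)
    chains = [fit(ds.records, cov, spec, engine="mcmc", seed=s, n_draws=5000)
              for s in (12, 55, 77)]
    for name in ("alpha", "beta_grad"):
        la = fl.param_draws(name)
        lo_l, hi_l = np.quantile(la, [0.025, 0.975])
        lo_m = np.mean([np.quantile(c.param_draws(name), 0.025) for c in chains])
        hi_m = np.mean([np.quantile(c.param_draws(name), 0.975) for c in chains])
        mean_m = np.mean([c.param_draws(name).mean() for c in chains])
        assert abs(la.mean() - mean_m) < 0.05, name
        assert abs(lo_l - lo_m) < 0.1, (name, lo_l, lo_m)
        assert abs(hi_l - hi_m) < 0.1, (name, hi_l, hi_m)


def test_default_hyperprior_scales_with_region():
    locs = np.array([[0.0, 0.0], [300.0, 400.0]])  # diagonal 500 km
    hp = default_hyperprior(locs)
    assert hp.log_rho_mean == pytest.approx(np.log(100.0))
    assert hp.log_sigma_mean == 0.0
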