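"""BYM model: design, likelihood, both engines, and their contracts."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import poisson

from deprivmap import (ModelSpec, Priors, SimulationConfig, build_design,
                       fit_laplace, fit_mcmc, loglik, make_study, posterior_rr)
from deprivmap.bym import DesignError, unstandardize_coefficients
from deprivmap.graph import icar_structure, make_lattice
from deprivmap._laplace import GaussianObs, _LaplaceCore, run_laplace
from deprivmap._mcmc import tau_conditionals


def outcome_frame(n, rng, quintiles=True):
    df = pd.DataFrame({
        "tract_id": [f"t{i}" for i in range(n)],
        "pop": rng.integers(500, 2000, n),
        "deaths": rng.poisson(12, n),
        "age4564": rng.uniform(0.1, 0.4, n),
        "age65": rng.uniform(0.05, 0.3, n),
    })
    if quintiles:
        df["quintile"] = 1 + np.arange(n) % 5
    return df


class TestBuildDesign:
    def test_missing_quintile_level_rejected(self, rng):
        df = outcome_frame(20, rng)
        df["quintile"] = df["quintile"].replace(3, 2)
        with pytest.raises(DesignError, match="level 3"):
            build_design(df, ModelSpec())

    def test_all_reference_quintile_rejected(self, rng):
        df = outcome_frame(20, rng)
        df["quintile"] = 1
        with pytest.raises(DesignError, match="level 2"):
            build_design(df, ModelSpec())

    def test_dummy_block_structure(self, rng):
        df = outcome_frame(5, rng)
        df["quintile"] = [1, 2, 3, 4, 5]
        d = build_design(df, ModelSpec(include_age=False))
        block = d.X[:, 1:5]
        assert np.array_equal(block[0], np.zeros(4))
        assert np.array_equal(block[1:], np.eye(4))

    def test_standardized_age_columns(self, rng):
        df = outcome_frame(40, rng)
        d = build_design(df, ModelSpec())
        j = d.names.index("beta_age65")
        assert abs(d.X[:, j].mean()) < 1e-12
        assert abs(d.X[:, j].std(ddof=0) - 1) < 1e-12
        assert "beta_age65" in d.transform

    def test_back_transform_matches_unstandardized_fit(self, rng):
        # GLM-level check: the coefficient rescaling recovers the same fit
        import statsmodels.api as sm
        df = outcome_frame(60, rng)
        for std in (True, False):
            d = build_design(df, ModelSpec(covariate_standardization=std))
            m = sm.GLM(d.O, d.X, family=sm.families.Poisson(),
                       offset=d.log_offset).fit()
            coefs = unstandardize_coefficients(m.params, d)
            if std:
                ref = coefs
            else:
                for k, v in coefs.items():
                    assert abs(v - ref[k]) < 1e-6

    def test_zero_population_rejected(self, rng):
        df = outcome_frame(10, rng)
        df.loc[3, "pop"] = 0
        with pytest.raises(DesignError, match="population"):
            build_design(df, ModelSpec())


class TestLoglik:
    def test_all_zero_counts_unit_pop(self):
        n = 7
        val = loglik(np.zeros(n), np.zeros(n), np.ones(n))
        assert val == pytest.approx(-n)

    def test_single_tract_closed_form(self):
        # Poisson(mean 2) pmf at 2, frozen from scipy.stats.poisson
        expect = float(poisson.logpmf(2, 2.0))
        got = loglik(np.array([np.log(0.02)]), np.array([2.0]),
                     np.array([100.0]))
        assert got == pytest.approx(expect, abs=1e-10)
        assert got == pytest.approx(-1.3069, abs=5e-5)

    def test_nonfinite_eta_rejected(self):
        with pytest.raises(ValueError):
            loglik(np.array([np.inf]), np.array([1.0]), np.array([10.0]))


class TestTauConjugacy:
    def test_gibbs_conditionals_match_analytic_form(self, rng):
        g = make_lattice(5, 5)
        s = icar_structure(g)
        u = rng.normal(size=25)
        S = rng.normal(size=25)
        pri = Priors(logprec_het=(2.0, 0.1), logprec_spat=(3.0, 0.2))
        cond = tau_conditionals(u, S, s, pri)
        assert cond["tau_v"] == (2.0 + 12.5, pytest.approx(0.1 + (u @ u) / 2))
        shape, rate = cond["tau_S"]
        assert shape == 3.0 + 24 / 2.0  # rank = n - 1
        direct = sum((S[i] - S[j]) ** 2 for i, j in g.edges())
        assert rate == pytest.approx(0.2 + direct / 2)


class TestGaussianLimit:
    def test_laplace_exact_for_gaussian_response(self, rng):
        """With a known-variance Gaussian response the Gaussian
        approximation is exact: posterior means must match the
        constrained GLS closed form."""
        cfg = SimulationConfig(rows=6, cols=5, seed=1)
        st = make_study(cfg)
        d = build_design(st.outcomes, ModelSpec())
        struct = icar_structure(st.graph)
        noise_sd = 0.7
        y = rng.normal(size=d.n)
        obs = GaussianObs(y, noise_sd)
        tau_v, tau_s = 2.0, 3.0
        res = run_laplace(d, struct, Priors(), grid_strategy=[(tau_v, tau_s)],
                          latent_summaries=True, obs=obs)
        # closed form: H = P + B'B/s^2, mean = H^-1 B'y/s^2, then kriging
        n, p = d.n, d.p
        B = np.hstack([d.X, np.eye(n), np.eye(n)])
        P = np.zeros((p + 2 * n, p + 2 * n))
        P[:p, :p] = np.eye(p) / Priors().beta_sd**2
        P[p:p + n, p:p + n] = tau_v * np.eye(n)
        P[p + n:, p + n:] = tau_s * struct.Q.toarray()
        H = P + B.T @ B / noise_sd**2
        mean = np.linalg.solve(H, B.T @ y / noise_sd**2)
        A = np.zeros((1, p + 2 * n)); A[0, p + n:] = 1.0
        Hi_At = np.linalg.solve(H, A.T)
        mean -= (Hi_At @ np.linalg.solve(A @ Hi_At, A @ mean)).ravel()
        got = np.concatenate([
            res.fixed["mean"].to_numpy(),
            res.latent["u_mean"].to_numpy(),
            res.latent["S_mean"].to_numpy(),
        ])
        assert np.max(np.abs(got - mean)) < 1e-8


class TestEngines:
    def test_intercept_only_recovers_rate(self):
        # constant rate, tight random effects: alpha posterior ~ log r
        cfg = SimulationConfig(rows=10, cols=10, sigma_S=0.0, sigma_v=0.01,
                               true_log_rr=(0, 0, 0, 0), beta_age4564=0.0,
                               beta_age65=0.0, baseline_rate=0.02,
                               pop_min=5000, pop_max=5000, seed=2)
        st = make_study(cfg)
        spec = ModelSpec(deprivation=None, include_age=False)
        res = fit_mcmc(spec, st.outcomes, st.graph, n_iter=4000, n_burn=1500,
                       seed=0)
        a = res.fixed.loc["alpha"]
        assert abs(a["mean"] - np.log(0.02)) < 2 * max(a["sd"], 0.01)

    def test_mcmc_reproducible_across_runs(self, small_study):
        st = small_study
        kw = dict(n_iter=800, n_burn=300, seed=9)
        a = fit_mcmc(ModelSpec(), st.outcomes, st.graph, **kw)
        b = fit_mcmc(ModelSpec(), st.outcomes, st.graph, **kw)
        pd.testing.assert_frame_equal(a.fixed, b.fixed)
        pd.testing.assert_frame_equal(a.hyper, b.hyper)

    def test_posterior_S_sums_to_zero_both_engines(self, small_study):
        st = small_study
        rm = fit_mcmc(ModelSpec(), st.outcomes, st.graph, n_iter=1500,
                      n_burn=500, seed=3)
        rl = fit_laplace(ModelSpec(), st.outcomes, st.graph)
        for r in (rm, rl):
            assert abs(r.latent["S_mean"].sum()) < 1e-6

    def test_offset_contract_population_rate_model(self, small_study):
        """Doubling every population with deaths fixed shifts alpha by
        about -log 2 and leaves the quintile effects stable."""
        st = small_study
        res = fit_laplace(ModelSpec(), st.outcomes, st.graph)
        doubled = st.outcomes.copy()
        doubled["pop"] = doubled["pop"] * 2
        res2 = fit_laplace(ModelSpec(), doubled, st.graph)
        da = res2.fixed.loc["alpha", "mean"] - res.fixed.loc["alpha", "mean"]
        assert abs(da + np.log(2)) < 2 * res.fixed.loc["alpha", "sd"]
        db = (res2.fixed.loc["beta_q5", "mean"]
              - res.fixed.loc["beta_q5", "mean"])
        assert abs(db) < 2 * res.fixed.loc["beta_q5", "sd"]

    def test_masked_tract_heterogeneity_reverts_to_prior(self, small_study):
        st = small_study
        mask = np.zeros(st.graph.n, dtype=bool)
        mask[[5, 50]] = True
        res = fit_laplace(ModelSpec(), st.outcomes, st.graph, mask=mask)
        prior_sd = res.hyper.loc["sigma_v", "mean"]
        for i in (5, 50):
            assert res.latent.loc[i, "u_sd"] == pytest.approx(prior_sd,
                                                              rel=0.10)

    def test_single_point_grid_close_to_ccd_at_larger_n(self):
        st = make_study(SimulationConfig(rows=15, cols=15, seed=6))
        full = fit_laplace(ModelSpec(), st.outcomes, st.graph,
                           latent_summaries=False)
        single = fit_laplace(ModelSpec(), st.outcomes, st.graph,
                             grid_strategy="mode", latent_summaries=False)
        for name in full.fixed.index:
            a = full.fixed.loc[name, "mean"]
            b = single.fixed.loc[name, "mean"]
            assert abs(a - b) <= 0.02 * max(1.0, abs(a))


class TestReporting:
    def test_rr_is_exp_of_beta_quantiles(self, small_study):
        res = fit_laplace(ModelSpec(), small_study.outcomes, small_study.graph)
        rr = posterior_rr(res).set_index("parameter")
        for k in range(2, 6):
            row = res.fixed.loc[f"beta_q{k}"]
            got = rr.loc[f"RR Q{k}"]
            assert got["estimate"] == pytest.approx(np.exp(row["mean"]), abs=1e-12)
            assert got["lo95"] == pytest.approx(np.exp(row["q2.5"]), abs=1e-12)
            assert got["hi95"] == pytest.approx(np.exp(row["q97.5"]), abs=1e-12)

    def test_rr_reporting_format_example(self):
        # the conventional layout: RR (95% CI) from log-scale quantiles
        q = {"mean": np.log(0.78), "q2.5": np.log(0.65), "q97.5": np.log(0.93)}
        assert f"{np.exp(q['mean']):.2f}" == "0.78"
        assert f"{np.exp(q['q2.5']):.2f}" == "0.65"
        assert f"{np.exp(q['q97.5']):.2f}" == "0.93"

    def test_estimator_class_api(self, small_study):
        from deprivmap import BYMPoissonRegression
        m = BYMPoissonRegression(engine="laplace")
        m.set_params(latent_summaries=True)
        m.fit(small_study.outcomes, graph=small_study.graph)
        assert m.rr_.shape[0] >= 6
        assert m.sigma_s_ > 0 and m.sigma_v_ > 0
        pred = m.predict()
        assert pred.shape == (small_study.graph.n,)
        # posterior-mean fit tracks the data at this count scale
        assert np.corrcoef(pred, small_study.outcomes["deaths"])[0, 1] > 0.9
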