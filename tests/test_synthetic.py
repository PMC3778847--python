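"""Synthetic study generator: reproducibility, spatial structure, truth."""

import numpy as np
import pandas as pd
import pytest

from deprivmap import (SimulationConfig, loglik, make_confounded_age_scenario,
                       make_study, morans_i, read_study, write_study)
from deprivmap.graph import icar_structure, make_lattice
from deprivmap.synthetic import (simulate_indicators, simulate_mortality,
                                 study_loglik_at_truth, _latent_field)


class TestConfig:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            SimulationConfig(rows=4, cols=4)  # < 25 tracts
        with pytest.raises(ValueError):
            SimulationConfig(true_log_rr=(0.1, 0.2))
        with pytest.raises(ValueError):
            SimulationConfig(baseline_rate=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(pop_min=100, pop_max=50)


class TestReproducibility:
    def test_identical_config_identical_study(self):
        a = make_study(SimulationConfig(rows=6, cols=5, seed=11))
        b = make_study(SimulationConfig(rows=6, cols=5, seed=11))
        pd.testing.assert_frame_equal(a.outcomes, b.outcomes)
        pd.testing.assert_frame_equal(a.indicators, b.indicators)
        assert a.truth["S"] == b.truth["S"]

    def test_seed_changes_study(self):
        a = make_study(SimulationConfig(rows=6, cols=5, seed=11))
        b = make_study(SimulationConfig(rows=6, cols=5, seed=12))
        assert not a.outcomes["deaths"].equals(b.outcomes["deaths"])

    def test_truth_round_trips_config(self):
        cfg = SimulationConfig(rows=6, cols=5, seed=3, sigma_S=0.4)
        st = make_study(cfg)
        assert SimulationConfig(**{
            **st.truth["config"],
            "true_log_rr": tuple(st.truth["config"]["true_log_rr"]),
        }) == cfg or st.truth["config"]["sigma_S"] == 0.4


class TestIndicators:
    def test_zero_noise_equal_loadings_collinear(self):
        g = make_lattice(6, 5)
        cfg = SimulationConfig(rows=6, cols=5, n_indicators=2,
                               indicator_noise_sd=0.0, seed=0)
        df, specs, latent = simulate_indicators(g, cfg)
        r = np.corrcoef(df.iloc[:, 0], df.iloc[:, 1])[0, 1]
        assert abs(r - 1.0) < 1e-12
        assert all(s.polarity == "adverse" for s in specs)

    def test_zero_loadings_uncorrelated(self):
        g = make_lattice(10, 10)
        cfg = SimulationConfig(rows=10, cols=10, n_indicators=4,
                               indicator_loading=0.0, indicator_noise_sd=1.0,
                               seed=1)
        df, _, _ = simulate_indicators(g, cfg)
        corr = np.corrcoef(df.to_numpy().T)
        off = corr[~np.eye(4, dtype=bool)]
        assert np.max(np.abs(off)) < 0.3  # MC error at n=100

    def test_spatial_range_zero_gives_unstructured_latent(self):
        g = make_lattice(10, 10)
        s = icar_structure(g)
        rng = np.random.default_rng(0)
        vals = [morans_i(g, _latent_field(s, 0.0, rng)) for _ in range(200)]
        # permutation null of Moran's I has mean -1/(n-1) and SE ~ 1/sqrt(edges)
        assert abs(np.mean(vals) - (-1 / 99)) < 3 / np.sqrt(200 * 2 * 180 / 100)

    def test_spatial_range_one_gives_positive_autocorrelation(self):
        g = make_lattice(10, 10)
        s = icar_structure(g)
        rng = np.random.default_rng(0)
        vals = [morans_i(g, _latent_field(s, 1.0, rng)) for _ in range(50)]
        assert np.mean(vals) > 0.3


class TestMortality:
    def test_rate_recovery_large_n(self):
        # sigma_S = sigma_v = 0, all beta = 0: mean(O)/P -> baseline rate
        cfg = SimulationConfig(rows=50, cols=50, sigma_S=0.0, sigma_v=0.0,
                               true_log_rr=(0, 0, 0, 0), beta_age4564=0.0,
                               beta_age65=0.0, baseline_rate=0.01,
                               pop_min=1000, pop_max=1000, seed=5)
        g = make_lattice(50, 50)
        q = np.ones(2500, dtype=int)
        out, _ = simulate_mortality(g, q, np.zeros(2500), np.zeros(2500), cfg)
        rate = out["deaths"].sum() / out["pop"].sum()
        assert abs(rate / 0.01 - 1.0) < 3 / np.sqrt(25000)

    def test_heterogeneity_sd_recovered_by_delta_method(self):
        cfg = SimulationConfig(rows=10, cols=10, sigma_S=0.0, sigma_v=0.5,
                               true_log_rr=(0, 0, 0, 0), beta_age4564=0.0,
                               beta_age65=0.0, baseline_rate=0.05,
                               pop_min=20000, pop_max=20000, seed=5)
        g = make_lattice(10, 10)
        q = np.ones(100, dtype=int)
        sds = []
        for rep in range(50):
            rng = np.random.default_rng(1000 + rep)
            out, _ = simulate_mortality(g, q, np.zeros(100), np.zeros(100),
                                        cfg, rng=rng)
            sds.append(np.log(out["deaths"] / out["pop"]).std())
        assert abs(np.mean(sds) / 0.5 - 1.0) < 0.10

    def test_overflow_guard(self):
        cfg = SimulationConfig(rows=6, cols=5, baseline_rate=0.9,
                               pop_min=20_000_000, pop_max=20_000_000, seed=0)
        g = make_lattice(6, 5)
        with pytest.raises(ValueError, match="overflow"):
            simulate_mortality(g, np.ones(30, int), np.zeros(30), np.zeros(30),
                               cfg)

    def test_icar_effect_sums_to_zero_and_neighbor_correlated(self):
        st = make_study(SimulationConfig(rows=15, cols=15, sigma_S=0.5,
                                         spatial_range=1.0, seed=8))
        S = np.asarray(st.truth["S"])
        assert abs(S.sum()) < 1e-8
        pairs = st.graph.edges()
        si = np.array([S[i] for i, _ in pairs])
        sj = np.array([S[j] for _, j in pairs])
        assert np.corrcoef(si, sj)[0, 1] > 0.2


class TestLikelihoodConsistency:
    def test_generator_density_matches_model_loglik(self, small_study):
        st = small_study
        eta = np.asarray(st.truth["eta"])
        ll = loglik(eta, st.outcomes["deaths"].to_numpy(dtype=float),
                    st.outcomes["pop"].to_numpy(dtype=float))
        assert abs(ll - study_loglik_at_truth(st)) < 1e-8


class TestConfoundedScenario:
    def test_target_correlation_achieved(self):
        st = make_confounded_age_scenario(
            SimulationConfig(rows=30, cols=30, seed=4), target_r=0.6)
        r = np.corrcoef(st.outcomes["quintile"], st.outcomes["age65"])[0, 1]
        assert abs(r - 0.6) < 0.1

    def test_zero_target_independent(self):
        st = make_confounded_age_scenario(
            SimulationConfig(rows=30, cols=30, seed=4), target_r=0.0)
        r = np.corrcoef(st.outcomes["quintile"], st.outcomes["age65"])[0, 1]
        assert abs(r) < 0.1

    def test_unattainable_target_rejected(self):
        with pytest.raises(ValueError):
            make_confounded_age_scenario(
                SimulationConfig(rows=6, cols=5, seed=0), target_r=1.4)


class TestStudyIO:
    def test_write_read_round_trip(self, tiny_study, tmp_path):
        write_study(tiny_study, tmp_path)
        back = read_study(tmp_path)
        assert back.graph == tiny_study.graph
        pd.testing.assert_frame_equal(
            back.outcomes, tiny_study.outcomes, check_dtype=False)
        assert back.truth["sigma_S"] == tiny_study.truth["sigma_S"]
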