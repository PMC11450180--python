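import numpy as np
import pandas as pd
import pytest
from scipy import stats

import landgea as lg
from landgea.datatypes import MISSING
from landgea.gea import (LatentFactorMixedModel, TauResult, bonferroni_threshold,
                         calibrate_pvalues, env_per_individual, impute_missing,
                         kendall_tau_env, lfmm_fit, wza)

from conftest import build_gm, env_current


class TestImputeMissing:
    def test_population_mode_fill(self):
        G = np.array([[0], [0], [1], [MISSING]])
        out = impute_missing(build_gm(G))
        assert out[3, 0] == 0

    def test_global_mode_fallback(self):
        G = np.array([[MISSING], [MISSING], [2], [2], [1]])
        gm = build_gm(G, pops=["a", "a", "b", "b", "b"])
        out = impute_missing(gm)
        assert out[0, 0] == 2 and out[1, 0] == 2

    def test_tie_breaks_to_smaller_dosage(self):
        G = np.array([[0], [2], [MISSING]])
        assert impute_missing(build_gm(G))[2, 0] == 0

    def test_identity_without_missing(self, small_sim):
        complete = impute_missing(small_sim.gm)
        called = small_sim.gm.called_mask()
        assert np.array_equal(complete[called], small_sim.gm.genotypes[called])
        assert (complete != MISSING).all()

    def test_fully_missing_variant_rejected(self):
        G = np.array([[MISSING], [MISSING]])
        with pytest.raises(ValueError):
            impute_missing(build_gm(G))


class TestLfmm:
    def test_perfect_association_k0(self):
        rng = np.random.default_rng(0)
        n = 60
        e = rng.standard_normal(n)
        e = (e - e.mean()) / e.std()
        X = rng.standard_normal((n, 20))
        X[:, 7] = 2.0 * e
        res = lfmm_fit(X, pd.DataFrame({"env": e}), K=0, calibrate=False)
        assert res.table.loc[res.table["variant"] == 7, "p_raw"].iloc[0] < 1e-12

    def test_k0_equals_closed_form_least_squares(self):
        rng = np.random.default_rng(1)
        n, m = 80, 30
        X = rng.binomial(2, 0.4, size=(n, m)).astype(float)
        e = rng.standard_normal(n)
        res = lfmm_fit(X, pd.DataFrame({"env": e}), K=0, calibrate=False)
        es = (e - e.mean()) / e.std()
        D = np.column_stack([np.ones(n), es])
        beta_hat, *_ = np.linalg.lstsq(D, X, rcond=None)
        resid = X - D @ beta_hat
        s2 = (resid ** 2).sum(0) / (n - 2)
        se = np.sqrt(s2 * np.linalg.inv(D.T @ D)[1, 1])
        t_oracle = beta_hat[1] / se
        sub = res.for_var("env")
        assert np.allclose(sub["beta"], beta_hat[1], atol=1e-10)
        assert np.allclose(sub["z"], t_oracle, atol=1e-10)

    def test_noise_environment_is_calibrated_uniform(self, default_sim):
        rng = np.random.default_rng(42)
        e = rng.standard_normal(default_sim.gm.n_individuals)
        res = lfmm_fit(default_sim.gm, pd.DataFrame({"noise": e}), K=3)
        p = res.for_var("noise")["p_cal"].to_numpy()
        p = p[p < 1.0]  # monomorphic columns sit at exactly 1
        assert stats.kstest(p, "uniform").statistic < 0.05

    def test_planted_loci_enriched_in_tail(self, default_sim):
        E = env_per_individual(default_sim.gm, default_sim.env)[["bio6"]]
        res = lfmm_fit(default_sim.gm, E, K=3)
        p = res.for_var("bio6")["p_cal"].to_numpy()
        ad = default_sim.truth["adaptive"].to_numpy()
        n_top = int(np.ceil(0.01 * p.size))
        top = np.argsort(p)[:n_top]
        frac_planted_top = ad[top].mean()
        assert frac_planted_top > 20 * ad.mean()  # strong enrichment

    def test_invalid_k_and_constant_env_rejected(self):
        X = np.random.default_rng(0).binomial(2, 0.5, size=(20, 10)).astype(float)
        with pytest.raises(ValueError):
            lfmm_fit(X, pd.DataFrame({"e": np.arange(20.0)}), K=18)
        with pytest.raises(ValueError):
            lfmm_fit(X, pd.DataFrame({"e": np.ones(20)}), K=2)


class TestCalibratePvalues:
    def test_standard_normal_lambda_near_one(self):
        rng = np.random.default_rng(0)
        lam, _ = calibrate_pvalues(rng.standard_normal(100_000))
        assert lam == pytest.approx(1.0, abs=0.02)

    def test_rescaling_equivariance(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal(5000)
        lam1, p1 = calibrate_pvalues(z)
        lam2, p2 = calibrate_pvalues(2.0 * z)
        assert lam2 == pytest.approx(4.0 * lam1, rel=1e-12)
        assert np.allclose(p1, p2, atol=1e-12)

    def test_chi2_quantiles_map_to_uniform_grid(self):
        u = np.linspace(0.01, 0.99, 99)
        z = np.sqrt(stats.chi2.ppf(u, df=1))
        lam, p = calibrate_pvalues(z)
        # oracle: closed-form quantile transform; median of z^2 is the
        # chi2 median so lambda == chi2_median/0.456 and p = 1 - u / lam-scale
        expect = stats.chi2.sf(stats.chi2.ppf(u, 1) / lam, 1)
        assert np.allclose(p, expect, atol=1e-12)
        assert lam == pytest.approx(stats.chi2.median(1) / 0.456, rel=1e-9)

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError):
            calibrate_pvalues(np.ones(5))


class TestBonferroni:
    def test_study_scale_threshold(self):
        assert f"{bonferroni_threshold(540_566):.3g}" == "9.25e-08"

    @pytest.mark.parametrize("n,alpha,expected", [(1, 0.05, 0.05),
                                                  (1000, 0.05, 5e-5)])
    def test_small_cases(self, n, alpha, expected):
        assert bonferroni_threshold(n, alpha) == pytest.approx(expected)

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)


class TestKendallTau:
    def _freqs(self, rows, pops=5):
        cols = [f"p{i}" for i in range(pops)]
        return pd.DataFrame(rows, columns=cols)

    def test_monotone_increasing_is_one(self):
        f = self._freqs([[0.1, 0.2, 0.3, 0.4, 0.5]])
        env = pd.DataFrame({"e": [1, 2, 3, 4, 5]}, index=f.columns)
        res = kendall_tau_env(f, env)
        assert res.table["tau"].iloc[0] == pytest.approx(1.0)

    def test_anti_monotone_is_minus_one(self):
        f = self._freqs([[0.5, 0.4, 0.3, 0.2, 0.1]])
        env = pd.DataFrame({"e": [1, 2, 3, 4, 5]}, index=f.columns)
        assert kendall_tau_env(f, env).table["tau"].iloc[0] == pytest.approx(-1.0)

    def test_constant_frequency_missing(self):
        f = self._freqs([[0.3] * 5])
        env = pd.DataFrame({"e": [1, 2, 3, 4, 5]}, index=f.columns)
        out = kendall_tau_env(f, env).table
        assert np.isnan(out["tau"].iloc[0]) and np.isnan(out["p"].iloc[0])

    def test_weights_are_mean_pq(self):
        f = self._freqs([[0.1, 0.2, 0.3, 0.4, 0.5]])
        env = pd.DataFrame({"e": [1, 2, 3, 4, 5]}, index=f.columns)
        res = kendall_tau_env(f, env)
        pq = np.mean([p * (1 - p) for p in [0.1, 0.2, 0.3, 0.4, 0.5]])
        assert res.weights[0] == pytest.approx(pq)


class TestWza:
    def _tau_result(self, p_values, weights, variants):
        table = pd.DataFrame({"variant": np.arange(len(p_values)),
                              "var": "e", "tau": 0.1, "p": p_values})
        return TauResult(table=table, weights=np.asarray(weights),
                         variants=variants)

    def test_single_variant_window_equals_own_z(self):
        variants = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [100, 20_100]})
        tau = self._tau_result([0.2, 0.8], [0.3, 0.07], variants)
        out = wza(tau, variants)
        # Hazen empirical p of the two variants: 0.25 and 0.75
        z = stats.norm.ppf([1 - 0.25, 1 - 0.75])
        assert np.allclose(np.sort(out["z_w"]), np.sort(z), atol=1e-12)

    def test_equal_weights_two_variant_window(self):
        variants = pd.DataFrame({"chrom": ["chr1"] * 4,
                                 "pos": [10, 20, 30_010, 30_020]})
        # first two variants get the two smallest p -> both z > 0
        tau = self._tau_result([0.01, 0.02, 0.6, 0.9], [0.2] * 4, variants)
        out = wza(tau, variants).set_index("start")
        emp = (stats.rankdata([0.01, 0.02, 0.6, 0.9]) - 0.5) / 4
        z = stats.norm.ppf(1 - emp)
        assert out.loc[1, "z_w"] == pytest.approx((z[0] + z[1]) / np.sqrt(2),
                                                  abs=1e-12)

    def test_null_windows_are_standard_normal(self):
        rng = np.random.default_rng(0)
        n_win, per = 2000, 5
        variants = pd.DataFrame({
            "chrom": "chr1",
            "pos": np.arange(n_win * per) * (10_000 // per) + 1})
        p = rng.uniform(size=n_win * per)
        w = rng.uniform(0.05, 0.25, size=n_win * per)
        out = wza(self._tau_result(p, w, variants), variants)
        assert abs(out["z_w"].mean()) < 0.1
        assert 0.9 < out["z_w"].std() < 1.1

    def test_planted_cluster_window_ranks_first(self):
        from landgea.simulate import SimConfig, simulate_landscape
        wins = 0
        for seed in (1, 2, 3, 4, 5):
            ds = simulate_landscape(SimConfig(seed=seed))
            F = lg.allele_frequencies(ds.gm, by="population")
            e = env_current(ds, "bio6").loc[F.columns]
            tau = kendall_tau_env(F, pd.DataFrame({"bio6": e}))
            out = wza(tau, ds.gm.variants)
            top = out.sort_values("z_w", ascending=False).iloc[0]
            ad = ds.truth[ds.truth["adaptive"]]
            ad_windows = set(zip(ad["chrom"], (ad["pos"] - 1) // 10_000))
            wins += (top["chrom"], (top["start"] - 1) // 10_000) in ad_windows
        assert wins >= 4


def test_env_broadcast_to_individuals(small_sim):
    E = env_per_individual(small_sim.gm, small_sim.env)
    wide = small_sim.env[(small_sim.env["scenario"] == "current")
                         & (small_sim.env["var"] == "bio6")]
    lookup = wide.set_index("pop_id")["value"]
    expect = lookup.loc[small_sim.gm.individuals["pop_id"]].to_numpy()
    assert np.allclose(E["bio6"].to_numpy(), expect)
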