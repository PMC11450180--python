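import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gammaln

import landgea as lg
from landgea.datatypes import MISSING
from landgea.qc import (depth_mode_cutoffs, filter_variants, het_missing_outliers,
                        hwe_exact_test, ld_prune, ld_r2)

from conftest import build_gm


# -- independent enumeration oracle for the HWE exact test -------------------
#
# Exact rational arithmetic: the number of distinct diploid configurations
# with h heterozygotes given fixed allele counts is n!/(nAA! h! naa!) * 2^h,
# out of C(2n, na) equally likely allele pairings.

def hwe_oracle(n_aa, n_ab, n_bb):
    from fractions import Fraction
    from math import comb, factorial

    n = n_aa + n_ab + n_bb
    na, nb = 2 * n_aa + n_ab, 2 * n_bb + n_ab
    if na == 0 or nb == 0:
        return 1.0
    rare = min(na, nb)
    total = comb(2 * n, min(na, nb))
    probs = {}
    for h in range(rare % 2, rare + 1, 2):
        hr = (rare - h) // 2
        hc = n - h - hr
        ways = factorial(n) // (factorial(hr) * factorial(h) * factorial(hc)) * 2 ** h
        probs[h] = Fraction(ways, total)
    assert sum(probs.values()) == 1
    p_obs = probs[n_ab]
    return float(min(1, sum(p for p in probs.values() if p <= p_obs)))


class TestDepthModeCutoffs:
    def test_mode_forty(self):
        dp = np.concatenate([np.full(50, 40.0), np.linspace(10, 80, 30)])
        assert depth_mode_cutoffs(dp) == (30.0, 60.0)

    def test_mode_thirty_three_two(self):
        rng = np.random.default_rng(0)
        dp = np.concatenate([rng.normal(33.2, 0.02, 500), rng.uniform(5, 90, 200)])
        assert depth_mode_cutoffs(dp) == (24.9, 49.8)

    @pytest.mark.parametrize("d", [12.0, 33.2, 57.9])
    def test_degenerate_all_equal(self, d):
        low, high = depth_mode_cutoffs(np.full(20, d))
        assert low == round(0.75 * d, 1) and high == round(1.5 * d, 1)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            depth_mode_cutoffs([])


class TestHweExactTest:
    @pytest.mark.parametrize("counts", [(5, 0, 5), (25, 50, 25), (3, 7, 2),
                                        (0, 1, 0), (10, 5, 1)])
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(hwe_oracle(*counts),
                                                        abs=1e-12)

    def test_monomorphic_is_one(self):
        assert hwe_exact_test(17, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 9) == 1.0

    def test_modal_configuration_not_significant(self):
        assert hwe_exact_test(25, 50, 25) > 0.5

    @settings(max_examples=150, deadline=None)
    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    def test_oracle_equivalence_all_small_triples(self, a, b, c):
        if a + b + c == 0:
            return
        assert hwe_exact_test(a, b, c) == pytest.approx(hwe_oracle(a, b, c),
                                                        abs=1e-12)


class TestFilterVariants:
    def _engineered(self):
        """Six variants, one failing each filter step, one surviving."""
        rng = np.random.default_rng(1)
        n = 100
        cols = {}
        # v0: depth too low; genotypes otherwise fine
        hw = rng.binomial(2, 0.5, n)
        cols["v0"] = (hw, 5.0)
        # v1: 15% missing
        g = rng.binomial(2, 0.5, n)
        g[: int(0.15 * n)] = MISSING
        cols["v1"] = (g, 40.0)
        # v2: MAF below 0.01 (single het among 100 diploids -> 1/200)
        g = np.zeros(n, int); g[0] = 1
        cols["v2"] = (g, 40.0)
        # v3: extreme HWE deviation (all hets)
        cols["v3"] = (np.ones(n, int), 40.0)
        # v4: survivor
        cols["v4"] = (rng.binomial(2, 0.4, n), 41.0)
        # v5: depth too high
        cols["v5"] = (rng.binomial(2, 0.5, n), 90.0)
        G = np.stack([c[0] for c in cols.values()], axis=1)
        dp = np.array([c[1] for c in cols.values()])
        return build_gm(G), dp

    def test_engineered_cascade(self):
        gm, dp = self._engineered()
        out, report = filter_variants(gm, dp=dp, dp_rule=(30.0, 60.0))
        assert list(out.variants["id"]) == ["chr1:5"]  # v4 at pos 5
        steps = {r["step"]: r["n_removed"] for r in report.steps}
        assert steps == {"depth": 2, "missingness": 1, "biallelic": 0,
                         "maf": 1, "hwe": 1}
        assert report.n_input - sum(steps.values()) == report.n_output

    def test_missingness_threshold_strict(self):
        n = 100
        g = np.ones(n, int)
        g11 = g.copy(); g11[:11] = MISSING      # 11% missing -> removed
        g10 = g.copy(); g10[:10] = MISSING      # 10% missing -> kept
        gm = build_gm(np.stack([g11, g10], axis=1))
        out, _ = filter_variants(gm, maf_min=0.0, hwe_min_p=0.0)
        assert out.n_variants == 1 and out.variants["pos"].iloc[0] == 2

    def test_maf_boundary(self):
        n = 500  # 1000 alleles
        def col(alt):
            g = np.zeros(n, int); g[:alt] = 1
            return g
        gm = build_gm(np.stack([col(9), col(11)], axis=1))  # MAF 0.009 / 0.011
        out, _ = filter_variants(gm, hwe_min_p=0.0)
        assert out.n_variants == 1 and out.variants["pos"].iloc[0] == 2

    def test_idempotent_on_own_output(self, default_sim):
        gm = default_sim.gm.subset(var_idx=np.arange(800))
        dp = default_sim.dp[:800]
        out1, rep1 = filter_variants(gm, dp=dp)
        kept = np.flatnonzero(np.isin(gm.variants["id"], out1.variants["id"]))
        out2, rep2 = filter_variants(out1, dp=dp[kept])
        assert out2.n_variants == out1.n_variants

    def test_misaligned_dp_rejected(self, small_sim):
        with pytest.raises(ValueError):
            filter_variants(small_sim.gm, dp=np.ones(3))


class TestLdR2:
    def test_identical_vectors(self):
        g = np.array([0, 1, 2, 1, 0, 2])
        assert ld_r2(g, g) == pytest.approx(1.0)

    def test_perfect_negative_ld(self):
        g = np.array([0, 1, 2, 1, 0, 2])
        assert ld_r2(g, 2 - g) == pytest.approx(1.0)

    def test_orthogonal_dosage_vectors_give_zero(self):
        # constructed so the sample correlation is exactly 0
        x = np.array([0, 0, 1, 1, 2, 2])
        y = np.array([2, 0, 1, 1, 0, 2])
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(0.0, abs=1e-15)  # oracle
        assert ld_r2(x, y) == pytest.approx(0.0, abs=1e-15)

    def test_matches_direct_correlation_with_missing(self):
        rng = np.random.default_rng(5)
        a = rng.choice([0, 1, 2, MISSING], size=100, p=[0.3, 0.3, 0.3, 0.1])
        b = rng.choice([0, 1, 2, MISSING], size=100, p=[0.3, 0.3, 0.3, 0.1])
        ok = (a != MISSING) & (b != MISSING)
        oracle = np.corrcoef(a[ok], b[ok])[0, 1] ** 2
        assert ld_r2(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_monomorphic_returns_nan(self):
        assert np.isnan(ld_r2(np.zeros(10, int), np.array([0, 1] * 5)))

    def test_too_few_complete_pairs(self):
        a = np.array([1, MISSING, MISSING])
        b = np.array([1, 1, MISSING])
        with pytest.raises(ValueError):
            ld_r2(a, b)


class TestLdPrune:
    def test_duplicated_adjacent_variant(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(2, 0.5, 60)
        other = rng.binomial(2, 0.5, 60)
        gm = build_gm(np.stack([g, g, other], axis=1))
        kept = ld_prune(gm)
        assert len(kept) == 2
        assert 2 in kept  # independent variant retained

    def test_independent_variants_all_retained(self):
        rng = np.random.default_rng(1)
        G = rng.binomial(2, 0.5, size=(300, 30))
        gm = build_gm(G)
        assert len(ld_prune(gm)) == 30

    def test_two_duplicate_pairs(self):
        rng = np.random.default_rng(2)
        a, b, c = (rng.binomial(2, 0.5, 80) for _ in range(3))
        gm = build_gm(np.stack([a, a, b, c, c], axis=1))
        kept = ld_prune(gm)
        assert len(kept) == 3
        # oracle: no surviving pair with r2 > 0.2
        for i in kept:
            for j in kept:
                if i < j:
                    r2 = ld_r2(gm.genotypes[:, i], gm.genotypes[:, j])
                    assert np.isnan(r2) or r2 <= 0.2

    def test_no_high_ld_pair_survives_windows(self, default_sim):
        gm = default_sim.gm.subset(var_idx=np.arange(300))
        kept = ld_prune(gm, window_size_variants=50, step=25, r2_max=0.2)
        g = gm.genotypes
        # brute force within every window over the kept set
        kept_list = list(kept)
        for w0 in range(0, 300, 25):
            win = [i for i in kept_list if w0 <= i < w0 + 50]
            for a in range(len(win)):
                for b in range(a + 1, len(win)):
                    r2 = ld_r2(g[:, win[a]], g[:, win[b]])
                    assert np.isnan(r2) or r2 <= 0.2 + 1e-12


class TestHetMissingOutliers:
    def test_high_missingness_individual_removed(self):
        rng = np.random.default_rng(0)
        G = rng.binomial(2, 0.5, size=(10, 200))
        G[0, : int(0.78 * 200)] = MISSING  # 78% missing vs ~0% for the rest
        gm = build_gm(G)
        assert gm.individuals["ind_id"][0] in het_missing_outliers(gm)

    def test_identical_individuals_no_outliers(self):
        G = np.tile(np.array([0, 1, 2, 1] * 25), (6, 1))
        gm = build_gm(G)
        assert het_missing_outliers(gm) == []

    def test_planted_heterozygosity_outlier_removed(self):
        rng = np.random.default_rng(3)
        G = rng.binomial(2, 0.5, size=(40, 500))
        G[5] = 1  # all-heterozygous individual, far above the mean
        gm = build_gm(G)
        out = het_missing_outliers(gm)
        het = (G == 1).mean(axis=1)
        z = (het[5] - np.delete(het, 5).mean()) / np.delete(het, 5).std()
        assert z > 3  # oracle: direct z-score computation
        assert gm.individuals["ind_id"][5] in out
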