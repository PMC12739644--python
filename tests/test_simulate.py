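"""Synthetic genotypes, effect sizes, summary statistics, and scenarios."""

import math

import numpy as np
import pytest

import logica as lg
from logica.errors import InvalidLDError
from logica.inference import score_test_h2
from logica.simulate import RegionTruth, _pc_scores

from conftest import ar1


class TestSimulateGenotypes:
    def test_columns_standardized(self):
        G = lg.simulate_genotypes(500, 20, 0.8, seed=1)
        np.testing.assert_allclose(G.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(G.std(axis=0), 1.0, atol=1e-10)

    def test_ar1_adjacent_correlation_attenuated_but_strong(self):
        """The Gaussian copula attenuates the latent AR(1) correlation; a
        large-sample oracle run pins the attenuated target."""
        rng = np.random.default_rng(7)
        maf = rng.uniform(0.05, 0.5, size=2)
        oracle = lg.simulate_genotypes(60_000, 2, 0.9, seed=10, maf=maf)
        target = np.corrcoef(oracle.T)[0, 1]
        G = lg.simulate_genotypes(5_000, 2, 0.9, seed=11, maf=maf)
        got = np.corrcoef(G.T)[0, 1]
        assert got == pytest.approx(target, abs=0.05)
        assert 0.5 < got < 0.9  # attenuated below the latent 0.9, still strong

    def test_zero_decay_gives_independence(self):
        G = lg.simulate_genotypes(4_000, 10, 0.0, seed=2)
        R = np.corrcoef(G.T)
        off = R[np.triu_indices(10, 1)]
        assert np.abs(off).max() < 0.08

    def test_reproducible_under_seed(self):
        a = lg.simulate_genotypes(100, 5, 0.5, seed=3)
        b = lg.simulate_genotypes(100, 5, 0.5, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_non_psd_spec_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # not PSD
        with pytest.raises(InvalidLDError):
            lg.simulate_genotypes(50, 2, {"kind": "matrix", "R": bad}, seed=0)

    def test_two_subpopulations_diverge(self):
        G = lg.simulate_genotypes(2_000, 30, 0.0, seed=4, n_subpops=2, fst=0.2)
        half = 1_000
        sep = np.abs(G[:half].mean(axis=0) - G[half:].mean(axis=0))
        assert sep.mean() > 0.05  # allele-frequency divergence visible


class TestSimulateEffects:
    def _truth(self, h1=5e-4, h2=5e-4, gamma=0.5, category="both"):
        rho = gamma * math.sqrt(h1 * h2) if category == "both" else 0.0
        return RegionTruth("r", category, h1, h2,
                           gamma if category == "both" else float("nan"), rho)

    def test_perfect_correlation_aligns_effects(self):
        b1, b2 = lg.simulate_effects(self._truth(gamma=1.0), 100, seed=0)
        np.testing.assert_allclose(b1, b2, atol=1e-12)

    def test_null_category_all_zero(self):
        t = RegionTruth("r", "null", 0.0, 0.0, float("nan"), 0.0)
        b1, b2 = lg.simulate_effects(t, 50, seed=1)
        assert not b1.any() and not b2.any()

    def test_cross_ancestry_correlation_recovered(self):
        """corr(beta1, beta2) on shared causals matches gamma = 0.5 within
        Monte-Carlo error."""
        rng = np.random.default_rng(5)
        cors = []
        for _ in range(200):
            b1, b2 = lg.simulate_effects(self._truth(gamma=0.5), 2_000, seed=rng)
            cors.append(np.corrcoef(b1, b2)[0, 1])
        cors = np.array(cors)
        se = cors.std(ddof=1) / math.sqrt(cors.size)
        assert abs(cors.mean() - 0.5) < 2 * se

    def test_sparsity_preserves_total_heritability(self):
        """Var(X beta) = beta' R beta stays at h^2 under sparse causal sets."""
        m = 400
        R = ar1(m, 0.5)
        rng = np.random.default_rng(6)
        tot = []
        for _ in range(150):
            b1, _ = lg.simulate_effects(self._truth(), m,
                                        causal_fractions=(0.1, 0.5), seed=rng)
            tot.append(b1 @ R @ b1)
        tot = np.array(tot)
        se = tot.std(ddof=1) / math.sqrt(tot.size)
        assert abs(tot.mean() - 5e-4) < 2 * se + 1e-5


class TestSimulateSummaryStats:
    def test_null_z_covariance_matches_ld(self):
        """With beta = 0 the construction implies z ~ N(0, R) given the
        panel genotypes."""
        rng = np.random.default_rng(8)
        m = 20
        G = lg.simulate_genotypes(800, m, 0.7, seed=3)
        R = G.T @ G / 800
        draws = np.array([
            lg.simulate_summary_stats(np.zeros(m), 1e5, 0.0, genotypes=G,
                                      seed=rng)
            for _ in range(2_000)])
        emp = draws.T @ draws / draws.shape[0]
        scale = np.abs(R) + 3.0 / math.sqrt(2_000)
        assert np.max(np.abs(emp - R) / scale) < 3.0

    def test_identity_ld_no_leakage(self):
        """Single causal SNP, identity LD: E[z_j] = sqrt(n) beta_j, other
        coordinates centered at zero."""
        rng = np.random.default_rng(9)
        m, n = 10, 1e4
        beta = np.zeros(m)
        beta[4] = 0.02
        draws = np.array([
            lg.simulate_summary_stats(beta, n, 4e-3, R=np.eye(m), seed=rng)
            for _ in range(2_000)])
        mean = draws.mean(axis=0)
        assert mean[4] == pytest.approx(math.sqrt(n) * 0.02, abs=0.1)
        others = np.delete(mean, 4)
        assert np.abs(others).max() < 0.1

    def test_bitwise_reproducible(self):
        m = 8
        G = lg.simulate_genotypes(200, m, 0.5, seed=1)
        a = lg.simulate_summary_stats(np.zeros(m), 1e4, 0.0, genotypes=G, seed=42)
        b = lg.simulate_summary_stats(np.zeros(m), 1e4, 0.0, genotypes=G, seed=42)
        np.testing.assert_array_equal(a, b)


class TestGenerateScenario:
    def test_exact_category_counts(self):
        cfg = lg.ScenarioConfig(K=100, m_range=(10, 10), n_ref1=100,
                                n_ref2=100, seed=0)
        _, truths = lg.generate_scenario(cfg)
        counts = {c: sum(t.category == c for t in truths)
                  for c in ("null", "one_ancestry", "both")}
        assert counts == {"null": 40, "one_ancestry": 20, "both": 40}

    def test_deterministic_under_seed(self):
        cfg = lg.ScenarioConfig(K=5, m_range=(15, 15), n_ref1=150, n_ref2=120,
                                seed=3)
        ra, ta = lg.generate_scenario(cfg)
        rb, tb = lg.generate_scenario(cfg)
        for a, b in zip(ta, tb):
            assert a.category == b.category
            np.testing.assert_array_equal(  # NaN-safe field comparison
                [a.h1_sq, a.h2_sq, a.gamma, a.rho_g],
                [b.h1_sq, b.h2_sq, b.gamma, b.rho_g])
        for a, b in zip(ra, rb):
            np.testing.assert_array_equal(a.z1, b.z1)
            np.testing.assert_array_equal(a.z2, b.z2)

    def test_truth_labels_consistent(self):
        cfg = lg.ScenarioConfig(K=30, m_range=(10, 10), n_ref1=100,
                                n_ref2=100, seed=1)
        _, truths = lg.generate_scenario(cfg)
        for t in truths:
            if t.category == "null":
                assert t.h1_sq == 0 and t.h2_sq == 0 and t.rho_g == 0
            elif t.category == "one_ancestry":
                assert (t.h1_sq == 0) != (t.h2_sq == 0)
                assert math.isnan(t.gamma)
            else:
                assert t.h1_sq > 0 and t.h2_sq > 0
                assert abs(t.rho_g - t.gamma * math.sqrt(t.h1_sq * t.h2_sq)) \
                    < 1e-18

    def test_stratification_inflates_null_score_statistics(self):
        """Unadjusted structure (two subpopulations + PC effects on the null
        phenotype) inflates the heritability score statistic on truly null
        regions relative to the clean generator."""
        stats = {}
        for strat in (False, True):
            cfg = lg.ScenarioConfig(K=40, m_range=(40, 40), n_ref1=800,
                                    n_ref2=400, frac_null=1.0, frac_one=0.0,
                                    frac_both=0.0, stratification=strat,
                                    seed=12)
            regions, _ = lg.generate_scenario(cfg)
            stats[strat] = np.mean([
                score_test_h2(rg, 1).statistic / rg.fac1.r for rg in regions])
        assert stats[True] > stats[False]


def test_pc_scores_shape():
    G = lg.simulate_genotypes(300, 40, 0.5, seed=0)
    pcs = _pc_scores(G)
    assert pcs.shape == (300, 10)
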