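"""Score tests, composite heritability p-values, LRT, BH, and the scan."""

import math

import numpy as np
import pytest
from scipy.stats import chi2

import logica as lg
from logica.errors import InsufficientRegionsError, LogicaError
from logica.inference import NullProportions, ScanConfig, score_test_h2

from conftest import ar1, make_region


class TestScoreTest:
    def test_identity_ld_collapses_to_chi_square(self):
        """Flat eigenvalue spectrum: T = sum w_i^2 referred to chi^2_r
        (with sigma_hat^2 scaled to 1)."""
        m = 6
        fac = lg.decorrelate_region(np.eye(m), 1e-6)
        z = np.array([0.5, -1.2, 0.3, 2.0, -0.7, 1.1])
        z = z / math.sqrt(np.mean(z**2))  # make sigma_hat^2 exactly 1
        rg = lg.RegionData("r", z, z, 100, 100, fac, fac)
        st = score_test_h2(rg, 1)
        assert st.statistic == pytest.approx(np.sum(z**2))
        assert st.pvalue == pytest.approx(chi2.sf(st.statistic, m), rel=1e-6)

    def test_null_pvalues_uniform_quick(self, rng):
        """Moderate-size uniformity smoke check (the full 10,000-draw oracle
        lives in the acceptance suite)."""
        m = 40
        R = ar1(m, 0.6)
        fac = lg.decorrelate_region(R, 1e-6)
        L = np.linalg.cholesky(R)
        ps = []
        for _ in range(400):
            z = L @ rng.standard_normal(m)
            rg = lg.RegionData("r", z, z, 1e5, 1e5, fac, fac)
            ps.append(score_test_h2(rg, 1).pvalue)
        ps = np.sort(ps)
        # crude KS bound at alpha ~ 1e-3
        ks = np.max(np.abs(ps - np.arange(1, 401) / 400))
        assert ks < 1.95 / math.sqrt(400)

    def test_high_power_at_printed_setting(self):
        """h2 = 5e-4, n = 3e5, m = 200: overwhelming evidence per region."""
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(20):
            rg = make_region(m=200, h1=5e-4, h2=5e-4, gamma=0.0, seed=rng)
            ps.append(score_test_h2(rg, 1).pvalue)
        assert np.median(ps) < 1e-4

    def test_invalid_ancestry(self):
        rg = make_region(m=10, seed=0)
        with pytest.raises(ValueError):
            score_test_h2(rg, 3)


class TestNullProportions:
    def test_all_null_lists_give_pi00_near_one(self, rng):
        p1 = rng.uniform(size=2000)
        p2 = rng.uniform(size=2000)
        props = lg.estimate_null_proportions(p1, p2)
        assert props.pi_00 == pytest.approx(1.0, abs=0.1)

    def test_one_ancestry_signal_gives_pi10_mass(self, rng):
        """Ancestry 1 all non-null (tiny p), ancestry 2 null: the H10 slot
        (h1 != 0, h2 = 0) absorbs the mass."""
        p1 = np.full(2000, 1e-9)
        p2 = rng.uniform(size=2000)
        props = lg.estimate_null_proportions(p1, p2)
        assert props.pi_10 == pytest.approx(1.0, abs=0.1)
        assert props.pi_00 < 0.1

    def test_sum_at_most_one(self, rng):
        for _ in range(20):
            p1 = rng.uniform(size=50) ** rng.uniform(0.2, 3)
            p2 = rng.uniform(size=50) ** rng.uniform(0.2, 3)
            props = lg.estimate_null_proportions(p1, p2)
            assert props.pi_00 + props.pi_01 + props.pi_10 <= 1.0 + 1e-9
            assert props.pi_11 >= 0.0

    def test_too_few_regions(self):
        with pytest.raises(InsufficientRegionsError):
            lg.estimate_null_proportions(np.ones(5), np.ones(5))


class TestCompositePvalue:
    def test_textbook_arithmetic(self):
        props = NullProportions(pi_00=0.6, pi_01=0.3, pi_10=0.1)
        p = lg.composite_h2_pvalue(0.02, 0.1, props)
        assert p == pytest.approx(0.4 * 0.1 + 0.6 * 0.01)

    def test_boundary_p_one(self):
        props = NullProportions(pi_00=0.5, pi_01=0.25, pi_10=0.25)
        assert lg.composite_h2_pvalue(1.0, 1.0, props) == 1.0

    def test_pure_double_null_square_law(self):
        props = NullProportions(pi_00=1.0, pi_01=0.0, pi_10=0.0)
        assert lg.composite_h2_pvalue(0.3, 0.2, props) == pytest.approx(0.09)

    def test_invalid_inputs(self):
        props = NullProportions(pi_00=1.0, pi_01=0.0, pi_10=0.0)
        with pytest.raises(ValueError):
            lg.composite_h2_pvalue(-0.1, 0.5, props)


class TestLRT:
    def _fits(self, seed=0, gamma=0.9):
        rg = make_region(m=40, gamma=gamma, seed=seed)
        return lg.fit_pxem(rg), lg.fit_null_rho(rg)

    def test_identical_fits_give_p_one(self):
        alt, null = self._fits()
        alt.loglik = null.loglik
        T, p = lg.lrt_rho(alt, null)
        assert T == 0.0 and p == 1.0

    def test_chi2_quantile_arithmetic(self):
        alt, null = self._fits()
        alt.loglik = null.loglik + 1.920729410347062  # chi2_1 95th pct / 2
        T, p = lg.lrt_rho(alt, null)
        assert T == pytest.approx(3.8415, abs=1e-3)
        assert p == pytest.approx(0.05, abs=1e-4)

    def test_region_mismatch_rejected(self):
        alt, _ = self._fits(seed=0)
        _, null = self._fits(seed=1)
        null.region_id = "other_region"
        with pytest.raises(LogicaError):
            lg.lrt_rho(alt, null)


class TestBH:
    @pytest.mark.parametrize("raw,expected", [
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([0.2], [0.2]),
        ([0.04, 0.5], [0.08, 0.5]),
    ])
    def test_step_up_arithmetic(self, raw, expected):
        np.testing.assert_allclose(lg.bh_adjust(raw), expected, atol=1e-12)

    def test_monotone_and_bounded(self, rng):
        p = rng.uniform(size=100)
        adj = lg.bh_adjust(p)
        assert np.all(adj <= 1.0) and np.all(adj >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestGenomeScan:
    def _small_scan(self, K=24, screen=True, seed=5, threads=1):
        cfg = lg.ScenarioConfig(K=K, m_range=(40, 40), n_ref1=500, n_ref2=300,
                                seed=seed)
        regions, truths = lg.generate_scenario(cfg)
        results = lg.run_genome_scan(
            regions, ScanConfig(screen=screen, threads=threads))
        return regions, truths, results

    def test_every_region_gets_a_row_with_estimates(self):
        _, _, results = self._small_scan()
        assert len(results) == 24
        for res in results:
            assert np.isfinite(res.h1_sq) and np.isfinite(res.h2_sq)
            assert 0.0 <= res.p_composite_bh <= 1.0
            assert res.category in (1, 2, 3)

    def test_screened_out_regions_carry_no_lrt(self):
        _, _, results = self._small_scan()
        for res in results:
            if "screened_out" in res.flags:
                assert math.isnan(res.p_rho)
                assert math.isnan(res.T_lrt)

    def test_screening_consistency(self):
        """Screening only restricts which regions are LRT-tested; estimates
        agree on the tested subset, and the no-screen run is a superset."""
        _, _, with_screen = self._small_scan(screen=True)
        _, _, without = self._small_scan(screen=False)
        tested_s = {r.region_id for r in with_screen if np.isfinite(r.p_rho)}
        tested_n = {r.region_id for r in without if np.isfinite(r.p_rho)}
        assert tested_s <= tested_n
        by_id = {r.region_id: r for r in without}
        for r in with_screen:
            if r.region_id in tested_s:
                assert r.p_rho == pytest.approx(by_id[r.region_id].p_rho,
                                                abs=1e-10)

    def test_single_region_scan_bh_equals_raw(self):
        cfg = lg.ScenarioConfig(K=1, m_range=(30, 30), n_ref1=400, n_ref2=300,
                                frac_null=0.0, frac_one=0.0, frac_both=1.0,
                                seed=9)
        regions, _ = lg.generate_scenario(cfg)
        results = lg.run_genome_scan(regions, ScanConfig(screen=False))
        assert len(results) == 1
        res = results[0]
        assert res.p_rho_bh == pytest.approx(res.p_rho)
        assert res.p_composite_bh == pytest.approx(res.p_composite)

    def test_threaded_scan_identical(self):
        _, _, seq = self._small_scan(threads=1)
        _, _, par = self._small_scan(threads=2)
        for a, b in zip(seq, par):
            assert a.region_id == b.region_id
            assert a.h1_sq == b.h1_sq and a.rho_g == b.rho_g
            assert (a.p_rho == b.p_rho) or (
                math.isnan(a.p_rho) and math.isnan(b.p_rho))

    def test_empty_scan_rejected(self):
        with pytest.raises(ValueError):
            lg.run_genome_scan([])
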