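"""Hypothesis testing and the two-step genome scan.

Per region the workflow is:

1. *Heritability screening.*  For each ancestry a score-type statistic
   ``T_a = w_a' diag(d_a) w_a`` is referred to its null law — a mixture
   ``sum_i sigma_a^2 d_{a,i} chi^2_1`` — giving per-ancestry p-values
   ``p_1, p_2``.  Because the null "heritable in both ancestries" hypothesis
   is composite (a union of three sub-nulls), the per-region joint p-value is

       p = (pi_01 + pi_10) p_max + pi_00 p_max^2,     p_max = max(p_1, p_2),

   with the sub-null proportions estimated genome-wide by a Storey-type
   estimator under a cross-region independence working assumption.

2. *Genetic-covariance LRT.*  For regions passing the (optional) BH screen
   on the composite p-value, the model is fitted under the alternative and
   under ``rho_g = 0`` and ``T_LRT = 2 (l_alt - l_null)`` is referred to
   chi-square with 1 df.

Benjamini-Hochberg adjustment is applied across regions separately for the
composite and LRT p-values, and each region receives one of three labels:
category 1 (no evidence of heritability in either ancestry), category 3
(heritable in both ancestries with significant genetic correlation), and
category 2 (everything in between).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientRegionsError, LogicaError
from .estimation import FitConfig, FitResult, fit_null_rho, fit_pxem, genetic_correlation
from .mixturechi2 import indefinite_quad_sf, wchi2_sf
from .region import RegionData

__all__ = [
    "NullProportions",
    "RegionTestResult",
    "ScanConfig",
    "ScoreTest",
    "score_test_h2",
    "estimate_null_proportions",
    "composite_h2_pvalue",
    "lrt_rho",
    "bh_adjust",
    "run_genome_scan",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoreTest:
    statistic: float
    pvalue: float
    method: str  # tail evaluation route: "imhof" or "liu"


@dataclass(frozen=True)
class NullProportions:
    """Estimated proportions of the three heritability sub-nulls.

    ``pi_00``: both ancestries null; ``pi_01``: ancestry 1 null only;
    ``pi_10``: ancestry 2 null only.  The both-heritable remainder is
    ``1 - pi_00 - pi_01 - pi_10``.
    """

    pi_00: float
    pi_01: float
    pi_10: float

    def __post_init__(self) -> None:
        for v in (self.pi_00, self.pi_01, self.pi_10):
            if not 0.0 <= v <= 1.0 + 1e-12:
                raise ValueError("proportions must lie in [0, 1]")
        if self.pi_00 + self.pi_01 + self.pi_10 > 1.0 + 1e-9:
            raise ValueError("sub-null proportions must sum to at most 1")

    @property
    def pi_11(self) -> float:
        return max(0.0, 1.0 - self.pi_00 - self.pi_01 - self.pi_10)


@dataclass
class RegionTestResult:
    """Per-region scan output row."""

    region_id: str
    m: int
    h1_sq: float = float("nan")
    h2_sq: float = float("nan")
    rho_g: float = float("nan")
    gamma_g: float = float("nan")
    p1: float = float("nan")
    p2: float = float("nan")
    p_composite: float = float("nan")
    p_composite_bh: float = float("nan")
    T_lrt: float = float("nan")
    p_rho: float = float("nan")
    p_rho_bh: float = float("nan")
    category: int = 0
    flags: list[str] = field(default_factory=list)
    chrom: str | None = None
    start: int | None = None
    end: int | None = None


@dataclass(frozen=True)
class ScanConfig:
    """Genome-scan settings.

    ``threads`` parallelizes the per-region model fits; regions are
    independent, so results are identical regardless of thread count.
    """

    fit: FitConfig = field(default_factory=FitConfig)
    screen: bool = True
    screen_threshold: float = 0.05
    alpha: float = 0.05
    storey_lambda: float = 0.5
    threads: int = 1


def score_test_h2(region: RegionData, ancestry: int) -> ScoreTest:
    """Score-type test of zero local heritability in one ancestry.

    Under ``h^2 = 0`` the whitened scores are iid N(0, sigma^2) and the
    statistic ``T = w' diag(d) w`` follows the positively weighted mixture
    ``sum_i sigma^2 d_i chi^2_1``.  When a confounding intercept fixes
    ``sigma^2``, the mixture tail is evaluated directly at T.  When
    ``sigma^2`` must be estimated from the same region (its null MLE is
    ``mean(w^2)``), the plug-in mixture is miscalibrated at moderate rank
    because T and ``sigma_hat^2`` are correlated; the exact scale-invariant
    form is used instead:

        p = P( sum_i (d_i - r0) chi^2_1 > 0 ),    r0 = T / (w'w),

    which is the same mixture-of-chi-squares family with the estimation of
    ``sigma^2`` accounted for exactly (the unknown scale cancels from the
    ratio).  For near-flat eigenvalue spectra the ratio is degenerate
    (``h^2`` and ``sigma^2`` are confounded) and the plug-in form is used,
    flagged by the region's weak-identifiability marker.
    """
    if ancestry not in (1, 2):
        raise ValueError("ancestry must be 1 or 2")
    w = region.w1 if ancestry == 1 else region.w2
    fac = region.fac1 if ancestry == 1 else region.fac2
    d = fac.eigenvalues
    lam = region.lambda1 if ancestry == 1 else region.lambda2
    if d.size == 0:
        raise LogicaError("no retained eigenvalues; cannot test")
    T = float(w @ (d * w))
    if lam != 1.0:
        tail = wchi2_sf(T, float(lam) * d)
    elif fac.weakly_identified or d.size < 2:
        sigma2 = max(float(np.mean(w**2)), 1e-12)
        tail = wchi2_sf(T, sigma2 * d)
    else:
        r0 = T / max(float(w @ w), 1e-300)
        tail = indefinite_quad_sf(0.0, d - r0)
    return ScoreTest(statistic=T, pvalue=tail.pvalue, method=tail.method)


def estimate_null_proportions(
    p1_list: np.ndarray, p2_list: np.ndarray, storey_lambda: float = 0.5
) -> NullProportions:
    """Storey-type estimation of the three sub-null proportions.

    Per ancestry, ``pi0 = #{p > lambda} / ((1 - lambda) K)`` (clipped to
    [0, 1]); the three joint proportions follow from a cross-region
    independence working assumption and are renormalized if their sum
    exceeds one.
    """
    p1 = np.asarray(p1_list, float)
    p2 = np.asarray(p2_list, float)
    if p1.size != p2.size:
        raise ValueError("p-value lists must have equal length")
    K = p1.size
    if K < 20:
        raise InsufficientRegionsError(
            f"need >= 20 regions to estimate null proportions, got {K}")
    if not 0.0 < storey_lambda < 1.0:
        raise ValueError("storey_lambda must be in (0, 1)")

    def pi0(p: np.ndarray) -> float:
        return float(np.clip(np.mean(p > storey_lambda) / (1.0 - storey_lambda),
                             0.0, 1.0))

    pi0_1, pi0_2 = pi0(p1), pi0(p2)
    pi_00 = pi0_1 * pi0_2
    pi_01 = pi0_1 * (1.0 - pi0_2)
    pi_10 = (1.0 - pi0_1) * pi0_2
    total = pi_00 + pi_01 + pi_10
    if total > 1.0:
        pi_00, pi_01, pi_10 = (v / total for v in (pi_00, pi_01, pi_10))
    return NullProportions(pi_00=pi_00, pi_01=pi_01, pi_10=pi_10)


def composite_h2_pvalue(p1: float, p2: float, props: NullProportions) -> float:
    """Composite p-value for "heritable in both ancestries":
    ``(pi_01 + pi_10) p_max + pi_00 p_max^2`` with ``p_max = max(p1, p2)``."""
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValueError("p-values must lie in [0, 1]")
    p_max = max(p1, p2)
    p = (props.pi_01 + props.pi_10) * p_max + props.pi_00 * p_max**2
    return float(np.clip(p, 0.0, 1.0))


def lrt_rho(alt: FitResult, null: FitResult) -> tuple[float, float]:
    """Likelihood-ratio test of zero local genetic covariance.

    ``T = 2 (l_alt - l_null)`` clipped at zero, referred to chi-square with
    one degree of freedom.
    """
    if alt.region_id != null.region_id:
        raise LogicaError(
            f"fits come from different regions: {alt.region_id!r} vs "
            f"{null.region_id!r}")
    if alt.loglik < null.loglik - 1e-8:
        raise LogicaError("alternative log-likelihood below null beyond slack; "
                          "refit with tighter tolerance")
    T = max(0.0, 2.0 * (alt.loglik - null.loglik))
    return T, float(chi2.sf(T, 1))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_genome_scan(
    regions: list[RegionData], config: ScanConfig | None = None
) -> list[RegionTestResult]:
    """Two-step scan over a list of harmonized regions.

    Step 1 computes per-ancestry score tests and the BH-adjusted composite
    heritability p-value for every region.  Step 2 fits the bivariate model
    (alternative and rho_g = 0 null) and performs the genetic-covariance LRT
    on the regions passing the composite screen — or on all regions when
    screening is off.  Null (univariate) fits run for every region, so each
    row always carries heritability estimates; per-region failures are
    recorded as flags and never abort the scan.
    """
    config = config or ScanConfig()
    if len(regions) == 0:
        raise ValueError("need at least one region")
    results = [RegionTestResult(region_id=rg.region_id, m=rg.m, chrom=rg.chrom,
                                start=rg.start, end=rg.end) for rg in regions]

    # step 1: score tests
    for rg, res in zip(regions, results):
        if rg.weakly_identified:
            res.flags.append("weak_identifiability")
        try:
            res.p1 = score_test_h2(rg, 1).pvalue
            res.p2 = score_test_h2(rg, 2).pvalue
        except LogicaError as exc:
            logger.warning("score test failed on region %s: %s", rg.region_id, exc)
            res.flags.append("score_test_failed")

    scored = [res for res in results if "score_test_failed" not in res.flags]
    p1s = np.array([res.p1 for res in scored])
    p2s = np.array([res.p2 for res in scored])
    if len(scored) >= 20:
        props = estimate_null_proportions(p1s, p2s, config.storey_lambda)
    else:
        # too few regions for Storey estimation; fall back to the most
        # conservative mixture (everything under the double null)
        props = NullProportions(pi_00=1.0, pi_01=0.0, pi_10=0.0)
    for res in scored:
        res.p_composite = composite_h2_pvalue(res.p1, res.p2, props)
    adj = bh_adjust([res.p_composite for res in scored])
    for res, a in zip(scored, adj):
        res.p_composite_bh = float(a)

    # step 2: fits and LRT (regions are independent; optionally threaded)
    def fit_one(rg: RegionData, res: RegionTestResult) -> None:
        screened_out = (config.screen
                        and not (res.p_composite_bh < config.screen_threshold))
        try:
            null_fit = fit_null_rho(rg, config.fit)
            res.h1_sq = null_fit.vc.h1_sq
            res.h2_sq = null_fit.vc.h2_sq
            if screened_out:
                res.flags.append("screened_out")
                res.rho_g = 0.0
                res.gamma_g = genetic_correlation(null_fit.vc)
                return
            alt_fit = fit_pxem(rg, config.fit)
            res.h1_sq = alt_fit.vc.h1_sq
            res.h2_sq = alt_fit.vc.h2_sq
            res.rho_g = alt_fit.vc.rho_g
            res.gamma_g = alt_fit.gamma_g
            if alt_fit.boundary:
                res.flags.append("boundary")
            if not alt_fit.converged:
                res.flags.append("not_converged")
            res.T_lrt, res.p_rho = lrt_rho(alt_fit, null_fit)
        except LogicaError as exc:
            logger.warning("fit failed on region %s: %s", rg.region_id, exc)
            res.flags.append("fit_failed")

    if config.threads > 1:
        from concurrent.futures import ThreadPoolExecutor

        with ThreadPoolExecutor(max_workers=config.threads) as pool:
            list(pool.map(fit_one, regions, results))
    else:
        for rg, res in zip(regions, results):
            fit_one(rg, res)
    tested = [res for res in results if np.isfinite(res.p_rho)]
    if tested:
        adj = bh_adjust([res.p_rho for res in tested])
        for res, a in zip(tested, adj):
            res.p_rho_bh = float(a)

    # three-category stratification
    alpha = config.alpha
    p1_adj = bh_adjust([res.p1 for res in scored])
    p2_adj = bh_adjust([res.p2 for res in scored])
    per_anc = {res.region_id: (a1, a2) for res, a1, a2 in zip(scored, p1_adj, p2_adj)}
    for res in results:
        herit_both = np.isfinite(res.p_composite_bh) and res.p_composite_bh < alpha
        corr = np.isfinite(res.p_rho_bh) and res.p_rho_bh < alpha
        a1, a2 = per_anc.get(res.region_id, (1.0, 1.0))
        if herit_both and corr:
            res.category = 3
        elif a1 >= alpha and a2 >= alpha:
            res.category = 1
        else:
            res.category = 2
    return results
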