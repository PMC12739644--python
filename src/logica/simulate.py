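"""Synthetic-data generation for calibration and power evaluation.

The generator emulates a two-ancestry GWAS world, one LD block at a time:

* *Reference genotypes* are synthetic diploid dosages with realistic allele
  frequencies (MAF ~ U(0.05, 0.5)) and controllable LD, produced by
  thresholding a latent Gaussian field (AR(1) by default) through a Gaussian
  copula into Binomial(2, MAF) counts, then column-standardized.
* *Effects* for heritable regions are drawn from the polygenic
  bivariate-normal prior: per-SNP variance ``h^2 / m_causal`` and
  cross-ancestry correlation ``gamma`` on the shared causal set.
* *Summary statistics* follow the large-GWAS emulation strategy: the
  marginal effect estimates are ``beta_hat = R beta + eps`` where the
  estimation noise comes from regressing a null phenotype
  ``N(0, 1 - h^2)`` on the reference genotypes and rescaling by
  ``sqrt(n_ref / n_target)``; Z scores are ``z = sqrt(n_target) beta_hat``.
  Under the null this yields exactly ``z ~ N(0, R)`` given the panel.

Region categories follow a 40/20/40 split between null regions (no
heritability in either ancestry), one-ancestry-heritable regions, and
both-heritable regions; heritabilities default to {3e-4, 5e-4} and genetic
correlations to {0, 0.25, 0.5, 0.75, 1}, with GWAS sample sizes of 300,000
per ancestry.  Reference panels default to 5,000 and 504 individuals — a
desk-scale stand-in for biobank-sized panels that keeps LD estimation noise
realistic for the smaller ancestry.

An optional population-stratification mode draws the panel from two
subpopulations (Balding-Nichols allele-frequency divergence) and adds the
top ten genotype principal components, with total effect variance 0.1, to
the null phenotype before the noise regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

from .errors import InvalidLDError, ValidationError
from .region import LDFactorization, RegionData, decorrelate_region

__all__ = [
    "ScenarioConfig",
    "RegionTruth",
    "simulate_genotypes",
    "simulate_effects",
    "simulate_summary_stats",
    "generate_scenario",
    "SCENARIOS",
]

_N_PCS = 10
_PC_EFFECT_VAR = 0.1
_STRAT_FST = 0.05


@dataclass(frozen=True)
class RegionTruth:
    """Generating truth for one region."""

    region_id: str
    category: str  # "null" | "one_ancestry" | "both"
    h1_sq: float
    h2_sq: float
    gamma: float  # NaN when undefined (any zero heritability)
    rho_g: float

    def __post_init__(self) -> None:
        if self.category not in {"null", "one_ancestry", "both"}:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "null" and (self.h1_sq != 0 or self.h2_sq != 0):
            raise ValueError("null regions must have zero heritability")
        if self.category == "one_ancestry" and (
                (self.h1_sq == 0) == (self.h2_sq == 0)):
            raise ValueError("one-ancestry regions need exactly one zero h2")
        if self.category == "both" and (self.h1_sq <= 0 or self.h2_sq <= 0):
            raise ValueError("both-heritable regions need two positive h2")


@dataclass(frozen=True)
class ScenarioConfig:
    """Simulation-scenario settings (defaults = the baseline setting)."""

    K: int = 200
    m_range: tuple[int, int] = (200, 200)
    frac_null: float = 0.40
    frac_one: float = 0.20
    frac_both: float = 0.40
    h2_values: tuple[float, ...] = (3e-4, 5e-4)
    gamma_values: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    n1: float = 3e5
    n2: float = 3e5
    n_ref1: int = 5000
    n_ref2: int = 504
    causal_fraction1: float = 1.0
    causal_fraction2: float = 1.0
    stratification: bool = False
    decay1: float = 0.9
    decay2: float = 0.8
    trunc_tol: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.frac_null + self.frac_one + self.frac_both - 1.0) > 1e-9:
            raise ValueError("category fractions must sum to 1")
        if self.n_ref1 < 2 or self.n_ref2 < 2:
            raise ValueError("reference panels need at least 2 individuals")
        for f in (self.causal_fraction1, self.causal_fraction2):
            if not 0.0 < f <= 1.0:
                raise ValueError("causal fractions must lie in (0, 1]")
        if self.K < 1 or self.m_range[0] < 1 or self.m_range[0] > self.m_range[1]:
            raise ValueError("invalid K or m_range")


#: named presets mirroring the six evaluation scenarios
SCENARIOS: dict[str, dict] = {
    "baseline": {},
    "sparse": {"causal_fraction1": 0.1, "causal_fraction2": 0.5},
    "stratified": {"stratification": True},
    "imbalanced": {"n2": 1e5},
    "small-panel": {"n_ref1": 5000, "n_ref2": 200},
    "small-panel-1kg": {"n_ref1": 503, "n_ref2": 504},
}


def _latent_field(n: int, m: int, ld_spec, rng: np.random.Generator) -> np.ndarray:
    """n x m latent Gaussian draws with the requested column correlation."""
    if isinstance(ld_spec, (int, float)):
        ld_spec = {"kind": "ar1", "decay": float(ld_spec)}
    if isinstance(ld_spec, np.ndarray):
        ld_spec = {"kind": "matrix", "R": ld_spec}
    kind = ld_spec.get("kind", "ar1")
    if kind == "ar1":
        decay = float(ld_spec.get("decay", 0.0))
        if not -1.0 < decay < 1.0:
            raise InvalidLDError("AR(1) decay must lie in (-1, 1)")
        Z = np.empty((n, m))
        Z[:, 0] = rng.standard_normal(n)
        innov = math.sqrt(1.0 - decay**2)
        for j in range(1, m):
            Z[:, j] = decay * Z[:, j - 1] + innov * rng.standard_normal(n)
        return Z
    if kind == "matrix":
        R = np.asarray(ld_spec["R"], float)
        if R.shape != (m, m):
            raise InvalidLDError("LD matrix shape does not match m")
        try:
            L = np.linalg.cholesky(R + 1e-10 * np.eye(m))
        except np.linalg.LinAlgError as exc:
            raise InvalidLDError("latent LD specification is not PSD") from exc
        return rng.standard_normal((n, m)) @ L.T
    raise InvalidLDError(f"unknown ld_spec kind {kind!r}")


def simulate_genotypes(
    n: int,
    m: int,
    ld_spec,
    seed=None,
    *,
    maf: np.ndarray | None = None,
    n_subpops: int = 1,
    fst: float = _STRAT_FST,
) -> np.ndarray:
    """Standardized synthetic genotypes with copula-induced LD.

    Latent Gaussian vectors with the requested correlation (``ld_spec`` is an
    AR(1) decay, an explicit latent correlation matrix, or a dict) are
    thresholded through a Gaussian copula into Binomial(2, MAF) dosages with
    MAF ~ U(0.05, 0.5), then each column is centered and scaled to unit
    standard deviation.  With ``n_subpops = 2`` the sample is split evenly
    between two subpopulations whose allele frequencies diverge under a
    Balding-Nichols model with the given ``fst`` (population structure for
    the stratification scenario).
    """
    if n < 2 or m < 1:
        raise ValueError("need n >= 2 and m >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Z = _latent_field(n, m, ld_spec, rng)
    if maf is None:
        maf = rng.uniform(0.05, 0.5, size=m)
    G = np.empty((n, m))
    if n_subpops == 1:
        pop_maf = [maf]
        pop_rows = [np.arange(n)]
    elif n_subpops == 2:
        a = (1.0 - fst) / fst
        pop_maf = [np.clip(rng.beta(maf * a, (1.0 - maf) * a), 0.01, 0.99)
                   for _ in range(2)]
        half = n // 2
        pop_rows = [np.arange(half), np.arange(half, n)]
    else:
        raise ValueError("n_subpops must be 1 or 2")
    for rows, p in zip(pop_rows, pop_maf):
        # Binomial(2, p) quantile thresholds of the latent Gaussian
        t0 = norm.ppf((1.0 - p) ** 2)
        t1 = norm.ppf(1.0 - p**2)
        g = (Z[rows] > t0[None, :]).astype(float) + (Z[rows] > t1[None, :])
        G[rows] = g
    mean = G.mean(axis=0)
    sd = G.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValidationError(f"monomorphic synthetic genotype column {bad}")
    return (G - mean) / sd


def simulate_effects(
    truth: RegionTruth,
    m: int,
    causal_fractions: tuple[float, float] = (1.0, 1.0),
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-SNP effect sizes (beta1, beta2) for one region.

    Causal SNPs are sampled per ancestry at the stated fractions; causal
    effects have per-SNP variance ``h^2 / m_causal`` (total regional
    heritability is preserved under sparsity) and cross-ancestry correlation
    ``gamma`` on the shared causal overlap.  Non-causal entries are zero.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    beta1 = np.zeros(m)
    beta2 = np.zeros(m)
    mc1 = max(1, round(causal_fractions[0] * m))
    mc2 = max(1, round(causal_fractions[1] * m))
    c1 = rng.choice(m, size=mc1, replace=False) if truth.h1_sq > 0 else np.array([], int)
    c2 = rng.choice(m, size=mc2, replace=False) if truth.h2_sq > 0 else np.array([], int)
    v1 = truth.h1_sq / mc1
    v2 = truth.h2_sq / mc2
    if truth.category == "both":
        shared = np.intersect1d(c1, c2)
        gamma = truth.gamma
        cov = gamma * math.sqrt(v1 * v2)
        cov_mat = np.array([[v1, cov], [cov, v2]])
        if shared.size:
            # eigen square root: exact for |gamma| = 1 (singular covariance)
            evals, evecs = np.linalg.eigh(cov_mat)
            L = evecs * np.sqrt(np.clip(evals, 0.0, None))
            draws = rng.standard_normal((shared.size, 2)) @ L.T
            beta1[shared] = draws[:, 0]
            beta2[shared] = draws[:, 1]
        only1 = np.setdiff1d(c1, shared)
        only2 = np.setdiff1d(c2, shared)
        beta1[only1] = rng.normal(0.0, math.sqrt(v1), size=only1.size)
        beta2[only2] = rng.normal(0.0, math.sqrt(v2), size=only2.size)
    else:
        if c1.size:
            beta1[c1] = rng.normal(0.0, math.sqrt(v1), size=c1.size)
        if c2.size:
            beta2[c2] = rng.normal(0.0, math.sqrt(v2), size=c2.size)
    return beta1, beta2


def simulate_summary_stats(
    beta: np.ndarray,
    n_target: float,
    h2: float,
    *,
    genotypes: np.ndarray | None = None,
    R: np.ndarray | None = None,
    n_ref: int | None = None,
    seed=None,
    pc_scores: np.ndarray | None = None,
    pc_effect_var: float = 0.0,
) -> np.ndarray:
    """Marginal Z scores for a GWAS of ``n_target`` individuals.

    ``beta_hat = R beta + eps`` with estimation noise from regressing a null
    phenotype ``N(0, 1 - h2)`` on the reference genotypes, rescaled by
    ``sqrt(n_ref / n_target)``; ``z = sqrt(n_target) beta_hat``.  When only
    an LD matrix ``R`` is given the equivalent noise law
    ``eps ~ N(0, (1 - h2) R / n_target)`` is drawn directly.  ``pc_scores``
    (reference-panel principal components, one column per PC) add
    unadjusted population-stratification signal of total variance
    ``pc_effect_var`` to the null phenotype.
    """
    beta = np.asarray(beta, float).ravel()
    m = beta.size
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if genotypes is not None:
        G = np.asarray(genotypes, float)
        if G.shape[1] != m:
            raise ValueError("genotype columns must match beta length")
        n_ref = G.shape[0]
        if n_ref < 2:
            raise ValueError("reference panel needs at least 2 individuals")
        Rmat = G.T @ G / n_ref
        y = rng.normal(0.0, math.sqrt(max(1.0 - h2, 1e-12)), size=n_ref)
        if pc_scores is not None and pc_effect_var > 0:
            scores = np.asarray(pc_scores, float)
            scores = (scores - scores.mean(axis=0)) / scores.std(axis=0)
            u = rng.normal(0.0, math.sqrt(pc_effect_var / scores.shape[1]),
                           size=scores.shape[1])
            y = y + scores @ u
        beta_tilde = G.T @ y / n_ref
        eps = math.sqrt(n_ref / n_target) * beta_tilde
    elif R is not None:
        Rmat = np.asarray(R, float)
        if Rmat.shape != (m, m):
            raise ValueError("R shape must match beta length")
        if n_ref is not None and n_ref < 2:
            raise ValueError("reference panel needs at least 2 individuals")
        d, u = np.linalg.eigh((Rmat + Rmat.T) / 2.0)
        d = np.clip(d, 0.0, None)
        root = u * np.sqrt(d)
        eps = root @ rng.standard_normal(m) * math.sqrt(
            max(1.0 - h2, 1e-12) / n_target)
    else:
        raise ValueError("provide genotypes or R")
    beta_hat = Rmat @ beta + eps
    return math.sqrt(n_target) * beta_hat


def _pc_scores(G: np.ndarray, k: int = _N_PCS) -> np.ndarray:
    u, s, _ = np.linalg.svd(G, full_matrices=False)
    return u[:, :k] * s[:k]


def generate_scenario(
    config: ScenarioConfig,
    *,
    return_ld: bool = False,
):
    """Generate a full scenario: per-region summary data plus ground truth.

    Region categories are assigned by exact stratified counts and shuffled;
    each region gets an independent random substream derived from the root
    seed, so the dataset is reproducible and regions are exchangeable.
    With ``return_ld=True`` a third list of per-region ``(R1, R2)`` LD
    matrices is returned (for serialization).
    """
    root = np.random.SeedSequence(config.seed)
    assign_rng = np.random.default_rng(root.spawn(1)[0])
    n_null = round(config.frac_null * config.K)
    n_one = round(config.frac_one * config.K)
    n_both = config.K - n_null - n_one
    categories = (["null"] * n_null + ["one_ancestry"] * n_one + ["both"] * n_both)
    assign_rng.shuffle(categories)
    streams = root.spawn(config.K + 1)[1:]

    regions: list[RegionData] = []
    truths: list[RegionTruth] = []
    ld_mats: list[tuple[np.ndarray, np.ndarray]] = []
    for k, (category, stream) in enumerate(zip(categories, streams)):
        rng = np.random.default_rng(stream)
        region_id = f"region_{k:04d}"
        m = int(rng.integers(config.m_range[0], config.m_range[1] + 1))

        h2_val = float(rng.choice(config.h2_values))
        if category == "null":
            h1, h2, gamma = 0.0, 0.0, float("nan")
        elif category == "one_ancestry":
            if rng.random() < 0.5:
                h1, h2 = h2_val, 0.0
            else:
                h1, h2 = 0.0, h2_val
            gamma = float("nan")
        else:
            h1 = h2 = h2_val
            gamma = float(rng.choice(config.gamma_values))
        truth = RegionTruth(region_id=region_id, category=category,
                            h1_sq=h1, h2_sq=h2, gamma=gamma,
                            rho_g=0.0 if category != "both"
                            else gamma * math.sqrt(h1 * h2))

        n_subpops = 2 if config.stratification else 1
        G1 = simulate_genotypes(config.n_ref1, m, config.decay1, rng,
                                n_subpops=n_subpops)
        G2 = simulate_genotypes(config.n_ref2, m, config.decay2, rng,
                                n_subpops=n_subpops)
        beta1, beta2 = simulate_effects(
            truth, m, (config.causal_fraction1, config.causal_fraction2), rng)
        # effective genetic covariance given the realized causal overlap
        if category == "both":
            overlap = float(beta1[(beta1 != 0) & (beta2 != 0)].size)
            mc1 = max(1, round(config.causal_fraction1 * m))
            mc2 = max(1, round(config.causal_fraction2 * m))
            truth = replace(truth, rho_g=overlap * gamma
                            * math.sqrt(h1 * h2 / (mc1 * mc2)))
        pc_kwargs1 = pc_kwargs2 = {}
        if config.stratification:
            pc_kwargs1 = {"pc_scores": _pc_scores(G1), "pc_effect_var": _PC_EFFECT_VAR}
            pc_kwargs2 = {"pc_scores": _pc_scores(G2), "pc_effect_var": _PC_EFFECT_VAR}
        z1 = simulate_summary_stats(beta1, config.n1, h1, genotypes=G1,
                                    seed=rng, **pc_kwargs1)
        z2 = simulate_summary_stats(beta2, config.n2, h2, genotypes=G2,
                                    seed=rng, **pc_kwargs2)
        R1 = G1.T @ G1 / config.n_ref1
        R2 = G2.T @ G2 / config.n_ref2
        np.fill_diagonal(R1, 1.0)
        np.fill_diagonal(R2, 1.0)
        fac1 = decorrelate_region(R1, config.trunc_tol)
        fac2 = decorrelate_region(R2, config.trunc_tol)
        regions.append(RegionData(
            region_id=region_id, z1=z1, z2=z2, n1=config.n1, n2=config.n2,
            fac1=fac1, fac2=fac2,
            snp_ids=[f"r{k}s{j}" for j in range(m)],
            chrom="1", start=k * 10_000_000, end=k * 10_000_000 + 5_000_000))
        truths.append(truth)
        if return_ld:
            ld_mats.append((R1, R2))
    if return_ld:
        return regions, truths, ld_mats
    return regions, truths
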