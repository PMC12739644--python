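"""Shared fixtures and small simulation helpers for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

import logica as lg


def ar1(m: int, rho: float) -> np.ndarray:
    """AR(1) correlation matrix: R_ij = rho^|i-j|."""
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def make_region(
    m: int = 50,
    h1: float = 5e-4,
    h2: float = 5e-4,
    gamma: float = 0.5,
    n1: float = 3e5,
    n2: float = 3e5,
    rho_ld1: float = 0.9,
    rho_ld2: float = 0.8,
    seed: int | np.random.Generator = 0,
    trunc_tol: float = 1e-4,
    region_id: str = "test_region",
    lambda1: float = 1.0,
    lambda2: float = 1.0,
) -> lg.RegionData:
    """One synthetic region simulated directly from the model's stated world
    (analytic AR(1) LD; noise drawn from its implied law N(0, (1-h^2)R/n)).

    This is the fast oracle-world generator used across the suite; the full
    reference-panel pipeline is exercised via ``generate_scenario``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    R1, R2 = ar1(m, rho_ld1), ar1(m, rho_ld2)
    cov = np.array([[h1, gamma * math.sqrt(h1 * h2)],
                    [gamma * math.sqrt(h1 * h2), h2]]) / m
    evals, evecs = np.linalg.eigh(cov)
    L = evecs * np.sqrt(np.clip(evals, 0.0, None))
    b = rng.standard_normal((m, 2)) @ L.T
    z1 = lg.simulate_summary_stats(b[:, 0], n1, h1, R=R1, seed=rng)
    z2 = lg.simulate_summary_stats(b[:, 1], n2, h2, R=R2, seed=rng)
    return lg.RegionData(
        region_id=region_id, z1=z1, z2=z2, n1=n1, n2=n2,
        fac1=lg.decorrelate_region(R1, trunc_tol),
        fac2=lg.decorrelate_region(R2, trunc_tol),
        lambda1=lambda1, lambda2=lambda2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
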