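"""Core data types and the bivariate summary-statistics likelihood.

The model treats one LD block at a time.  For ancestry ``a`` with GWAS
sample size ``n_a`` over ``m`` standardized SNPs, the marginal Z scores
``z_a = X_a' y_a / sqrt(n_a)`` follow, under a polygenic bivariate-normal
effect prior with local heritabilities ``h_a^2`` and genetic covariance
``rho_g``,

    Var(z_a)      = (n_a h_a^2 / m) R_a^2 + sigma_ea^2 R_a
    Cov(z_1, z_2) = sqrt(n_1 n_2) (rho_g / m) R_1 R_2

where ``R_a = X_a' X_a / n_a`` is the SNP-SNP correlation (LD) matrix.
All computations happen in an eigen-decorrelated ("whitened") basis
``w_a = D_a^{-1/2} U_a' z_a`` obtained from a truncated eigendecomposition
``R_a ~= U_a D_a U_a'``, in which the covariance blocks are diagonal up to
the cross-ancestry coupling ``K = U_1' U_2``:

    Var(w_a)      = sigma_ea^2 I + (n_a h_a^2 / m) D_a
    Cov(w_1, w_2) = sqrt(n_1 n_2) (rho_g / m) D_1^{1/2} K D_2^{1/2}

Log-likelihoods are reported for the whitened vector (the constant Jacobian
of the change of basis is dropped); the constant is identical for every
parameter value on a given region, so likelihood differences — which is all
inference uses — are exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import (
    BoundaryLikelihoodError,
    DegenerateLDError,
    DimensionError,
    InvalidLDError,
)

__all__ = [
    "LDFactorization",
    "RegionData",
    "VarianceComponents",
    "decorrelate_region",
    "whiten",
    "joint_loglik",
    "whitened_covariance",
]

#: relative eigenvalue cutoff used when regularizing reference-panel LD
DEFAULT_TRUNC_TOL = 1e-4

#: retained eigenvalue spread below which h2 and sigma2 are near-confounded
WEAK_IDENT_SPREAD = 1.05


@dataclass(frozen=True)
class LDFactorization:
    """Truncated eigendecomposition of one ancestry's regional LD matrix.

    ``eigenvalues`` (length ``r``) are strictly positive and descending;
    ``eigenvectors`` is the matching ``m x r`` column-orthonormal matrix.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    trunc_tol: float

    def __post_init__(self) -> None:
        d = np.asarray(self.eigenvalues, dtype=float)
        u = np.asarray(self.eigenvectors, dtype=float)
        object.__setattr__(self, "eigenvalues", d)
        object.__setattr__(self, "eigenvectors", u)
        if d.ndim != 1 or u.ndim != 2 or u.shape[1] != d.size:
            raise DimensionError("eigenvalues/eigenvectors shapes inconsistent")
        if d.size == 0:
            raise DegenerateLDError("no retained eigenvalues")
        if np.any(d <= 0) or np.any(np.diff(d) > 0):
            raise InvalidLDError("eigenvalues must be positive and non-increasing")

    @property
    def r(self) -> int:
        """Retained rank."""
        return int(self.eigenvalues.size)

    @property
    def m(self) -> int:
        """Number of SNPs the factorization was built over."""
        return int(self.eigenvectors.shape[0])

    @property
    def weakly_identified(self) -> bool:
        """True when the eigenvalue spread is too flat to separate h2 from
        the residual variance (identity-like LD)."""
        d = self.eigenvalues
        return bool(d[0] / d[-1] < WEAK_IDENT_SPREAD)

    def reconstruct(self) -> np.ndarray:
        """U diag(d) U' — the PSD reconstruction of the (truncated) LD."""
        return (self.eigenvectors * self.eigenvalues) @ self.eigenvectors.T


@dataclass(frozen=True)
class VarianceComponents:
    """Variance components of the bivariate model for one region.

    ``h1_sq``/``h2_sq`` are local heritabilities (fractions of phenotypic
    variance, in [0, 1]); ``rho_g`` is the local genetic covariance, bounded
    by ``|rho_g| <= sqrt(h1_sq * h2_sq)`` (positive semidefiniteness of the
    per-SNP effect covariance); ``sigma_e1_sq``/``sigma_e2_sq`` are the
    residual variances (> 0).
    """

    h1_sq: float
    h2_sq: float
    rho_g: float
    sigma_e1_sq: float = 1.0
    sigma_e2_sq: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.h1_sq <= 1.0 and 0.0 <= self.h2_sq <= 1.0):
            raise ValueError("heritabilities must lie in [0, 1]")
        bound = math.sqrt(self.h1_sq * self.h2_sq)
        if abs(self.rho_g) > bound * (1.0 + 1e-9) + 1e-300:
            raise ValueError(
                f"|rho_g|={abs(self.rho_g):.3g} exceeds PSD bound {bound:.3g}"
            )
        if self.sigma_e1_sq <= 0 or self.sigma_e2_sq <= 0:
            raise ValueError("residual variances must be positive")

    @property
    def gamma_g(self) -> float:
        """Local genetic correlation rho_g / sqrt(h1^2 h2^2); NaN when
        undefined (either heritability at zero)."""
        from .estimation import genetic_correlation

        return genetic_correlation(self)


@dataclass
class RegionData:
    """One LD block's harmonized summary data for two ancestries.

    ``z1``/``z2`` are the marginal Z scores over the same ordered ``snp_ids``;
    ``fac1``/``fac2`` the per-ancestry LD factorizations over that ordering;
    ``n1``/``n2`` the GWAS sample sizes.  ``lambda1``/``lambda2`` are
    confounding intercepts (LD eigenvalue regression scale); the default 1.0
    means "no adjustment" and leaves the residual variances free.
    """

    region_id: str
    z1: np.ndarray
    z2: np.ndarray
    n1: float
    n2: float
    fac1: LDFactorization
    fac2: LDFactorization
    snp_ids: list[str] | None = None
    lambda1: float = 1.0
    lambda2: float = 1.0
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    # caches filled lazily
    _w1: np.ndarray | None = field(default=None, repr=False)
    _w2: np.ndarray | None = field(default=None, repr=False)
    _K: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.z1 = np.asarray(self.z1, dtype=float).ravel()
        self.z2 = np.asarray(self.z2, dtype=float).ravel()
        m = self.z1.size
        if m < 1:
            raise DimensionError("region must contain at least one SNP")
        if self.z2.size != m:
            raise DimensionError("z1 and z2 must have equal length")
        if self.snp_ids is not None and len(self.snp_ids) != m:
            raise DimensionError("snp_ids length must match z vectors")
        if self.fac1.m != m or self.fac2.m != m:
            raise DimensionError("LD factorizations must cover the same m SNPs")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("sample sizes must be >= 1")

    @property
    def m(self) -> int:
        return int(self.z1.size)

    @property
    def w1(self) -> np.ndarray:
        """Whitened Z scores, ancestry 1."""
        if self._w1 is None:
            self._w1 = whiten(self.z1, self.fac1)
        return self._w1

    @property
    def w2(self) -> np.ndarray:
        if self._w2 is None:
            self._w2 = whiten(self.z2, self.fac2)
        return self._w2

    @property
    def cross_basis(self) -> np.ndarray:
        """K = U1' U2, the coupling between the two retained eigenbases."""
        if self._K is None:
            self._K = self.fac1.eigenvectors.T @ self.fac2.eigenvectors
        return self._K

    @property
    def weakly_identified(self) -> bool:
        return self.fac1.weakly_identified or self.fac2.weakly_identified


def decorrelate_region(R: np.ndarray, trunc_tol: float = DEFAULT_TRUNC_TOL) -> LDFactorization:
    """Eigendecompose a regional LD matrix, truncating small eigenvalues.

    Eigenpairs with eigenvalue > ``trunc_tol`` times the largest eigenvalue
    are retained, ordered descending.  Truncation regularizes rank-deficient
    reference-panel LD (a panel of n individuals supports rank <= n).

    Raises
    ------
    InvalidLDError
        if ``R`` is not square/symmetric (1e-6) or its diagonal is not 1 (1e-6).
    DegenerateLDError
        if the largest eigenvalue is not positive.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise InvalidLDError("LD matrix must be square")
    if not np.allclose(R, R.T, atol=1e-6):
        raise InvalidLDError("LD matrix must be symmetric within 1e-6")
    if not np.allclose(np.diag(R), 1.0, atol=1e-6):
        raise InvalidLDError("LD matrix diagonal must equal 1 within 1e-6")
    if not (0 < trunc_tol < 1):
        raise ValueError("trunc_tol must be in (0, 1)")
    d, u = scipy.linalg.eigh((R + R.T) / 2.0)
    # canonical ordering: descending, stable under ties (identity stays identity)
    order = np.argsort(-d, kind="stable")
    d = d[order]
    u = u[:, order]
    # canonical sign: largest-magnitude component of each eigenvector positive
    flip = u[np.abs(u).argmax(axis=0), np.arange(u.shape[1])] < 0
    u[:, flip] *= -1.0
    if d[0] <= 0:
        raise DegenerateLDError("largest eigenvalue is not positive")
    keep = d > trunc_tol * d[0]
    return LDFactorization(eigenvalues=d[keep], eigenvectors=u[:, keep], trunc_tol=trunc_tol)


def whiten(z: np.ndarray, fac: LDFactorization) -> np.ndarray:
    """Project ``z`` onto the retained eigenbasis and rescale:
    ``w = D^{-1/2} U' z`` (length ``r``)."""
    z = np.asarray(z, dtype=float).ravel()
    if z.size != fac.m:
        raise DimensionError(f"z has length {z.size}, factorization covers m={fac.m}")
    return (fac.eigenvectors.T @ z) / np.sqrt(fac.eigenvalues)


def whitened_covariance(vc: VarianceComponents, region: RegionData) -> np.ndarray:
    """Joint covariance of (w1, w2) under ``vc``: the (r1+r2) square matrix

    ``[[s1 I + a1 D1, c D1^{1/2} K D2^{1/2}], [., s2 I + a2 D2]]``

    with a_a = n_a h_a^2 / m, c = sqrt(n1 n2) rho_g / m.
    """
    d1 = region.fac1.eigenvalues
    d2 = region.fac2.eigenvalues
    m = region.m
    a1 = region.n1 * vc.h1_sq / m
    a2 = region.n2 * vc.h2_sq / m
    c = math.sqrt(region.n1 * region.n2) * vc.rho_g / m
    r1, r2 = d1.size, d2.size
    V = np.zeros((r1 + r2, r1 + r2))
    V[:r1, :r1] = np.diag(vc.sigma_e1_sq + a1 * d1)
    V[r1:, r1:] = np.diag(vc.sigma_e2_sq + a2 * d2)
    if c != 0.0:
        cross = c * (np.sqrt(d1)[:, None] * region.cross_basis * np.sqrt(d2)[None, :])
        V[:r1, r1:] = cross
        V[r1:, :r1] = cross.T
    return V


def joint_loglik(vc: VarianceComponents, region: RegionData) -> float:
    """Log-density of the whitened Z scores (w1, w2) under ``vc``.

    Computed via a Cholesky factorization of the (r1+r2)-dimensional
    whitened covariance.  Raises :class:`BoundaryLikelihoodError` when that
    covariance is not positive definite (possible at the |rho_g| boundary
    when the two truncated eigenbases do not span the same subspace); the
    caller should shrink rho_g toward the interior.
    """
    V = whitened_covariance(vc, region)
    w = np.concatenate([region.w1, region.w2])
    try:
        L = scipy.linalg.cholesky(V, lower=True)
    except scipy.linalg.LinAlgError as exc:
        raise BoundaryLikelihoodError(
            f"whitened covariance not positive definite on region {region.region_id}"
        ) from exc
    half = scipy.linalg.solve_triangular(L, w, lower=True)
    k = w.size
    return float(
        -0.5 * k * math.log(2.0 * math.pi)
        - np.sum(np.log(np.diag(L)))
        - 0.5 * half @ half
    )
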