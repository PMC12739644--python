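"""Initialization and maximum-likelihood fitting of the bivariate model.

The latent-variable view used throughout: stack the per-SNP effects
``beta = (beta_1, beta_2)`` with iid bivariate-normal prior
``(beta_1j, beta_2j) ~ N(0, [[h1^2, rho_g], [rho_g, h2^2]] / m)`` and write
the whitened Z scores as

    w_a = P_a' beta_a + eta_a,   P_a = sqrt(n_a) U_a D_a^{1/2},
    eta_a ~ N(0, sigma_ea^2 I_{r_a}).

The E-step needs only r-dimensional cross-products (``P_a' P_b`` reduces to
the eigenvalues and the basis coupling ``K = U_1' U_2``), so no m x m matrix
is ever formed.  The M-step is closed form; parameter expansion introduces
per-ancestry rescalings ``alpha_a`` of the latent effects, maximized jointly
with the other parameters and folded back via ``h_a^2 <- alpha_a^2 h_a^2``,
``rho_g <- alpha_1 alpha_2 rho_g``, which markedly accelerates convergence
while preserving the monotone-likelihood property of EM.

Constraints: heritabilities are clipped to [0, 1] and the genetic covariance
projected to ``|rho_g| <= (1 - 1e-8) sqrt(h1^2 h2^2)`` (positive
semidefiniteness of the effect prior), which keeps the whitened covariance
positive definite for positive residual variances.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg
from scipy.optimize import minimize_scalar

from .errors import (
    BoundaryLikelihoodError,
    InsufficientRankError,
    InternalConsistencyError,
)
from .region import RegionData, VarianceComponents, joint_loglik, whitened_covariance

__all__ = [
    "FitConfig",
    "FitResult",
    "init_univariate",
    "init_mom",
    "init_random",
    "fit_pxem",
    "fit_null_rho",
    "genetic_correlation",
]

logger = logging.getLogger(__name__)

_LOG2PI = math.log(2.0 * math.pi)
_H2_FLOOR = 1e-12  # below this a heritability counts as zero
_RHO_SHRINK = 1.0 - 1e-8  # keep rho_g strictly inside the PSD cone
_MONOTONE_SLACK = 1e-8


@dataclass(frozen=True)
class FitConfig:
    """Settings for the EM fit.

    ``rel_tol`` applies to ``|delta loglik| / (|loglik| + 1)``; ``init_mode``
    is one of ``{"univariate", "mom", "random", "user"}`` (``user`` requires
    ``init_vc``); ``seed`` only matters for random initialization;
    ``trunc_tol`` is recorded for provenance (truncation happens when LD is
    factorized, not here).
    """

    max_iter: int = 1000
    rel_tol: float = 1e-6
    init_mode: str = "univariate"
    trunc_tol: float = 1e-4
    seed: int | None = None
    init_vc: VarianceComponents | None = None

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be positive")
        if self.init_mode not in {"univariate", "mom", "random", "user"}:
            raise ValueError(f"unknown init_mode {self.init_mode!r}")
        if self.init_mode == "user" and self.init_vc is None:
            raise ValueError("init_mode='user' requires init_vc")


@dataclass
class FitResult:
    """Outcome of one likelihood maximization on one region."""

    vc: VarianceComponents
    loglik: float
    n_iter: int
    converged: bool
    init_mode: str
    boundary: bool
    loglik_trace: list[float] = field(default_factory=list)
    region_id: str | None = None
    weakly_identified: bool = False

    @property
    def gamma_g(self) -> float:
        return genetic_correlation(self.vc)


def genetic_correlation(vc: VarianceComponents) -> float:
    """gamma_g = rho_g / sqrt(h1^2 h2^2), or NaN when undefined.

    The correlation is undefined whenever either local heritability is zero
    (below a 1e-12 floor); the genetic covariance ``vc.rho_g`` remains the
    meaningful quantity in that case.  Returning an explicit marker instead
    of failing is deliberate: a likelihood fit never produces the negative
    heritabilities that make moment-based estimators crash.
    """
    if vc.h1_sq <= _H2_FLOOR or vc.h2_sq <= _H2_FLOOR:
        return float("nan")
    g = vc.rho_g / math.sqrt(vc.h1_sq * vc.h2_sq)
    return float(np.clip(g, -1.0, 1.0))


# ---------------------------------------------------------------------------
# univariate likelihood (initialization and the rho_g = 0 null fit)
# ---------------------------------------------------------------------------


def _univariate_loglik(w: np.ndarray, d: np.ndarray, a: float, s: float) -> float:
    """Log-density of w ~ N(0, s I + a diag(d)) in the whitened basis."""
    var = s + a * d
    return float(-0.5 * np.sum(_LOG2PI + np.log(var) + w**2 / var))


def _univariate_ml(
    w: np.ndarray,
    d: np.ndarray,
    n: float,
    m: int,
    sigma_fixed: float | None = None,
) -> tuple[float, float, float]:
    """Maximize the univariate whitened likelihood over (h2, sigma2).

    Bounded scalar search over h2 in [0, 1] with sigma2 profiled numerically
    at each candidate (or held at ``sigma_fixed``).  Returns
    ``(h2_hat, sigma2_hat, loglik)``.
    """
    w = np.asarray(w, float)
    d = np.asarray(d, float)

    def profile_sigma(a: float) -> tuple[float, float]:
        if sigma_fixed is not None:
            return sigma_fixed, _univariate_loglik(w, d, a, sigma_fixed)
        obj = lambda logs: -_univariate_loglik(w, d, a, math.exp(logs))
        res = minimize_scalar(obj, bounds=(math.log(1e-8), math.log(1e3)),
                              method="bounded", options={"xatol": 1e-10})
        return math.exp(res.x), -res.fun

    def neg_profile(h2: float) -> float:
        return -profile_sigma(n * h2 / m)[1]

    res = minimize_scalar(neg_profile, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-13})
    h2 = float(res.x)
    # the bounded optimizer never returns the exact boundary; test it explicitly
    if neg_profile(0.0) <= res.fun:
        h2 = 0.0
    s, ll = profile_sigma(n * h2 / m)
    return h2, float(s), float(ll)


def init_univariate(region: RegionData) -> VarianceComponents:
    """Per-ancestry univariate maximum likelihood, rho_g initialized to 0.

    This is the default initializer and doubles as the exact null fit for
    the genetic-covariance LRT (the model factorizes at rho_g = 0).
    """
    try:
        h1, s1, _ = _univariate_ml(
            region.w1, region.fac1.eigenvalues, region.n1, region.m,
            sigma_fixed=None if region.lambda1 == 1.0 else region.lambda1)
        h2, s2, _ = _univariate_ml(
            region.w2, region.fac2.eigenvalues, region.n2, region.m,
            sigma_fixed=None if region.lambda2 == 1.0 else region.lambda2)
    except Exception:  # pragma: no cover - defensive fallback
        logger.warning("univariate initialization failed on region %s; "
                       "falling back to method-of-moments", region.region_id)
        return init_mom(region)
    return VarianceComponents(h1_sq=h1, h2_sq=h2, rho_g=0.0,
                              sigma_e1_sq=s1, sigma_e2_sq=s2)


def init_mom(region: RegionData) -> VarianceComponents:
    """Method-of-moments initialization.

    Per ancestry, E[w_i^2] = sigma2 + (n h2 / m) d_i, so a least-squares
    regression of w_i^2 on (n/m) d_i yields slope h2 and intercept sigma2.
    The cross term uses E[w1 w2'] = sqrt(n1 n2) (rho_g/m) D1^{1/2} K D2^{1/2};
    projecting the observed outer product onto that template gives rho_g.
    Estimates are clipped into the valid cone.
    """
    if region.fac1.r < 2 or region.fac2.r < 2:
        raise InsufficientRankError("method-of-moments needs retained rank >= 2")

    def marginal(w: np.ndarray, d: np.ndarray, n: float) -> tuple[float, float]:
        x = (n / region.m) * d
        X = np.column_stack([x, np.ones_like(x)])
        (slope, intercept), *_ = np.linalg.lstsq(X, w**2, rcond=None)
        # the residual variance of a Z score is ~1 by construction; flooring
        # a negative fitted intercept well above 0 keeps the subsequent EM
        # out of the degenerate sigma -> 0 basin
        return float(np.clip(slope, 0.0, 1.0)), float(max(intercept, 1e-2))

    h1, s1 = marginal(region.w1, region.fac1.eigenvalues, region.n1)
    h2, s2 = marginal(region.w2, region.fac2.eigenvalues, region.n2)
    Q = (np.sqrt(region.fac1.eigenvalues)[:, None] * region.cross_basis
         * np.sqrt(region.fac2.eigenvalues)[None, :])
    qq = float(np.sum(Q * Q))
    if qq > 0:
        c_hat = float(region.w1 @ Q @ region.w2) / qq
        rho = region.m * c_hat / math.sqrt(region.n1 * region.n2)
    else:
        rho = 0.0
    bound = _RHO_SHRINK * math.sqrt(h1 * h2)
    rho = float(np.clip(rho, -bound, bound))
    return VarianceComponents(h1_sq=h1, h2_sq=h2, rho_g=rho,
                              sigma_e1_sq=s1, sigma_e2_sq=s2)


def init_random(region: RegionData, seed: int | None = None) -> VarianceComponents:
    """Random initialization: h2 ~ 10^U(-20, -4) per ancestry, genetic
    correlation ~ U(-0.99, 0.99), residual variances 1."""
    rng = np.random.default_rng(seed)
    h1 = 10.0 ** rng.uniform(-20.0, -4.0)
    h2 = 10.0 ** rng.uniform(-20.0, -4.0)
    gamma = rng.uniform(-0.99, 0.99)
    return VarianceComponents(h1_sq=h1, h2_sq=h2,
                              rho_g=gamma * math.sqrt(h1 * h2))


# ---------------------------------------------------------------------------
# PX-EM
# ---------------------------------------------------------------------------


class _FitContext:
    """Per-region constants shared by every E-step."""

    __slots__ = ("region", "d1", "d2", "r1", "r2", "m", "w1", "w2", "J11",
                 "J22", "J12", "sumJ11", "sumJ22", "JTJ", "JJT", "eye2")

    def __init__(self, region: RegionData) -> None:
        self.region = region
        self.d1 = region.fac1.eigenvalues
        self.d2 = region.fac2.eigenvalues
        self.r1, self.r2 = self.d1.size, self.d2.size
        self.m = region.m
        self.w1 = region.w1
        self.w2 = region.w2
        # cross-products of the design P_a = sqrt(n_a) U_a D_a^{1/2}
        self.J11 = region.n1 * self.d1              # diag of P1'P1
        self.J22 = region.n2 * self.d2
        self.J12 = math.sqrt(region.n1 * region.n2) * (
            np.sqrt(self.d1)[:, None] * region.cross_basis
            * np.sqrt(self.d2)[None, :])            # P1'P2
        self.sumJ11 = float(np.sum(self.J11))
        self.sumJ22 = float(np.sum(self.J22))
        self.JTJ = self.J12.T @ self.J12
        self.JJT = self.J12 @ self.J12.T
        self.eye2 = np.eye(self.r2)


class _EStep:
    """All sufficient statistics of one E-step at the current parameters.

    The whitened covariance ``V = [[A, C], [C', B]]`` has *diagonal* diagonal
    blocks, so everything is computed through the Schur complement
    ``S = B - C' A^{-1} C`` — one r2-dimensional Cholesky per step instead of
    an (r1+r2)-dimensional inverse.
    """

    __slots__ = ("loglik", "S11", "S22", "S12", "num1", "den1", "num2", "den2",
                 "ww1", "ww2")

    def __init__(self, ctx: _FitContext, vc: VarianceComponents) -> None:
        r1, r2, m = ctx.r1, ctx.r2, ctx.m
        J11, J22, J12 = ctx.J11, ctx.J22, ctx.J12
        w1, w2 = ctx.w1, ctx.w2
        H1, H2, rho = vc.h1_sq, vc.h2_sq, vc.rho_g
        c = rho / m  # coefficient of J12 in both the covariance cross block
        #              and the posterior-mean maps G_a

        A = vc.sigma_e1_sq + (ctx.region.n1 * H1 / m) * ctx.d1
        B = vc.sigma_e2_sq + (ctx.region.n2 * H2 / m) * ctx.d2
        ainv = 1.0 / A
        if c != 0.0:
            C = c * J12
            W = ainv[:, None] * C
            S = np.diag(B) - C.T @ W
        else:
            W = np.zeros((r1, r2))
            S = np.diag(B)
        try:
            Ls = scipy.linalg.cholesky(S, lower=True, check_finite=False)
        except scipy.linalg.LinAlgError as exc:
            raise BoundaryLikelihoodError(
                "whitened covariance lost positive definiteness during EM "
                f"on region {ctx.region.region_id}") from exc
        # V^{-1} w by block elimination
        v2 = scipy.linalg.cho_solve((Ls, True), w2 - W.T @ w1,
                                    check_finite=False)
        v1 = ainv * w1 - W @ v2
        quad = float(w1 @ v1 + w2 @ v2)
        logdet = float(np.sum(np.log(A)) + 2.0 * np.sum(np.log(np.diag(Ls))))
        self.loglik = -0.5 * ((r1 + r2) * _LOG2PI + logdet + quad)

        # V^{-1} blocks (Vinv11 = diag(ainv) - Vinv12 W')
        Vinv22 = scipy.linalg.cho_solve((Ls, True), ctx.eye2, check_finite=False)
        Vinv12 = -W @ Vinv22
        Vinv11 = -Vinv12 @ W.T
        dVinv11 = np.diag(Vinv11) + ainv

        T11 = float(dVinv11 @ J11)
        T22 = float(np.diag(Vinv22) @ J22)
        T12 = float(np.sum(Vinv12 * J12))
        q11 = float(J11 @ v1**2)
        q22 = float(J22 @ v2**2)
        q12 = float(v1 @ J12 @ v2)
        X11 = (T11 - q11) / m**2
        X12 = (T12 - q12) / m**2
        X22 = (T22 - q22) / m**2

        # posterior second moments of the per-SNP effects, summed over SNPs
        self.S11 = H1 - (H1**2 * X11 + 2 * H1 * rho * X12 + rho**2 * X22)
        self.S22 = H2 - (rho**2 * X11 + 2 * H2 * rho * X12 + H2**2 * X22)
        self.S12 = rho - (H1 * rho * X11 + (H1 * H2 + rho**2) * X12
                          + H2 * rho * X22)

        # fitted-signal moments t_a = P_a' beta_a for the residual/expansion
        # updates; the map E[t_a] = G_a V^{-1} w has G1 = [diag(g1), c J12],
        # G2 = [c J12', diag(g2)]
        g1 = H1 * J11 / m
        g2 = H2 * J22 / m
        Jv2 = J12 @ v2
        Jtv1 = J12.T @ v1
        Et1 = g1 * v1 + c * Jv2
        Et2 = c * Jtv1 + g2 * v2
        self.num1 = float(w1 @ Et1)
        self.num2 = float(w2 @ Et2)
        # tr(V^{-1} G_a' G_a) assembled from the V^{-1} blocks
        trG1 = (float(dVinv11 @ g1**2)
                + 2.0 * c * float(np.sum(Vinv12 * (g1[:, None] * J12)))
                + c**2 * float(np.sum(Vinv22 * ctx.JTJ)))
        trG2 = (c**2 * (float(np.sum(Vinv11 * ctx.JJT))
                        + float(ainv @ np.diag(ctx.JJT)))
                + 2.0 * c * float(np.sum(Vinv12 * (J12 * g2[None, :])))
                + float(np.diag(Vinv22) @ g2**2))
        self.den1 = float(Et1 @ Et1 + (H1 / m) * ctx.sumJ11 - trG1)
        self.den2 = float(Et2 @ Et2 + (H2 / m) * ctx.sumJ22 - trG2)
        self.ww1 = float(w1 @ w1)
        self.ww2 = float(w2 @ w2)


def _clip_vc(h1: float, h2: float, rho: float, s1: float, s2: float) -> VarianceComponents:
    h1 = float(np.clip(h1, 0.0, 1.0))
    h2 = float(np.clip(h2, 0.0, 1.0))
    bound = _RHO_SHRINK * math.sqrt(h1 * h2)
    rho = float(np.clip(rho, -bound, bound))
    return VarianceComponents(h1_sq=h1, h2_sq=h2, rho_g=rho,
                              sigma_e1_sq=max(s1, 1e-8), sigma_e2_sq=max(s2, 1e-8))


def _m_step(vc: VarianceComponents, e: _EStep, region: RegionData,
            expand: bool) -> VarianceComponents:
    s1_free = region.lambda1 == 1.0
    s2_free = region.lambda2 == 1.0
    r1, r2 = region.fac1.r, region.fac2.r
    if expand:
        a1 = e.num1 / e.den1 if e.den1 > 1e-300 else 1.0
        a2 = e.num2 / e.den2 if e.den2 > 1e-300 else 1.0
        h1 = a1**2 * e.S11
        h2 = a2**2 * e.S22
        rho = a1 * a2 * e.S12
        s1 = (e.ww1 - e.num1**2 / e.den1) / r1 if s1_free and e.den1 > 1e-300 \
            else ((e.ww1 - 2 * e.num1 + e.den1) / r1 if s1_free else region.lambda1)
        s2 = (e.ww2 - e.num2**2 / e.den2) / r2 if s2_free and e.den2 > 1e-300 \
            else ((e.ww2 - 2 * e.num2 + e.den2) / r2 if s2_free else region.lambda2)
    else:
        h1, h2, rho = e.S11, e.S22, e.S12
        s1 = (e.ww1 - 2 * e.num1 + e.den1) / r1 if s1_free else region.lambda1
        s2 = (e.ww2 - 2 * e.num2 + e.den2) / r2 if s2_free else region.lambda2
    return _clip_vc(h1, h2, rho, s1, s2)


def _was_clipped(vc: VarianceComponents, e: _EStep, region: RegionData) -> bool:
    """True when the plain EM update from this E-step hits a constraint
    (heritability bounds or the PSD cone), voiding the ascent guarantee."""
    bound = _RHO_SHRINK * math.sqrt(
        float(np.clip(e.S11, 0.0, 1.0)) * float(np.clip(e.S22, 0.0, 1.0)))
    return (e.S11 < 0 or e.S11 > 1 or e.S22 < 0 or e.S22 > 1
            or abs(e.S12) > bound)


def _blend_vc(a: VarianceComponents, b: VarianceComponents,
              s: float) -> VarianceComponents:
    """Convex combination (1-s) a + s b, re-projected into the valid cone."""
    lerp = lambda x, y: (1.0 - s) * x + s * y
    return _clip_vc(lerp(a.h1_sq, b.h1_sq), lerp(a.h2_sq, b.h2_sq),
                    lerp(a.rho_g, b.rho_g),
                    lerp(a.sigma_e1_sq, b.sigma_e1_sq),
                    lerp(a.sigma_e2_sq, b.sigma_e2_sq))


def _polish_stall(ctx: _FitContext, vc: VarianceComponents,
                  sigma_free: tuple[bool, bool]) -> VarianceComponents | None:
    """Derivative-free ascent from a cone-boundary stall.

    EM's projected update can stagnate on the PSD boundary even when ascent
    exists in a joint (h^2, gamma) direction.  A short quasi-Newton run in a
    box-constrained parameterization (log h^2, gamma, log sigma^2) escapes
    such points; the result is accepted only if it improves the likelihood
    (monotonicity is preserved by the caller).
    """
    from scipy.optimize import minimize

    h_floor = 1e-40
    g_eps = 1e-9

    gamma0 = 0.0
    if vc.h1_sq > h_floor and vc.h2_sq > h_floor:
        gamma0 = vc.rho_g / math.sqrt(vc.h1_sq * vc.h2_sq)
    x0 = [math.log(max(vc.h1_sq, h_floor)), math.log(max(vc.h2_sq, h_floor)),
          float(np.clip(gamma0, -1 + g_eps, 1 - g_eps))]
    bounds = [(-95.0, 0.0), (-95.0, 0.0), (-1 + g_eps, 1 - g_eps)]
    if sigma_free[0]:
        x0.append(math.log(vc.sigma_e1_sq))
        bounds.append((-20.0, 5.0))
    if sigma_free[1]:
        x0.append(math.log(vc.sigma_e2_sq))
        bounds.append((-20.0, 5.0))

    def unpack(x) -> VarianceComponents:
        h1 = min(math.exp(x[0]), 1.0)
        h2 = min(math.exp(x[1]), 1.0)
        i = 3
        s1 = math.exp(x[i]) if sigma_free[0] else ctx.region.lambda1
        i += sigma_free[0]
        s2 = math.exp(x[i]) if sigma_free[1] else ctx.region.lambda2
        return _clip_vc(h1, h2, x[2] * math.sqrt(h1 * h2), s1, s2)

    def neg_ll(x) -> float:
        try:
            return -_EStep(ctx, unpack(x)).loglik
        except BoundaryLikelihoodError:
            return 1e10

    res = minimize(neg_ll, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 200})
    return unpack(res.x)


def _initial_vc(region: RegionData, config: FitConfig) -> VarianceComponents:
    if config.init_mode == "univariate":
        return init_univariate(region)
    if config.init_mode == "mom":
        return init_mom(region)
    if config.init_mode == "random":
        return init_random(region, config.seed)
    return config.init_vc  # user


def fit_pxem(region: RegionData, config: FitConfig | None = None) -> FitResult:
    """Fit the full bivariate model by PX-EM.

    Iterates E/M steps until the relative log-likelihood change drops below
    ``config.rel_tol`` or ``config.max_iter`` is reached.  The log-likelihood
    trace is monotone up to a 1e-8 slack; when the expanded update is blocked
    by the PSD-cone projection the plain EM update is used for that
    iteration, and if that too cannot ascend (a constrained stall on the
    boundary) iteration stops.  With confounding intercepts supplied
    (``lambda != 1``) the residual variances stay fixed at the intercepts.
    """
    config = config or FitConfig()
    vc = _initial_vc(region, config)
    ctx = _FitContext(region)
    state = _EStep(ctx, vc)
    trace = [state.loglik]
    converged = False
    n_iter = 0

    def near_cone_boundary(v: VarianceComponents) -> bool:
        # EM crawls (vanishing steps without stationarity) well before the
        # projection actually binds, so treat |gamma| > 0.9 as suspect
        b = math.sqrt(v.h1_sq * v.h2_sq)
        return b > 0 and abs(v.rho_g) >= 0.9 * b

    for n_iter in range(1, config.max_iter + 1):
        cand_vc = _m_step(vc, state, region, expand=True)
        cand = _EStep(ctx, cand_vc)
        if cand.loglik < state.loglik - _MONOTONE_SLACK:
            em_vc = _m_step(vc, state, region, expand=False)
            cand_vc, cand = em_vc, _EStep(ctx, em_vc)
            if cand.loglik < state.loglik - _MONOTONE_SLACK:
                if not _was_clipped(vc, state, region):
                    raise InternalConsistencyError(
                        f"EM log-likelihood decreased by "
                        f"{state.loglik - cand.loglik:.3g} on region "
                        f"{region.region_id}")
                # PSD-cone projection can turn the M-step into a descent
                # direction; step-halve toward the projected EM candidate
                # and accept the first strict ascent
                rescued = False
                for s in (0.5, 0.25, 0.1, 0.03, 0.01):
                    blend = _blend_vc(vc, em_vc, s)
                    trial = _EStep(ctx, blend)
                    if trial.loglik > state.loglik + _MONOTONE_SLACK:
                        cand_vc, cand = blend, trial
                        rescued = True
                        break
                if not rescued:
                    converged = True  # constrained stationary point
                    break
        vc, state = cand_vc, cand
        trace.append(state.loglik)
        if n_iter % 500 == 0 and near_cone_boundary(vc):
            # EM creeps with vanishing steps along the cone boundary; jump
            # ahead with a polish, or stop if no ascent remains
            polished = _polish_stall(
                ctx, vc, (region.lambda1 == 1.0, region.lambda2 == 1.0))
            trial = _EStep(ctx, polished)
            if trial.loglik > state.loglik + max(
                    10 * _MONOTONE_SLACK,
                    config.rel_tol * (abs(state.loglik) + 1.0)):
                vc, state = polished, trial
                trace.append(state.loglik)
                continue
            converged = True
            break
        if abs(trace[-1] - trace[-2]) / (abs(trace[-1]) + 1.0) < config.rel_tol:
            converged = True
            # on the PSD-cone boundary the projected EM step can have a
            # vanishing step size without being stationary: ascent may exist
            # in a joint (h^2, gamma) direction the projection cannot take.
            # Verify with a derivative-free polish and resume EM if it helps.
            if near_cone_boundary(vc):
                polished = _polish_stall(
                    ctx, vc, (region.lambda1 == 1.0, region.lambda2 == 1.0))
                trial = _EStep(ctx, polished)
                if trial.loglik > state.loglik + max(
                        10 * _MONOTONE_SLACK,
                        config.rel_tol * (abs(state.loglik) + 1.0)):
                    vc, state = polished, trial
                    trace.append(state.loglik)
                    converged = False
                    continue
            break
    else:
        # max_iter exhausted — often slow creep toward the PSD cone
        # boundary; one polish pass recovers the remaining gap
        if near_cone_boundary(vc):
            polished = _polish_stall(
                ctx, vc, (region.lambda1 == 1.0, region.lambda2 == 1.0))
            trial = _EStep(ctx, polished)
            if trial.loglik > state.loglik + 10 * _MONOTONE_SLACK:
                vc, state = polished, trial
                trace.append(state.loglik)
    bound = math.sqrt(vc.h1_sq * vc.h2_sq)
    at_boundary = (vc.h1_sq <= _H2_FLOOR or vc.h2_sq <= _H2_FLOOR
                   or vc.h1_sq >= 1.0 - 1e-9 or vc.h2_sq >= 1.0 - 1e-9
                   or (bound > 0 and abs(vc.rho_g) >= (1.0 - 1e-6) * bound))
    return FitResult(vc=vc, loglik=trace[-1], n_iter=n_iter, converged=converged,
                     init_mode=config.init_mode, boundary=at_boundary,
                     loglik_trace=trace, region_id=region.region_id,
                     weakly_identified=region.weakly_identified)


def fit_null_rho(region: RegionData, config: FitConfig | None = None) -> FitResult:
    """Maximum likelihood under the null rho_g = 0.

    At rho_g = 0 the bivariate likelihood factorizes into the two univariate
    likelihoods, so the null fit is two independent univariate maximizations
    and its log-likelihood is their sum (in the same whitened metric as
    :func:`fit_pxem`, so the two are directly comparable for the LRT).
    """
    config = config or FitConfig()
    h1, s1, ll1 = _univariate_ml(
        region.w1, region.fac1.eigenvalues, region.n1, region.m,
        sigma_fixed=None if region.lambda1 == 1.0 else region.lambda1)
    h2, s2, ll2 = _univariate_ml(
        region.w2, region.fac2.eigenvalues, region.n2, region.m,
        sigma_fixed=None if region.lambda2 == 1.0 else region.lambda2)
    vc = VarianceComponents(h1_sq=h1, h2_sq=h2, rho_g=0.0,
                            sigma_e1_sq=s1, sigma_e2_sq=s2)
    ll = ll1 + ll2
    at_boundary = (h1 <= _H2_FLOOR or h2 <= _H2_FLOOR
                   or h1 >= 1.0 - 1e-9 or h2 >= 1.0 - 1e-9)
    return FitResult(vc=vc, loglik=ll, n_iter=1, converged=True,
                     init_mode="univariate", boundary=at_boundary,
                     loglik_trace=[ll], region_id=region.region_id,
                     weakly_identified=region.weakly_identified)
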