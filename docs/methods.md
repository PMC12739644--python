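# Methods

`logica` estimates local (per-LD-block) heritability and cross-ancestry
genetic correlation from GWAS summary statistics, using a bivariate linear
mixed model fitted by maximum likelihood. This note documents the model,
the algorithms, the synthetic-data world the tests run in, and the numerical
choices a maintainer would want to know about.

## Model

One LD block with `m` SNPs is analyzed at a time. For ancestry
`a ∈ {1, 2}` with GWAS sample size `n_a`, phenotypes and genotype columns
are centered and standardized, and the inputs are the marginal Z scores
`z_a = X_a' y_a / √n_a` and the SNP-SNP correlation (LD) matrix
`R_a = X_a' X_a / n_a` (from the GWAS sample or a reference panel). Per-SNP
effects are bivariate normal across ancestries,

    (β_1j, β_2j) ~ N(0, [[h1², ρ_g], [ρ_g, h2²]] / m),

where `h_a²` is the block's heritability in ancestry `a` and `ρ_g` the
local genetic covariance. The local genetic correlation is
`γ_g = ρ_g / √(h1² h2²)`, undefined when either heritability is zero — the
package reports an explicit NaN marker plus the covariance in that case
rather than failing (likelihood estimates can never go negative, unlike
moment estimators). Marginalizing the effects gives

    Var(z_a)      = (n_a h_a²/m) R_a² + σ_ea² R_a,
    Cov(z_1, z_2) = √(n_1 n_2) (ρ_g/m) R_1 R_2.

### Whitened representation

Each `R_a` is eigendecomposed with relative truncation: eigenpairs with
`d > trunc_tol · d_max` are retained (`trunc_tol = 1e-4` by default,
configurable). Truncation regularizes rank-deficient reference-panel LD (a
panel of n individuals supports rank at most n). In the whitened basis
`w_a = D_a^{-1/2} U_a' z_a` the covariance blocks become

    Var(w_a)      = σ_ea² I + (n_a h_a²/m) D_a,
    Cov(w_1, w_2) = √(n_1 n_2) (ρ_g/m) D_1^{1/2} (U_1'U_2) D_2^{1/2},

diagonal up to the cross-ancestry basis coupling `K = U_1'U_2`. All
log-likelihoods are densities of `(w_1, w_2)`; the whitening Jacobian is a
parameter-free constant per region and is dropped, so likelihood
*differences* (all that inference uses) are exact. Equivalence with the
dense 2m-dimensional MVN density is enforced by an oracle test.

When a block's retained eigenvalue spread is below 1.05, `h²` and `σ²` are
near-collinear (identity-like LD); the region is flagged
`weak_identifiability` rather than rejected.

## Fitting: PX-EM

Treating the effects as latent, `w_a = P_a' β_a + η_a` with
`P_a = √n_a U_a D_a^{1/2}` and `η_a ~ N(0, σ_ea² I)`. The E-step needs only
r-dimensional cross-products (never an m×m matrix), and since the diagonal
blocks of the whitened covariance are themselves diagonal, each E-step is
computed through the Schur complement of one block — one r₂-dimensional
Cholesky instead of an (r₁+r₂)-dimensional inverse (verified numerically
equivalent to the naive implementation).

The M-step is closed form. Parameter expansion adds per-ancestry scalings
`α_a` of the latent effects, jointly maximized and folded back as
`h_a² ← α_a² h_a²`, `ρ_g ← α_1 α_2 ρ_g`, `σ_a²` from the joint residual
update; this substantially accelerates the otherwise slow EM crawl.
Convergence is declared when `|Δl|/(|l|+1) < rel_tol` (default 1e-6,
max 1000 iterations).

Constraints: `h_a² ∈ [0, 1]`; `|ρ_g| ≤ (1−1e-8)·√(h1²h2²)` (PSD of the
effect prior), which keeps the whitened covariance positive definite
whenever `σ² > 0`.

**Boundary handling.** Projection onto the PSD cone can defeat EM in two
ways: the projected update can become a descent direction, or the step size
can vanish on the boundary while ascent still exists in a joint
`(h², γ)` direction. The fitter therefore (a) step-halves toward the
projected EM candidate when a decrease is detected, accepting only strict
ascent, and (b) on convergence or iteration exhaustion with `|γ̂| > 0.9`,
runs a short box-constrained quasi-Newton polish in
`(log h1², log h2², γ, log σ²)` coordinates, accepting the result only if it
improves the likelihood and resuming EM from it. The monotone-trace
invariant is preserved throughout and enforced by tests. A likelihood
decrease at an unconstrained step raises an internal-consistency error (bug
trap).

Initializations: `univariate` (default) fits each ancestry separately by a
bounded 1-D search over `h² ∈ [0,1]` with `σ²` profiled by an inner 1-D
numerical search (no closed form exists for `σ²` under a non-scalar
covariance); `mom` regresses `w_i²` on `(n/m)d_i` per ancestry and projects
the observed cross-product onto its expectation template for `ρ_g`; `random`
draws `h² ~ 10^U(−20,−4)` and `γ ~ U(−0.99, 0.99)`. The MoM intercept is
floored at 1e-2 rather than ~0: a Z score's residual variance is ~1 by
construction, and a near-zero starting `σ²` traps EM in a degenerate basin
where the genetic variance absorbs everything.

The `ρ_g = 0` null fit is two independent univariate maximizations (the
model factorizes), in the same whitened metric as the full fit, so the two
log-likelihoods are directly comparable. Because the default initializer
*is* the null fit, EM ascent automatically guarantees the nesting
`l_alt ≥ l_null`.

Confounding intercepts from LD eigenvalue regression (their estimation is
out of scope) may be supplied per ancestry as `lambda1`/`lambda2`; a value
≠ 1 fixes that ancestry's residual variance at the intercept, and only the
genetic components update. The default 1.0 means "no adjustment": residual
variances are estimated freely.

## Hypothesis testing

**Per-ancestry heritability (score-type test).** Under `h² = 0`,
`w ~ N(0, σ² I)` and `T = w' diag(d) w` follows the positively weighted
mixture `Σ σ² d_i χ²₁`. When `σ²` is fixed by a confounding intercept, the
mixture tail is evaluated at T directly. When `σ²` must be estimated from
the same region, the plug-in mixture is measurably non-uniform at moderate
rank (T and `σ̂² = mean(w²)` are correlated), so the exact scale-invariant
form is used instead: `p = P(Σ (d_i − r₀) χ²₁ > 0)` with `r₀ = T / w'w`.
The unknown scale cancels from the ratio, making the p-value exactly
uniform under the null at any rank — verified against a 10,000-draw
Monte-Carlo oracle. Near-flat spectra (where the ratio is degenerate) fall
back to the plug-in form under the weak-identifiability flag.

Mixture tails: single weights are exact scaled chi-squares; within six SDs
of the mixture mean, Imhof's characteristic-function inversion (adaptive
quadrature, ~1e-8 accuracy); beyond that a Lugannani-Rice/Kuonen
saddlepoint (a few percent relative accuracy down to the 1e-300 floor,
supports indefinite weights — validated against a 1.5e8-draw Monte-Carlo
run); Liu's four-moment match as last resort.

**Joint heritability (composite null).** "Heritable in both ancestries" has
a composite complement (h1²=0 and/or h2²=0). With per-ancestry p-values
`p_1, p_2` and estimated sub-null proportions, the combined p-value is

    p = (π̂_01 + π̂_10) p_max + π̂_00 p_max²,   p_max = max(p_1, p_2).

Sub-null proportions are estimated by a Storey estimator per ancestry
(`π₀ = #{p > λ}/((1−λ)K)`, λ = 0.5, configurable) combined under a
cross-region independence working assumption, clipped and renormalized to
sum ≤ 1. Calibration (approximate uniformity when one sub-null dominates)
is enforced by simulation tests rather than by estimator identity. With
fewer than 20 scored regions the scan falls back to the most conservative
mixture (π₀₀ = 1, giving the intersection-union square law).

**Genetic covariance (LRT).** `T = 2(l_alt − l_null)` clipped at 0,
referred to χ²₁. Because `ρ_g = 0` is interior to its parameter space
(given positive heritabilities), the standard 1-df calibration applies;
null simulations confirm nominal type-I error.

**Genome scan.** Step 1: score tests per ancestry, composite p per region,
BH across regions. Step 2: regions passing the composite screen (BH < 0.05
by default; screening can be disabled to fit every region) get the
alternative and null fits and the LRT, with BH across tested regions. Null
(univariate) fits run for *every* region, so each output row carries
heritability estimates regardless of screening; per-region failures become
flags, never aborts. Each region is labeled category 1 (no per-ancestry
evidence), 3 (heritable in both + significant correlation), or 2
(everything between). Regions are independent, so the optional thread pool
changes nothing but wall time.

## Synthetic-data world

The generator reproduces the evaluation design end to end with no external
data:

* **Reference genotypes**: latent Gaussian field with AR(1) column
  correlation (decay 0.9 / 0.8 for the two ancestries by default — dense
  local LD typical of common-variant panels), pushed through a Gaussian
  copula into Binomial(2, MAF) dosages with MAF ~ U(0.05, 0.5), then
  standardized. The copula attenuates the latent correlation; the realized
  LD is whatever the panel exhibits, exactly as with real panels.
* **Truth assignment**: exact stratified 40/20/40 split into null /
  one-ancestry-heritable / both-heritable regions; `h²` drawn from
  {3e-4, 5e-4} (the Methods-text values; a figure caption elsewhere prints
  3e-5/5e-5 — the discrepancy is unresolved upstream, and the value set is
  configurable), `γ` from {0, 0.25, 0.5, 0.75, 1} for both-heritable
  regions.
* **Effects**: bivariate normal on the causal set, per-SNP variance
  `h²/m_causal` (total regional heritability preserved under sparsity),
  correlation γ on the shared-causal overlap; the recorded truth `ρ_g`
  accounts for the realized overlap.
* **Summary statistics**: `β̂ = R̃ β + ε` where `ε` comes from regressing a
  null phenotype `N(0, 1−h²)` on the panel genotypes and rescaling by
  `√(n_ref/n_target)`; `z = √n_target β̂`. Under the null this implies
  `z ~ N(0, R̃)` given the panel (oracle-checked). Target GWAS sizes default
  to 300,000 per ancestry.
* **Stratification scenario**: the panel is drawn from two subpopulations
  (Balding-Nichols allele-frequency divergence, Fst 0.05), and the top ten
  genotype PCs with total effect variance 0.1 are added to the null
  phenotype before the noise regression.
* **Panels**: defaults are 5,000 and 504 individuals. 5,000 is a deliberate
  desk-scale stand-in for a biobank-sized panel (it is also the published
  small-panel robustness setting); 504 matches the 1000-Genomes-scale East
  Asian panel. Biobank scale (5e4) is reachable by config but not the
  default, to keep the full simulation suite within a single-CPU CI budget.
* Per-region random substreams under one root seed: datasets are bitwise
  reproducible and regions exchangeable.

What a green test does *not* establish: real LD is not AR(1)-copula
(long-range structure, MAF-LD coupling are absent), panels here are
in-sample for the z-noise (no panel-mismatch bias), and absolute MSE
magnitudes from the original biobank-scale evaluation are not reproducible
at desk scale — calibration and recovery properties are the portable
claims.

## Known limitations

* The mean of the constrained MLE of γ cannot reach a truth of |γ| = 1:
  estimates are confined to the PSD cone, so at the boundary the estimator
  is necessarily biased toward the interior (measured ≈ −0.02 to −0.04 at
  desk scale). Interior grid points recover within Monte-Carlo error.
* At very small block sizes (m ≲ 50) the likelihood can be genuinely
  multimodal in γ; different initializations may land in different modes.
  At m = 200 and realistic signal the optimum is unique in practice.
* Two ancestries only; LD blocks are consumed as inputs, never derived;
  confounding intercepts are consumed, never estimated.
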