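# Methods

## The discrepancy measure

For a continuous posterior π(θ | y) and a precise hypothesis H₀: θ = θ₀ the
Bayesian Discrepancy Measure is δ_H = 1 − 2·min(P, 1 − P) with
P = P(θ ≥ θ₀ | y).  Equivalently, δ_H is the posterior mass of the smallest
equi-tailed credible interval containing θ₀, so δ_H = 0 at the posterior
median and δ_H → 1 in the tails.  With nuisance parameters the same
definition applies to the marginal posterior of the scalar interest
parameter ψ.  For vector θ₀ the package uses center-outward ranks: the norm
of the image of θ₀ under a transport map that pushes the (approximated)
posterior to the standard normal, turned into a probability through the χ²_d
distribution.  No significance thresholds are imposed on δ_H.

All univariate methods report both a raw δ and a value clipped to [0, 1];
approximate tail areas can leave the unit interval and the raw value is
preserved in the result record.  A tail probability of exactly 1/2 reports
side "center" and δ = 0.

## Ladder of approximations

**Exact (scalar).** A model-supplied closed-form posterior CDF when
available (the exponential fixture's inverse-gamma posterior uses the
regularized incomplete gamma function); otherwise the posterior kernel is
normalized by adaptive quadrature over the window mode ± 12 posterior sd,
extended in 6-sd blocks until the added mass is below 1e−10, with absolute
tolerance 1e−8 on the tail integral.  The posterior median solves
P(θ ≥ m | y) = 1/2 by bracketed root-finding to 1e−10 in probability.

**First order.** δ ≈ 2Φ(|θ₀ − θ̂| j(θ̂)^{1/2}) − 1 with observed information
j = −ℓ″; the profile version substitutes ψ̂ and j_p(ψ̂).  For vector θ₀,
δ ≈ P(χ²_d ≤ W) with W either the likelihood-ratio statistic or the Wald
quadratic form.

**Third order (modified likelihood root).**
r\*_B(θ) = r(θ) + log(q(θ)/r(θ))/r(θ) with the likelihood root r and
q = ℓ′(θ) j(θ̂)^{−1/2} π(θ̂)/π(θ); the posterior tail is Φ(r\*_B) to
O(n^{−3/2}).  Only the prior *ratio* enters, so improper priors are fine.
A `jeffreys` variant uses expected-information ratios instead of the prior
ratio; for models where the Jeffreys prior is i(θ)^{1/2} the two coincide
(tested).  The nuisance version uses the profile root r_p and

q_B(ψ) = ℓ_p′(ψ) j_p(ψ̂)^{−1/2} · {|j_λλ(ψ, λ̂_ψ)| / |j_λλ(ψ̂, λ̂)|}^{1/2} ·
π(ψ̂, λ̂)/π(ψ, λ̂_ψ).

A user-supplied frequentist correction q_p(ψ) may replace q_B (matching-prior
route); no construction of q_p is shipped.  r\*_B is 0/0 at θ̂: for |r| <
0.05 the value is obtained by quadratic interpolation through the six points
where |r| ∈ {0.1, 0.15, 0.2} on both sides of θ̂.  Consequently the method
returns the smooth (near-exact) value at θ̂ itself rather than 0.  Credible
intervals solve |r\*_B| = z_{1−α/2} and the posterior median solves
r\*_B = 0, both by outward-walking bracketed root-finding that respects the
parameter domain.

**Skew-modal (SKS).** At the MAP θ̃, with h = √n(θ − θ̃) and
ω̃ = n j(θ̃)^{−1}, the density is 2φ(h; 0, ω̃)Φ(α̃(h)) with
α̃(h) = √(2π)/12 · ℓ⁽³⁾(θ̃) n^{−3/2} h³.  The coefficient is fixed by
requiring the linearization Φ(α̃) ≈ 1/2 + φ(0)·α̃ to reproduce the
ℓ⁽³⁾/(6n^{3/2}) tail term, which also yields the closed-form tail

P(θ ≥ θ₀ | y) ≈ 1 − Φ(z₀) + [ℓ⁽³⁾(θ̃)/(6n^{3/2})] ω̃^{3/2} φ(z₀)(z₀² + 2),
z₀ = h₀/√ω̃.

The numeric variant integrates the density directly (absolute tolerance
1e−9, window mode ± 12√ω̃ with adaptive extension) and normalizes by the
full integral; the closed and numeric routes agree exactly when ℓ⁽³⁾ = 0 and
converge to each other as n grows (both tested).

*Marginal SKS.* For interest coordinate 1 of a d-dimensional model, with
Ω = (j(θ̃)/n)^{−1}, slope b = Ω_{·1}/Ω₁₁ and conditional covariance
Σc = Ω − Ω_{·1}Ω_{1·}/Ω₁₁, the marginal skewing polynomial has coefficients

v₁,₁ = 3 Σ_{stl} ℓ⁽³⁾_{stl} b_s Σc_{tl},  v₃,₁₁₁ = Σ_{stl} ℓ⁽³⁾_{stl} b_s b_t b_l,

entering α_ψ(h) = √(2π)/12 · n^{−3/2}(v₁,₁ h + v₃,₁₁₁ h³).  These follow
from taking conditional third moments of the nuisance block in the
linearized joint density; they reduce to (0, ℓ⁽³⁾) at d = 1 and are verified
against a numerical-marginalization oracle in the tests.  The marginal BDM
is computed from the quadrature tail.

*Derivative convention.* SKS (and the SN fit below) differentiate the
log-posterior at θ̃ by default, consistent with the skew-modal construction
in which the approximation targets the posterior; a switch
(`estimate_set(use_prior_derivs=False)`) selects log-likelihood-only
derivatives for users who want the prior to enter only through the MAP.
Both conventions are legitimate readings of mode-centered expansions; the
default reproduces the worked exponential example best.

**Skew-normal + optimal transport.** The posterior is approximated by
f(x) = 2φ_d(x; ξ, Ω)Φ(αᵀ(x − ξ)) — note the shape multiplies the *raw*
deviation; the standardized Azzalini shape would be ωα.  Matching mode m,
negative Hessian j(θ̃) and unmixed third derivatives t reduces to scalar
root-finding in κ = αᵀ(m − ξ): α_i = (t_i/ζ₃(κ))^{1/3},
Ω^{−1} = j(θ̃) + ζ₂(κ)ααᵀ, m − ξ = ζ₁(κ)Ωα, residual κ − ζ₁(κ)αᵀΩα.
Since ζ₁ > 0 and Ω ≻ 0 the root satisfies κ > 0; the precision loses
positive definiteness for small κ, and the residual runs from −∞ at that
boundary to +∞ for large κ, so the solver scans a log grid, refines toward
the boundary if needed, and falls back to the Gaussian member (α = 0) with a
warning only if no bracket exists.  The ζ_k are evaluated from a log-space
inverse Mills ratio, stable to κ ≈ −40.

The transport map T = T₃∘T₂∘T₁: T₁ rotates by Q (complete QR of α, signs
fixed so the first column is α/‖α‖), after which the rotated shape is
(‖α‖, 0, …, 0) and the first coordinate is marginally SN(0, σ², ‖α‖) with
σ² = [QᵀΩQ]₁₁; T₂ Gaussianizes that coordinate through Φ⁻¹(F_SN(·)) — left
tail via the CDF, right tail via the survival function to avoid
double-precision saturation — and rescales it to the coordinate's actual
mean μ₁ and variance V₁; T₃ whitens with the symmetric inverse square root
of V = QᵀΩQ − (2/π)(Qᵀδ)(Qᵀδ)ᵀ, δ = Ωα/√(1 + αᵀΩα), centered at
μ_z = √(2/π)Qᵀδ.  T₂ is the gradient of a convex potential and T₁, T₃ are
affine, so T is an optimal transport map.  The rotated nuisance coordinates
are treated as Gaussian; this is exact only for special Ω, and the
Monte-Carlo push-forward test (mean within ±0.01 of 0, covariance within
±0.02 of I on 10⁵ samples) is the operative check.  Finally
δ = P(χ²_d ≤ ‖T(θ₀)‖²); the squared norm is required for the α = 0 case to
collapse to the MAP-centered Wald/χ² answer (tested to 1e−10), and at d = 1
the definition reduces to 2Φ(|u|) − 1.  Univariate SN marginals are computed
in closed form by conditioning the shape on the retained coordinate.

## Maximization and differentiation

MLE/MAP use BFGS with a Nelder–Mead fallback and up to five jittered
restarts (fixed jitter seed 0, so results are reproducible).  A maximum is
flagged as a boundary case (warning, not error) when stepping beyond the
returned point along the travel direction still increases the objective —
this catches monotone likelihoods such as complete separation in logistic
regression.  Central finite differences use steps ε^{1/3}, ε^{1/4}, ε^{1/5}
(× max(1, |θ_i|)) for first, second and third derivatives; the ε^{1/4}
Hessian step is the truncation/rounding optimum for second differences —
ε^{1/3} was measured rounding-dominated at ~2.6e−4 relative error versus
~4e−7 for ε^{1/4} on the logistic fixture.  Documented agreement targets
against closed forms: 1e−6 (gradients), 1e−5 (Hessians), 1e−4 (third
derivatives), relative, enforced in the tests at 20 random interior points.
Analytic derivatives, when a model supplies them (all fixtures do), are used
everywhere instead.

Profile likelihoods are cached on a user grid, maximized outward from ψ̂
with warm starts in both directions; failed grid points are flagged and
excluded.  The profile score ℓ_p′(ψ₀) and the log-determinant of the
nuisance information block are interpolated with cubic splines — on grid
interiors the spline derivative is the centered three-point stencil, and it
remains defined between grid nodes.  j_p(ψ̂) is obtained by central
differencing of ℓ_p.

## Fixtures and what the tests do (and do not) show

The exponential fixture (E(Y) = θ, Jeffreys prior, posterior inverse gamma
with shape n and rate t_n) is parameterized directly by (n, MLE); its study
conditions are n ∈ {6, 12, 20, 40} with the MLE held at 1.2.  The logistic
fixture uses independent N(0, 25) coefficient priors; because the original
27-patient endocrine study data are not bundled, a *synthetic* emulator with
the same layout (binary response, intercept plus two binary covariates,
n = 27, fixed seed) exercises the nuisance-parameter and multivariate paths.
Simulators take explicit integer seeds and never touch global random state.

Passing tests therefore demonstrate: correctness of every closed form
against independent oracles, calibration of the exact δ_H under H₀
(uniformity via KS on 2000 simulated size-20 datasets at the 1% level),
consistency under the alternative, reparametrization invariance, and
internal consistency of the approximation ladder.  They do not certify
accuracy on real, possibly misspecified data, on posteriors with multiple
modes or heavy tails (where mode-local expansions can fail), or for discrete
parameters, which are out of scope.

## Problem sizes and defaults

Default quadrature tolerances: 1e−8 (exact tails), 1e−9 (SKS).  Root-finding
tolerances: 1e−10 in probability for medians, brentq xtol 1e−12 elsewhere.
The uniformity check uses 2000 replicates, the push-forward check 10⁵
samples, and the consistency check 40 replicates per n at n ∈ {50, 200,
500} — sizes chosen so each property is sharply resolved while the whole
suite stays interactive.  The near-MLE interpolation threshold |r| < 0.05
and nodes {0.1, 0.15, 0.2} follow standard practice for r\*-type formulas.

## Known limitations

The closed-form SKS tail is a linearization and can leave [0, 1] near the
mode (raw values are reported alongside clipped ones).  The marginal SKS and
SN-marginal routes require the third-derivative tensor, whose cost grows as
d³.  The transport map treats rotated nuisance directions as exactly
Gaussian.  The higher-order vector-hypothesis modification of the likelihood
ratio (an analogue of r\* for d > 1) is not implemented; vector hypotheses
go through the first-order χ² forms or the SN surrogate.
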