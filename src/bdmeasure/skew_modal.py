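"""Skew-modal (SKS) posterior approximation and its BDM.

The scalar SKS density is a mode-centered Gaussian perturbed by a skewing
factor built from the third log-posterior derivative at the MAP θ̃.  In the
rescaled coordinate h = √n(θ - θ̃) with ω̃ = n j(θ̃)^{-1},

    π_SKS(θ | y) ∝ 2 φ(h; 0, ω̃) Φ(α̃(h)),
    α̃(h) = √(2π)/12 · ℓ⁽³⁾(θ̃) n^{-3/2} h³,

which linearizes to the classical third-order tail term ℓ⁽³⁾/(6 n^{3/2}).
The tail area admits a closed form (the `sks_bdm_closed` route) and a direct
numerical quadrature (`sks_tail_numeric`).  For a scalar interest parameter
inside a d-dimensional model, the marginal SKS density carries a linear and
a cubic skewness coefficient (v_{1,1}, v_{3,111}) obtained by contracting
the third-derivative tensor with the scaled inverse information
Ω = (j(θ̃)/n)^{-1}.

Derivatives default to the log-posterior at θ̃; a switch selects
log-likelihood-only derivatives (``EstimateSet.use_prior_derivs``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from .core import BDMResult, TailArea, _result_from_prob, bdm_from_tail
from .model import EstimateSet, ParametricModel

__all__ = [
    "SKSApprox",
    "MarginalSKS",
    "sks_approx",
    "sks_density",
    "sks_bdm_closed",
    "sks_tail_numeric",
    "sks_bdm_numeric",
    "marginal_sks_coeffs",
    "marginal_sks_bdm",
]

_C = np.sqrt(2.0 * np.pi) / 12.0   # skewness coefficient: linearizes to 1/6·√(2/π)⁻¹…
_QUAD_TOL = 1e-9


@dataclass
class SKSApprox:
    """Scalar skew-modal approximation at the MAP."""

    map: float        # θ̃
    omega: float      # ω̃ = n j(θ̃)^{-1}
    ell3: float       # third derivative of the chosen log target at θ̃
    n_obs: int

    def __post_init__(self):
        if self.omega <= 0:
            raise ValueError("omega must be positive")

    def h(self, theta):
        return np.sqrt(self.n_obs) * (np.asarray(theta, dtype=float) - self.map)

    def alpha(self, h):
        return _C * self.ell3 * self.n_obs ** -1.5 * np.asarray(h, dtype=float) ** 3


@dataclass
class MarginalSKS:
    """Marginal skew-modal approximation for one interest coordinate."""

    map_psi: float
    Omega: np.ndarray     # (j(θ̃)/n)^{-1}
    Omega11: float
    v11: float
    v3111: float
    n_obs: int

    def h(self, psi):
        return np.sqrt(self.n_obs) * (np.asarray(psi, dtype=float) - self.map_psi)

    def alpha(self, h):
        h = np.asarray(h, dtype=float)
        return _C * self.n_obs ** -1.5 * (self.v11 * h + self.v3111 * h ** 3)


def sks_approx(model: ParametricModel, est: EstimateSet) -> SKSApprox:
    """Assemble the scalar SKS approximation from an :class:`EstimateSet`."""
    if model.dim != 1:
        raise ValueError("sks_approx is scalar; use marginal_sks_coeffs for d >= 2")
    n = est.n_obs
    j = float(est.info_map[0, 0])
    if j <= 0:
        raise ValueError("non-positive information at the MAP")
    return SKSApprox(map=float(est.map[0]), omega=n / j,
                     ell3=float(est.third_unmixed_map[0]), n_obs=n)


def sks_density(approx: SKSApprox, theta) -> np.ndarray:
    """Unnormalized SKS density 2 φ(h; 0, ω̃) Φ(α̃(h)) in the h coordinate."""
    h = approx.h(theta)
    sd = np.sqrt(approx.omega)
    return 2.0 * stats.norm.pdf(h, scale=sd) * stats.norm.cdf(approx.alpha(h))


def _closed_tail(approx: SKSApprox, theta0: float) -> float:
    """Closed-form (linearized) SKS tail; may leave [0, 1]."""
    h0 = float(approx.h(theta0))
    sd = np.sqrt(approx.omega)
    z0 = h0 / sd
    c = approx.ell3 / (6.0 * approx.n_obs ** 1.5)
    return float(stats.norm.sf(z0)
                 + c * approx.omega ** 1.5 * stats.norm.pdf(z0) * (z0 ** 2 + 2.0))


def sks_bdm_closed(approx: SKSApprox, theta0: float) -> BDMResult:
    """Closed-form SKS BDM.

    Equivalent to δ = 2Φ(|z0|) - 1 - 2 sign(h0)·[ℓ⁽³⁾(θ̃)/(6 n^{3/2})]·
    ω̃^{3/2} φ(z0)(z0² + 2), with h0 = √n(θ0 - θ̃), z0 = h0/√ω̃.  The raw
    value can leave [0, 1]; both raw and clipped values are reported.
    """
    prob = _closed_tail(approx, theta0)
    return _result_from_prob(prob, float(theta0), "sks_closed",
                             {"h0": float(approx.h(theta0)), "omega": approx.omega,
                              "ell3": approx.ell3})


def _sks_norm_and_tail(approx: SKSApprox, h0: float):
    sd = np.sqrt(approx.omega)
    dens = lambda h: 2.0 * stats.norm.pdf(h, scale=sd) * stats.norm.cdf(approx.alpha(h))
    lo, hi = -12.0 * sd, 12.0 * sd
    total, _ = integrate.quad(dens, lo, hi, epsabs=_QUAD_TOL, limit=200)
    for _ in range(20):
        addl, _ = integrate.quad(dens, lo - 6 * sd, lo, epsabs=_QUAD_TOL, limit=200)
        addr, _ = integrate.quad(dens, hi, hi + 6 * sd, epsabs=_QUAD_TOL, limit=200)
        total += addl + addr
        lo, hi = lo - 6 * sd, hi + 6 * sd
        if addl + addr < 1e-12:
            break
    if not np.isfinite(total) or total <= 0:
        raise RuntimeError("SKS quadrature failed to converge")
    h0c = min(max(h0, lo), hi)
    upper, _ = integrate.quad(dens, h0c, hi, epsabs=_QUAD_TOL, limit=200)
    return total, upper


def sks_tail_numeric(approx: SKSApprox, theta0: float) -> TailArea:
    """SKS tail by adaptive quadrature of 2φΦ, normalized by the full integral."""
    h0 = float(approx.h(theta0))
    total, upper = _sks_norm_and_tail(approx, h0)
    prob = min(max(upper / total, 0.0), 1.0)
    return TailArea(theta0=float(theta0), prob=prob, method="sks_numeric",
                    meta={"normalization": total})


def sks_bdm_numeric(approx: SKSApprox, theta0: float) -> BDMResult:
    tail = sks_tail_numeric(approx, theta0)
    return _result_from_prob(tail.prob, float(theta0), "sks_numeric", tail.meta)


# ---------------------------------------------------------------------------
# marginal (nuisance-parameter) SKS
# ---------------------------------------------------------------------------

def marginal_sks_coeffs(model: ParametricModel, est: EstimateSet,
                        interest_index: int = 0) -> MarginalSKS:
    """Skewness coefficients of the marginal SKS density for one coordinate.

    With the interest coordinate permuted to index 0, Ω = (j(θ̃)/n)^{-1},
    slope vector b = Ω[:,0]/Ω[0,0] and conditional covariance
    Σc = Ω - Ω[:,0]Ω[0,:]/Ω[0,0]:

        v_{1,1}   = 3 Σ_{stl} ℓ⁽³⁾_{stl} b_s Σc_{tl},
        v_{3,111} =   Σ_{stl} ℓ⁽³⁾_{stl} b_s b_t b_l.

    These are the linear and cubic coefficients of the skewing polynomial of
    the marginal density; at d = 1 they reduce to (0, ℓ⁽³⁾).
    """
    if model.dim < 2:
        raise ValueError("marginal_sks_coeffs requires d >= 2")
    if est.third_tensor_map is None:
        raise ValueError("EstimateSet must carry the third-derivative tensor")
    d = model.dim
    perm = [interest_index] + [i for i in range(d) if i != interest_index]
    J = est.info_map[np.ix_(perm, perm)]
    T = est.third_tensor_map[np.ix_(perm, perm, perm)]
    n = est.n_obs
    try:
        Omega = np.linalg.inv(J / n)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError("singular information at the MAP") from e
    O11 = float(Omega[0, 0])
    b = Omega[:, 0] / O11
    Sc = Omega - np.outer(Omega[:, 0], Omega[0, :]) / O11
    v11 = 3.0 * float(np.einsum("stl,s,tl->", T, b, Sc))
    v3111 = float(np.einsum("stl,s,t,l->", T, b, b, b))
    return MarginalSKS(map_psi=float(est.map[perm[0]]), Omega=Omega, Omega11=O11,
                       v11=v11, v3111=v3111, n_obs=n)


def marginal_sks_tail(msks: MarginalSKS, psi0: float) -> TailArea:
    """Numerical tail of the marginal SKS density 2φ(h;0,Ω11)Φ(α_ψ(h))."""
    sd = np.sqrt(msks.Omega11)
    dens = lambda h: 2.0 * stats.norm.pdf(h, scale=sd) * stats.norm.cdf(msks.alpha(h))
    lo, hi = -12.0 * sd, 12.0 * sd
    total, _ = integrate.quad(dens, lo, hi, epsabs=_QUAD_TOL, limit=200)
    h0 = float(msks.h(psi0))
    h0c = min(max(h0, lo), hi)
    upper, _ = integrate.quad(dens, h0c, hi, epsabs=_QUAD_TOL, limit=200)
    prob = min(max(upper / total, 0.0), 1.0)
    return TailArea(theta0=float(psi0), prob=prob, method="sks_numeric",
                    meta={"normalization": total, "v11": msks.v11,
                          "v3111": msks.v3111})


def marginal_sks_bdm(msks: MarginalSKS, psi0: float) -> BDMResult:
    """Marginal SKS BDM δ = 1 - 2 min(P, 1-P) from the numerical tail."""
    tail = marginal_sks_tail(msks, psi0)
    delta = bdm_from_tail(tail.prob)
    return BDMResult(delta=delta, delta_raw=delta, tail=tail,
                     hypothesis=float(psi0),
                     side="upper" if tail.prob < 0.5 else "lower")
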