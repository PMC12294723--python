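"""Multivariate skew-normal posterior approximation and its transport map.

The posterior is approximated by a d-variate skew-normal (SN) density

    f(x) = 2 φ_d(x; ξ, Ω) Φ(αᵀ(x - ξ)),

whose parameters (ξ, Ω, α) are obtained by matching the posterior mode m,
the negative log-posterior Hessian j(θ̃) and the vector t of unmixed third
derivatives at the mode.  The matching system

    0 = -Ω^{-1}(m - ξ) + ζ1(κ) α,
    j(θ̃) = Ω^{-1} - ζ2(κ) α αᵀ,
    t = ζ3(κ) α∘³,
    κ = αᵀ(m - ξ),

(ζ_k the k-th derivative of log Φ) reduces to one-dimensional root-finding
in κ.  The note on the shape convention: α here multiplies the raw deviation
(x - ξ); in the usual standardized parametrization the shape would be ωα.
The mean and covariance identities E[X] = ξ + √(2/π) δ and
Var(X) = Ω - (2/π) δδᵀ with δ = Ωα/√(1 + αᵀΩα) hold verbatim in this
convention.

The optimal transport map T = T3∘T2∘T1 pushes SN_d(ξ, Ω, α) to N_d(0, I):
T1 rotates so the skewness loads on the first coordinate (Q from a QR
factorization of α), T2 Gaussianizes that coordinate through the univariate
SN CDF, and T3 whitens.  ‖T(θ0)‖² then plays the role of a chi-square
statistic: δ_H = P(χ²_d ≤ ‖T(θ0)‖²).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import log_ndtr

from .core import BDMResult, TailArea
from .model import EstimateSet

__all__ = [
    "SNParams",
    "OTMap",
    "zeta",
    "sn_match",
    "sn_match_residuals",
    "build_ot_map",
    "sn_bdm",
    "sn_marginal",
    "sn_sample",
    "sn_approx",
]


def zeta(k: int, kappa) -> np.ndarray:
    """ζ_k(κ), the k-th derivative of log Φ(κ), for k ∈ {1, 2, 3}.

    ζ1 is the inverse Mills ratio, evaluated in log space so the recursion
    stays stable far into the left tail (κ ≈ -40).
    """
    kappa = np.asarray(kappa, dtype=float)
    z1 = np.exp(stats.norm.logpdf(kappa) - log_ndtr(kappa))
    if k == 1:
        out = z1
    elif k == 2:
        out = -z1 * (kappa + z1)
    elif k == 3:
        z2 = -z1 * (kappa + z1)
        out = -z2 * (kappa + z1) - z1 * (1.0 + z2)
    else:
        raise ValueError("k must be in {1, 2, 3}")
    return out if out.shape else float(out)


@dataclass
class SNParams:
    """Parameters of the matched d-dimensional skew-normal approximation."""

    xi: np.ndarray
    Omega: np.ndarray
    alpha: np.ndarray
    kappa: float
    delta_sn: np.ndarray = field(default=None)

    def __post_init__(self):
        self.xi = np.atleast_1d(np.asarray(self.xi, dtype=float))
        self.Omega = np.atleast_2d(np.asarray(self.Omega, dtype=float))
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        if self.delta_sn is None:
            a, O = self.alpha, self.Omega
            self.delta_sn = O @ a / np.sqrt(1.0 + a @ O @ a)

    @property
    def dim(self) -> int:
        return self.xi.size

    def logpdf(self, x) -> float:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        d = self.dim
        dev = x - self.xi
        return float(np.log(2.0)
                     + stats.multivariate_normal.logpdf(x, mean=self.xi, cov=self.Omega)
                     + log_ndtr(self.alpha @ dev))


def sn_match(mode, neg_hessian, third_unmixed) -> SNParams:
    """Fit SN_d(ξ, Ω, α) by derivative matching at the mode.

    For a trial κ the shape is α_i = cbrt(t_i / ζ3(κ)), the precision is
    Ω^{-1} = j(θ̃) + ζ2(κ) ααᵀ and the location offset m - ξ = ζ1(κ) Ω α;
    the remaining scalar residual κ - ζ1(κ) αᵀΩα is driven to zero by
    bracketed root-finding.  If no sign-definite bracket exists the fit
    falls back to the Gaussian member (α = 0) with a warning.
    """
    m = np.atleast_1d(np.asarray(mode, dtype=float))
    J = np.atleast_2d(np.asarray(neg_hessian, dtype=float))
    t = np.atleast_1d(np.asarray(third_unmixed, dtype=float))
    d = m.size

    def gaussian():
        O = np.linalg.inv(J)
        return SNParams(xi=m.copy(), Omega=O, alpha=np.zeros(d), kappa=0.0)

    if np.all(np.abs(t) < 1e-12):
        return gaussian()

    def parts(kap):
        z3 = zeta(3, kap)
        if z3 <= 0:
            return None
        alpha = np.cbrt(t / z3)
        Oinv = J + zeta(2, kap) * np.outer(alpha, alpha)
        try:
            L = np.linalg.cholesky(Oinv)
        except np.linalg.LinAlgError:
            return None
        Oalpha = np.linalg.solve(Oinv, alpha)
        return alpha, Oinv, float(alpha @ Oalpha)

    def resid(kap):
        p = parts(kap)
        if p is None:
            return None
        return kap - zeta(1, kap) * p[2]

    # κ = ζ1(κ) αᵀΩα > 0.  The trial precision j + ζ2(κ)ααᵀ loses positive
    # definiteness for small κ (large trial shape); inside the PD region the
    # residual runs from -∞ (at the PD boundary, where αᵀΩα blows up) to +∞
    # for large κ, so scan a log grid for a sign change and shrink toward the
    # boundary when the first evaluable point is already positive.
    bracket = None
    grid = np.logspace(-6, 4, 161)
    prev_k = prev_f = None
    first_pd = None
    last_bad = 0.0
    for kap in grid:
        f = resid(kap)
        if f is None:
            last_bad = kap
            prev_k = prev_f = None
            continue
        if first_pd is None:
            first_pd = kap
        if prev_f is not None and prev_f < 0 <= f:
            bracket = (prev_k, kap)
            break
        prev_k, prev_f = kap, f
    if bracket is None and first_pd is not None and resid(first_pd) > 0:
        # refine toward the PD boundary where the residual dives to -∞
        lo, hi = last_bad, first_pd
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            f = resid(mid)
            if f is None:
                lo = mid
            elif f < 0:
                bracket = (mid, first_pd)
                break
            else:
                hi = mid
            if hi - lo < 1e-13 * max(1.0, hi):
                break
    if bracket is None:
        warnings.warn("no sign-definite bracket for the SN matching root; "
                      "falling back to the Gaussian approximation (alpha = 0)",
                      UserWarning)
        return gaussian()
    kappa = float(optimize.brentq(resid, *bracket, xtol=1e-14, maxiter=300))
    alpha, Oinv, _ = parts(kappa)
    Omega = np.linalg.inv(Oinv)
    Omega = 0.5 * (Omega + Omega.T)
    xi = m - zeta(1, kappa) * (Omega @ alpha)
    return SNParams(xi=xi, Omega=Omega, alpha=alpha, kappa=kappa)


def sn_match_residuals(sn: SNParams, mode, neg_hessian, third_unmixed) -> dict:
    """Residuals of the four matching equations at a fitted solution."""
    m = np.atleast_1d(np.asarray(mode, dtype=float))
    J = np.atleast_2d(np.asarray(neg_hessian, dtype=float))
    t = np.atleast_1d(np.asarray(third_unmixed, dtype=float))
    Oinv = np.linalg.inv(sn.Omega)
    k = sn.kappa
    return {
        "mode": float(np.max(np.abs(-Oinv @ (m - sn.xi) + zeta(1, k) * sn.alpha))),
        "hessian": float(np.max(np.abs(J - (Oinv - zeta(2, k) * np.outer(sn.alpha, sn.alpha))))),
        "third": float(np.max(np.abs(t - zeta(3, k) * sn.alpha ** 3))),
        "kappa": float(abs(k - sn.alpha @ (m - sn.xi))),
    }


def sn_approx(est: EstimateSet) -> SNParams:
    """Match an SN approximation to the posterior at the MAP."""
    return sn_match(est.map, est.info_map, est.third_unmixed_map)


def sn_sample(sn: SNParams, size: int, rng) -> np.ndarray:
    """Exact SN_d draws by the sign-flip representation.

    With W ~ N_d(0, Ω) and T ~ N(0, 1), the vector ξ + W·sign(αᵀW - T) has
    density 2 φ_d(·; ξ, Ω) Φ(αᵀ(· - ξ)).
    """
    W = rng.multivariate_normal(np.zeros(sn.dim), sn.Omega, size=size,
                                method="cholesky")
    T = rng.standard_normal(size)
    flip = np.where(W @ sn.alpha >= T, 1.0, -1.0)
    return sn.xi + W * flip[:, None]


@dataclass
class OTMap:
    """The composed transport T = T3∘T2∘T1 from SN_d(ξ, Ω, α) to N_d(0, I)."""

    sn: SNParams
    Q: np.ndarray
    sigma2: float
    alpha_rot: np.ndarray
    mu_z: np.ndarray
    V: np.ndarray
    mu1: float
    V1: float
    whitener: np.ndarray
    skew_shape: float   # scipy shape parameter of the rotated first coordinate

    def __call__(self, x) -> np.ndarray:
        """Apply T to one point (shape (d,)) or a batch (shape (n, d))."""
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        X = np.atleast_2d(x)
        Z = (X - self.sn.xi) @ self.Q
        if self.skew_shape != 0.0:
            Z = Z.copy()
            Z[:, 0] = self.gaussianize_first(Z[:, 0])
        U = (Z - self.mu_z) @ self.whitener
        return U[0] if single else U

    def gaussianize_first(self, z1) -> np.ndarray:
        """T2 on the first rotated coordinate: Φ⁻¹(F_SN(z1); μ1, V1).

        The left and right tails go through the CDF and the survival
        function respectively, so the map stays strictly increasing far
        beyond ±8σ without double-precision saturation.
        """
        z1 = np.atleast_1d(np.asarray(z1, dtype=float))
        scale = np.sqrt(self.sigma2)
        u = stats.skewnorm.cdf(z1, a=self.skew_shape, loc=0.0, scale=scale)
        s = stats.skewnorm.sf(z1, a=self.skew_shape, loc=0.0, scale=scale)
        q = np.where(u <= 0.5,
                     stats.norm.ppf(np.clip(u, 1e-300, 1.0)),
                     -stats.norm.ppf(np.clip(s, 1e-300, 1.0)))
        return self.mu1 + np.sqrt(self.V1) * q


def _inv_sqrt_sym(V: np.ndarray) -> np.ndarray:
    w, U = np.linalg.eigh(V)
    if np.any(w <= 0):
        raise np.linalg.LinAlgError("covariance not positive definite")
    return (U * (w ** -0.5)) @ U.T


def build_ot_map(sn: SNParams) -> OTMap:
    """Assemble the rotation, Gaussianization and whitening steps.

    Q comes from the (complete) QR factorization of α, signs flipped so the
    first column equals α/‖α‖; then the rotated shape is (‖α‖, 0, …, 0), the
    first coordinate Z1 ~ SN1(0, σ², ‖α‖) (raw-deviation shape convention)
    and Z2:d are treated as Gaussian.
    """
    d = sn.dim
    anorm = float(np.linalg.norm(sn.alpha))
    if anorm < 1e-14:
        Q = np.eye(d)
    else:
        Q, R = np.linalg.qr(sn.alpha.reshape(d, 1), mode="complete")
        if R[0, 0] < 0:
            Q = -Q
        # re-orthogonalize sign of remaining columns is irrelevant
    QtOQ = Q.T @ sn.Omega @ Q
    sigma2 = float(QtOQ[0, 0])
    alpha_rot = Q.T @ sn.alpha
    qd = Q.T @ sn.delta_sn
    mu_z = qd * np.sqrt(2.0 / np.pi)
    V = QtOQ - (2.0 / np.pi) * np.outer(qd, qd)
    mu1 = float(mu_z[0])
    V1 = float(V[0, 0])
    # scipy skewnorm uses the standardized shape a = ‖α‖·σ
    skew_shape = anorm * np.sqrt(sigma2) if anorm >= 1e-14 else 0.0
    return OTMap(sn=sn, Q=Q, sigma2=sigma2, alpha_rot=alpha_rot, mu_z=mu_z,
                 V=V, mu1=mu1, V1=V1, whitener=_inv_sqrt_sym(V),
                 skew_shape=skew_shape)


def sn_bdm(sn: SNParams, theta0, ot: OTMap = None) -> BDMResult:
    """SN approximation of the (multivariate) BDM.

    δ = P(χ²_d ≤ ‖T(θ0)‖²) = F_χd(‖u‖), the norm of the center-outward rank
    of θ0 under the SN surrogate.  At d = 1 this reduces to 2Φ(|u|) - 1.
    """
    if ot is None:
        ot = build_ot_map(sn)
    theta0 = np.atleast_1d(np.asarray(theta0, dtype=float))
    u = ot(theta0)
    w = float(u @ u)
    delta = float(stats.chi2.cdf(w, df=sn.dim))
    tail = TailArea(theta0=theta0, prob=float(stats.chi2.sf(w, df=sn.dim)),
                    method="sn", meta={"u": u.tolist(), "norm2": w})
    return BDMResult(delta=delta, delta_raw=delta, tail=tail,
                     hypothesis=theta0, side="radial")


def sn_marginal(sn: SNParams, index: int):
    """Closed-form univariate SN marginal of one coordinate.

    Returns (location, scale², shape) in the raw-deviation convention, i.e.
    density 2 φ(x; loc, scale²) Φ(shape·(x - loc)).
    """
    d = sn.dim
    A = [index]
    B = [i for i in range(d) if i != index]
    O_AA = sn.Omega[np.ix_(A, A)]
    if not B:
        return float(sn.xi[index]), float(O_AA[0, 0]), float(sn.alpha[index])
    O_AB = sn.Omega[np.ix_(A, B)]
    O_BB = sn.Omega[np.ix_(B, B)]
    a_A = sn.alpha[A]
    a_B = sn.alpha[B]
    cond = O_BB - O_AB.T @ np.linalg.inv(O_AA) @ O_AB
    shape = (a_A + np.linalg.inv(O_AA) @ O_AB @ a_B) / \
        np.sqrt(1.0 + a_B @ cond @ a_B)
    return float(sn.xi[index]), float(O_AA[0, 0]), float(shape[0])
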