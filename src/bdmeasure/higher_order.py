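"""Third-order tail areas via the Bayesian modified likelihood root r*_B.

For a scalar parameter the posterior tail is approximated to O(n^{-3/2}) by
Φ(r*_B(θ0)) with

    r*_B(θ) = r(θ) + log(q(θ)/r(θ)) / r(θ),
    r(θ)    = sign(θ̂ - θ) [2(ℓ(θ̂) - ℓ(θ))]^{1/2},
    q(θ)    = ℓ'(θ) j(θ̂)^{-1/2} π(θ̂)/π(θ),

and with the Jeffreys prior q reduces to the probability-matching form
ℓ'(θ) j(θ̂)^{-1/2} (i(θ̂)/i(θ))^{1/2}, making the Bayesian tail agree with
the frequentist modified likelihood root.  The
nuisance-parameter version replaces r, q by their profile counterparts
r_p, q_B computed from a cached profile log-likelihood.

The raw expression is 0/0 at θ = θ̂; near the MLE r*_B is evaluated by local
quadratic interpolation through points with |r| ∈ {0.1, 0.15, 0.2} on each
side.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np
from scipy import interpolate, optimize, stats

from .core import BDMResult, TailArea, _result_from_prob
from .model import EstimateSet, ParametricModel, ProfileCache, fd_gradient

__all__ = [
    "RStarResult",
    "likelihood_root",
    "q_correction",
    "r_star",
    "r_star_tail",
    "ho_bdm",
    "qB_nuisance",
    "r_star_profile",
    "r_star_profile_bdm",
    "credible_interval_rstar",
    "median_rstar",
]

_R_SINGULAR = 0.05          # |r| below this -> interpolate
_R_NODES = (0.1, 0.15, 0.2)  # interpolation nodes in |r|


class RStarResult:
    """r, q and r*_B at a hypothesized value (scalar or profile case)."""

    def __init__(self, theta0, r, q, r_star, near_singular=False):
        self.theta0 = theta0
        self.r = r
        self.q = q
        self.r_star = r_star
        self.near_singular = near_singular

    def __repr__(self):  # pragma: no cover
        return (f"RStarResult(theta0={self.theta0:.6g}, r={self.r:.6g}, "
                f"q={self.q}, r_star={self.r_star:.6g})")


def likelihood_root(model: ParametricModel, theta0: float, est: EstimateSet) -> float:
    """Signed likelihood root r(θ0) = sign(θ̂-θ0) √(2(ℓ(θ̂)-ℓ(θ0)))."""
    l0 = float(model.loglik(np.atleast_1d(theta0)))
    lhat = float(model.loglik(est.mle))
    if not np.isfinite(l0):
        raise ValueError("loglik not finite at theta0")
    drop = lhat - l0
    if drop < -1e-8 * max(1.0, abs(lhat)):
        raise ValueError("loglik at theta0 exceeds the maximized value; "
                         "upstream optimizer failure")
    drop = max(drop, 0.0)
    return float(np.sign(est.mle[0] - theta0) * np.sqrt(2.0 * drop))


def _score(model: ParametricModel, theta0: float) -> float:
    if model.score is not None:
        return float(np.atleast_1d(model.score(np.atleast_1d(float(theta0))))[0])
    return float(fd_gradient(lambda th: model.loglik(th), np.atleast_1d(float(theta0)))[0])


def q_correction(model: ParametricModel, theta0: float, est: EstimateSet,
                 variant: str = "general") -> float:
    """The correction factor q(θ0) entering r*_B.

    ``general``: q = ℓ'(θ0) j(θ̂)^{-1/2} π(θ̂)/π(θ0) (prior ratio; improper
    priors allowed).  ``jeffreys``: the probability-matching form
    q = ℓ'(θ0) j(θ̂)^{-1/2} i(θ̂)^{1/2}/i(θ0)^{1/2} with the model-supplied
    expected information.
    """
    if model.dim != 1:
        raise ValueError("q_correction is for scalar parameters; see qB_nuisance")
    score0 = _score(model, theta0)
    jroot = float(est.info_mle[0, 0]) ** -0.5
    if variant == "jeffreys":
        if model.expected_info is None:
            raise ValueError("jeffreys variant needs model.expected_info")
        ihat = float(np.atleast_2d(model.expected_info(est.mle))[0, 0])
        i0 = float(np.atleast_2d(model.expected_info(np.atleast_1d(float(theta0))))[0, 0])
        ratio = np.sqrt(ihat / i0)
    elif variant == "general":
        lp_hat = float(model.logprior(est.mle))
        lp_0 = float(model.logprior(np.atleast_1d(float(theta0))))
        if not np.isfinite(lp_0):
            raise ValueError("prior density vanishes at theta0 (Cromwell violation)")
        ratio = np.exp(lp_hat - lp_0)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return float(score0 * jroot * ratio)


def _rstar_raw(r: float, q: float) -> float:
    ratio = q / r
    if ratio <= 0:
        raise ValueError("q/r <= 0 away from the MLE: inconsistent inputs")
    return r + np.log(ratio) / r


def _interp_rstar(theta0: float, theta_hat: float,
                  r_of: Callable[[float], float],
                  rstar_of: Callable[[float], float],
                  scale: float) -> float:
    """Quadratic interpolation of r*(θ) through |r| ∈ {0.1, 0.15, 0.2} nodes.

    Nodes are located by walking outward from θ̂ (r is decreasing in θ) and
    refining with brentq; steps that leave the parameter domain stop the walk.
    """
    def node(target):
        # r(θ̂)=0; walk in the direction where r approaches `target`
        direction = -1.0 if target > 0 else 1.0
        prev = theta_hat
        step = 0.25 * scale
        for _ in range(200):
            cand = prev + direction * step
            try:
                rc = r_of(cand)
            except ValueError:
                step *= 0.5
                continue
            if (target > 0 and rc >= target) or (target < 0 and rc <= target):
                f = lambda th: r_of(th) - target
                a, b = (cand, prev) if cand < prev else (prev, cand)
                return float(optimize.brentq(f, a, b, xtol=1e-12, maxiter=200))
            prev = cand
        raise RuntimeError(f"could not locate interpolation node r={target}")

    nodes_th, nodes_rs = [], []
    for c in _R_NODES:
        for sgn in (+1.0, -1.0):
            th_node = node(sgn * c)
            nodes_th.append(th_node)
            nodes_rs.append(rstar_of(th_node))
    coef = np.polyfit(np.asarray(nodes_th) - theta_hat, nodes_rs, 2)
    return float(np.polyval(coef, theta0 - theta_hat))


def _directional_root(g, start, step, direction, max_iter=200):
    """Walk outward from ``start`` until g changes sign, then refine.

    Steps that leave the parameter domain (ValueError from g) are halved;
    raises when no sign change is found within the scan range.
    """
    prev, fprev = start, g(start)
    s = step
    for _ in range(max_iter):
        cand = prev + direction * s
        try:
            fc = g(cand)
        except ValueError:
            s *= 0.5
            if s < 1e-12 * max(1.0, abs(start)):
                break
            continue
        if fprev * fc <= 0:
            a, b = (prev, cand) if prev < cand else (cand, prev)
            return float(optimize.brentq(g, a, b, xtol=1e-12, maxiter=200))
        prev, fprev = cand, fc
        s *= 1.3
    raise RuntimeError("root not bracketed within the scan range")


def r_star(model: ParametricModel, theta0: float, est: EstimateSet,
           variant: str = "general") -> RStarResult:
    """r*_B(θ0), with the near-MLE singularity handled by interpolation."""
    r = likelihood_root(model, theta0, est)
    q = q_correction(model, theta0, est, variant=variant)
    if abs(r) >= _R_SINGULAR:
        return RStarResult(theta0, r, q, _rstar_raw(r, q))
    scale = float(est.info_mle[0, 0]) ** -0.5
    rs = _interp_rstar(
        float(theta0), float(est.mle[0]),
        r_of=lambda th: likelihood_root(model, th, est),
        rstar_of=lambda th: _rstar_raw(likelihood_root(model, th, est),
                                       q_correction(model, th, est, variant=variant)),
        scale=scale)
    return RStarResult(theta0, r, q, rs, near_singular=True)


def r_star_tail(model: ParametricModel, theta0: float, est: EstimateSet,
                variant: str = "general") -> TailArea:
    """Third-order posterior tail P(θ ≥ θ0 | y) ≈ Φ(r*_B(θ0))."""
    rs = r_star(model, theta0, est, variant=variant)
    prob = float(stats.norm.cdf(rs.r_star))
    return TailArea(theta0=float(theta0), prob=prob, method="higher_order",
                    meta={"r": rs.r, "q": rs.q, "r_star": rs.r_star,
                          "near_singular": rs.near_singular})


def ho_bdm(model: ParametricModel, theta0: float, est: EstimateSet,
           variant: str = "general") -> BDMResult:
    """Third-order BDM, δ = 2Φ(|r*_B(θ0)|) - 1."""
    tail = r_star_tail(model, theta0, est, variant=variant)
    return _result_from_prob(tail.prob, float(theta0), "higher_order", tail.meta)


# ---------------------------------------------------------------------------
# nuisance-parameter (profile) case
# ---------------------------------------------------------------------------

def _profile_splines(cache: ProfileCache):
    ok = cache.ok if cache.ok is not None else np.ones(cache.psi_grid.size, bool)
    psi = cache.psi_grid[ok]
    lp = cache.lp[ok]
    ld = cache.jll_logdet[ok]
    if psi.size < 4:
        raise ValueError("too few valid profile points")
    return (interpolate.CubicSpline(psi, lp),
            interpolate.CubicSpline(psi, ld))


def _profile_root(cache: ProfileCache, psi0: float, lp_spline) -> float:
    drop = cache.lp_max - float(lp_spline(psi0))
    drop = max(drop, 0.0)
    return float(np.sign(cache.psi_hat - psi0) * np.sqrt(2.0 * drop))


def qB_nuisance(model: ParametricModel, psi0: float, cache: ProfileCache,
                est: EstimateSet) -> float:
    """Bayesian correction q_B(ψ0) for the profile modified likelihood root.

    q_B = ℓ_p'(ψ0) j_p(ψ̂)^{-1/2} · {|j_λλ(ψ0, λ̂_ψ0)| / |j_λλ(ψ̂, λ̂)|}^{1/2}
          · π(θ̂)/π(ψ0, λ̂_ψ0),

    with the profile score taken from the derivative of the cached profile
    log-likelihood.
    """
    lp_spline, ld_spline = _profile_splines(cache)
    score_p = float(lp_spline(psi0, 1))
    if cache.jp_at_mle <= 0:
        raise ValueError("non-positive profile information at the MLE")
    jp_root = cache.jp_at_mle ** -0.5
    ld0 = float(ld_spline(psi0))
    if not np.isfinite(ld0):
        raise ValueError(f"singular nuisance block at psi0={psi0:.6g}")
    det_ratio = np.exp(0.5 * (ld0 - cache.jll_logdet_at_mle))

    idx = [i for i in range(model.dim) if i != cache.interest_index]
    theta_hat = np.empty(model.dim)
    theta_hat[cache.interest_index] = cache.psi_hat
    theta_hat[idx] = cache.lambda_at_mle
    # nuisance maximizer at psi0 from the cache (nearest grid interpolation)
    k = int(np.argmin(np.abs(cache.psi_grid - psi0)))
    theta0 = np.empty(model.dim)
    theta0[cache.interest_index] = psi0
    theta0[idx] = cache.lambda_hat[k]
    lp_hat = float(model.logprior(theta_hat))
    lp_0 = float(model.logprior(theta0))
    if not np.isfinite(lp_0):
        raise ValueError("prior density vanishes at (psi0, lambda_hat_psi0)")
    prior_ratio = np.exp(lp_hat - lp_0)
    return float(score_p * jp_root * det_ratio * prior_ratio)


def r_star_profile(model: ParametricModel, psi0: float, cache: ProfileCache,
                   est: EstimateSet,
                   qp: Optional[Callable[[float], float]] = None) -> RStarResult:
    """Profile modified likelihood root r*_Bp(ψ0).

    ``qp``: optional user-supplied frequentist correction term replacing the
    Bayesian q_B (matching-prior route); it must map ψ0 to the scalar q_p(ψ0).
    """
    lp_spline, _ = _profile_splines(cache)
    r_of = lambda p: _profile_root(cache, p, lp_spline)
    q_of = (lambda p: float(qp(p))) if qp is not None else \
           (lambda p: qB_nuisance(model, p, cache, est))
    r = r_of(psi0)
    q = q_of(psi0)
    if abs(r) >= _R_SINGULAR:
        return RStarResult(psi0, r, q, _rstar_raw(r, q))
    scale = cache.jp_at_mle ** -0.5
    rs = _interp_rstar(float(psi0), cache.psi_hat, r_of,
                       lambda p: _rstar_raw(r_of(p), q_of(p)), scale)
    return RStarResult(psi0, r, q, rs, near_singular=True)


def r_star_profile_bdm(model: ParametricModel, psi0: float, cache: ProfileCache,
                       est: EstimateSet, qp=None) -> BDMResult:
    """Third-order marginal BDM, δ = 2Φ(|r*_Bp(ψ0)|) - 1."""
    rs = r_star_profile(model, psi0, cache, est, qp=qp)
    prob = float(stats.norm.cdf(rs.r_star))
    return _result_from_prob(prob, float(psi0), "higher_order",
                             {"r_p": rs.r, "q_B": rs.q, "r_star": rs.r_star,
                              "near_singular": rs.near_singular})


# ---------------------------------------------------------------------------
# r*-based credible intervals and medians
# ---------------------------------------------------------------------------

def _rstar_fn(model, est, cache, variant):
    if cache is not None:
        return lambda th: r_star_profile(model, th, cache, est).r_star, \
            cache.psi_hat, cache.jp_at_mle ** -0.5
    return lambda th: r_star(model, th, est, variant=variant).r_star, \
        float(est.mle[0]), float(est.info_mle[0, 0]) ** -0.5


def credible_interval_rstar(model: ParametricModel, est: EstimateSet,
                            level: float = 0.95,
                            cache: Optional[ProfileCache] = None,
                            variant: str = "general"):
    """Equi-tailed credible interval {θ : |r*_B(θ)| ≤ z_{1-α/2}}.

    r*_B is decreasing in θ, so the endpoints solve r*_B(θ) = ±z.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    fn, center, scale = _rstar_fn(model, est, cache, variant)
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    # r*_B is decreasing in θ: Φ(r*) = 1 - α/2 at the lower endpoint
    lo = _directional_root(lambda th: fn(th) - z, center, 0.5 * scale, -1.0)
    hi = _directional_root(lambda th: fn(th) + z, center, 0.5 * scale, +1.0)
    return float(lo), float(hi)


def median_rstar(model: ParametricModel, est: EstimateSet,
                 cache: Optional[ProfileCache] = None,
                 variant: str = "general") -> float:
    """Posterior median as the root of r*_B(θ) = 0 (third-order accurate)."""
    fn, center, scale = _rstar_fn(model, est, cache, variant)
    direction = 1.0 if fn(center) > 0 else -1.0  # r*_B decreasing in θ
    return _directional_root(fn, center, 0.25 * scale, direction)
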