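"""Model abstraction, numerical differentiation, and maximization machinery.

Everything downstream (exact tails, r*-type tail areas, skew-modal and
skew-normal approximations) consumes a :class:`ParametricModel` plus an
:class:`EstimateSet` holding the MLE, the MAP and local derivative
information of the log-likelihood / log-posterior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "ParametricModel",
    "EstimateSet",
    "ProfileCache",
    "ConvergenceError",
    "BoundaryWarning",
    "find_mle",
    "find_map",
    "observed_info",
    "third_derivatives",
    "profile",
    "estimate_set",
]

_EPS = np.finfo(float).eps
# Central-difference steps, balancing truncation against rounding per
# derivative order: eps^(1/3) for gradients, eps^(1/4) for Hessians,
# eps^(1/5) for third derivatives.
_H1 = _EPS ** (1.0 / 3.0)
_H2 = _EPS ** (1.0 / 4.0)
_H3 = _EPS ** (1.0 / 5.0)


class ConvergenceError(RuntimeError):
    """Raised when an optimizer fails after all retries."""


class BoundaryWarning(UserWarning):
    """Emitted when a maximum appears to lie on the boundary of the domain
    (e.g. monotone likelihood under complete separation)."""


@dataclass
class ParametricModel:
    """A parametric sampling model with prior.

    The log-likelihood and log-prior must return ``-inf`` outside the open
    parameter domain.  Analytic derivative callables, when supplied, take
    precedence over finite differences everywhere.  All derivative callables
    refer to the *log-likelihood*; prior derivatives are separate so that
    log-posterior derivatives can be assembled on demand.
    """

    dim: int
    loglik: Callable[[np.ndarray], float]
    logprior: Callable[[np.ndarray], float]
    param_names: Sequence[str] = ()
    posterior_cdf: Optional[Callable[[float], float]] = None
    data: object = None
    n_obs: Optional[int] = None
    # optional analytic derivatives of the log-likelihood
    score: Optional[Callable[[np.ndarray], np.ndarray]] = None
    hessian: Optional[Callable[[np.ndarray], np.ndarray]] = None
    third: Optional[Callable[[np.ndarray], np.ndarray]] = None
    expected_info: Optional[Callable[[np.ndarray], np.ndarray]] = None
    # optional analytic derivatives of the log-prior
    prior_score: Optional[Callable[[np.ndarray], np.ndarray]] = None
    prior_hessian: Optional[Callable[[np.ndarray], np.ndarray]] = None
    prior_third: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def __post_init__(self):
        if self.dim < 1:
            raise ValueError("dim must be a positive integer")
        if not self.param_names:
            self.param_names = [f"theta{i}" for i in range(self.dim)]

    def logpost(self, theta) -> float:
        """Unnormalized log-posterior kernel ℓ(θ) + log π(θ)."""
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        lp = self.logprior(theta)
        if not np.isfinite(lp):
            return -np.inf
        return float(self.loglik(theta)) + float(lp)

    def objective(self, use_prior: bool) -> Callable[[np.ndarray], float]:
        return self.logpost if use_prior else (
            lambda th: float(self.loglik(np.atleast_1d(np.asarray(th, float)))))


@dataclass
class EstimateSet:
    """MLE/MAP estimates with local information used by the approximations."""

    mle: np.ndarray
    map: np.ndarray
    info_mle: np.ndarray            # -∇²ℓ at the MLE
    info_map: np.ndarray            # -∇² of log-posterior (default) at the MAP
    third_unmixed_map: np.ndarray   # length-d vector of unmixed third derivatives at the MAP
    n_obs: int
    third_tensor_map: Optional[np.ndarray] = None
    use_prior_derivs: bool = True   # convention used for info_map / third derivatives


@dataclass
class ProfileCache:
    """Profile log-likelihood over a grid of the interest parameter."""

    interest_index: int
    psi_grid: np.ndarray
    lambda_hat: np.ndarray          # (len(grid), d-1) constrained maximizers
    lp: np.ndarray                  # profile log-likelihood values
    jp_at_mle: float                # j_p(ψ̂) by finite differencing ℓ_p
    jll_logdet: np.ndarray          # log|j_λλ(ψ, λ̂_ψ)| per grid point
    jll_logdet_at_mle: float
    psi_hat: float
    lambda_at_mle: np.ndarray
    lp_max: float                   # ℓ(θ̂) = ℓ_p(ψ̂)
    ok: np.ndarray = field(default=None)  # per-point convergence mask


# ---------------------------------------------------------------------------
# finite differences
# ---------------------------------------------------------------------------

def fd_gradient(f: Callable, x: np.ndarray, rel_step: float = _H1) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    g = np.empty_like(x)
    for i in range(x.size):
        h = rel_step * max(1.0, abs(x[i]))
        e = np.zeros_like(x)
        e[i] = h
        g[i] = (f(x + e) - f(x - e)) / (2.0 * h)
    return g


def fd_hessian(f: Callable, x: np.ndarray, rel_step: float = _H2) -> np.ndarray:
    """Central-difference Hessian with step h_i = rel_step * max(1, |x_i|)."""
    x = np.asarray(x, dtype=float)
    d = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d); ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / (h[i] ** 2)
        for j in range(i + 1, d):
            ej = np.zeros(d); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    if not np.all(np.isfinite(H)):
        bad = np.argwhere(~np.isfinite(H))[0]
        raise FloatingPointError(
            f"non-finite Hessian entry at coordinate pair ({bad[0]}, {bad[1]})")
    return H


def fd_third(f: Callable, x: np.ndarray, rel_step: float = _H3,
             unmixed_only: bool = False) -> np.ndarray:
    """Third partial derivatives by nested central differences.

    Returns a length-d vector of unmixed derivatives when ``unmixed_only``,
    else the full d×d×d tensor, symmetrized over index permutations.
    """
    x = np.asarray(x, dtype=float)
    d = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    if np.any(h < 8 * _EPS * np.maximum(1.0, np.abs(x))):
        raise FloatingPointError("step-size underflow; rescale the parameters")

    def unmixed(i):
        e = np.zeros(d); e[i] = h[i]
        return (f(x + 2 * e) - 2 * f(x + e) + 2 * f(x - e) - f(x - 2 * e)) / (2 * h[i] ** 3)

    if unmixed_only:
        return np.array([unmixed(i) for i in range(d)])

    T = np.empty((d, d, d))
    # d³f/dxi dxj dxk as a central difference (in i) of central Hessian entries (j,k)
    for i in range(d):
        ei = np.zeros(d); ei[i] = h[i]
        Hp = fd_hessian(f, x + ei, rel_step=rel_step)
        Hm = fd_hessian(f, x - ei, rel_step=rel_step)
        T[i] = (Hp - Hm) / (2.0 * h[i])
    # symmetrize over all index permutations
    T = (T + T.transpose(1, 0, 2) + T.transpose(2, 1, 0)
         + T.transpose(0, 2, 1) + T.transpose(1, 2, 0) + T.transpose(2, 0, 1)) / 6.0
    return T


# ---------------------------------------------------------------------------
# maximization
# ---------------------------------------------------------------------------

def _maximize(obj: Callable, start: np.ndarray, grad: Optional[Callable],
              gtol: float = 1e-8, retries: int = 5, seed: int = 0):
    """Quasi-Newton with simplex fallback and jittered restarts.

    Returns (x, fval). Raises :class:`ConvergenceError` on failure.
    """
    start = np.atleast_1d(np.asarray(start, dtype=float))
    neg = lambda th: -obj(th)
    ngrad = (lambda th: -np.asarray(grad(th))) if grad is not None else None
    rng = np.random.default_rng(seed)
    best = None
    x0 = start.copy()

    def _boundary_probe(x):
        """Detect a monotone objective: a step past x along the travel
        direction keeps climbing when the maximum sits on the boundary
        (e.g. complete separation)."""
        direction = x - start
        nd = np.linalg.norm(direction)
        if nd < 1e-8:
            return False
        probe = x + direction / nd * max(1.0, 0.2 * np.linalg.norm(x))
        fp = obj(probe)
        return np.isfinite(fp) and fp > obj(x) + 1e-9

    with np.errstate(invalid="ignore", over="ignore"):
        for attempt in range(retries + 1):
            res = optimize.minimize(neg, x0, jac=ngrad, method="BFGS",
                                    options={"gtol": gtol, "maxiter": 500})
            if not res.success or not np.isfinite(res.fun):
                res = optimize.minimize(neg, x0, method="Nelder-Mead",
                                        options={"xatol": 1e-10, "fatol": 1e-12,
                                                 "maxiter": 4000})
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
            if best is not None:
                x = np.atleast_1d(best.x)
                if _boundary_probe(x):
                    warnings.warn(
                        "maximum appears to lie on the domain boundary "
                        "(objective still increasing beyond the returned point)",
                        BoundaryWarning)
                    return x, -best.fun
                g = fd_gradient(obj, x) if grad is None else np.asarray(grad(x))
                if np.linalg.norm(g) <= 1e-5 * max(1.0, abs(best.fun)):
                    return x, -best.fun
            x0 = start * (1.0 + 0.1 * rng.standard_normal(start.size)) + \
                0.01 * rng.standard_normal(start.size)
    if best is None:
        raise ConvergenceError("optimizer failed on every restart")
    warnings.warn("maximum appears to lie on the domain boundary "
                  "(gradient does not vanish at the returned point)",
                  BoundaryWarning)
    return np.atleast_1d(best.x), -best.fun


def find_mle(model: ParametricModel, start=None) -> np.ndarray:
    """Maximum likelihood estimate θ̂.

    Emits :class:`BoundaryWarning` when the likelihood appears monotone
    (maximum on the boundary, e.g. complete separation in logistic models).
    """
    if start is None:
        start = np.zeros(model.dim) + 0.5
    obj = model.objective(use_prior=False)
    if not np.isfinite(obj(np.atleast_1d(np.asarray(start, float)))):
        raise ValueError("start point outside the parameter domain")
    x, _ = _maximize(obj, start, model.score)
    return x


def find_map(model: ParametricModel, start=None) -> np.ndarray:
    """Maximum a posteriori estimate θ̃ (mode of ℓ + log π)."""
    if start is None:
        start = np.zeros(model.dim) + 0.5
    grad = None
    if model.score is not None and model.prior_score is not None:
        grad = lambda th: np.asarray(model.score(th)) + np.asarray(model.prior_score(th))
    x, _ = _maximize(model.logpost, start, grad)
    return x


def observed_info(model: ParametricModel, at, use_prior: bool = False) -> np.ndarray:
    """Observed information j(θ) = -∇²ℓ(θ) (or of ℓ + log π when ``use_prior``).

    Uses analytic Hessians when the model supplies them, otherwise central
    finite differences.
    """
    at = np.atleast_1d(np.asarray(at, dtype=float))
    if model.hessian is not None and (not use_prior or model.prior_hessian is not None):
        H = np.atleast_2d(np.asarray(model.hessian(at), dtype=float))
        if use_prior:
            H = H + np.atleast_2d(np.asarray(model.prior_hessian(at), dtype=float))
    else:
        H = fd_hessian(model.objective(use_prior), at)
    J = -H
    return 0.5 * (J + J.T)


def third_derivatives(model: ParametricModel, at, use_prior: bool = False,
                      unmixed_only: bool = False) -> np.ndarray:
    """Third derivatives of ℓ (or ℓ + log π): unmixed vector t or full tensor."""
    at = np.atleast_1d(np.asarray(at, dtype=float))
    if model.third is not None and (not use_prior or model.prior_third is not None):
        T = np.asarray(model.third(at), dtype=float)
        T = T.reshape((model.dim,) * 3)
        if use_prior:
            T = T + np.asarray(model.prior_third(at), dtype=float).reshape((model.dim,) * 3)
        return np.einsum("iii->i", T).copy() if unmixed_only else T
    return fd_third(model.objective(use_prior), at, unmixed_only=unmixed_only)


def estimate_set(model: ParametricModel, start=None, use_prior_derivs: bool = True,
                 with_tensor: bool = False) -> EstimateSet:
    """Compute θ̂, θ̃ and the local derivative information in one pass.

    ``use_prior_derivs`` selects the derivative target at the MAP: the
    log-posterior (default, consistent with the skew-modal construction) or
    the log-likelihood only.
    """
    mle = find_mle(model, start=start)
    map_ = find_map(model, start=mle)
    n = model.n_obs if model.n_obs is not None else 1
    return EstimateSet(
        mle=mle,
        map=map_,
        info_mle=observed_info(model, mle, use_prior=False),
        info_map=observed_info(model, map_, use_prior=use_prior_derivs),
        third_unmixed_map=third_derivatives(model, map_, use_prior=use_prior_derivs,
                                            unmixed_only=True),
        third_tensor_map=(third_derivatives(model, map_, use_prior=use_prior_derivs)
                          if with_tensor else None),
        n_obs=int(n),
        use_prior_derivs=use_prior_derivs,
    )


# ---------------------------------------------------------------------------
# profile likelihood
# ---------------------------------------------------------------------------

def _constrained_max(model: ParametricModel, interest_index: int, psi: float,
                     lam_start: np.ndarray):
    """Maximize ℓ over the nuisance block at fixed ψ."""
    idx = [i for i in range(model.dim) if i != interest_index]

    def assemble(lam):
        th = np.empty(model.dim)
        th[interest_index] = psi
        th[idx] = lam
        return th

    neg = lambda lam: -float(model.loglik(assemble(lam)))
    res = optimize.minimize(neg, lam_start, method="BFGS",
                            options={"gtol": 1e-9, "maxiter": 500})
    if not res.success:
        res2 = optimize.minimize(neg, res.x if np.all(np.isfinite(res.x)) else lam_start,
                                 method="Nelder-Mead",
                                 options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
        if np.isfinite(res2.fun) and res2.fun <= res.fun:
            res = res2
    ok = np.isfinite(res.fun)
    lam = np.atleast_1d(res.x)
    return lam, -res.fun, ok, assemble(lam)


def profile(model: ParametricModel, interest_index: int, psi_grid) -> ProfileCache:
    """Profile log-likelihood ℓ_p(ψ) over ``psi_grid`` with warm starts.

    The grid must cover ψ̂.  Points where the constrained optimization fails
    are flagged (``cache.ok``) and excluded by downstream consumers.
    """
    if model.dim < 2:
        raise ValueError("profile requires d >= 2")
    psi_grid = np.sort(np.asarray(psi_grid, dtype=float))
    mle = find_mle(model)
    psi_hat = float(mle[interest_index])
    idx = [i for i in range(model.dim) if i != interest_index]
    lam_hat = mle[idx]
    if not (psi_grid.min() <= psi_hat <= psi_grid.max()):
        raise ValueError("psi_grid does not cover the MLE of the interest parameter")

    m = psi_grid.size
    lp = np.full(m, -np.inf)
    lams = np.zeros((m, model.dim - 1))
    jll_ld = np.full(m, np.nan)
    ok = np.zeros(m, dtype=bool)

    def jll_logdet(theta):
        J = observed_info(model, theta, use_prior=False)
        sub = J[np.ix_(idx, idx)]
        sign, ld = np.linalg.slogdet(sub)
        if sign <= 0:
            raise np.linalg.LinAlgError(
                f"singular nuisance information block at psi={theta[interest_index]:.6g}")
        return ld

    # proceed outward from the grid point nearest ψ̂ in both directions
    k0 = int(np.argmin(np.abs(psi_grid - psi_hat)))
    order = list(range(k0, m)) + list(range(k0 - 1, -1, -1))
    warm = {k0: lam_hat, k0 - 1: lam_hat}
    for k in order:
        start = warm.get(k, lam_hat)
        lam, val, good, theta = _constrained_max(model, interest_index, psi_grid[k], start)
        lams[k] = lam
        lp[k] = val
        ok[k] = good
        if good:
            try:
                jll_ld[k] = jll_logdet(theta)
            except np.linalg.LinAlgError:
                ok[k] = False
            if k >= k0 and k + 1 < m:
                warm[k + 1] = lam
            if k < k0 and k - 1 >= 0:
                warm[k - 1] = lam
        if not good:
            warnings.warn(f"constrained maximization failed at psi={psi_grid[k]:.6g}; "
                          "point excluded", UserWarning)

    lp_max = float(model.loglik(mle))
    # j_p(ψ̂) by central difference of ℓ_p around ψ̂
    h = _H2 ** 0.75 * max(1.0, abs(psi_hat))
    _, lp_p, _, _ = _constrained_max(model, interest_index, psi_hat + h, lam_hat)
    _, lp_m, _, _ = _constrained_max(model, interest_index, psi_hat - h, lam_hat)
    jp = -(lp_p - 2.0 * lp_max + lp_m) / h**2

    theta_hat = np.empty(model.dim)
    theta_hat[interest_index] = psi_hat
    theta_hat[idx] = lam_hat
    return ProfileCache(
        interest_index=interest_index, psi_grid=psi_grid, lambda_hat=lams, lp=lp,
        jp_at_mle=float(jp), jll_logdet=jll_ld, jll_logdet_at_mle=jll_logdet(theta_hat),
        psi_hat=psi_hat, lambda_at_mle=lam_hat, lp_max=lp_max, ok=ok,
    )
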