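"""Built-in example models, closed-form oracles, and simulators.

Two fixtures cover the two posterior shapes the approximations are aimed at:

* an exponential sampling model E(Y) = θ with the Jeffreys prior π(θ) ∝ 1/θ,
  whose posterior is inverse gamma with shape n and rate t_n = Σ y_i and
  therefore admits an exact tail area through the regularized incomplete
  gamma function;
* a logistic regression with independent N(0, 25) coefficient priors, the
  standard mildly-skewed multivariate posterior.

Everything is generated programmatically; no data files ship with the
package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special

from .model import ParametricModel

__all__ = [
    "make_exponential",
    "simulate_exponential",
    "make_logistic",
    "simulate_logistic",
    "make_synthetic_cushing",
    "MODEL_REGISTRY",
    "write_dataset",
    "read_dataset",
]


def make_exponential(n: int, mle: float) -> ParametricModel:
    """Exponential scale model summarized by (n, θ̂), Jeffreys prior.

    ℓ(θ) = -n log θ - t_n/θ with t_n = n·θ̂.  The posterior is inverse gamma
    (shape n, rate t_n): P(θ ≤ θ0 | y) = Q(n, t_n/θ0) with Q the upper
    regularized incomplete gamma function.
    """
    if n < 1 or mle <= 0:
        raise ValueError("need n >= 1 and mle > 0")
    n = int(n)
    t = n * float(mle)

    def loglik(theta):
        th = float(np.atleast_1d(theta)[0])
        if th <= 0:
            return -np.inf
        return -n * np.log(th) - t / th

    def logprior(theta):
        th = float(np.atleast_1d(theta)[0])
        if th <= 0:
            return -np.inf
        return -np.log(th)

    def posterior_cdf(theta0):
        th = float(theta0)
        if th <= 0:
            return 0.0
        return float(special.gammaincc(n, t / th))

    score = lambda th: np.array([-n / th[0] + t / th[0] ** 2])
    hessian = lambda th: np.array([[n / th[0] ** 2 - 2 * t / th[0] ** 3]])
    third = lambda th: np.array([-2 * n / th[0] ** 3 + 6 * t / th[0] ** 4]).reshape(1, 1, 1)
    expected_info = lambda th: np.array([[n / th[0] ** 2]])
    prior_score = lambda th: np.array([-1.0 / th[0]])
    prior_hessian = lambda th: np.array([[1.0 / th[0] ** 2]])
    prior_third = lambda th: np.array([-2.0 / th[0] ** 3]).reshape(1, 1, 1)

    return ParametricModel(
        dim=1, loglik=loglik, logprior=logprior, param_names=["theta"],
        posterior_cdf=posterior_cdf, data={"n": n, "t": t, "mle": float(mle)},
        n_obs=n, score=score, hessian=hessian, third=third,
        expected_info=expected_info, prior_score=prior_score,
        prior_hessian=prior_hessian, prior_third=prior_third,
    )


def simulate_exponential(theta: float, n: int, seed: int) -> np.ndarray:
    """Reproducible i.i.d. exponential draws with mean θ."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    if n < 1:
        raise ValueError("n must be a positive integer")
    rng = np.random.default_rng(seed)
    return rng.exponential(scale=theta, size=int(n))


def make_logistic(design, response, prior_sd: float = 5.0) -> ParametricModel:
    """Logistic regression with independent N(0, prior_sd²) coefficient priors.

    The design matrix must include the intercept column and have full column
    rank.  Analytic score -- Xᵀ(y - p) -- Hessian -XᵀWX and third-derivative
    tensor -Σ w_i(1-2p_i) x_i⊗x_i⊗x_i are supplied, with w = p(1-p).
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("design/response shapes disagree")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    n, p = X.shape
    v = float(prior_sd) ** 2

    def _probs(beta):
        return special.expit(X @ beta)

    def loglik(beta):
        beta = np.asarray(beta, dtype=float).ravel()
        eta = X @ beta
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    def logprior(beta):
        beta = np.asarray(beta, dtype=float).ravel()
        return float(-0.5 * np.dot(beta, beta) / v)

    def score(beta):
        return X.T @ (y - _probs(beta))

    def hessian(beta):
        w = _probs(beta)
        w = w * (1.0 - w)
        return -(X.T * w) @ X

    def third(beta):
        pr = _probs(beta)
        w = pr * (1.0 - pr) * (1.0 - 2.0 * pr)
        return -np.einsum("n,ni,nj,nk->ijk", w, X, X, X)

    def expected_info(beta):
        return -hessian(beta)

    prior_score = lambda b: -np.asarray(b, dtype=float).ravel() / v
    prior_hessian = lambda b: -np.eye(p) / v
    prior_third = lambda b: np.zeros((p, p, p))

    names = [f"beta{i}" for i in range(p)]
    return ParametricModel(
        dim=p, loglik=loglik, logprior=logprior, param_names=names,
        data={"design": X, "response": y, "prior_sd": float(prior_sd)},
        n_obs=n, score=score, hessian=hessian, third=third,
        expected_info=expected_info, prior_score=prior_score,
        prior_hessian=prior_hessian, prior_third=prior_third,
    )


def simulate_logistic(beta, design, seed: int) -> np.ndarray:
    """Reproducible Bernoulli draws with mean logit⁻¹(Xβ)."""
    X = np.asarray(design, dtype=float)
    beta = np.asarray(beta, dtype=float).ravel()
    if X.shape[1] != beta.size:
        raise ValueError("design/beta shapes disagree")
    rng = np.random.default_rng(seed)
    prob = special.expit(X @ beta)
    return (rng.random(X.shape[0]) < prob).astype(float)


def make_synthetic_cushing(seed: int = 7, beta=(-0.1, 0.2, -0.9),
                           prior_sd: float = 5.0) -> ParametricModel:
    """Synthetic stand-in with the layout of the 27-patient Cushing's-syndrome
    logistic study: binary response, intercept plus two binary covariates.

    This is *simulated* data (the real metabolite measurements are not
    bundled); it reproduces only the structure needed to exercise the
    nuisance-parameter and multivariate methods.
    """
    rng = np.random.default_rng(seed)
    n = 27
    X = np.column_stack([
        np.ones(n),
        (rng.random(n) < 0.5).astype(float),
        (rng.random(n) < 0.4).astype(float),
    ])
    # guard against rank deficiency in an unlucky draw
    while np.linalg.matrix_rank(X) < 3:  # pragma: no cover
        X[:, 1] = (rng.random(n) < 0.5).astype(float)
        X[:, 2] = (rng.random(n) < 0.4).astype(float)
    y = simulate_logistic(beta, X, seed=seed + 1)
    return make_logistic(X, y, prior_sd=prior_sd)


def write_dataset(path, data: np.ndarray, columns=None) -> None:
    """CSV round-trip writer for generated datasets (one row per observation)."""
    arr = np.atleast_2d(np.asarray(data, dtype=float))
    if arr.shape[0] == 1 and arr.shape[1] > 1:
        arr = arr.T
    if columns is None:
        columns = [f"y{i}" for i in range(arr.shape[1])] if arr.shape[1] > 1 else ["y"]
    pd.DataFrame(arr, columns=columns).to_csv(path, index=False)


def read_dataset(path) -> pd.DataFrame:
    """Read a delimited dataset (CSV/TSV autodetected by extension)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep)


def _registry_exponential(*, n=None, mle=None, data=None, **_):
    if data is not None:
        y = np.asarray(data, dtype=float).ravel()
        return make_exponential(len(y), float(np.mean(y)))
    return make_exponential(int(n), float(mle))


def _registry_logistic(*, data=None, prior_sd=5.0, response_col=None, **_):
    if data is None:
        return make_synthetic_cushing(prior_sd=prior_sd)
    df = pd.DataFrame(data)
    rcol = response_col or df.columns[-1]
    y = df[rcol].to_numpy(dtype=float)
    X = df.drop(columns=[rcol]).to_numpy(dtype=float)
    if not np.allclose(X[:, 0], 1.0):
        X = np.column_stack([np.ones(len(y)), X])
    return make_logistic(X, y, prior_sd=prior_sd)


MODEL_REGISTRY = {
    "exponential": _registry_exponential,
    "logistic": _registry_logistic,
}
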