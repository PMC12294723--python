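import numpy as np
import pytest

import bdmeasure as b


@pytest.fixture(scope="session")
def exp6():
    """Exponential fixture with n=6, MLE 1.2, plus its estimate set."""
    model = b.make_exponential(6, 1.2)
    return model, b.estimate_set(model)


@pytest.fixture(scope="session")
def exp_by_n():
    """Exponential fixtures for n in {6, 12, 20, 40} with MLE fixed at 1.2."""
    out = {}
    for n in (6, 12, 20, 40):
        model = b.make_exponential(n, 1.2)
        out[n] = (model, b.estimate_set(model))
    return out


@pytest.fixture(scope="session")
def logistic_fixture():
    """Synthetic 27-row logistic model (binary response, two binary dummies)."""
    model = b.make_synthetic_cushing()
    return model, b.estimate_set(model, with_tensor=True)


@pytest.fixture(scope="session")
def rate_exponential():
    """The n=6 exponential model reparametrized by the rate λ = 1/θ.

    Jeffreys' prior transforms to π(λ) ∝ 1/λ and the posterior of λ is
    Gamma(n, rate t_n); used for reparametrization-invariance checks.
    """
    from scipy import stats

    n, mle = 6, 1.2
    tn = n * mle

    def loglik(lam):
        lam = float(np.atleast_1d(lam)[0])
        return -np.inf if lam <= 0 else n * np.log(lam) - tn * lam

    def logprior(lam):
        lam = float(np.atleast_1d(lam)[0])
        return -np.inf if lam <= 0 else -np.log(lam)

    model = b.ParametricModel(
        dim=1, loglik=loglik, logprior=logprior,
        posterior_cdf=lambda lam: float(stats.gamma.cdf(lam, n, scale=1.0 / tn)),
        n_obs=n,
        expected_info=lambda lam: np.array([[n / lam[0] ** 2]]),
    )
    return model, b.estimate_set(model, start=[1.0])
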