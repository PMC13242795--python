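"""Training objectives: time weighting, printed discrete divergence, Laplace KL."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import digamma, gammaln

from pifgen.distributions import kl_dirichlet_exact, DirichletParams
from pifgen.losses import (
    LossWeights,
    eq_weight_continuous,
    loss_continuous,
    loss_discrete,
    loss_laplace,
    total_loss,
)


def scalar_discrete_divergence(a_true, a_hat):
    """Independent scalar re-implementation of the printed type objective."""
    total = 0.0
    for at, ah in zip(a_true, a_hat):
        total += gammaln(at) - gammaln(ah) + (ah - at) * (digamma(ah) - digamma(1.0))
    return total


class TestContinuousLoss:
    def test_zero_at_truth_any_time(self, rng):
        mu = rng.normal(size=(5, 3))
        for t in (0.0, 0.3, 0.99):
            assert loss_continuous(mu, mu, t, 0.009, 1.0) == 0.0

    def test_zero_weight_at_t0(self, rng):
        mu = rng.normal(size=(4, 3))
        assert loss_continuous(mu, mu + 1.0, 0.0, 0.009, 1.0) == 0.0

    def test_printed_weight_at_half(self):
        """Single atom, unit error along x: loss equals the printed weight."""
        g = 0.009
        w = (1 - g**0.5) ** 2 / (2 * g**0.5)
        got = loss_continuous(
            np.array([[1.0, 0, 0]]), np.zeros((1, 3)), 0.5, g, 1.0
        )
        assert got == pytest.approx(w, rel=1e-12)

    def test_weight_increasing_in_t(self):
        grid = np.linspace(0, 1, 101)
        w = [eq_weight_continuous(t, 0.009, 1.0) for t in grid]
        assert np.all(np.diff(w) > 0) and w[0] == 0.0

    def test_weight_finite_at_t1(self):
        assert np.isfinite(eq_weight_continuous(1.0, 0.009, 1.0))


class TestDiscreteLoss:
    def test_zero_at_truth(self, rng):
        a = rng.uniform(0.1, 2.0, size=(6, 4))
        assert loss_discrete(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_scalar_implementation(self, rng):
        a_true = np.array([0.75, 0.25])
        a_hat = np.array([0.5, 0.5])
        assert loss_discrete(a_hat, a_true) == pytest.approx(
            scalar_discrete_divergence(a_true, a_hat), rel=1e-12
        )
        for _ in range(20):
            at = rng.uniform(0.05, 3.0, size=5)
            ah = rng.uniform(0.05, 3.0, size=5)
            assert loss_discrete(ah, at) == pytest.approx(
                scalar_discrete_divergence(at, ah), rel=1e-10
            )

    def test_perturbation_toward_truth_decreases(self, rng):
        """On equal-total-concentration pairs (the interpolation-path regime,
        where one-hot data and the uniform prior both sum to 1) moving the
        prediction toward the truth lowers the objective."""
        for _ in range(100):
            at = rng.dirichlet(np.ones(4))  # sums to 1 like every Eq-6 interpolant
            ah = rng.dirichlet(np.ones(4))
            at, ah = at + 0.05, ah + 0.05  # keep away from the boundary
            at, ah = at / at.sum(), ah / ah.sum()
            l0 = loss_discrete(ah, at)
            l1 = loss_discrete(ah + 0.01 * (at - ah), at)
            assert l1 < l0

    def test_nonnegative_on_equal_sum_pairs(self, rng):
        for _ in range(1000):
            at = rng.dirichlet(np.ones(3)) + 1e-3
            ah = rng.dirichlet(np.ones(3)) + 1e-3
            at, ah = at / at.sum(), ah / ah.sum()
            assert loss_discrete(ah, at) >= 0.0

    def test_exact_kl_form_agrees_with_oracle(self, rng):
        at = rng.uniform(0.2, 2.0, size=4)
        ah = rng.uniform(0.2, 2.0, size=4)
        got = loss_discrete(ah, at, form="exact_kl")
        ref = kl_dirichlet_exact(DirichletParams(at), DirichletParams(ah))
        assert got == pytest.approx(ref, rel=1e-12)

    def test_printed_vs_exact_kl_discrepancy_is_finite_and_reported(self, rng):
        """The printed objective is not the closed-form KL; record the gap."""
        worst = 0.0
        for _ in range(1000):
            at = rng.dirichlet(np.ones(3)) + 1e-2
            ah = rng.dirichlet(np.ones(3)) + 1e-2
            at, ah = at / at.sum(), ah / ah.sum()
            worst = max(
                worst, abs(loss_discrete(ah, at) - loss_discrete(ah, at, "exact_kl"))
            )
        assert np.isfinite(worst)

    def test_boundary_rejected(self):
        with pytest.raises(ValueError):
            loss_discrete(np.array([1.0, 0.0]), np.array([0.5, 0.5]))


class TestLaplaceLoss:
    def test_zero_at_truth(self, rng):
        mu = rng.normal(size=(3, 3))
        assert loss_laplace(mu, mu, 0.5, 0.009, 1.0) == 0.0

    def test_small_error_taylor_limit(self):
        """|d|/b + exp(-|d|/b) - 1 -> d^2/(2 b^2) for small d."""
        d = 1e-4
        t, g, b0 = 0.5, 0.009, 1.0
        b_t = g**t * b0
        got = loss_laplace(np.array([[d, 0, 0]]), np.zeros((1, 3)), t, g, b0)
        assert got == pytest.approx(d**2 / (2 * b_t**2), rel=1e-3)

    def test_matches_laplace_kl_quadrature(self):
        from scipy.stats import laplace

        d, b = 0.7, 0.4
        ref = quad(
            lambda x: laplace.pdf(x, 0, b)
            * (laplace.logpdf(x, 0, b) - laplace.logpdf(x, d, b)),
            -30,
            30,
        )[0]
        u = d / b
        assert u + np.expm1(-u) == pytest.approx(ref, abs=1e-6)
        # and the loss of a single-axis error d at b_t = b reproduces it
        t = np.log(b) / np.log(0.009)  # b_t = gamma^t = b
        got = loss_laplace(np.array([[d, 0, 0]]), np.zeros((1, 3)), t, 0.009, 1.0)
        assert got == pytest.approx(ref, abs=1e-6)

    def test_dirac_endpoint_convention(self):
        mu = np.ones((2, 3))
        assert loss_laplace(mu, mu, 1.0, 0.009, 0.0) == 0.0
        assert loss_laplace(mu, mu + 1, 1.0, 0.009, 0.0) == np.inf


class TestTotalLoss:
    def _args(self, rng, n=5, K=4):
        mu_t = rng.normal(size=(n, 3))
        mu_h = rng.normal(size=(n, 3))
        a_t = rng.uniform(0.1, 1.0, size=(n, K))
        a_h = rng.uniform(0.1, 1.0, size=(n, K))
        return mu_h, a_h, mu_t, a_t

    def test_perfect_prediction_zero(self, rng):
        mu_h, a_h, _, _ = self._args(rng)
        assert total_loss(mu_h, a_h, mu_h, a_h, 0.5, 0.009, 1.0) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_lambda_linearity(self, rng):
        mu_h, a_h, mu_t, a_t = self._args(rng)
        base_x = total_loss(
            mu_h, a_t, mu_t, a_t, 0.5, 0.009, 1.0, LossWeights(1.0, 1.0)
        )
        double_x = total_loss(
            mu_h, a_t, mu_t, a_t, 0.5, 0.009, 1.0, LossWeights(2.0, 1.0)
        )
        assert double_x == pytest.approx(2 * base_x, rel=1e-12)

    def test_lambda_x_zero_equiv(self, rng):
        mu_h, a_h, mu_t, a_t = self._args(rng)
        lv_only = total_loss(
            mu_t, a_h, mu_t, a_t, 0.5, 0.009, 1.0, LossWeights(1e-12, 3.0)
        )
        assert lv_only == pytest.approx(3.0 * loss_discrete(a_h, a_t), rel=1e-9)

    def test_fixed_atoms_excluded(self, rng):
        """Perturbing predictions on non-target atoms leaves the loss unchanged."""
        mu_h, a_h, mu_t, a_t = self._args(rng)
        mask = np.array([True, True, False, False, True])
        l0 = total_loss(mu_h, a_h, mu_t, a_t, 0.5, 0.009, 1.0, target_mask=mask)
        mu_h2, a_h2 = mu_h.copy(), a_h.copy()
        mu_h2[~mask] += 100.0
        a_h2[~mask] *= 7.0
        l1 = total_loss(mu_h2, a_h2, mu_t, a_t, 0.5, 0.009, 1.0, target_mask=mask)
        assert l0 == l1
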