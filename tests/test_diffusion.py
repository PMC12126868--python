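"""Forward/posterior diffusion kernels against closed forms and brute force."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from poligen.diffusion import (EmpiricalPrior, categorical_forward,
                               categorical_posterior, categorical_posterior_step,
                               gaussian_forward, gaussian_posterior_step,
                               project_zero_com, sample_prior, _Q)
from poligen.schedule import NoiseSchedule


@pytest.fixture(scope="module")
def sched():
    return NoiseSchedule(T=8)


class TestZeroCom:
    def test_constant_input_maps_to_origin(self):
        x = np.tile([1.0, 2.0, 3.0], (4, 1))
        assert np.allclose(project_zero_com(x), 0.0)

    def test_idempotent(self, rng):
        x = project_zero_com(rng.normal(size=(5, 3)))
        assert np.allclose(project_zero_com(x), x)

    def test_mean_below_tolerance(self, rng):
        x = project_zero_com(rng.normal(size=(5, 3)))
        assert np.linalg.norm(x.mean(axis=0)) < 1e-12


class TestGaussianForward:
    def test_t_zero_is_nearly_identity(self, sched, rng):
        X0 = project_zero_com(rng.normal(size=(6, 3)))
        eps = project_zero_com(rng.normal(size=(6, 3)))
        Xt = gaussian_forward(X0, 0, sched, eps)
        assert np.allclose(Xt, X0, atol=0.05)  # alpha_bar_0 ~ 1 up to clamp

    def test_closed_form_mixing(self, sched, rng):
        # with alpha_bar=0.25: Xt = 0.5 X0 + sqrt(0.75) eps exactly
        X0 = project_zero_com(rng.normal(size=(5, 3)))
        eps = project_zero_com(rng.normal(size=(5, 3)))
        ab = 0.25
        expected = 0.5 * X0 + np.sqrt(0.75) * eps
        assert np.allclose(np.sqrt(ab) * X0 + np.sqrt(1 - ab) * eps, expected)
        # and the schedule-driven version preserves zero CoM
        Xt = gaussian_forward(X0, 4, sched, eps)
        assert np.linalg.norm(Xt.mean(axis=0)) < 1e-6


class TestGaussianPosterior:
    def test_final_step_returns_clean_prediction(self, rng):
        # at t=1 with alpha_bar_0 clamped to ~1 the posterior mean tends to
        # X0_hat with vanishing variance (exact only at alpha_bar_0 = 1; the
        # clamp leaves a relative error ~ (1-ab_0)/(1-ab_1))
        sched = NoiseSchedule(T=8, nu={"coords": 1.0})
        X0h = project_zero_com(rng.normal(size=(4, 3)))
        Xt = project_zero_com(rng.normal(size=(4, 3)))
        out = gaussian_posterior_step(X0h, Xt, 1, sched, rng)
        # error bound: (1-ab_0)/(1-ab_1) * (|X0h| + |Xt|) ~ 0.0036 * 4
        assert np.allclose(out, X0h, atol=0.02)
        # deterministic: the t=1 step adds no noise
        out2 = gaussian_posterior_step(X0h, Xt, 1, sched, rng)
        assert np.array_equal(out, out2)

    def test_degenerate_identity(self, sched, rng):
        # X0_hat = Xt and nearly flat schedule segment -> mean ~ Xt
        X = project_zero_com(rng.normal(size=(4, 3)))
        ab_t = sched.alpha_bar(2, "coords")
        ab_p = sched.alpha_bar(1, "coords")
        a_t = ab_t / ab_p
        mean = (np.sqrt(ab_p) * (1 - a_t) / (1 - ab_t)) * X \
            + (np.sqrt(a_t) * (1 - ab_p) / (1 - ab_t)) * X
        coeff_sum = (np.sqrt(ab_p) * (1 - a_t) + np.sqrt(a_t) * (1 - ab_p)) / (1 - ab_t)
        assert np.allclose(mean, coeff_sum * X)
        assert coeff_sum == pytest.approx(1.0, abs=0.05)

    def test_monte_carlo_moments_match_formulas(self, sched):
        rng = np.random.default_rng(7)
        t = 5
        X0h = project_zero_com(rng.normal(size=(3, 3)))
        Xt = project_zero_com(rng.normal(size=(3, 3)))
        n = 100_000
        draws = np.stack([gaussian_posterior_step(X0h, Xt, t, sched, rng)
                          for _ in range(n // 100)])
        ab_t = sched.alpha_bar(t, "coords")
        ab_p = sched.alpha_bar(t - 1, "coords")
        a_t = float(sched.alpha(t, "coords"))
        b_t = 1 - a_t
        mean = (np.sqrt(ab_p) * b_t / (1 - ab_t)) * X0h \
            + (np.sqrt(a_t) * (1 - ab_p) / (1 - ab_t)) * Xt
        var = b_t * (1 - ab_p) / (1 - ab_t)
        m = draws.shape[0]
        se_mean = np.sqrt(var / m)
        assert np.all(np.abs(draws.mean(axis=0) - mean) < 3.5 * se_mean + 1e-9)
        # zero-CoM projected noise reduces per-coordinate variance by (1 - 1/N)
        exp_var = var * (1 - 1.0 / 3)
        sample_var = draws.var(axis=0)
        se_var = exp_var * np.sqrt(2.0 / (m - 1))
        assert np.all(np.abs(sample_var - exp_var) < 4 * se_var)


class TestCategorical:
    def test_transition_rows_are_stochastic(self, sched):
        p = np.array([0.5, 0.3, 0.2])
        for t in range(1, 9):
            Q = _Q(float(sched.alpha_bar(t, "atom_types")), p)
            assert np.allclose(Q.sum(axis=1), 1.0)
            assert np.all(Q >= 0)

    def test_identity_limit(self, sched, rng):
        H0 = np.eye(4)[[0, 2, 1, 3, 3]]
        out = categorical_forward(H0, 0, sched, np.full(4, 0.25), rng, "atom_types")
        assert np.array_equal(out, H0.argmax(axis=1))

    def test_prior_limit(self, sched):
        rng = np.random.default_rng(3)
        p = np.array([0.7, 0.2, 0.1])
        H0 = np.eye(3)[np.zeros(30_000, dtype=int)]
        out = categorical_forward(H0, sched.T, sched, p, rng, "atom_types")
        freq = np.bincount(out, minlength=3) / len(out)
        se = np.sqrt(p * (1 - p) / len(out))
        assert np.all(np.abs(freq - p) < 3.5 * se + 1e-3)

    def test_posterior_equals_bayes_enumeration(self):
        # independent oracle: compose single-step kernels by matrix product,
        # then apply Bayes' rule by exhaustive enumeration over x_{t-1}
        sched = NoiseSchedule(T=4)
        p = np.array([0.5, 0.2, 0.2, 0.05, 0.05])
        K = 5
        for t in range(2, 5):
            Qs = [_Q(float(sched.alpha(i, "bond_types")), p) for i in range(1, t + 1)]
            Qbar_prev = _Q(float(sched.alpha_bar(0, "bond_types")), p)
            for Qi in Qs[:-1]:
                Qbar_prev = Qbar_prev @ Qi
            Qt = Qs[-1]
            for x0 in range(K):
                for xt in range(K):
                    joint = np.array([Qbar_prev[x0, i] * Qt[i, xt] for i in range(K)])
                    oracle = joint / joint.sum()
                    H0 = np.eye(K)[[x0]]
                    ours = categorical_posterior(H0, np.array([xt]), t, sched,
                                                 p, "bond_types")[0]
                    assert np.allclose(ours, oracle, atol=1e-10)

    def test_final_step_point_mass(self, sched):
        p = np.full(4, 0.25)
        H0h = np.eye(4)[[2]]
        post = categorical_posterior(H0h, np.array([1]), 1, sched, p, "atom_types")
        # point mass at x0_hat up to the alpha_bar_0 clamp (~1 - 1.6e-4)
        assert post[0, 2] > 0.99

    def test_posterior_rows_normalized(self, sched, rng):
        p = np.array([0.4, 0.3, 0.3])
        H0h = rng.dirichlet(np.ones(3), size=6)
        xt = rng.integers(0, 3, size=6)
        post = categorical_posterior(H0h, xt, 4, sched, p, "atom_types")
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_forward_composition_matches_marginal(self, sched):
        # composing single-step kernels equals the closed-form Q_bar
        p = np.array([0.6, 0.3, 0.1])
        for t in (2, 5, 8):
            composed = _Q(float(sched.alpha_bar(0, "atom_types")), p)
            for i in range(1, t + 1):
                composed = composed @ _Q(float(sched.alpha(i, "atom_types")), p)
            direct = _Q(float(sched.alpha_bar(t, "atom_types")), p)
            assert np.allclose(composed, direct, atol=1e-8)


class TestPriorSample:
    def test_geometry_and_symmetry(self, rng):
        prior = EmpiricalPrior.uniform()
        s = sample_prior(8, prior, rng, t=10)
        assert np.linalg.norm(s.coords.mean(axis=0)) < 1e-6
        assert np.array_equal(s.bond_cats, s.bond_cats.T)
        assert np.all(np.diag(s.bond_cats) == 0)

    def test_atom_frequencies_match_prior(self):
        rng = np.random.default_rng(11)
        p_atom = np.array([0.5, 0.25, 0.15, 0.1])
        prior = EmpiricalPrior(p_atom, np.full(4, 0.25))
        draws = np.concatenate([
            sample_prior(20, prior, rng).atom_cats for _ in range(2500)])
        freq = np.bincount(draws, minlength=4) / len(draws)
        se = np.sqrt(p_atom * (1 - p_atom) / len(draws))
        assert np.all(np.abs(freq - p_atom) < 3.5 * se + 1e-4)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st.integers(0, 10_000), t=st.integers(2, 8))
def test_posterior_probability_rows_always_normalize(seed, t):
    rng = np.random.default_rng(seed)
    sched = NoiseSchedule(T=8)
    K = int(rng.integers(2, 6))
    p = rng.dirichlet(np.ones(K))
    H0h = rng.dirichlet(np.ones(K), size=4)
    xt = rng.integers(0, K, size=4)
    post = categorical_posterior(H0h, xt, t, sched, p, "atom_types")
    assert np.allclose(post.sum(axis=1), 1.0, atol=1e-10)
    assert np.all(post >= 0)
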