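"""Joint log-density oracles and generative-model contracts."""

import numpy as np
import pytest
from scipy import stats

from rnfltrend.model import (
    DomainError,
    PopulationParams,
    PriorSpec,
    SectorDataset,
    log_density,
    sample_lkj,
    sample_prior,
    simulate_from_model,
)


def _toy_pop(rho=0.25):
    mu = np.array([60.0, 64.0, -0.7, -0.4, 0.3, 0.6])
    sd = np.array([10.0, 9.0, 0.5, 0.5, 0.3, 0.3])
    R = np.eye(6)
    R[0, 1] = R[1, 0] = 0.8
    R[2, 3] = R[3, 2] = 0.5
    R[4, 5] = R[5, 4] = 0.4
    return PopulationParams(mu=mu, Sigma=np.outer(sd, sd) * R, rho=rho)


def _toy_dataset():
    # 2 eyes x 3 visits, all paired, fixed arbitrary values
    return SectorDataset(
        eye_ids=["a", "b"],
        eye_index=np.array([0, 0, 0, 1, 1, 1]),
        t=np.array([0.0, 0.9, 2.1, 0.0, 1.1, 1.9]),
        y_s=np.array([61.2, 60.1, 58.9, 55.0, 54.2, 53.8]),
        y_c=np.array([64.8, 64.1, 63.0, 58.7, 58.1, 57.2]),
    )


def _toy_effects():
    return np.array(
        [
            [61.0, 64.5, -1.0, -0.8, 0.2, 0.5],
            [55.2, 58.5, -0.6, -0.7, 0.4, 0.7],
        ]
    )


def brute_force_log_density(data, b, pop, priors=None):
    """Term-by-term reference: explicit loops, scipy densities only."""
    total = 0.0
    for j in range(data.t.size):
        i = data.eye_index[j]
        t = data.t[j]
        r_s = data.y_s[j] - b[i, 0] - b[i, 2] * t
        r_c = data.y_c[j] - b[i, 1] - b[i, 3] * t
        s_s, s_c = np.exp(b[i, 4]), np.exp(b[i, 5])
        if np.isfinite(r_s) and np.isfinite(r_c):
            cov = np.array(
                [
                    [s_s**2, pop.rho * s_s * s_c],
                    [pop.rho * s_s * s_c, s_c**2],
                ]
            )
            total += stats.multivariate_normal.logpdf([r_s, r_c], cov=cov)
        elif np.isfinite(r_s):
            total += stats.norm.logpdf(r_s, scale=s_s)
        else:
            total += stats.norm.logpdf(r_c, scale=s_c)
    for i in range(len(data.eye_ids)):
        total += stats.multivariate_normal.logpdf(b[i], mean=pop.mu, cov=pop.Sigma)
    if priors is not None:
        total += np.sum(stats.norm.logpdf(pop.mu, priors.mu_loc, priors.mu_scale))
        sd = np.sqrt(np.diag(pop.Sigma))
        R = pop.Sigma / np.outer(sd, sd)
        total += np.sum(stats.halfnorm.logpdf(sd, scale=priors.sd_scale))
        total += (priors.lkj_eta - 1.0) * np.linalg.slogdet(R)[1]
        total -= 6 * np.log(2.0) + 6 * np.sum(np.log(sd))
        total += -np.log(2.0)
    return total


class TestLogDensity:
    def test_matches_brute_force_term_sum(self):
        data, b, pop = _toy_dataset(), _toy_effects(), _toy_pop()
        priors = PriorSpec()
        expected = brute_force_log_density(data, b, pop, priors)
        assert log_density(data, b, pop, priors) == pytest.approx(expected, abs=1e-10)

    def test_brute_force_with_unpaired_visits(self):
        data = _toy_dataset()
        data.y_c[1] = np.nan  # Spectralis-only visit
        data.y_s[4] = np.nan  # Cirrus-only visit
        b, pop = _toy_effects(), _toy_pop()
        expected = brute_force_log_density(data, b, pop)
        assert log_density(data, b, pop) == pytest.approx(expected, abs=1e-10)

    def test_zero_residual_paired_visit_closed_form(self):
        """One interpolated paired visit at unit SDs contributes -log(2*pi)."""
        pop = _toy_pop(rho=0.0)
        data = SectorDataset(
            eye_ids=["a"],
            eye_index=np.array([0]),
            t=np.array([0.0]),
            y_s=np.array([61.0]),
            y_c=np.array([64.0]),
        )
        b = np.array([[61.0, 64.0, -1.0, -1.0, 0.0, 0.0]])
        resid_term = log_density(data, b, pop) - stats.multivariate_normal.logpdf(
            b[0], mean=pop.mu, cov=pop.Sigma
        )
        assert resid_term == pytest.approx(-np.log(2 * np.pi), abs=1e-12)

    def test_rho_zero_factorizes_into_device_margins(self):
        data, b = _toy_dataset(), _toy_effects()
        pop = _toy_pop(rho=0.0)
        data_s = SectorDataset(
            eye_ids=data.eye_ids,
            eye_index=data.eye_index,
            t=data.t,
            y_s=data.y_s,
            y_c=np.full_like(data.y_c, np.nan),
        )
        data_c = SectorDataset(
            eye_ids=data.eye_ids,
            eye_index=data.eye_index,
            t=data.t,
            y_s=np.full_like(data.y_s, np.nan),
            y_c=data.y_c,
        )
        effects_term = sum(
            stats.multivariate_normal.logpdf(b[i], mean=pop.mu, cov=pop.Sigma)
            for i in range(2)
        )
        lhs = log_density(data, b, pop)
        rhs = log_density(data_s, b, pop) + log_density(data_c, b, pop) - effects_term
        assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_device_label_symmetry(self):
        data, b, pop = _toy_dataset(), _toy_effects(), _toy_pop()
        perm = [1, 0, 3, 2, 5, 4]
        data_sw = SectorDataset(
            eye_ids=data.eye_ids,
            eye_index=data.eye_index,
            t=data.t,
            y_s=data.y_c.copy(),
            y_c=data.y_s.copy(),
        )
        pop_sw = PopulationParams(
            mu=pop.mu[perm], Sigma=pop.Sigma[np.ix_(perm, perm)], rho=pop.rho
        )
        priors = PriorSpec()
        assert log_density(data_sw, b[:, perm], pop_sw, priors) == pytest.approx(
            log_density(data, b, pop, priors), abs=1e-10
        )

    def test_time_shift_with_intercept_compensation_is_invariant(self):
        data, b, pop = _toy_dataset(), _toy_effects(), _toy_pop()
        c = 1.7
        data_shift = SectorDataset(
            eye_ids=data.eye_ids,
            eye_index=data.eye_index,
            t=data.t + c,
            y_s=data.y_s,
            y_c=data.y_c,
        )
        b_shift = b.copy()
        b_shift[:, 0] -= b[:, 2] * c
        b_shift[:, 1] -= b[:, 3] * c
        # compare likelihood terms only: the effects prior is not shift-invariant
        def resid_term(d, eff):
            mvn = sum(
                stats.multivariate_normal.logpdf(eff[i], mean=pop.mu, cov=pop.Sigma)
                for i in range(2)
            )
            return log_density(d, eff, pop) - mvn

        assert resid_term(data_shift, b_shift) == pytest.approx(
            resid_term(data, b), abs=1e-10
        )

    def test_domain_errors(self):
        data, b = _toy_dataset(), _toy_effects()
        with pytest.raises(DomainError, match="positive definite"):
            PopulationParams(mu=np.zeros(6), Sigma=-np.eye(6), rho=0.0)
        with pytest.raises(DomainError, match="rho"):
            PopulationParams(mu=np.zeros(6), Sigma=np.eye(6), rho=1.0)
        pop = _toy_pop()
        with pytest.raises(ValueError, match="2 eyes"):
            log_density(data, b[:1], pop)


class TestSimulate:
    def test_degenerate_noise_limit_reproduces_population_lines(self):
        pop = _toy_pop()
        tiny = PopulationParams(
            mu=pop.mu.copy(),
            Sigma=np.eye(6) * 1e-12,
            rho=0.0,
        )
        tiny_mu = tiny.mu.copy()
        tiny_mu[4:] = np.log(1e-7)  # residual SDs ~ 0
        tiny = PopulationParams(mu=tiny_mu, Sigma=tiny.Sigma, rho=0.0)
        data, _ = simulate_from_model(tiny, [np.array([0.0, 1.0, 2.0])] * 3, seed=0)
        expected_s = tiny_mu[0] + tiny_mu[2] * data.t
        expected_c = tiny_mu[1] + tiny_mu[3] * data.t
        np.testing.assert_allclose(data.y_s, expected_s, atol=1e-5)
        np.testing.assert_allclose(data.y_c, expected_c, atol=1e-5)

    def test_effect_moments_match_population(self):
        """500 simulated eyes: effect means/covariances within 3 SEs."""
        pop = _toy_pop()
        n = 500
        _, b = simulate_from_model(pop, [np.array([0.0, 1.0])] * n, seed=123)
        se_mean = np.sqrt(np.diag(pop.Sigma) / n)
        np.testing.assert_array_less(np.abs(b.mean(axis=0) - pop.mu), 3 * se_mean)
        emp_cov = np.cov(b, rowvar=False)
        var = pop.Sigma
        se_cov = np.sqrt(
            (np.outer(np.diag(var), np.diag(var)) + var**2) / n
        )
        np.testing.assert_array_less(np.abs(emp_cov - var), 3.5 * se_cov)

    def test_seeded_determinism(self):
        pop = _toy_pop()
        design = [np.array([0.0, 0.5, 1.0])] * 4
        d1, b1 = simulate_from_model(pop, design, seed=9)
        d2, b2 = simulate_from_model(pop, design, seed=9)
        np.testing.assert_array_equal(d1.y_s, d2.y_s)
        np.testing.assert_array_equal(d1.y_c, d2.y_c)
        np.testing.assert_array_equal(b1, b2)

    def test_density_higher_at_generating_parameters(self):
        """Self-consistency: average log-density peaks near the truth."""
        pop = _toy_pop()
        design = [np.array([0.0, 0.75, 1.5, 2.25, 3.0])] * 30
        perturbed = PopulationParams(
            mu=pop.mu + np.array([5.0, -5.0, 0.5, -0.5, 0.5, -0.5]),
            Sigma=pop.Sigma,
            rho=pop.rho,
        )
        wins = 0
        for seed in range(10):
            data, b = simulate_from_model(pop, design, seed=seed)
            if log_density(data, b, pop) > log_density(data, b, perturbed):
                wins += 1
        assert wins >= 9


class TestPriorSampling:
    def test_lkj_draws_are_valid_correlation_matrices(self, rng):
        for _ in range(25):
            R = sample_lkj(6, 1.0, rng)
            np.testing.assert_allclose(np.diag(R), 1.0, atol=1e-12)
            assert np.all(np.linalg.eigvalsh(R) > -1e-10)

    def test_lkj_marginal_moments(self):
        """LKJ(1) off-diagonals: mean 0, var 1/(p+1) for p=3 matrices."""
        rng = np.random.default_rng(5)
        draws = np.array([sample_lkj(3, 1.0, rng)[0, 1] for _ in range(4000)])
        assert abs(draws.mean()) < 0.03
        assert draws.var() == pytest.approx(1.0 / 4.0, rel=0.1)

    def test_sample_prior_returns_valid_population(self, rng):
        priors = PriorSpec()
        for _ in range(20):
            pop = sample_prior(priors, rng)
            assert np.all(np.isfinite(pop.mu))
            assert abs(pop.rho) < 1
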