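"""Posterior summaries, slope classification, and Bayesian McNemar tests."""

import numpy as np
import pytest

from rnfltrend.cohort import CIRRUS, SPECTRALIS
from rnfltrend.sampler import PosteriorDraws
from rnfltrend.summaries import (
    bayesian_mcnemar,
    classify_slopes,
    mcnemar_from_table,
    proportions,
    summarize_sector,
)


def _draws_from_arrays(mu, Sigma=None, rho=None, beta=None, eye_ids=None):
    chains, n = mu.shape[:2]
    if Sigma is None:
        Sigma = np.zeros((chains, n, 6, 6))
        for k in range(6):
            Sigma[..., k, k] = 1.0
    if rho is None:
        rho = np.zeros((chains, n))
    if beta is None:
        beta = np.zeros((chains, n, 1, 2))
    eye_ids = eye_ids or [f"e{i}" for i in range(beta.shape[2])]
    zero = np.zeros_like(beta)
    return PosteriorDraws(
        sector="G", eye_ids=eye_ids, mu=mu, Sigma=Sigma, rho=rho,
        alpha=zero.copy(), beta=beta, lam=zero.copy(),
    )


class TestSummarizeSector:
    def test_point_mass_slope_difference(self):
        """Degenerate draws at -0.70 / -0.45: difference -0.25, CrI a point,
        verdict significantly faster (more negative) for the first device."""
        mu = np.zeros((2, 100, 6))
        mu[..., 2] = -0.70
        mu[..., 3] = -0.45
        s = summarize_sector(_draws_from_arrays(mu))
        d = s.diff_slope
        assert d["mean"] == pytest.approx(-0.25)
        assert d["lower"] == pytest.approx(-0.25)
        assert d["upper"] == pytest.approx(-0.25)
        assert s.verdicts["diff_slope"] == "negative"

    def test_credible_interval_classification_semantics(self, rng):
        """A slope posterior spanning (-0.88, -0.51) is significantly negative;
        one spanning (-0.21, 0.34) is null."""
        mu = np.zeros((2, 4000, 6))
        mu[..., 2] = rng.normal(-0.70, 0.094, size=(2, 4000))
        mu[..., 3] = rng.normal(0.065, 0.14, size=(2, 4000))
        s = summarize_sector(_draws_from_arrays(mu))
        assert s.slope[SPECTRALIS]["lower"] == pytest.approx(-0.88, abs=0.02)
        assert s.slope[SPECTRALIS]["upper"] == pytest.approx(-0.51, abs=0.02)
        assert s.verdicts[f"slope_{SPECTRALIS}"] == "negative"
        assert s.slope[CIRRUS]["lower"] < 0 < s.slope[CIRRUS]["upper"]
        assert s.verdicts[f"slope_{CIRRUS}"] == "null"

    def test_unit_ratio_is_neither_smaller_nor_larger(self):
        mu = np.zeros((2, 50, 6))
        mu[..., 4] = mu[..., 5] = np.log(2.0)
        s = summarize_sector(_draws_from_arrays(mu))
        assert s.ratio_resid_sd["mean"] == pytest.approx(1.0)
        assert s.verdicts["ratio_resid_sd"] == "null"

    def test_average_resid_sd_is_lognormal_mean_per_draw(self):
        mu = np.zeros((1, 10, 6))
        mu[..., 4] = np.log(1.8)
        Sigma = np.zeros((1, 10, 6, 6))
        for k in range(6):
            Sigma[..., k, k] = 0.16
        s = summarize_sector(_draws_from_arrays(mu, Sigma=Sigma))
        assert s.resid_sd[SPECTRALIS]["mean"] == pytest.approx(1.8 * np.exp(0.08))

    def test_refuses_failed_diagnostics_without_override(self, rng):
        mu = rng.standard_normal((2, 50, 6))
        d = _draws_from_arrays(mu)
        from rnfltrend.sampler import DiagnosticsReport
        import pandas as pd

        d.diagnostics = DiagnosticsReport(
            table=pd.DataFrame(), passed=False, rhat_max=1.01, ess_min=400
        )
        with pytest.raises(ValueError, match="diagnostics"):
            summarize_sector(d)
        summarize_sector(d, allow_failed_diagnostics=True)


class TestClassifySlopes:
    def test_point_mass_and_symmetric_draws(self, rng):
        beta = np.zeros((2, 500, 2, 2))
        beta[..., 0, :] = -0.5                       # point mass below zero
        beta[..., 1, :] = rng.standard_normal((2, 500, 2))  # symmetric about 0
        cl = classify_slopes(_draws_from_arrays(np.zeros((2, 500, 6)), beta=beta))
        assert cl.verdicts[SPECTRALIS][0] == "negative"
        assert cl.verdicts[SPECTRALIS][1] == "null"
        assert cl.verdicts[CIRRUS][0] == "negative"

    def test_matches_explicit_quantile_rule(self, rng):
        """Verdicts equal the explicit 2.5%/97.5% empirical-quantile rule."""
        for _ in range(100):
            loc = rng.uniform(-1, 1)
            scale = rng.uniform(0.05, 0.5)
            draws = rng.normal(loc, scale, size=(2, 200, 1, 2))
            cl = classify_slopes(
                _draws_from_arrays(np.zeros((2, 200, 6)), beta=draws)
            )
            pooled = draws[..., 0, 0].reshape(-1)
            lo, hi = np.quantile(pooled, [0.025, 0.975])
            expected = "negative" if hi < 0 else ("positive" if lo > 0 else "null")
            assert cl.verdicts[SPECTRALIS][0] == expected

    def test_classification_is_monotone_under_downward_shift(self, rng):
        beta = rng.normal(-0.3, 0.2, size=(2, 300, 3, 2))
        base = classify_slopes(_draws_from_arrays(np.zeros((2, 300, 6)), beta=beta))
        shifted = classify_slopes(
            _draws_from_arrays(np.zeros((2, 300, 6)), beta=beta - 0.4)
        )
        for dev in (SPECTRALIS, CIRRUS):
            for v0, v1 in zip(base.verdicts[dev], shifted.verdicts[dev]):
                if v0 == "negative":
                    assert v1 == "negative"


class TestProportions:
    def test_counts_and_proportions(self, rng):
        beta = np.zeros((1, 400, 10, 2))
        beta[..., :4, 0] = -1.0     # 4 Spectralis eyes clearly negative
        beta[..., :2, 1] = -1.0     # 2 Cirrus eyes clearly negative
        beta[..., 4:, 0] = rng.normal(0, 0.3, size=(1, 400, 6))
        beta[..., 2:, 1] = rng.normal(0, 0.3, size=(1, 400, 8))
        cl = classify_slopes(_draws_from_arrays(np.zeros((1, 400, 6)), beta=beta))
        table = proportions(cl).set_index(["device", "direction"])
        assert table.loc[(SPECTRALIS, "negative"), "proportion"] == pytest.approx(0.40)
        assert table.loc[(CIRRUS, "negative"), "proportion"] == pytest.approx(0.20)
        # proportions times denominator reproduce the integer counts exactly
        for (dev, direction), row in table.iterrows():
            assert row["proportion"] * row["n_eyes"] == pytest.approx(row["count"])

    def test_all_null_classification(self):
        beta = np.concatenate(
            [np.full((1, 100, 3, 2), -0.1), np.full((1, 100, 3, 2), 0.1)], axis=1
        )
        cl = classify_slopes(_draws_from_arrays(np.zeros((1, 200, 6)), beta=beta))
        table = proportions(cl)
        assert (table["proportion"] == 0).all()


def _dirichlet_difference_oracle(counts, prior=(1, 1, 1, 1), grid=1500):
    """High-resolution grid integration over the aggregated Dirichlet density
    of (p_s_only, p_c_only); independent of the Monte Carlo implementation."""
    a_s = prior[1] + counts[1]
    a_c = prior[2] + counts[2]
    a_rest = prior[0] + counts[0] + prior[3] + counts[3]
    xs = (np.arange(grid) + 0.5) / grid
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    inside = X + Y < 1.0
    logpdf = np.where(
        inside,
        (a_s - 1) * np.log(X) + (a_c - 1) * np.log(Y)
        + (a_rest - 1) * np.log1p(-(X + Y), where=inside, out=np.zeros_like(X)),
        -np.inf,
    )
    w = np.exp(logpdf - logpdf[inside].max())
    w[~inside] = 0.0
    w /= w.sum()
    prob_greater = float(w[X > Y].sum())
    diff = (X - Y).ravel()
    order = np.argsort(diff)
    cdf = np.cumsum(w.ravel()[order])
    lo = float(diff[order][np.searchsorted(cdf, 0.025)])
    hi = float(diff[order][np.searchsorted(cdf, 0.975)])
    mean = float(np.sum(w * (X - Y)))
    return mean, lo, hi, prob_greater


class TestBayesianMcNemar:
    def test_symmetric_discordance_not_significant(self):
        res = mcnemar_from_table(both=5, s_only=6, c_only=6, neither=10)
        assert abs(res.diff_mean) < 0.02
        assert not res.significant
        assert res.diff_lower < 0 < res.diff_upper

    def test_matches_numerical_integration_oracle(self):
        counts = (3, 12, 1, 78)
        res = mcnemar_from_table(*counts)
        mean, lo, hi, p_gt = _dirichlet_difference_oracle(counts)
        assert res.prob_s_greater == pytest.approx(p_gt, abs=0.005)
        assert res.diff_mean == pytest.approx(mean, abs=0.005)
        assert res.diff_lower == pytest.approx(lo, abs=0.005)
        assert res.diff_upper == pytest.approx(hi, abs=0.005)
        assert res.significant

    def test_empty_signal_not_significant(self):
        res = mcnemar_from_table(both=0, s_only=0, c_only=0, neither=40)
        assert not res.significant
        assert res.diff_lower < 0 < res.diff_upper

    def test_prob_depends_only_on_discordant_cells(self):
        """Dirichlet aggregation: Pr(p_S > p_C) is invariant to concordant
        counts at fixed discordant counts."""
        a = mcnemar_from_table(both=0, s_only=9, c_only=3, neither=10)
        b = mcnemar_from_table(both=30, s_only=9, c_only=3, neither=60)
        assert a.prob_s_greater == pytest.approx(b.prob_s_greater, abs=0.005)

    def test_counts_sum_to_eyes_and_direction_validated(self, rng):
        beta = rng.normal(-0.4, 0.3, size=(1, 300, 12, 2))
        cl = classify_slopes(_draws_from_arrays(np.zeros((1, 300, 6)), beta=beta))
        res = bayesian_mcnemar(cl, direction="negative")
        assert res.n_eyes == 12
        with pytest.raises(ValueError, match="direction"):
            bayesian_mcnemar(cl, direction="sideways")

    def test_type_i_rate_under_identical_devices(self):
        """With p_s_only = p_c_only the significance rate sits near 5%."""
        rng = np.random.default_rng(314)
        n_sig = 0
        reps = 200
        for _ in range(reps):
            table = rng.multinomial(94, [0.05, 0.10, 0.10, 0.75])
            res = mcnemar_from_table(*table, n_samples=20_000)
            n_sig += res.significant
        rate = n_sig / reps
        assert 0.05 - 0.031 <= rate <= 0.05 + 0.031
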