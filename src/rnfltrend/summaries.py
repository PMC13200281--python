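"""Inferential products: sector summaries, slope classification, paired tests.

All derived quantities (device differences, residual-SD ratios) are computed
draw-wise and then summarized with posterior means and equal-tailed 95%
credible intervals — never as differences of marginal summaries. An effect is
declared significantly negative/positive when the CrI lies entirely below/above
zero (for ratios, below/above one), equivalent to a one-sided posterior
probability of 0.975. Device proportions of significant per-eye slopes are
compared with a Bayesian McNemar construction: a Dirichlet posterior on the
2x2 paired-indicator table and the posterior of the discordant-probability
difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rnfltrend.cohort import CIRRUS, SPECTRALIS
from rnfltrend.sampler import PosteriorDraws

CI_LEVEL = 0.95


def _etci(draws: np.ndarray, level: float = CI_LEVEL) -> tuple[float, float]:
    """Equal-tailed credible interval of a pooled draw array."""
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(np.asarray(draws).reshape(-1), [a, 1.0 - a])
    return float(lo), float(hi)


def _summ(draws: np.ndarray, level: float = CI_LEVEL) -> dict[str, float]:
    lo, hi = _etci(draws, level)
    return {"mean": float(np.mean(draws)), "lower": lo, "upper": hi}


def _verdict(lo: float, hi: float, null: float = 0.0) -> str:
    if hi < null:
        return "negative"
    if lo > null:
        return "positive"
    return "null"


@dataclass
class SectorSummary:
    """Posterior summary of one sector's population parameters.

    Per device: intercept (um), rate of change (um/yr) and average residual SD
    (um), each with posterior mean and equal-tailed 95% CrI; plus the
    Spectralis - Cirrus differences for intercept and RoC and the
    Spectralis / Cirrus ratio for residual SD, with significance verdicts.
    """

    sector: str
    intercept: dict[str, dict[str, float]]
    slope: dict[str, dict[str, float]]
    resid_sd: dict[str, dict[str, float]]
    diff_intercept: dict[str, float]
    diff_slope: dict[str, float]
    ratio_resid_sd: dict[str, float]
    verdicts: dict[str, str] = field(default_factory=dict)

    def to_row(self) -> dict:
        """Flatten to one Table-2-style CSV row."""
        row: dict[str, object] = {"sector": self.sector}
        for quantity, per_dev in (
            ("intercept", self.intercept),
            ("slope", self.slope),
            ("resid_sd", self.resid_sd),
        ):
            for dev in (SPECTRALIS, CIRRUS):
                for k, v in per_dev[dev].items():
                    row[f"{quantity}_{dev}_{k}"] = v
        for name, d in (
            ("diff_intercept", self.diff_intercept),
            ("diff_slope", self.diff_slope),
            ("ratio_resid_sd", self.ratio_resid_sd),
        ):
            for k, v in d.items():
                row[f"{name}_{k}"] = v
        row.update({f"verdict_{k}": v for k, v in self.verdicts.items()})
        return row


def summarize_sector(
    draws: PosteriorDraws,
    level: float = CI_LEVEL,
    allow_failed_diagnostics: bool = False,
) -> SectorSummary:
    """Summarize one sector's posterior into Table-2-style quantities.

    Differences and ratios are formed draw-wise before summarizing. The
    population "average residual SD" is the mean of the lognormal eye-level
    residual-SD law, exp(mu_lambda + Sigma_lambda,lambda / 2), per draw.
    Refuses draws whose convergence diagnostics failed unless explicitly
    overridden.
    """
    if draws.mu.size == 0:
        raise ValueError("empty posterior draws")
    if (
        draws.diagnostics is not None
        and not draws.diagnostics.passed
        and not allow_failed_diagnostics
    ):
        raise ValueError(
            "draws failed convergence diagnostics; pass "
            "allow_failed_diagnostics=True to summarize anyway"
        )

    intercept = {
        SPECTRALIS: _summ(draws.mu[..., 0], level),
        CIRRUS: _summ(draws.mu[..., 1], level),
    }
    slope = {
        SPECTRALIS: _summ(draws.mu[..., 2], level),
        CIRRUS: _summ(draws.mu[..., 3], level),
    }
    resid_sd = {
        SPECTRALIS: _summ(draws.avg_resid_sd(SPECTRALIS), level),
        CIRRUS: _summ(draws.avg_resid_sd(CIRRUS), level),
    }
    d_int = _summ(draws.diff_intercept(), level)
    d_slope = _summ(draws.diff_slope(), level)
    r_sd = _summ(draws.ratio_resid_sd(), level)

    verdicts = {
        f"slope_{SPECTRALIS}": _verdict(slope[SPECTRALIS]["lower"], slope[SPECTRALIS]["upper"]),
        f"slope_{CIRRUS}": _verdict(slope[CIRRUS]["lower"], slope[CIRRUS]["upper"]),
        "diff_intercept": _verdict(d_int["lower"], d_int["upper"]),
        "diff_slope": _verdict(d_slope["lower"], d_slope["upper"]),
        "ratio_resid_sd": {
            "negative": "smaller", "positive": "larger", "null": "null"
        }[_verdict(r_sd["lower"], r_sd["upper"], null=1.0)],
    }
    return SectorSummary(
        sector=draws.sector,
        intercept=intercept,
        slope=slope,
        resid_sd=resid_sd,
        diff_intercept=d_int,
        diff_slope=d_slope,
        ratio_resid_sd=r_sd,
        verdicts=verdicts,
    )


@dataclass
class SlopeClassification:
    """Per eye x device progression verdicts from eye-level slope CrIs.

    ``negative`` iff the equal-tailed 95% CrI upper limit < 0; ``positive``
    iff the lower limit > 0; otherwise ``null``.
    """

    sector: str
    eye_ids: list[str]
    verdicts: dict[str, list[str]]
    intervals: dict[str, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for dev in (SPECTRALIS, CIRRUS):
            for e, eye in enumerate(self.eye_ids):
                lo, hi = self.intervals[dev][e]
                rows.append(
                    {
                        "sector": self.sector,
                        "eye_id": eye,
                        "device": dev,
                        "ci_lower": lo,
                        "ci_upper": hi,
                        "verdict": self.verdicts[dev][e],
                    }
                )
        return pd.DataFrame(rows)


def classify_slopes(draws: PosteriorDraws, level: float = CI_LEVEL) -> SlopeClassification:
    """Classify each eye's device-specific slope by its posterior CrI."""
    a = (1.0 - level) / 2.0
    verdicts: dict[str, list[str]] = {}
    intervals: dict[str, np.ndarray] = {}
    for dev in (SPECTRALIS, CIRRUS):
        sl = draws.eye_slopes(dev)  # (chain, draw, n_eyes)
        pooled = sl.reshape(-1, sl.shape[-1])
        lo = np.quantile(pooled, a, axis=0)
        hi = np.quantile(pooled, 1.0 - a, axis=0)
        intervals[dev] = np.column_stack([lo, hi])
        verdicts[dev] = [_verdict(l, h) for l, h in zip(lo, hi)]
    return SlopeClassification(
        sector=draws.sector,
        eye_ids=list(draws.eye_ids),
        verdicts=verdicts,
        intervals=intervals,
    )


def proportions(classification: SlopeClassification) -> pd.DataFrame:
    """Counts and proportions of significant slopes per device and direction."""
    n = len(classification.eye_ids)
    if n == 0:
        raise ValueError("classification contains no eyes")
    rows = []
    for dev in (SPECTRALIS, CIRRUS):
        v = classification.verdicts[dev]
        for direction in ("negative", "positive"):
            count = sum(1 for x in v if x == direction)
            rows.append(
                {
                    "sector": classification.sector,
                    "device": dev,
                    "direction": direction,
                    "count": count,
                    "n_eyes": n,
                    "proportion": count / n,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class McNemarResult:
    """Bayesian McNemar comparison of paired per-eye significance indicators.

    Cells of the 2x2 table: ``both`` (significant on both devices),
    ``s_only``, ``c_only``, ``neither``. The posterior of
    p_S - p_C = p_{s_only} - p_{c_only} is summarized with its mean, 95% CrI
    and the probability that the Spectralis proportion exceeds the Cirrus one.
    """

    sector: str
    direction: str
    both: int
    s_only: int
    c_only: int
    neither: int
    diff_mean: float
    diff_lower: float
    diff_upper: float
    prob_s_greater: float
    significant: bool

    @property
    def n_eyes(self) -> int:
        return self.both + self.s_only + self.c_only + self.neither

    def to_row(self) -> dict:
        return {
            "sector": self.sector,
            "direction": self.direction,
            "both": self.both,
            "s_only": self.s_only,
            "c_only": self.c_only,
            "neither": self.neither,
            "diff_mean": self.diff_mean,
            "diff_lower": self.diff_lower,
            "diff_upper": self.diff_upper,
            "prob_s_greater": self.prob_s_greater,
            "significant": self.significant,
        }


def mcnemar_from_table(
    both: int,
    s_only: int,
    c_only: int,
    neither: int,
    direction: str = "negative",
    sector: str = "G",
    prior: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
    n_samples: int = 200_000,
    seed: int = 20_240_913,
    level: float = CI_LEVEL,
) -> McNemarResult:
    """Bayesian McNemar test on explicit 2x2 paired-indicator counts.

    Places a Dirichlet(prior + counts) posterior on the cell probabilities
    (p_both, p_s_only, p_c_only, p_neither) and reports the Monte Carlo
    posterior of the proportion difference p_S - p_C = p_s_only - p_c_only.
    The internal Monte Carlo seed is fixed so results are reproducible;
    significant iff the 95% CrI of the difference excludes 0.
    """
    counts = np.array([both, s_only, c_only, neither], dtype=float)
    if np.any(counts < 0):
        raise ValueError("cell counts must be >= 0")
    rng = np.random.default_rng(seed)
    post = rng.dirichlet(np.asarray(prior, dtype=float) + counts, size=n_samples)
    diff = post[:, 1] - post[:, 2]
    lo, hi = _etci(diff, level)
    return McNemarResult(
        sector=sector,
        direction=direction,
        both=int(both),
        s_only=int(s_only),
        c_only=int(c_only),
        neither=int(neither),
        diff_mean=float(diff.mean()),
        diff_lower=lo,
        diff_upper=hi,
        prob_s_greater=float(np.mean(diff > 0)),
        significant=bool(hi < 0 or lo > 0),
    )


def bayesian_mcnemar(
    classification: SlopeClassification,
    direction: str = "negative",
    prior: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
    n_samples: int = 200_000,
    seed: int = 20_240_913,
    level: float = CI_LEVEL,
) -> McNemarResult:
    """Compare the devices' proportions of significant slopes in one direction."""
    if direction not in ("negative", "positive"):
        raise ValueError("direction must be 'negative' or 'positive'")
    s = np.array([v == direction for v in classification.verdicts[SPECTRALIS]])
    c = np.array([v == direction for v in classification.verdicts[CIRRUS]])
    if s.size == 0:
        raise ValueError("classification contains no eyes")
    return mcnemar_from_table(
        both=int(np.sum(s & c)),
        s_only=int(np.sum(s & ~c)),
        c_only=int(np.sum(~s & c)),
        neither=int(np.sum(~s & ~c)),
        direction=direction,
        sector=classification.sector,
        prior=prior,
        n_samples=n_samples,
        seed=seed,
        level=level,
    )


def summaries_to_frame(summaries: list[SectorSummary]) -> pd.DataFrame:
    """Stack sector summaries into one Table-2-style frame."""
    return pd.DataFrame([s.to_row() for s in summaries])
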