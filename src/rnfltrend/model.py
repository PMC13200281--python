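"""Generative bivariate hierarchical model and its exact joint log-density.

One sector at a time, eye ``i`` with visits at times ``t_ij`` contributes a
pair of thickness observations per visit, one per device. The model:

.. math::

    y^{S}_{ij} = \\alpha^S_i + \\beta^S_i t_{ij} + e^S_{ij}, \\qquad
    y^{C}_{ij} = \\alpha^C_i + \\beta^C_i t_{ij} + e^C_{ij},

with within-visit residuals bivariate normal, SDs
:math:`\\exp(\\lambda^S_i), \\exp(\\lambda^C_i)` and cross-device correlation
:math:`\\rho`, and eye effects
:math:`b_i = (\\alpha^S_i, \\alpha^C_i, \\beta^S_i, \\beta^C_i,
\\lambda^S_i, \\lambda^C_i) \\sim \\mathrm{MVN}(\\mu, \\Sigma)` with an
unstructured 6x6 covariance. Visits observed on a single device contribute the
corresponding univariate margin. Both the MCMC sampler and the cohort
simulator are built on exactly this density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from rnfltrend.cohort import CIRRUS, SPECTRALIS, PairedCohort, validate_sector

# Component order of eye effects and population mean vector.
IDX_ALPHA_S, IDX_ALPHA_C, IDX_BETA_S, IDX_BETA_C, IDX_LAM_S, IDX_LAM_C = range(6)
EFFECT_NAMES = ("alpha_s", "alpha_c", "beta_s", "beta_c", "lam_s", "lam_c")
P = 6

LOG_2PI = float(np.log(2.0 * np.pi))


class DomainError(ValueError):
    """Parameter values outside the model's domain (non-PD Sigma, |rho| >= 1)."""


@dataclass(frozen=True)
class EyeEffects:
    """Latent effects of one eye: intercepts (um), slopes (um/yr), log residual SDs."""

    alpha_s: float
    alpha_c: float
    beta_s: float
    beta_c: float
    lam_s: float
    lam_c: float

    def to_array(self) -> np.ndarray:
        a = np.array(
            [self.alpha_s, self.alpha_c, self.beta_s, self.beta_c, self.lam_s, self.lam_c],
            dtype=float,
        )
        if not np.all(np.isfinite(a)):
            raise DomainError("eye effects must be finite")
        return a

    @staticmethod
    def from_array(a: np.ndarray) -> "EyeEffects":
        return EyeEffects(*(float(x) for x in np.asarray(a, dtype=float)))


def effects_to_array(effects) -> np.ndarray:
    """Normalize effects input — (n, 6) array or list of EyeEffects — to (n, 6)."""
    if isinstance(effects, np.ndarray):
        b = np.asarray(effects, dtype=float)
        if b.ndim == 1:
            b = b[None, :]
    else:
        b = np.stack([e.to_array() for e in effects])
    if b.shape[1] != P or not np.all(np.isfinite(b)):
        raise DomainError(f"effects must be finite with {P} components per eye")
    return b


@dataclass(frozen=True)
class PopulationParams:
    """Population law of the eye effects plus the residual correlation.

    ``mu``: 6-vector of means in component order
    (alpha_S, alpha_C, beta_S, beta_C, lambda_S, lambda_C);
    ``Sigma``: 6x6 symmetric positive-definite covariance of eye effects;
    ``rho``: within-visit cross-device residual correlation, |rho| < 1.
    """

    mu: np.ndarray
    Sigma: np.ndarray
    rho: float

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        Sigma = np.asarray(self.Sigma, dtype=float)
        if mu.shape != (P,) or not np.all(np.isfinite(mu)):
            raise DomainError("mu must be a finite 6-vector")
        if Sigma.shape != (P, P) or not np.all(np.isfinite(Sigma)):
            raise DomainError("Sigma must be a finite 6x6 matrix")
        if not np.allclose(Sigma, Sigma.T, atol=1e-10):
            raise DomainError("Sigma must be symmetric")
        try:
            np.linalg.cholesky(Sigma)
        except np.linalg.LinAlgError as exc:
            raise DomainError("Sigma must be positive definite") from exc
        if not (-1.0 < float(self.rho) < 1.0):
            raise DomainError("rho must lie in (-1, 1)")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "Sigma", Sigma)
        object.__setattr__(self, "rho", float(self.rho))

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.Sigma))

    @property
    def corr(self) -> np.ndarray:
        s = self.sd
        return self.Sigma / np.outer(s, s)


@dataclass(frozen=True)
class PriorSpec:
    """Priors for the population parameters, weakly informative on the um scale.

    Population means get independent normals; Sigma is decomposed into
    per-component SDs (half-normal priors) and a correlation matrix with an
    LKJ-family prior (density proportional to ``det(R)^(eta-1)``; ``eta = 1``
    is uniform over correlation matrices); rho is uniform on (-1, 1).
    """

    mu_loc: np.ndarray = field(
        default_factory=lambda: np.array(
            [75.0, 75.0, 0.0, 0.0, np.log(3.0), np.log(3.0)]
        )
    )
    mu_scale: np.ndarray = field(
        default_factory=lambda: np.array([50.0, 50.0, 10.0, 10.0, 1.5, 1.5])
    )
    sd_scale: np.ndarray = field(
        default_factory=lambda: np.array([20.0, 20.0, 2.0, 2.0, 1.0, 1.0])
    )
    lkj_eta: float = 1.0

    def __post_init__(self) -> None:
        for name in ("mu_loc", "mu_scale", "sd_scale"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (P,) or not np.all(np.isfinite(v)):
                raise DomainError(f"{name} must be a finite 6-vector")
            object.__setattr__(self, name, v)
        if np.any(self.mu_scale <= 0) or np.any(self.sd_scale <= 0):
            raise DomainError("prior scales must be > 0")
        if not self.lkj_eta > 0:
            raise DomainError("lkj_eta must be > 0")


@dataclass
class SectorDataset:
    """Single-sector data in visit-row form, ready for likelihood evaluation.

    One row per (eye, visit): ``t`` in years, ``y_s``/``y_c`` thickness in um
    with NaN where that device is missing at the visit. ``eye_index`` maps each
    row to ``eye_ids``.
    """

    eye_ids: list[str]
    eye_index: np.ndarray
    t: np.ndarray
    y_s: np.ndarray
    y_c: np.ndarray
    sector: str = "G"

    def __post_init__(self) -> None:
        self.eye_index = np.asarray(self.eye_index, dtype=int)
        self.t = np.asarray(self.t, dtype=float)
        self.y_s = np.asarray(self.y_s, dtype=float)
        self.y_c = np.asarray(self.y_c, dtype=float)
        m = self.t.shape[0]
        if not (self.eye_index.shape == self.y_s.shape == self.y_c.shape == (m,)):
            raise ValueError("eye_index, t, y_s, y_c must be aligned 1-d arrays")
        if np.any(np.isnan(self.y_s) & np.isnan(self.y_c)):
            raise ValueError("every visit row must have at least one device observed")

    @property
    def n_eyes(self) -> int:
        return len(self.eye_ids)

    @property
    def n_visits(self) -> int:
        return int(self.t.shape[0])

    @property
    def mask_both(self) -> np.ndarray:
        return np.isfinite(self.y_s) & np.isfinite(self.y_c)

    @property
    def mask_s_only(self) -> np.ndarray:
        return np.isfinite(self.y_s) & ~np.isfinite(self.y_c)

    @property
    def mask_c_only(self) -> np.ndarray:
        return ~np.isfinite(self.y_s) & np.isfinite(self.y_c)

    @staticmethod
    def from_cohort(
        cohort: PairedCohort,
        sector: str,
        pairing_tol: float = 1e-9,
        min_visits: int = 1,
    ) -> tuple["SectorDataset", list[str]]:
        """Extract one sector; returns the dataset and any dropped eye ids.

        Visits from the two devices are matched into one row when their times
        agree within ``pairing_tol`` years. Eyes with fewer than ``min_visits``
        retained visit rows are dropped (and reported), since an eye-level
        slope is unidentifiable below two visits.
        """
        validate_sector(sector)
        sub = cohort.sector_frame(sector)
        rows: list[tuple[str, float, float, float]] = []
        for eye, grp in sub.groupby("eye_id", sort=True):
            s = grp[grp["device"] == SPECTRALIS].sort_values("t")
            c = grp[grp["device"] == CIRRUS].sort_values("t")
            c_t = c["t"].to_numpy()
            c_y = c["thickness"].to_numpy()
            used_c = np.zeros(len(c_t), dtype=bool)
            for t_s, y_s in zip(s["t"].to_numpy(), s["thickness"].to_numpy()):
                j = None
                if len(c_t):
                    d = np.abs(c_t - t_s)
                    d[used_c] = np.inf
                    jm = int(np.argmin(d))
                    if d[jm] <= pairing_tol:
                        j = jm
                if j is None:
                    rows.append((str(eye), float(t_s), float(y_s), np.nan))
                else:
                    used_c[j] = True
                    rows.append((str(eye), 0.5 * (t_s + c_t[j]), float(y_s), float(c_y[j])))
            for j in np.flatnonzero(~used_c):
                rows.append((str(eye), float(c_t[j]), np.nan, float(c_y[j])))

        frame = pd.DataFrame(rows, columns=["eye_id", "t", "y_s", "y_c"])
        counts = frame.groupby("eye_id")["t"].count()
        kept = sorted(counts.index[counts >= min_visits])
        dropped = sorted(counts.index[counts < min_visits])
        frame = frame[frame["eye_id"].isin(kept)].sort_values(["eye_id", "t"])
        index = {e: i for i, e in enumerate(kept)}
        return (
            SectorDataset(
                eye_ids=list(kept),
                eye_index=frame["eye_id"].map(index).to_numpy(),
                t=frame["t"].to_numpy(),
                y_s=frame["y_s"].to_numpy(),
                y_c=frame["y_c"].to_numpy(),
                sector=sector,
            ),
            [str(e) for e in dropped],
        )


def _check_rho(rho: float) -> float:
    rho = float(rho)
    if not (-1.0 < rho < 1.0):
        raise DomainError("rho must lie in (-1, 1)")
    return rho


def paired_loglik(r_s, r_c, sd_s, sd_c, rho: float):
    """Elementwise bivariate-normal log-density of paired residuals."""
    rho = _check_rho(rho)
    z_s = r_s / sd_s
    z_c = r_c / sd_c
    om = 1.0 - rho * rho
    q = (z_s * z_s - 2.0 * rho * z_s * z_c + z_c * z_c) / om
    return -LOG_2PI - np.log(sd_s) - np.log(sd_c) - 0.5 * np.log(om) - 0.5 * q


def single_loglik(r, sd):
    """Elementwise univariate-normal log-density of unpaired residuals."""
    z = r / sd
    return -0.5 * LOG_2PI - np.log(sd) - 0.5 * z * z


def residual_loglik_terms(
    data: SectorDataset, b: np.ndarray, rho: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-eye sums of residual log-likelihood, split into (paired, unpaired).

    ``b`` is the (n_eyes, 6) effects array. Returns two (n_eyes,) arrays so the
    sampler can reuse them blockwise; their sum is the residual term of
    :func:`log_density`.
    """
    i = data.eye_index
    alpha_s = b[i, IDX_ALPHA_S]
    alpha_c = b[i, IDX_ALPHA_C]
    beta_s = b[i, IDX_BETA_S]
    beta_c = b[i, IDX_BETA_C]
    sd_s = np.exp(b[i, IDX_LAM_S])
    sd_c = np.exp(b[i, IDX_LAM_C])
    n = data.n_eyes

    out_pair = np.zeros(n)
    out_single = np.zeros(n)
    mb = data.mask_both
    if mb.any():
        ll = paired_loglik(
            data.y_s[mb] - alpha_s[mb] - beta_s[mb] * data.t[mb],
            data.y_c[mb] - alpha_c[mb] - beta_c[mb] * data.t[mb],
            sd_s[mb], sd_c[mb], rho,
        )
        out_pair = np.bincount(i[mb], weights=ll, minlength=n)
    ms = data.mask_s_only
    if ms.any():
        ll = single_loglik(
            data.y_s[ms] - alpha_s[ms] - beta_s[ms] * data.t[ms], sd_s[ms]
        )
        out_single = out_single + np.bincount(i[ms], weights=ll, minlength=n)
    mc = data.mask_c_only
    if mc.any():
        ll = single_loglik(
            data.y_c[mc] - alpha_c[mc] - beta_c[mc] * data.t[mc], sd_c[mc]
        )
        out_single = out_single + np.bincount(i[mc], weights=ll, minlength=n)
    return out_pair, out_single


def sigma_prior_logpdf(Sigma: np.ndarray, priors: PriorSpec) -> float:
    """Log-density over Sigma of the scale-decomposed prior.

    Half-normal priors on the component SDs and an LKJ(eta) prior on the
    correlation matrix, expressed as a density over the covariance matrix via
    the change of variables Sigma = D R D (log-Jacobian
    ``p log 2 + p sum(log sd)``). The LKJ term is unnormalized: its constant
    does not depend on parameters.
    """
    Sigma = np.asarray(Sigma, dtype=float)
    try:
        np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError as exc:
        raise DomainError("Sigma must be positive definite") from exc
    sd = np.sqrt(np.diag(Sigma))
    R = Sigma / np.outer(sd, sd)
    lp = float(np.sum(stats.halfnorm.logpdf(sd, scale=priors.sd_scale)))
    sign, logdet_r = np.linalg.slogdet(R)
    lp += (priors.lkj_eta - 1.0) * float(logdet_r)
    lp -= P * np.log(2.0) + P * float(np.sum(np.log(sd)))
    return lp


def hyperprior_logpdf(pop: PopulationParams, priors: PriorSpec) -> float:
    """Log prior density of (mu, Sigma, rho)."""
    lp = float(np.sum(stats.norm.logpdf(pop.mu, priors.mu_loc, priors.mu_scale)))
    lp += sigma_prior_logpdf(pop.Sigma, priors)
    lp += -np.log(2.0)  # rho ~ Uniform(-1, 1)
    return lp


def log_density(
    data: SectorDataset,
    effects,
    pop: PopulationParams,
    priors: PriorSpec | None = None,
) -> float:
    """Exact joint log-density of data, eye effects, and population parameters.

    Sum of (a) per-visit residual log-likelihood (bivariate normal for paired
    visits, the univariate margin for single-device visits), (b) the 6-d MVN
    log-density of each eye's effects under (mu, Sigma), and (c) the prior
    log-densities when ``priors`` is given.
    """
    b = effects_to_array(effects)
    if b.shape[0] != data.n_eyes:
        raise ValueError(f"expected effects for {data.n_eyes} eyes, got {b.shape[0]}")
    lp_pair, lp_single = residual_loglik_terms(data, b, pop.rho)
    total = float(lp_pair.sum() + lp_single.sum())
    total += float(
        np.sum(stats.multivariate_normal.logpdf(b, mean=pop.mu, cov=pop.Sigma))
    )
    if priors is not None:
        total += hyperprior_logpdf(pop, priors)
    return total


def simulate_from_model(
    pop: PopulationParams,
    design: list[np.ndarray],
    seed: int | np.random.Generator,
    eye_ids: list[str] | None = None,
    sector: str = "G",
) -> tuple[SectorDataset, np.ndarray]:
    """Draw one sector dataset from the generative model.

    ``design`` gives each eye's visit-time grid (years). Eye effects are drawn
    from MVN(mu, Sigma), then per-visit residuals from the bivariate residual
    law. Returns the dataset and the (n_eyes, 6) latent-truth array.
    Deterministic given a seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(design)
    if n == 0:
        raise ValueError("design must contain at least one eye")
    if eye_ids is None:
        eye_ids = [f"eye{k:03d}" for k in range(n)]
    L = np.linalg.cholesky(pop.Sigma)
    b = pop.mu + rng.standard_normal((n, P)) @ L.T
    rho = _check_rho(pop.rho)

    eye_index, tt, ys, yc = [], [], [], []
    for k, times in enumerate(design):
        times = np.asarray(times, dtype=float)
        sd_s = np.exp(b[k, IDX_LAM_S])
        sd_c = np.exp(b[k, IDX_LAM_C])
        z = rng.standard_normal((times.size, 2))
        e_s = sd_s * z[:, 0]
        e_c = sd_c * (rho * z[:, 0] + np.sqrt(1.0 - rho * rho) * z[:, 1])
        eye_index.extend([k] * times.size)
        tt.extend(times)
        ys.extend(b[k, IDX_ALPHA_S] + b[k, IDX_BETA_S] * times + e_s)
        yc.extend(b[k, IDX_ALPHA_C] + b[k, IDX_BETA_C] * times + e_c)
    data = SectorDataset(
        eye_ids=list(eye_ids),
        eye_index=np.array(eye_index, dtype=int),
        t=np.array(tt),
        y_s=np.array(ys),
        y_c=np.array(yc),
        sector=sector,
    )
    return data, b


def sample_lkj(p: int, eta: float, rng: np.random.Generator) -> np.ndarray:
    """Draw a p x p correlation matrix from the LKJ(eta) family (onion method)."""
    if p == 1:
        return np.ones((1, 1))
    beta = eta + (p - 2) / 2.0
    r12 = 2.0 * rng.beta(beta, beta) - 1.0
    R = np.array([[1.0, r12], [r12, 1.0]])
    for k in range(2, p):
        beta -= 0.5
        y = rng.beta(k / 2.0, beta)
        u = rng.standard_normal(k)
        u /= np.linalg.norm(u)
        w = np.sqrt(y) * u
        A = np.linalg.cholesky(R)
        z = A @ w
        R = np.block([[R, z[:, None]], [z[None, :], np.ones((1, 1))]])
    return R


def sample_prior(priors: PriorSpec, rng: np.random.Generator) -> PopulationParams:
    """Draw population parameters from the prior (used for calibration checks)."""
    mu = rng.normal(priors.mu_loc, priors.mu_scale)
    sd = np.abs(rng.normal(0.0, priors.sd_scale))
    R = sample_lkj(P, priors.lkj_eta, rng)
    Sigma = np.outer(sd, sd) * R
    # Tiny ridge keeps Cholesky factorizable when a half-normal draw is ~0.
    Sigma = Sigma + 1e-10 * np.eye(P)
    rho = rng.uniform(-1.0, 1.0)
    return PopulationParams(mu=mu, Sigma=Sigma, rho=rho)
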