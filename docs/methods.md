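# Methods

## Problem and model

Glaucoma management tracks the peripapillary retinal nerve fiber layer (RNFL)
thickness over time; a significantly negative rate of change (RoC) is the
standard trend-analysis proxy for structural progression. Two OCT instruments
imaging the same eye in the same session produce systematically different
thickness values and different noise levels, so their RoCs and detection rates
cannot be assumed interchangeable. This package quantifies that disagreement
with a single joint model rather than two separate per-device fits.

For one sector (a clock hour 1–12 in right-eye format, or the global average
G), eye *i* at visit time *t_ij* (years since the eye's first scan) yields a
pair of observations:

    y^S_ij = alpha^S_i + beta^S_i t_ij + e^S_ij
    y^C_ij = alpha^C_i + beta^C_i t_ij + e^C_ij

with within-visit residuals bivariate normal,

    (e^S_ij, e^C_ij) ~ N2( 0, [ sigma^S_i^2,            rho sigma^S_i sigma^C_i ;
                                rho sigma^S_i sigma^C_i, sigma^C_i^2 ] ),

where `sigma^d_i = exp(lambda^d_i)`. The six eye-level effects

    b_i = (alpha^S_i, alpha^C_i, beta^S_i, beta^C_i, lambda^S_i, lambda^C_i)
        ~ MVN(mu, Sigma)

share one unstructured 6×6 covariance, so intercepts, slopes, and
log-residual-SDs are all correlated across devices — the cross-device
covariances are exactly what "do the two instruments see the same eye the
same way" means in this model. `rho` is a single population-level scalar per
sector: nothing suggests eye-specific same-session residual correlation, and
one scalar keeps it identifiable. Visits observed on only one device
contribute the corresponding univariate margin.

Modeling the residual SD as a log-scale random effect keeps it positive by
construction and makes eye-level measurement noise a first-class, correlated
quantity instead of a nuisance. Integer quantization of one device's export
is *not* modeled in the likelihood (the rounded values are treated as
continuous); rounding exists only as a simulator option for sensitivity
analysis, which mirrors how such data are analyzed in practice.

### Priors

Priors are data, not code: all are fields of `PriorSpec` and appear in the
shipped configuration.

| parameter | prior | default |
|---|---|---|
| mu_alpha (per device) | Normal | (75, 50²) μm |
| mu_beta | Normal | (0, 10²) μm/yr |
| mu_lambda | Normal | (log 3, 1.5²) |
| component SDs of Sigma | half-Normal | scales (20, 20, 2, 2, 1, 1) |
| correlation matrix of Sigma | LKJ family | eta = 1 (uniform) |
| rho | Uniform(−1, 1) | — |

These are weakly informative on the micrometer scale of peripapillary RNFL
data; posteriors at the study's size are likelihood-dominated.

Derived population quantities are computed draw-wise, never from marginal
summaries: the device differences (Spectralis − Cirrus) of intercept and RoC,
and the residual-SD ratio (Spectralis / Cirrus). The "average residual SD"
per device is the population mean of the lognormal eye-level SD law,
`exp(mu_lambda + Sigma_lambda,lambda / 2)`, evaluated per draw; the averaging
rule is a declared choice (it is the model-consistent mean of the eye-level
SD distribution).

### Decision rules

All intervals are equal-tailed 95% credible intervals; equal-tailed (not HPD)
because the decision rules read off the 2.5%/97.5% limits and correspond to
one-sided posterior probability 0.975. An RoC, difference, or eye-level slope
is *significantly negative/positive* when its CrI lies entirely below/above
zero; a residual-SD ratio is *smaller/larger* when its CrI excludes one. No
multiplicity adjustment is applied across the 13 sector analyses: each sector
is reported with its own unadjusted 95% CrI, and readers should interpret the
sector map accordingly.

Device proportions of significant per-eye slopes are compared with a Bayesian
McNemar construction: the per-eye (Spectralis, Cirrus) significance
indicators form a 2×2 table with cells (both, S-only, C-only, neither); a
Dirichlet(1,1,1,1) prior on the cell probabilities gives a
Dirichlet(1+counts) posterior, and the proportion difference
`p_S − p_C = p_{S-only} − p_{C-only}` is summarized by Monte Carlo (200 000
draws, fixed internal seed). By the Dirichlet aggregation property,
`Pr(p_S > p_C)` depends only on the discordant cells, as a McNemar-type test
should.

## Posterior computation

Sampling is by a blocked Gibbs/Metropolis scheme written directly against the
model's conditional structure (see `rnfltrend.sampler`):

1. **Per-eye (intercepts, slopes)** — the likelihood is Gaussian and linear
   in these four components, and their conditional prior given the log-SD
   effects is Gaussian, so they are drawn *exactly* from the conjugate 4-d
   normal, vectorized over eyes.
2. **Per-eye log residual SDs** — 2-d random-walk Metropolis per eye with
   per-eye step sizes adapted during warmup (target acceptance 0.35); all
   eyes are updated in one vectorized pass using per-eye residual
   cross-products.
3. **Population mean vector** — exact conjugate 6-d normal draw.
4. **Random-effects covariance** — independence Metropolis with an
   inverse-Wishart proposal whose degrees of freedom (n − 1) absorb both the
   conditional likelihood and the determinant part of the Jacobian of the
   Sigma → (SDs, correlation) decomposition; only the half-normal/LKJ factors
   enter the acceptance ratio (observed acceptance ≈ 0.4).
5. **Interweaving (ASIS)** — after the centered covariance update, each
   component SD is re-updated in *non-centered* form (deviations rescale with
   the SD, so `b*_k = mu_k + f (b_k − mu_k)` and the Sigma row/column scale
   by `f`), and the log-SD population means are re-updated by shifting
   `mu_lambda` and every `lambda_i` together. Centered updates mix well when
   the per-eye likelihood is informative, non-centered ones when it is weak;
   interweaving the two removes the funnel between eye effects and their
   covariance that makes plain Gibbs mix poorly for variance components.
6. **rho** — random-walk Metropolis on atanh(rho) with warmup adaptation.

Scale parameters decorrelate more slowly than location parameters, so blocks
2–6 are swept `scale_sweeps = 3` times per kept draw. Adaptation runs during
warmup only; the post-warmup kernel is fixed and hence a valid MCMC. All
randomness flows through one `numpy` Generator per chain seeded as
`[seed, chain]`, so identical inputs are bit-reproducible. Defaults: 4 chains
× 1000 warmup × 1000 kept; the seed is a required field.

Initialization is deterministic: per-eye, per-device least squares for
intercepts/slopes, residual SDs (floored at 0.3 μm) for the log-SD effects,
moment estimates (eigenvalue-floored) for (mu, Sigma), rho = 0.

Diagnostics (`diagnose`) report split R-hat and bulk ESS (via ArviZ) for the
population-level scalars and the slope difference; the default pass rule is
R-hat ≤ 1.01 and ESS ≥ 400. Short runs typically pass for the means and the
slope difference first; the hardest-mixing quantities are the slope- and
log-SD-dispersion components of Sigma, and fits are *flagged*, never silently
accepted, when any monitored scalar misses the thresholds. Summaries refuse
flagged draws unless explicitly overridden.

Correctness of the sampler is established three ways rather than by trusting
the algebra: (a) a restricted conjugate special case (one eye, one device,
known SD) where an independent Laplace-proposal MCMC must match the
closed-form posterior; (b) parameter recovery on synthetic cohorts at the
generator's defaults; and (c) simulation-based calibration — truths drawn
from the prior must have approximately uniform posterior ranks, which is
sensitive to prior/Jacobian inconsistencies anywhere in the blocks.

## Outlier screening

Real longitudinal OCT series contain occasional gross artifacts (segmentation
failures, refixation). Screening is per (eye, sector, device) series: a
Theil–Sen slope with median intercept, residuals scaled by 1.4826 × MAD, and
a flag when |residual| > k × scale with k = 4 by default. Two guards make
this behave on clinical-scale data: series shorter than 4 visits are never
screened (too little information to call anything "obvious"), and the robust
scale is floored at 2 μm — on 4–7 visits the robust line interpolates much of
the series and the MAD can collapse toward zero, which would otherwise flag
ordinary measurement noise (or integer rounding) as outliers; deviations
below k × 2 μm are within test–retest variability and are never obvious
artifacts. The global series is screened on its own values, independently of
the sector series. A user-supplied manual exclusion list realizes the manual
arm of a semi-automated review. The screen is deterministic.

Because both devices image the same session, a cell flagged on either device
is removed from *both* (`apply_paired_removal`), so the retained
(eye, t, sector) support is identical across devices; the report attributes
each flag to Spectralis-only / Cirrus-only / both.

On clean simulated cohorts the false-flag rate is ≈ 0.1–0.4% of observations;
injected 25 μm spikes at 1% prevalence are recovered at ≈ 93–95%. Misses
concentrate in the shortest series, where a single spike approaches the
robust fit's breakdown point.

## Synthetic cohorts

The generator (`rnfltrend.synthetic`) emulates a two-device prospective
glaucoma cohort and is the package's test bed; every default is overridable.

* **Design**: 94 eyes; visit counts `4 + Binomial(9, 1/3)` (median 7, range
  4–13); visit gaps 0.75 ± 0.08 yr (a 6-month protocol plus skipped and
  quality-excluded visits), floored at 0.25 yr; follow-up rescaled into a
  6.7 yr maximum. This jointly reproduces a median of ~7 visit pairs over a
  median ~4.5 yr of follow-up.
* **Population anchors**: global intercepts (61.5, 65.3) μm with SDs
  (13.3, 10.5) μm and cross-device intercept correlation 0.85; per-sector RoC
  means for all 13 sectors (global: −0.70 vs −0.45 μm/yr).
* **Declared stand-ins** (not published quantities): sector-level intercept
  means reuse the global values; population-mean residual SDs are 1.8 μm
  (Spectralis) vs 2.4 μm (Cirrus) — realistic trend-noise scales with the
  quieter device on Spectralis; slope SDs 0.6 μm/yr; log-SD SDs 0.4;
  slope and log-SD cross-device correlations 0.6; other cross-effect
  correlations 0; within-visit residual correlation rho = 0.3.
* **Device quirks**: Cirrus values are rounded to integers by default
  (matching how that device exports); Spectralis rounding is a sensitivity
  toggle. Gross outliers are injected by adding ±25 μm to one randomly
  chosen device of a visit cell at a configurable rate (0 by default); the
  truth record registers every injection and every latent eye effect.

What the generator does *not* emulate — and therefore what passing tests do
not establish about real data: measurement-floor nonlinearity (trajectories
are linear without a floor), temporal autocorrelation of residuals within a
device, visit-level quality covariates (signal strength, media opacity),
informative dropout, and real segmentation-artifact morphology (injected
outliers are clean symmetric spikes). Cohort-level conclusions about real
instruments require real paired data; the synthetic cohort validates the
*machinery* (recovery, calibration, QC, decision rules), not the clinical
numbers.

## Numerical choices and edge cases

* Visit pairing joins cross-device visits within 14 days (0.0383 yr) by
  default; package-generated data pair exactly.
* Eyes with fewer than 2 visits in a sector are dropped from that sector's
  fit with a logged warning (eye-level slope unidentifiable), and eyes with
  fewer than `min_visits` (default 4) fail cohort validation when enforced.
* Profile aggregation assigns each of the 768 pixels to the nearest clock
  hour under a declared anchor (pixel 0 at the temporal midline, 9 o'clock,
  clockwise in right-eye format); each hour receives exactly 64 contiguous
  pixels, so the mean of the 12 sector means equals the global mean to
  floating tolerance. The anchor is a field, so alternative export
  conventions are testable; left-eye data are expected pre-mirrored to
  right-eye format.
* Sigma draws are symmetrized and Cholesky-validated; non-PD proposals are
  rejected; `|rho| ≥ 1` and non-PD inputs raise domain errors at
  construction.
* Non-finite likelihood values from extreme Metropolis proposals are mapped
  to −inf (rejection) rather than propagating NaNs.
* Thickness values are floored at 1 μm after optional rounding in the
  simulator — a guard far outside the emulated regime, not a measurement
  floor model.

## Problem sizes used in the shipped checks

Test-suite and acceptance-script problem sizes are scaled to keep the full
suite fast while leaving every check statistically meaningful: recovery uses
40-eye cohorts with 2 chains × (500 + 500) draws and 10 replicates;
interval calibration uses 50 replicates of 30 eyes × 5 visits; calibration
(SBC) uses 40 prior-draw replicates of 20 eyes; the acceptance script runs
the full pipeline at the study's 94-eye size with 4 chains × (1000 + 1000).
One check deserves a caveat: the conjugate-oracle comparison at 4000 kept
draws has ~1–1.6% irreducible Monte Carlo noise on the compared scales, so
its 2% tolerance is asserted on the average over five fixed-seed runs (each
run individually bounded at 6%).

## Known limitations

* The outlier screen is a deterministic stand-in for a semi-automated
  (human-in-the-loop) review; it makes no claim of equivalence to any
  specific published algorithm, and its removal counts on real data would
  differ.
* Residuals are assumed independent across visits given the eye effects;
  within-device temporal autocorrelation would inflate apparent residual SDs
  and is flagged for sensitivity analysis rather than modeled.
* The likelihood treats integer-rounded exports as continuous; at RNFL noise
  scales (≥ ~1.5 μm SD) the attenuation is negligible, and the simulator's
  rounding toggle lets users measure it.
* Sector fits are fully independent; no spatial smoothing across adjacent
  clock hours, matching the per-sector reporting convention.
* The Sigma-dispersion components (slope and log-SD SDs) are the
  slowest-mixing quantities; default-length runs can flag diagnostics on
  them even when the reported location contrasts are well resolved. Longer
  runs (or more `scale_sweeps`) resolve this at proportional cost.
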