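# Methods

## Problem and estimator

The package estimates the expected life lost attributable to lifetime PM2.5
exposure across a set of small areas, each contributing one cohort of
60–79-year-olds followed for about 16 years. Because roughly half of such a
cohort is still alive at the administrative end of follow-up, life expectancy
(LE) requires extrapolating the survival function to the end of life. The
estimator works on a uniform monthly grid from the cohort start date to the
life-table cap (age 110; annual death probabilities q convert to monthly
factors (1−q)^(1/12), i.e. constant hazard within a year).

The chain for one cohort:

1. **Observed survival.** Product-limit (Kaplan–Meier) estimate S(t) on the
   monthly grid, via lifelines.
2. **General reference.** Sg(t): the exact participant-mix average of matched
   life-table recursions SG(t | s, a, y). We compute the expectation directly
   rather than simulating referent deaths — the simulated referent
   population's curve converges to exactly this average, without Monte-Carlo
   noise.
3. **Healthy reference.** If Sg ≥ S at every observed grid point (ties count),
   Sh ≡ Sg, continued past follow-up by the same recursion. Otherwise each
   participant's referent time is drawn in two stages, r ~ U(0, SG(t_obs)),
   v ~ U(0, r), t_ref = SG⁻¹(v) (monotone linear interpolation, ties toward
   the later time), so t_ref ≥ t_obs and the empirical curve of the t_ref
   values dominates the cohort everywhere. One referent per participant; the
   observed (possibly censored) follow-up time serves as t_obs. Beyond the
   last drawn time Sh continues along the Sg shape rescaled for continuity.
   The closed-form marginal of one draw, P(t_ref > t) = (u/p)(1 + ln(p/u))
   with u = SG(t), p = SG(t_obs), anchors the test suite.
4. **Relative survival.** W = S/Sh clamped to [ε, 1−ε], ε = 1e-4; halving ε
   moves LE by well under 0.5% on standard scenarios.
5. **Rolling extrapolation.** logit W is extended one month at a time: a
   restricted cubic spline (truncated-power basis, linear beyond the boundary
   knots) is fitted by least squares over a fixed-length window (default: the
   full observed period), the knot count is chosen per window by AIC, the
   one-step-ahead prediction is appended as observed, and the window slides.
   On the uniform grid each window's quantile knots are the previous window's
   shifted by one month, so a single QR factorization per knot count serves
   every step. Candidate knot counts default to {3, 5, 8, 12, 15}: with only
   3–5 knots the spline cannot absorb the steep early descent of logit W
   (which starts near logit(1−ε) ≈ 9.2) and its boundary behaviour — hence
   every one-step prediction — is visibly distorted; the wider set lets AIC
   pick a fit whose window-end slope matches the local data. Windows with a
   constant response or singular bases fall back to a linear fit.
6. **Composition and integration.** S(t) = expit(logit W(t))·Sh(t), monotone
   by cumulative minimum; LE is the trapezoidal integral / 12;
   SLED = LE − LE(Sg).
7. **Uncertainty.** Nonparametric bootstrap over participants (default 50
   replicates), rerunning the entire chain; replicates that fail on a
   degenerate resample are skipped, and at least 80% must succeed.

## Exposure

A complete monthly PM2.5 series per area is assembled from three segments:
an OLS backcast from PM10 over the pre-monitoring years (fit on the overlap,
≥ 24 months required, negative predictions floored at 0.5 µg/m³); the
observed months; and an ARIMA forecast with the order chosen by AIC over a
small fixed grid ((0,1,1), (1,1,0), (1,1,1), (0,1,2), (2,1,0); optional
seasonal (0,1,1,12)), clamped from below at 10 µg/m³ — or at the final
observed year's annual mean when that mean is already below 10. A
non-convergent grid falls back to a seasonal-naive drift forecast.

The lifetime weighted average E = Σ S(t)C(t)Δ / Σ S(t)Δ uses the same
trapezoid-consistent monthly weights as the LE integral, so the weights sum
to exactly 1 and a constant series returns itself. C(t) is taken at monthly
resolution on the survival grid. The per-participant exposure window runs
from 12 complete months before the start month through the month follow-up
ended, both endpoints inclusive (13 values at zero follow-up).

## Area-level model

Y_i = β₀ + β₁E_i + Σγ_jX_ji + ε_i with ε_i ~ N(0, s_i²σ²) and
corr(ε_i, ε_j) = exp(−d_ij/δ), d_ij Euclidean on planar km coordinates (a
haversine option exists for lon/lat). Stage one is bidirectional stepwise
selection by AIC on the 1/s_i² weighted model with the exposure term always
retained — it is the target, not a candidate. Stage two re-estimates by GLS,
profiling δ with the restricted likelihood on a 25-point log-spaced grid
(0.5–2000 km) plus bounded local refinement; a flat profile is reported with
a boundary flag. The adjusted R² is defined on the whitened (decorrelated)
scale against the whitened intercept-only fit, so unadjusted-vs-adjusted
comparisons are well defined under spatial correlation. Expected years of
life lost are −β₁ × (excess lifetime exposure above the 10 µg/m³ guideline
baseline), optionally expressed relative to a reference LE.

## Individual-level model

Cox proportional hazards on the monthly time scale with Efron ties (the
monthly grid creates heavy ties; Breslow would bias toward the null), time
origin at the start of follow-up and age at start as a covariate.
Covariates that are collinear with the rest of the design (common when a few
areas share several area-level descriptors) are dropped with a warning;
cluster-robust variance by area is available.

**Exposure endogeneity.** The operational lifetime-average exposure ends at
the participant's own death or censoring month. Under a declining pollution
trend this makes the covariate depend on the outcome: longer-lived
participants mechanically average over cleaner years. In synthetic data with
a generative log-HR of 0.0242 per µg/m³ the windowed covariate yields ≈ 0.044.
Parameter-recovery experiments therefore use the generative covariate — the
area's fixed lifetime-average level (`area_exposure=` in
`build_individual_design`) — while the windowed definition remains the
default operational choice.

## Synthetic-data generator

The generator emulates the target study design: 63 small areas (configurable)
in four region clusters on a planar km grid; cohorts entering 2001-01-01 aged
60–79 (ages geometrically weighted, mean ≈ 68; 54% women); administrative
censoring at 16 years plus a small independent exponential loss (0.5%/year);
monthly PM2.5 declining ≈ 38% between 2006 and 2018 from region-dependent
2006 levels spanning ≈ 15–50 µg/m³, with a winter-peaking seasonal cycle,
AR(1) noise, a 10 µg/m³ floor on the trend, and a linearly linked PM10 series
whose noise is scaled for a monthly PM2.5–PM10 correlation near 0.9 over the
monitored window.

Mortality follows a Gompertz life table (q(60) = 0.008 women / 0.013 men,
log-hazard slope 0.085 per year of age, 1% annual calendar improvement,
q(110) = 1) multiplied by exp(η_i), where η_i combines the exposure term
b·(A_i − centre) — A_i the area's true lifetime-weighted PM2.5, b defaulting
to 0.0242 per µg/m³ — and optional area-covariate terms that make
hospitalization and college share genuine spatial confounders. A Gompertz
baseline keeps hazards exactly proportional across age, sex and calendar
time, so the generative model is an exactly specified Cox model and every
truth (LE, SLED, the SLED-vs-exposure slope) is computable by direct
recursion; `calibrate_excess_coeff` solves for the b that yields a chosen
true slope (e.g. −0.034 years per µg/m³). Under the defaults the 16-year
survival fraction is ≈ 0.49 and the mix LE ≈ 18 years.

What the generator does **not** emulate: claims-based cohort construction
(clinic-visit selection, end-date rules), ICD9 comorbidity structure (flags
would enter as plain covariates), monitor-level measurement error, migration
between areas, and dependent censoring — losses are independent of health
status, a simplification the real end-date rule does not guarantee. Passing
tests therefore validate the estimators under an idealized sampling design,
not the claims-processing pipeline.

## Known limitations

- **Full-lifetime extrapolation bias in the healthy-draw regime.** When the
  cohort outperforms its general reference (so the two-stage draw is used),
  the true logit W beyond follow-up decelerates: logit W = ln W − ln(1−W),
  and the −ln(1−W) term decays as W falls from ≈ 0.57 at the end of
  follow-up. A linear continuation — which is what any spline with linear
  tails produces once real data end — is therefore too steep: even continuing
  logit W at its *true* end slope underestimates a null cohort's LE by
  ≈ 0.7–0.9 years on the default scenario, and the implemented roller sits at
  that structural limit (≈ −0.85 y). The effect is a near-constant shift
  across areas, so it is absorbed by the intercept of the area model and does
  not materially bias the exposure slope; but SLED point estimates for
  healthier-than-reference cohorts carry it. In the opposite regime
  (Sh ≡ Sg) full-lifetime LE is recovered to ≈ 0.7% at n = 20,000, and the
  truncate-and-extrapolate check (cut at 10 of 16 years, compare restricted
  mean survival at 16 years) shows mean relative absolute errors well under
  1% in both regimes.
- **Single-realization LE variance.** Kaplan–Meier noise in the window-end
  slope is amplified over the ~400 extrapolated months; at n = 20,000 the LE
  has ≈ 1% SD across realizations. The bootstrap SE reflects this.
- **Regime switching.** Whether a cohort triggers the healthy draw depends on
  a pointwise comparison that is noise-sensitive when the cohort is close to
  its reference, so mixed-area scenarios can contain both regimes; per-area
  bootstrap SEs do not capture the between-regime bias difference.

## Problem sizes and defaults

Tests and examples run the generator at 400–20,000 participants per cohort
and 4–63 areas, with bootstrap sizes 4–50; these sizes were chosen so that
every stage's sampling noise is visible but the generative truth remains
recoverable. Monthly grid throughout; extrapolation cap at age 110; seeds are
explicit everywhere (one seeded stream per cohort and stage, derived by CRC
from a global seed, so runs are bit-for-bit reproducible).
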