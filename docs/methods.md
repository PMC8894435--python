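# Methods

## Generative model

Each case defines four Gaussian RT cells (Age x Trial Type) in
milliseconds, shared by all studies, plus a between-study disturbance.
For participant j of study i, a single standardized AR(1) process
z_t (z_1 ~ N(0,1), z_t = rho z_{t-1} + sqrt(1-rho^2) eps_t, rho = 0.60)
spans the full 40-trial sequence, with trial types alternating
deterministically (congruent, incongruent, ...). The RT at position t is

    RT_t = m_cell(t) + s_cell(t) * z_t

where m is the disturbance-adjusted cell mean and s the cell SD. Every
z_t is marginally standard normal with lag-k correlation rho^k, so the
AR structure couples trials both within and across trial types. No
truncation is applied: at the stated means/SDs a negative draw is a
~5-sigma event, and none of the moments used downstream are affected.
Accuracy, error trials and RT skew are deliberately out of scope; the
generator is Gaussian per cell with all trials treated as correct.

### Disturbance schemes

Between-study variability enters through per-study adjustments of the
cell means:

- **Grand shift (Cases A-F).** One draw g_i ~ N(0, sigma_study^2) added
  to all four cells. It cancels exactly from every within-study contrast,
  so the interaction contrast stays at its design value (50 ms for Case A)
  in every study.
- **Grand shift + per-cell noise (Case G).** Additionally one independent
  draw ~ N(0, sigma_interaction^2) per cell per study. This perturbs the
  interaction contrast (variance 4 sigma_interaction^2) and, incidentally,
  both main effects — the "study-specific means" scheme. An alternative
  reading (a single increment to the old-incongruent cell only) was
  rejected because it leaves the young means noise-free and therefore
  cannot produce the attenuated study-level slope (~0.7) and depressed
  marginal R^2 that this case is meant to exhibit.
- **Grand shift + systematic interaction (Case H).** Additionally
  kappa * g_i added to the old-incongruent cell, tying the interaction
  magnitude to the study's overall RT level: slow studies show large
  interactions, which is what makes the study-level analysis finally
  detect two lines.

### Disturbance magnitudes (defaults; all configurable)

The published design does not state the disturbance SDs, so the defaults
are calibrated once against the attenuation relation
beta2 ~ sigma_study^2 / (sigma_study^2 + v), where v is the sampling
variance of a study-condition mean (~46 ms^2 for the young cells at
50 participants x 20 AR-correlated trials):

- `sigma_study = 100` ms gives beta2 ~ 0.995, matching the reported ~0.99
  restricted slope of the homogeneous cases;
- `sigma_interaction = 62` ms gives
  beta2 ~ 10^4 / (10^4 + 62^2 + 46) ~ 0.72 for Case G, matching its
  reported attenuated slope (and, as a consequence, the ~80 ms restricted
  Trial Type offset, since E[beta1] ~ 150 − beta2 * 100);
- `kappa = 1.5` for Case H (any clearly positive gain produces the
  two-line decision; the value only scales how fanned-out the modified
  plot looks).

### Seeding

One `numpy.random.SeedSequence(seed)` per case is split into a
disturbance substream plus one substream per study; each study substream
spawns one child per participant. Disturbances are drawn as one row of
standard normals per study. Consequently the output is bit-reproducible
given (spec, seed), and enlarging `n_studies` or `n_per_group` never
changes the draws of earlier studies/participants.

## Study-level Brinley model

On the study x condition means (TT = 0/1, congruent reference):

    old_ij = b0 + b1 TT_j + b2 young_ij + b3 TT_j young_ij
             + u0_i + u1_i young_ij + e_ij,   (u0, u1) ~ N(0, Psi),  e ~ N(0, s2)

estimated by full ML (not REML) so the 1-df likelihood-ratio test of the
full (with b3) against the restricted model is valid.

**Why a custom optimizer.** With two observations per study and a
bivariate random effect the model has as many random effects as
observations; fits are routinely boundary-singular and generic
mixed-model optimizers (statsmodels MixedLM, lme4 — which refuses the
model outright unless its identifiability check is disabled) land in
different local optima for the two nested fits. Since the decisions turn
on Delta-chi-square values of order 0.1-1, optimizer noise of that same
order corrupts them. We therefore maximize the *profiled* deviance
directly: beta and s2 have closed-form GLS/ML solutions given the
relative RE covariance Psi/s2, each study contributes a 2x2 marginal
covariance block, and what remains is a 3-parameter log-Cholesky
optimization shared by both models. The fit uses a deterministic 17-point
multistart grid (L-BFGS-B, Nelder-Mead polish). `fit_brinley_models`
additionally warm-starts the full fit at the restricted optimum — which
guarantees Delta-chi-square >= 0, because that point is feasible for the
full model — and re-polishes the restricted fit from the full optimum, so
both models receive symmetric optimization effort. statsmodels MixedLM is
kept as an independent cross-check in the tests (the profiled optimizer
matches or exceeds its likelihood with matching coefficients).

Reported quantities: coefficients with model-based SEs
(s2 (X' V^-1 X)^-1, normal-reference Wald p-values), RE variance
components mapped back from the internally standardized covariate scale,
ML log-likelihood, and the Nakagawa-Schielzeth marginal R^2
(fixed-effect predictor variance over fixed + RE-at-observed-covariates +
residual variance). AIC/BIC use the reported-df convention of the source
tables (restricted 5, full 6) rather than the literal free-parameter
count of the unstructured model (7/8): deviance = -2 loglik,
aic = deviance + 2k, bic = deviance + k ln(n). Boundary (singular) RE
covariances are allowed and logged, not errors. The intercept-slope
covariance is estimated (unstructured Psi), not fixed at zero.

## Trial-level three-level model

    RT_ijk = g000 + g010 Age + g100 TT + g110 Age*TT
             + u00k (study) + r0jk (participant) + e_ijk

with 0/1 coding (young, congruent reference) and *conditionally
independent* residuals — the analysis model deliberately ignores the
generative AR(1) dependence, as the standard formulation does. Random
intercepts only: the quoted model formula and the reported df imply no
random slopes, so none are exposed.

Because the design is fully balanced, the marginal likelihood factorizes
over orthogonal strata (within-cell residuals; per-participant trial-type
contrasts; within study-age-group participant contrasts; per-study age
contrasts; per-study means), each stratum's mean model is saturated, and
ML reduces to closed form: the fixed effects are the four cell-mean
contrasts and the variance components are stratum-wise moment ratios
(clamped at zero, with a constrained numerical polish if a clamp binds —
which does not occur at the default parameters). This makes a 200,000-row
fit run in <0.1 s; the closed form is verified against statsmodels
MixedLM (estimates, SEs, variance components, log-likelihood to ~1e-8) on
small datasets in the test suite. p-values use the standard-normal
reference: with ~2e5 trials, df corrections are numerically irrelevant.

Note on standard errors: because the fitted model ignores the AR(1)
dependence, its model-based SEs are not consistency-guaranteed for the
generative world; they are reported exactly as the fitted (iid-residual)
model implies, which is also what the source analysis printed. Point
estimates are unbiased for the design contrasts regardless.

## Plots

The standard Brinley plot scatters (young, old) per condition with one
OLS line per trial type, equal axis limits, no reference line. The
modified plot adds one segment per study from its congruent to its
incongruent point and the unit-slope no-age-difference diagonal. All
geometric claims are tested through `segment_geometry` (per-study segment
slope Delta-old/Delta-young, NaN when the young contrast is zero, and
elevation = mean (old − young)); image files are smoke-tested for
existence only, since pixel comparisons are brittle.

## What the synthetic world does and does not establish

The generator reproduces the stated factorial means/SDs, the AR(1)
intertrial dependence, and three stylized forms of between-study
variability. It does not emulate RT skew, error trials, speed-accuracy
tradeoffs, unequal study sizes, or participant-level trait variance
beyond what the AR process induces, so green tests establish the
behaviour of the two analysis families under the idealized world, not
under real meta-analytic data. External study-means tables can still be
plotted via the means-CSV reader, but no such data ships with the
package.

## Numerical choices and edge cases

- Significance threshold 0.05 everywhere; no multiplicity adjustment.
- Likelihood-ratio statistic clamped at 0 below 1e-6 tolerance; a larger
  negative value raises (it cannot occur with the warm-started fits).
- Zero-noise (sd = 0) inputs are supported for testing: fixed effects are
  exact, variance components collapse to 0, and the unbounded likelihood
  is reported as NaN with a warning.
- Degenerate x-variance in the standard plot skips the fit lines with a
  warning; a zero young-contrast in segment geometry yields NaN slope,
  not an error.
- Trial tables and study-means tables are plain CSV with full-precision
  floats; readers validate schema and enum values and name the offending
  column or study in errors.
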