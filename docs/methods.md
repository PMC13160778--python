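# Methods

`rpntcp` implements normal-tissue-complication-probability (NTCP) modelling
for grade ≥2 radiation pneumonitis (RP) after thoracic radiotherapy: a
registry of published fixed-coefficient logistic risk models, the
closed-testing updating ladder used to adapt such models to a new
population, a validation metric panel, decision curve analysis, and a
synthetic cohort generator that makes every stage testable without patient
data. This note records the model conventions, the defaults, and the design
choices made where the published material leaves the design open.

## Risk models

Every model is a logistic regression with frozen coefficients,

    NTCP = [1 + exp(−LP)]⁻¹,   LP = β₀ + Σⱼ βⱼ xⱼ.

The registry ships eight models in two families:

| family | members | predictors |
|---|---|---|
| QUANTEC | original (−3.87, MLD 0.126), recalibrated (−1.742, 0.164), final ridge-shrunk update (−1.652, 0.155) | MLD only |
| Appelt | original, model A (intercept-recalibrated, −1.7575), model B (fully recalibrated: every coefficient × 0.6159), model C (BIC-simplified to MLD, −1.7422 + 0.1637·MLD), final simplified local model D | MLD plus clinical covariates; model D adds stage, NLR, SII, V30 |

Model B's construction is a registry self-test: each of its coefficients
must equal the original Appelt coefficient times the calibration slope
0.6159 within 0.001 (e.g. 0.47 × 0.6159 = 0.2895).

Conventions the printed equations do not pin down:

* **Model D scales.** Model D is shipped on raw clinical scales (age in
  years, stage 1–4 numeric, NLR/SII/V30/MLD as measured). That is the only
  reading fully determined by the printed equation; it is recorded in the
  model's provenance that the equation's intercept is then hard to
  reconcile with a ~30% event rate at cohort-mean covariates (suggesting
  undocumented standardization upstream), so absolute risks from the
  shipped Model D run high and local intercept recalibration is advised
  before absolute-risk use. Users can attach `center`/`scale` transforms
  without touching coefficients.
* **Appelt "old age".** The source cutoff is not printed. The indicator is
  declared as an explicit `indicator_threshold` transform, default 63
  years (just under the cohort median of 64), configurable per encoding.
* **Mid-or-inferior location.** The data code tumor location on three
  levels while the model term is binary; levels {1, 2} map to 1 by
  default, configurable (`EncodingOptions.midinf_levels`).
* **Sequential chemotherapy.** Encoded as chemotherapy given but never
  concurrently; requires the phase flags, which are not mutually exclusive.
* **Numerics.** The LP is clamped to ±700 before exponentiation and the
  probability clipped to [1e−12, 1 − 1e−12], so predictions are strictly
  inside (0, 1) in double precision even for absurd covariate values.

## Validation metrics

* **AUC** is the Mann–Whitney statistic with midrank tie handling — exactly
  invariant under any strictly increasing transform of the predictions, so
  recalibration never changes it. The bootstrap CI is percentile-based over
  paired patient resamples (single-class resamples redrawn and logged);
  the seed is a mandatory argument.
* **Calibration.** CITL is the intercept of a maximum-likelihood logistic
  fit of outcomes on logit(pred) entered as a fixed offset; the calibration
  slope is the LP coefficient of a separate free intercept+slope fit. These
  are two separate fits (the dominant convention); the joint fit's
  intercept is also reported for transparency because published tables
  often cannot disambiguate the convention. Probabilities are clipped at
  1e−12 before the logit, with a log message when clipping triggers.
* **Hosmer–Lemeshow** uses quantile bins on the predictions (default
  deciles), right-closed on unique edges with duplicate cut-points dropped;
  the χ² sums (O−E)²/E over *both* outcome classes per bin. The df policy
  is explicit because the literature is inconsistent: `fitted` charges
  g − 2 df (model estimated on the evaluated data), `external` charges g
  (coefficients fixed elsewhere). Under true probabilities with the
  external policy the p-values are verified uniform by simulation.
* **Fit statistics.** LL/AIC/BIC on fixed predictions with a caller-chosen
  parameter count k; Nagelkerke R² rescales Cox–Snell against the
  prevalence model. At external validation AIC/BIC are charged
  k = #terms + 1 for table continuity even though nothing was estimated —
  a labelled convention, not a likelihood-theory claim.

## Updating ladder

`closed_test` fits four nested levels — original, intercept-recalibrated,
intercept+slope-recalibrated, fully revised — and runs likelihood-ratio
tests in a fixed order at α = 0.05 (default): intercept vs none (df 1),
slope vs intercept (df 1), revision vs slope (df = #terms − 1). The ladder
escalates only while the test against the currently accepted level rejects,
and the full test trace is returned so alternative orderings can be
audited. For a single-term model the revision level coincides with the
slope level (0 extra df); its test is reported with p = 1. By construction
the log-likelihoods are monotone up the ladder on the fitting data.

Full recalibration folds the fitted (a, b) back into the model: intercept
a + b·β₀, every slope b·βⱼ — so the update is visible as a coefficient
rescaling, and discrimination is unchanged exactly.

Revision supports ridge and lasso. Covariates are standardized internally
and coefficients reported back on the input scale; the intercept is never
penalized. The penalty weight λ is chosen by 10-fold cross-validated
deviance on a 25-point logarithmic grid (1e−4 … 1e2), seed-controlled;
λ multiplies the squared/absolute coefficient norm relative to the summed
log-likelihood (scikit-learn's C = 1/λ). For lasso, an optional relaxed
refit re-estimates the selected support without penalty, because
information criteria on penalized likelihoods are ill-defined.

`bic_simplify` is deterministic backward elimination: at each step drop the
term whose removal lowers BIC most, stop when none does, ties broken by
canonical term order; forced terms are never dropped. MLD–V30 collinearity
is left to the BIC criterion itself (both survive only if joint inclusion
improves fit); no variance-inflation cutoff is imposed.

`rcs_nonlinearity_check` tests departures from linearity with restricted
cubic splines in the Harrell linear-tail parametrization, knots at standard
quantiles (3 knots at 0.1/0.5/0.9), via a likelihood-ratio test with
k − 2 df.

## Decision curves

Net benefit NB(t) = TP/n − (FP/n)·t/(1−t); treat-all and treat-none are the
comparators. Classification is `pred >= t` (closed on the left) — stated
because boundary patients move curves at small n. The default grid is
0.01–0.50 in steps of 0.01, covering the low-to-intermediate thresholds
that matter for RP management; curves are exported raw, unsmoothed.

## Validation protocols

Bootstrap internal validation holds the predictor set fixed, refits in
resamples of the original size, and scores each refit on its own resample
and on the original cohort; optimism is the mean difference and is
subtracted from apparent performance. Optimism is computed for AUC and,
as labelled extensions, Brier and calibration slope. Failed resamples are
skipped (not redrawn) to keep the resample plan reproducible; more than 5%
failures is an error. A known limitation: under heavy overfitting (tens of
noise predictors against a few hundred patients) the simple bootstrap
under-corrects — corrected AUC for pure noise lands near, but measurably
above, 0.5; this residual bias is the reason 0.632-type estimators exist
and is visible in the test suite's tolerances.

External validation locks the coefficients, applies the model to an
independent cohort, and reports the full panel with the external HL policy
and a 4-group calibration preset for small cohorts.

## Synthetic cohorts

The generator emulates the development cohort's baseline table:

* age ~ truncated normal on [24, 86], MLD ~ truncated normal on (0, ∞);
  the (loc, scale) are *solved* so the post-truncation mean/SD hit the
  targets (63.23 ± 9.61 y; 9.90 ± 4.14 Gy) — naive parameters would miss
  the MLD mean by ~0.1 Gy;
* V30 ~ log-normal truncated at 100%, moment-matched *after* truncation
  (15.97 ± 18.72; the SD exceeds the mean, which rules out a normal
  marginal); NLR, SII, lymphocytes ~ moment-matched log-normal;
* the MLD–V30 pair is joined by a Gaussian copula at Pearson
  r = 2·sin(π·ρₛ/6) so the Spearman correlation hits 0.768; this is the
  only dependence the source quantifies, and all other covariates are
  drawn independently — an explicit simplification;
* blood counts are derived so NLR = N/L and SII = PLT·N/L hold bit-exactly;
  V5/V20 are monotone functions of MLD plus noise, clipped to [0, 100]
  (no shipped model uses them);
* categorical frequencies follow the development column (smoking
  never/former/current 0.355/0.631/0.014, comorbidity 0.479, stage
  0.040/0.034/0.391/0.534, location 0.476/0.162/0.362, chemo 0.740,
  immunotherapy 0.524, with phase flags at their conditional rates).

Outcomes are Bernoulli draws from a true logistic model (default: the
shipped Model D) whose intercept is tuned by bisection so the mean risk
hits the target prevalence (default 0.307); a drift (δ0, δ1) then maps the
true LP to δ0 + δ1·LP before drawing, which is how miscalibration and
between-center baseline-risk shifts are injected. The tuned true model is
attached to the returned cohort so recovery experiments know the truth, and
`make_center_pair` reuses one tuned truth for both centers (default
external drift δ0 = −1, n = 100). Events default to grade 2; an optional
mixture assigns grades 2–5 at 0.691/0.242/0.062/0.006.

The generator reproduces marginal moments and the one quantified
correlation; it does not reproduce joint clinical covariate structure,
treatment-planning physics, or longitudinal follow-up. Tests passing on
synthetic cohorts therefore demonstrate the statistical machinery's
correctness under known truth, not clinical performance on real patients.

## Problem sizes and determinism

Simulation-based tests use: n = 100,000 for marginal-moment recovery,
n = 20,000–50,000 for coefficient/drift recovery (tolerances set at 3
Monte-Carlo standard errors), n = 2,000 with 1,000 outcome-redraw
replicates for the closed test's type-I error (accepted band 3–7% at
α = 0.05) and 200 replicates for its power under an intercept shift, and
B = 150–500 bootstrap resamples. Every stochastic routine takes an explicit
seed (`numpy.random.default_rng`); identical config + seed reproduces a
cohort bit-exactly.

## Known limitations

* Model D's printed equation is used verbatim; without the original
  cohort its coefficients cannot be re-derived, and its raw-scale absolute
  risks carry the intercept caveat above.
* The closed test's exact test ordering and the HL df convention are fixed
  choices among defensible alternatives; both expose their full trace /
  policy argument so alternatives can be audited.
* Simple-bootstrap optimism correction under-corrects in the heavy-overfit
  regime (see above).
* The generator's covariate-independence assumption understates real
  clinical collinearity; only MLD–V30 dependence is modelled.
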