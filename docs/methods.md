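# Methods

This note documents the models, parameters, numerical choices and known
limitations of `hyperdisc` in the package's own terms.

## Choice model and estimation

Subjective value is hyperbolic, `U(A, D) = A / (1 + k·D)`, with `k` (1/day)
the temporal discount rate; the immediate option has `D = 0` and utility
equal to its face amount.  The probability of choosing the immediate option
is a logistic function of the utility difference with inverse temperature
`beta` (1/currency-unit):

    P(immediate) = 1 / (1 + exp(-beta · (U_immediate − U_delayed))).

Some published statements of this softmax write the utility difference in
the opposite order, `U_delayed − U_immediate`, inside `P(immediate)`; that
ordering makes immediate choices *more* likely as the delayed option gains
value, contradicting the model's own downstream use (higher `k` must raise
`P(immediate)`).  We treat that ordering as a sign typo and implement the
form above.

**Likelihood.**  Trials are conditionally independent Bernoulli draws; the
negative log-likelihood sums `−log p(observed)` with probabilities clipped
to `[1e-12, 1 − 1e-12]` so the NLL stays finite (per-trial cap ≈ 27.63
nats).  Computation uses `log1p`/`logaddexp` and is stable for arbitrarily
large `|beta·ΔU|`.

**Bounds.**  `k ∈ [1e-4, 0.25]` by default — the range recoverable with the
27-item design, whose item indifference rates span ~1.6e-4 to 0.25/day.
The instrument's nominal sensitive range is often quoted more broadly
(1e-5 to 1); the bank validator reports both ranges side by side rather
than reconciling them, and flags banks whose indifference ladder does not
come within a factor of 10 of each fit bound.  `beta ∈ [1e-3, 10]` per
currency unit: near-indifference utility gaps on this instrument are of
order $1–$35, so this spans effectively random to effectively deterministic
choice.

**Optimisation.**  The NLL is minimised over `(log k, log beta)` (better
conditioning; bounds map to a box) with an analytic gradient.  A 5×5
log-spaced grid of starts spanning the bounds is evaluated vectorised; the
best 3 starts are refined with L-BFGS-B and the lowest NLL wins, with
deterministic tie-breaking (NLL to 1e-9, then smaller `k`, then smaller
`beta`).  The procedure is exactly reproducible and, on simulated
participants across the whole parameter box, never loses to an exhaustive
1000×100 grid search by more than 1e-3 nats (it is typically ~1e-12 better).
Estimates pinned at a `k` bound are flagged (`boundary_flag`): an
all-immediate chooser, for instance, has a monotone likelihood in `k` and
lands exactly on the upper bound.

**Diagnostics.**  Pseudo-R² is McFadden's `1 − NLL/(n·ln 2)` against an
uninformed coin-flip null — the convention that gives a [0, 1]-ish scale
for binary-choice designs (it can be negative for fits worse than chance).
Balanced accuracy is the mean of per-class recalls of the 0.5-threshold
classifier; a probability of exactly 0.5 predicts *delayed* (ties count
against the model), and when only one choice class was observed that
class's recall is reported (avoiding 0/0).

## Parameter recovery

`recovery_study` simulates choices at known `(k, beta)` on a grid,
refits each replicate, and reports the median fitted `k`, the log-k bias
and RMSE per cell.  A cell counts as *recoverable* when the median fitted
log k is within ln 2 of the truth (a factor of 2 on `k`) — this package's
own criterion.  Per-rep seeds derive from the master seed by counter
(`seed + cell·n_reps + rep`), so any single replicate can be reproduced in
isolation.  With the canonical bank at `beta = 1`, the correlation between
true and median-recovered log k across a 10-point grid in [5e-4, 0.2]
exceeds 0.95.

## Synthetic cohort generator

The generator emulates the two-wave study design the analyses assume.  Its
defaults are the study conditions; those not fixed by published moments are
explicit calibrations, noted below.

* **Demographics.** Age truncated-normal (mean 44, SD 15.6, support
  [18, 85]); P(male) = 0.477 (gender coded 1 = male, 0 = female); household
  income log-normal with median 52,500 (log-SD 0.75, a typical US
  income-dispersion value; calibration); education five-level ordinal with
  probabilities (0.10, 0.25, 0.30, 0.25, 0.10) (calibration).
* **Income shock.** A latent standard normal thresholded at cut points
  (−0.674, −0.253, 0, 0.772, 1.476) mapping to Likert 1–6.  Chosen to give
  a mean of ~3.1 and ~50% of mass at 4–6, so the midpoint-binarised
  variable is balanced.
* **Emotions.** Fear/sad/anger are a single-factor Gaussian copula with
  pairwise latent correlation 0.65, giving pairwise Spearman correlations
  ≈ 0.6 after scaling margins to mean 43, SD 25 and clipping to [0, 100].
  The affect factor correlates with the shock latent at only 0.025: shock
  and affect are *independent causes* in the generative model, so any
  mediation detected downstream is a false positive — the pipeline's key
  negative control.
* **Discount rate.** `log k = log(0.0137) + S·Σ b_j z_j + σ·ε` with
  z-scored encoded covariates, standardized effects
  `b = (0.12 shock, 0.082 affect, −0.14 education, −0.15 income,
  −0.06 age, −0.009 gender)`, noise SD `σ = 1.3` natural-log units (typical
  monetary-choice-questionnaire spread; calibration — the cross-sectional
  SD of log k is not pinned by a published moment), and
  `S = σ/√(1 − Σb²)` so each planted standardized coefficient equals its
  configured value under orthogonal covariates.  The result is clipped to
  the fit bounds; effect sizes with `Σb² ≥ 1` (negative residual variance)
  are rejected.
* **Choice sensitivity.** `beta` is log-normal (median 0.18, log-SD 0.7),
  calibrated so that fitted cohorts show mean pseudo-R² ≈ 0.69 and balanced
  accuracy ≈ 0.87 at wave 1.  At wave 2 choices are empirically more
  deterministic (repeat administration); `beta` is scaled by 2.5
  (calibrated to wave-2 diagnostics of pseudo-R² ≈ 0.875, balanced
  accuracy ≈ 0.94).
* **Wave 2.** The shock latent drifts down by 0.18 (+ individual noise,
  SD 0.6), producing a mean Likert drop of ~0.27.  The change in log k is
  `b_Δ·z(Δshock01) + σ_Δ·ε` with `b_Δ = 0.16` standardized and
  `σ_Δ = 1.0` (consistent with a plausible ~0.75 test–retest correlation
  of log k at SD 1.39; calibration).  Exactly `round(0.08·n)` participants
  are flagged as reporting a *positive* shock (a deterministic count over a
  random subset, so exclusion arithmetic such as 200 → 184 is exact); the
  flag is drawn independently of the simulated shock values.

**What the generator does not emulate:** attention/catch-trial behaviour,
missing data, panel attrition, demographic correlations (age–income etc.),
or any causal income→affect pathway.  Passing tests therefore demonstrate
that the *pipeline* recovers what was planted under the stated structure —
not that real cohorts satisfy that structure.

**Measurement attenuation.**  Because the pipeline regresses *fitted*
log k, measurement noise from 27 binary choices inflates the outcome SD and
attenuates standardized coefficients by a factor
`S/√(S² + σ_m²)` (per-wave `σ_m ≈ 0.55` at wave-1 fit quality, ~0.93
attenuation cross-sectionally; change scores carry both waves' noise and
attenuate more).  Recovered effects are therefore expected a few percent
below their planted values, and coverage of ±2 SE bands is correspondingly
tighter than the no-measurement-noise ideal.  This mirrors the situation in
real data, where reported effects are likewise on estimated rates.

## Covariate encoding

* Income-shock Likert: {1, 2, 3} → 0, {4, 5, 6} → 1.
* Emotion ratings: `< 33.33 → 0`, `> 66.66 → 1`, else 0.5.  The published
  rule uses strict inequalities, leaving ratings exactly at a boundary
  unassigned; both boundaries fall in the middle bin by default (continuity),
  configurable via `boundary_policy` ("middle" / "down" / "up").
* Negative affect: the mean of the three converted values
  (convert-then-average).  The alternative order — average raw ratings then
  convert — is implemented behind `order="average_first"`; conversion is a
  reporting-policy step applied per emotion, so convert-first is the
  default.
* Standardization: `(x − mean)/SD` with the sample (n−1) SD; constant
  columns are an error.  Gender, although binary, is standardized like
  every other predictor (standardized coefficients are reported for it).
* Change scores: `Δ = wave 2 − wave 1` for log k and for the *binarised*
  shock (Δ ∈ {−1, 0, 1}); raw-Likert differencing is available behind
  `delta_shock_scale="likert"`.  Demographics enter the panel model at
  their wave-1 values.  Participants flagged positive-shock at wave 2 are
  excluded by default (switchable), and participants missing a wave are
  dropped with a warning; all row counts are kept in `attrs` and asserted
  to conserve.

## Inference layer

* **Robust regression** is IRLS with Tukey bisquare weights (`c = 4.685`,
  ~95% Gaussian efficiency), residual scale by the median absolute
  deviation (consistency factor 0.6745), iterated on the weights to 1e-8 or
  50 iterations (statsmodels RLM underneath).  Predictors and response are
  z-scored *before* fitting by default, so estimates are standardized
  betas; t = estimate/SE with `df = n − p − 1` and two-tailed p from the t
  distribution.  R² is the squared Pearson correlation of fitted and
  observed values — identical to classical R² under OLS and a sensible
  analogue for robust fits.  A perfect linear fit degenerates the MAD
  scale; that case falls back to exact least squares.  Note that bisquare
  weights are strictly below 1 for any nonzero residual, so on clean
  Gaussian data the robust estimate agrees with OLS only statistically
  (to a fraction of a standard error), not to machine precision; exact
  agreement holds in the all-weights-one (perfect-fit) limit.
* **Coefficient comparison**: `t = (b_a − b_b)/√(v_a + v_b − 2c_ab)` with
  the fit's residual df.
* **Sobel test**: statistic `a·b/√(b²se_a² + a²se_b²)`; p from the
  standard normal reference, with a df-matched t-reference p reported
  alongside (published mediation tables sometimes print t with df; the two
  differ negligibly at the sample sizes involved).  The statistic is
  conservative near the null, which the negative-control calibration
  (rejection ≤ 6% at nominal 5% over 1000 null cohorts) confirms.
* **Bayes factors**: each model is scored against the intercept-only model
  by the Jeffreys–Zellner–Siow default-prior integral over the g-prior
  scale, which depends on the data only through n, p and R²;
  BF(full vs reduced) is the ratio.  The integrand is evaluated in log
  space after substituting `g = e^t`, centred at its mode, and integrated
  by adaptive quadrature; a Laplace (saddle-point) approximation is the
  overflow-proof fallback and agrees with quadrature to ~1e-2 in log BF at
  n ≈ 1000.  The R² fed in is the robust fit's squared fitted–observed
  correlation (the integral's derivation assumes OLS R²; this is the
  natural robust analogue).  BF < 1/3 is read as evidence for the null.
* **Power**: smallest n for a two-sided test of a standardized association,
  Fisher-z formula `n = ((z_{1−α/2} + z_{pow})/atanh(ρ))² + 3` rounded up
  (effect 0.2, α = 0.05, power 0.8 → n = 194, i.e. "about 200"); an
  exact noncentral-t search is available and agrees to within a few
  participants.
* No multiple-testing correction is applied anywhere; p-values are raw.

## Problem sizes used in the test and acceptance runs

Cohort studies run at n = 1145 (cross-section) and n = 200 → 184 (panel),
matching the design the generator emulates; coverage studies use 50 seeds;
the mediation negative control uses 1000 covariate-only cohorts (the
mediation layer operates on the generated log k directly — choice fitting
adds nothing to a *calibration* check of the regression/Sobel machinery and
would dominate the runtime); Bayes-factor calibration uses 500 replicates
at n = 184; parameter recovery uses 10 grid points × 50 replicates.

## Known limitations

* Only the hyperbolic discount function is implemented (no exponential or
  quasi-hyperbolic alternatives) and estimation is per-participant maximum
  likelihood — no hierarchical pooling.
* The Sobel test is the only mediation machinery (no bootstrap CIs).
* The generator's demographics are marginally realistic but mutually
  independent; planted standardized effects assume near-orthogonal
  covariates.
* Standardized betas from robust fits are compared against OLS-style
  expectations; with heavy contamination the two scales can drift apart.
* The JZS Bayes factor assumes the fixed-design linear-model derivation;
  feeding it a robust R² is an approximation, reasonable when weights are
  near 1.
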