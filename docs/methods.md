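# Methods

This note describes, in the package's own terms, every method `predsize`
implements and each implementation decision that affects results.

## 1. Setting and notation

A clinical prediction model (CPM) estimates the risk `p_i` of a binary
outcome `y_i` from predictors `x_i`. We plan the *development* sample size
`n`: the number of participants used to fit the CPM. Performance is always
judged in a large *target population* of `n_T` individuals (default
100,000) whose true risks are known by construction, so every estimate of
degradation is exact up to Monte-Carlo error, not optimism-corrected.

Key quantity: **degradation** = (performance of the developed model) −
(performance of the true model), both evaluated in the target population.
The true model's calibration slope is 1 and its MAPE 0 by construction, so
slope degradation is `slope − 1` and MAPE is its own degradation.

## 2. Case-mix generation (`predsize.casemix`)

The anticipated joint predictor distribution is specified per variable
(continuous with mean/sd, binary with prevalence, categorical with level
probabilities) plus an optional latent correlation matrix. Sampling uses a
Gaussian copula: draw multivariate normal `z` with the given correlation
(factorised by symmetric eigendecomposition, valid for PSD matrices);
continuous variables are `mean + sd * z`; binary variables threshold `z`
at the normal quantile of `1 − prevalence`; categorical variables cut `z`
at cumulative-probability quantiles and expand to `k − 1` dummy columns
(first level is the reference). The latent correlation is therefore not
exactly the observed-scale correlation for discretised variables; tests
compare generated correlations against a large oracle draw of the same
generator rather than against the latent matrix.

Alternatively an existing dataset's predictor rows can be loaded from CSV
and treated as a finite pool, sampled *without replacement* for both the
population and each development set. Columns declared as fairness groups
are kept out of the design matrix and carried alongside for subgroup
metrics.

## 3. Reference model and calibration (`predsize.refmodel`)

The true model is logistic:

```
logit(p_i) = alpha + delta * (beta' x_i)
```

`beta` encodes anticipated relative weights (e.g. all equal when no better
knowledge exists); `delta` scales discrimination and `alpha` sets overall
risk. When the user anticipates only a c-statistic `C*` and prevalence
`phi*`, `calibrate_reference` finds `(alpha, delta)`:

- inner step: at any candidate `delta`, solve `alpha` by Brent root-finding
  so that `mean(expit(alpha + delta * eta)) = phi*` (monotone in `alpha`);
- outer step: bisection on `delta` against the achieved c-statistic,
  bracketing by doubling from `delta = 1`.

The achieved c-statistic is computed against outcomes generated by **common
random numbers**: one uniform vector `u` drawn once, outcomes
`y = (u < p)`. This makes achieved-C a smooth, nondecreasing function of
`delta`, so bisection converges; with independently redrawn outcomes the
curve would be noisy at the 1e-3 level, comparable to the stopping
tolerance (|C − C*| ≤ 0.002 and |prevalence − phi*| ≤ 0.002, at most 50
outer iterations). Degenerate case mixes (constant linear predictor) and
plateauing brackets raise a `CalibrationError` carrying the best achieved
state.

Uncertainty about the true model is a finite `ReferenceMixture` with
selection probabilities; each replicate draws one component. A
single-component mixture is collapsed to the plain single-model path so the
two specifications give bitwise-identical runs.

## 4. Development strategies (`predsize.strategies`)

All continuous predictors are standardised to the development sample's mean
and sd (stored and reapplied at prediction time). Fits that are unstable
(separation, non-convergence, non-positive shrinkage, fully shrunk
penalised fits, single-class tree samples) are **kept and flagged**, never
dropped — small-sample instability is the phenomenon under study.

- **logistic**: unpenalised MLE (statsmodels Newton fit); on failure a
  near-unpenalised fallback is retained with a separation flag.
- **logistic_shrinkage**: MLE followed by heuristic uniform shrinkage
  `S = (chi2_LR − P) / chi2_LR` applied to the slopes, where `chi2_LR` is
  the likelihood-ratio statistic and `P` the predictor count; the intercept
  is re-estimated by an intercept-only logistic fit with the shrunken
  linear predictor as offset, restoring calibration-in-the-large.
- **ridge_cv / lasso_cv**: penalised logistic regression with the penalty
  chosen by 10-fold stratified cross-validated binomial deviance over a
  100-point log-spaced grid from near-unpenalised to fully shrunk (grid
  anchored at the lasso's zero-coefficient bound `max |Z'(y − ybar)| / n`,
  inflated for ridge). Reported `lambda` relates to scikit-learn's `C` by
  `lambda = 1 / (C n)`. Folds are reduced (with a warning) when the rarer
  class cannot populate 10 folds.
- **bayes_ridge / bayes_lasso**: exact Bernoulli likelihood with shrinkage
  priors — ridge `beta_j ~ N(0, lambda^2)`,
  `lambda^2 ~ inverse-gamma(0.01, 0.01)`; lasso `beta_j ~ Laplace(0,
  1/lambda)`, `lambda^2 ~ gamma(shape 1, scale 1/1.78)`; vague `N(0, 1e6)`
  intercept prior — sampled by adaptive random-walk Metropolis–Hastings on
  `(alpha, beta, log lambda^2)` (Jacobian included), burn-in 5,000,
  thinning 10, 1,000 retained draws by default. The fitted model uses the
  posterior-mean coefficient vector (posterior-mean risk is available as an
  option). Acceptance rates outside (0.05, 0.8) raise a warning.
- **random_forest** (100 trees, default depth 3) and **gradient_boosting**
  (100 trees, depth 15, learning rate 0.1): probabilities from the
  scikit-learn ensembles on standardised inputs. These defaults mirror a
  shallow-forest / deep-boosting contrast; tree-method results are
  implementation-dependent across libraries and are treated qualitatively.
- **oracle**: returns the reference model itself; used to validate that the
  evaluation machinery reports zero degradation when nothing is estimated.

## 5. Performance metrics (`predsize.metrics`)

Per replicate, on the target population:

- **c-statistic**: midrank-based concordance (ties counted 1/2).
- **calibration slope**: logistic regression of `y` on `logit(p_hat)`;
  **calibration-in-the-large**: intercept re-estimated with `logit(p_hat)`
  as a fixed offset. A flexible observed-vs-expected curve uses a
  restricted cubic spline (4 knots) of `logit(p_hat)`. Degenerate
  (constant) predictions are recorded as slope 0 with a flag.
- **MAPE / RMSPE**: mean absolute and root-mean-squared difference between
  estimated and true risks — possible only because true risks are known.
- **R²**: Cox–Snell from Bernoulli log-likelihoods against the prevalence
  null; Nagelkerke rescales by the maximum attainable value.
- **Net benefit** at threshold `t`: `TP/n − FP/n * t/(1−t)`; treat-all
  `phi − (1−phi) t/(1−t)`; treat-none 0. `NB_max` evaluates the true
  risks — the ceiling a model of these predictors can reach. **RVSI**
  (relative value of sample information) = `100 * NB_model / NB_max`
  (undefined with a warning when `NB_max ≤ 0`); EVSI-style degradation is
  `NB_model − NB_max`. The **winner** strategy picks
  model/treat-all/treat-none by development-sample net benefit (ties favour
  the model) and reports the winner's population net benefit.
- **Instability**: across replicates, each tracked individual's risk draws
  give a 95% interval width, an effective sample size
  `p̄(1−p̄)/var(draws)` (capped and flagged at zero variance), and a
  misclassification probability against the threshold (values at the
  threshold count as positive). To bound memory, a random subsample of
  2,000 individuals is tracked by default (configurable up to all of the
  population); subsampling is unbiased for all summary curves.
- **Subgroup metrics**: c, slope and MAPE recomputed within declared
  fairness groups; single-class subgroups yield flagged partial results.

## 6. Engine (`predsize.engine`)

`SampleSizeSimulation.fit()` runs the replicate loop and returns
`SampleSizeResults` (replicates table, summaries, assurance, instability,
report writers). Design decisions:

- **Randomness**: one master `SeedSequence` spawns substreams for the
  population, reference calibration, and each replicate; each replicate
  spawns further streams for development draw, strategy randomness, outcome
  regeneration and mixture selection. Consequence: changing the strategy
  does not perturb the simulated data; runs are bitwise reproducible.
- **Population**: fixed across replicates under a single reference model
  (performance differences between replicates then reflect only development
  sampling); under a true mixture, each replicate regenerates true risks
  and outcomes from its drawn component.
- **Failures**: a replicate whose fit raises is recorded as a flagged row
  with missing metrics; the run aborts if failures exceed 20% of `n_sims`
  (configurable).
- **Summaries**: mean, empirical 2.5/97.5 percentiles, Monte-Carlo standard
  error `sd/sqrt(n_sims)`, and assurance probabilities for interval
  targets (defaults: slope within [0.9, 1.1] and [0.85, 1.15], MAPE below
  0.05, c-degradation above −0.025, RVSI at least 90 at each threshold).
- **Sweeps**: criteria are explicit mean bounds or assurance thresholds; the
  smallest grid `n` meeting all is reported, with no interpolation between
  grid points (metric–n curves are noisy and sizes are discrete decisions).

## 7. Fisher-information approximation (`predsize.fisher`)

The expensive part of the full simulation is refitting. The approximation
replaces refits with draws of the anticipated posterior of the coefficient
vector. The **unit information** is `I = mean_i[w_i x_i x_i']` with
`w_i = p_i (1 − p_i)` at the reference model's risks, averaged over a large
case-mix sample; at size `n` the approximate posterior of the MLE is
`MVN(beta_ref, n^{-1} I^{-1})`. For shrinkage methods, the same MVN term is
used as a pseudo-likelihood and combined with the ridge/lasso priors above,
sampled by the shared adaptive MH kernel (default burn-in 10,000 on this
path). Draws are evaluated on the population exactly like simulated fits,
in the same results container. The approximation inherits the usual
asymptotic caveats: it ignores finite-sample skew of the likelihood,
separation, and CV-selection noise, so it is a screening tool, not a
replacement for the full simulation near small `n`.

## 8. Starter sample sizes (`predsize.starters`)

- **Shrinkage criterion**: `n = P / ((S − 1) ln(1 − R2_CS / S))` for target
  expected shrinkage `S` (default 0.9). When only a c-statistic is
  anticipated, `R2_CS` is obtained by simulating one large dataset
  (default 1e6 rows) whose linear predictor is normal within outcome
  classes with means separated by `sqrt(2) * Phi^{-1}(C)` — the separation
  implying concordance `C` — fitting a logistic calibration model, and
  converting the likelihood-ratio statistic via
  `R2_CS = 1 − exp(−chi2_LR / n)`.
- **Risk precision**: `n = 1.96^2 phi (1 − phi) / (w/2)^2` so the 95% CI
  for the overall risk has total width at most `w` (default 0.1).
- The combined starter is the maximum, with expected events
  `round(n * phi)`. At `phi = 0.68` the risk-precision criterion gives
  `n = 335` with `round(335 * 0.68) = 228` expected events.

These remain *starting* values: the simulation then quantifies what the
closed forms cannot (assurance, instability, utility, non-MLE strategies).

## 9. Reproducibility and tolerances

Every simulated number in the documentation and acceptance suite is
recomputed from scratch by `scripts/acceptance.py` under seed substreams of
a single master seed. Closed-form targets are exact. Simulation targets
carry two tolerances: Monte-Carlo error (controlled by replicate counts and
reported as MC-SE) and case-mix approximation — the built-in independent
standard-normal case mix calibrated to C = 0.76 / prevalence 0.68 is not
any particular real dataset's case mix, and quantities like the mean MLE
calibration slope are mildly case-mix dependent (we observe ≈ 0.86–0.89 at
n = 456 across case mixes with identical C, prevalence and P).
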