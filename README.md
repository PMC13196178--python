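# predsize

Simulation-based sample-size planning for clinical prediction models.

## The problem

Before collecting data to develop a clinical prediction model (CPM) — a
logistic model, penalised regression, or tree ensemble mapping a patient's
predictors to an outcome risk — you must decide how many participants to
recruit. Closed-form criteria (events per variable, shrinkage-based minimum
sizes) answer only a narrow question: they bound the *expected* shrinkage of
a maximum-likelihood logistic model. They say nothing about the probability
that one particular developed model will calibrate well, discriminate well,
or be clinically useful, and nothing at all about machine-learning
strategies, penalised estimators, or individual-level prediction
instability.

`predsize` answers the broader question by simulation. You encode what you
anticipate about the setting — the case mix (joint predictor distribution),
a reference "true" model, a candidate development strategy and sample size —
and the package simulates the whole development-and-deployment pipeline many
times, reporting the full distribution of model performance, and thus the
*assurance* (probability) that a model developed at that size will be good
enough.

## The core model

Everything is anchored to a logistic **reference model**

```
logit(p_i) = alpha + delta * (beta' x_i)
```

where `beta` carries anticipated *relative* predictor weights and
`(alpha, delta)` are calibrated iteratively so the model achieves a target
c-statistic and outcome prevalence on a large generated case-mix sample
(bisection on `delta`, root-finding on `alpha` at every step, common random
numbers for smoothness).

One simulation run then repeats, for each of `n_sims` replicates:

1. draw a development dataset of size `n` from the case mix, with outcomes
   from the reference model's true risks;
2. fit the chosen strategy (unpenalised MLE, heuristic uniform shrinkage,
   CV-tuned ridge/lasso, Bayesian ridge/lasso via MCMC, random forest,
   gradient boosting);
3. predict on a fixed target population of 100,000 individuals;
4. score the developed model against the truth: c-statistic, calibration
   slope and calibration-in-the-large, MAPE/RMSPE of risk estimates,
   Cox–Snell and Nagelkerke R², net benefit at clinical thresholds, the
   relative value of sample information (RVSI), and the *degradation* of
   each (developed minus true performance).

Across replicates the package reports posterior summaries (mean, 95% range,
Monte-Carlo SE), assurance probabilities (e.g. `P(0.9 <= slope <= 1.1)`),
per-individual prediction instability (interval width, effective sample
size, misclassification probability), and — swept over a grid of candidate
sizes — the smallest `n` meeting your criteria.

Two shortcuts complement the full simulation:

- **starter sizes** (`predsize.starters`): closed-form minimum `n` from the
  expected-shrinkage and risk-precision criteria, with a simulation-based
  conversion from an anticipated c-statistic to the Cox–Snell R² the
  shrinkage formula needs;
- **Fisher approximation** (`predsize.fisher`): instead of thousands of
  refits, draw anticipated-posterior coefficient vectors from
  `MVN(beta_ref, n^{-1} I^{-1})` built from the unit Fisher information of
  the case mix — or push that pseudo-likelihood through shrinkage priors by
  Metropolis–Hastings — and evaluate the draws on the population.

## Worked example

The setting used throughout the documentation: 10 standardised predictors,
anticipated c-statistic 0.76, outcome prevalence 0.68.

```python
import predsize as ps

# 1. closed-form starting size
start = ps.minimum_sample_size(n_predictors=10, prev=0.68, c=0.76, seed=1)
print(start.n)          # ~456 from the shrinkage criterion
print(start.n_risk)     # 335 from risk precision

# 2. simulate what actually happens at that size
sim = ps.SampleSizeSimulation(
    casemix=ps.CaseMixSpec.standard_normal(10),
    reference={"relative_beta": [1.0] * 10,
               "target_c": 0.76, "target_prev": 0.68},
    strategy="logistic",
    n=start.n,
    n_sims=1000,
    seed=42,
)
results = sim.fit()
print(results.summary())
# mean calibration slope ~ 0.89: noticeable expected overfitting even at
# the closed-form "minimum" size
print(results.assurance)           # e.g. P(slope in [0.9, 1.1]) ~ 0.45

# 3. does shrinkage fix it? sweep sample sizes with explicit criteria
cfg = ps.SimulationConfig(
    casemix=ps.CaseMixSpec.standard_normal(10),
    reference={"relative_beta": [1.0] * 10,
               "target_c": 0.76, "target_prev": 0.68},
    strategy="logistic_shrinkage",
    n_grid=(335, 456, 1000),
    n_sims=500,
    seed=42,
)
sweep = ps.sweep_sample_sizes(
    cfg,
    [ps.Criterion("cal_slope", lower=0.9, upper=1.1, min_prob=0.7),
     ps.Criterion("mape", max_mean=0.05)],
)
print(sweep.table)
print(sweep.n_min)     # smallest grid size meeting both, or None
```

The same run from the command line:

```bash
predsize starters -p 10 --prevalence 0.68 --c-statistic 0.76
predsize simulate config.yaml --n 456 --out results/
predsize sweep config.yaml --criterion "cal_slope,lower=0.9,upper=1.1,min_prob=0.7"
predsize approx config.yaml --n 456 --prior ridge   # fast approximation
predsize report results/replicates.csv              # re-summarise saved runs
```

with `config.yaml`:

```yaml
casemix:
  standard_normal: 10
reference:
  relative_beta: [1, 1, 1, 1, 1, 1, 1, 1, 1, 1]
  target_c: 0.76
  target_prev: 0.68
strategy:
  name: logistic
run:
  n_grid: [335, 456, 1000]
  n_sims: 1000
  seed: 42
```

A case mix can also be a fully specified list of variables (continuous,
binary, categorical, with a latent Gaussian-copula correlation matrix) or an
external CSV (`casemix: {file: mix.csv}`); reference-model uncertainty is
expressed as a mixture of plausible reference models, one drawn per
replicate.

## Reproduction

All headline numbers are recomputed from scratch by:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

(about 4 minutes on one CPU). The test suite, including a test per headline
number, runs with:

```bash
python -m pytest
```

Simulation-derived values carry Monte-Carlo tolerance; the built-in
standard-normal case mix approximates (rather than reproduces) any
particular real dataset's case mix, so simulation targets are checked
within an explicit comparison slack, while closed-form values are exact.

See `docs/methods.md` for the full methods note.
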