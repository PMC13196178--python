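"""Model-development strategies: each maps a development dataset to a fitted
prediction model exposing risks for new predictor rows.

Strategies mirror common practice for clinical prediction models:
unpenalised maximum-likelihood logistic regression, the same followed by a
heuristic uniform shrinkage, frequentist ridge/lasso with ten-fold
cross-validated tuning, fully Bayesian ridge/lasso via Metropolis–Hastings
with shrinkage priors, random forests, and gradient boosting.  An oracle
strategy returning the reference model itself is included as a harness for
testing the degradation machinery (its degradation should be ~0).

Every strategy standardises the predictors using the development sample's
means and standard deviations and stores those parameters in the fitted
model, so predictions can be made for new individuals in original units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.special import expit
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from .casemix import DevelopmentData
from .fisher import MCMCConfig, PriorSpec, adaptive_random_walk, log_prior

__all__ = [
    "FittedModel",
    "LinearFittedModel",
    "EnsembleFittedModel",
    "OracleModel",
    "ShrinkageFit",
    "fit_logistic_mle",
    "fit_logistic_uniform_shrinkage",
    "fit_penalized_cv",
    "fit_bayes_penalized",
    "fit_random_forest",
    "fit_gradient_boosting",
    "oracle_strategy",
    "Strategy",
    "make_strategy",
    "STRATEGY_NAMES",
]


@dataclass
class Scaling:
    """Standardisation parameters estimated on the development sample."""

    mean: np.ndarray
    sd: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd


def _fit_scaling(X: np.ndarray) -> Scaling:
    m = X.mean(axis=0)
    s = X.std(axis=0)
    s = np.where(s < 1e-12, 1.0, s)
    return Scaling(mean=m, sd=s)


class FittedModel:
    """Contract for a fitted prediction model: deterministic risks in [0,1]."""

    strategy_name: str = "abstract"
    details: dict
    scaling: Scaling | None = None

    def predict_risk(self, X) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    @property
    def flags(self) -> dict:
        return {k: v for k, v in self.details.items() if k.startswith("flag_")}


@dataclass
class LinearFittedModel(FittedModel):
    """Logistic model on standardised predictors (intercept first)."""

    coef: np.ndarray
    scaling: Scaling
    strategy_name: str
    details: dict = field(default_factory=dict)

    def predict_risk(self, X) -> np.ndarray:
        Z = self.scaling.transform(X)
        return expit(self.coef[0] + Z @ self.coef[1:])


@dataclass
class EnsembleFittedModel(FittedModel):
    """Tree-ensemble model; probabilities from the underlying estimator."""

    estimator: object
    scaling: Scaling
    strategy_name: str
    details: dict = field(default_factory=dict)
    constant: float | None = None  # one-class development sample

    def predict_risk(self, X) -> np.ndarray:
        Z = self.scaling.transform(X)
        if self.constant is not None:
            return np.full(Z.shape[0], self.constant)
        proba = self.estimator.predict_proba(Z)
        return proba[:, list(self.estimator.classes_).index(1.0)]


@dataclass
class OracleModel(FittedModel):
    """Test-harness strategy returning the reference model's own risks."""

    reference: object
    strategy_name: str = "oracle"
    details: dict = field(default_factory=dict)
    scaling: Scaling | None = None

    def predict_risk(self, X) -> np.ndarray:
        return self.reference.true_risks(X)


@dataclass
class ShrinkageFit:
    """Heuristic uniform-shrinkage summary S = (chi2_LR - P) / chi2_LR."""

    S: float
    lr_chisq: float
    P: int
    reestimated_intercept: float
    flagged: bool = False


def _check_dev(dev: DevelopmentData, require_both_classes: bool = True):
    y = dev.y
    if require_both_classes and (y.sum() == 0 or y.sum() == y.size):
        raise ValueError("development outcome is single-class; cannot fit")
    return dev.X, y


def _null_loglik(y: np.ndarray) -> float:
    phi = y.mean()
    if phi in (0.0, 1.0):
        return 0.0
    return float(y.size * (phi * np.log(phi) + (1 - phi) * np.log(1 - phi)))


def fit_logistic_mle(dev: DevelopmentData, rng=None, reference=None) -> LinearFittedModel:
    """Unpenalised maximum-likelihood logistic regression (no selection).

    Separated or otherwise unstable fits are retained and flagged rather
    than dropped: small-sample instability is precisely what the simulation
    is meant to reveal.
    """
    X, y = _check_dev(dev)
    scaling = _fit_scaling(X)
    Z = sm.add_constant(scaling.transform(X), has_constant="add")
    details: dict = {}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Z).fit(disp=0, maxiter=200)
        coef = np.asarray(res.params, dtype=float)
        details["converged"] = bool(res.mle_retvals.get("converged", True))
        details["llf"] = float(res.llf)
        details["llnull"] = float(res.llnull)
    except Exception:  # complete separation: keep a near-unpenalised fit
        lr = LogisticRegression(l1_ratio=0.0, C=1e8, solver="lbfgs", max_iter=2000)
        lr.fit(Z[:, 1:], y)
        coef = np.concatenate([lr.intercept_, lr.coef_.ravel()])
        eta = Z @ coef
        p = expit(eta)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        details["llf"] = float(y @ np.log(p) + (1 - y) @ np.log(1 - p))
        details["llnull"] = _null_loglik(y)
        details["converged"] = False
        details["flag_separation"] = True
    if np.abs(coef).max() > 15.0:
        details["flag_separation"] = True
    if not details["converged"]:
        details["flag_nonconverged"] = True
    return LinearFittedModel(coef=coef, scaling=scaling, strategy_name="logistic", details=details)


def fit_logistic_uniform_shrinkage(
    dev: DevelopmentData, rng=None, reference=None
) -> LinearFittedModel:
    """MLE logistic regression followed by heuristic uniform shrinkage.

    Slopes are multiplied by S = (chi2_LR - P) / chi2_LR and the intercept is
    re-estimated by an intercept-only logistic fit with the shrunken linear
    predictor as a fixed offset.  S <= 0 (possible when the likelihood-ratio
    chi-square is small) is retained sign and all, with a flag — mirroring
    the heavy-tailed slope distributions such fits produce.
    """
    mle = fit_logistic_mle(dev)
    X, y = dev.X, dev.y
    P = X.shape[1]
    lr_chisq = 2.0 * (mle.details["llf"] - mle.details["llnull"])
    flagged = False
    if lr_chisq > 0:
        S = (lr_chisq - P) / lr_chisq
        if S <= 0:
            flagged = True
    else:
        S = 0.0
        flagged = True
    Z = mle.scaling.transform(X)
    offset = S * (Z @ mle.coef[1:])
    # intercept-only refit with shrunken linear predictor as offset
    a = 0.0
    for _ in range(50):
        mu = expit(a + offset)
        step = float((y - mu).sum() / max((mu * (1 - mu)).sum(), 1e-12))
        a += step
        if abs(step) < 1e-10:
            break
    coef = np.concatenate([[a], S * mle.coef[1:]])
    details = dict(mle.details)
    details["shrinkage"] = ShrinkageFit(
        S=float(S), lr_chisq=float(lr_chisq), P=P, reestimated_intercept=float(a),
        flagged=flagged,
    )
    if flagged:
        details["flag_nonpositive_shrinkage"] = True
    return LinearFittedModel(
        coef=coef, scaling=mle.scaling, strategy_name="logistic_shrinkage", details=details
    )


def _lambda_grid(Z: np.ndarray, y: np.ndarray, penalty: str, n_lambdas: int) -> np.ndarray:
    """glmnet-style grid from the fully-shrunk to near-unpenalised range."""
    n = y.size
    lam_max = float(np.abs(Z.T @ (y - y.mean())).max()) / n
    lam_max = max(lam_max, 1e-4)
    if penalty == "ridge":
        lam_max *= 1000.0  # ridge never fully shrinks at the lasso lam_max
    return np.geomspace(lam_max, lam_max * 1e-4, n_lambdas)


def fit_penalized_cv(
    dev: DevelopmentData,
    penalty: str = "ridge",
    folds: int = 10,
    rng=None,
    *,
    n_lambdas: int = 100,
    fixed_lambda: float | None = None,
    reference=None,
) -> LinearFittedModel:
    """Frequentist penalised logistic regression with CV-tuned penalty.

    The penalty parameter is selected by minimising the cross-validated
    binomial deviance over a log-spaced grid (stratified folds, seeded from
    ``rng``), then the model is refit on the full development data at the
    chosen value.  ``fixed_lambda`` (glmnet scale: mean-deviance + lambda *
    penalty) skips the CV.  The recorded ``lambda`` relates to sklearn's
    ``C`` by lambda = 1 / (C * n).
    """
    if penalty not in ("ridge", "lasso"):
        raise ValueError(f"penalty must be 'ridge' or 'lasso', got {penalty!r}")
    X, y = _check_dev(dev)
    scaling = _fit_scaling(X)
    Z = scaling.transform(X)
    n = y.size
    l1 = penalty == "lasso"
    solver = "saga" if l1 else "lbfgs"
    details: dict = {"penalty": penalty}

    if fixed_lambda is not None:
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        C = 1.0 / (fixed_lambda * n)
        est = LogisticRegression(
            l1_ratio=1.0 if l1 else 0.0, C=C, solver=solver, max_iter=5000, tol=1e-8,
            random_state=int(rng.integers(2**31 - 1)),
        )
        est.fit(Z, y)
        details["lambda"] = float(fixed_lambda)
    else:
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        seed = int(rng.integers(2**31 - 1))
        min_class = int(min(y.sum(), n - y.sum()))
        if min_class < 2:
            raise ValueError("cannot form stratified folds: a class has < 2 members")
        if folds > min_class:
            warnings.warn(
                f"reducing folds from {folds} to {min_class} so every stratified "
                f"fold contains both classes",
                RuntimeWarning,
                stacklevel=2,
            )
            folds = min_class
        if n < folds:
            raise ValueError(f"n={n} smaller than the number of folds {folds}")
        lambdas = _lambda_grid(Z, y, penalty, n_lambdas)
        Cs = 1.0 / (lambdas * n)
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = LogisticRegressionCV(
                Cs=Cs,
                cv=cv,
                l1_ratios=[1.0 if l1 else 0.0],
                solver=solver,
                scoring="neg_log_loss",
                max_iter=5000,
                tol=1e-6,
                refit=True,
                random_state=seed,
            )
            est.fit(Z, y)
        chosen_C = float(est.C_[0])
        details["lambda"] = 1.0 / (chosen_C * n)
        details["lambda_grid"] = lambdas
        details["cv_seed"] = seed
        details["folds"] = folds
    coef = np.concatenate([np.atleast_1d(est.intercept_), est.coef_.ravel()])
    if np.abs(coef[1:]).max() < 1e-10:
        details["flag_fully_shrunk"] = True
    return LinearFittedModel(
        coef=coef, scaling=scaling, strategy_name=f"{penalty}_cv", details=details
    )


def fit_bayes_penalized(
    dev: DevelopmentData,
    prior: PriorSpec = PriorSpec("ridge"),
    mcmc: MCMCConfig = MCMCConfig(burn_in=5000, thin=10, draws=1000),
    rng=None,
    *,
    point: str = "beta_mean",
    keep_draws: bool = True,
    reference=None,
) -> LinearFittedModel:
    """Bayesian penalised logistic regression on the exact Bernoulli
    likelihood, sampled by adaptive random-walk Metropolis–Hastings.

    The shrinkage priors and the hyperprior on lambda^2 are shared with the
    Fisher-approximation module.  The fitted prediction model uses the
    posterior-mean coefficient vector by default (``point="beta_mean"``);
    ``point="risk_mean"`` instead averages risks over the retained draws.
    """
    if point not in ("beta_mean", "risk_mean"):
        raise ValueError("point must be 'beta_mean' or 'risk_mean'")
    X, y = _check_dev(dev)
    scaling = _fit_scaling(X)
    Z1 = np.column_stack([np.ones(y.size), scaling.transform(X)])
    P = X.shape[1]

    def log_target(theta):
        eta = Z1 @ theta[: P + 1]
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        return ll + log_prior(theta, P, prior)

    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    dim = P + 1 + (0 if prior.fixed_lambda2 is not None else 1)
    x0 = np.zeros(dim)
    phi = y.mean()
    x0[0] = np.log(phi / (1 - phi))
    chain, rate = adaptive_random_walk(
        log_target, x0, mcmc.total_iterations, rng,
        adapt_until=mcmc.burn_in, target_accept=mcmc.target_accept,
    )
    if not 0.05 < rate < 0.8:
        warnings.warn(
            f"MH acceptance rate {rate:.2f} outside (0.05, 0.8)", RuntimeWarning, stacklevel=2
        )
    kept = chain[mcmc.burn_in :: mcmc.thin][: mcmc.draws]
    draws = kept[:, : P + 1]
    details: dict = {
        "prior": prior,
        "mcmc": mcmc,
        "acceptance_rate": float(rate),
        "point": point,
    }
    if keep_draws:
        details["draws"] = draws
    if prior.fixed_lambda2 is None:
        details["lambda2_mean"] = float(np.exp(kept[:, P + 1]).mean())
    if point == "beta_mean":
        coef = draws.mean(axis=0)
        return LinearFittedModel(
            coef=coef, scaling=scaling, strategy_name=f"bayes_{prior.family}", details=details
        )
    return _PosteriorMeanRiskModel(
        draws=draws, scaling=scaling, strategy_name=f"bayes_{prior.family}", details=details
    )


@dataclass
class _PosteriorMeanRiskModel(FittedModel):
    """Bayesian fit predicting posterior-mean risk (averaged over draws)."""

    draws: np.ndarray
    scaling: Scaling
    strategy_name: str
    details: dict = field(default_factory=dict)

    def predict_risk(self, X) -> np.ndarray:
        Z1 = np.column_stack([np.ones(len(X)), self.scaling.transform(X)])
        return expit(Z1 @ self.draws.T).mean(axis=1)


def _fit_tree(dev, estimator_cls, name, rng, **kw) -> EnsembleFittedModel:
    X, y = _check_dev(dev, require_both_classes=False)
    scaling = _fit_scaling(X)
    if y.sum() in (0, y.size):
        return EnsembleFittedModel(
            estimator=None, scaling=scaling, strategy_name=name,
            details={"flag_single_class": True}, constant=float(y.mean()),
        )
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    seed = int(rng.integers(2**31 - 1))
    est = estimator_cls(random_state=seed, **kw)
    est.fit(scaling.transform(X), y)
    return EnsembleFittedModel(
        estimator=est, scaling=scaling, strategy_name=name, details={"seed": seed, **kw}
    )


def fit_random_forest(
    dev: DevelopmentData, n_trees: int = 100, max_depth: int = 3, rng=None, reference=None
) -> EnsembleFittedModel:
    """Random forest (probability = mean of per-tree leaf class proportions)."""
    return _fit_tree(
        dev, RandomForestClassifier, f"random_forest_d{max_depth}", rng,
        n_estimators=n_trees, max_depth=max_depth,
    )


def fit_gradient_boosting(
    dev: DevelopmentData,
    n_trees: int = 100,
    max_depth: int = 15,
    learning_rate: float = 0.1,
    rng=None,
    reference=None,
) -> EnsembleFittedModel:
    """Gradient boosting of decision trees with logistic loss."""
    return _fit_tree(
        dev, GradientBoostingClassifier, "gradient_boosting", rng,
        n_estimators=n_trees, max_depth=max_depth, learning_rate=learning_rate,
    )


def oracle_strategy(reference) -> OracleModel:
    """Strategy returning the reference model itself (degradation ~ 0)."""
    return OracleModel(reference=reference)


class Strategy:
    """Named, configured strategy: callable (dev, rng, reference) -> model."""

    def __init__(self, name: str, fn, kwargs: dict):
        self.name = name
        self._fn = fn
        self.kwargs = kwargs

    def __call__(self, dev: DevelopmentData, rng=None, reference=None) -> FittedModel:
        return self._fn(dev, rng=rng, reference=reference, **self.kwargs)

    def __repr__(self):
        return f"Strategy({self.name!r}, {self.kwargs})"


def _oracle_fn(dev, rng=None, reference=None):
    if reference is None:
        raise ValueError("the oracle strategy needs the reference model")
    return oracle_strategy(reference)


_REGISTRY = {
    "logistic": lambda dev, rng=None, reference=None, **kw: fit_logistic_mle(dev, rng, **kw),
    "logistic_shrinkage": lambda dev, rng=None, reference=None, **kw: fit_logistic_uniform_shrinkage(dev, rng, **kw),
    "ridge_cv": lambda dev, rng=None, reference=None, **kw: fit_penalized_cv(dev, "ridge", rng=rng, **kw),
    "lasso_cv": lambda dev, rng=None, reference=None, **kw: fit_penalized_cv(dev, "lasso", rng=rng, **kw),
    "bayes_ridge": lambda dev, rng=None, reference=None, **kw: fit_bayes_penalized(dev, kw.pop("prior", PriorSpec("ridge")), rng=rng, **kw),
    "bayes_lasso": lambda dev, rng=None, reference=None, **kw: fit_bayes_penalized(dev, kw.pop("prior", PriorSpec("lasso")), rng=rng, **kw),
    "random_forest": lambda dev, rng=None, reference=None, **kw: fit_random_forest(dev, rng=rng, **kw),
    "gradient_boosting": lambda dev, rng=None, reference=None, **kw: fit_gradient_boosting(dev, rng=rng, **kw),
    "oracle": _oracle_fn,
}

STRATEGY_NAMES = tuple(_REGISTRY)


def make_strategy(name: str, **kwargs) -> Strategy:
    """Build a configured strategy by name (see ``STRATEGY_NAMES``)."""
    if name not in _REGISTRY:
        raise ValueError(f"unknown strategy {name!r}; choose from {STRATEGY_NAMES}")
    return Strategy(name, _REGISTRY[name], kwargs)
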