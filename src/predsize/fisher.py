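"""Fast posterior approximation via Fisher's unit-information decomposition.

For unpenalised logistic regression the large-sample posterior of the
coefficient vector is multivariate normal with covariance ``n^{-1} I^{-1}``,
where ``I`` is the per-observation (unit) expected information matrix
averaged over the case mix.  Because ``I`` does not depend on ``n``, it is
computed once; anticipated posteriors at any candidate sample size then come
from direct MVN sampling (:func:`sample_unpenalized_posterior`) — no
development datasets or model fits required.

For Bayesian penalised regression the exact Bernoulli likelihood is replaced
by the MVN pseudo-likelihood ``beta_hat ~ MVN(beta, n^{-1} I^{-1})`` with
``beta_hat`` set to the reference model's coefficients, combined with ridge
or lasso shrinkage priors and a hyperprior on the penalty, and sampled by
adaptive random-walk Metropolis–Hastings
(:func:`mh_shrinkage_posterior`).  This is a Laplace-style approximation: it
is accurate unless the effective sample size is small relative to the number
of predictor parameters.

:class:`FisherApproximation` wraps either route as a model object whose
``fit()`` returns the same results container as the full simulation engine,
so summaries, assurance probabilities and reports are shared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "UnitInformation",
    "PriorSpec",
    "MCMCConfig",
    "unit_information",
    "sample_unpenalized_posterior",
    "mh_shrinkage_posterior",
    "adaptive_random_walk",
    "log_prior",
    "FisherApproximation",
]


@dataclass(frozen=True)
class UnitInformation:
    """Per-observation expected Fisher information (intercept first)."""

    I: np.ndarray
    basis: tuple[str, ...] = ()

    def __post_init__(self):
        I = np.atleast_2d(np.asarray(self.I, dtype=float))
        if I.shape[0] != I.shape[1] or not np.allclose(I, I.T, atol=1e-10):
            raise ValueError("unit information matrix must be square and symmetric")
        object.__setattr__(self, "I", I)

    @property
    def dim(self) -> int:
        return self.I.shape[0]

    def posterior_covariance(self, n: int) -> np.ndarray:
        """Approximate posterior covariance n^{-1} I^{-1}."""
        if n < 1:
            raise ValueError("n must be >= 1")
        cond = np.linalg.cond(self.I)
        try:
            inv = np.linalg.inv(self.I)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"unit information is singular (condition number {cond:.3g})"
            ) from err
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                f"unit information is numerically singular (condition number {cond:.3g})"
            )
        return inv / n


def unit_information(beta, X, basis: tuple[str, ...] = ()) -> UnitInformation:
    """Average w_i x_i x_i' over case-mix rows, w_i = p_i (1 - p_i).

    ``beta`` is the coefficient vector including the intercept; ``X`` is the
    case-mix matrix *without* an intercept column (it is prepended here).
    The average should be taken over a large case-mix sample so that ``I``
    approximates the population expectation.
    """
    beta = np.asarray(beta, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != beta.size - 1:
        raise ValueError(
            f"X must have {beta.size - 1} predictor columns for a coefficient "
            f"vector of length {beta.size} (intercept first)"
        )
    X1 = np.column_stack([np.ones(X.shape[0]), X])
    if np.linalg.matrix_rank(X1) < X1.shape[1]:
        warnings.warn("case-mix design is rank deficient", RuntimeWarning, stacklevel=2)
    eta = X1 @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    I = (X1 * w[:, None]).T @ X1 / X.shape[0]
    if not basis:
        basis = ("intercept",) + tuple(f"x{j + 1}" for j in range(X.shape[1]))
    return UnitInformation(I=I, basis=tuple(basis))


def sample_unpenalized_posterior(beta_ref, info: UnitInformation, n: int, n_draws: int, rng):
    """Draw coefficient vectors from MVN(beta_ref, n^{-1} I^{-1})."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    beta_ref = np.asarray(beta_ref, dtype=float)
    cov = info.posterior_covariance(n)
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        w = np.linalg.eigvalsh(cov)
        raise np.linalg.LinAlgError(
            f"posterior covariance not positive definite "
            f"(eigenvalue range [{w.min():.3g}, {w.max():.3g}])"
        ) from err
    return beta_ref + rng.standard_normal((n_draws, beta_ref.size)) @ L.T


@dataclass(frozen=True)
class PriorSpec:
    """Shrinkage priors mirroring ridge and lasso penalties.

    Ridge: beta_j ~ N(0, lambda^2) with lambda^2 ~ inverse-gamma(0.01, 0.01)
    (shape–rate by default; switchable).  Lasso: beta_j ~ Laplace(0, 1/lambda)
    with lambda^2 ~ gamma(shape 1, scale 1/1.78) — larger lambda means
    stronger shrinkage.  The intercept always gets a vague N(0, 1e6) prior.
    ``fixed_lambda2`` pins lambda^2 instead of sampling it.
    """

    family: str = "ridge"
    intercept_var: float = 1e6
    ig_shape: float = 0.01
    ig_rate: float = 0.01
    ig_parameterisation: str = "rate"  # or "scale"
    gamma_shape: float = 1.0
    gamma_scale: float = 1.0 / 1.78
    fixed_lambda2: float | None = None

    def __post_init__(self):
        if self.family not in ("ridge", "lasso"):
            raise ValueError(f"unknown prior family {self.family!r}")
        for name in ("intercept_var", "ig_shape", "ig_rate", "gamma_shape", "gamma_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ig_parameterisation not in ("rate", "scale"):
            raise ValueError("ig_parameterisation must be 'rate' or 'scale'")
        if self.fixed_lambda2 is not None and self.fixed_lambda2 <= 0:
            raise ValueError("fixed_lambda2 must be positive")


@dataclass(frozen=True)
class MCMCConfig:
    """Metropolis–Hastings settings: burn-in, thinning and retained draws.

    Total iterations = burn_in + thin * draws.  The proposal is an adaptive
    Gaussian random walk tuned toward ``target_accept`` during burn-in and
    frozen afterwards.
    """

    burn_in: int = 10_000
    thin: int = 10
    draws: int = 1000
    target_accept: float = 0.25

    def __post_init__(self):
        if min(self.burn_in, self.thin, self.draws) < 1:
            raise ValueError("burn_in, thin and draws must all be positive")
        if not 0.0 < self.target_accept < 1.0:
            raise ValueError("target_accept must lie in (0, 1)")

    @property
    def total_iterations(self) -> int:
        return self.burn_in + self.thin * self.draws


def log_prior(theta: np.ndarray, n_predictors: int, prior: PriorSpec) -> float:
    """Joint log prior of (alpha, beta_1..beta_P[, log lambda^2]).

    When lambda^2 is sampled, ``theta`` carries z = log(lambda^2) as its last
    entry and the returned density includes the Jacobian of the log
    transform.  Normalising constants that do not involve theta are dropped.
    """
    P = n_predictors
    a = theta[0]
    b = theta[1 : P + 1]
    lp = -0.5 * a * a / prior.intercept_var
    if prior.fixed_lambda2 is not None:
        lam2, z = prior.fixed_lambda2, None
    else:
        z = theta[P + 1]
        lam2 = np.exp(z)
    if prior.family == "ridge":
        lp += -0.5 * P * np.log(lam2) - 0.5 * float(b @ b) / lam2
    else:
        scale = np.sqrt(1.0 / lam2)  # Laplace scale 1/lambda
        lp += -P * np.log(2.0 * scale) - float(np.abs(b).sum()) / scale
    if z is not None:
        if prior.family == "ridge":
            rate = prior.ig_rate if prior.ig_parameterisation == "rate" else 1.0 / prior.ig_rate
            lp += -(prior.ig_shape + 1.0) * z - rate / lam2
        else:
            lp += (prior.gamma_shape - 1.0) * z - lam2 / prior.gamma_scale
        lp += z  # Jacobian d(lambda^2)/dz
    return lp


def adaptive_random_walk(
    log_target,
    x0: np.ndarray,
    n_iter: int,
    rng,
    *,
    adapt_until: int,
    target_accept: float = 0.25,
):
    """Gaussian random-walk Metropolis with scale and covariance adaptation.

    During the first ``adapt_until`` iterations the global proposal scale is
    tuned toward ``target_accept`` (Robbins–Monro) and the proposal
    covariance tracks the running chain covariance; both freeze afterwards
    so the retained chain targets the exact posterior.  Returns
    ``(chain, acceptance_rate)``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x = np.asarray(x0, dtype=float).copy()
    d = x.size
    lp = log_target(x)
    if not np.isfinite(lp):
        raise ValueError("log target is not finite at the initial state")
    scale = 2.38 / np.sqrt(d)
    chol = np.eye(d)
    chain = np.empty((n_iter, d))
    accepted = 0
    mean = x.copy()
    M2 = np.eye(d) * 1e-8
    count = 1
    for i in range(n_iter):
        prop = x + scale * (chol @ rng.standard_normal(d))
        lp_prop = log_target(prop)
        if np.log(rng.random()) < lp_prop - lp:
            x, lp = prop, lp_prop
            accepted += 1
        chain[i] = x
        count += 1
        dx = x - mean
        mean += dx / count
        M2 += np.outer(dx, x - mean)
        if i < adapt_until:
            rate = accepted / (i + 1)
            scale *= np.exp(10.0 * (rate - target_accept) / (1 + i) ** 0.6)
            if i > 200 and i % 100 == 0:
                cov = M2 / count + 1e-9 * np.eye(d)
                try:
                    chol = np.linalg.cholesky(cov)
                except np.linalg.LinAlgError:
                    warnings.warn(
                        "proposal covariance adaptation failed; keeping previous "
                        f"proposal (acceptance so far {rate:.2f})",
                        RuntimeWarning,
                        stacklevel=2,
                    )
    return chain, accepted / n_iter


def _check_acceptance(rate: float) -> None:
    if not 0.05 < rate < 0.8:
        warnings.warn(
            f"MH acceptance rate {rate:.2f} outside (0.05, 0.8) after adaptation",
            RuntimeWarning,
            stacklevel=3,
        )


def mh_shrinkage_posterior(
    beta_ref,
    info: UnitInformation,
    n: int,
    prior: PriorSpec,
    mcmc: MCMCConfig = MCMCConfig(),
    rng=None,
    *,
    return_lambda2: bool = False,
):
    """Sample the shrinkage-prior posterior under the MVN pseudo-likelihood.

    Targets ``p(alpha) * prod_j p(beta_j | lambda) * p(lambda^2) *
    MVN(beta_ref; theta, n^{-1} I^{-1})`` by adaptive random-walk MH on
    (alpha, beta, log lambda^2); burn-in then thinned retention of exactly
    ``mcmc.draws`` coefficient draws.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    beta_ref = np.asarray(beta_ref, dtype=float)
    P = beta_ref.size - 1
    prec = np.linalg.inv(info.posterior_covariance(n))

    def log_target(theta):
        r = beta_ref - theta[: P + 1]
        return -0.5 * float(r @ prec @ r) + log_prior(theta, P, prior)

    dim = P + 1 + (0 if prior.fixed_lambda2 is not None else 1)
    x0 = np.zeros(dim)
    x0[: P + 1] = beta_ref
    chain, rate = adaptive_random_walk(
        log_target, x0, mcmc.total_iterations, rng,
        adapt_until=mcmc.burn_in, target_accept=mcmc.target_accept,
    )
    _check_acceptance(rate)
    kept = chain[mcmc.burn_in :: mcmc.thin][: mcmc.draws]
    draws = kept[:, : P + 1]
    if return_lambda2:
        lam2 = (
            np.full(len(kept), prior.fixed_lambda2)
            if prior.fixed_lambda2 is not None
            else np.exp(kept[:, P + 1])
        )
        return draws, lam2, rate
    return draws


class FisherApproximation:
    """Anticipated-posterior model via the unit-information decomposition.

    Plays the same role as the full simulation engine but generates the
    coefficient draws directly: frequentist (``prior=None``) from the MVN
    posterior, or Bayesian (``prior=PriorSpec(...)``) from the shrinkage
    sampler.  ``fit()`` evaluates each draw as one anticipated model on the
    target population and returns the engine's results container.

    Parameters
    ----------
    casemix : CaseMixSpec or CaseMixSample
        Case-mix source; the unit information is averaged over it (a fresh
        ``info_sample_size`` draw when a spec is given).
    reference : ReferenceModel
        Calibrated reference model; its coefficient vector is ``beta_hat``.
    n : int
        Development sample size of interest.
    """

    def __init__(
        self,
        casemix,
        reference,
        n: int,
        *,
        prior: PriorSpec | None = None,
        mcmc: MCMCConfig = MCMCConfig(),
        n_draws: int = 1000,
        population_size: int = 100_000,
        thresholds=(0.5,),
        assurance=None,
        seed=0,
        info_sample_size: int = 100_000,
        instability_individuals: int | None = 2000,
    ):
        self.casemix = casemix
        self.reference = reference
        self.n = int(n)
        self.prior = prior
        self.mcmc = mcmc if prior is None else replace(mcmc, draws=n_draws)
        self.n_draws = int(n_draws)
        self.population_size = int(population_size)
        self.thresholds = tuple(thresholds)
        self.assurance = assurance
        self.seed = seed
        self.info_sample_size = int(info_sample_size)
        self.instability_individuals = instability_individuals

    def draw_coefficients(self, rng_info, rng_draws) -> np.ndarray:
        from .casemix import CaseMixSample, generate_casemix

        if isinstance(self.casemix, CaseMixSample):
            sample = self.casemix
        else:
            sample = generate_casemix(self.casemix, self.info_sample_size, rng_info)
        info = unit_information(
            self.reference.coefficients, sample.X,
            basis=("intercept",) + tuple(sample.columns),
        )
        self.info_ = info
        if self.prior is None:
            return sample_unpenalized_posterior(
                self.reference.coefficients, info, self.n, self.n_draws, rng_draws
            )
        return mh_shrinkage_posterior(
            self.reference.coefficients, info, self.n, self.prior, self.mcmc, rng_draws
        )

    def fit(self):
        """Generate the anticipated posterior draws and evaluate them on the
        target population; returns a ``SampleSizeResults``."""
        from .engine import _results_from_coefficient_draws  # avoids an import cycle

        return _results_from_coefficient_draws(self)
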