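"""Reference ("true") models, their calibration, and target populations.

A reference model is a logistic equation
``logit(p_i) = alpha + delta * (beta_1 x_1i + ... + beta_P x_Pi)``
encoding the anticipated relative predictor weights (beta), an overall
slope-scaling factor (delta) controlling discrimination, and an intercept
(alpha) controlling overall risk.  It plays the role of the true model: the
benchmark against which every developed model's degradation is measured.

When only a target c-statistic and prevalence are anticipated,
:func:`calibrate_reference` finds (alpha, delta) by an iterative search —
outer bisection on delta (the achieved c-statistic is nondecreasing in
delta), inner root-finding on alpha so the mean risk matches the target
prevalence at every candidate delta.

Uncertainty in the reference model is expressed as a
:class:`ReferenceMixture`: a finite set of plausible reference models with
selection probabilities, one of which is drawn per simulation replicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .casemix import CaseMixSample, CaseMixSpec, generate_casemix
from .metrics import c_statistic

__all__ = [
    "ReferenceModel",
    "ReferenceMixture",
    "PopulationData",
    "CalibrationError",
    "true_risks",
    "calibrate_reference",
    "simulate_outcomes",
    "draw_reference",
    "make_population",
]


class CalibrationError(RuntimeError):
    """Raised when the iterative (alpha, delta) search cannot reach the
    target c-statistic / prevalence; carries the best state reached."""

    def __init__(self, message, *, alpha=None, delta=None, achieved_c=None, achieved_prev=None):
        super().__init__(message)
        self.alpha = alpha
        self.delta = delta
        self.achieved_c = achieved_c
        self.achieved_prev = achieved_prev


@dataclass(frozen=True)
class ReferenceModel:
    """Logistic reference model with intercept, slope-scaling and weights."""

    alpha: float
    delta: float
    beta: np.ndarray
    predictor_names: tuple[str, ...] = ()

    def __post_init__(self):
        b = np.atleast_1d(np.asarray(self.beta, dtype=float))
        object.__setattr__(self, "beta", b)
        if self.predictor_names:
            names = tuple(self.predictor_names)
            if len(names) != b.size:
                raise ValueError("length(beta) must match predictor_names")
            object.__setattr__(self, "predictor_names", names)
        if not np.isfinite(self.delta) or not np.isfinite(self.alpha):
            raise ValueError("alpha and delta must be finite")
        if not np.isfinite(b).all():
            raise ValueError("beta must be finite")

    @property
    def n_predictors(self) -> int:
        return self.beta.size

    @property
    def coefficients(self) -> np.ndarray:
        """Coefficient vector (intercept first) of the collapsed equation
        logit(p) = alpha + (delta*beta)'x."""
        return np.concatenate([[self.alpha], self.delta * self.beta])

    def _check_columns(self, X, columns):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.beta.size:
            raise ValueError(
                f"X has {X.shape[1]} columns but the reference model expects "
                f"{self.beta.size}"
            )
        if columns is not None and self.predictor_names:
            if tuple(columns) != self.predictor_names:
                raise ValueError(
                    f"predictor columns {list(columns)} do not match the reference "
                    f"model's {list(self.predictor_names)}"
                )
        return X

    def linear_predictor(self, X, columns=None) -> np.ndarray:
        X = self._check_columns(X, columns)
        return self.alpha + self.delta * (X @ self.beta)

    def true_risks(self, X, columns=None) -> np.ndarray:
        """True risks p_i = expit(alpha + delta * X beta)."""
        return expit(self.linear_predictor(X, columns))


def true_risks(model: ReferenceModel, X, columns=None) -> np.ndarray:
    """Functional alias for :meth:`ReferenceModel.true_risks`."""
    return model.true_risks(X, columns)


@dataclass(frozen=True)
class ReferenceMixture:
    """A finite mixture of plausible reference models with selection probs."""

    models: tuple[ReferenceModel, ...]
    probs: tuple[float, ...]

    def __post_init__(self):
        models = tuple(self.models)
        probs = tuple(float(p) for p in self.probs)
        if len(models) < 1 or len(models) != len(probs):
            raise ValueError("need >= 1 model with one selection probability each")
        if any(p < 0 for p in probs):
            raise ValueError("selection probabilities must be nonnegative")
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ValueError(f"selection probabilities must sum to 1, got {sum(probs)}")
        object.__setattr__(self, "models", models)
        object.__setattr__(self, "probs", probs)

    def __len__(self):
        return len(self.models)


def draw_reference(mix: ReferenceMixture, rng) -> ReferenceModel:
    """Draw one reference model with the mixture's selection probabilities."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    idx = rng.choice(len(mix.models), p=np.asarray(mix.probs))
    return mix.models[idx]


@dataclass
class PopulationData:
    """The large target-population dataset: design matrix, true risks and
    simulated outcomes."""

    X: np.ndarray
    p: np.ndarray
    y: np.ndarray
    n_T: int
    columns: list[str] | None = None
    groups: pd.DataFrame | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.p) == len(self.y) == self.X.shape[0] == self.n_T):
            raise ValueError("X, p, y and n_T must have consistent lengths")
        if ((self.p <= 0) | (self.p >= 1)).any():
            raise ValueError("true risks must lie strictly in (0, 1)")
        if not np.isin(self.y, (0.0, 1.0)).all():
            raise ValueError("y must be binary 0/1")

    @property
    def prevalence(self) -> float:
        return float(self.y.mean())


def simulate_outcomes(p, rng) -> np.ndarray:
    """Independent Bernoulli(p_i) outcome draws."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("risks must lie in [0, 1]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return (rng.random(p.size) < p).astype(float)


def make_population(source, model: ReferenceModel, n_T: int, rng) -> PopulationData:
    """Generate the target-population dataset: case-mix rows, true risks from
    the reference model, and one simulated outcome per individual."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if isinstance(source, CaseMixSpec):
        sample = generate_casemix(source, n_T, rng)
    elif isinstance(source, CaseMixSample):
        if n_T > source.n:
            raise ValueError(
                f"population size {n_T} exceeds the finite case-mix pool ({source.n})"
            )
        idx = rng.choice(source.n, size=n_T, replace=False)
        sample = CaseMixSample(
            X=source.X[idx],
            columns=source.columns,
            groups=None if source.groups is None else source.groups.iloc[idx].reset_index(drop=True),
            meta=source.meta,
        )
    else:
        raise TypeError("source must be a CaseMixSpec or CaseMixSample")
    p = model.true_risks(sample.X, columns=sample.columns)
    y = simulate_outcomes(p, rng)
    return PopulationData(
        X=sample.X, p=p, y=y, n_T=n_T, columns=list(sample.columns), groups=sample.groups
    )


def _achieved(eta0, u, delta, target_prev):
    """Solve alpha for the target prevalence at this delta; return the state."""

    def prev_err(alpha):
        return expit(alpha + delta * eta0).mean() - target_prev

    alpha = brentq(prev_err, -40.0, 40.0, xtol=1e-12)
    p = expit(alpha + delta * eta0)
    y = (u < p).astype(float)
    return alpha, p, y, c_statistic(p, y)


def calibrate_reference(
    skeleton: ReferenceModel,
    casemix: CaseMixSample,
    target_c: float,
    target_prev: float,
    *,
    tol: float = 0.002,
    max_iter: int = 50,
    rng=None,
) -> ReferenceModel:
    """Find (alpha, delta) so the model hits a target c-statistic and
    prevalence on a large case-mix sample.

    The skeleton supplies the *relative* weights beta.  The achieved
    c-statistic is computed from the model's true risks against outcomes
    generated by common random numbers (one fixed uniform vector drawn at the
    start), which makes C(delta) smooth and monotone so plain bisection on
    delta converges; alpha is root-found at every candidate delta so the
    prevalence constraint holds throughout.

    Raises :class:`CalibrationError` (reporting the best state) when the
    target discrimination is unattainable for this case mix — e.g. a single
    binary predictor bounds the achievable c-statistic.
    """
    if not 0.5 <= target_c < 1.0:
        raise ValueError("target_c must lie in [0.5, 1)")
    if not 0.0 < target_prev < 1.0:
        raise ValueError("target_prev must lie in (0, 1)")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    u = rng.random(casemix.n)
    eta0 = casemix.X @ skeleton.beta
    if eta0.std() < 1e-12 and target_c > 0.5 + tol:
        raise CalibrationError(
            "case-mix linear predictor is constant: no discrimination attainable",
            achieved_c=0.5,
        )

    def result(alpha, delta, c, prev):
        m = ReferenceModel(
            alpha=alpha, delta=delta, beta=skeleton.beta,
            predictor_names=tuple(casemix.columns) if casemix.columns else (),
        )
        return m

    alpha0, p0, y0, c0 = _achieved(eta0, u, 0.0, target_prev)
    if abs(c0 - target_c) <= tol:
        return result(alpha0, 0.0, c0, p0.mean())

    # expand the upper bracket until the target C is exceeded or C plateaus
    hi, c_hi = 1.0, None
    alpha_hi = None
    prev_c = c0
    for _ in range(60):
        alpha_hi, p_hi, _, c_hi = _achieved(eta0, u, hi, target_prev)
        if c_hi >= target_c:
            break
        if c_hi - prev_c < 1e-6:  # plateau: unattainable discrimination
            raise CalibrationError(
                f"target c-statistic {target_c} unattainable for this case mix "
                f"(best achieved {c_hi:.4f} at delta={hi:g})",
                alpha=alpha_hi, delta=hi, achieved_c=c_hi, achieved_prev=float(p_hi.mean()),
            )
        prev_c = c_hi
        hi *= 2.0
    else:
        raise CalibrationError(
            f"bracket expansion failed (best C {c_hi:.4f})",
            alpha=alpha_hi, delta=hi, achieved_c=c_hi,
        )

    lo = 0.0
    alpha, delta, c, prev = alpha_hi, hi, c_hi, target_prev
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        alpha, p, _, c = _achieved(eta0, u, mid, target_prev)
        delta, prev = mid, float(p.mean())
        if abs(c - target_c) <= tol and abs(prev - target_prev) <= tol:
            return result(alpha, delta, c, prev)
        if c < target_c:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(
        f"calibration did not converge in {max_iter} iterations "
        f"(alpha={alpha:.4f}, delta={delta:.4f}, C={c:.4f}, prevalence={prev:.4f})",
        alpha=alpha, delta=delta, achieved_c=c, achieved_prev=prev,
    )
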