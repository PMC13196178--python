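"""Closed-form starting sample sizes for the simulation sweep.

Before running simulations, a minimum development sample size can be
computed from three criteria for a logistic model with P predictors, an
anticipated outcome prevalence phi and an anticipated Cox–Snell R-squared:

1. expected uniform shrinkage of at least S (default 0.9),
2. small absolute difference between apparent and optimism-adjusted
   R-squared (implied by 1 with S = 0.9), and
3. precise estimation of the overall risk (half-width of the 95% CI for
   phi at most ci_width/2, default total width 0.1... i.e. +/- 0.05).

When only a c-statistic is anticipated rather than an R-squared,
:func:`cstat_to_r2cs` converts C and prevalence to an approximate Cox–Snell
R-squared by simulating a large dataset whose linear predictor is normal
within each outcome class, separated so that the implied C matches.

The resulting n is a *starting* value: the simulation engine then evaluates
stability, calibration and net benefit at and around it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtri
from scipy.stats import norm

from .metrics import _logistic_irls

__all__ = [
    "StarterResult",
    "cstat_to_r2cs",
    "n_slope_criterion",
    "n_risk_precision",
    "minimum_sample_size",
]


@dataclass(frozen=True)
class StarterResult:
    """Combined starting sample size with its per-criterion components."""

    n: int
    n_shrinkage: int
    n_risk: int
    expected_events: int
    r2_cs: float
    epp: float
    details: dict = field(default_factory=dict)


def cstat_to_r2cs(c: float, prev: float, *, sim_size: int = 1_000_000, seed: int = 0) -> float:
    """Approximate Cox–Snell R-squared implied by a c-statistic and prevalence.

    Simulates one large dataset where the linear predictor is normal with
    unit variance in each outcome class and the class means are separated by
    sqrt(2) * Phi^{-1}(C) — the separation that yields discrimination C —
    then fits a logistic calibration model and converts the likelihood-ratio
    statistic: R2_CS = 1 - exp(-LR_chi2 / n).
    """
    if not 0.5 < c < 1.0:
        raise ValueError("c must lie in (0.5, 1)")
    if not 0.0 < prev < 1.0:
        raise ValueError("prev must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    mu = math.sqrt(2.0) * ndtri(c)
    n1 = int(round(sim_size * prev))
    n0 = sim_size - n1
    lp = np.concatenate([rng.normal(0.0, 1.0, n0), rng.normal(mu, 1.0, n1)])
    y = np.concatenate([np.zeros(n0), np.ones(n1)])
    X = np.column_stack([np.ones(sim_size), lp])
    beta = _logistic_irls(X, y)
    eta = X @ beta
    llf = float(y @ eta - np.logaddexp(0.0, eta).sum())
    ybar = y.mean()
    llnull = sim_size * (ybar * math.log(ybar) + (1 - ybar) * math.log(1 - ybar))
    lr = 2.0 * (llf - llnull)
    return float(1.0 - math.exp(-lr / sim_size))


def n_slope_criterion(n_predictors: int, r2_cs: float, shrinkage: float = 0.9) -> int:
    """Sample size for an expected uniform shrinkage factor of at least
    ``shrinkage``: n = P / ((S - 1) * ln(1 - R2_CS / S))."""
    if n_predictors < 1:
        raise ValueError("n_predictors must be >= 1")
    if not 0.0 < shrinkage < 1.0:
        raise ValueError("shrinkage must lie in (0, 1)")
    if not 0.0 < r2_cs < 1.0:
        raise ValueError("r2_cs must lie in (0, 1)")
    if r2_cs >= shrinkage:
        raise ValueError(
            f"r2_cs ({r2_cs:g}) must be below the shrinkage target ({shrinkage:g}); "
            "the formula's log argument would be nonpositive"
        )
    n = n_predictors / ((shrinkage - 1.0) * math.log(1.0 - r2_cs / shrinkage))
    return int(math.ceil(n))


def n_risk_precision(prev: float, ci_width: float = 0.1) -> int:
    """Sample size so the 95% CI for the overall risk has total width at most
    ``ci_width``: n = 1.96^2 * phi(1-phi) / (width/2)^2."""
    if not 0.0 < prev < 1.0:
        raise ValueError("prev must lie in (0, 1)")
    if not 0.0 < ci_width < 1.0:
        raise ValueError("ci_width must lie in (0, 1)")
    z = norm.ppf(0.975)
    half = ci_width / 2.0
    return int(math.ceil(z * z * prev * (1.0 - prev) / (half * half)))


def minimum_sample_size(
    n_predictors: int,
    prev: float,
    *,
    r2_cs: float | None = None,
    c: float | None = None,
    shrinkage: float = 0.9,
    ci_width: float = 0.1,
    sim_size: int = 1_000_000,
    seed: int = 0,
) -> StarterResult:
    """Combined minimum starting n: the maximum over the criteria.

    Provide either an anticipated Cox–Snell R-squared (``r2_cs``) or an
    anticipated c-statistic (``c``, converted via :func:`cstat_to_r2cs`).
    """
    if (r2_cs is None) == (c is None):
        raise ValueError("provide exactly one of r2_cs or c")
    details: dict = {}
    if r2_cs is None:
        r2_cs = cstat_to_r2cs(c, prev, sim_size=sim_size, seed=seed)
        details["c"] = c
        details["r2_from_c_simulation"] = True
    n_shrink = n_slope_criterion(n_predictors, r2_cs, shrinkage)
    n_risk = n_risk_precision(prev, ci_width)
    n = max(n_shrink, n_risk)
    events = int(round(n * prev))
    return StarterResult(
        n=n,
        n_shrinkage=n_shrink,
        n_risk=n_risk,
        expected_events=events,
        r2_cs=float(r2_cs),
        epp=events / n_predictors,
        details=details,
    )
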