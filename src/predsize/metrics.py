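"""Performance, degradation, instability and value-of-information metrics.

All measures compare a model's estimated risks against observed outcomes
and/or against the *true* risks of the reference model in the target
population: discrimination (c-statistic), calibration (slope,
calibration-in-the-large, flexible curve), prediction error (MAPE/RMSPE),
explained variation (Cox–Snell and Nagelkerke R²), clinical utility (net
benefit at a risk threshold, its value-of-sample-information summaries), and
per-individual instability (interval width, effective sample size,
misclassification probability).

Degradation is always (developed-model performance) − (true-model
performance), both evaluated in the same target population; the true model
has calibration slope 1 by construction, so slope degradation is slope − 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata

__all__ = [
    "ReplicateMetrics",
    "PredictionMatrix",
    "NetBenefitResult",
    "c_statistic",
    "calibration",
    "calibration_curve",
    "prediction_error",
    "net_benefit",
    "treat_all_net_benefit",
    "value_of_information",
    "winner_net_benefit",
    "misclassification_probability",
    "instability_summaries",
    "r2_measures",
    "subgroup_metrics",
    "evaluate_predictions",
]

LOGIT_EPS = 1e-8  # clipping before logit: tree models emit exact 0/1 risks
_ESS_CAP = 1e12


def _clipped_logit(p: np.ndarray, eps: float = LOGIT_EPS) -> np.ndarray:
    p = np.clip(p, eps, 1.0 - eps)
    return np.log(p / (1.0 - p))


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcomes must be binary 0/1")
    return y


def c_statistic(p_hat, y) -> float:
    """Rank-based concordance (AUROC), ties counted one half.

    Probability that a randomly chosen event individual receives a higher
    estimated risk than a randomly chosen non-event individual.  Midranks
    make the ½-tie correction exact.
    """
    y = _check_binary(y)
    p_hat = np.asarray(p_hat, dtype=float)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("c-statistic undefined: only one outcome class present")
    r = rankdata(p_hat)
    return float((r[y == 1.0].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _logistic_irls(X, y, offset=None, max_iter=50, tol=1e-9):
    """Newton-IRLS for a small logistic regression with optional offset.

    Used for the repeated 1–2 parameter calibration fits; cross-checked
    against statsmodels GLM in the test suite.
    """
    n, k = X.shape
    beta = np.zeros(k)
    off = 0.0 if offset is None else offset
    for _ in range(max_iter):
        eta = X @ beta + off
        mu = expit(eta)
        w = mu * (1.0 - mu) + 1e-12
        grad = X.T @ (y - mu)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    return beta


def calibration(p_hat, y, *, eps: float = LOGIT_EPS, return_curve: bool = False):
    """Calibration slope and calibration-in-the-large of estimated risks.

    The slope is from a logistic regression of ``y`` on logit(p_hat); the
    intercept (calibration-in-the-large) is re-estimated with the slope fixed
    at 1, i.e. with logit(p_hat) as an offset.  Ideal values are 1 and 0.

    Degenerate predictions (logit variance below tolerance, e.g. a constant
    model) are recorded as slope 0 with ``flagged=True`` rather than an
    error, matching the convention that a fully shrunken model carries no
    calibration information.

    Returns ``(slope, intercept, curve)`` where ``curve`` is ``None`` unless
    ``return_curve`` is set.
    """
    y = _check_binary(y)
    if y.sum() in (0, y.size):
        raise ValueError("calibration undefined: only one outcome class present")
    lp = _clipped_logit(np.asarray(p_hat, dtype=float), eps)
    flagged = False
    if lp.var() < 1e-12:
        slope = 0.0
        flagged = True
    else:
        design = np.column_stack([np.ones_like(lp), lp])
        slope = float(_logistic_irls(design, y)[1])
    intercept = float(_logistic_irls(np.ones((lp.size, 1)), y, offset=lp)[0])
    curve = calibration_curve(p_hat, y) if return_curve else None
    return slope, intercept, curve, flagged


def _rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted cubic spline basis (Harrell's parameterisation)."""
    k = knots
    t_last, t_pen = k[-1], k[-2]
    scale = (t_last - k[0]) ** 2

    def pos3(u):
        return np.clip(u, 0.0, None) ** 3

    cols = [x]
    for j in range(len(k) - 2):
        term = (
            pos3(x - k[j])
            - pos3(x - t_pen) * (t_last - k[j]) / (t_last - t_pen)
            + pos3(x - t_last) * (t_pen - k[j]) / (t_last - t_pen)
        )
        cols.append(term / scale)
    return np.column_stack(cols)


def calibration_curve(p_hat, y, n_grid: int = 100, n_knots: int = 4):
    """Flexible observed-vs-predicted curve: logistic regression of ``y`` on a
    restricted cubic spline (4 knots by default) of logit(p_hat).

    Returns ``(grid_p_hat, observed_risk)`` arrays of length ``n_grid``.
    """
    y = _check_binary(y)
    lp = _clipped_logit(np.asarray(p_hat, dtype=float))
    qs = np.linspace(0.05, 0.95, n_knots)
    knots = np.quantile(lp, qs)
    if np.unique(knots).size < n_knots:  # near-constant predictions
        grid = np.quantile(lp, np.linspace(0.01, 0.99, n_grid))
        return expit(grid), np.full(n_grid, y.mean())
    B = _rcs_basis(lp, knots)
    design = np.column_stack([np.ones(lp.size), B])
    beta = _logistic_irls(design, y)
    grid = np.quantile(lp, np.linspace(0.01, 0.99, n_grid))
    Bg = _rcs_basis(grid, knots)
    obs = expit(np.column_stack([np.ones(n_grid), Bg]) @ beta)
    return expit(grid), obs


def prediction_error(p_hat, p_true) -> tuple[float, float]:
    """Mean absolute (MAPE) and root mean squared (RMSPE) prediction error
    of estimated risks against the true-model risks."""
    p_hat = np.asarray(p_hat, dtype=float)
    p_true = np.asarray(p_true, dtype=float)
    if p_hat.shape != p_true.shape:
        raise ValueError("p_hat and p_true must have the same length")
    diff = p_hat - p_true
    return float(np.abs(diff).mean()), float(np.sqrt((diff**2).mean()))


def net_benefit(classify, y, threshold: float) -> float:
    """Net benefit TP/n − FP/n × t/(1−t) of a classification rule.

    ``classify`` is either a boolean/0-1 vector of treat decisions or a risk
    vector classified by ``p_hat >= threshold``.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    y = _check_binary(y)
    c = np.asarray(classify)
    if c.dtype != bool and not np.isin(np.unique(c), (0.0, 1.0)).all():
        c = c >= threshold
    c = c.astype(bool)
    n = y.size
    tp = float((c & (y == 1.0)).sum()) / n
    fp = float((c & (y == 0.0)).sum()) / n
    return tp - fp * threshold / (1.0 - threshold)


def treat_all_net_benefit(prevalence: float, threshold: float) -> float:
    """Closed-form treat-all net benefit φ − (1−φ)·t/(1−t)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    return prevalence - (1.0 - prevalence) * threshold / (1.0 - threshold)


@dataclass
class NetBenefitResult:
    """Net benefit decomposition at one risk threshold."""

    threshold: float
    nb_true: float  # NB_max: true-model (reference) net benefit
    nb_model: float
    nb_treat_all: float
    nb_treat_none: float = 0.0
    nb_winner: float | None = None

    @property
    def evsi_degradation(self) -> float:
        return self.nb_model - self.nb_true

    @property
    def rvsi(self) -> float:
        ed, rv = value_of_information(self.nb_model, self.nb_true)
        return rv


def value_of_information(nb_model: float, nb_max: float):
    """EVSI degradation (NB_model − NB_max) and RVSI = 100·NB_model/NB_max.

    RVSI is undefined (NaN, with a warning) when NB_max ≤ 0.
    """
    degradation = nb_model - nb_max
    if nb_max <= 0:
        warnings.warn("NB_max <= 0: RVSI undefined", RuntimeWarning, stacklevel=2)
        return degradation, float("nan")
    return degradation, 100.0 * nb_model / nb_max


def winner_net_benefit(p_hat_dev, y_dev, p_hat_pop, y_pop, threshold: float) -> float:
    """Population net benefit of the strategy that wins in the development
    sample, among {developed model, treat all, treat none}.

    Ties break by precedence model > treat all > treat none.
    """
    y_dev = _check_binary(y_dev)
    candidates = [
        ("model", net_benefit(np.asarray(p_hat_dev) >= threshold, y_dev, threshold)),
        ("treat_all", net_benefit(np.ones(y_dev.size, bool), y_dev, threshold)),
        ("treat_none", 0.0),
    ]
    winner = max(candidates, key=lambda kv: kv[1])[0]  # stable: first max wins ties
    if winner == "model":
        return net_benefit(np.asarray(p_hat_pop) >= threshold, y_pop, threshold)
    if winner == "treat_all":
        return net_benefit(np.ones(np.asarray(y_pop).size, bool), y_pop, threshold)
    return 0.0


@dataclass
class PredictionMatrix:
    """Per-individual posterior draws of estimated risk.

    ``values`` has one row per tracked individual and one column per
    simulated model; ``truth`` holds the aligned true risks.
    """

    values: np.ndarray
    truth: np.ndarray
    ids: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.truth = np.asarray(self.truth, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.truth.shape[0]:
            raise ValueError("values must be (n_individuals, n_sims) aligned with truth")
        if ((self.values < 0) | (self.values > 1)).any():
            raise ValueError("prediction matrix entries must lie in [0, 1]")
        if self.ids is None:
            self.ids = np.arange(self.values.shape[0])

    @property
    def n_sims(self) -> int:
        return self.values.shape[1]


def misclassification_probability(pm: PredictionMatrix, threshold: float) -> np.ndarray:
    """Per-individual probability that a simulated model classifies them on
    the opposite side of the threshold from their true risk.

    Values equal to the threshold count as "at or above".
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    true_side = pm.truth >= threshold
    draw_side = pm.values >= threshold
    return (draw_side != true_side[:, None]).mean(axis=1)


def instability_summaries(pm: PredictionMatrix) -> pd.DataFrame:
    """Per-individual 95% interval width and effective sample size.

    Width is the 97.5th − 2.5th percentile of the individual's risk draws.
    The effective sample size treats the draws as estimates of a binomial
    proportion: ESS = p̄(1−p̄)/var(draws); zero-variance draws are capped and
    flagged.
    """
    lo, hi = np.percentile(pm.values, [2.5, 97.5], axis=1)
    width = hi - lo
    pbar = pm.values.mean(axis=1)
    var = pm.values.var(axis=1)
    capped = var < 1e-12
    ess = np.where(capped, _ESS_CAP, pbar * (1.0 - pbar) / np.where(capped, 1.0, var))
    return pd.DataFrame(
        {
            "id": pm.ids,
            "true_risk": pm.truth,
            "mean_p_hat": pbar,
            "interval_width": width,
            "ess": ess,
            "ess_capped": capped,
        }
    )


def r2_measures(p_hat, y) -> tuple[float, float]:
    """Cox–Snell and Nagelkerke R² of estimated risks against outcomes.

    Computed from Bernoulli log-likelihoods of ``p_hat`` versus the
    outcome-prevalence null; Nagelkerke rescales Cox–Snell by its maximum
    attainable value at the observed prevalence.
    """
    y = _check_binary(y)
    p = np.clip(np.asarray(p_hat, dtype=float), LOGIT_EPS, 1 - LOGIT_EPS)
    n = y.size
    ll_model = float(y @ np.log(p) + (1.0 - y) @ np.log(1.0 - p))
    phi = y.mean()
    if phi in (0.0, 1.0):
        raise ValueError("R2 undefined: only one outcome class present")
    ll_null = n * (phi * np.log(phi) + (1.0 - phi) * np.log(1.0 - phi))
    r2_cs = 1.0 - np.exp(-2.0 * (ll_model - ll_null) / n)
    max_r2 = 1.0 - np.exp(2.0 * ll_null / n)
    return float(r2_cs), float(r2_cs / max_r2)


@dataclass
class ReplicateMetrics:
    """All per-replicate performance and degradation values.

    Net-benefit quantities are keyed by threshold.  ``degradations`` holds
    (developed − true) values for each base metric.
    """

    c: float
    cal_slope: float
    cal_intercept: float
    mape: float
    rmspe: float
    r2_cs: float
    r2_nagelkerke: float
    nb_model: dict[float, float] = field(default_factory=dict)
    nb_max: dict[float, float] = field(default_factory=dict)
    nb_winner: dict[float, float] = field(default_factory=dict)
    rvsi: dict[float, float] = field(default_factory=dict)
    degradations: dict[str, float] = field(default_factory=dict)
    flags: dict[str, bool] = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "c": self.c,
            "cal_slope": self.cal_slope,
            "cal_intercept": self.cal_intercept,
            "mape": self.mape,
            "rmspe": self.rmspe,
            "r2_cs": self.r2_cs,
            "r2_nagelkerke": self.r2_nagelkerke,
        }
        for t in self.nb_model:
            row[f"nb_model@{t:g}"] = self.nb_model[t]
            row[f"nb_max@{t:g}"] = self.nb_max[t]
            row[f"rvsi@{t:g}"] = self.rvsi[t]
            if t in self.nb_winner:
                row[f"nb_winner@{t:g}"] = self.nb_winner[t]
        for k, v in self.degradations.items():
            row[f"degradation_{k}"] = v
        for k, v in self.flags.items():
            row[f"flag_{k}"] = bool(v)
        return row


def evaluate_predictions(
    p_hat,
    population,
    *,
    c_true: float,
    thresholds=(0.5,),
    dev=None,
    p_hat_dev=None,
) -> ReplicateMetrics:
    """Compute the full set of replicate metrics for one fitted model's
    population predictions.

    ``population`` must expose ``p`` (true risks) and ``y`` (simulated
    outcomes).  ``c_true`` is the true model's c-statistic in the same
    population (its calibration slope is 1 and its MAPE 0 by construction).
    When the development data and its predictions are supplied, the
    winner-strategy net benefit is also computed.
    """
    p_hat = np.asarray(p_hat, dtype=float)
    y, p_true = population.y, population.p
    c = c_statistic(p_hat, y)
    slope, intercept, _, flagged = calibration(p_hat, y)
    mape, rmspe = prediction_error(p_hat, p_true)
    r2_cs, r2_n = r2_measures(p_hat, y)
    m = ReplicateMetrics(
        c=c,
        cal_slope=slope,
        cal_intercept=intercept,
        mape=mape,
        rmspe=rmspe,
        r2_cs=r2_cs,
        r2_nagelkerke=r2_n,
    )
    m.flags["constant_predictions"] = flagged
    m.degradations["c"] = c - c_true
    m.degradations["cal_slope"] = slope - 1.0
    for t in thresholds:
        nb_m = net_benefit(p_hat, y, t)
        nb_t = net_benefit(p_true, y, t)
        m.nb_model[t] = nb_m
        m.nb_max[t] = nb_t
        _, rv = value_of_information(nb_m, nb_t)
        m.rvsi[t] = rv
        m.degradations[f"nb@{t:g}"] = nb_m - nb_t
        if dev is not None and p_hat_dev is not None:
            m.nb_winner[t] = winner_net_benefit(p_hat_dev, dev.y, p_hat, y, t)
    return m


def subgroup_metrics(
    p_hat, population, groups, group_column: str, *, thresholds=(0.5,), c_true=None
) -> dict:
    """Recompute the replicate metrics within each subgroup label.

    Groups whose outcomes are single-class yield a flagged partial result
    (prediction error only).  ``c_true`` may be a per-group dict; when absent
    the true model's subgroup c-statistic is computed from the population.
    """
    labels = np.asarray(groups[group_column])
    out: dict = {}
    for lab in pd.unique(labels):
        idx = labels == lab
        if idx.sum() == 0:
            raise ValueError(f"subgroup {lab!r} has size 0")
        sub = _SubPop(population.p[idx], population.y[idx])
        ph = np.asarray(p_hat)[idx]
        if sub.y.sum() in (0, sub.y.size):
            mape, rmspe = prediction_error(ph, sub.p)
            m = ReplicateMetrics(
                c=float("nan"),
                cal_slope=float("nan"),
                cal_intercept=float("nan"),
                mape=mape,
                rmspe=rmspe,
                r2_cs=float("nan"),
                r2_nagelkerke=float("nan"),
            )
            m.flags["single_class_subgroup"] = True
            out[lab] = m
            continue
        ct = c_true[lab] if isinstance(c_true, dict) else c_statistic(sub.p, sub.y)
        out[lab] = evaluate_predictions(ph, sub, c_true=ct, thresholds=thresholds)
    return out


@dataclass
class _SubPop:
    p: np.ndarray
    y: np.ndarray
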