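"""Simulation engine: anticipate model performance at candidate sample sizes.

The central object is :class:`SampleSizeSimulation`, a model-style design
object: it holds the case mix, the reference model (or mixture), the chosen
development strategy and a candidate development sample size ``n``.  Its
``fit()`` runs the replicate loop — generate a development dataset, fit the
strategy, predict on the fixed target population, score performance and
degradation — ``n_sims`` times, and returns a :class:`SampleSizeResults`
carrying the per-replicate draws, their posterior summaries (mean, 95%
range, Monte-Carlo standard error) and assurance probabilities, with a
``summary()`` table and CSV/JSON report writers.

``sweep_sample_sizes`` repeats the fit across a grid of sample sizes and
reports the smallest grid value meeting user criteria (no interpolation:
metric–n curves are noisy and candidate sizes are discrete in practice).

Randomness is organised as one master seed spawning named substreams
(population, calibration, one per replicate, each split into development /
strategy / outcome / mixture-draw streams), so swapping the strategy leaves
the simulated data unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .casemix import CaseMixSample, CaseMixSpec, Variable, draw_development, load_casemix
from .fisher import MCMCConfig, PriorSpec
from .metrics import (
    PredictionMatrix,
    c_statistic,
    evaluate_predictions,
    instability_summaries,
    misclassification_probability,
    subgroup_metrics,
)
from .refmodel import (
    PopulationData,
    ReferenceMixture,
    ReferenceModel,
    calibrate_reference,
    draw_reference,
    make_population,
    simulate_outcomes,
)
from .strategies import Strategy, make_strategy

__all__ = [
    "AssuranceTarget",
    "Criterion",
    "SimulationConfig",
    "PosteriorSummary",
    "SampleSizeSimulation",
    "SampleSizeResults",
    "SweepResult",
    "run_simulation",
    "summarise",
    "sweep_sample_sizes",
    "parse_config",
    "write_report",
    "summarise_replicates",
]


@dataclass(frozen=True)
class AssuranceTarget:
    """A performance interval whose attainment probability is reported.

    The assurance probability is the fraction of simulated models whose
    metric value lies in [lower, upper] (either bound may be open-ended).
    """

    name: str
    metric: str
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self):
        if self.lower is None and self.upper is None:
            raise ValueError(f"assurance target {self.name!r} needs at least one bound")
        if self.lower is not None and self.upper is not None and self.lower > self.upper:
            raise ValueError(f"assurance target {self.name!r}: lower > upper")

    def satisfied(self, values: np.ndarray) -> np.ndarray:
        ok = np.ones(values.shape, dtype=bool)
        if self.lower is not None:
            ok &= values >= self.lower
        if self.upper is not None:
            ok &= values <= self.upper
        ok &= np.isfinite(values)
        return ok


def default_assurance_targets(thresholds=(0.5,)) -> tuple[AssuranceTarget, ...]:
    """Common targets: slope near 1, RVSI >= 90%, MAPE < 0.05, small
    c-statistic degradation."""
    targets = [
        AssuranceTarget("slope_in_0.9_1.1", "cal_slope", 0.9, 1.1),
        AssuranceTarget("slope_in_0.85_1.15", "cal_slope", 0.85, 1.15),
        AssuranceTarget("mape_below_0.05", "mape", upper=0.05),
        AssuranceTarget("c_degradation_above_-0.025", "degradation_c", lower=-0.025),
    ]
    for t in thresholds:
        targets.append(AssuranceTarget(f"rvsi@{t:g}_at_least_90", f"rvsi@{t:g}", lower=90.0))
    return tuple(targets)


@dataclass(frozen=True)
class Criterion:
    """A sample-size criterion: a bound on a metric's mean, or a minimum
    assurance probability for an interval on that metric."""

    metric: str
    lower: float | None = None
    upper: float | None = None
    min_prob: float | None = None
    max_mean: float | None = None
    min_mean: float | None = None

    def __post_init__(self):
        is_assurance = self.min_prob is not None
        is_mean = self.max_mean is not None or self.min_mean is not None
        if is_assurance == is_mean:
            raise ValueError(
                "a criterion is either an assurance (min_prob with bounds) or a "
                "mean bound (max_mean/min_mean), exactly one"
            )
        if is_assurance and self.lower is None and self.upper is None:
            raise ValueError("assurance criterion needs lower and/or upper bounds")

    def check(self, replicates: pd.DataFrame) -> bool:
        values = replicates[self.metric].to_numpy(dtype=float)
        values = values[np.isfinite(values)]
        if values.size == 0:
            return False
        if self.min_prob is not None:
            tgt = AssuranceTarget("criterion", self.metric, self.lower, self.upper)
            return bool(tgt.satisfied(values).mean() >= self.min_prob)
        mean = values.mean()
        if self.max_mean is not None and mean > self.max_mean:
            return False
        if self.min_mean is not None and mean < self.min_mean:
            return False
        return True

    def describe(self) -> str:
        if self.min_prob is not None:
            lo = "-inf" if self.lower is None else f"{self.lower:g}"
            hi = "inf" if self.upper is None else f"{self.upper:g}"
            return f"P({lo} <= {self.metric} <= {hi}) >= {self.min_prob:g}"
        if self.max_mean is not None:
            return f"mean({self.metric}) <= {self.max_mean:g}"
        return f"mean({self.metric}) >= {self.min_mean:g}"


@dataclass
class SimulationConfig:
    """Full run configuration (parsed from YAML/JSON by :func:`parse_config`)."""

    casemix: CaseMixSpec | CaseMixSample
    reference: ReferenceModel | ReferenceMixture | dict
    strategy: Strategy | str | dict
    n_grid: tuple[int, ...] = (456,)
    n_sims: int = 1000
    population_size: int = 100_000
    thresholds: tuple[float, ...] = (0.5,)
    assurance: tuple[AssuranceTarget, ...] | None = None
    seed: int = 0
    instability_individuals: int | None = 2000
    max_failure_rate: float = 0.2
    compute_subgroups: bool = True

    def __post_init__(self):
        self.n_grid = tuple(int(n) for n in self.n_grid)
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if any(n < 1 for n in self.n_grid) or not self.n_grid:
            raise ValueError("n_grid must contain positive sample sizes")
        if self.assurance is None:
            self.assurance = default_assurance_targets(self.thresholds)


@dataclass
class PosteriorSummary:
    """Posterior summary of one metric across the simulated models."""

    metric: str
    mean: float
    q025: float
    q975: float
    mc_se: float
    n_draws: int
    assurance: dict[str, float] = field(default_factory=dict)
    flagged: bool = False


def summarise(values, targets: tuple[AssuranceTarget, ...] = (), metric: str = "") -> PosteriorSummary:
    """Mean, empirical 2.5/97.5 percentiles, assurance probabilities and the
    Monte-Carlo standard error of the mean (sd/sqrt(n_sims)).

    A single draw leaves the MC error undefined (NaN, flagged).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return PosteriorSummary(metric, np.nan, np.nan, np.nan, np.nan, 0, {}, True)
    q025, q975 = np.percentile(v, [2.5, 97.5])
    mc_se = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan")
    assurance = {t.name: float(t.satisfied(v).mean()) for t in targets if t.metric == metric}
    return PosteriorSummary(
        metric=metric, mean=float(v.mean()), q025=float(q025), q975=float(q975),
        mc_se=mc_se, n_draws=int(v.size), assurance=assurance, flagged=v.size <= 1,
    )


_SUMMARY_METRICS_ORDER = [
    "mape", "rmspe", "cal_slope", "cal_intercept", "c", "r2_cs", "r2_nagelkerke",
]


class SampleSizeResults:
    """Results of one simulated sample-size evaluation.

    Attributes
    ----------
    replicates : pandas.DataFrame
        One row per simulated model with every metric, degradation and flag.
    prediction_matrix : PredictionMatrix
        Risk draws for the tracked population individuals.
    population : PopulationData
        The fixed target-population dataset.
    """

    def __init__(
        self,
        *,
        replicates: pd.DataFrame,
        prediction_matrix: PredictionMatrix | None,
        population: PopulationData,
        reference,
        strategy_name: str,
        n: int,
        thresholds,
        assurance,
        seed,
        subgroup_replicates: pd.DataFrame | None = None,
        meta: dict | None = None,
    ):
        self.replicates = replicates
        self.prediction_matrix = prediction_matrix
        self.population = population
        self.reference = reference
        self.strategy_name = strategy_name
        self.n = n
        self.thresholds = tuple(thresholds)
        self.assurance_targets = tuple(assurance)
        self.seed = seed
        self.subgroup_replicates = subgroup_replicates
        self.meta = meta or {}

    # -- summaries -----------------------------------------------------
    @property
    def n_sims(self) -> int:
        return len(self.replicates)

    @property
    def n_failed(self) -> int:
        if "flag_failed" not in self.replicates:
            return 0
        return int(self.replicates["flag_failed"].sum())

    def metric_columns(self) -> list[str]:
        skip = ("replicate", "strategy", "n")
        return [
            c for c in self.replicates.columns
            if c not in skip and not c.startswith("flag_")
            and np.issubdtype(self.replicates[c].dtype, np.number)
        ]

    @property
    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for col in self.metric_columns():
            s = summarise(self.replicates[col], self.assurance_targets, metric=col)
            rows.append(
                {"metric": col, "mean": s.mean, "q2.5": s.q025, "q97.5": s.q975,
                 "mc_se": s.mc_se, "n_draws": s.n_draws}
            )
        return pd.DataFrame(rows).set_index("metric")

    @property
    def assurance(self) -> pd.DataFrame:
        rows = []
        for t in self.assurance_targets:
            if t.metric not in self.replicates:
                continue
            v = self.replicates[t.metric].to_numpy(dtype=float)
            v = v[np.isfinite(v)]
            prob = float(t.satisfied(v).mean()) if v.size else float("nan")
            rows.append({"target": t.name, "metric": t.metric, "probability": prob})
        return pd.DataFrame(rows).set_index("target")

    def assurance_probability(self, name: str) -> float:
        return float(self.assurance.loc[name, "probability"])

    @property
    def instability(self) -> pd.DataFrame | None:
        if self.prediction_matrix is None:
            return None
        tab = instability_summaries(self.prediction_matrix)
        for t in self.thresholds:
            tab[f"p_misclassification@{t:g}"] = misclassification_probability(
                self.prediction_matrix, t
            )
        return tab

    def summary(self) -> str:
        """Human-readable report in the spirit of a regression summary."""
        sf = self.summary_frame
        lines = [
            "Sample-size simulation results",
            "=" * 66,
            f"strategy: {self.strategy_name:<28} development n: {self.n}",
            f"replicates: {self.n_sims:<26} failed/flagged: {self.n_failed}",
            f"population size: {self.population.n_T:<21} prevalence: "
            f"{self.population.prevalence:.3f}",
            "-" * 66,
            f"{'metric':<24}{'mean':>10}{'2.5%':>10}{'97.5%':>10}{'MC-SE':>10}",
        ]
        order = [m for m in _SUMMARY_METRICS_ORDER if m in sf.index]
        order += [m for m in sf.index if m not in order]
        for m in order:
            r = sf.loc[m]
            lines.append(
                f"{m:<24}{r['mean']:>10.4f}{r['q2.5']:>10.4f}{r['q97.5']:>10.4f}"
                f"{r['mc_se']:>10.4f}"
            )
        lines.append("-" * 66)
        lines.append("assurance probabilities:")
        for name, row in self.assurance.iterrows():
            lines.append(f"  P[{name}] = {row['probability']:.3f}")
        return "\n".join(lines)

    # -- export --------------------------------------------------------
    def to_long_frame(self) -> pd.DataFrame:
        """Long-format per-replicate metrics: replicate, strategy, n, metric,
        value, subgroup (the raw material for summary tables and plots)."""
        wide = self.replicates[["replicate"] + self.metric_columns()].copy()
        long = wide.melt(id_vars="replicate", var_name="metric", value_name="value")
        long.insert(1, "strategy", self.strategy_name)
        long.insert(2, "n", self.n)
        long["subgroup"] = "overall"
        if self.subgroup_replicates is not None:
            long = pd.concat([long, self.subgroup_replicates], ignore_index=True)
        return long

    def save(self, directory) -> dict[str, Path]:
        return write_report(self, directory)


def _merge_flags(row: dict, details: dict) -> None:
    for k, v in details.items():
        if k.startswith("flag_"):
            row[k] = bool(v)


class SampleSizeSimulation:
    """Design object for one simulated sample-size evaluation.

    Parameters
    ----------
    casemix : CaseMixSpec or CaseMixSample
        Source of predictor rows for both the target population and the
        development samples (a finite sample is drawn without replacement).
    reference : ReferenceModel, ReferenceMixture or dict
        The true model.  A dict of calibration targets
        (``relative_beta``/``target_c``/``target_prev``) is calibrated on a
        large case-mix draw before the replicate loop.
    strategy : Strategy, str or dict
        Development strategy (see ``predsize.strategies.STRATEGY_NAMES``).
    n : int
        Development sample size under evaluation.
    """

    def __init__(
        self,
        casemix,
        reference,
        strategy,
        n: int,
        *,
        n_sims: int = 1000,
        population_size: int = 100_000,
        thresholds=(0.5,),
        assurance=None,
        seed: int = 0,
        instability_individuals: int | None = 2000,
        max_failure_rate: float = 0.2,
        compute_subgroups: bool = True,
        calibration_sample_size: int = 100_000,
    ):
        self.casemix = casemix
        self.reference = reference
        self.strategy = self._resolve_strategy(strategy)
        self.n = int(n)
        self.n_sims = int(n_sims)
        self.population_size = int(population_size)
        self.thresholds = tuple(thresholds)
        self.assurance = (
            tuple(assurance) if assurance is not None
            else default_assurance_targets(self.thresholds)
        )
        self.seed = seed
        self.instability_individuals = instability_individuals
        self.max_failure_rate = max_failure_rate
        self.compute_subgroups = compute_subgroups
        self.calibration_sample_size = calibration_sample_size

    @staticmethod
    def _resolve_strategy(strategy) -> Strategy:
        if isinstance(strategy, Strategy):
            return strategy
        if isinstance(strategy, str):
            return make_strategy(strategy)
        if isinstance(strategy, dict):
            kw = dict(strategy)
            return make_strategy(kw.pop("name"), **kw)
        raise TypeError("strategy must be a Strategy, name, or config dict")

    @classmethod
    def from_config(cls, cfg: SimulationConfig | str | Path, n: int | None = None):
        if not isinstance(cfg, SimulationConfig):
            cfg = parse_config(cfg)
        if n is None:
            if len(cfg.n_grid) != 1:
                raise ValueError(
                    "config has several sample sizes; pass n= or use sweep_sample_sizes"
                )
            n = cfg.n_grid[0]
        return cls(
            cfg.casemix, cfg.reference, cfg.strategy, n,
            n_sims=cfg.n_sims, population_size=cfg.population_size,
            thresholds=cfg.thresholds, assurance=cfg.assurance, seed=cfg.seed,
            instability_individuals=cfg.instability_individuals,
            max_failure_rate=cfg.max_failure_rate,
            compute_subgroups=cfg.compute_subgroups,
        )

    # -- reference resolution ------------------------------------------
    def _resolve_reference(self, rng_cal):
        ref = self.reference
        if isinstance(ref, dict):
            ref = _calibrate_from_spec(
                ref, self.casemix, rng_cal, self.calibration_sample_size
            )
        if isinstance(ref, ReferenceMixture) and len(ref) == 1:
            ref = ref.models[0]  # collapse so mixture-of-one matches exactly
        return ref

    def fit(self) -> SampleSizeResults:
        """Run the replicate loop and summarise the posterior draws."""
        ss = np.random.SeedSequence(self.seed)
        ss_pop, ss_cal, ss_reps, ss_extra = ss.spawn(4)
        rng_cal = np.random.default_rng(ss_cal)
        ref = self._resolve_reference(rng_cal)
        mixture = isinstance(ref, ReferenceMixture)

        rng_pop = np.random.default_rng(ss_pop)
        pop_model = ref.models[int(np.argmax(ref.probs))] if mixture else ref
        population = make_population(self.casemix, pop_model, self.population_size, rng_pop)
        c_true_fixed = None if mixture else c_statistic(population.p, population.y)

        track_idx = _tracked_indices(
            self.population_size, self.instability_individuals, np.random.default_rng(ss_extra)
        )
        pred = (
            None if track_idx is None
            else np.empty((track_idx.size, self.n_sims), dtype=float)
        )

        rep_seeds = ss_reps.spawn(self.n_sims)
        rows: list[dict] = []
        sub_rows: list[dict] = []
        failures = 0
        groups = population.groups if self.compute_subgroups else None

        for r, rep_ss in enumerate(rep_seeds):
            s_dev, s_strat, s_out, s_mix = rep_ss.spawn(4)
            if mixture:
                model_ref = draw_reference(ref, np.random.default_rng(s_mix))
                p = model_ref.true_risks(population.X, columns=population.columns)
                y = simulate_outcomes(p, np.random.default_rng(s_out))
                pop_r = PopulationData(
                    X=population.X, p=p, y=y, n_T=population.n_T,
                    columns=population.columns, groups=population.groups,
                )
                c_true = c_statistic(p, y)
            else:
                model_ref, pop_r, c_true = ref, population, c_true_fixed

            row: dict = {"replicate": r, "flag_failed": False}
            try:
                dev = draw_development(
                    self.casemix, model_ref, self.n, np.random.default_rng(s_dev)
                )
                model = self.strategy(dev, np.random.default_rng(s_strat), reference=model_ref)
                p_hat = np.clip(model.predict_risk(pop_r.X), 0.0, 1.0)
                p_hat_dev = np.clip(model.predict_risk(dev.X), 0.0, 1.0)
            except Exception as err:  # noqa: BLE001 - replicate-level isolation
                failures += 1
                row["flag_failed"] = True
                rows.append(row)
                if pred is not None:
                    pred[:, r] = np.nan
                if failures > self.max_failure_rate * self.n_sims:
                    raise RuntimeError(
                        f"{failures} of {r + 1} replicates failed "
                        f"(> {self.max_failure_rate:.0%} of n_sims); last error: {err!r}"
                    ) from err
                continue

            m = evaluate_predictions(
                p_hat, pop_r, c_true=c_true, thresholds=self.thresholds,
                dev=dev, p_hat_dev=p_hat_dev,
            )
            row.update(m.to_row())
            _merge_flags(row, model.details)
            rows.append(row)
            if pred is not None:
                pred[:, r] = p_hat[track_idx]
            if groups is not None:
                for col in groups.columns:
                    by = subgroup_metrics(
                        p_hat, pop_r, groups, col, thresholds=self.thresholds
                    )
                    for lab, gm in by.items():
                        for metric in ("c", "cal_slope", "mape"):
                            sub_rows.append(
                                {"replicate": r, "strategy": self.strategy.name,
                                 "n": self.n, "metric": metric,
                                 "value": getattr(gm, metric),
                                 "subgroup": f"{col}={lab}"}
                            )

        replicates = pd.DataFrame(rows)
        flag_cols = [c for c in replicates.columns if c.startswith("flag_")]
        replicates[flag_cols] = replicates[flag_cols].fillna(False).astype(bool)
        pm = None
        if pred is not None:
            keep = ~np.isnan(pred).all(axis=0)
            pm = PredictionMatrix(
                values=pred[:, keep], truth=population.p[track_idx], ids=track_idx
            )
        return SampleSizeResults(
            replicates=replicates,
            prediction_matrix=pm,
            population=population,
            reference=ref,
            strategy_name=self.strategy.name,
            n=self.n,
            thresholds=self.thresholds,
            assurance=self.assurance,
            seed=self.seed,
            subgroup_replicates=pd.DataFrame(sub_rows) if sub_rows else None,
            meta={
                "n_sims": self.n_sims,
                "population_size": self.population_size,
                "failures": failures,
                "mixture": mixture,
            },
        )


def _tracked_indices(n_T: int, k: int | None, rng) -> np.ndarray | None:
    if k == 0:
        return None
    if k is None or k >= n_T:
        return np.arange(n_T)
    return np.sort(rng.choice(n_T, size=k, replace=False))


def _calibrate_from_spec(spec: dict, casemix, rng, sample_size: int) -> ReferenceModel:
    """Build a reference model (or mixture) from a config dict."""
    from .casemix import generate_casemix

    if "models" in spec:  # mixture block
        models = []
        probs = []
        for sub in spec["models"]:
            sub = dict(sub)
            probs.append(float(sub.pop("prob")))
            models.append(_calibrate_from_spec(sub, casemix, rng, sample_size))
        return ReferenceMixture(models=tuple(models), probs=tuple(probs))
    if "alpha" in spec and "beta" in spec:
        return ReferenceModel(
            alpha=float(spec["alpha"]),
            delta=float(spec.get("delta", 1.0)),
            beta=np.asarray(spec["beta"], dtype=float),
            predictor_names=tuple(spec.get("predictor_names", ())),
        )
    required = {"relative_beta", "target_c", "target_prev"}
    missing = required - set(spec)
    if missing:
        raise ValueError(f"reference spec missing keys: {sorted(missing)}")
    if isinstance(casemix, CaseMixSample):
        sample = casemix
    else:
        sample = generate_casemix(casemix, sample_size, rng)
    skeleton = ReferenceModel(
        alpha=0.0, delta=1.0, beta=np.asarray(spec["relative_beta"], dtype=float)
    )
    return calibrate_reference(
        skeleton, sample,
        float(spec["target_c"]), float(spec["target_prev"]),
        tol=float(spec.get("tol", 0.002)), rng=rng,
    )


def run_simulation(cfg: SimulationConfig, n: int | None = None) -> SampleSizeResults:
    """Functional wrapper: build the simulation from a config and fit it."""
    return SampleSizeSimulation.from_config(cfg, n=n).fit()


@dataclass
class SweepResult:
    """Outcome of a sample-size sweep over a grid."""

    table: pd.DataFrame
    n_min: int | None
    results: dict[int, SampleSizeResults]
    criteria: tuple[Criterion, ...]

    @property
    def all_met(self) -> bool:
        return self.n_min is not None


def sweep_sample_sizes(cfg: SimulationConfig, criteria) -> SweepResult:
    """Run the simulation at every grid sample size and report the smallest
    one meeting every criterion (``n_min=None`` when none does)."""
    if not cfg.n_grid:
        raise ValueError("empty sample-size grid")
    criteria = tuple(
        c if isinstance(c, Criterion) else Criterion(**c) for c in criteria
    )
    rows = []
    results: dict[int, SampleSizeResults] = {}
    n_min: int | None = None
    for n in sorted(cfg.n_grid):
        res = run_simulation(cfg, n=n)
        results[n] = res
        row: dict = {"n": n}
        met_all = True
        for c in criteria:
            ok = c.check(res.replicates)
            row[c.describe()] = ok
            met_all &= ok
        row["all_criteria_met"] = met_all
        for m in ("mape", "cal_slope", "c"):
            if m in res.replicates:
                row[f"mean_{m}"] = float(np.nanmean(res.replicates[m]))
        rows.append(row)
        if met_all and n_min is None:
            n_min = n
    return SweepResult(
        table=pd.DataFrame(rows).set_index("n"), n_min=n_min,
        results=results, criteria=criteria,
    )


# ----------------------------------------------------------------------
# configuration parsing and report output
# ----------------------------------------------------------------------

_RUN_KEYS = {
    "n", "n_grid", "n_sims", "population_size", "thresholds", "seed",
    "assurance", "instability_individuals", "max_failure_rate", "compute_subgroups",
}
_CASEMIX_KEYS = {"variables", "correlation", "groups", "file", "standard_normal"}


def _parse_variables(entries) -> tuple[Variable, ...]:
    out = []
    for e in entries:
        e = dict(e)
        name = e.pop("name")
        kind = e.pop("type", "continuous")
        out.append(Variable(name=name, kind=kind, **e))
    return tuple(out)


def _parse_casemix(block: dict):
    unknown = set(block) - _CASEMIX_KEYS
    if unknown:
        raise ValueError(f"unknown casemix key(s): {sorted(unknown)}")
    groups = tuple(block.get("groups", ()))
    if "file" in block:
        return load_casemix(block["file"], declared_groups=groups)
    if "standard_normal" in block:
        spec = CaseMixSpec.standard_normal(int(block["standard_normal"]))
        return spec
    corr = block.get("correlation")
    return CaseMixSpec(
        variables=_parse_variables(block["variables"]),
        correlation=None if corr is None else np.asarray(corr, dtype=float),
        fairness_groups=groups,
    )


def _parse_strategy(block) -> Strategy:
    if isinstance(block, str):
        return make_strategy(block)
    kw = dict(block)
    name = kw.pop("name")
    if "prior" in kw and isinstance(kw["prior"], dict):
        kw["prior"] = PriorSpec(**kw["prior"])
    if "mcmc" in kw and isinstance(kw["mcmc"], dict):
        kw["mcmc"] = MCMCConfig(**kw["mcmc"])
    return make_strategy(name, **kw)


def parse_config(path_or_dict) -> SimulationConfig:
    """Parse and validate a YAML/JSON run configuration.

    Top-level blocks: ``casemix``, ``reference``, ``strategy``, ``run``.
    Unknown keys are rejected by name so typos surface immediately.
    """
    if isinstance(path_or_dict, dict):
        raw = path_or_dict
    else:
        text = Path(path_or_dict).read_text()
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    unknown = set(raw) - {"casemix", "reference", "strategy", "run"}
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    for key in ("casemix", "reference", "strategy"):
        if key not in raw:
            raise ValueError(f"config is missing the {key!r} block")
    run = dict(raw.get("run", {}))
    unknown = set(run) - _RUN_KEYS
    if unknown:
        raise ValueError(f"unknown run key(s): {sorted(unknown)}")
    if "n" in run:
        run["n_grid"] = [run.pop("n")]
    assurance = run.pop("assurance", None)
    if assurance is not None:
        assurance = tuple(
            a if isinstance(a, AssuranceTarget) else AssuranceTarget(**a) for a in assurance
        )
    reference = raw["reference"]
    if isinstance(reference, list):
        reference = {"models": reference}
    if "thresholds" in run:
        run["thresholds"] = tuple(float(t) for t in run["thresholds"])
    return SimulationConfig(
        casemix=_parse_casemix(dict(raw["casemix"])),
        reference=reference,
        strategy=_parse_strategy(raw["strategy"]),
        assurance=assurance,
        **run,
    )


def summarise_replicates(
    long_df: pd.DataFrame, assurance: tuple[AssuranceTarget, ...] = ()
) -> pd.DataFrame:
    """Regenerate the summary table from a saved long-format replicate CSV."""
    overall = long_df[long_df["subgroup"] == "overall"]
    rows = []
    for (strategy, n, metric), grp in overall.groupby(["strategy", "n", "metric"]):
        s = summarise(grp["value"], assurance, metric=metric)
        rows.append(
            {"strategy": strategy, "n": n, "metric": metric, "mean": s.mean,
             "q2.5": s.q025, "q97.5": s.q975, "mc_se": s.mc_se}
        )
    return pd.DataFrame(rows)


def write_report(results: SampleSizeResults, directory) -> dict[str, Path]:
    """Write the run outputs: summary table, long-format replicate CSV,
    per-individual instability CSV and a JSON manifest with seeds/versions."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    summary = results.summary_frame.reset_index()
    summary.insert(0, "strategy", results.strategy_name)
    summary.insert(1, "n", results.n)
    paths["summary"] = directory / "summary.csv"
    summary.to_csv(paths["summary"], index=False)

    paths["replicates"] = directory / "replicates.csv"
    results.to_long_frame().to_csv(paths["replicates"], index=False)

    paths["assurance"] = directory / "assurance.csv"
    results.assurance.reset_index().to_csv(paths["assurance"], index=False)

    inst = results.instability
    if inst is not None:
        paths["instability"] = directory / "instability.csv"
        inst.to_csv(paths["instability"], index=False)

    manifest = {
        "package": "predsize",
        "version": __version__,
        "strategy": results.strategy_name,
        "n": results.n,
        "seed": results.seed,
        "thresholds": list(results.thresholds),
        "n_sims": results.meta.get("n_sims"),
        "population_size": results.meta.get("population_size"),
        "failures": results.meta.get("failures"),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    paths["manifest"] = directory / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths


# ----------------------------------------------------------------------
# bridge used by the Fisher-approximation model object
# ----------------------------------------------------------------------

def _results_from_coefficient_draws(approx) -> SampleSizeResults:
    """Evaluate anticipated-posterior coefficient draws on a fresh target
    population; shared results container with the full simulation."""
    from scipy.special import expit

    ss = np.random.SeedSequence(approx.seed)
    ss_pop, ss_info, ss_draws, ss_extra = ss.spawn(4)
    population = make_population(
        approx.casemix, approx.reference, approx.population_size,
        np.random.default_rng(ss_pop),
    )
    c_true = c_statistic(population.p, population.y)
    draws = approx.draw_coefficients(
        np.random.default_rng(ss_info), np.random.default_rng(ss_draws)
    )
    track_idx = _tracked_indices(
        approx.population_size, approx.instability_individuals,
        np.random.default_rng(ss_extra),
    )
    pred = None if track_idx is None else np.empty((track_idx.size, len(draws)))
    X1 = np.column_stack([np.ones(population.n_T), population.X])
    rows = []
    for r, coef in enumerate(draws):
        p_hat = expit(X1 @ coef)
        m = evaluate_predictions(
            p_hat, population, c_true=c_true, thresholds=approx.thresholds
        )
        row = {"replicate": r, "flag_failed": False}
        row.update(m.to_row())
        rows.append(row)
        if pred is not None:
            pred[:, r] = p_hat[track_idx]
    name = (
        "fisher_mvn" if approx.prior is None else f"fisher_bayes_{approx.prior.family}"
    )
    assurance = (
        tuple(approx.assurance) if approx.assurance is not None
        else default_assurance_targets(approx.thresholds)
    )
    pm = None
    if pred is not None:
        pm = PredictionMatrix(values=pred, truth=population.p[track_idx], ids=track_idx)
    return SampleSizeResults(
        replicates=pd.DataFrame(rows),
        prediction_matrix=pm,
        population=population,
        reference=approx.reference,
        strategy_name=name,
        n=approx.n,
        thresholds=approx.thresholds,
        assurance=assurance,
        seed=approx.seed,
        meta={"n_sims": len(draws), "population_size": approx.population_size,
              "failures": 0, "approximation": True},
    )
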