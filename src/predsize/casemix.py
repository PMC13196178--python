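"""Case-mix distributions: the joint distribution of candidate predictors.

The target population of a prediction model is characterised by its *case mix*
— the joint distribution of the candidate predictor values.  This module
defines that distribution either from a generator specification
(:class:`CaseMixSpec`: marginal types with an optional latent-Gaussian
correlation structure) or from an existing delimited file
(:func:`load_casemix`), and draws development samples from it
(:func:`draw_development`).

Predictors may be continuous (standard normal by default), binary, or
categorical with more than two levels (expanded to reference-coded dummy
columns).  Correlated draws use a Gaussian copula: a latent multivariate
normal vector is transformed to the requested marginals, one latent dimension
per declared variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri

__all__ = [
    "Variable",
    "CaseMixSpec",
    "CaseMixSample",
    "DevelopmentData",
    "generate_casemix",
    "load_casemix",
    "save_casemix",
    "draw_development",
]

_VALID_KINDS = ("continuous", "binary", "categorical")


@dataclass(frozen=True)
class Variable:
    """Marginal description of one case-mix variable.

    Parameters
    ----------
    name : str
        Variable name, unique within a spec.
    kind : {"continuous", "binary", "categorical"}
        Marginal type.
    mean, sd : float
        Location and scale for continuous variables (defaults give a
        standardised predictor, mean 0 and sd 1).
    prevalence : float
        P(X = 1) for binary variables; must lie strictly in (0, 1).
    levels, probs : sequence
        Level labels and probabilities for categorical variables.
    """

    name: str
    kind: str = "continuous"
    mean: float = 0.0
    sd: float = 1.0
    prevalence: float | None = None
    levels: tuple = ()
    probs: tuple = ()

    def __post_init__(self):
        if self.kind not in _VALID_KINDS:
            raise ValueError(f"unknown variable kind {self.kind!r} for {self.name!r}")
        if self.kind == "continuous" and self.sd <= 0:
            raise ValueError(f"{self.name!r}: sd must be positive")
        if self.kind == "binary":
            if self.prevalence is None or not 0 < self.prevalence < 1:
                raise ValueError(f"{self.name!r}: binary prevalence must lie in (0, 1)")
        if self.kind == "categorical":
            object.__setattr__(self, "levels", tuple(self.levels))
            object.__setattr__(self, "probs", tuple(float(p) for p in self.probs))
            if len(self.levels) < 2 or len(self.levels) != len(self.probs):
                raise ValueError(f"{self.name!r}: need >=2 levels with matching probs")
            if any(p <= 0 for p in self.probs) or abs(sum(self.probs) - 1) > 1e-9:
                raise ValueError(f"{self.name!r}: level probs must be positive and sum to 1")

    @property
    def columns(self) -> list[str]:
        """Names of the numeric design columns this variable expands to."""
        if self.kind == "categorical":
            return [f"{self.name}_{lvl}" for lvl in self.levels[1:]]
        return [self.name]


@dataclass(frozen=True)
class CaseMixSpec:
    """Generator specification for the joint predictor distribution.

    ``correlation`` (optional) is the latent-Gaussian correlation matrix, one
    row/column per variable in declaration order.  ``fairness_groups`` names
    variables used only for subgroup reporting; they are excluded from the
    design matrix.
    """

    variables: tuple[Variable, ...]
    correlation: np.ndarray | None = None
    fairness_groups: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(self, "fairness_groups", tuple(self.fairness_groups))
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("variable names must be unique")
        unknown = set(self.fairness_groups) - set(names)
        if unknown:
            raise ValueError(f"fairness group(s) not declared as variables: {sorted(unknown)}")
        if self.correlation is not None:
            R = np.asarray(self.correlation, dtype=float)
            k = len(self.variables)
            if R.shape != (k, k):
                raise ValueError(f"correlation matrix must be {k}x{k}, got {R.shape}")
            if not np.allclose(R, R.T, atol=1e-10):
                raise ValueError("correlation matrix must be symmetric")
            if not np.allclose(np.diag(R), 1.0, atol=1e-10):
                raise ValueError("correlation matrix must have unit diagonal")
            w = np.linalg.eigvalsh(R)
            if w.min() < -1e-10:
                raise ValueError(
                    f"correlation matrix is not positive semi-definite "
                    f"(smallest eigenvalue {w.min():.3g})"
                )
            object.__setattr__(self, "correlation", R)

    @classmethod
    def standard_normal(cls, p: int, prefix: str = "x") -> "CaseMixSpec":
        """``p`` independent standardised continuous predictors x1..xp."""
        return cls(tuple(Variable(f"{prefix}{j + 1}") for j in range(p)))

    @property
    def predictor_variables(self) -> tuple[Variable, ...]:
        return tuple(v for v in self.variables if v.name not in self.fairness_groups)

    @property
    def column_names(self) -> list[str]:
        names: list[str] = []
        for v in self.predictor_variables:
            names.extend(v.columns)
        return names


@dataclass
class CaseMixSample:
    """A realised case-mix sample: numeric design matrix plus descriptors.

    ``X`` holds one column per numeric predictor column (categorical
    variables already dummy-coded, no intercept column).  ``groups`` holds
    per-row subgroup labels for fairness reporting, or ``None``.
    """

    X: np.ndarray
    columns: list[str]
    groups: pd.DataFrame | None = None
    meta: tuple[Variable, ...] = ()

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] < 1:
            raise ValueError("X must be a 2-d matrix with n >= 1 rows")
        if self.X.shape[1] != len(self.columns):
            raise ValueError("column count of X does not match column names")
        if np.isnan(self.X).any():
            raise ValueError("case-mix sample contains missing values")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_predictors(self) -> int:
        return self.X.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.columns)
        if self.groups is not None:
            for c in self.groups.columns:
                df[c] = self.groups[c].to_numpy()
        return df


@dataclass
class DevelopmentData:
    """Predictors and simulated outcomes for one development dataset."""

    X: np.ndarray
    y: np.ndarray
    n: int
    columns: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.shape[0] != self.y.shape[0] or self.X.shape[0] != self.n:
            raise ValueError("rows(X), length(y) and n must agree")
        if not np.isin(self.y, (0.0, 1.0)).all():
            raise ValueError("y must be binary 0/1")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_casemix(spec: CaseMixSpec, n: int, seed=None) -> CaseMixSample:
    """Draw ``n`` i.i.d. individuals from a case-mix specification.

    Independent marginals by default; with ``spec.correlation`` set, a latent
    multivariate-normal draw is transformed to the requested marginals
    (Gaussian copula).  Reproducible for a fixed ``seed`` (an int or a
    ``numpy.random.Generator``).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = _as_rng(seed)
    k = len(spec.variables)

    if spec.correlation is None:
        Z = rng.standard_normal((n, k))
    else:
        # eigendecomposition handles PSD-but-singular correlation matrices
        w, V = np.linalg.eigh(spec.correlation)
        L = V * np.sqrt(np.clip(w, 0.0, None))
        Z = rng.standard_normal((n, k)) @ L.T

    cols: list[np.ndarray] = []
    names: list[str] = []
    group_data: dict[str, np.ndarray] = {}
    for j, v in enumerate(spec.variables):
        z = Z[:, j]
        if v.kind == "continuous":
            values = v.mean + v.sd * z
            labels = None
        elif v.kind == "binary":
            # P(Z > ndtri(1 - prev)) = prev, preserving latent ordering
            values = (z > ndtri(1.0 - v.prevalence)).astype(float)
            labels = values
        else:
            edges = ndtri(np.cumsum(v.probs)[:-1])
            idx = np.searchsorted(edges, z)
            labels = np.asarray(v.levels, dtype=object)[idx]
            values = np.column_stack(
                [(idx == lv).astype(float) for lv in range(1, len(v.levels))]
            )
        if v.name in spec.fairness_groups:
            group_data[v.name] = labels if labels is not None else values
            continue
        if v.kind == "categorical":
            cols.extend(values.T)
        else:
            cols.append(values)
        names.extend(v.columns)

    X = np.column_stack(cols) if cols else np.empty((n, 0))
    groups = pd.DataFrame(group_data) if group_data else None
    return CaseMixSample(X=X, columns=names, groups=groups, meta=spec.predictor_variables)


def load_casemix(path, declared_groups: Sequence[str] = ()) -> CaseMixSample:
    """Load a case-mix sample from a delimited file (comma, header row).

    Columns named in ``declared_groups`` are removed from the design matrix
    and stored as subgroup labels.  Missing cells are an error (no
    imputation), reported with their row and column.
    """
    df = pd.read_csv(path)
    declared_groups = list(declared_groups)
    missing_cols = set(declared_groups) - set(df.columns)
    if missing_cols:
        raise ValueError(f"declared group column(s) not in file: {sorted(missing_cols)}")
    if df.isna().any().any():
        mask = df.isna()
        row = int(mask.any(axis=1).idxmax())
        col = mask.loc[row].idxmax()
        raise ValueError(f"missing value at row {row} (0-based), column {col!r}")
    groups = df[declared_groups].copy() if declared_groups else None
    Xdf = df.drop(columns=declared_groups)
    for c in Xdf.columns:
        if not np.issubdtype(Xdf[c].dtype, np.number):
            raise ValueError(
                f"column {c!r} is non-numeric; declare it as a fairness group "
                f"or encode it numerically"
            )
    return CaseMixSample(
        X=Xdf.to_numpy(dtype=float), columns=list(Xdf.columns), groups=groups
    )


def save_casemix(sample: CaseMixSample, path) -> None:
    """Write a case-mix sample back to CSV (numeric content round-trips)."""
    sample.to_dataframe().to_csv(path, index=False)


def draw_development(source, ref, n: int, rng, *, replace: bool = False) -> DevelopmentData:
    """Draw one development dataset of size ``n`` (simulation step: sample
    predictors from the case mix, then outcomes from the reference model).

    ``source`` is a :class:`CaseMixSpec` (fresh rows are generated) or a
    finite :class:`CaseMixSample` (rows sampled without replacement unless
    ``replace=True``).  Outcomes are Bernoulli draws from the reference
    model's true risks.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = _as_rng(rng)
    if isinstance(source, CaseMixSpec):
        sample = generate_casemix(source, n, rng)
        X, columns = sample.X, sample.columns
    elif isinstance(source, CaseMixSample):
        if not replace and n > source.n:
            raise ValueError(
                f"requested n={n} exceeds the finite case-mix pool of {source.n} "
                f"rows (pass replace=True to sample with replacement)"
            )
        idx = rng.choice(source.n, size=n, replace=replace)
        X, columns = source.X[idx], source.columns
    else:
        raise TypeError("source must be a CaseMixSpec or CaseMixSample")
    p = ref.true_risks(X, columns=columns)
    y = (rng.random(n) < p).astype(float)
    return DevelopmentData(X=X, y=y, n=n, columns=list(columns))
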