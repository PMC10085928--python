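"""Bayesian age-at-death estimation from ordinal stage profiles.

The method is a naive-Bayes classifier over 5-year age-at-death classes.
For a reference collection of documented individuals the prior probability
of class :math:`c` is the fraction of reference individuals in that class,

.. math:: P(c) = n_c / N,

and the likelihood of observing stage :math:`k` of variable :math:`v`
given class :math:`c` is the conditional stage frequency in the reference,
optionally additively smoothed,

.. math:: P(s_v = k \\mid c) = (m_{vck} + \\alpha) / (m_{vc\\cdot} + \\alpha K_v),

where :math:`m_{vck}` counts reference individuals of class :math:`c`
scored at stage :math:`k`, :math:`m_{vc\\cdot}` those scored at all, and
:math:`K_v` is the number of stages of the variable.  Scored variables are
treated as conditionally independent given the age class, so the posterior
is the normalised product of the prior with one likelihood factor per
scored variable; missing variables contribute no factor.  When the product
carries zero total mass (a stage combination never co-occurring with any
populated class, possible at :math:`\\alpha = 0`) the outcome is an
explicit *no estimation* rather than a forced guess.  The single-year
point estimate is the posterior expectation of the class central ages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .catalog import AgeClassGrid, VariableCatalog, default_catalog, default_grid
from .records import SkeletalRecord

NO_ESTIMATION = "no_estimation"
ESTIMATED = "estimated"


@dataclass
class ReferenceTable:
    """Per-class counts derived from a reference collection.

    ``class_count[c]`` is the number of reference individuals in age class
    ``c`` (the prior's numerator); ``stage_count[v][c, k]`` the number of
    those individuals scored at stage ``k`` of variable ``v`` (the
    likelihood's numerator).  Individuals missing a variable are excluded
    from that variable's stage counts but still count toward their class.
    """

    grid: AgeClassGrid
    catalog: VariableCatalog
    class_count: np.ndarray
    stage_count: dict[str, np.ndarray]
    population: str = ""
    sex: str = ""

    @property
    def n(self) -> int:
        return int(self.class_count.sum())

    def to_json(self, fp: IO[str] | None = None) -> str:
        payload = {
            "grid": self.grid.to_dict(),
            "catalog": {
                v: {"min_stage": lo, "max_stage": hi}
                for v, (lo, hi) in self.catalog.stage_ranges.items()
            },
            "class_count": self.class_count.tolist(),
            "stage_count": {v: m.tolist() for v, m in self.stage_count.items()},
            "population": self.population,
            "sex": self.sex,
        }
        text = json.dumps(payload, indent=2)
        if fp is not None:
            fp.write(text)
        return text

    @classmethod
    def from_json(cls, source: str | IO[str]) -> "ReferenceTable":
        payload = json.loads(source if isinstance(source, str) else source.read())
        catalog = VariableCatalog(
            stage_ranges={
                v: (int(s["min_stage"]), int(s["max_stage"]))
                for v, s in payload["catalog"].items()
            }
        )
        return cls(
            grid=AgeClassGrid.from_dict(payload["grid"]),
            catalog=catalog,
            class_count=np.asarray(payload["class_count"], dtype=int),
            stage_count={
                v: np.asarray(m, dtype=int) for v, m in payload["stage_count"].items()
            },
            population=payload.get("population", ""),
            sex=payload.get("sex", ""),
        )


def build_reference_table(
    reference: Sequence[SkeletalRecord],
    grid: AgeClassGrid | None = None,
    catalog: VariableCatalog | None = None,
    population: str = "",
    sex: str = "",
) -> ReferenceTable:
    """Count reference individuals per class and per (variable, stage)."""
    if len(reference) == 0:
        raise ValueError("cannot build a reference table from an empty collection")
    grid = grid or default_grid()
    catalog = catalog or default_catalog()
    class_count = np.zeros(grid.n_classes, dtype=int)
    stage_count = {
        v: np.zeros((grid.n_classes, catalog.n_stages(v)), dtype=int) for v in catalog
    }
    for rec in reference:
        c = grid.index_of(rec.age)
        class_count[c] += 1
        for v in catalog:
            s = rec.profile.get(v)
            if s is not None:
                stage_count[v][c, int(s)] += 1
    if not population:
        pops = {r.population for r in reference}
        population = pops.pop() if len(pops) == 1 else "mixed"
    if not sex:
        sexes = {r.sex for r in reference}
        sex = sexes.pop() if len(sexes) == 1 else "pooled"
    return ReferenceTable(grid, catalog, class_count, stage_count, population, sex)


def class_prior(table: ReferenceTable) -> np.ndarray:
    """Prior over age classes: the reference class fractions."""
    n = table.n
    if n <= 0:
        raise ValueError("reference table is empty")
    return table.class_count / n


def stage_likelihood(
    table: ReferenceTable, variable: str, stage: int, alpha: float = 0.0
) -> np.ndarray:
    """Conditional stage frequency per age class, additively smoothed.

    Classes where no individual was scored on the variable get 0 when
    ``alpha == 0`` (the 0/0 guard); with smoothing the formula itself is
    well defined there (``1/K``).
    """
    if not table.catalog.in_range(variable, stage):
        lo, hi = table.catalog.stage_ranges[variable]
        raise ValueError(f"{variable}: stage {stage} outside [{lo}, {hi}]")
    counts = table.stage_count[variable]
    scored = counts.sum(axis=1)
    k = table.catalog.n_stages(variable)
    num = counts[:, stage] + alpha
    den = scored + alpha * k
    out = np.zeros(len(scored), dtype=float)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


@dataclass
class AgePosterior:
    """Probability distribution over the grid's age classes (sums to 1)."""

    probabilities: np.ndarray
    grid: AgeClassGrid

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-9):
            raise ValueError("posterior must be non-negative and sum to 1")
        self.probabilities = p


@dataclass
class AgeEstimate:
    """Outcome for one individual: a posterior + point estimate, or not."""

    individual_id: str
    status: str
    posterior: AgePosterior | None = None
    point_estimate: float | None = None

    @property
    def estimated(self) -> bool:
        return self.status == ESTIMATED


def posterior(
    profile: dict[str, int | None],
    table: ReferenceTable,
    alpha: float = 0.0,
) -> AgePosterior | None:
    """Posterior over age classes for a stage profile; ``None`` = no estimation.

    Raises on an all-missing profile (distinct from the no-estimation
    outcome, which is a property of the data/reference combination).
    """
    scored = [(v, int(s)) for v, s in profile.items()
              if s is not None and v in table.catalog.stage_ranges]
    if not scored:
        raise ValueError("profile has no scored variable")
    mass = class_prior(table).copy()
    for v, s in scored:
        mass *= stage_likelihood(table, v, s, alpha=alpha)
    total = mass.sum()
    if total <= 0.0:
        return None
    return AgePosterior(mass / total, table.grid)


def point_estimate(post: AgePosterior) -> float:
    """Expected value of the posterior using class central ages."""
    return float(post.probabilities @ post.grid.central_ages)


def estimate_record(
    record: SkeletalRecord, table: ReferenceTable, alpha: float = 0.0
) -> AgeEstimate:
    post = posterior(record.profile, table, alpha=alpha)
    if post is None:
        return AgeEstimate(record.individual_id, NO_ESTIMATION)
    return AgeEstimate(record.individual_id, ESTIMATED, post, point_estimate(post))


def estimate_batch(
    test: Sequence[SkeletalRecord], table: ReferenceTable, alpha: float = 0.0
) -> list[AgeEstimate]:
    """One estimate per record, input order preserved."""
    if len(test) == 0:
        raise ValueError("empty test collection")
    return [estimate_record(rec, table, alpha=alpha) for rec in test]


def estimates_to_frame(estimates: Iterable[AgeEstimate],
                       grid: AgeClassGrid | None = None) -> pd.DataFrame:
    """Tabulate estimates: id, status, point estimate, per-class posterior."""
    grid = grid or default_grid()
    rows = []
    for est in estimates:
        row: dict = {
            "individual_id": est.individual_id,
            "status": est.status,
            "point_estimate": est.point_estimate if est.estimated else np.nan,
        }
        probs = (est.posterior.probabilities if est.estimated
                 else np.full(grid.n_classes, np.nan))
        for label, p in zip(grid.labels, probs):
            row[f"p_{label}"] = p
        rows.append(row)
    return pd.DataFrame(rows)


class BayesianAgeEstimator(RegressorMixin, BaseEstimator):
    """Scikit-learn style front end to the naive-Bayes age estimator.

    Parameters
    ----------
    alpha : float, default 0.0
        Additive smoothing of the conditional stage frequencies.  At the
        default 0, stage profiles with zero posterior mass yield a
        no-estimation outcome (``NaN`` from :meth:`predict`); positive
        values trade those failures for estimates pulled toward the prior.
    age_min, age_max, class_width : int
        Age-class grid specification (defaults: 5-year classes 15-104).
    catalog : VariableCatalog, optional
        Stage ranges per variable.  When ``X`` is a DataFrame its columns
        are matched against the catalog; otherwise columns are taken in
        catalog order.

    Attributes
    ----------
    reference_table_ : ReferenceTable
        Class and stage counts of the fitted reference collection.
    grid_ : AgeClassGrid
    feature_names_in_ : ndarray of str
    n_features_in_ : int
    """

    def __init__(self, alpha: float = 0.0, age_min: int = 15, age_max: int = 104,
                 class_width: int = 5, catalog: VariableCatalog | None = None):
        self.alpha = alpha
        self.age_min = age_min
        self.age_max = age_max
        self.class_width = class_width
        self.catalog = catalog

    def _resolve_catalog(self) -> VariableCatalog:
        return self.catalog if self.catalog is not None else default_catalog()

    def _coerce_X(self, X) -> tuple[np.ndarray, list[str]]:
        catalog = self._resolve_catalog()
        if isinstance(X, pd.DataFrame):
            names = [v for v in catalog if v in X.columns]
            missing = [v for v in catalog if v not in X.columns]
            if missing:
                raise ValueError(f"X lacks catalog variables: {missing}")
            arr = X[names].to_numpy(dtype=float)
        else:
            arr = np.asarray(X, dtype=float)
            if arr.ndim != 2:
                raise ValueError("X must be 2-dimensional")
            names = catalog.variables
            if arr.shape[1] != len(names):
                raise ValueError(
                    f"X has {arr.shape[1]} columns, catalog defines {len(names)}"
                )
        for j, v in enumerate(names):
            col = arr[:, j]
            present = ~np.isnan(col)
            if np.any(col[present] != np.round(col[present])):
                raise ValueError(f"{v}: stages must be integers (NaN = missing)")
            lo, hi = catalog.stage_ranges[v]
            if np.any((col[present] < lo) | (col[present] > hi)):
                raise ValueError(f"{v}: stage outside [{lo}, {hi}]")
        return arr, names

    def fit(self, X, y) -> "BayesianAgeEstimator":
        """Fit reference counts from stage profiles ``X`` and known ages ``y``."""
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        arr, names = self._coerce_X(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != len(arr):
            raise ValueError("X and y lengths differ")
        if len(y) == 0:
            raise ValueError("cannot fit on an empty reference")
        catalog = self._resolve_catalog()
        grid = AgeClassGrid(self.age_min, self.age_max, self.class_width)
        idx = grid.indices_of(y)
        class_count = np.bincount(idx, minlength=grid.n_classes)
        stage_count = {
            v: np.zeros((grid.n_classes, catalog.n_stages(v)), dtype=int)
            for v in names
        }
        for j, v in enumerate(names):
            col = arr[:, j]
            present = ~np.isnan(col)
            np.add.at(stage_count[v], (idx[present], col[present].astype(int)), 1)
        self.grid_ = grid
        self.reference_table_ = ReferenceTable(
            grid=grid,
            catalog=VariableCatalog({v: catalog.stage_ranges[v] for v in names}),
            class_count=class_count,
            stage_count=stage_count,
        )
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = len(names)
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Posterior matrix (n_samples, n_classes); NaN rows = no estimation."""
        check_is_fitted(self, "reference_table_")
        arr, names = self._coerce_X(X)
        out = np.full((len(arr), self.grid_.n_classes), np.nan)
        for i, row in enumerate(arr):
            profile = {v: (None if np.isnan(row[j]) else int(row[j]))
                       for j, v in enumerate(names)}
            if all(s is None for s in profile.values()):
                raise ValueError(f"row {i}: no variable scored")
            post = posterior(profile, self.reference_table_, alpha=self.alpha)
            if post is not None:
                out[i] = post.probabilities
        return out

    def predict(self, X) -> np.ndarray:
        """Point estimates in years; NaN marks no-estimation outcomes."""
        proba = self.predict_proba(X)
        return proba @ self.grid_.central_ages

    def estimate(self, records: Sequence[SkeletalRecord]) -> list[AgeEstimate]:
        """Rich per-record outcomes for domain-level pipelines."""
        check_is_fitted(self, "reference_table_")
        return estimate_batch(records, self.reference_table_, alpha=self.alpha)
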