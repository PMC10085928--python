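"""Synthetic skeletal collections with age-progressive ordinal stages.

Each variable follows a cumulative-logit (proportional-odds style) aging
process: stage attainment is governed by ordered thresholds τ_k (years),

    P(stage >= k | age) = logistic((age − (τ_k + δ)) / s),

so the stage probabilities are successive differences of these cumulative
terms.  δ is an additive aging-rate shift on the age axis (negative =
stages attained earlier = faster aging); s is the transition-noise scale.
Thresholds are calibrated as midpoints between consecutive published
per-stage mean ages (the anchors in :mod:`acetage.presets`).  Ages are
drawn piecewise-uniformly over decade bins weighted like the documented
collections, whose age structure is skewed old.

Variables are sampled conditionally independently given age, matching the
estimator's assumption; an optional individual-level frailty scale adds a
shared random shift per individual to break that independence when
robustness to the assumption is under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from . import presets
from .catalog import VariableCatalog, default_catalog
from .records import SkeletalRecord

DEFAULT_TRANSITION_SCALE = 8.0  # years; puts per-stage age SDs in the
                                # 8-19 year range seen in documented data
DEFAULT_FAST_POPULATION_SHIFT = -5.0  # years


@dataclass(frozen=True)
class VariableAgingModel:
    """Ordered attainment thresholds (years) and transition-noise scale."""

    thresholds: tuple[float, ...]
    scale: float = DEFAULT_TRANSITION_SCALE

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        if len(t) == 0:
            raise ValueError("model needs at least one threshold (two stages)")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"thresholds must be strictly increasing: {t.tolist()}")
        if self.scale <= 0:
            raise ValueError("transition scale must be positive")

    @property
    def n_stages(self) -> int:
        return len(self.thresholds) + 1


def stage_probabilities(
    age: float, model: VariableAgingModel, shift: float = 0.0
) -> np.ndarray:
    """Probability vector over stages 0..K−1 at a given age.

    Telescoping construction: cumulative attainment probabilities are
    logistic in age, so successive differences are non-negative and sum
    to 1 exactly.
    """
    tau = np.asarray(model.thresholds, dtype=float)
    cumulative = expit((age - (tau + shift)) / model.scale)
    upper = np.concatenate([[1.0], cumulative])
    lower = np.concatenate([cumulative, [0.0]])
    return upper - lower


def default_config_from_anchors(
    anchors: Mapping[str, Sequence[float]],
    scale: float = DEFAULT_TRANSITION_SCALE,
) -> dict[str, VariableAgingModel]:
    """Build aging models from per-variable stage mean-age anchors.

    τ_k is placed at the midpoint between the stage k−1 and stage k
    anchor means; anchors must be strictly increasing in stage.
    """
    models = {}
    for var, means in anchors.items():
        means = np.asarray(means, dtype=float)
        if len(means) < 2:
            raise ValueError(f"{var}: need anchors for at least two stages")
        if np.any(np.isnan(means)):
            raise ValueError(f"{var}: anchors contain missing values")
        if np.any(np.diff(means) <= 0):
            raise ValueError(
                f"{var}: anchors are not strictly increasing: {means.tolist()}"
            )
        thresholds = tuple((means[:-1] + means[1:]) / 2.0)
        models[var] = VariableAgingModel(thresholds=thresholds, scale=scale)
    return models


@dataclass
class PopulationConfig:
    """One simulated population arm: size, aging shift, age structure."""

    label: str
    sex: str
    n: int
    shift: float = 0.0  # years; negative = faster aging
    age_bin_edges: Sequence[tuple[int, int]] = field(
        default_factory=lambda: list(presets.AGE_BIN_EDGES)
    )
    age_bin_weights: Sequence[float] | None = None  # None = uniform over bins
    missingness: float | Mapping[str, float] = 0.0
    frailty_scale: float = 0.0  # years; >0 adds shared per-individual shift
    collection: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("population size must be >= 1")
        lo = min(e[0] for e in self.age_bin_edges)
        hi = max(e[1] for e in self.age_bin_edges)
        if lo < 15 or hi > 104:
            raise ValueError("age support must lie within [15, 104]")
        rates = (self.missingness.values()
                 if isinstance(self.missingness, Mapping) else [self.missingness])
        for r in rates:
            if not (0.0 <= r < 1.0):
                raise ValueError("missingness rates must be in [0, 1)")

    def missing_rate(self, variable: str) -> float:
        if isinstance(self.missingness, Mapping):
            return float(self.missingness.get(variable, 0.0))
        return float(self.missingness)


def _sample_ages(config: PopulationConfig, rng: np.random.Generator) -> np.ndarray:
    edges = list(config.age_bin_edges)
    if config.age_bin_weights is None:
        weights = np.ones(len(edges))
    else:
        weights = np.asarray(config.age_bin_weights, dtype=float)
        if len(weights) != len(edges) or weights.sum() <= 0:
            raise ValueError("age bin weights must match bins and sum > 0")
    p = weights / weights.sum()
    bins = rng.choice(len(edges), size=config.n, p=p)
    ages = np.empty(config.n, dtype=int)
    for i, b in enumerate(bins):
        lo, hi = edges[b]
        ages[i] = rng.integers(lo, hi + 1)
    return ages


def simulate_collection(
    config: PopulationConfig,
    models: Mapping[str, VariableAgingModel],
    seed: int,
    catalog: VariableCatalog | None = None,
) -> list[SkeletalRecord]:
    """Draw a synthetic collection; identical seed gives identical output."""
    catalog = catalog or default_catalog()
    for var in catalog:
        if var not in models:
            raise ValueError(f"no aging model for variable {var}")
        if models[var].n_stages != catalog.n_stages(var):
            raise ValueError(
                f"{var}: model has {models[var].n_stages} stages, "
                f"catalog defines {catalog.n_stages(var)}"
            )
    rng = np.random.default_rng(seed)
    ages = _sample_ages(config, rng)
    records = []
    for i, age in enumerate(ages):
        shift = config.shift
        if config.frailty_scale > 0:
            shift += rng.normal(0.0, config.frailty_scale)
        profile: dict[str, int | None] = {}
        for var in catalog:
            probs = stage_probabilities(float(age), models[var], shift=shift)
            stage = int(rng.choice(len(probs), p=probs))
            if rng.random() < config.missing_rate(var):
                profile[var] = None
            else:
                profile[var] = stage
        records.append(
            SkeletalRecord(
                individual_id=f"{config.label}-{config.sex}-{i:04d}",
                collection=config.collection,
                population=config.label,
                sex=config.sex,
                age=int(age),
                profile=profile,
            )
        )
    return records


def preset_models(name: str, sex: str) -> dict[str, VariableAgingModel]:
    """Aging models for a named preset ("PT-like" or "NA-like").

    Both presets share thresholds anchored on the Portuguese per-stage
    mean ages (the only complete, monotone published anchor set); the
    NA-like preset is distinguished by its aging shift and age weights
    (see :func:`preset_config`).
    """
    if name not in ("PT-like", "NA-like"):
        raise ValueError(f"unknown preset {name!r}")
    anchors = presets.stage_mean_anchors("PT", sex)
    return default_config_from_anchors(anchors)


def preset_config(name: str, sex: str, n: int, **overrides) -> PopulationConfig:
    """Population config for a named preset with documented age weights.

    "PT-like" uses the Portuguese decade-bin weights and no shift;
    "NA-like" uses the North-American weights and the default fast-aging
    shift of −5 years.
    """
    if name == "PT-like":
        pop, shift = "PT", 0.0
    elif name == "NA-like":
        pop, shift = "NA", DEFAULT_FAST_POPULATION_SHIFT
    else:
        raise ValueError(f"unknown preset {name!r}")
    kwargs = dict(
        label=name.replace("-like", ""),
        sex=sex,
        n=n,
        shift=shift,
        age_bin_weights=presets.AGE_BIN_COUNTS[(pop, sex)],
    )
    kwargs.update(overrides)
    return PopulationConfig(**kwargs)
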