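"""Variable catalog and age-class grid.

The acetabular method scores seven ordinal variables (V1-V7), each an
integer stage starting at 0.  Ages at death are binned into contiguous
5-year classes (15-19, 20-24, ..., 100-104); each class carries a central
age used when collapsing a posterior to a single-year estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import IO, Iterator

import numpy as np

#: Inclusive stage ranges of the seven acetabular variables.
DEFAULT_STAGE_RANGES: dict[str, tuple[int, int]] = {
    "v1": (0, 3),
    "v2": (0, 6),
    "v3": (0, 5),
    "v4": (0, 4),
    "v5": (0, 2),
    "v6": (0, 3),
    "v7": (0, 4),
}


@dataclass(frozen=True)
class VariableCatalog:
    """Ordinal variables and their inclusive stage ranges.

    Stage ranges are contiguous integer intervals starting at 0.  The
    catalog is data-driven so markers other than the seven acetabular
    variables can be configured.
    """

    stage_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_RANGES)
    )

    def __post_init__(self) -> None:
        if not self.stage_ranges:
            raise ValueError("catalog must define at least one variable")
        for var, (lo, hi) in self.stage_ranges.items():
            if lo != 0:
                raise ValueError(f"{var}: stage range must start at 0, got {lo}")
            if hi < lo:
                raise ValueError(f"{var}: empty stage range ({lo}, {hi})")

    @property
    def variables(self) -> list[str]:
        return list(self.stage_ranges)

    def __iter__(self) -> Iterator[str]:
        return iter(self.stage_ranges)

    def __len__(self) -> int:
        return len(self.stage_ranges)

    def n_stages(self, variable: str) -> int:
        lo, hi = self.stage_ranges[variable]
        return hi - lo + 1

    def in_range(self, variable: str, stage: int) -> bool:
        lo, hi = self.stage_ranges[variable]
        return lo <= stage <= hi

    def to_json(self, fp: IO[str] | None = None) -> str:
        payload = {
            v: {"min_stage": lo, "max_stage": hi}
            for v, (lo, hi) in self.stage_ranges.items()
        }
        text = json.dumps(payload, indent=2)
        if fp is not None:
            fp.write(text)
        return text

    @classmethod
    def from_json(cls, source: str | IO[str]) -> "VariableCatalog":
        payload = json.loads(source if isinstance(source, str) else source.read())
        ranges = {
            v: (int(spec["min_stage"]), int(spec["max_stage"]))
            for v, spec in payload.items()
        }
        return cls(stage_ranges=ranges)


def default_catalog() -> VariableCatalog:
    """The seven-variable acetabular catalog."""
    return VariableCatalog()


@dataclass(frozen=True)
class AgeClassGrid:
    """Ordered, contiguous, equal-width integer age classes.

    Each class is the inclusive interval ``[lower, lower + width - 1]``;
    its central age is the arithmetic midpoint of the interval (15-19 ->
    17, 20-24 -> 22, ...).
    """

    age_min: int = 15
    age_max: int = 104
    width: int = 5

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError("class width must be >= 1")
        span = self.age_max - self.age_min + 1
        if span <= 0 or span % self.width != 0:
            raise ValueError(
                f"[{self.age_min}, {self.age_max}] does not divide into "
                f"classes of width {self.width}"
            )

    @property
    def n_classes(self) -> int:
        return (self.age_max - self.age_min + 1) // self.width

    @property
    def lower_bounds(self) -> np.ndarray:
        return self.age_min + self.width * np.arange(self.n_classes)

    @property
    def central_ages(self) -> np.ndarray:
        # midpoint of the inclusive interval [lo, lo + width - 1]
        return self.lower_bounds + (self.width - 1) / 2.0

    @property
    def labels(self) -> list[str]:
        return [f"{lo}-{lo + self.width - 1}" for lo in self.lower_bounds]

    def index_of(self, age: float) -> int:
        """Class index of a chronological age; total and unique on the span."""
        if not (self.age_min <= age <= self.age_max):
            raise ValueError(
                f"age {age} outside grid span [{self.age_min}, {self.age_max}]"
            )
        return int((age - self.age_min) // self.width)

    def indices_of(self, ages: np.ndarray) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        if np.any(ages < self.age_min) or np.any(ages > self.age_max):
            bad = ages[(ages < self.age_min) | (ages > self.age_max)]
            raise ValueError(f"ages outside grid span: {bad[:5].tolist()}")
        return ((ages - self.age_min) // self.width).astype(int)

    def to_dict(self) -> dict:
        return {"age_min": self.age_min, "age_max": self.age_max, "width": self.width}

    @classmethod
    def from_dict(cls, d: dict) -> "AgeClassGrid":
        return cls(age_min=int(d["age_min"]), age_max=int(d["age_max"]),
                   width=int(d["width"]))


def default_grid() -> AgeClassGrid:
    """5-year classes 15-19 through 100-104 (18 classes)."""
    return AgeClassGrid()
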