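import numpy as np
import pytest

from acetage import (
    AgeClassGrid,
    SkeletalRecord,
    VariableCatalog,
    default_catalog,
    default_grid,
)


@pytest.fixture
def catalog() -> VariableCatalog:
    return default_catalog()


@pytest.fixture
def grid() -> AgeClassGrid:
    return default_grid()


def make_record(i, age, sex="M", population="PT", **stages) -> SkeletalRecord:
    profile = {f"v{k}": None for k in range(1, 8)}
    profile.update(stages)
    if all(v is None for v in profile.values()):
        profile["v1"] = 0
    return SkeletalRecord(
        individual_id=str(i), population=population, sex=sex, age=age,
        profile=profile,
    )


@pytest.fixture
def small_collection() -> list[SkeletalRecord]:
    """Ten hand-made records spanning young to old ages."""
    rows = [
        (20, dict(v1=0, v2=1, v5=0)),
        (24, dict(v1=0, v2=1, v5=0)),
        (33, dict(v1=1, v2=2, v5=0)),
        (41, dict(v1=1, v2=3, v5=0)),
        (47, dict(v1=1, v2=4, v5=1)),
        (55, dict(v1=2, v2=4, v5=1)),
        (62, dict(v1=2, v2=4, v5=1)),
        (70, dict(v1=2, v2=5, v5=1)),
        (78, dict(v1=3, v2=5, v5=2)),
        (86, dict(v1=3, v2=6, v5=2)),
    ]
    return [make_record(i, age, **st) for i, (age, st) in enumerate(rows)]


def random_records(rng, n, n_classes=4, variables=("v1", "v2"), grid=None):
    """Random small reference collections for oracle comparisons."""
    grid = grid or default_grid()
    catalog = default_catalog()
    records = []
    for i in range(n):
        c = int(rng.integers(0, n_classes))
        lo = grid.age_min + grid.width * c
        age = int(rng.integers(lo, lo + grid.width))
        profile = {}
        for v in variables:
            if rng.random() < 0.15:
                profile[v] = None
            else:
                lo_s, hi_s = catalog.stage_ranges[v]
                profile[v] = int(rng.integers(lo_s, hi_s + 1))
        records.append(SkeletalRecord(str(i), "POP", "M", age, profile))
    return records
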