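"""Skeletal records: domain type, validation, CSV round-trip, splitting.

A collection CSV has columns
``individual_id,collection,population,sex,age,side,v1,...,v7`` (one stage
column per catalog variable); blank stage cells are missing scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

from .catalog import VariableCatalog, default_catalog

AGE_FLOOR = 15
AGE_CEILING = 110

METADATA_COLUMNS = ["individual_id", "collection", "population", "sex", "age", "side"]

#: Stage profile: variable id -> integer stage; absent / None = not scored.
StageProfile = dict


@dataclass
class SkeletalRecord:
    """One documented or simulated individual."""

    individual_id: str
    population: str
    sex: str
    age: int
    profile: dict[str, int | None] = field(default_factory=dict)
    collection: str = ""
    side: str = "L"

    def stage(self, variable: str) -> int | None:
        v = self.profile.get(variable)
        return None if v is None else int(v)

    def scored_variables(self) -> list[str]:
        return [v for v, s in self.profile.items() if s is not None]


def validate_record(
    record: SkeletalRecord, catalog: VariableCatalog | None = None
) -> list[str]:
    """Return human-readable invariant violations (empty list = valid).

    Violations are returned, never raised, so callers can collect them
    across a whole collection.
    """
    catalog = catalog or default_catalog()
    problems: list[str] = []
    if not str(record.population).strip():
        problems.append("population: must be non-empty")
    if str(record.sex) not in ("M", "F"):
        problems.append(f"sex: expected 'M' or 'F', got {record.sex!r}")
    if record.side not in ("L", "R"):
        problems.append(f"side: expected 'L' or 'R', got {record.side!r}")
    try:
        age = float(record.age)
        if not (AGE_FLOOR <= age <= AGE_CEILING):
            problems.append(
                f"age: {record.age} outside [{AGE_FLOOR}, {AGE_CEILING}]"
            )
    except (TypeError, ValueError):
        problems.append(f"age: not a number ({record.age!r})")
    scored = 0
    for var in catalog:
        stage = record.profile.get(var)
        if stage is None:
            continue
        scored += 1
        if not catalog.in_range(var, int(stage)):
            lo, hi = catalog.stage_ranges[var]
            problems.append(f"{var}: stage {stage} outside [{lo}, {hi}]")
    if scored == 0:
        problems.append("profile: no variable scored")
    return problems


def _require_columns(columns: Sequence[str], catalog: VariableCatalog) -> None:
    expected = METADATA_COLUMNS + catalog.variables
    missing = [c for c in expected if c not in columns]
    if missing:
        raise ValueError(f"collection CSV is missing columns: {missing}")


def read_collection(
    source: str | IO[str],
    catalog: VariableCatalog | None = None,
    validate: bool = True,
) -> list[SkeletalRecord]:
    """Read a collection CSV into records (row order preserved)."""
    catalog = catalog or default_catalog()
    frame = pd.read_csv(source, dtype={"individual_id": str, "collection": str,
                                       "population": str, "sex": str, "side": str})
    _require_columns(frame.columns, catalog)
    records = frame_to_records(frame, catalog)
    if validate:
        for i, rec in enumerate(records):
            problems = validate_record(rec, catalog)
            if problems:
                raise ValueError(
                    f"row {i} (individual {rec.individual_id}): " + "; ".join(problems)
                )
    return records


def write_collection(
    records: Iterable[SkeletalRecord],
    sink: str | IO[str],
    catalog: VariableCatalog | None = None,
) -> None:
    """Write records as a collection CSV; missing stages become blank cells."""
    catalog = catalog or default_catalog()
    records_to_frame(records, catalog).to_csv(sink, index=False)


def frame_to_records(
    frame: pd.DataFrame, catalog: VariableCatalog | None = None
) -> list[SkeletalRecord]:
    catalog = catalog or default_catalog()
    records = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        profile: dict[str, int | None] = {}
        for var in catalog:
            raw = d[var]
            profile[var] = None if pd.isna(raw) else int(raw)
        records.append(
            SkeletalRecord(
                individual_id=str(d["individual_id"]),
                collection="" if pd.isna(d["collection"]) else str(d["collection"]),
                population=str(d["population"]),
                sex=str(d["sex"]),
                age=int(d["age"]),
                side="L" if pd.isna(d["side"]) else str(d["side"]),
                profile=profile,
            )
        )
    return records


def records_to_frame(
    records: Iterable[SkeletalRecord], catalog: VariableCatalog | None = None
) -> pd.DataFrame:
    catalog = catalog or default_catalog()
    rows = []
    for rec in records:
        row: dict = {
            "individual_id": rec.individual_id,
            "collection": rec.collection,
            "population": rec.population,
            "sex": rec.sex,
            "age": rec.age,
            "side": rec.side,
        }
        for var in catalog:
            stage = rec.profile.get(var)
            row[var] = np.nan if stage is None else int(stage)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=METADATA_COLUMNS + catalog.variables)
    for var in catalog.variables:
        frame[var] = frame[var].astype("Int64")
    return frame


def split_reference_test(
    records: Sequence[SkeletalRecord],
    reference_fraction: float,
    seed: int,
    stratify_by: Iterable[str] = (),
) -> tuple[list[SkeletalRecord], list[SkeletalRecord]]:
    """Seeded partition into (reference, test) lists.

    Within every stratum (records grouped by the requested fields;
    ``"age_class"`` strata use 5-year bins of age), the reference arm gets
    ``round(fraction * stratum size)`` records.  Strata with fewer than two
    records go wholly to the reference arm with a warning.
    """
    if not (0.0 < reference_fraction < 1.0):
        raise ValueError("reference_fraction must be strictly between 0 and 1")
    stratify_by = list(stratify_by)

    def stratum_key(rec: SkeletalRecord) -> tuple:
        key = []
        for f in stratify_by:
            if f == "age_class":
                key.append(int(rec.age) // 5)
            else:
                key.append(getattr(rec, f))
        return tuple(key)

    strata: dict[tuple, list[int]] = {}
    for i, rec in enumerate(records):
        strata.setdefault(stratum_key(rec), []).append(i)

    rng = np.random.default_rng(seed)
    ref_idx: list[int] = []
    for key in sorted(strata, key=repr):
        idx = np.array(strata[key])
        if len(idx) < 2:
            warnings.warn(
                f"stratum {key!r} has {len(idx)} record(s); assigned to reference",
                stacklevel=2,
            )
            ref_idx.extend(idx.tolist())
            continue
        n_ref = int(round(reference_fraction * len(idx)))
        n_ref = min(max(n_ref, 0), len(idx))
        chosen = rng.choice(idx, size=n_ref, replace=False)
        ref_idx.extend(chosen.tolist())
    ref_set = set(ref_idx)
    reference = [records[i] for i in sorted(ref_set)]
    test = [records[i] for i in range(len(records)) if i not in ref_set]
    return reference, test
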