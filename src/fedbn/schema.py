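"""Categorical data model: variables, schemas, station datasets, splits.

Records are complete categorical assignments over a fixed, ordered set of
variables.  Exactly one variable plays the ``class`` role (the label being
predicted, e.g. the fraud type); all others are ``feature`` variables.  The
canonical variable order of a :class:`DatasetSchema` is stable across
serialization and drives every downstream tie-break (TAN root choice, CPT
layout, lexicographic edge ordering).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("fedbn")

Record = tuple[str, ...]


def _round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (0.5 -> 1)."""
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class VariableSpec:
    """One categorical variable: its name, ordered state list and role.

    Parameters
    ----------
    name
        Variable identifier (e.g. ``"Fraud type"``, ``"Product"``).
    states
        Ordered list of category labels.  Labels must be unique and
        non-empty.  Lexicographic state order is the package-wide
        convention (see :func:`harmonize_schemas`).
    role
        ``"class"`` for the label variable, ``"feature"`` otherwise.
    """

    name: str
    states: tuple[str, ...]
    role: str = "feature"

    def __post_init__(self) -> None:
        if self.role not in ("class", "feature"):
            raise ValueError(f"role must be 'class' or 'feature', got {self.role!r}")
        object.__setattr__(self, "states", tuple(self.states))
        if any(not s for s in self.states):
            raise ValueError(f"variable {self.name!r} has an empty state label")
        if len(set(self.states)) != len(self.states):
            raise ValueError(f"variable {self.name!r} has duplicate state labels")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.states)}


@dataclass(frozen=True)
class DatasetSchema:
    """An ordered collection of :class:`VariableSpec` with exactly one class variable."""

    variables: tuple[VariableSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("variable names must be unique")
        n_class = sum(1 for v in self.variables if v.role == "class")
        if n_class != 1:
            raise ValueError(f"schema must have exactly one class variable, found {n_class}")

    @property
    def variable_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    @property
    def class_var(self) -> VariableSpec:
        return next(v for v in self.variables if v.role == "class")

    @property
    def feature_vars(self) -> tuple[VariableSpec, ...]:
        """Feature variables in canonical (schema) order."""
        return tuple(v for v in self.variables if v.role == "feature")

    def __getitem__(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(v.name == name for v in self.variables)

    def index_of(self, name: str) -> int:
        for i, v in enumerate(self.variables):
            if v.name == name:
                return i
        raise KeyError(name)

    def canonical_json(self) -> str:
        """Deterministic JSON serialization; basis of the schema fingerprint."""
        payload = [
            {"name": v.name, "states": list(v.states), "role": v.role}
            for v in self.variables
        ]
        return json.dumps(payload, sort_keys=True, separators=(",", ":"))


@dataclass
class StationDataset:
    """One station's records plus its identifier and provenance tag.

    ``records`` holds complete assignments as tuples of state labels in the
    schema's canonical variable order.  Every value must be a declared state;
    ingestion routines reject (and count) records violating this.
    """

    station_id: str
    schema: DatasetSchema
    records: list[Record] = field(default_factory=list)
    provenance: str = ""
    n_rejected: int = 0  # records dropped at ingestion (missing/unknown values)

    def __post_init__(self) -> None:
        self.records = [tuple(r) for r in self.records]
        self.validate()

    def validate(self) -> None:
        nvar = len(self.schema.variables)
        for i, rec in enumerate(self.records):
            if len(rec) != nvar:
                raise ValueError(
                    f"record {i} has {len(rec)} values, schema has {nvar} variables"
                )
            for v, val in zip(self.schema.variables, rec):
                if val not in v.states:
                    raise ValueError(
                        f"record {i}: value {val!r} not a declared state of {v.name!r}"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def class_labels(self) -> list[str]:
        ci = self.schema.index_of(self.schema.class_var.name)
        return [r[ci] for r in self.records]

    def class_counts(self) -> dict[str, int]:
        counts = {s: 0 for s in self.schema.class_var.states}
        for lab in self.class_labels():
            counts[lab] += 1
        return counts

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.records, columns=list(self.schema.variable_names))

    def with_schema(self, schema: DatasetSchema) -> "StationDataset":
        """Re-express the records under a (typically harmonized) super-schema.

        Variables are matched by name; every record value must be a state of
        the new schema.
        """
        order = [self.schema.index_of(n) for n in schema.variable_names]
        recs = [tuple(r[i] for i in order) for r in self.records]
        return StationDataset(self.station_id, schema, recs, provenance=self.provenance)


@dataclass
class SplitResult:
    """Outcome of a seeded train/test partition."""

    train: StationDataset
    test: StationDataset
    seed: int
    fraction: float


def observed_schema(data: StationDataset) -> DatasetSchema:
    """Schema restricted to the states actually observed in ``data``.

    Used by the federation handshake: it discloses variable names and state
    lists only, never counts.
    """
    cols = list(zip(*data.records)) if data.records else [() for _ in data.schema.variables]
    specs = []
    for v, col in zip(data.schema.variables, cols):
        states = tuple(sorted(set(col)))
        specs.append(VariableSpec(v.name, states, v.role))
    return DatasetSchema(tuple(specs))


def harmonize_schemas(schemas: Iterable[DatasetSchema]) -> DatasetSchema:
    """Union the per-station state lists into one shared schema.

    Per variable, the harmonized state list is the lexicographically sorted
    union of all stations' states.  The result is deterministic and
    independent of input order; variable names and roles must agree across
    inputs.  This is what lets a station that never observed a class (e.g. a
    fraud type absent locally) still receive predictions over the full class
    space.
    """
    schemas = list(schemas)
    if not schemas:
        raise ValueError("harmonize_schemas needs at least one schema")
    ref = schemas[0]
    names = ref.variable_names
    for s in schemas[1:]:
        if s.variable_names != names:
            raise ValueError(
                f"schemas disagree on variables: {names} vs {s.variable_names}"
            )
    specs = []
    for name in names:
        roles = {s[name].role for s in schemas}
        if len(roles) != 1:
            raise ValueError(f"conflicting roles for variable {name!r}: {sorted(roles)}")
        states: set[str] = set()
        for s in schemas:
            states.update(s[name].states)
        specs.append(VariableSpec(name, tuple(sorted(states)), roles.pop()))
    return DatasetSchema(tuple(specs))


def split_indices(n: int, fraction: float, seed: int) -> tuple[list[int], list[int]]:
    """Plain (unstratified) seeded index split; |train| = round(fraction * n)."""
    rng = np.random.default_rng(seed)
    total_train = _round_half_up(fraction * n)
    perm = rng.permutation(n)
    chosen = set(perm[:total_train].tolist())
    train = [i for i in range(n) if i in chosen]
    test = [i for i in range(n) if i not in chosen]
    return train, test


def split_train_test(
    data: StationDataset,
    fraction: float = 0.8,
    seed: int = 0,
    stratify: bool = True,
) -> SplitResult:
    """Seeded, reproducible train/test split (default 80/20, stratified).

    With ``stratify=True`` each class contributes ``round(fraction * n_class)``
    records to train, subject to a global largest-remainder correction so that
    ``|train| = round(fraction * n)`` exactly.  A class with a single record
    always goes to train (a warning is logged) so that no observed class
    vanishes from training.  Same seed, same data -> identical partition.
    """
    n = len(data)
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if n < 2:
        raise ValueError(f"need at least 2 records to split, got {n}")
    rng = np.random.default_rng(seed)
    total_train = _round_half_up(fraction * n)

    if not stratify:
        train_list, _ = split_indices(n, fraction, seed)
        train_idx = set(train_list)
    else:
        ci = data.schema.index_of(data.schema.class_var.name)
        by_class: dict[str, list[int]] = {}
        for i, rec in enumerate(data.records):
            by_class.setdefault(rec[ci], []).append(i)
        labels = sorted(by_class)
        targets: dict[str, int] = {}
        pinned: set[str] = set()
        for lab in labels:
            n_c = len(by_class[lab])
            if n_c == 1:
                logger.warning(
                    "class %r has a single record; forced into train", lab
                )
                targets[lab] = 1
                pinned.add(lab)
            else:
                targets[lab] = _round_half_up(fraction * n_c)
        # largest-remainder correction toward the global total
        diff = sum(targets.values()) - total_train
        if diff != 0:
            step = -1 if diff > 0 else 1
            # rank adjustable classes by fractional remainder, ties by label
            def remainder(lab: str) -> float:
                frac = fraction * len(by_class[lab])
                return frac - np.floor(frac)

            adjustable = [l for l in labels if l not in pinned]
            order = sorted(
                adjustable,
                key=lambda l: (remainder(l) if step > 0 else -remainder(l), l),
                reverse=step > 0,
            )
            k = 0
            while diff != 0 and order:
                lab = order[k % len(order)]
                new = targets[lab] + step
                if 0 <= new <= len(by_class[lab]):
                    targets[lab] = new
                    diff += step
                k += 1
                if k > 10 * (len(order) + abs(diff) + 1):  # pragma: no cover
                    raise RuntimeError("split correction failed to converge")
        train_idx = set()
        for lab in labels:
            idx = np.array(by_class[lab])
            perm = rng.permutation(len(idx))
            train_idx.update(idx[perm[: targets[lab]]].tolist())

    train_recs = [r for i, r in enumerate(data.records) if i in train_idx]
    test_recs = [r for i, r in enumerate(data.records) if i not in train_idx]
    train = StationDataset(data.station_id, data.schema, train_recs, data.provenance)
    test = StationDataset(data.station_id, data.schema, test_recs, data.provenance)
    return SplitResult(train=train, test=test, seed=seed, fraction=fraction)


def pool_datasets(datasets: Sequence[StationDataset], station_id: str = "POOLED") -> StationDataset:
    """Concatenate several stations' records under the harmonized schema."""
    schema = harmonize_schemas([d.schema for d in datasets])
    recs: list[Record] = []
    for d in datasets:
        recs.extend(d.with_schema(schema).records)
    return StationDataset(station_id, schema, recs)
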