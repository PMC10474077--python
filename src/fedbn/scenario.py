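"""Synthetic station-data generator.

Emulates multi-site categorical surveillance data: each station holds incident
records with a fraud-type label, a product category, a year and two country
variables, with station-specific class mixes, year spans and class imbalance.
The canonical three-station scenario reproduces a fixed reference per-station
composition exactly (class counts are deterministic; only attribute values are
stochastic), so every downstream module is testable without any download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from fedbn.schema import DatasetSchema, Record, StationDataset, VariableSpec
from fedbn.tan import TANModel

YEAR_VARIABLE = "Year"

#: The three fraud-type class states of the canonical scenario.
FRAUD_TYPES = (
    "Artificial enhancement/Improvement",
    "Smuggling-Mislabeling-Origin Masking",
    "Substitution-Dilution",
)

_PRODUCTS = (
    "Alcoholic beverages",
    "Dairy",
    "Fish_Seafood",
    "Herbs_Spices",
    "Meat",
    "Oils_Fats",
)
_ORIGIN_COUNTRIES = (
    "China", "Croatia", "India", "Italy", "South Korea", "Spain", "Turkey", "Vietnam",
)
_REPORT_COUNTRIES = (
    "Belgium", "France", "Germany", "Netherlands", "United Kingdom", "United States",
)
_YEARS = tuple(str(y) for y in range(2008, 2019))


@dataclass
class ClassProfile:
    """Recipe for one class's records at one station.

    ``count`` records carry ``class_label``; each feature value is drawn
    independently from ``attribute_dists[feature]`` (a categorical
    distribution over state labels).  A feature named ``Year`` without an
    explicit distribution is drawn uniformly from the inclusive
    ``year_range``.
    """

    class_label: str
    count: int
    attribute_dists: dict[str, dict[str, float]] = field(default_factory=dict)
    year_range: tuple[int, int] | None = None

    def validate(self, schema: DatasetSchema) -> None:
        if self.count < 0:
            raise ValueError(f"profile count must be >= 0, got {self.count}")
        if self.class_label not in schema.class_var.states:
            raise ValueError(f"class label {self.class_label!r} not in schema")
        for feat, dist in self.attribute_dists.items():
            if feat not in schema:
                raise ValueError(f"distribution given for unknown variable {feat!r}")
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"distribution for {feat!r} sums to {total}, not 1")
            for state, p in dist.items():
                if p > 0 and state not in schema[feat].states:
                    raise ValueError(
                        f"state {state!r} with positive mass not in schema for {feat!r}"
                    )


@dataclass
class ScenarioConfig:
    """A full multi-station scenario: per-station class profiles plus a seed."""

    stations: list[tuple[str, list[ClassProfile]]]
    schema: DatasetSchema
    seed: int = 0

    def validate(self) -> None:
        ids = [sid for sid, _ in self.stations]
        if len(set(ids)) != len(ids):
            raise ValueError("station ids must be unique")
        for sid, profiles in self.stations:
            labels = [p.class_label for p in profiles]
            if len(set(labels)) != len(labels):
                raise ValueError(f"duplicate class labels in station {sid!r}")
            for p in profiles:
                p.validate(self.schema)


def _child_seed(seed: int, index: int) -> int:
    # stable per-station sub-seed, kept below 2**31
    return int((seed * 1_000_003 + 7919 * (index + 1)) % (2**31 - 1))


def generate_station(
    profiles: Sequence[ClassProfile],
    schema: DatasetSchema,
    station_id: str,
    seed: int,
) -> StationDataset:
    """Generate one station's dataset from class profiles.

    Exactly ``profile.count`` records per profile (counts are deterministic
    regardless of seed; only attribute values are stochastic).  One global
    random stream per call, consumed in fixed order — per profile, per
    record, per feature variable in canonical schema order — then a final
    shuffle of record order from the same stream.
    """
    for p in profiles:
        p.validate(schema)
    rng = np.random.default_rng(seed)
    ci = schema.index_of(schema.class_var.name)
    records: list[Record] = []
    for prof in profiles:
        samplers = {}
        for v in schema.feature_vars:
            if v.name in prof.attribute_dists:
                dist = prof.attribute_dists[v.name]
                states = [s for s in v.states if dist.get(s, 0.0) > 0]
                probs = np.array([dist[s] for s in states], dtype=float)
                probs = probs / probs.sum()
                samplers[v.name] = (states, probs)
            elif v.name == YEAR_VARIABLE and prof.year_range is not None:
                lo, hi = prof.year_range
                states = [str(y) for y in range(lo, hi + 1)]
                unknown = [s for s in states if s not in v.states]
                if unknown:
                    raise ValueError(f"year states {unknown} not in schema")
                samplers[v.name] = (states, np.full(len(states), 1.0 / len(states)))
            else:
                raise ValueError(
                    f"profile for {prof.class_label!r} gives no distribution for {v.name!r}"
                )
        for _ in range(prof.count):
            rec = [""] * len(schema.variables)
            rec[ci] = prof.class_label
            for v in schema.feature_vars:
                states, probs = samplers[v.name]
                rec[schema.index_of(v.name)] = states[rng.choice(len(states), p=probs)]
            records.append(tuple(rec))
    perm = rng.permutation(len(records))
    records = [records[i] for i in perm]
    return StationDataset(station_id, schema, records, provenance=f"synthetic(seed={seed})")


def _peaked(states: Sequence[str], peak_index: int, peak_mass: float = 0.5) -> dict[str, float]:
    """Categorical distribution with one dominant state, rest uniform."""
    k = len(states)
    rest = (1.0 - peak_mass) / (k - 1)
    return {s: (peak_mass if i == peak_index else rest) for i, s in enumerate(states)}


def reference_scenario_schema() -> DatasetSchema:
    """The five-variable schema of the canonical three-station scenario."""
    return DatasetSchema((
        VariableSpec("Fraud type", FRAUD_TYPES, "class"),
        VariableSpec("Product", _PRODUCTS, "feature"),
        VariableSpec(YEAR_VARIABLE, _YEARS, "feature"),
        VariableSpec("Country (O)", _ORIGIN_COUNTRIES, "feature"),
        VariableSpec("Country (N)", _REPORT_COUNTRIES, "feature"),
    ))


def reference_scenario_config(seed: int = 0) -> ScenarioConfig:
    """The canonical scenario: three stations with fixed class counts and year spans.

    STATION-1 holds 202 records of two fraud types from 2008-2013; STATION-2
    holds 144 records from 2014-2018 with a single record of the third type;
    STATION-3 holds 95 records spanning 2008-2018 with all three types.
    Feature distributions are built-in class-dependent peaked multinomials
    (distinct dominant product/country per class) so the class signal is
    learnable; they make no attempt to match the real incident databases'
    marginals.
    """
    schema = reference_scenario_schema()
    # class index -> dominant state index per feature; distinct per class
    peaks = {
        FRAUD_TYPES[0]: {"Product": 0, "Country (O)": 1, "Country (N)": 0},
        FRAUD_TYPES[1]: {"Product": 2, "Country (O)": 4, "Country (N)": 3},
        FRAUD_TYPES[2]: {"Product": 4, "Country (O)": 6, "Country (N)": 5},
    }

    def profile(label: str, count: int, years: tuple[int, int]) -> ClassProfile:
        dists = {
            "Product": _peaked(_PRODUCTS, peaks[label]["Product"]),
            "Country (O)": _peaked(_ORIGIN_COUNTRIES, peaks[label]["Country (O)"]),
            "Country (N)": _peaked(_REPORT_COUNTRIES, peaks[label]["Country (N)"]),
        }
        return ClassProfile(label, count, dists, year_range=years)

    stations = [
        ("STATION-1", [
            profile(FRAUD_TYPES[1], 105, (2008, 2013)),
            profile(FRAUD_TYPES[2], 97, (2008, 2013)),
        ]),
        ("STATION-2", [
            profile(FRAUD_TYPES[0], 1, (2014, 2018)),
            profile(FRAUD_TYPES[1], 135, (2014, 2018)),
            profile(FRAUD_TYPES[2], 8, (2014, 2018)),
        ]),
        ("STATION-3", [
            profile(FRAUD_TYPES[0], 21, (2008, 2018)),
            profile(FRAUD_TYPES[1], 23, (2008, 2018)),
            profile(FRAUD_TYPES[2], 51, (2008, 2018)),
        ]),
    ]
    return ScenarioConfig(stations=stations, schema=schema, seed=seed)


def generate_scenario(config: ScenarioConfig) -> list[StationDataset]:
    """Generate every station of a scenario with per-station derived seeds."""
    config.validate()
    return [
        generate_station(profiles, config.schema, sid, _child_seed(config.seed, i))
        for i, (sid, profiles) in enumerate(config.stations)
    ]


def generate_reference_scenario(seed: int = 0) -> list[StationDataset]:
    """Three station datasets with exactly the canonical composition (202/144/95)."""
    return generate_scenario(reference_scenario_config(seed))


def generate_from_tan(
    model: TANModel, n: int, seed: int, station_id: str = "SAMPLED"
) -> StationDataset:
    """Ancestral sampling from a fitted TAN (class first, then features root-down)."""
    rng = np.random.default_rng(seed)
    schema = model.schema
    cls = schema.class_var
    ci = schema.index_of(cls.name)
    order = model.structure.topological_order()
    pm = model.structure.feature_parent
    records: list[Record] = []
    for _ in range(n):
        rec = [""] * len(schema.variables)
        c = int(rng.choice(cls.n_states, p=model.class_prior.table))
        rec[ci] = cls.states[c]
        drawn: dict[str, int] = {}
        for name in order:
            cpt = model.cpts[name]
            fp = pm[name]
            row = cpt.table[c] if fp is None else cpt.table[c, drawn[fp]]
            k = int(rng.choice(len(row), p=row / row.sum()))
            drawn[name] = k
            rec[schema.index_of(name)] = schema[name].states[k]
        records.append(tuple(rec))
    return StationDataset(station_id, schema, records, provenance=f"tan-sample(seed={seed})")
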