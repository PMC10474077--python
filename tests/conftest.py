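"""Shared fixtures and independent oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest

from fedbn.schema import DatasetSchema, StationDataset, VariableSpec
from fedbn.scenario import generate_reference_scenario


@pytest.fixture
def toy_schema() -> DatasetSchema:
    """Two-class schema with three small features."""
    return DatasetSchema((
        VariableSpec("C", ("c0", "c1"), "class"),
        VariableSpec("X", ("x0", "x1"), "feature"),
        VariableSpec("Y", ("y0", "y1", "y2"), "feature"),
        VariableSpec("Z", ("z0", "z1"), "feature"),
    ))


@pytest.fixture(scope="session")
def reference_stations():
    """The canonical three-station synthetic scenario (fixed seed)."""
    return generate_reference_scenario(7)


def random_schema(rng: np.random.Generator, n_features: int, n_classes: int,
                  max_states: int = 3) -> DatasetSchema:
    specs = [VariableSpec("CLS", tuple(f"c{i}" for i in range(n_classes)), "class")]
    for f in range(n_features):
        k = int(rng.integers(2, max_states + 1))
        specs.append(VariableSpec(f"F{f}", tuple(f"s{j}" for j in range(k)), "feature"))
    return DatasetSchema(tuple(specs))


def random_dataset(rng: np.random.Generator, schema: DatasetSchema, n: int,
                   station_id: str = "R") -> StationDataset:
    """Records drawn from random class-dependent categorical distributions."""
    cls = schema.class_var
    class_p = rng.dirichlet(np.ones(cls.n_states) * 2.0)
    feat_p = {
        v.name: rng.dirichlet(np.ones(v.n_states), size=cls.n_states)
        for v in schema.feature_vars
    }
    records = []
    for _ in range(n):
        c = int(rng.choice(cls.n_states, p=class_p))
        rec = []
        for v in schema.variables:
            if v.role == "class":
                rec.append(cls.states[c])
            else:
                rec.append(v.states[int(rng.choice(v.n_states, p=feat_p[v.name][c]))])
        records.append(tuple(rec))
    return StationDataset(station_id, schema, records)


def partition_dataset(rng: np.random.Generator, data: StationDataset, k: int):
    """Random assignment of records to k stations (some possibly empty)."""
    assign = rng.integers(0, k, size=len(data))
    parts = []
    for s in range(k):
        recs = [r for r, a in zip(data.records, assign) if a == s]
        parts.append(StationDataset(f"PART-{s}", data.schema, recs))
    return [p for p in parts if len(p) > 0]


# ---------------------------------------------------------------- oracles

def cmi_brute_force(stats, xi: str, xj: str) -> float:
    """Direct triple-loop plug-in conditional mutual information (nats)."""
    t = stats.pair(xi, xj)
    N = float(stats.n)
    total = 0.0
    for c in range(t.shape[0]):
        n_c = float(stats.class_counts[c])
        for a in range(t.shape[1]):
            n_ca = float(stats.single_counts[xi][c, a])
            for b in range(t.shape[2]):
                n_cab = float(t[c, a, b])
                if n_cab > 0:
                    n_cb = float(stats.single_counts[xj][c, b])
                    total += (n_cab / N) * np.log(n_cab * n_c / (n_ca * n_cb))
    return total


def posterior_brute_force(model, record_values: dict) -> dict:
    """Normalize the explicitly multiplied joint over all class states."""
    schema = model.schema
    cls = schema.class_var
    pm = model.structure.feature_parent
    joint = []
    for c in range(cls.n_states):
        p = model.class_prior.table[c]
        for v in schema.feature_vars:
            cpt = model.cpts[v.name]
            k = v.state_index()[record_values[v.name]]
            fp = pm[v.name]
            if fp is None:
                p *= cpt.table[c, k]
            else:
                j = schema[fp].state_index()[record_values[fp]]
                p *= cpt.table[c, j, k]
        joint.append(p)
    joint = np.asarray(joint)
    joint = joint / joint.sum()
    return dict(zip(cls.states, joint))


def all_spanning_trees(nodes: list[str]):
    """Every labeled spanning tree on ``nodes`` as a frozenset of edges."""
    from itertools import combinations

    all_edges = list(combinations(nodes, 2))
    trees = []
    for subset in combinations(all_edges, len(nodes) - 1):
        parent = {n: n for n in nodes}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for a, b in subset:
            ra, rb = find(a), find(b)
            if ra == rb:
                ok = False
                break
            parent[ra] = rb
        if ok:
            trees.append(frozenset(frozenset(e) for e in subset))
    return trees


def micro_auc_brute_force(observed, scores, classes) -> float:
    """Pooled one-vs-rest concordance probability (ties count one half)."""
    idx = {c: i for i, c in enumerate(classes)}
    pos, neg = [], []
    for r, lab in enumerate(observed):
        for j in range(len(classes)):
            (pos if idx[lab] == j else neg).append(scores[r][j])
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
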