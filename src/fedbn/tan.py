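"""Tree-Augmented Naive Bayes: sufficient statistics, structure, parameters, prediction.

A TAN classifier is a Bayesian network in which every feature has the class as
a parent and at most one other feature as a second parent, the feature-feature
edges forming a spanning tree.  The tree is the maximum-weight spanning tree
under class-conditional mutual information (the classic Chow-Liu construction
conditioned on the class).  Everything here is computed from additive
class-conditional contingency counts (:class:`SufficientStatistics`), which is
what makes exact federated training possible: counts from disjoint data
partitions sum to the counts of the pooled data.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np

from fedbn.schema import DatasetSchema, Record, StationDataset


def _pair_key(schema: DatasetSchema, xi: str, xj: str) -> tuple[str, str]:
    """Canonical (schema-order) key for an unordered feature pair."""
    order = {v.name: k for k, v in enumerate(schema.feature_vars)}
    return (xi, xj) if order[xi] < order[xj] else (xj, xi)


@dataclass
class SufficientStatistics:
    """Class-conditional contingency counts — the only object a station exports.

    ``class_counts[c]`` counts records with class state ``c``;
    ``single_counts[X][c, a]`` counts records with class ``c`` and ``X = a``;
    ``pair_counts[(X, Y)][c, a, b]`` counts records with class ``c``, ``X = a``
    and ``Y = b`` (pairs keyed in canonical schema order).  All tensors are
    dense over the (harmonized) state space, zero-filled for locally unseen
    states, so that statistics from different stations are directly addable.
    """

    schema: DatasetSchema
    n: int
    class_counts: np.ndarray
    single_counts: dict[str, np.ndarray]
    pair_counts: dict[tuple[str, str], np.ndarray]

    @classmethod
    def zeros(cls, schema: DatasetSchema) -> "SufficientStatistics":
        C = schema.class_var.n_states
        feats = schema.feature_vars
        singles = {v.name: np.zeros((C, v.n_states), dtype=np.int64) for v in feats}
        pairs = {}
        for i, vi in enumerate(feats):
            for vj in feats[i + 1 :]:
                pairs[(vi.name, vj.name)] = np.zeros(
                    (C, vi.n_states, vj.n_states), dtype=np.int64
                )
        return cls(schema, 0, np.zeros(C, dtype=np.int64), singles, pairs)

    def pair(self, xi: str, xj: str) -> np.ndarray:
        """Pair tensor with axes (class, xi, xj) regardless of stored order."""
        key = _pair_key(self.schema, xi, xj)
        t = self.pair_counts[key]
        return t if key == (xi, xj) else t.transpose(0, 2, 1)

    def __add__(self, other: "SufficientStatistics") -> "SufficientStatistics":
        if self.schema.canonical_json() != other.schema.canonical_json():
            raise ValueError("cannot add statistics over different schemas")
        return SufficientStatistics(
            self.schema,
            self.n + other.n,
            self.class_counts + other.class_counts,
            {k: v + other.single_counts[k] for k, v in self.single_counts.items()},
            {k: v + other.pair_counts[k] for k, v in self.pair_counts.items()},
        )

    def validate(self) -> None:
        """Check marginal consistency of all tensors (raises on violation)."""
        if int(self.class_counts.sum()) != self.n:
            raise ValueError("class_counts do not sum to n")
        if (self.class_counts < 0).any():
            raise ValueError("negative class counts")
        for name, t in self.single_counts.items():
            if (t < 0).any():
                raise ValueError(f"negative counts for {name}")
            if not np.array_equal(t.sum(axis=1), self.class_counts):
                raise ValueError(f"single counts for {name} inconsistent with class counts")
        for (ni, nj), t in self.pair_counts.items():
            if not np.array_equal(t.sum(axis=2), self.single_counts[ni]):
                raise ValueError(f"pair ({ni},{nj}) inconsistent with singles of {ni}")
            if not np.array_equal(t.sum(axis=1), self.single_counts[nj]):
                raise ValueError(f"pair ({ni},{nj}) inconsistent with singles of {nj}")

    # -- canonical JSON payload (the federation wire format) --

    def to_payload(self) -> dict:
        def tensor(t: np.ndarray) -> dict:
            return {"shape": list(t.shape), "counts": t.ravel(order="C").tolist()}

        return {
            "n": int(self.n),
            "class_counts": self.class_counts.tolist(),
            "single_counts": {k: tensor(v) for k, v in sorted(self.single_counts.items())},
            "pair_counts": {
                f"{a}␟{b}": tensor(t) for (a, b), t in sorted(self.pair_counts.items())
            },
        }

    @classmethod
    def from_payload(cls, payload: dict, schema: DatasetSchema) -> "SufficientStatistics":
        def untensor(d: dict) -> np.ndarray:
            return np.asarray(d["counts"], dtype=np.int64).reshape(d["shape"])

        singles = {k: untensor(v) for k, v in payload["single_counts"].items()}
        pairs = {}
        for key, v in payload["pair_counts"].items():
            a, b = key.split("␟")
            pairs[(a, b)] = untensor(v)
        return cls(
            schema,
            int(payload["n"]),
            np.asarray(payload["class_counts"], dtype=np.int64),
            singles,
            pairs,
        )


def compute_sufficient_statistics(
    data: StationDataset, schema: DatasetSchema | None = None
) -> SufficientStatistics:
    """Exact contingency counts of ``data`` over ``schema`` (default: its own).

    Tensors are dense over the full state space; states never observed locally
    get zero counts.  A record value outside the schema is a hard error —
    ingestion is responsible for filtering.
    """
    if schema is None:
        schema = data.schema
    if data.schema is not schema and data.schema.canonical_json() != schema.canonical_json():
        data = data.with_schema(schema)
    stats = SufficientStatistics.zeros(schema)
    if not data.records:
        return stats
    cls = schema.class_var
    ci = schema.index_of(cls.name)
    cls_idx = cls.state_index()
    feats = schema.feature_vars
    fidx = {v.name: (schema.index_of(v.name), v.state_index()) for v in feats}

    n = len(data.records)
    c_codes = np.fromiter((cls_idx[r[ci]] for r in data.records), dtype=np.int64, count=n)
    f_codes = {}
    for v in feats:
        col, smap = fidx[v.name]
        f_codes[v.name] = np.fromiter(
            (smap[r[col]] for r in data.records), dtype=np.int64, count=n
        )

    stats.n = n
    np.add.at(stats.class_counts, c_codes, 1)
    for v in feats:
        np.add.at(stats.single_counts[v.name], (c_codes, f_codes[v.name]), 1)
    for (a, b), t in stats.pair_counts.items():
        np.add.at(t, (c_codes, f_codes[a], f_codes[b]), 1)
    return stats


def conditional_mutual_information(stats: SufficientStatistics, xi: str, xj: str) -> float:
    """Plug-in class-conditional mutual information I(Xi; Xj | C) in nats.

    Computed as  sum_{c,a,b} (N_cab / N) * ln( N_cab * N_c / (N_ca * N_cb) ),
    with zero-count cells contributing zero.  Symmetric in its arguments and
    non-negative (tiny negatives from floating rounding are clamped to 0).
    """
    if xi == xj:
        raise ValueError("conditional mutual information requires two distinct features")
    if stats.n <= 0:
        raise ValueError("statistics are empty (n = 0)")
    N = float(stats.n)
    N_cab = stats.pair(xi, xj).astype(float)  # (C, a, b)
    N_c = stats.class_counts.astype(float)[:, None, None]
    N_ca = stats.single_counts[xi].astype(float)[:, :, None]
    N_cb = stats.single_counts[xj].astype(float)[:, None, :]
    mask = N_cab > 0
    ratio = np.ones_like(N_cab)
    np.divide(N_cab * N_c, N_ca * N_cb, out=ratio, where=mask)
    val = float(np.sum(np.where(mask, (N_cab / N) * np.log(ratio), 0.0)))
    return max(val, 0.0)


@dataclass(frozen=True)
class TANStructure:
    """TAN topology: class variable, tree root, directed feature-tree edges.

    Every feature has the class as a parent; every non-root feature
    additionally has exactly one feature parent, ``tree_edges`` forming a
    directed tree rooted at ``root`` spanning all features.
    """

    class_var: str
    root: str
    tree_edges: tuple[tuple[str, str], ...]  # (parent, child), oriented away from root

    @property
    def feature_parent(self) -> dict[str, str | None]:
        pm: dict[str, str | None] = {self.root: None}
        for p, c in self.tree_edges:
            pm[c] = p
        return pm

    @property
    def features(self) -> tuple[str, ...]:
        names = {self.root}
        for p, c in self.tree_edges:
            names.add(p)
            names.add(c)
        return tuple(sorted(names))

    def topological_order(self) -> list[str]:
        """Features root-first, children after parents (BFS order)."""
        children: dict[str, list[str]] = {}
        for p, c in self.tree_edges:
            children.setdefault(p, []).append(c)
        order, queue = [], [self.root]
        while queue:
            node = queue.pop(0)
            order.append(node)
            queue.extend(sorted(children.get(node, [])))
        return order

    def validate(self, schema: DatasetSchema) -> None:
        feats = [v.name for v in schema.feature_vars]
        if set(self.features) != set(feats):
            raise ValueError("structure does not span the schema's features")
        if len(self.tree_edges) != len(feats) - 1:
            raise ValueError("tree must have n_features - 1 edges")
        pm = self.feature_parent
        if len(pm) != len(feats):
            raise ValueError("a feature has more than one feature parent")


def learn_tan_structure(stats: SufficientStatistics, root: str | None = None) -> TANStructure:
    """Maximum-weight spanning tree over features with CMI edge weights.

    Kruskal's algorithm with ties broken by the lexicographic edge key
    ``(min name, max name)``; zero-weight edges remain eligible so the result
    is always a spanning tree.  The root defaults to the first feature in
    canonical schema order and edges are oriented away from it by
    breadth-first traversal.
    """
    schema = stats.schema
    feats = [v.name for v in schema.feature_vars]
    if len(feats) < 2:
        raise ValueError(
            "TAN needs at least 2 feature variables (plain naive Bayes is out of scope)"
        )
    if root is None:
        root = feats[0]
    if root not in feats:
        raise ValueError(f"root {root!r} is not a feature variable")

    edges = []
    for i, a in enumerate(feats):
        for b in feats[i + 1 :]:
            w = conditional_mutual_information(stats, a, b)
            key = (min(a, b), max(a, b))
            edges.append((w, key, a, b))
    edges.sort(key=lambda e: (-e[0], e[1]))

    parent = {f: f for f in feats}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    undirected: dict[str, set[str]] = {f: set() for f in feats}
    taken = 0
    for w, key, a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            undirected[a].add(b)
            undirected[b].add(a)
            taken += 1
            if taken == len(feats) - 1:
                break

    directed: list[tuple[str, str]] = []
    seen = {root}
    queue = [root]
    while queue:
        node = queue.pop(0)
        for nb in sorted(undirected[node]):
            if nb not in seen:
                seen.add(nb)
                directed.append((node, nb))
                queue.append(nb)
    return TANStructure(schema.class_var.name, root, tuple(directed))


@dataclass
class CPT:
    """Conditional probability table of ``child`` given ``parents``.

    ``table`` is indexed ``[parent states..., child state]`` with axes in
    ``parents`` order followed by the child axis; every row (fixed parent
    configuration) sums to 1.
    """

    child: str
    parents: tuple[str, ...]
    table: np.ndarray

    def validate(self) -> None:
        rows = self.table.reshape(-1, self.table.shape[-1])
        if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"CPT rows of {self.child!r} do not sum to 1")
        if (self.table < 0).any():
            raise ValueError(f"CPT of {self.child!r} has negative entries")


@dataclass
class TANModel:
    """A fitted TAN classifier: structure, class prior and per-feature CPTs."""

    schema: DatasetSchema
    structure: TANStructure
    class_prior: CPT
    cpts: dict[str, CPT]
    iss: float = 1.0

    def validate(self) -> None:
        self.structure.validate(self.schema)
        self.class_prior.validate()
        pm = self.structure.feature_parent
        for name, cpt in self.cpts.items():
            cpt.validate()
            expected = (
                (self.structure.class_var,)
                if pm[name] is None
                else (self.structure.class_var, pm[name])
            )
            if cpt.parents != expected:
                raise ValueError(f"CPT parents of {name!r} do not match the structure")


def fit_parameters_bayes(
    stats: SufficientStatistics, structure: TANStructure, iss: float = 1.0
) -> TANModel:
    """Posterior-mean (Dirichlet / "Bayes") parameter estimation.

    Each CPT cell is  theta(k | pa) = (N(k, pa) + iss/(r*q)) / (N(pa) + iss/q)
    where ``r`` is the child's state count and ``q`` the number of parent
    configurations; the class prior uses q = 1.  The imaginary sample size
    ``iss`` is the total pseudo-count of a uniform Dirichlet prior spread over
    the whole CPT: iss -> 0 recovers maximum likelihood, iss -> infinity
    flattens every row to uniform.  All entries are strictly positive when
    iss > 0, which is what lets a station assign mass to a class it never
    observed.
    """
    if iss < 0:
        raise ValueError(f"imaginary sample size must be non-negative, got {iss}")
    schema = stats.schema
    cls = schema.class_var
    C = cls.n_states

    def smooth(counts: np.ndarray) -> np.ndarray:
        r = counts.shape[-1]
        q = int(np.prod(counts.shape[:-1])) if counts.ndim > 1 else 1
        num = counts.astype(float) + iss / (r * q)
        den = counts.sum(axis=-1, keepdims=True).astype(float) + iss / q
        with np.errstate(invalid="ignore", divide="ignore"):
            theta = num / den
        # iss = 0 with an unobserved parent configuration: fall back to uniform
        bad = ~np.isfinite(theta)
        if bad.any():
            theta[bad] = 1.0 / r
        return theta

    prior = CPT(cls.name, (), smooth(stats.class_counts))
    pm = structure.feature_parent
    cpts: dict[str, CPT] = {}
    for v in schema.feature_vars:
        fp = pm[v.name]
        if fp is None:
            counts = stats.single_counts[v.name]  # (C, r)
            cpts[v.name] = CPT(v.name, (cls.name,), smooth(counts))
        else:
            counts = stats.pair(fp, v.name)  # (C, r_parent, r_child)
            cpts[v.name] = CPT(v.name, (cls.name, fp), smooth(counts))
    model = TANModel(schema, structure, prior, cpts, iss=iss)
    model.validate()
    return model


def train_tan(
    data_or_stats: Union[StationDataset, SufficientStatistics],
    iss: float = 1.0,
    root: str | None = None,
) -> TANModel:
    """Structure learning followed by Bayes parameter fitting, in one call."""
    if isinstance(data_or_stats, StationDataset):
        stats = compute_sufficient_statistics(data_or_stats)
    else:
        stats = data_or_stats
    structure = learn_tan_structure(stats, root=root)
    return fit_parameters_bayes(stats, structure, iss=iss)


# ---------------------------------------------------------------- prediction

def _record_values(model: TANModel, record: Union[Mapping[str, str], Sequence[str]]) -> dict[str, str]:
    feats = model.schema.feature_vars
    if isinstance(record, Mapping):
        vals = {}
        for v in feats:
            if v.name not in record:
                raise ValueError(f"record is missing feature {v.name!r}")
            vals[v.name] = record[v.name]
    else:
        record = tuple(record)
        if len(record) == len(model.schema.variables):
            vals = {
                v.name: record[model.schema.index_of(v.name)] for v in feats
            }
        elif len(record) == len(feats):
            vals = {v.name: val for v, val in zip(feats, record)}
        else:
            raise ValueError("record length matches neither the schema nor its features")
    for v in feats:
        if vals[v.name] not in v.states:
            raise ValueError(f"value {vals[v.name]!r} not a state of {v.name!r}")
    return vals


def predict_posterior(
    model: TANModel, record: Union[Mapping[str, str], Sequence[str]]
) -> dict[str, float]:
    """P(class | features), computed in log space and normalized to sum to 1.

    ``record`` is a mapping from feature name to state, a feature tuple in
    canonical order, or a full record tuple (its class value is ignored).
    """
    vals = _record_values(model, record)
    cls = model.schema.class_var
    pm = model.structure.feature_parent
    with np.errstate(divide="ignore"):  # zero-probability cells are legal at iss = 0
        logp = np.log(model.class_prior.table)
        for v in model.schema.feature_vars:
            cpt = model.cpts[v.name]
            k = v.state_index()[vals[v.name]]
            fp = pm[v.name]
            if fp is None:
                logp = logp + np.log(cpt.table[:, k])
            else:
                j = model.schema[fp].state_index()[vals[fp]]
                logp = logp + np.log(cpt.table[:, j, k])
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    return {s: float(pi) for s, pi in zip(cls.states, p)}


def predict_class(model: TANModel, record: Union[Mapping[str, str], Sequence[str]]) -> str:
    """Argmax of the posterior; exact ties go to the first class in canonical order."""
    post = predict_posterior(model, record)
    states = model.schema.class_var.states
    arr = np.array([post[s] for s in states])
    return states[int(np.argmax(arr))]


def predict_proba(model: TANModel, data: StationDataset) -> np.ndarray:
    """Posterior matrix (n_records, n_classes) in canonical class-state order."""
    states = model.schema.class_var.states
    rows = []
    for rec in data.records:
        post = predict_posterior(model, rec)
        rows.append([post[s] for s in states])
    return np.asarray(rows, dtype=float)


# ---------------------------------------------------------------- model JSON

def model_to_json(model: TANModel, path=None) -> str:
    """Serialize a TANModel (structure, states, CPTs, iss, schema hash) to JSON."""
    schema_json = model.schema.canonical_json()
    payload = {
        "format": "fedbn-tan-model",
        "version": 1,
        "schema": json.loads(schema_json),
        "schema_fingerprint": hashlib.sha256(schema_json.encode()).hexdigest(),
        "iss": model.iss,
        "structure": {
            "class_var": model.structure.class_var,
            "root": model.structure.root,
            "tree_edges": [list(e) for e in model.structure.tree_edges],
        },
        "class_prior": model.class_prior.table.tolist(),
        "cpts": {
            name: {
                "parents": list(cpt.parents),
                "shape": list(cpt.table.shape),
                "values": cpt.table.ravel(order="C").tolist(),
            }
            for name, cpt in sorted(model.cpts.items())
        },
    }
    text = json.dumps(payload, sort_keys=True, indent=1)
    if path is not None:
        from pathlib import Path

        Path(path).write_text(text, encoding="utf-8")
    return text


def model_from_json(source) -> TANModel:
    """Inverse of :func:`model_to_json`; accepts a JSON string or file path."""
    from pathlib import Path

    text = source
    if isinstance(source, Path) or (isinstance(source, str) and not source.lstrip().startswith("{")):
        text = Path(source).read_text(encoding="utf-8")
    payload = json.loads(text)
    from fedbn.io import schema_from_json

    schema = schema_from_json(json.dumps(payload["schema"]))
    structure = TANStructure(
        payload["structure"]["class_var"],
        payload["structure"]["root"],
        tuple(tuple(e) for e in payload["structure"]["tree_edges"]),
    )
    prior = CPT(structure.class_var, (), np.asarray(payload["class_prior"], dtype=float))
    cpts = {
        name: CPT(
            name,
            tuple(d["parents"]),
            np.asarray(d["values"], dtype=float).reshape(d["shape"]),
        )
        for name, d in payload["cpts"].items()
    }
    model = TANModel(schema, structure, prior, cpts, iss=float(payload["iss"]))
    model.validate()
    return model
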