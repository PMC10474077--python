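"""Station/coordinator protocol: exact federated TAN training by count pooling.

Stations hold raw records locally and never export them.  What crosses the
station boundary is a versioned JSON message carrying class-conditional
contingency counts over a harmonized state space.  Because those counts are
additive across data partitions, the coordinator's pooled statistics equal
the statistics of the pooled data exactly, and the combined model is
byte-for-byte the model centralized training would produce — federation loses
nothing relative to pooling the data.

A non-default ``average-cpt`` mode is provided for comparison: stations fit
local models and the coordinator averages their parameters.  It is lossy (no
averaging rule recovers the pooled-data model in general) and exists only to
quantify what the count-pooling design buys.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from fedbn.schema import DatasetSchema, StationDataset, harmonize_schemas, observed_schema
from fedbn.tan import (
    CPT,
    SufficientStatistics,
    TANModel,
    compute_sufficient_statistics,
    fit_parameters_bayes,
    learn_tan_structure,
)

logger = logging.getLogger("fedbn")

PROTOCOL_VERSION = 1


def schema_fingerprint(schema: DatasetSchema) -> str:
    """SHA-256 of the canonical schema JSON; the handshake token."""
    return hashlib.sha256(schema.canonical_json().encode()).hexdigest()


@dataclass
class StationNode:
    """A data station: local records plus a disclosure policy.

    ``min_cell_count`` > 0 makes the station refuse to export statistics when
    any class would be revealed with a small positive count (a count in
    ``(0, threshold)`` identifies near-unique records); refusal is all-or-
    nothing — counts are never perturbed.
    """

    station_id: str
    data: StationDataset
    min_cell_count: int = 0


@dataclass
class StatsMessage:
    """The only payload that crosses the station boundary: counts, not records."""

    station_id: str
    schema_fingerprint: str
    payload: dict
    protocol_version: int = PROTOCOL_VERSION

    def to_json(self) -> str:
        return json.dumps(
            {
                "protocol_version": self.protocol_version,
                "station_id": self.station_id,
                "schema_fingerprint": self.schema_fingerprint,
                "payload": self.payload,
            },
            sort_keys=True,
            separators=(",", ":"),
        )

    @classmethod
    def from_json(cls, text: str) -> "StatsMessage":
        d = json.loads(text)
        return cls(
            d["station_id"], d["schema_fingerprint"], d["payload"], d["protocol_version"]
        )


@dataclass
class Refusal:
    """A station declining to contribute (policy violation)."""

    station_id: str
    reason: str


@dataclass
class CoordinatorState:
    """What the coordinator accumulates: schema, messages, pooled counts."""

    harmonized: DatasetSchema
    messages: dict[str, StatsMessage] = field(default_factory=dict)
    pooled: SufficientStatistics | None = None

    def receive(self, msg: StatsMessage) -> None:
        expected = schema_fingerprint(self.harmonized)
        if msg.schema_fingerprint != expected:
            raise ValueError(
                f"station {msg.station_id!r} sent statistics over a different schema"
            )
        self.messages[msg.station_id] = msg
        stats = SufficientStatistics.from_payload(msg.payload, self.harmonized)
        self.pooled = stats if self.pooled is None else self.pooled + stats


def station_local_schema(node: StationNode) -> DatasetSchema:
    """Handshake step: variable names and observed state lists only, no counts."""
    return observed_schema(node.data)


def station_compute_stats(node: StationNode, harmonized: DatasetSchema) -> StatsMessage | Refusal:
    """Compute this station's statistics over the harmonized state space.

    With ``min_cell_count`` t > 0, any class count strictly between 0 and t
    triggers a :class:`Refusal` instead of a message — small positive counts
    pinpoint individual records, and the policy forbids perturbing them.
    """
    stats = compute_sufficient_statistics(node.data, harmonized)
    t = node.min_cell_count
    if t > 0:
        small = [
            s
            for s, c in zip(harmonized.class_var.states, stats.class_counts.tolist())
            if 0 < c < t
        ]
        if small:
            reason = f"class counts below threshold {t}: {small}"
            logger.warning("station %s refuses to contribute: %s", node.station_id, reason)
            return Refusal(node.station_id, reason)
    return StatsMessage(node.station_id, schema_fingerprint(harmonized), stats.to_payload())


def aggregate_statistics(
    messages: list[StatsMessage], schema: DatasetSchema
) -> SufficientStatistics:
    """Elementwise sum of all stations' count tensors (order-independent)."""
    if not messages:
        raise ValueError("no statistics messages to aggregate")
    expected = schema_fingerprint(schema)
    for msg in messages:
        if msg.schema_fingerprint != expected:
            raise ValueError(
                f"schema fingerprint mismatch from station {msg.station_id!r}"
            )
    total = SufficientStatistics.zeros(schema)
    for msg in messages:
        total = total + SufficientStatistics.from_payload(msg.payload, schema)
    return total


def coordinator_train_combined(
    messages: list[StatsMessage],
    schema: DatasetSchema,
    iss: float = 1.0,
    root: str | None = None,
) -> TANModel:
    """Learn the combined TAN from pooled statistics (deterministic)."""
    pooled = aggregate_statistics(messages, schema)
    structure = learn_tan_structure(pooled, root=root)
    return fit_parameters_bayes(pooled, structure, iss=iss)


def _average_cpt_combine(
    nodes: list[StationNode], harmonized: DatasetSchema, iss: float, root: str | None,
    audit: dict,
) -> TANModel:
    # Lossy comparison mode.  Round 1: stations fit local models; the
    # coordinator adopts the structure of the largest station.  Round 2:
    # stations refit parameters under that shared structure; the coordinator
    # averages CPTs weighted by local sample size.
    local_stats = {nd.station_id: compute_sufficient_statistics(nd.data, harmonized) for nd in nodes}
    sizes = {sid: st.n for sid, st in local_stats.items()}
    largest = max(nodes, key=lambda nd: (sizes[nd.station_id], -nodes.index(nd)))
    structure = learn_tan_structure(local_stats[largest.station_id], root=root)
    total_n = sum(sizes.values())
    weights = {sid: sizes[sid] / total_n for sid in sizes}
    locals_ = {}
    for nd in nodes:
        model = fit_parameters_bayes(local_stats[nd.station_id], structure, iss=iss)
        from fedbn.tan import model_to_json

        text = model_to_json(model)
        audit["messages_serialized"].append(text)
        audit["events"].append(
            {"event": "model", "station": nd.station_id, "bytes": len(text)}
        )
        locals_[nd.station_id] = model
    prior = sum(weights[s] * locals_[s].class_prior.table for s in weights)
    prior = prior / prior.sum()
    cpts = {}
    for v in harmonized.feature_vars:
        table = sum(weights[s] * locals_[s].cpts[v.name].table for s in weights)
        table = table / table.sum(axis=-1, keepdims=True)
        cpts[v.name] = CPT(v.name, locals_[largest.station_id].cpts[v.name].parents, table)
    return TANModel(harmonized, structure, CPT(harmonized.class_var.name, (), prior), cpts, iss=iss)


def run_federation(
    stations: list[StationNode | StationDataset],
    iss: float = 1.0,
    root: str | None = None,
    combine: str = "pool-stats",
) -> tuple[TANModel, dict]:
    """Orchestrate a full federated training round.

    Handshake (observed schemas) -> harmonize -> per-station statistics ->
    aggregate -> train.  Returns the combined model and an audit log with the
    exact serialized bytes exchanged, message sizes, and which stations
    contributed or refused.  Raw records never appear in any serialized
    message.
    """
    nodes = [
        nd if isinstance(nd, StationNode) else StationNode(nd.station_id, nd)
        for nd in stations
    ]
    if not nodes:
        raise ValueError("run_federation needs at least one station")
    audit: dict = {"events": [], "messages_serialized": [], "contributing": [], "refused": []}

    local_schemas = []
    for nd in nodes:
        sch = station_local_schema(nd)
        text = sch.canonical_json()
        audit["messages_serialized"].append(text)
        audit["events"].append({"event": "handshake", "station": nd.station_id, "bytes": len(text)})
        local_schemas.append(sch)
    harmonized = harmonize_schemas(local_schemas)
    audit["schema_fingerprint"] = schema_fingerprint(harmonized)

    if combine == "average-cpt":
        model = _average_cpt_combine(nodes, harmonized, iss, root, audit)
        audit["contributing"] = [nd.station_id for nd in nodes]
        return model, audit

    if combine != "pool-stats":
        raise ValueError(f"unknown combine mode {combine!r}")

    messages = []
    for nd in nodes:
        result = station_compute_stats(nd, harmonized)
        if isinstance(result, Refusal):
            audit["refused"].append(nd.station_id)
            audit["events"].append(
                {"event": "refusal", "station": nd.station_id, "reason": result.reason}
            )
            continue
        text = result.to_json()
        audit["messages_serialized"].append(text)
        audit["events"].append(
            {"event": "stats", "station": nd.station_id, "bytes": len(text)}
        )
        messages.append(result)
        audit["contributing"].append(nd.station_id)
    if not messages:
        raise RuntimeError("all stations refused; no statistics to train on")
    model = coordinator_train_combined(messages, harmonized, iss=iss, root=root)
    return model, audit
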