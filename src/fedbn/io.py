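"""Reading and writing station datasets: CSV (RFC 4180), minimal RDF, schema JSON.

CSV is the canonical on-disk format (comma-separated, UTF-8, header row,
RFC 4180 quoting).  A station may instead publish its records as RDF triples;
:func:`read_rdf_station` flattens one-subject-per-record triples into the same
tabular schema via a predicate map (predicate IRI -> variable name).
Records with missing or out-of-schema values are rejected at read time,
counted, and logged — the downstream model is complete-data only.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Mapping, Union

from fedbn import _rdf
from fedbn.schema import DatasetSchema, Record, StationDataset, VariableSpec

logger = logging.getLogger("fedbn")


# ---------------------------------------------------------------- CSV

def read_csv_dataset(
    path: Union[str, Path],
    schema: Union[DatasetSchema, str] = "infer",
    station_id: str = "",
    class_var: str | None = None,
) -> StationDataset:
    """Read a station's records from CSV.

    Parameters
    ----------
    path
        CSV file with a header row naming the variables.
    schema
        Explicit :class:`DatasetSchema`, or ``"infer"`` to build one from the
        file (states = sorted distinct values per column; ``class_var`` names
        the column given the class role).
    station_id
        Label attached to the resulting dataset.
    class_var
        Required when ``schema="infer"``.

    Records whose values fall outside the declared schema, or that have
    missing values, are rejected with a logged warning carrying the row
    number; the count is available as ``dataset.n_rejected``.  A missing
    required column is a hard error; an empty file yields an empty dataset.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        rows = list(reader)
    if not rows:
        if schema == "infer":
            raise ValueError(f"{path}: cannot infer a schema from an empty file")
        return StationDataset(station_id, schema, [])
    header = [h.strip() for h in rows[0]]
    body = rows[1:]

    if schema == "infer":
        if class_var is None:
            raise ValueError("schema='infer' requires class_var naming the class column")
        if class_var not in header:
            raise ValueError(f"{path}: missing required column {class_var!r}")
        cols: dict[str, set[str]] = {h: set() for h in header}
        for row in body:
            for h, v in zip(header, row):
                if v != "":
                    cols[h].add(v)
        specs = tuple(
            VariableSpec(h, tuple(sorted(cols[h])), "class" if h == class_var else "feature")
            for h in header
        )
        schema = DatasetSchema(specs)

    col_idx = {}
    for v in schema.variables:
        if v.name not in header:
            raise ValueError(f"{path}: missing required column {v.name!r}")
        col_idx[v.name] = header.index(v.name)

    records: list[Record] = []
    n_rejected = 0
    for rownum, row in enumerate(body, start=2):  # 1-based incl. header
        if not any(cell != "" for cell in row):
            continue  # blank line
        rec, bad = [], None
        for v in schema.variables:
            val = row[col_idx[v.name]].strip() if col_idx[v.name] < len(row) else ""
            if val == "":
                bad = f"missing value for {v.name!r}"
                break
            if val not in v.states:
                bad = f"value {val!r} outside declared states of {v.name!r}"
                break
            rec.append(val)
        if bad is not None:
            n_rejected += 1
            logger.warning("%s row %d rejected: %s", path.name, rownum, bad)
            continue
        records.append(tuple(rec))
    return StationDataset(station_id, schema, records, provenance=str(path), n_rejected=n_rejected)


def write_csv_dataset(data: StationDataset, path: Union[str, Path]) -> None:
    """Write records as RFC 4180 CSV with a header row, in record order."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(data.schema.variable_names)
        writer.writerows(data.records)


# ---------------------------------------------------------------- RDF

def read_rdf_station(
    path: Union[str, Path],
    predicate_map: Mapping[str, str],
    schema: DatasetSchema,
    station_id: str = "",
) -> StationDataset:
    """Flatten per-subject RDF triples into tabular records.

    ``predicate_map`` maps predicate IRIs to schema variable names and must
    cover every schema variable.  Each distinct subject carrying all mapped
    predicates becomes one record; subjects missing a mapped predicate, or
    holding two conflicting values for one, are rejected and counted.
    Literal objects are used verbatim; IRI objects fall back to their local
    name (text after the last ``#`` or ``/``) when the full IRI is not a
    declared state — ontology terms are treated as opaque identifiers.
    """
    path = Path(path)
    missing = [v.name for v in schema.variables if v.name not in predicate_map.values()]
    if missing:
        raise ValueError(f"predicate_map does not cover schema variables: {missing}")
    try:
        triples = _rdf.parse_triples(path.read_text(encoding="utf-8"))
    except _rdf.RDFParseError as exc:
        raise ValueError(f"{path}: unparseable RDF: {exc}") from exc

    subjects: dict[str, dict[str, str]] = {}
    conflicted: set[str] = set()
    order: list[str] = []
    for t in triples:
        var = predicate_map.get(t.predicate)
        if var is None:
            logger.debug("ignoring unmapped predicate %s", t.predicate)
            continue
        if t.obj_is_literal:
            val = t.obj
        else:
            val = t.obj if t.obj in schema[var].states else t.obj.rstrip("/#").rsplit("#", 1)[-1].rsplit("/", 1)[-1]
        if t.subject not in subjects:
            subjects[t.subject] = {}
            order.append(t.subject)
        seen = subjects[t.subject].get(var)
        if seen is not None and seen != val:
            conflicted.add(t.subject)
        subjects[t.subject][var] = val

    records: list[Record] = []
    n_rejected = 0
    for subj in order:
        vals = subjects[subj]
        if subj in conflicted:
            n_rejected += 1
            logger.warning("subject %s rejected: conflicting values", subj)
            continue
        if any(v.name not in vals for v in schema.variables):
            n_rejected += 1
            logger.warning("subject %s rejected: missing mapped predicate(s)", subj)
            continue
        rec = []
        bad = None
        for v in schema.variables:
            val = vals[v.name]
            if val not in v.states:
                bad = f"value {val!r} outside declared states of {v.name!r}"
                break
            rec.append(val)
        if bad is not None:
            n_rejected += 1
            logger.warning("subject %s rejected: %s", subj, bad)
            continue
        records.append(tuple(rec))
    return StationDataset(station_id, schema, records, provenance=str(path), n_rejected=n_rejected)


def write_rdf_dataset(
    data: StationDataset,
    path: Union[str, Path],
    predicate_map: Mapping[str, str],
    subject_prefix: str = "urn:record:",
) -> None:
    """Emit a dataset as N-Triples (inverse of :func:`read_rdf_station`).

    Mainly used for round-trip checks and for stations that publish RDF.
    """
    inv = {var: pred for pred, var in predicate_map.items()}
    triples = []
    for i, rec in enumerate(data.records):
        subj = f"{subject_prefix}{i}"
        for v, val in zip(data.schema.variables, rec):
            triples.append(_rdf.Triple(subj, inv[v.name], val, True))
    Path(path).write_text(_rdf.emit_ntriples(triples), encoding="utf-8")


def load_predicate_map(path: Union[str, Path]) -> dict[str, str]:
    """Load a predicate-map config block (YAML or JSON: predicate IRI -> variable)."""
    import yaml

    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: predicate map must be a mapping")
    return {str(k): str(v) for k, v in data.items()}


# ---------------------------------------------------------------- schema JSON

def schema_to_json(schema: DatasetSchema, path: Union[str, Path, None] = None) -> str:
    """Serialize a schema to (canonical) JSON; optionally write it to ``path``."""
    text = schema.canonical_json()
    if path is not None:
        Path(path).write_text(text + "\n", encoding="utf-8")
    return text


def schema_from_json(source: Union[str, Path]) -> DatasetSchema:
    """Read a schema from a JSON string or file path."""
    if isinstance(source, Path) or (isinstance(source, str) and not source.lstrip().startswith("[")):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source
    payload = json.loads(text)
    specs = tuple(
        VariableSpec(item["name"], tuple(item["states"]), item["role"]) for item in payload
    )
    return DatasetSchema(specs)
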