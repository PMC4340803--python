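"""Readers and writers for the model, trace and query dialects.

Models, traces and queries travel as JSON (schemas shipped under
``medmod/schemas/``); traces additionally round-trip through a flat CSV
event-log dialect (RFC 4180) with one column per declared attribute.
Parsing is separated from validation: a structurally well-formed document
always loads, and semantic problems (a missing master flag, a bad causal
link) are reported by the validators — so load errors always mean the
document itself is broken, and carry a JSON-pointer-style path to the
offending element.

All writers are deterministic — fixed key order, repr-precision floats —
so golden-file comparisons are exact.
"""

from __future__ import annotations

import csv
import json
from datetime import datetime
from pathlib import Path

from .errors import LoadError, StructureError
from .model import (
    COMPOSITION,
    EDGE_KINDS,
    EXTENSION,
    ActivityDef,
    AttributeDef,
    Edge,
    EnumerationDef,
    ProcessModel,
)
from .query import (
    ComparisonCondition,
    GroupingDef,
    IntervalDef,
    PartitionCondition,
    Query,
    Retrieval,
    SliceAggregateCondition,
)
from .trace import CausalLink, Dataset, Instance, Slice

TRACE_CSV_FIXED_COLUMNS = (
    "slice_id",
    "instance_id",
    "activity",
    "start_time",
    "end_time",
    "caused_by_id",
    "caused_by_kind",
)


def _require(obj, key, pointer, typ=None):
    if not isinstance(obj, dict):
        raise LoadError(f"expected an object, got {type(obj).__name__}", pointer)
    if key not in obj:
        raise LoadError(f"missing required key {key!r}", pointer)
    value = obj[key]
    if typ is not None and not isinstance(value, typ):
        raise LoadError(
            f"{key!r} must be {getattr(typ, '__name__', typ)}, "
            f"got {type(value).__name__}",
            f"{pointer}/{key}",
        )
    return value


def _parse_dt(text, pointer) -> datetime:
    if not isinstance(text, str):
        raise LoadError(f"expected an ISO-8601 timestamp, got {text!r}", pointer)
    try:
        return datetime.fromisoformat(text.replace("Z", "+00:00"))
    except ValueError as exc:
        raise LoadError(f"bad timestamp {text!r}: {exc}", pointer) from exc


def _load_json(path) -> object:
    path = Path(path)
    try:
        with open(path, encoding="utf-8") as fh:
            return json.load(fh)
    except json.JSONDecodeError as exc:
        raise LoadError(f"malformed JSON in {path}: {exc}") from exc


# --------------------------------------------------------------------------
# process models


def model_from_dict(doc) -> ProcessModel:
    name = _require(doc, "name", "", str)
    enums = []
    for i, ed in enumerate(doc.get("enumerations", [])):
        p = f"/enumerations/{i}"
        literals = _require(ed, "literals", p, list)
        if not all(isinstance(x, str) for x in literals):
            raise LoadError("literals must be strings", f"{p}/literals")
        enums.append(EnumerationDef(_require(ed, "name", p, str), tuple(literals)))
    activities = []
    for i, ad in enumerate(doc.get("activities", [])):
        p = f"/activities/{i}"
        attrs = []
        for j, at in enumerate(ad.get("attributes", []) if isinstance(ad, dict) else []):
            pp = f"{p}/attributes/{j}"
            attrs.append(
                AttributeDef(_require(at, "name", pp, str), _require(at, "type", pp, str))
            )
        is_master = ad.get("is_master", False) if isinstance(ad, dict) else False
        if not isinstance(is_master, bool):
            raise LoadError("is_master must be a boolean", f"{p}/is_master")
        activities.append(
            ActivityDef(_require(ad, "name", p, str), tuple(attrs), is_master)
        )
    edges = []
    for i, ed in enumerate(doc.get("edges", [])):
        p = f"/edges/{i}"
        kind = _require(ed, "kind", p, str)
        if kind not in EDGE_KINDS:
            raise LoadError(f"unknown edge kind {kind!r}", f"{p}/kind")
        edges.append(
            Edge(
                kind,
                _require(ed, "source", p, str),
                _require(ed, "target", p, str),
                cardinality=ed.get("cardinality"),
                extension_point=ed.get("extension_point"),
            )
        )
    return ProcessModel(name, tuple(enums), tuple(activities), tuple(edges))


def model_to_dict(model: ProcessModel) -> dict:
    doc = {"name": model.name, "enumerations": [], "activities": [], "edges": []}
    for en in model.enumerations:
        doc["enumerations"].append({"name": en.name, "literals": list(en.literals)})
    for act in model.activities:
        entry = {
            "name": act.name,
            "attributes": [{"name": a.name, "type": a.type} for a in act.attributes],
        }
        if act.is_master:
            entry["is_master"] = True
        doc["activities"].append(entry)
    for e in model.edges:
        entry = {"kind": e.kind, "source": e.source, "target": e.target}
        if e.kind == COMPOSITION and e.cardinality is not None:
            entry["cardinality"] = e.cardinality
        if e.kind == EXTENSION and e.extension_point is not None:
            entry["extension_point"] = e.extension_point
        doc["edges"].append(entry)
    return doc


def read_model(path) -> ProcessModel:
    """Load a process model document; schema problems raise
    :class:`LoadError` naming the offending JSON pointer.  Semantic
    well-formedness is a separate step (``validate_model``)."""
    return model_from_dict(_load_json(path))


def write_model(model: ProcessModel, path) -> None:
    _dump_json(model_to_dict(model), path)


# --------------------------------------------------------------------------
# traces


def _attr_value_from_json(value, typ, model, pointer):
    if value is None:
        return None
    if typ == "DateTime":
        return _parse_dt(value, pointer)
    return value


def dataset_from_dict(doc, model: ProcessModel) -> Dataset:
    slices = []
    seen_ids: set[str] = set()
    for i, sd in enumerate(_require(doc, "slices", "", list)):
        p = f"/slices/{i}"
        slice_id = _require(sd, "slice_id", p, str)
        instances = []
        for j, idoc in enumerate(_require(sd, "instances", p, list)):
            pp = f"{p}/instances/{j}"
            iid = _require(idoc, "instance_id", pp, str)
            if iid in seen_ids:
                raise LoadError(f"duplicate instance_id {iid!r}", pp)
            seen_ids.add(iid)
            activity = _require(idoc, "activity", pp, str)
            act = model.activity(activity)
            if act is None:
                raise LoadError(f"unknown activity {activity!r}", f"{pp}/activity")
            end_raw = idoc.get("end_time")
            caused = idoc.get("caused_by")
            link = None
            if caused is not None:
                link = CausalLink(
                    _require(caused, "predecessor", f"{pp}/caused_by", str),
                    _require(caused, "kind", f"{pp}/caused_by", str),
                )
            attributes = {}
            for name, value in (idoc.get("attributes") or {}).items():
                attr = act.attribute(name)
                typ = attr.type if attr is not None else None
                attributes[name] = _attr_value_from_json(
                    value, typ, model, f"{pp}/attributes/{name}"
                )
            instances.append(
                Instance(
                    instance_id=iid,
                    activity=activity,
                    slice_id=slice_id,
                    start_time=_parse_dt(
                        _require(idoc, "start_time", pp), f"{pp}/start_time"
                    ),
                    end_time=None if end_raw is None else _parse_dt(end_raw, pp),
                    attributes=attributes,
                    caused_by=link,
                )
            )
        slices.append(Slice(slice_id, instances))
    return Dataset(model, slices)


def dataset_to_dict(dataset: Dataset) -> dict:
    doc = {"model": dataset.model.name, "slices": []}
    for s in dataset.slices:
        sd = {"slice_id": s.slice_id, "instances": []}
        for inst in s.instances:
            entry = {
                "instance_id": inst.instance_id,
                "activity": inst.activity,
                "start_time": inst.start_time.isoformat(),
                "end_time": inst.end_time.isoformat() if inst.end_time else None,
            }
            if inst.caused_by is not None:
                entry["caused_by"] = {
                    "predecessor": inst.caused_by.predecessor,
                    "kind": inst.caused_by.kind,
                }
            if inst.attributes:
                entry["attributes"] = {
                    k: (v.isoformat() if isinstance(v, datetime) else v)
                    for k, v in inst.attributes.items()
                }
            sd["instances"].append(entry)
        doc["slices"].append(sd)
    return doc


def trace_attribute_columns(model: ProcessModel) -> list[str]:
    """Attribute columns of the CSV dialect: the union of declared names in
    model order (activities, then declaration order), first occurrence wins."""
    cols: list[str] = []
    for act in model.activities:
        for attr in act.attributes:
            if attr.name not in cols:
                cols.append(attr.name)
    return cols


def _format_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    if isinstance(value, datetime):
        return value.isoformat()
    return str(value)


def _parse_cell(text: str, typ: str, model: ProcessModel, pointer: str):
    if text == "":
        return None
    try:
        if typ == "Integer":
            return int(text)
        if typ == "Real":
            return float(text)
        if typ == "Boolean":
            if text not in ("true", "false"):
                raise ValueError(f"bad boolean {text!r}")
            return text == "true"
        if typ == "DateTime":
            return _parse_dt(text, pointer)
    except ValueError as exc:
        raise LoadError(str(exc), pointer) from exc
    return text  # String / enumeration literals


def write_trace_csv(dataset: Dataset, path) -> None:
    attr_cols = trace_attribute_columns(dataset.model)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(TRACE_CSV_FIXED_COLUMNS) + attr_cols)
        for s in dataset.slices:
            for inst in s.instances:
                link = inst.caused_by
                row = [
                    s.slice_id,
                    inst.instance_id,
                    inst.activity,
                    inst.start_time.isoformat(),
                    inst.end_time.isoformat() if inst.end_time else "",
                    link.predecessor if link else "",
                    link.kind if link else "",
                ]
                for col in attr_cols:
                    row.append(
                        _format_cell(inst.attributes.get(col))
                        if col in inst.attributes
                        else ""
                    )
                writer.writerow(row)


def read_trace_csv(path, model: ProcessModel) -> Dataset:
    attr_cols = trace_attribute_columns(model)
    expected = list(TRACE_CSV_FIXED_COLUMNS) + attr_cols
    slices: dict[str, Slice] = {}
    seen_ids: set[str] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != expected:
            raise LoadError(
                f"unexpected CSV header; expected {expected}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            p = f"/row/{lineno}"
            if len(row) != len(expected):
                raise LoadError(f"expected {len(expected)} cells, got {len(row)}", p)
            (sid, iid, activity, start, end, cb_id, cb_kind), attr_cells = (
                row[:7],
                row[7:],
            )
            act = model.activity(activity)
            if act is None:
                raise LoadError(f"unknown activity {activity!r}", p)
            if iid in seen_ids:
                raise LoadError(f"duplicate instance_id {iid!r}", p)
            seen_ids.add(iid)
            attributes = {}
            for col, cell in zip(attr_cols, attr_cells):
                attr = act.attribute(col)
                if attr is None:
                    if cell != "":
                        raise LoadError(
                            f"value in column {col!r} not declared on {activity!r}",
                            p,
                        )
                    continue
                value = _parse_cell(cell, attr.type, model, f"{p}/{col}")
                if value is not None:
                    attributes[col] = value
            slices.setdefault(sid, Slice(sid, [])).instances.append(
                Instance(
                    instance_id=iid,
                    activity=activity,
                    slice_id=sid,
                    start_time=_parse_dt(start, f"{p}/start_time"),
                    end_time=None if end == "" else _parse_dt(end, f"{p}/end_time"),
                    attributes=attributes,
                    caused_by=CausalLink(cb_id, cb_kind) if cb_id else None,
                )
            )
    return Dataset(model, list(slices.values()))


def read_trace(path, model: ProcessModel) -> Dataset:
    """Load a trace in either dialect, chosen by file extension
    (.csv → event-log CSV, anything else → JSON)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return read_trace_csv(path, model)
    return dataset_from_dict(_load_json(path), model)


def write_trace(dataset: Dataset, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        write_trace_csv(dataset, path)
    else:
        _dump_json(dataset_to_dict(dataset), path)


# --------------------------------------------------------------------------
# queries


def _comparison_from_dict(cd, pointer) -> ComparisonCondition:
    return ComparisonCondition(
        activity=_require(cd, "activity", pointer, str),
        attribute=_require(cd, "attribute", pointer, str),
        op=_require(cd, "op", pointer, str),
        value=_require(cd, "value", pointer),
        combine=cd.get("combine"),
        op2=cd.get("op2"),
        value2=cd.get("value2"),
    )


def query_from_dict(doc) -> Query:
    query = Query()
    for i, cd in enumerate(doc.get("conditions", [])):
        p = f"/conditions/{i}"
        ctype = _require(cd, "type", p, str)
        if ctype == "comparison":
            query.conditions.append(_comparison_from_dict(cd, p))
        elif ctype == "aggregate":
            query.conditions.append(
                SliceAggregateCondition(
                    activity=_require(cd, "activity", p, str),
                    function=_require(cd, "function", p, str),
                    op=_require(cd, "op", p, str),
                    value=_require(cd, "value", p),
                    attribute=cd.get("attribute"),
                )
            )
        else:
            raise LoadError(f"unknown condition type {ctype!r}", f"{p}/type")
    for i, pd_ in enumerate(doc.get("partitions", [])):
        p = f"/partitions/{i}"
        query.partitions.append(
            PartitionCondition(
                activity=_require(pd_, "activity", p, str),
                attribute=_require(pd_, "attribute", p, str),
                direction=_require(pd_, "direction", p, str),
                k=_require(pd_, "k", p, int),
            )
        )
    for i, idd in enumerate(doc.get("intervals", [])):
        p = f"/intervals/{i}"
        pairing = idd.get("pairing") or {}
        query.intervals.append(
            IntervalDef(
                name=_require(idd, "name", p, str),
                start_activity=_require(idd, "start_activity", p, str),
                end_activity=_require(idd, "end_activity", p, str),
                start_attribute=idd.get("start_attribute"),
                end_attribute=idd.get("end_attribute"),
                pairing_start_attribute=pairing.get("start_attribute"),
                pairing_end_attribute=pairing.get("end_attribute"),
            )
        )
    if doc.get("grouping") is not None:
        gd = doc["grouping"]
        query.grouping = GroupingDef(
            activity=_require(gd, "activity", "/grouping", str),
            attribute=_require(gd, "attribute", "/grouping", str),
        )
    for i, rd in enumerate(doc.get("retrievals", [])):
        p = f"/retrievals/{i}"
        kind = _require(rd, "kind", p, str)
        if kind not in ("count", "sum", "average", "table"):
            raise LoadError(f"unknown retrieval kind {kind!r}", f"{p}/kind")
        query.retrievals.append(
            Retrieval(kind, _require(rd, "activity", p, str), rd.get("attribute"))
        )
    return query


def read_query(path) -> Query:
    return query_from_dict(_load_json(path))


# --------------------------------------------------------------------------
# results


def results_to_dict(result) -> dict:
    return {
        "n_slices": len(result.dataset.slices),
        "n_instances": result.dataset.n_instances,
        "activity_counts": dict(result.activity_counts),
        "aggregates": list(result.aggregates),
        "inspection_count": result.inspection_count,
    }


def _dump_json(doc, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, allow_nan=False)
        fh.write("\n")


def write_results(result, path) -> None:
    _dump_json(results_to_dict(result), path)


def write_table_csv(table, path) -> None:
    """Write an instance table as RFC-4180 CSV."""
    table.to_csv(path, index=False, lineterminator="\r\n")
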