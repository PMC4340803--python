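"""Run-time traces: instances, slices, datasets, conformance, time windows.

An *instance* is one concrete execution of an activity — with a start
moment, an end moment (absent while still running), attribute values, and a
causal link to the instance that created it (via a follows, composition,
interruption or extension edge).  The set of all instances reachable from
one master instance is a *slice* (one transaction, e.g. one hospital stay);
slices never share instances.  A *dataset* is a set of disjoint slices and
is the unit every query filters — ``n_instances`` is the ``n`` of the
engine's linear-time guarantee.

Timestamps are timezone-aware instants (ISO-8601 on disk); durations are
reported in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime

from .errors import QueryArgumentError, StructureError
from .model import (
    CARDINALITY_BOUNDS,
    COMPOSITION,
    EDGE_KINDS,
    FOLLOWS,
    INTERRUPTION,
    PRIMITIVE_TYPES,
    ProcessModel,
    Violation,
)


@dataclass(frozen=True)
class CausalLink:
    """Which instance created this one, and over which edge kind."""

    predecessor: str
    kind: str


@dataclass
class Instance:
    instance_id: str
    activity: str
    slice_id: str
    start_time: datetime
    end_time: datetime | None = None
    attributes: dict = field(default_factory=dict)
    caused_by: CausalLink | None = None
    #: derived multi-valued attributes (interval durations, seconds);
    #: attached by the query engine, never serialized, excluded from equality
    derived: dict = field(default_factory=dict, compare=False)


@dataclass
class Slice:
    slice_id: str
    instances: list[Instance] = field(default_factory=list)

    def of_activity(self, name: str) -> list[Instance]:
        return [i for i in self.instances if i.activity == name]

    def __len__(self) -> int:
        return len(self.instances)


@dataclass
class Dataset:
    model: ProcessModel
    slices: list[Slice] = field(default_factory=list)
    #: names of derived attributes (defined intervals) usable in conditions
    derived_names: set = field(default_factory=set, compare=False)

    @property
    def n_instances(self) -> int:
        return sum(len(s) for s in self.slices)

    @property
    def slice_ids(self) -> list[str]:
        return [s.slice_id for s in self.slices]

    def get_slice(self, slice_id: str) -> Slice | None:
        for s in self.slices:
            if s.slice_id == slice_id:
                return s
        return None

    def subset(self, slice_ids) -> "Dataset":
        """A new dataset keeping the given slices, in original order."""
        keep = set(slice_ids)
        return Dataset(
            self.model,
            [s for s in self.slices if s.slice_id in keep],
            set(self.derived_names),
        )


def _value_type_ok(value, type_name: str, model: ProcessModel) -> bool:
    if type_name == "Integer":
        return isinstance(value, int) and not isinstance(value, bool)
    if type_name == "Real":
        return isinstance(value, (int, float)) and not isinstance(value, bool)
    if type_name == "String":
        return isinstance(value, str)
    if type_name == "Boolean":
        return isinstance(value, bool)
    if type_name == "DateTime":
        return isinstance(value, datetime)
    en = model.enumeration(type_name)
    return en is not None and value in en.literals


def validate_trace(dataset: Dataset, model: ProcessModel | None = None) -> list[Violation]:
    """Check a dataset's conformance to its process model.

    Returns one record per violation of:

    T1  slice disjointness (no instance id in two slices, instance slice_id
        fields consistent);
    T2  exactly one master instance per slice, carrying no causal link;
    T3  every non-master instance has a causal link matching an edge of the
        model (same source/target activities and kind);
    T4  follows timing — a successor starts no earlier than its predecessor
        ends (an open-ended predecessor yields a warning, not a violation);
    T5  XOR — an instance is the follows-predecessor of at most one
        successor;
    T6  composition cardinalities respected per aggregate instance;
    T7  interruption — no component of an aggregate instance starts after
        the interrupting instance started;
    T8  attribute values type-check (incl. enumeration membership) and
        start_time <= end_time.

    Dangling causal references raise :class:`StructureError` instead of
    being reported as violations: the trace is then not a checkable object.
    """
    if model is None:
        model = dataset.model
    out: list[Violation] = []
    master = model.master
    master_name = master.name if master is not None else None

    # T1 + structural index
    by_id: dict[str, Instance] = {}
    slice_of: dict[str, str] = {}
    seen_slice_ids: set[str] = set()
    for s in dataset.slices:
        if s.slice_id in seen_slice_ids:
            out.append(Violation("T1", s.slice_id, "duplicate slice id"))
        seen_slice_ids.add(s.slice_id)
        for inst in s.instances:
            if inst.instance_id in by_id:
                out.append(
                    Violation(
                        "T1",
                        inst.instance_id,
                        "instance appears in two slices or twice in one",
                    )
                )
            by_id[inst.instance_id] = inst
            slice_of[inst.instance_id] = s.slice_id
            if inst.slice_id != s.slice_id:
                out.append(
                    Violation(
                        "T1",
                        inst.instance_id,
                        f"instance labelled {inst.slice_id!r} stored in "
                        f"slice {s.slice_id!r}",
                    )
                )

    dangling = [
        i.instance_id
        for s in dataset.slices
        for i in s.instances
        if i.caused_by is not None and i.caused_by.predecessor not in by_id
    ]
    if dangling:
        raise StructureError(
            f"dangling causal predecessor references from: {', '.join(dangling)}"
        )

    edge_set = {(e.kind, e.source, e.target) for e in model.edges}

    for s in dataset.slices:
        # T2
        masters_here = [i for i in s.instances if i.activity == master_name]
        if len(masters_here) != 1:
            out.append(
                Violation(
                    "T2",
                    s.slice_id,
                    f"slice has {len(masters_here)} master instances, expected 1",
                )
            )
        for m in masters_here:
            if m.caused_by is not None:
                out.append(
                    Violation(
                        "T2", m.instance_id, "master instance has a causal link"
                    )
                )

        follows_succ: dict[str, int] = {}
        for inst in s.instances:
            # T8 — timestamps and attribute typing
            if inst.end_time is not None and inst.end_time < inst.start_time:
                out.append(
                    Violation("T8", inst.instance_id, "end_time before start_time")
                )
            act = model.activity(inst.activity)
            if act is None:
                out.append(
                    Violation(
                        "T8", inst.instance_id, f"unknown activity {inst.activity!r}"
                    )
                )
                continue
            for name, value in inst.attributes.items():
                attr = act.attribute(name)
                if attr is None:
                    out.append(
                        Violation(
                            "T8",
                            inst.instance_id,
                            f"undeclared attribute {name!r} on {inst.activity!r}",
                        )
                    )
                elif value is not None and not _value_type_ok(value, attr.type, model):
                    out.append(
                        Violation(
                            "T8",
                            inst.instance_id,
                            f"value {value!r} does not type-check against "
                            f"{attr.type} attribute {name!r}",
                        )
                    )

            # T3 — causal links exist in the model
            if inst.activity == master_name:
                continue
            link = inst.caused_by
            if link is None:
                out.append(
                    Violation(
                        "T3", inst.instance_id, "non-master instance lacks a causal link"
                    )
                )
                continue
            pred = by_id[link.predecessor]
            if slice_of[link.predecessor] != s.slice_id:
                out.append(
                    Violation(
                        "T3",
                        inst.instance_id,
                        "causal predecessor lives in a different slice",
                    )
                )
            if link.kind not in EDGE_KINDS or (
                link.kind,
                pred.activity,
                inst.activity,
            ) not in edge_set:
                out.append(
                    Violation(
                        "T3",
                        inst.instance_id,
                        f"no {link.kind} edge {pred.activity!r} -> "
                        f"{inst.activity!r} in the model",
                    )
                )
                continue

            if link.kind == FOLLOWS:
                follows_succ[link.predecessor] = (
                    follows_succ.get(link.predecessor, 0) + 1
                )
                # T4 — follows timing
                if pred.end_time is None:
                    out.append(
                        Violation(
                            "T4",
                            inst.instance_id,
                            "follows-predecessor has no end time yet",
                            severity="warning",
                        )
                    )
                elif inst.start_time < pred.end_time:
                    out.append(
                        Violation(
                            "T4",
                            inst.instance_id,
                            "successor starts before its predecessor ends",
                        )
                    )

        # T5 — XOR on outgoing follows
        for pred_id, count in follows_succ.items():
            if count > 1:
                out.append(
                    Violation(
                        "T5",
                        pred_id,
                        f"instance has {count} follows-successors, expected <= 1",
                    )
                )

        # T6/T7 — per aggregate instance
        for inst in s.instances:
            comp_edges = model.edges_from(inst.activity, COMPOSITION)
            if comp_edges:
                components = [
                    i
                    for i in s.instances
                    if i.caused_by is not None
                    and i.caused_by.predecessor == inst.instance_id
                    and i.caused_by.kind == COMPOSITION
                ]
                for e in comp_edges:
                    lo, hi = CARDINALITY_BOUNDS.get(e.cardinality or "1", (0, None))
                    got = sum(1 for c in components if c.activity == e.target)
                    if got < lo or (hi is not None and got > hi):
                        out.append(
                            Violation(
                                "T6",
                                inst.instance_id,
                                f"{got} component instances of {e.target!r} "
                                f"violate cardinality {e.cardinality or '1'}",
                            )
                        )
                interrupters = [
                    i
                    for i in s.instances
                    if i.caused_by is not None
                    and i.caused_by.predecessor == inst.instance_id
                    and i.caused_by.kind == INTERRUPTION
                ]
                for b in interrupters:
                    for c in components:
                        if c.start_time > b.start_time:
                            out.append(
                                Violation(
                                    "T7",
                                    c.instance_id,
                                    "component starts after the aggregate "
                                    "was interrupted",
                                )
                            )

    return out


def build_initial_dataset(
    dataset: Dataset, window_start: datetime, window_end: datetime
) -> Dataset:
    """Select the whole slices whose transaction began inside the half-open
    time window ``[window_start, window_end)``.

    Membership is keyed on the master instance's start time — the birth of
    the transaction — so disjoint windows partition the slices and slices
    are never split.
    """
    if not window_start < window_end:
        raise QueryArgumentError(
            f"window start {window_start.isoformat()} must precede "
            f"window end {window_end.isoformat()}"
        )
    master = dataset.model.master
    if master is None:
        raise StructureError("model has no unique master activity")
    keep = []
    for s in dataset.slices:
        roots = s.of_activity(master.name)
        if roots and window_start <= roots[0].start_time < window_end:
            keep.append(s.slice_id)
    return dataset.subset(keep)


def copy_slice(s: Slice) -> Slice:
    """A shallow-per-instance copy safe to annotate with derived values."""
    return Slice(
        s.slice_id,
        [replace(i, derived=dict(i.derived)) for i in s.instances],
    )
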