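"""The PQL engine: filtering conditions, partitions, intervals, grouping and
data retrieval over slice datasets, with instrumented linear-time evaluation.

Filtering works at slice granularity: a condition keeps the *whole* slices
that contain at least one instance satisfying it, mirroring the way a
clinician reasons about transactions ("the patients whose stay contains
..."), and conditions applied in sequence intersect at slice level.  Every
evaluation routine threads an :class:`InspectionCounter`; the engine
guarantees at most ``n`` instance inspections for a comparison or slice
aggregate condition and at most ``k*n`` for a Top/Bottom-k partition, where
``n`` is the number of instances in the dataset it filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import pandas as pd

from .errors import QueryArgumentError, ResolutionError, TypeMismatchError
from .model import PRIMITIVE_TYPES, ProcessModel
from .trace import Dataset, Instance, Slice, copy_slice

# --------------------------------------------------------------------------
# operators

#: comparison operators legal per data type
_ORDER_OPS = ("eq", "ne", "gt", "lt", "ge", "le")
_STRING_OPS = ("eq", "ne", "contains", "begins_with", "ends_with")
_FLAG_OPS = ("eq", "ne")

OPS_BY_TYPE = {
    "Integer": _ORDER_OPS,
    "Real": _ORDER_OPS,
    "DateTime": _ORDER_OPS,
    "String": _STRING_OPS,
    "Boolean": _FLAG_OPS,
}

COUNT_TARGET = "count"  # reserved attribute target: per-slice instance count

DEFAULT_K_MAX = 100


class InspectionCounter:
    """Counts instance inspections, certifying the engine's cost contract."""

    __slots__ = ("total",)

    def __init__(self):
        self.total = 0

    def add(self, n: int = 1) -> None:
        self.total += n


# --------------------------------------------------------------------------
# condition types


@dataclass(frozen=True)
class ComparisonCondition:
    """An attribute-level filter with at most one extra AND/OR term.

    ``attribute`` names a declared attribute of ``activity``, the reserved
    target ``"count"`` (the per-slice number of instances of the activity),
    or a previously defined interval (a derived, possibly multi-valued
    duration in seconds attached to the slice's master instance).
    """

    activity: str
    attribute: str
    op: str
    value: object
    combine: str | None = None  # "and" | "or"
    op2: str | None = None
    value2: object | None = None


@dataclass(frozen=True)
class SliceAggregateCondition:
    """A filter on the per-slice Sum/Average of an attribute or Count of
    instances of one activity."""

    activity: str
    function: str  # "sum" | "average" | "count"
    op: str
    value: float
    attribute: str | None = None  # absent for count


@dataclass(frozen=True)
class PartitionCondition:
    """Top/Bottom-k selection of slices by an attribute's extreme value."""

    activity: str
    attribute: str
    direction: str  # "top" | "bottom"
    k: int


@dataclass(frozen=True)
class IntervalDef:
    """A named duration between two activities' timestamps within a slice.

    Endpoints default to the instances' intrinsic start moments; an optional
    pairing condition restricts pairs to those where a start-instance
    attribute equals an end-instance attribute (e.g. matching procedure
    codes).
    """

    name: str
    start_activity: str
    end_activity: str
    start_attribute: str | None = None
    end_attribute: str | None = None
    pairing_start_attribute: str | None = None
    pairing_end_attribute: str | None = None


@dataclass(frozen=True)
class GroupingDef:
    """Merge slices sharing one attribute value (e.g. a patient surname),
    so intervals may span a patient's multiple transactions."""

    activity: str
    attribute: str


@dataclass(frozen=True)
class Retrieval:
    """One data-retrieval request: ``kind`` is count/sum/average/table."""

    kind: str
    activity: str
    attribute: str | None = None


@dataclass
class Query:
    """An ordered filtering pipeline plus retrieval requests."""

    conditions: list = field(default_factory=list)
    partitions: list = field(default_factory=list)
    intervals: list = field(default_factory=list)
    grouping: GroupingDef | None = None
    retrievals: list = field(default_factory=list)


@dataclass
class QueryResult:
    dataset: Dataset
    activity_counts: dict
    aggregates: list
    tables: dict
    inspection_count: int


# --------------------------------------------------------------------------
# resolution and matching


def _parse_dt(value) -> datetime:
    if isinstance(value, datetime):
        return value
    if isinstance(value, str):
        return datetime.fromisoformat(value.replace("Z", "+00:00"))
    raise TypeMismatchError(f"{value!r} is not a DateTime constant")


def _resolve(model: ProcessModel, dataset: Dataset, activity: str, attribute: str):
    """Resolve a condition target to ``(type_name, kind)`` where kind is
    ``declared``/``count``/``derived``."""
    if model.activity(activity) is None:
        raise ResolutionError(f"unknown activity {activity!r}")
    if attribute == COUNT_TARGET:
        return "Integer", "count"
    typ = model.attribute_type(activity, attribute)
    if typ is not None:
        return typ, "declared"
    if attribute in dataset.derived_names:
        return "Real", "derived"  # interval durations, seconds
    raise ResolutionError(
        f"unknown attribute {attribute!r} on activity {activity!r}"
    )


def _check_op(op: str, typ: str, model: ProcessModel) -> None:
    legal = OPS_BY_TYPE.get(typ, _FLAG_OPS)  # enumerations: eq/ne only
    if op not in legal:
        raise TypeMismatchError(f"operator {op!r} is illegal for type {typ}")


def _coerce_constant(value, typ: str, model: ProcessModel):
    if typ in ("Integer", "Real"):
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise TypeMismatchError(f"{value!r} is not a numeric constant")
        return value
    if typ == "String":
        if not isinstance(value, str):
            raise TypeMismatchError(f"{value!r} is not a string constant")
        return value
    if typ == "Boolean":
        if not isinstance(value, bool):
            raise TypeMismatchError(f"{value!r} is not a boolean constant")
        return value
    if typ == "DateTime":
        return _parse_dt(value)
    en = model.enumeration(typ)
    if en is None:
        raise TypeMismatchError(f"unknown type {typ!r}")
    if value not in en.literals:
        raise TypeMismatchError(
            f"{value!r} is not a literal of enumeration {typ!r}"
        )
    return value


def _term(op: str, actual, constant) -> bool:
    if op == "eq":
        return actual == constant
    if op == "ne":
        return actual != constant
    if op == "gt":
        return actual > constant
    if op == "lt":
        return actual < constant
    if op == "ge":
        return actual >= constant
    if op == "le":
        return actual <= constant
    if op == "contains":
        return constant in actual
    if op == "begins_with":
        return actual.startswith(constant)
    if op == "ends_with":
        return actual.endswith(constant)
    raise TypeMismatchError(f"unknown operator {op!r}")


class _CompiledComparison:
    """A type-checked comparison ready to evaluate on single values.

    Within one two-term condition both terms apply to the same value (the
    same instance), unlike separate conditions which intersect slice-wise.
    """

    def __init__(self, cond: ComparisonCondition, model: ProcessModel, dataset: Dataset):
        self.cond = cond
        self.typ, self.target_kind = _resolve(
            model, dataset, cond.activity, cond.attribute
        )
        _check_op(cond.op, self.typ, model)
        self.value = _coerce_constant(cond.value, self.typ, model)
        if cond.combine is not None:
            if cond.combine not in ("and", "or"):
                raise QueryArgumentError(
                    f"combine must be 'and' or 'or', got {cond.combine!r}"
                )
            if cond.op2 is None:
                raise QueryArgumentError("combine given without a second term")
            _check_op(cond.op2, self.typ, model)
            self.value2 = _coerce_constant(cond.value2, self.typ, model)
        elif cond.op2 is not None:
            raise QueryArgumentError("second term given without combine")

    def on_value(self, actual) -> bool:
        """Evaluate the full (possibly two-term) expression on one value.
        Absent values never match."""
        if actual is None:
            return False
        first = _term(self.cond.op, actual, self.value)
        if self.cond.combine is None:
            return first
        second = _term(self.cond.op2, actual, self.value2)
        return (first and second) if self.cond.combine == "and" else (first or second)

    def on_instance(self, inst: Instance) -> bool:
        if self.target_kind == "derived":
            values = inst.derived.get(self.cond.attribute)
            if not values:
                return False
            return any(self.on_value(v) for v in values)
        return self.on_value(inst.attributes.get(self.cond.attribute))


# --------------------------------------------------------------------------
# filtering operations


def evaluate_comparison(
    dataset: Dataset,
    cond: ComparisonCondition,
    counter: InspectionCounter | None = None,
) -> Dataset:
    """Keep the whole slices containing at least one instance of the named
    activity that satisfies the comparison.

    Scans each slice's instances and stops at the first match, so at most
    ``n`` instances are inspected over the whole dataset.
    """
    counter = counter if counter is not None else InspectionCounter()
    compiled = _CompiledComparison(cond, dataset.model, dataset)
    keep = []
    if compiled.target_kind == "count":
        for s in dataset.slices:
            count = 0
            for inst in s.instances:
                counter.add()
                if inst.activity == cond.activity:
                    count += 1
            if compiled.on_value(count):
                keep.append(s.slice_id)
        return dataset.subset(keep)
    for s in dataset.slices:
        for inst in s.instances:
            counter.add()
            if inst.activity == cond.activity and compiled.on_instance(inst):
                keep.append(s.slice_id)
                break
    return dataset.subset(keep)


def evaluate_slice_aggregate(
    dataset: Dataset,
    cond: SliceAggregateCondition,
    counter: InspectionCounter | None = None,
) -> Dataset:
    """Keep the slices whose per-slice Sum/Average/Count over one activity
    satisfies the comparison.

    A slice with no instance of the activity at all fails the condition
    outright (it does not "contain instances of the filtered type"); for
    Sum/Average, instances lacking the attribute value are excluded from the
    aggregate and a slice with zero valued instances fails too.  Count
    counts every instance of the activity regardless of attribute values.
    """
    counter = counter if counter is not None else InspectionCounter()
    model = dataset.model
    if model.activity(cond.activity) is None:
        raise ResolutionError(f"unknown activity {cond.activity!r}")
    func = cond.function
    if func not in ("sum", "average", "count"):
        raise QueryArgumentError(f"unknown aggregate function {func!r}")
    if func == "count":
        typ = "Integer"
    else:
        if cond.attribute is None:
            raise QueryArgumentError(f"{func} requires an attribute")
        typ = model.attribute_type(cond.activity, cond.attribute)
        if typ is None:
            raise ResolutionError(
                f"unknown attribute {cond.attribute!r} on {cond.activity!r}"
            )
        if typ not in ("Integer", "Real"):
            raise TypeMismatchError(f"{func} requires a numeric attribute, got {typ}")
    _check_op(cond.op, "Real", model)
    if isinstance(cond.value, bool) or not isinstance(cond.value, (int, float)):
        raise TypeMismatchError(f"{cond.value!r} is not a numeric constant")

    keep = []
    for s in dataset.slices:
        n_act = 0
        total = 0.0
        n_valued = 0
        for inst in s.instances:
            counter.add()
            if inst.activity != cond.activity:
                continue
            n_act += 1
            if func != "count":
                v = inst.attributes.get(cond.attribute)
                if v is not None:
                    total += v
                    n_valued += 1
        if n_act == 0:
            continue  # empty-aggregate rule: the slice fails
        if func == "count":
            agg = n_act
        elif n_valued == 0:
            continue
        elif func == "sum":
            agg = total
        else:
            agg = total / n_valued
        if _term(cond.op, agg, cond.value):
            keep.append(s.slice_id)
    return dataset.subset(keep)


def evaluate_partition(
    dataset: Dataset,
    cond: PartitionCondition,
    counter: InspectionCounter | None = None,
    k_max: int = DEFAULT_K_MAX,
) -> Dataset:
    """Return the k slices whose extreme attribute value over instances of
    the named activity is largest (Top) or smallest (Bottom).

    Slices are ranked by their per-slice extreme (max for Top, min for
    Bottom); ties break by slice_id ascending; slices with no valued
    instance are unranked and never returned.  The evaluation streams the
    dataset once, maintaining a bounded candidate list of at most k slices,
    so every instance is compared against at most k list entries — the
    inspection count never exceeds ``k * n``.
    """
    counter = counter if counter is not None else InspectionCounter()
    if cond.k < 1 or cond.k > k_max:
        raise QueryArgumentError(
            f"partition k must lie in [1, {k_max}], got {cond.k}"
        )
    if cond.direction not in ("top", "bottom"):
        raise QueryArgumentError(f"direction must be top or bottom, got {cond.direction!r}")
    model = dataset.model
    if model.activity(cond.activity) is None:
        raise ResolutionError(f"unknown activity {cond.activity!r}")
    typ = model.attribute_type(cond.activity, cond.attribute)
    if typ is None:
        if cond.attribute in dataset.derived_names:
            typ = "Real"
        else:
            raise ResolutionError(
                f"unknown attribute {cond.attribute!r} on {cond.activity!r}"
            )
    if typ not in ("Integer", "Real", "DateTime"):
        raise TypeMismatchError(
            f"partition attribute must be numeric or DateTime, got {typ}"
        )
    top = cond.direction == "top"

    def beats(v1, s1, v2, s2) -> bool:
        # does candidate (v1, s1) outrank list entry (v2, s2)?
        if v1 != v2:
            return v1 > v2 if top else v1 < v2
        return s1 < s2

    # candidate list: ordered best-first, entries (value, slice_id), <= k long
    candidates: list[tuple] = []
    derived_target = model.attribute_type(cond.activity, cond.attribute) is None

    def offer(value, slice_id) -> None:
        """Insert/refresh a slice's extreme; counts one inspection per list
        comparison (at least one per offered instance)."""
        comparisons = 0
        pos = None
        existing = None
        for idx, (v, sid) in enumerate(candidates):
            comparisons += 1
            if sid == slice_id:
                existing = idx
                break
            if pos is None and beats(value, slice_id, v, sid):
                pos = idx
        counter.add(max(comparisons, 1))
        if existing is not None:
            v, sid = candidates[existing]
            if beats(value, slice_id, v, sid):
                del candidates[existing]
                offer_insert(value, slice_id)
            return
        if pos is None:
            if len(candidates) < cond.k:
                candidates.append((value, slice_id))
        else:
            candidates.insert(pos, (value, slice_id))
            if len(candidates) > cond.k:
                candidates.pop()

    def offer_insert(value, slice_id) -> None:
        # re-insert an improved extreme at its correct rank (no extra count:
        # the scan already paid for this instance)
        for idx, (v, sid) in enumerate(candidates):
            if beats(value, slice_id, v, sid):
                candidates.insert(idx, (value, slice_id))
                return
        candidates.append((value, slice_id))

    for s in dataset.slices:
        for inst in s.instances:
            if inst.activity != cond.activity:
                counter.add()
                continue
            if derived_target:
                vals = inst.derived.get(cond.attribute) or []
                if not vals:
                    counter.add()
                    continue
                v = max(vals) if top else min(vals)
            else:
                v = inst.attributes.get(cond.attribute)
                if v is None:
                    counter.add()
                    continue
            offer(v, s.slice_id)

    return dataset.subset(sid for _, sid in candidates)


# --------------------------------------------------------------------------
# intervals and grouping


def compute_intervals(
    slice_: Slice, idef: IntervalDef, model: ProcessModel
) -> list[float]:
    """All duration values (seconds) of a named interval within one slice.

    Start events are the instances of the start activity, timed by the named
    DateTime attribute or, by default, their intrinsic start moment; end
    events likewise.  Without a pairing condition, events are paired
    adjacently in time: each start, in time order, takes the earliest
    not-yet-paired end at or after it.  With a pairing condition, the same
    greedy pairing runs separately inside each class of events whose pairing
    attributes are equal.  Durations are never negative by construction.
    """

    def event_time(inst: Instance, attr: str | None):
        if attr is None:
            return inst.start_time
        typ = model.attribute_type(inst.activity, attr)
        if typ != "DateTime":
            raise TypeMismatchError(
                f"interval endpoint attribute {attr!r} on {inst.activity!r} "
                f"is {typ}, expected DateTime"
            )
        return inst.attributes.get(attr)

    starts = []
    for inst in slice_.of_activity(idef.start_activity):
        t = event_time(inst, idef.start_attribute)
        if t is not None:
            starts.append((t, inst))
    ends = []
    for inst in slice_.of_activity(idef.end_activity):
        t = event_time(inst, idef.end_attribute)
        if t is not None:
            ends.append((t, inst))
    starts.sort(key=lambda p: (p[0], p[1].instance_id))
    ends.sort(key=lambda p: (p[0], p[1].instance_id))

    def key_of(inst: Instance, attr: str | None):
        return True if attr is None else inst.attributes.get(attr)

    durations: list[float] = []
    used: set[int] = set()
    for t_start, s_inst in starts:
        s_key = key_of(s_inst, idef.pairing_start_attribute)
        if s_key is None:
            continue
        for j, (t_end, e_inst) in enumerate(ends):
            if j in used or t_end < t_start:
                continue
            if key_of(e_inst, idef.pairing_end_attribute) != s_key:
                continue
            used.add(j)
            durations.append((t_end - t_start).total_seconds())
            break
    return durations


def attach_intervals(dataset: Dataset, idefs: list[IntervalDef]) -> Dataset:
    """A copy of the dataset whose master instances carry each interval's
    value list as a derived multi-valued attribute, usable in subsequent
    filtering conditions."""
    model = dataset.model
    master = model.master
    seen = set()
    for idef in idefs:
        if idef.name in seen:
            raise QueryArgumentError(f"duplicate interval name {idef.name!r}")
        seen.add(idef.name)
        for act in (idef.start_activity, idef.end_activity):
            if model.activity(act) is None:
                raise ResolutionError(f"unknown activity {act!r}")
    out_slices = []
    for s in dataset.slices:
        cp = copy_slice(s)
        values = {idef.name: compute_intervals(cp, idef, model) for idef in idefs}
        roots = cp.of_activity(master.name) if master is not None else []
        for root in roots[:1]:
            root.derived.update(values)
        out_slices.append(cp)
    out = Dataset(model, out_slices, set(dataset.derived_names))
    out.derived_names.update(idef.name for idef in idefs)
    return out


def group_slices(dataset: Dataset, g: GroupingDef) -> Dataset:
    """Merge slices that share one attribute value into group-slices.

    The grouping key of a slice is the attribute value carried by its
    earliest instance (by start time, then id) of the named activity; a
    slice whose key would be ambiguous is thereby assigned deterministically
    to exactly one group, preserving slice disjointness.  Slices with no
    valued instance of the activity remain singleton groups under their
    original ids.
    """
    model = dataset.model
    if model.activity(g.activity) is None:
        raise ResolutionError(f"unknown activity {g.activity!r}")
    if model.attribute_type(g.activity, g.attribute) is None:
        raise ResolutionError(
            f"unknown attribute {g.attribute!r} on {g.activity!r}"
        )
    groups: dict = {}
    order: list = []  # first-seen key order, for deterministic output
    singletons: list[Slice] = []
    for s in dataset.slices:
        keyed = sorted(
            (
                i
                for i in s.of_activity(g.activity)
                if i.attributes.get(g.attribute) is not None
            ),
            key=lambda i: (i.start_time, i.instance_id),
        )
        if not keyed:
            singletons.append(s)
            continue
        key = keyed[0].attributes[g.attribute]
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(s)
    out_slices: list[Slice] = []
    for key in order:
        members = groups[key]
        if len(members) == 1:
            out_slices.append(members[0])
            continue
        gid = f"group:{key}"
        merged = Slice(gid, [i for s in members for i in s.instances])
        out_slices.append(merged)
    out_slices.extend(singletons)
    return Dataset(model, out_slices, set(dataset.derived_names))


# --------------------------------------------------------------------------
# retrieval


def retrieve_aggregate(
    dataset: Dataset,
    activity: str,
    function: str,
    attribute: str | None = None,
    counter: InspectionCounter | None = None,
):
    """A single number over ALL instances of one activity in the dataset:
    Count of instances, or Sum/Average of an attribute's values (instances
    lacking the value are excluded).  Average of zero valued instances is
    undefined and returned as None; Sum of zero values is 0; Count of an
    empty dataset is 0.
    """
    counter = counter if counter is not None else InspectionCounter()
    model = dataset.model
    if model.activity(activity) is None:
        raise ResolutionError(f"unknown activity {activity!r}")
    if function not in ("count", "sum", "average"):
        raise QueryArgumentError(f"unknown aggregate function {function!r}")
    if function == "count":
        n = 0
        for s in dataset.slices:
            for inst in s.instances:
                counter.add()
                if inst.activity == activity:
                    n += 1
        return n
    if attribute is None:
        raise QueryArgumentError(f"{function} requires an attribute")
    typ = model.attribute_type(activity, attribute)
    if typ is None:
        raise ResolutionError(f"unknown attribute {attribute!r} on {activity!r}")
    if typ not in ("Integer", "Real"):
        raise TypeMismatchError(f"{function} requires a numeric attribute, got {typ}")
    total = 0.0
    n_valued = 0
    for s in dataset.slices:
        for inst in s.instances:
            counter.add()
            if inst.activity != activity:
                continue
            v = inst.attributes.get(attribute)
            if v is not None:
                total += v
                n_valued += 1
    if function == "sum":
        return total
    return (total / n_valued) if n_valued else None


def instance_table(dataset: Dataset, activity: str) -> pd.DataFrame:
    """All instances of one activity in the dataset, one row each.

    Columns: slice_id (of the containing — possibly merged — slice),
    instance_id, start_time, end_time (ISO-8601; empty while open), then the
    activity's declared attributes in model order.  Rows sort by
    (start_time, instance_id).
    """
    model = dataset.model
    act = model.activity(activity)
    if act is None:
        raise ResolutionError(f"unknown activity {activity!r}")
    attr_names = [a.name for a in act.attributes]
    rows = []
    for s in dataset.slices:
        for inst in s.of_activity(activity):
            rows.append((inst.start_time, inst.instance_id, s.slice_id, inst))
    rows.sort(key=lambda r: (r[0], r[1]))
    records = []
    for start, iid, sid, inst in rows:
        rec = {
            "slice_id": sid,
            "instance_id": iid,
            "start_time": start.isoformat(),
            "end_time": inst.end_time.isoformat() if inst.end_time else "",
        }
        for name in attr_names:
            v = inst.attributes.get(name)
            if isinstance(v, datetime):
                v = v.isoformat()
            rec[name] = v
        records.append(rec)
    return pd.DataFrame.from_records(
        records, columns=["slice_id", "instance_id", "start_time", "end_time"] + attr_names
    )


def implication_probability(
    dataset: Dataset,
    cond_a: ComparisonCondition,
    cond_b: ComparisonCondition,
    counter: InspectionCounter | None = None,
):
    """The manually computed association-rule strength: the fraction of
    slices matching condition A that also match condition B, i.e.
    ``|slices(A and B)| / |slices(A)|``; None (undefined) when no slice
    matches A."""
    ds_a = evaluate_comparison(dataset, cond_a, counter)
    if not ds_a.slices:
        return None
    ds_ab = evaluate_comparison(ds_a, cond_b, counter)
    return len(ds_ab.slices) / len(ds_a.slices)


# --------------------------------------------------------------------------
# whole-query execution


def apply_query(
    dataset: Dataset, query: Query, k_max: int = DEFAULT_K_MAX
) -> QueryResult:
    """Execute a full query: comparison and slice-aggregate conditions in
    sequence (slice-level intersection), then each partition on that result
    with the partition outputs intersected, then grouping; retrieval
    requests are evaluated on the final dataset.

    Intervals are attached before filtering so conditions may reference
    interval names; with grouping they are recomputed on the merged
    group-slices, where they may span a patient's multiple transactions.
    """
    counter = InspectionCounter()
    ds = dataset
    if query.intervals:
        ds = attach_intervals(ds, query.intervals)
    for cond in query.conditions:
        if isinstance(cond, ComparisonCondition):
            ds = evaluate_comparison(ds, cond, counter)
        elif isinstance(cond, SliceAggregateCondition):
            ds = evaluate_slice_aggregate(ds, cond, counter)
        else:
            raise QueryArgumentError(f"unknown condition object {cond!r}")
    if query.partitions:
        keep = None
        for part in query.partitions:
            sub = evaluate_partition(ds, part, counter, k_max)
            ids = set(sub.slice_ids)
            keep = ids if keep is None else (keep & ids)
        ds = ds.subset(keep)
    if query.grouping is not None:
        ds = group_slices(ds, query.grouping)
        if query.intervals:
            ds = attach_intervals(ds, query.intervals)

    activity_counts = {}
    for act in dataset.model.activities:
        n = 0
        for s in ds.slices:
            n += len(s.of_activity(act.name))
        activity_counts[act.name] = n

    aggregates = []
    tables = {}
    for req in query.retrievals:
        if req.kind == "table":
            tables[req.activity] = instance_table(ds, req.activity)
        else:
            value = retrieve_aggregate(
                ds, req.activity, req.kind, req.attribute, counter
            )
            aggregates.append(
                {
                    "kind": req.kind,
                    "activity": req.activity,
                    "attribute": req.attribute,
                    "value": value,
                }
            )
    return QueryResult(ds, activity_counts, aggregates, tables, counter.total)
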