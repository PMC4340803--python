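"""Brute-force reference implementations of every filtering operation.

Written as explicit set comprehensions over slices, with full sorts instead
of bounded candidate lists — deliberately independent of the engine's
single-pass evaluation strategy so the two can check each other.
"""

from __future__ import annotations


def term(op, actual, const):
    return {
        "eq": lambda: actual == const,
        "ne": lambda: actual != const,
        "gt": lambda: actual > const,
        "lt": lambda: actual < const,
        "ge": lambda: actual >= const,
        "le": lambda: actual <= const,
        "contains": lambda: const in actual,
        "begins_with": lambda: actual.startswith(const),
        "ends_with": lambda: actual.endswith(const),
    }[op]()


def _full(cond, value):
    if value is None:
        return False
    first = term(cond.op, value, cond.value)
    if cond.combine is None:
        return first
    second = term(cond.op2, value, cond.value2)
    return first and second if cond.combine == "and" else first or second


def comparison_slices(dataset, cond) -> set:
    """Slice ids a comparison condition keeps, by exhaustive scan."""
    if cond.attribute == "count":
        return {
            s.slice_id
            for s in dataset.slices
            if _full(cond, len(s.of_activity(cond.activity)))
        }
    out = set()
    for s in dataset.slices:
        for inst in s.of_activity(cond.activity):
            if cond.attribute in inst.derived:
                if any(_full(cond, v) for v in inst.derived[cond.attribute]):
                    out.add(s.slice_id)
            elif _full(cond, inst.attributes.get(cond.attribute)):
                out.add(s.slice_id)
    return out


def aggregate_slices(dataset, cond) -> set:
    out = set()
    for s in dataset.slices:
        insts = s.of_activity(cond.activity)
        if not insts:
            continue
        if cond.function == "count":
            agg = len(insts)
        else:
            values = [
                i.attributes[cond.attribute]
                for i in insts
                if i.attributes.get(cond.attribute) is not None
            ]
            if not values:
                continue
            agg = sum(values) if cond.function == "sum" else sum(values) / len(values)
        if term(cond.op, agg, cond.value):
            out.add(s.slice_id)
    return out


def partition_slices(dataset, cond) -> set:
    """Top/Bottom-k by per-slice extreme, ties by slice id, via a full sort."""
    extremes = {}
    for s in dataset.slices:
        values = []
        for i in s.of_activity(cond.activity):
            if cond.attribute in i.derived:
                values.extend(i.derived[cond.attribute])
            elif i.attributes.get(cond.attribute) is not None:
                values.append(i.attributes[cond.attribute])
        if values:
            extremes[s.slice_id] = (
                max(values) if cond.direction == "top" else min(values)
            )
    if cond.direction == "top":
        ranked = sorted(extremes, key=lambda sid: (-extremes[sid], sid))
    else:
        ranked = sorted(extremes, key=lambda sid: (extremes[sid], sid))
    return set(ranked[: cond.k])


def implication(dataset, cond_a, cond_b):
    a = comparison_slices(dataset, cond_a)
    if not a:
        return None
    sub = dataset.subset(a)
    ab = comparison_slices(sub, cond_b) & a
    return len(ab) / len(a)


def interval_durations(slice_, idef, model) -> list:
    """Greedy adjacent pairing by explicit enumeration over event pairs."""

    def ev_time(inst, attr):
        return inst.start_time if attr is None else inst.attributes.get(attr)

    def key(inst, attr):
        return True if attr is None else inst.attributes.get(attr)

    starts = sorted(
        (
            (ev_time(i, idef.start_attribute), i)
            for i in slice_.of_activity(idef.start_activity)
            if ev_time(i, idef.start_attribute) is not None
        ),
        key=lambda p: (p[0], p[1].instance_id),
    )
    ends = sorted(
        (
            (ev_time(i, idef.end_attribute), i)
            for i in slice_.of_activity(idef.end_activity)
            if ev_time(i, idef.end_attribute) is not None
        ),
        key=lambda p: (p[0], p[1].instance_id),
    )
    taken = [False] * len(ends)
    out = []
    for t_s, s_inst in starts:
        k_s = key(s_inst, idef.pairing_start_attribute)
        if k_s is None:
            continue
        for j, (t_e, e_inst) in enumerate(ends):
            if taken[j] or t_e < t_s:
                continue
            if key(e_inst, idef.pairing_end_attribute) != k_s:
                continue
            taken[j] = True
            out.append((t_e - t_s).total_seconds())
            break
    return out
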