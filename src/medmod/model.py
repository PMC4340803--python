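"""Metamodel for hospital process diagrams and its well-formedness rules.

A process model is a set of *activities* — task types with a start and an end
moment, optionally carrying typed attributes — connected by four kinds of
oriented edges:

``follows``
    Control flow: the target can only start after the source has ended.
    Several outgoing follows edges from one activity are exclusive (XOR);
    several incoming edges are inclusive (OR).
``composition``
    Containment: the source (*aggregate*) consists of instances of the
    target (*component*), repeated per the declared cardinality.
``interruption``
    Suspension: once the target activity starts, the source may create no
    further component instances; already running components finish normally.
``extension``
    Conditional call: the target may be invoked at some point during the
    execution of the source, guarded by a named extension point.

Exactly one activity is the *master*: every run-time execution of the
diagram starts there, and the master roots one transaction (*slice*).

Attribute types are the five primitives Integer, Real, String, Boolean and
DateTime, or the name of an enumeration declared in the same model (the
hospital domain leans heavily on enumerated procedure/diagnosis codes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

PRIMITIVE_TYPES = frozenset({"Integer", "Real", "String", "Boolean", "DateTime"})

FOLLOWS = "follows"
COMPOSITION = "composition"
INTERRUPTION = "interruption"
EXTENSION = "extension"
EDGE_KINDS = (FOLLOWS, COMPOSITION, INTERRUPTION, EXTENSION)

#: Allowed component cardinalities on composition edges.
CARDINALITIES = ("1", "0..1", "1..*", "*")

#: (min, max) realized-count bounds per cardinality token; None = unbounded.
CARDINALITY_BOUNDS = {"1": (1, 1), "0..1": (0, 1), "1..*": (1, None), "*": (0, None)}


@dataclass(frozen=True)
class EnumerationDef:
    """A closed value set, e.g. a procedure-code or diagnosis codificator."""

    name: str
    literals: tuple[str, ...]


@dataclass(frozen=True)
class AttributeDef:
    """A typed attribute declared on an activity.

    ``type`` is a primitive type name or the name of an enumeration
    declared in the owning model.
    """

    name: str
    type: str


@dataclass(frozen=True)
class ActivityDef:
    name: str
    attributes: tuple[AttributeDef, ...] = ()
    is_master: bool = False

    def attribute(self, name: str) -> AttributeDef | None:
        for a in self.attributes:
            if a.name == name:
                return a
        return None


@dataclass(frozen=True)
class Edge:
    """An oriented relation between two activities.

    ``cardinality`` is meaningful only on composition edges (default "1");
    ``extension_point`` only on extension edges.
    """

    kind: str
    source: str
    target: str
    cardinality: str | None = None
    extension_point: str | None = None


@dataclass(frozen=True)
class Violation:
    """One well-formedness or conformance finding.

    ``severity`` is ``"error"`` or ``"warning"``; only errors make a model
    or trace invalid.
    """

    rule: str
    element: str
    message: str
    severity: str = "error"


@dataclass(frozen=True)
class ProcessModel:
    name: str
    enumerations: tuple[EnumerationDef, ...] = ()
    activities: tuple[ActivityDef, ...] = ()
    edges: tuple[Edge, ...] = ()
    _act_index: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        object.__setattr__(
            self, "_act_index", {a.name: a for a in self.activities}
        )

    # -- lookups -----------------------------------------------------------
    def activity(self, name: str) -> ActivityDef | None:
        return self._act_index.get(name)

    def enumeration(self, name: str) -> EnumerationDef | None:
        for e in self.enumerations:
            if e.name == name:
                return e
        return None

    @property
    def master(self) -> ActivityDef | None:
        """The unique entry activity, or None on an ill-formed model."""
        masters = [a for a in self.activities if a.is_master]
        return masters[0] if len(masters) == 1 else None

    def edges_from(self, activity: str, kind: str | None = None) -> list[Edge]:
        return [
            e
            for e in self.edges
            if e.source == activity and (kind is None or e.kind == kind)
        ]

    def edges_to(self, activity: str, kind: str | None = None) -> list[Edge]:
        return [
            e
            for e in self.edges
            if e.target == activity and (kind is None or e.kind == kind)
        ]

    def is_aggregate(self, activity: str) -> bool:
        """Derived flag: an activity is an aggregate iff it is the source of
        at least one composition edge."""
        return any(e.kind == COMPOSITION and e.source == activity for e in self.edges)

    def attribute_type(self, activity: str, attribute: str) -> str | None:
        act = self.activity(activity)
        if act is None:
            return None
        attr = act.attribute(attribute)
        return attr.type if attr is not None else None


def validate_model(model: ProcessModel) -> list[Violation]:
    """Check a structurally parseable model against the well-formedness
    rules; returns every finding (an empty list means the model is valid).

    Rules
    -----
    V1  exactly one master activity;
    V2  no edge of any kind targets the master (it has no ingoing arrows);
    V3  duplicated follows edges (same source/target pair twice) — outgoing
        follows alternatives are XOR, so a duplicate is meaningless;
    V4  an interruption whose source is a plain activity with no unbounded
        component behaviour is suspicious but legal → warning only;
    V5  the composition graph is acyclic and every component has exactly one
        aggregate parent;
    V6  all references resolve (edge endpoints, enumeration types) and edge
        fields are structurally legal (cardinality only on composition,
        extension points only on extensions, enumerations non-empty);
    V7  names are unique (activities, enumerations, attributes within an
        activity, literals within an enumeration).
    """
    out: list[Violation] = []

    # V7 — uniqueness
    seen: set[str] = set()
    for a in model.activities:
        if a.name in seen:
            out.append(Violation("V7", a.name, "duplicate activity name"))
        seen.add(a.name)
        attr_seen: set[str] = set()
        for attr in a.attributes:
            if attr.name in attr_seen:
                out.append(
                    Violation(
                        "V7", f"{a.name}.{attr.name}", "duplicate attribute name"
                    )
                )
            attr_seen.add(attr.name)
    enum_seen: set[str] = set()
    for en in model.enumerations:
        if en.name in enum_seen:
            out.append(Violation("V7", en.name, "duplicate enumeration name"))
        enum_seen.add(en.name)
        if len(set(en.literals)) != len(en.literals):
            out.append(Violation("V7", en.name, "duplicate enumeration literal"))

    # V1 — exactly one master
    masters = [a.name for a in model.activities if a.is_master]
    if len(masters) != 1:
        out.append(
            Violation(
                "V1",
                model.name,
                f"expected exactly one master activity, found {len(masters)}",
            )
        )
    master = masters[0] if len(masters) == 1 else None

    # V6 — enumerations well-formed
    for en in model.enumerations:
        if not en.literals:
            out.append(Violation("V6", en.name, "enumeration has no literals"))

    # V6 — attribute types resolve
    enum_names = {en.name for en in model.enumerations}
    for a in model.activities:
        for attr in a.attributes:
            if attr.type not in PRIMITIVE_TYPES and attr.type not in enum_names:
                out.append(
                    Violation(
                        "V6",
                        f"{a.name}.{attr.name}",
                        f"unknown attribute type {attr.type!r}",
                    )
                )

    # edges: resolution, field legality, V2, V3
    follows_pairs: set[tuple[str, str]] = set()
    activity_names = {a.name for a in model.activities}
    for e in model.edges:
        label = f"{e.source}-[{e.kind}]->{e.target}"
        if e.kind not in EDGE_KINDS:
            out.append(Violation("V6", label, f"unknown edge kind {e.kind!r}"))
            continue
        for endpoint in (e.source, e.target):
            if endpoint not in activity_names:
                out.append(
                    Violation("V6", label, f"unknown activity {endpoint!r}")
                )
        if e.kind == COMPOSITION:
            card = e.cardinality if e.cardinality is not None else "1"
            if card not in CARDINALITIES:
                out.append(
                    Violation("V6", label, f"illegal cardinality {e.cardinality!r}")
                )
        elif e.cardinality is not None:
            out.append(
                Violation("V6", label, "cardinality is only legal on composition")
            )
        if e.kind == EXTENSION:
            if not e.extension_point:
                out.append(
                    Violation("V6", label, "extension edge lacks an extension point")
                )
        elif e.extension_point is not None:
            out.append(
                Violation(
                    "V6", label, "extension point is only legal on extension edges"
                )
            )
        if master is not None and e.target == master:
            out.append(
                Violation("V2", label, "master activity may have no ingoing arrows")
            )
        if e.kind == FOLLOWS:
            pair = (e.source, e.target)
            if pair in follows_pairs:
                out.append(
                    Violation("V3", label, "duplicated follows edge (XOR alternative)")
                )
            follows_pairs.add(pair)

    # V4 — interruption plausibility (warning only)
    for e in model.edges:
        if e.kind == INTERRUPTION and e.source in activity_names:
            if not model.is_aggregate(e.source):
                out.append(
                    Violation(
                        "V4",
                        f"{e.source}-[interruption]->{e.target}",
                        "interruption out of a plain activity with no "
                        "unbounded component behaviour",
                        severity="warning",
                    )
                )

    # V5 — composition shape
    parents: dict[str, list[str]] = {}
    children: dict[str, list[str]] = {}
    for e in model.edges:
        if e.kind == COMPOSITION:
            parents.setdefault(e.target, []).append(e.source)
            children.setdefault(e.source, []).append(e.target)
    for comp, pars in parents.items():
        if len(set(pars)) > 1:
            out.append(
                Violation(
                    "V5",
                    comp,
                    f"component has {len(set(pars))} aggregate parents, expected 1",
                )
            )
    # cycle detection by iterative DFS over the composition graph
    WHITE, GREY, BLACK = 0, 1, 2
    color = {name: WHITE for name in children}
    for root in sorted(children):
        if color[root] != WHITE:
            continue
        stack: list[tuple[str, int]] = [(root, 0)]
        color[root] = GREY
        while stack:
            node, i = stack[-1]
            kids = children.get(node, [])
            if i < len(kids):
                stack[-1] = (node, i + 1)
                kid = kids[i]
                if color.get(kid, WHITE) == GREY:
                    out.append(
                        Violation("V5", kid, "composition cycle detected")
                    )
                elif color.get(kid, WHITE) == WHITE and kid in children:
                    color[kid] = GREY
                    stack.append((kid, 0))
            else:
                color[node] = BLACK
                stack.pop()

    return out


def is_valid(model: ProcessModel) -> bool:
    """True when validate_model reports no error-severity findings."""
    return not any(v.severity == "error" for v in validate_model(model))
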