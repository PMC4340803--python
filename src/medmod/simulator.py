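"""Stochastic execution of process models into conformant synthetic traces.

The generator walks a process model per its run-time semantics — one master
instance roots each slice; a finished instance hands control to exactly one
of its follows-successors (XOR, sampled by branch weights); an aggregate
spawns component instances per sampled realized counts within the declared
cardinalities, and is then interrupted (the interrupting instance starts
only after the last component spawned, so suspension semantics hold by
construction); extensions fire with a per-edge probability at a uniform
point inside the host's execution span.  All timestamps are causally
ordered, so the output passes trace conformance with zero violations, and
the whole run is driven by a single seeded generator: identical
(model, config, seed) gives byte-identical traces.

A built-in hospital demo model ships with the package: a patient-admission
process with a ward aggregate whose components (procedure assignment and
execution, diagnosis setting) repeat freely, interrupted by transfer or
discharge, with a second-opinion extension — the shape of an inpatient
episode, with enumerated procedure/diagnosis codes and cost attributes so
every query construct is exercisable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone

import numpy as np

from .errors import ConfigurationError, SimulationError
from .model import (
    COMPOSITION,
    EXTENSION,
    FOLLOWS,
    INTERRUPTION,
    CARDINALITY_BOUNDS,
    ActivityDef,
    AttributeDef,
    Edge,
    EnumerationDef,
    ProcessModel,
)
from .trace import CausalLink, Dataset, Instance, Slice

# --------------------------------------------------------------------------
# distributions


@dataclass(frozen=True)
class Distribution:
    """A sampling spec: constant, uniform, exponential or categorical."""

    kind: str
    params: tuple

    def sample(self, rng: np.random.Generator):
        if self.kind == "constant":
            return self.params[0]
        if self.kind == "uniform":
            lo, hi = self.params
            return lo + (hi - lo) * rng.random()
        if self.kind == "exponential":
            return rng.exponential(self.params[0])
        if self.kind == "categorical":
            values, cum = self.params
            u = rng.random()
            for v, c in zip(values, cum):
                if u <= c:
                    return v
            return values[-1]
        raise ConfigurationError(f"unknown distribution kind {self.kind!r}")

    @property
    def support(self):
        """(min, max) over sampleable values where finitely describable."""
        if self.kind == "constant":
            return self.params[0], self.params[0]
        if self.kind == "uniform":
            return self.params
        if self.kind == "exponential":
            return 0.0, float("inf")
        values = self.params[0]
        return min(values), max(values)


def constant(v) -> Distribution:
    return Distribution("constant", (v,))


def uniform(lo: float, hi: float) -> Distribution:
    if hi < lo:
        raise ConfigurationError(f"uniform bounds inverted: [{lo}, {hi}]")
    return Distribution("uniform", (lo, hi))


def exponential(mean: float) -> Distribution:
    if mean <= 0:
        raise ConfigurationError(f"exponential mean must be positive, got {mean}")
    return Distribution("exponential", (mean,))


def categorical(weighted_values) -> Distribution:
    """``weighted_values``: mapping value -> weight, or (value, weight) pairs."""
    pairs = (
        list(weighted_values.items())
        if isinstance(weighted_values, dict)
        else [tuple(p) for p in weighted_values]
    )
    if not pairs:
        raise ConfigurationError("categorical distribution needs values")
    total = float(sum(w for _, w in pairs))
    if total <= 0:
        raise ConfigurationError("categorical weights must sum to a positive value")
    values = tuple(v for v, _ in pairs)
    cum = []
    acc = 0.0
    for _, w in pairs:
        if w < 0:
            raise ConfigurationError("categorical weights must be non-negative")
        acc += w / total
        cum.append(acc)
    return Distribution("categorical", (values, tuple(cum)))


def distribution_from_spec(spec) -> Distribution:
    """Build a distribution from its JSON/YAML form, e.g.
    ``{"uniform": [20, 250]}`` or ``{"categorical": {"A": 0.7, "B": 0.3}}``."""
    if isinstance(spec, Distribution):
        return spec
    if isinstance(spec, (int, float)):
        return constant(spec)
    if not isinstance(spec, dict) or len(spec) != 1:
        raise ConfigurationError(f"not a distribution spec: {spec!r}")
    (kind, arg), = spec.items()
    if kind == "constant":
        return constant(arg)
    if kind == "uniform":
        return uniform(*arg)
    if kind == "exponential":
        return exponential(arg)
    if kind == "categorical":
        return categorical(arg)
    raise ConfigurationError(f"unknown distribution kind {kind!r}")


# --------------------------------------------------------------------------
# configuration


@dataclass
class SimulationConfig:
    """Everything the generator samples from.

    Per-edge tables are keyed by (source, target) activity names.  Branch
    weights cover XOR follows choices (weights over one source's outgoing
    follows edges must sum to 1; a single outgoing edge needs no entry);
    interruption weights pick which interrupter fires on an aggregate.
    Durations and gaps are in seconds.  ``derived_sums`` lists
    (master_attribute, source_attribute) pairs filled after each slice is
    built with the sum of the source attribute over the slice (e.g. total
    expenses from per-procedure costs).
    """

    n_slices: int
    seed: int
    time_origin: datetime
    inter_arrival: Distribution
    branch_weights: dict = field(default_factory=dict)  # source -> {target: w}
    interruption_weights: dict = field(default_factory=dict)
    interruption_probability: dict = field(default_factory=dict)  # plain activities
    extension_probability: dict = field(default_factory=dict)  # (host, target) -> p
    component_counts: dict = field(default_factory=dict)  # (aggregate, comp) -> Dist
    durations: dict = field(default_factory=dict)  # activity -> Dist
    attribute_generators: dict = field(default_factory=dict)  # (act, attr) -> Dist
    derived_sums: list = field(default_factory=list)
    follow_gap: Distribution = field(default_factory=lambda: constant(0.0))
    spawn_gap: Distribution = field(default_factory=lambda: constant(0.0))
    interruption_gap: Distribution = field(default_factory=lambda: constant(0.0))
    max_instances_per_slice: int = 10_000


def validate_config(model: ProcessModel, config: SimulationConfig) -> None:
    """Raise ConfigurationError on ill-formed sampling tables."""
    if config.n_slices < 0:
        raise ConfigurationError(f"n_slices must be >= 0, got {config.n_slices}")
    for act in model.activities:
        outs = model.edges_from(act.name, FOLLOWS)
        if len(outs) > 1:
            weights = config.branch_weights.get(act.name)
            if weights is None:
                raise ConfigurationError(
                    f"activity {act.name!r} has {len(outs)} XOR alternatives "
                    "but no branch weights"
                )
            targets = {e.target for e in outs}
            if set(weights) != targets:
                raise ConfigurationError(
                    f"branch weights for {act.name!r} must cover exactly "
                    f"{sorted(targets)}"
                )
            total = sum(weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"branch weights for {act.name!r} sum to {total}, expected 1"
                )
    for e in model.edges:
        if e.kind != COMPOSITION:
            continue
        dist = config.component_counts.get((e.source, e.target))
        if dist is None:
            continue
        lo, hi = CARDINALITY_BOUNDS[e.cardinality or "1"]
        smin, smax = dist.support
        if smin < lo or (hi is not None and smax > hi):
            raise ConfigurationError(
                f"realized-count distribution for {e.source!r}->{e.target!r} "
                f"can leave cardinality {e.cardinality or '1'}"
            )


def config_from_dict(doc) -> SimulationConfig:
    """Build a configuration from its YAML/JSON form.

    Edge-keyed tables use ``"source -> target"`` keys; attribute generators
    nest as ``{activity: {attribute: distribution}}``.
    """

    def edge_key(text: str):
        parts = [p.strip() for p in text.split("->")]
        if len(parts) != 2:
            raise ConfigurationError(f"bad edge key {text!r}; use 'source -> target'")
        return tuple(parts)

    def edge_dists(table):
        return {edge_key(k): distribution_from_spec(v) for k, v in table.items()}

    try:
        origin = datetime.fromisoformat(str(doc["time_origin"]).replace("Z", "+00:00"))
    except (KeyError, ValueError) as exc:
        raise ConfigurationError(f"bad or missing time_origin: {exc}") from exc
    try:
        cfg = SimulationConfig(
            n_slices=int(doc["n_slices"]),
            seed=int(doc["seed"]),
            time_origin=origin,
            inter_arrival=distribution_from_spec(doc["inter_arrival"]),
        )
    except KeyError as exc:
        raise ConfigurationError(f"missing required config key {exc}") from exc
    cfg.branch_weights = {
        src: dict(ws) for src, ws in doc.get("branch_weights", {}).items()
    }
    cfg.interruption_weights = {
        src: dict(ws) for src, ws in doc.get("interruption_weights", {}).items()
    }
    cfg.interruption_probability = dict(doc.get("interruption_probability", {}))
    cfg.extension_probability = {
        edge_key(k): float(v) for k, v in doc.get("extension_probability", {}).items()
    }
    cfg.component_counts = edge_dists(doc.get("component_counts", {}))
    cfg.durations = {
        act: distribution_from_spec(d) for act, d in doc.get("durations", {}).items()
    }
    cfg.attribute_generators = {
        (act, attr): distribution_from_spec(d)
        for act, table in doc.get("attribute_generators", {}).items()
        for attr, d in table.items()
    }
    cfg.derived_sums = [tuple(pair) for pair in doc.get("derived_sums", [])]
    for gap in ("follow_gap", "spawn_gap", "interruption_gap"):
        if gap in doc:
            setattr(cfg, gap, distribution_from_spec(doc[gap]))
    return cfg


def config_from_file(path) -> SimulationConfig:
    """Load a simulation configuration from a YAML (or JSON — YAML is a
    superset) file."""
    import yaml

    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigurationError("configuration document must be a mapping")
    return config_from_dict(doc)


# --------------------------------------------------------------------------
# simulation


def _coerce(value, type_name: str):
    if type_name == "Integer":
        return int(round(value))
    if type_name == "Real":
        return round(float(value), 2)
    return value


def simulate(model: ProcessModel, config: SimulationConfig) -> Dataset:
    """Generate a dataset of ``config.n_slices`` conformant slices."""
    from .model import validate_model

    errors = [v for v in validate_model(model) if v.severity == "error"]
    if errors:
        raise ConfigurationError(
            f"cannot simulate an invalid model: {errors[0].message}"
        )
    validate_config(model, config)
    rng = np.random.default_rng(config.seed)
    master = model.master

    slices: list[Slice] = []
    t_arrival = config.time_origin
    for idx in range(config.n_slices):
        t_arrival = t_arrival + timedelta(
            seconds=float(config.inter_arrival.sample(rng))
        )
        slices.append(_run_slice(model, config, rng, idx, master.name, t_arrival))
    return Dataset(model, slices)


def _run_slice(model, config, rng, idx, master_name, t0) -> Slice:
    slice_id = f"S{idx:05d}"
    counter = 0
    instances: list[Instance] = []

    def duration(activity: str) -> float:
        dist = config.durations.get(activity)
        return float(dist.sample(rng)) if dist is not None else 0.0

    def new_instance(activity, start, caused_by, end=None) -> Instance:
        nonlocal counter
        counter += 1
        if counter > config.max_instances_per_slice:
            raise SimulationError(
                f"slice {slice_id} exceeded {config.max_instances_per_slice} "
                "instances; the model's control flow may loop"
            )
        if end is None:
            end = start + timedelta(seconds=duration(activity))
        inst = Instance(
            instance_id=f"{slice_id}-I{counter:04d}",
            activity=activity,
            slice_id=slice_id,
            start_time=start,
            end_time=end,
            caused_by=caused_by,
        )
        instances.append(inst)
        return inst

    def pick_weighted(weights: dict) -> str:
        items = list(weights.items())
        u = rng.random()
        acc = 0.0
        total = sum(w for _, w in items)
        for target, w in items:
            acc += w / total
            if u <= acc:
                return target
        return items[-1][0]

    root = new_instance(master_name, t0, None)
    queue = [root]
    while queue:
        inst = queue.pop(0)
        act = inst.activity

        comp_edges = model.edges_from(act, COMPOSITION)
        if comp_edges:
            t = inst.start_time
            components: list[Instance] = []
            for e in comp_edges:
                dist = config.component_counts.get((e.source, e.target))
                if dist is None:
                    lo, _ = CARDINALITY_BOUNDS[e.cardinality or "1"]
                    count = lo
                else:
                    count = int(round(float(dist.sample(rng))))
                for _ in range(count):
                    t = t + timedelta(seconds=float(config.spawn_gap.sample(rng)))
                    c = new_instance(e.target, t, CausalLink(inst.instance_id, COMPOSITION))
                    components.append(c)
                    queue.append(c)
            last_end = max(
                (c.end_time for c in components), default=inst.end_time or inst.start_time
            )
            intr_edges = model.edges_from(act, INTERRUPTION)
            if intr_edges:
                weights = config.interruption_weights.get(act) or {
                    e.target: 1.0 for e in intr_edges
                }
                target = pick_weighted(weights)
                t_int = t + timedelta(
                    seconds=float(config.interruption_gap.sample(rng))
                )
                b = new_instance(target, t_int, CausalLink(inst.instance_id, INTERRUPTION))
                queue.append(b)
                inst.end_time = max(last_end, t_int)
            else:
                inst.end_time = last_end
        else:
            intr_edges = model.edges_from(act, INTERRUPTION)
            if intr_edges:
                p = config.interruption_probability.get(act, 0.0)
                if rng.random() < p:
                    weights = config.interruption_weights.get(act) or {
                        e.target: 1.0 for e in intr_edges
                    }
                    target = pick_weighted(weights)
                    span = (inst.end_time - inst.start_time).total_seconds()
                    t_int = inst.start_time + timedelta(seconds=span * rng.random())
                    b = new_instance(
                        target, t_int, CausalLink(inst.instance_id, INTERRUPTION)
                    )
                    queue.append(b)
                    inst.end_time = t_int

        for e in model.edges_from(act, EXTENSION):
            p = config.extension_probability.get((e.source, e.target), 0.0)
            if rng.random() < p:
                span = (inst.end_time - inst.start_time).total_seconds()
                s = inst.start_time + timedelta(seconds=span * rng.random())
                x = new_instance(e.target, s, CausalLink(inst.instance_id, EXTENSION))
                queue.append(x)

        f_edges = model.edges_from(act, FOLLOWS)
        if f_edges:
            if len(f_edges) == 1:
                target = f_edges[0].target
            else:
                target = pick_weighted(config.branch_weights[act])
            s = inst.end_time + timedelta(seconds=float(config.follow_gap.sample(rng)))
            nxt = new_instance(target, s, CausalLink(inst.instance_id, FOLLOWS))
            queue.append(nxt)

    # attribute values, in creation order for determinism
    for inst in instances:
        act = model.activity(inst.activity)
        for attr in act.attributes:
            gen = config.attribute_generators.get((inst.activity, attr.name))
            if gen is None:
                continue
            inst.attributes[attr.name] = _coerce(gen.sample(rng), attr.type)

    for master_attr, source_attr in config.derived_sums:
        total = sum(
            inst.attributes[source_attr]
            for inst in instances
            if source_attr in inst.attributes
        )
        instances[0].attributes[master_attr] = round(float(total), 2)

    return Slice(slice_id, instances)


# --------------------------------------------------------------------------
# built-in hospital demo


#: Activity names of the demo process, exported for convenience.
PATIENT_ENTERS = "Patient enters the hospital"
PATIENT_ADMITTED = "Patient admitted to hospital ward"
PATIENT_SENT_HOME = "Patient sent home"
WARD_PROCESS = "Clinical process in ward"
ASSIGN_PROCEDURE = "Doctor assigns procedure"
SET_DIAGNOSIS = "Doctor sets diagnosis"
EXECUTE_PROCEDURE = "Procedure is executed"
SECOND_DOCTOR = "Patient consulted by second doctor"
TRANSFERRED = "Patient transferred to another ward"
DISCHARGED = "Patient discharged"

P_CODES = ("P012", "P047", "P103", "P215", "P330")
D_CODES = ("Chickenpox", "Pneumonia", "Stroke", "Influenza", "Fracture")
SURNAMES = (
    "Smith", "Jones", "Ozols", "Berzins", "Kalnins", "Liepa",
    "Miller", "Brown", "Osis", "Vitols", "Egle", "Lacis",
)


def demo_model() -> ProcessModel:
    """The packaged hospital admission process.

    A patient enters the hospital (master) and is either admitted to a ward
    or sent home (XOR).  The ward stay is an aggregate whose components —
    procedure assignment, procedure execution and diagnosis setting — repeat
    freely (cardinality ``*``) until the stay is interrupted by a transfer
    or a discharge; a transferred patient is eventually discharged.  While
    setting a diagnosis the doctor may judge that a second opinion is
    necessary, calling in a second doctor (extension).  Enumerated
    procedure codes (``pCode``) and diagnosis codes, per-procedure costs and
    the per-stay total expenses make every filtering construct exercisable.
    """
    return ProcessModel(
        name="hospital-admission",
        enumerations=(
            EnumerationDef("pCode", P_CODES),
            EnumerationDef("dCode", D_CODES),
        ),
        activities=(
            ActivityDef(
                PATIENT_ENTERS,
                attributes=(
                    AttributeDef("age", "Integer"),
                    AttributeDef("surname", "String"),
                    AttributeDef("total_expenses", "Real"),
                ),
                is_master=True,
            ),
            ActivityDef(PATIENT_ADMITTED),
            ActivityDef(PATIENT_SENT_HOME),
            ActivityDef(WARD_PROCESS),
            ActivityDef(
                ASSIGN_PROCEDURE,
                attributes=(AttributeDef("procedure_code", "pCode"),),
            ),
            ActivityDef(
                EXECUTE_PROCEDURE,
                attributes=(
                    AttributeDef("procedure_code", "pCode"),
                    AttributeDef("cost", "Real"),
                ),
            ),
            ActivityDef(
                SET_DIAGNOSIS,
                attributes=(AttributeDef("diagnosis", "dCode"),),
            ),
            ActivityDef(SECOND_DOCTOR),
            ActivityDef(TRANSFERRED),
            ActivityDef(DISCHARGED),
        ),
        edges=(
            Edge(FOLLOWS, PATIENT_ENTERS, PATIENT_ADMITTED),
            Edge(FOLLOWS, PATIENT_ENTERS, PATIENT_SENT_HOME),
            Edge(FOLLOWS, PATIENT_ADMITTED, WARD_PROCESS),
            Edge(COMPOSITION, WARD_PROCESS, ASSIGN_PROCEDURE, cardinality="*"),
            Edge(COMPOSITION, WARD_PROCESS, EXECUTE_PROCEDURE, cardinality="*"),
            Edge(COMPOSITION, WARD_PROCESS, SET_DIAGNOSIS, cardinality="*"),
            Edge(INTERRUPTION, WARD_PROCESS, TRANSFERRED),
            Edge(INTERRUPTION, WARD_PROCESS, DISCHARGED),
            Edge(FOLLOWS, TRANSFERRED, DISCHARGED),
            Edge(
                EXTENSION,
                SET_DIAGNOSIS,
                SECOND_DOCTOR,
                extension_point="second opinion is necessary",
            ),
        ),
    )


HOUR = 3600.0


def demo_config(n_slices: int = 5000, seed: int = 0) -> SimulationConfig:
    """Default study conditions for the demo hospital: admission rate, ward
    activity mix and cost ranges chosen so a 5000-slice run carries on the
    order of 64 000 instances (~13 per stay), the scale of a busy ward's
    yearly log."""
    return SimulationConfig(
        n_slices=n_slices,
        seed=seed,
        time_origin=datetime(2012, 1, 1, tzinfo=timezone.utc),
        inter_arrival=exponential(1.5 * HOUR),
        branch_weights={
            PATIENT_ENTERS: {PATIENT_ADMITTED: 0.7, PATIENT_SENT_HOME: 0.3},
        },
        interruption_weights={WARD_PROCESS: {DISCHARGED: 0.75, TRANSFERRED: 0.25}},
        extension_probability={(SET_DIAGNOSIS, SECOND_DOCTOR): 0.35},
        component_counts={
            (WARD_PROCESS, ASSIGN_PROCEDURE): categorical(
                {2: 1, 3: 1, 4: 1, 5: 1, 6: 1, 7: 1}
            ),
            (WARD_PROCESS, EXECUTE_PROCEDURE): categorical(
                {2: 1, 3: 1, 4: 1, 5: 1, 6: 1, 7: 1}
            ),
            (WARD_PROCESS, SET_DIAGNOSIS): categorical({2: 1, 3: 1, 4: 1, 5: 1}),
        },
        durations={
            PATIENT_ENTERS: uniform(0.5 * HOUR, 2 * HOUR),
            PATIENT_ADMITTED: uniform(1 * HOUR, 4 * HOUR),
            PATIENT_SENT_HOME: uniform(0.25 * HOUR, 1 * HOUR),
            ASSIGN_PROCEDURE: uniform(600, 3600),
            EXECUTE_PROCEDURE: uniform(1200, 7200),
            SET_DIAGNOSIS: uniform(600, 1800),
            SECOND_DOCTOR: uniform(1200, 3600),
            TRANSFERRED: uniform(1 * HOUR, 3 * HOUR),
            DISCHARGED: uniform(0.5 * HOUR, 1 * HOUR),
        },
        attribute_generators={
            (PATIENT_ENTERS, "age"): uniform(0, 95),
            (PATIENT_ENTERS, "surname"): categorical({s: 1 for s in SURNAMES}),
            (ASSIGN_PROCEDURE, "procedure_code"): categorical({c: 1 for c in P_CODES}),
            (EXECUTE_PROCEDURE, "procedure_code"): categorical({c: 1 for c in P_CODES}),
            (EXECUTE_PROCEDURE, "cost"): uniform(20, 250),
            (SET_DIAGNOSIS, "diagnosis"): categorical(
                {
                    "Chickenpox": 0.15,
                    "Pneumonia": 0.2,
                    "Stroke": 0.1,
                    "Influenza": 0.3,
                    "Fracture": 0.25,
                }
            ),
        },
        derived_sums=[("total_expenses", "cost")],
        follow_gap=uniform(0, 2 * HOUR),
        spawn_gap=exponential(4 * HOUR),
        interruption_gap=uniform(1 * HOUR, 12 * HOUR),
    )
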