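# Methods

This note records the semantics the engine implements, the choices made
where the design was genuinely open, and what the synthetic generator does
and does not emulate.

## Process metamodel

A model is a named set of activities, enumerations and edges.  Activities
are task types with intrinsic start/end moments and typed attributes; the
five primitive types are Integer, Real, String, Boolean and DateTime, plus
enumerations (closed literal sets standing in for clinical codificators).
Edges are `follows`, `composition`, `interruption` and `extension`.

Well-formedness is checked by `validate_model` (rules V1–V7, listed in its
docstring).  Decisions behind the less obvious rules:

- **Master in-degree zero (V2).** The master roots every transaction; any
  ingoing edge — of any kind — would make slice membership ill-founded.
- **XOR by structure (V3).** Several outgoing `follows` edges from one
  activity always mean exclusive alternatives; the branching diamond some
  notations draw is presentation, not model content, so a duplicated
  source/target pair carries no information and is flagged.
- **Interruption of plain activities (V4).** Interrupting an activity with
  no unbounded component behaviour is legal but usually a modeling smell;
  it is reported as a warning, not an error.
- **Composition shape (V5).** Aggregates may nest, but the composition
  graph must be acyclic and each component has exactly one aggregate
  parent — both are required for slices to be well-founded finite sets.
- Cardinalities form the closed set `1`, `0..1`, `1..*`, `*` (default `1`)
  — the smallest vocabulary covering the usual UML-style annotations.

## Traces, slices, conformance

Instances carry explicit `caused_by` provenance (predecessor instance and
edge kind).  This is a deliberate enrichment of the log format: without it,
XOR conformance (T5), composition cardinalities (T6) and interruption
semantics (T7) are not decidable from timestamps alone.  Timestamps are
timezone-aware ISO-8601 instants compared as absolute times; durations are
reported in seconds.  Missing attribute values are recorded as absent, never
imputed.

`validate_trace` reports rules T1–T8 (docstring).  Two boundary choices:

- A `follows` successor whose predecessor has no end time yet cannot be
  timing-checked; this yields a **warning**, not a violation, since the
  predecessor may legitimately still be running.
- Dangling causal references raise a structural error instead of producing
  violation records — such a trace is not a checkable object.

Time windows (`build_initial_dataset`) are half-open `[start, end)` and
keyed on the **master instance's start time** — the birth of the
transaction.  This makes disjoint windows partition the slices exactly, and
slices are never split: a stay that begins inside the window belongs to it
wholly, even if activity continues past the window's end.

## Query evaluation

Filtering is slice-granular: a condition keeps the whole slices containing
at least one instance of the named activity satisfying it.  Conditions
applied in sequence therefore intersect at slice level, which makes the
final slice set independent of condition order (asserted as a property
test).  Within a single two-term condition (`AND`/`OR`), both terms apply to
the *same* instance value; across separate conditions no single instance
needs to satisfy both.  Comparisons against absent values are false; string
comparisons are case-sensitive; no floating-point tolerance is applied
(exact IEEE semantics); enumeration constants must be declared literals —
a misspelled code is a type error rather than a silently empty result.

Operator legality by type: ordered types (Integer, Real, DateTime) take
`eq ne gt lt ge le`; String takes `eq ne contains begins_with ends_with`;
Boolean and enumerations take `eq ne` only.

**Slice aggregates.** `Sum`/`Average` are computed over the instances of the
activity that carry the attribute; `Count` counts all instances of the
activity regardless of attribute values.  A slice containing *no* instance
of the activity fails the condition outright — the filter reads "contains
instances of the filtered type whose aggregate …", so `Sum ≥ 0` does not
resurrect slices in which the activity never happened.  A slice with
instances but no attribute values likewise fails `Sum`/`Average`.

**Partitions.** `Top`/`Bottom`-k ranks slices by their per-slice extreme
value (max for Top, min for Bottom) of the attribute over instances of the
activity; ties break by slice id ascending; slices with no valued instance
are unranked and never returned; `k` is capped (default `k_max = 100`,
configurable).  An alternative instance-level reading — take the k extreme
*instances* and return their (possibly fewer) slices — exists; the
slice-level reading was chosen because the canonical use case asks for "the
10 stays with the largest total expenses".  Evaluation streams the dataset
once holding a best-first candidate list of at most k `(extreme, slice_id)`
entries; each instance is compared against at most k entries.  Streaming
eviction is sound because a slice's recorded extreme can only be re-offered
with a strictly better value: a worse later value is dominated by the entry
that evicted it.

**Cost accounting.** Every evaluation routine threads an
`InspectionCounter`.  A comparison or aggregate condition counts one
inspection per instance visited (comparisons stop scanning a slice at the
first match), hence ≤ n.  A partition counts one inspection per candidate
list comparison, at least one per instance, hence ≤ k·n.  The counters are
asserted against these bounds in the test suite on every run; `apply_query`
reports the total.

**Intervals.** An interval's events are the instances of its start/end
activities, timed by a named DateTime attribute or by default the intrinsic
start moment.  "Adjacent in time" pairing is implemented greedily: starts in
time order each take the earliest not-yet-paired end at or after them, so
durations are never negative.  With a pairing condition, the same greedy
scan runs inside each equivalence class of equal pairing-attribute values.
Interval value lists attach to the slice's master instance as derived
multi-valued attributes and may be used in subsequent conditions and
partitions (a multi-valued condition matches if any single value satisfies
the whole expression).  Intervals are attached before filtering; under
grouping they are recomputed on the merged group-slices, where they may span
a patient's multiple stays, and attach to the group-slice as a whole.

**Grouping.** Slices sharing an attribute value (on the named activity)
merge into one group-slice.  A slice carrying several different key values
joins exactly one group — the key of its earliest keyed instance — because
multi-membership would break slice disjointness, the invariant every
operation preserves.  Unkeyed slices stay singleton groups.

**Retrieval.** `Count`/`Sum`/`Average` over all instances of an activity in
the (filtered) dataset; `Average` of zero valued instances is undefined and
returned as `None`; `Sum` of zero values is `0`; `Count` of an empty dataset
is `0`.  Instance tables list one row per instance, columns `slice_id`,
`instance_id`, `start_time`, `end_time`, then declared attributes in model
order, sorted by `(start_time, instance_id)`.

## Simulator

The generator executes a model's run-time semantics with all randomness
drawn from one seeded generator, so identical (model, config, seed) gives
byte-identical traces.  Distribution vocabulary: `constant`, `uniform`,
`exponential`, `categorical`.  Design choices:

- **Termination.** Interruption is realized as a stopping time: component
  counts are sampled first (within the declared cardinalities), and the
  interrupting instance starts after the last component spawned — so the
  suspension rule (no component starts after the interrupter) holds by
  construction and every aggregate terminates.  A per-slice instance cap
  guards against looping control flow in user models.
- **Causal ordering.** A `follows` successor starts at the predecessor's
  end plus a sampled gap; components spawn sequentially from the aggregate's
  start; extensions fire at a uniform point inside the host's span.
- Real-valued attributes are rounded to 2 decimals (money-like values);
  Integer attributes round to int.

### Demo study conditions

The built-in hospital model and its default configuration define the
package's reference workload: exponential inter-arrivals (mean 1.5 h from
2012-01-01), a 0.7/0.3 XOR split between ward admission and being sent
home, 2–7 procedure assignments and executions and 2–5 diagnoses per stay,
a 0.35 second-opinion probability per diagnosis, discharge vs. transfer at
0.75/0.25, procedure costs uniform on [20, 250] with `total_expenses` the
per-stay cost sum, ages uniform on [0, 95], surnames and procedure codes
uniform over small pools, and diagnosis codes weighted (Influenza 0.30,
Fracture 0.25, Pneumonia 0.20, Chickenpox 0.15, Stroke 0.10).  These rates
make a 5000-stay log carry roughly 64–66 thousand instances (~13 per stay),
the scale used by the scale tests and the acceptance script; they were
chosen once as a plausible ward workload and are not tuned thereafter.

What the generator emulates: variable-order clinical activity, repeating
components, interrupted stays, enumerated codes, skewed diagnosis mixes,
costs aggregated per stay.  What it does not: calendars and shifts, bed or
staff capacity, correlated diagnoses within a patient, missing-data
patterns of real hospital systems, cross-slice patients (each stay draws an
independent surname, so grouping tests construct their own repeats).
Passing tests on simulated data therefore certify the *engine's semantics
and costs*, not the fidelity of any real hospital's log.

## Serialization

JSON is the primary dialect for models, traces and queries (schema
documents under `src/medmod/schemas/`, validated structurally on load with
JSON-pointer error paths).  Traces also round-trip through a flat CSV
event-log dialect: seven fixed columns, then one column per declared
attribute name, values typed via the model on read.  One CSV limitation: an
empty cell encodes an absent value, so a declared empty-string value is not
representable (JSON is lossless).  Writers are deterministic — fixed key
order, repr-precision floats — so byte-level golden comparisons are valid;
human-readable table output is the only place numbers are reformatted.

## Known limitations

- Arbitrary user models can be simulated only through the library/config
  path; the engine itself never limits model shape beyond well-formedness.
- Trace conformance assumes `caused_by` provenance is present; logs
  without it can be loaded and queried but only partially validated.
- Grouping keys compare by exact equality; no normalization (case,
  whitespace) is applied to string keys.
- The interval pairing rule is one reasonable formalization of "adjacent
  in time"; other matchings (e.g. interval-graph optimal) would give
  different multi-sets when events interleave irregularly.
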