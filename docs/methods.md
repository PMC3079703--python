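# Methods

This note documents the execution model, the choices made where the design
was genuinely open, the synthetic-data conditions under which the package
is tested, and known limitations.

## Event model and the current position pointer

An event is one coded clinical observation: mandatory `patient_id`,
timestamp and event type, plus optional subtype, observation, coded value,
flag, numeric value, text value, secondary terminology code and a
`sequence_id` tie-break key. Every coded field is a code/description pair;
matching prefers the code and falls back to the description only when no
code is recorded, so a label can never shadow a differing code. Missing
fields are explicit nulls, never empty strings.

Timelines sort by `(ev_time, sequence_id)` with a stable sort, so events
sharing both keys keep input order. Timestamps parse as
`YYYY-MM-DD[ HH:MM:SS[.f]]`; a bare date means midnight.

The pointer is the engine's temporal cursor. Its semantics, fixed here
because several are underdetermined in flowchart descriptions of chart
review:

* The pointer starts `BEFORE_FIRST`, and the first find scans the whole
  record *including* the first event.
* The *effective time* used by jump arithmetic is: the first event's time
  at `BEFORE_FIRST`, the anchored event's time at `AT_EVENT`, the jump
  target at `AT_TIME`, the last event's time at `AFTER_LAST`.
* A strict-mode find from `AT_EVENT(i)` scans indices strictly greater
  than *i* — a find can never re-match its own anchor. From `AT_TIME(t)`
  it scans events with time ≥ *t*: a jump lands *between* events and
  consumes none of them. This is the one place where two events at the
  same timestamp are treated differently depending on how the pointer got
  there; it keeps pointer time monotone under successful finds and
  forward jumps, which is the property the tests enforce.
* `jump_forward_months` advances by calendar months with the day-of-month
  clamped to the target month's length (Jan 31 + 1 month = Feb 28).

## Event-type families

The nine simple find operators each own an event-type *family*. Which
event types belong to a family and which coded field carries the family's
search code is configuration (`FamilyDialect`), not convention, because
real event tables put codes in different columns per family: in the
bundled example record, lab results code the observation column,
procedures the terminology2 column, and orders the coded-value column.
The shipped defaults cover the families of a typical coded-event
warehouse (lab, diagnosis, procedure, prescription, visit, vital sign,
textual report, order, microbiology). `patient_is_male` is a whole-record
demographic lookup and deliberately does not move the pointer; a node's
SATISFIED/FAILED outcome reflects the operator's raw truth value (so the
node "patient is male" reads FAILED for a female patient — transition
conditions, not outcomes, carry the screening intent).

## Operator registry and usage levels

Operators are tiered simple/advanced/ultimate; a scenario declares a
usage level and validation rejects calls above it. The published totals
(nine simple family finds, seven advanced operators, four ultimate
additions) are registry-conformance constants; beyond the finds, variable
operators, the temporal criterion, the exporter, the aggregates, the
value-set find and the two listeners, the advanced tier is completed by
two small utilities (`set_pointer_to_timestamp`, `get_event_property`)
this package defines. Pointer jumps and the gender lookup are registered
as simple-level utilities outside the nine-family count.

The two-timestamp criterion compares elapsed time exactly for hours and
days, and by calendar advance for months and years: `t2 − t1 ≤ m months`
holds iff `t2 ≤ t1 + m calendar months` (clamped). Calendar amounts must
be whole numbers. A null timestamp makes the criterion null, and null
conditions are never taken.

## Expression language

Transition conditions are infix boolean expressions over declared
variables and the node's last operator result (`result.found`,
`result.count`, `result.value_num`, …), with `==, !=, <, <=, >, >=`,
`and/or/not`, parentheses and literals. Logic is three-valued (Kleene):
nulls propagate through comparisons and connectives, and a null condition
falls through toward OTHERWISE — missing chart data never counts as
evidence. The single exception: `x == null` / `x != null` with a
syntactic `null` literal is a proper null *test* (like SQL's `IS NULL`),
since otherwise presence checks would be inexpressible.

Branching is deterministic: outgoing transitions evaluate in declared
order, first true wins, OTHERWISE last; with no true condition and no
OTHERWISE the execution simply ends. There are no join/split node types.

## Scenario serializations

The native dialect is YAML with a versioned `scenario_dialect` header and
round-trips to identity. The XPDL 1.0 subset honours Package,
WorkflowProcess, Activity, Transition (with Condition), Application,
Participant and DataField; node kinds, JSON-encoded operator calls,
declared transition order and variable types travel in extended
attributes under `ehrflow.*` names this package defines and documents —
the attribute layout of any particular workflow editor is not
reconstructed. Graphics coordinates and other vendor extensions are
ignored on read. XPDL round trips are checked by kind-respecting graph
isomorphism as well as field equality.

## Execution

Retrospective runs execute the scenario per patient over the complete
timeline, pointer reset to `BEFORE_FIRST`, variables reset to declared
initials. A node's operator calls run in order; the last result determines
the node outcome and is visible to conditions as `result`. Conclusion
nodes document a labelled conclusion; action nodes, if present
retrospectively, route to the report sink only. Listen nodes encountered
retrospectively execute as background searches (they share the find's
event pattern), which is what makes translation invertible. Subflows run
on the caller's variable state and trace. Every execution is bounded by a
configurable loop cap (default 1000 node visits per patient); a cap hit is
recorded as a per-patient error and the cohort run continues.

Prospective runs replay a time-ordered stream. The logical clock is the
event timestamps — no scheduler, so desk-scale testing is deterministic.
Each event first offers to resume paused instances of its patient (one
resume per delivery), then to the scenario's trigger patterns. Trigger and
listen nodes derive their event pattern from their first find-shaped
operator call; the pattern match mirrors the find's family/code semantics.
The default duplicate-trigger policy is *coalesce* (one instance per
scenario and patient, first trigger wins), chosen to mirror the
retrospective first-match semantics; *multiply* creates an instance per
matching event. Background steps inside an instance see only the events
already replayed, i.e. the past at the current clock. Patients are
isolated by construction: per-patient state never reads another patient's
events, and the tests verify interleaving-permutation invariance.

Translation retro→prospective is marker-driven — a marker file names the
background nodes that become triggers or listens and maps conclusion
nodes to action kinds — because which steps are future-oriented is
authorial intent, not derivable from the graph. Everything else (graph
shape, operator bindings, variables) is preserved, and `revert_translation`
restores the original. Translating a scenario that already contains
listen/action nodes warns that such logic cannot be fully tested
retrospectively without decomposition.

Prospective execution starts at the trigger node; nodes upstream of a
trigger would never run prospectively, so scenarios intended for both
modes should make the trigger their start node (the bundled fixture does).

## Reports

The summary report counts, per node, the patients that reached it and the
per-patient outcome (a patient counts once per node even through loops; a
node satisfies if any visit did, keeping every count ≤ cohort size).
Percentages carry two labelled denominators — executed cohort and
patients reaching the node — because either convention is defensible;
patients missing from the timeline set are reported separately and are in
neither. The detailed report reproduces trace content exactly; the
individual patient view is the full event table of one patient. Reports
are pure functions of traces and timelines.

## Synthetic data: what it emulates and what it does not

The generator emulates a chronological coded event stream for a
screening-age population: births 1920–1960, a demographic gender event at
birth, and per-family background events (lab, diagnosis, procedure,
prescription, visit) at Poisson rates of 1.5–4 events/patient/year over an
18-year active window starting at age 60 — modest, desk-scale rates chosen
so a 100-patient cohort holds roughly 20k events. Lab values are normal
draws per observation code. The fracture-risk pattern (female, fracture at
age 66–75, no density test or prevention drug before the fracture) is
planted at exact prevalence by a seeded permutation, with non-carriers
each assigned one explicit breaker (no fracture, male, fracture too young,
prior density test, or prior drug); a probabilistic i.i.d. mode exists
behind a flag. Some carriers receive a *post*-fracture density test to
exercise the pre-fracture search window.

The fixture scenario bounds its "never had a density test / prevention
drug" checks by the fracture date. This is the clinically sensible reading
(screening opportunities before the index event) and it is also what makes
retrospective and prospective runs provably equivalent: at trigger time a
prospective instance can only see the past, so a retrospective whole-record
search would disagree whenever the disqualifying event follows the
fracture.

What passing tests therefore show: the engine's search, window, pointer,
variable and lifecycle semantics are exact, and the two execution modes
agree on logic whose searches respect the trigger-time horizon. What they
do not show: performance or robustness on real EHR data — real records
have duplicated and contradictory codes, same-timestamp bursts across
families, terminology drift and missingness patterns the generator does
not model, and the illustrative code lists are not clinical assets.

## Numerical and procedural choices

* Concept codes are namespaced `terminology:code` so several
  terminologies coexist in one store; value-set expansion also matches the
  bare code as stored on events. Descendant closure excludes the root;
  relationship cycles are load errors so closure always terminates.
* Deterministic everywhere: cohort iteration is sorted, report tables have
  fixed column orders, the event writer is byte-stable, and repeated runs
  produce identical traces (asserted in tests).
* Problem sizes in the checks — 1000 oracle-equivalence cases, a
  100-patient cohort for mode equivalence and planted-truth recovery, 250
  pointer-invariant trials — were chosen as the smallest sizes at which
  every code path (empty windows, empty timelines, all pointer kinds, all
  breakers) is exercised; all complete in seconds.

## Known limitations

* No uncertainty handling: all coded facts are taken at face value; the
  three-valued logic covers missingness, not unreliability.
* The prospective engine is a replay harness with a logical clock; there
  is no wall-clock scheduler, messaging interface or EHR write-back —
  action sinks are pluggable callables/files.
* Foreign event schemas are supported only through column remapping
  (`EventDialect`); richer models (recursive attributes,
  observation-fact modifiers) are out of scope.
* Expression predicates inside serialized operator calls are limited to
  code/window matching; arbitrary Python predicates are available only
  through the library API.
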