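# ehrflow

Flowchart-driven clinical decision support over chronological EHR event
timelines.

Clinical logic — screening rules, quality-measure checks, adverse-event
detectors — is written as an executable flowchart (*scenario*): a directed
graph of typed nodes (trigger, background, analytical, listen, action,
conclusion) joined by condition-guarded transitions, with declared
variables passing information between steps. The same scenario
representation runs in two modes:

* **Retrospective** — the engine replays each patient's complete coded
  record like a chart abstractor, advancing a *current position pointer*
  through the chronologically ordered events. Conclusions are documented
  in cohort reports (summary, per-patient detailed, individual patient
  view), which is how logic is tested and tuned before deployment.
* **Prospective** — after a marker-driven translation (future-oriented
  background steps become trigger/listen steps, conclusions become
  actions), the same graph consumes a live event stream: trigger listeners
  instantiate the scenario, listen steps pause it until a matching event
  arrives, action steps emit alert records to configured sinks.

The package is aimed at clinical informaticians who want to prototype
decision-support logic on retrospective data and deploy the identical
representation prospectively, and at anyone needing a temporal,
single-patient query engine over coded event tables.

## The model in brief

A patient record is a sequence of events
*e₁ ≤ e₂ ≤ … ≤ eₙ* ordered by `(ev_time, sequence_id)`, each event carrying
an event type/subtype, observation, coded value, flag, numeric and text
values, and a secondary terminology code. Scenario execution maintains a
pointer position *p* ∈ {BEFORE_FIRST, AT_EVENT(i), AT_TIME(t), AFTER_LAST}.
A *strict-mode* find scans strictly after *p* and moves *p* to the first
match on success, leaving it untouched on failure, so the effective time of
*p* is non-decreasing along any chain of successful finds. *Custom-mode*
finds search an arbitrary window [*l*, *u*] without touching *p*.

Operators come in three usage levels: nine **simple** per-family finds
(`find_diagnosis(code)`, `find_lab_result(code)`, `find_visit(code)`, …)
returning only found/not-found; seven **advanced** operators (windowed
`find_coded_event` with full result sets and counts, variable assignment
and counters, a two-timestamp calendar criterion, CSV export, pointer
repositioning, event-property access); and four **ultimate** additions
(result-set aggregates, ontology value-set finds, trigger and relevant
event listeners). Value sets expand through an ontology of namespaced
concepts with typed relationships (`is_a`, `is_member`, …) supporting
multiple parents — e.g. a drug-class concept enumerating its dispensable
members.

Scenarios serialize to a native YAML dialect and to an XPDL 1.0 subset
(Package, WorkflowProcess, Activity, Transition/Condition, Application,
Participant, DataField), with node kinds and operator bindings carried in
extended attributes; both forms round-trip through the same in-memory
model.

## Worked example

Generate a 100-patient synthetic cohort with the osteoporosis screening
pattern planted in exactly 30% of patients, then run the bundled
retrospective scenario (women with a fracture after age 65, no bone
mineral density test and no prevention drug before the fracture):

```sh
ehrflow generate --seed 1 --n-patients 100 --out events.csv
python -c "from ehrflow import fixture_osteoporosis, write_native; \
           write_native(fixture_osteoporosis().retro, 'osteoporosis.yaml')"
ehrflow run-retro --scenario osteoporosis.yaml --events events.csv --out run/
```

which prints

```
executed 100 patients (0 missing, 0 errors); 30 concluded (30.0% of cohort)
```

`run/summary_nodes.csv` answers "how many cohort patients satisfied each
step": all 100 reach the fracture step, 81 have a fracture, 71 of those
are old enough at fracture, 43 are female, and after excluding prior
density tests (6) and prior prevention drugs (7), 30 patients reach the
conclusion — exactly the planted prevalence:

```
node_id,reached,satisfied,failed,pct_of_cohort,pct_of_reached
s_age,81,71,10,81.0,100.0
s_bmd,43,6,37,43.0,100.0
s_conclude,30,30,0,30.0,100.0
s_drug,37,7,30,37.0,100.0
s_female,71,28,43,71.0,100.0
s_fracture,100,81,19,100.0,100.0
...
```

Translating the same scenario with its marker file and replaying the full
event stream prospectively produces the same 30 patients as alert actions
instead of report conclusions:

```sh
ehrflow translate --scenario osteoporosis.yaml --markers markers.yaml --out prospective.yaml
ehrflow replay --scenario prospective.yaml --events events.csv --out replay/
# -> 81 instances, 30 actions
```

That retrospective/prospective agreement is the package's central
property: logic validated on historical cohorts deploys unchanged.

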