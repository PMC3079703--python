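"""Scenario execution: retrospective chart review, prospective event
replay, and the translation between the two.

Retrospective runs walk each cohort patient's complete timeline like a
chart abstractor: the scenario starts at the beginning of the record and
its find operators advance the current position pointer forward.  Scenario
conclusions are documented in the execution trace, never delivered
anywhere.

Prospective runs consume a time-ordered event stream.  Trigger nodes
register listeners that instantiate the scenario when a matching event
arrives; background nodes search only the part of the record already
replayed (the logical clock is the event timestamps); listen nodes pause
the instance until a matching later event resumes it; action nodes emit
records to configured sinks.  Patients are isolated: interleaving of
different patients' events never affects an individual outcome.

A retrospective scenario becomes a prospective one by marker-driven
translation: marked background nodes flip to listen (or trigger) nodes
with the same event pattern, and conclusion nodes flip to action nodes.
The graph shape is preserved, which is what makes logic tested on
historical data deployable unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime
from enum import Enum
from typing import Any, Callable, Iterable, Mapping, Optional, Sequence, Union

import yaml
from dateutil.relativedelta import relativedelta

from .events import (
    Event,
    PatientTimeline,
    Position,
    PositionKind,
    build_timelines,
    jump_forward_months,
    jump_to_last_ehr_event,
    parse_timestamp,
)
from .ontology import OntologyStore
from .operators import (
    DEFAULT_FAMILIES,
    DEFAULT_GENDER,
    FamilyDialect,
    FindResult,
    GenderMapping,
    ListenSpec,
    OperatorCall,
    PointerMode,
    SearchWindow,
    VariableState,
    aggregate_events,
    evaluate_two_timestamps_difference_criterion,
    find_events,
    get_event_property,
    patient_is_male,
    set_pointer_to_timestamp,
)
from .scenario import Node, NodeKind, Scenario, ScenarioError, Transition, validate

__all__ = [
    "NodeVisit",
    "ConclusionRecord",
    "ActionRecord",
    "ExecutionTrace",
    "RunOutput",
    "InstanceState",
    "ScenarioInstance",
    "ProspectiveRun",
    "TranslationMarkers",
    "ExecutionError",
    "run_retrospective",
    "run_prospective",
    "translate_retro_to_prospective",
    "revert_translation",
    "read_markers",
    "write_markers",
]

ACTION_KINDS = (
    "update_report",
    "update_registry",
    "send_email",
    "generate_alert",
    "create_order",
    "cancel_order",
)

DEFAULT_LOOP_CAP = 1000


class ExecutionError(RuntimeError):
    pass


class Outcome(str, Enum):
    SATISFIED = "SATISFIED"
    FAILED = "FAILED"
    SKIPPED = "SKIPPED"


@dataclass(frozen=True)
class NodeVisit:
    node_id: str
    outcome: str
    matched_events: tuple[str, ...]  # compact event summaries
    pointer_after: str


@dataclass(frozen=True)
class ConclusionRecord:
    label: str
    node_id: str
    at: Optional[datetime]


@dataclass(frozen=True)
class ActionRecord:
    action_kind: str
    payload: str
    target: str
    emitted_at: Optional[datetime]
    patient_id: str = ""
    node_id: str = ""


@dataclass
class ExecutionTrace:
    """Per-patient record of one scenario execution."""

    patient_id: str
    scenario_id: str
    visited: list[NodeVisit] = field(default_factory=list)
    variable_history: list[tuple[str, dict[str, Any]]] = field(default_factory=list)
    conclusions: list[ConclusionRecord] = field(default_factory=list)
    actions: list[ActionRecord] = field(default_factory=list)
    variables: dict[str, Any] = field(default_factory=dict)
    error: Optional[str] = None

    def conclusion_labels(self) -> tuple[str, ...]:
        """Conclusion labels plus action payloads, in emission order: the
        mode-independent summary of what the scenario decided."""
        records: list[tuple] = [(c, c.label) for c in self.conclusions]
        records += [(a, a.payload) for a in self.actions]
        return tuple(label for _, label in records)


class RunOutput(dict):
    """``patient_id -> ExecutionTrace`` plus run metadata."""

    def __init__(self, *args: Any, **kwargs: Any):
        super().__init__(*args, **kwargs)
        self.missing_patients: list[str] = []
        self.log: list[str] = []


# ---------------------------------------------------------------------------
# Operator invocation within a node


@dataclass
class _ResultView:
    """Uniform face of a node's last operator result for conditions:
    ``result.found``, ``result.count``, ``result.value_num`` etc."""

    raw: Any = None

    def __getattr__(self, name: str) -> Any:
        raw = object.__getattribute__(self, "raw")
        if isinstance(raw, FindResult):
            if name in ("found", "count", "matches", "first_match", "pointer_after"):
                return getattr(raw, name)
            if raw.first_match is not None and hasattr(raw.first_match, name):
                return getattr(raw.first_match, name)
            return None
        if name == "found":
            return None if raw is None else bool(raw)
        if name == "value":
            return raw
        if raw is not None and hasattr(raw, name):
            return getattr(raw, name)
        return None

    @property
    def truth(self) -> Optional[bool]:
        raw = self.raw
        if raw is None:
            return None
        if isinstance(raw, FindResult):
            return raw.found
        if isinstance(raw, bool):
            return raw
        return True  # positions, values, aggregates: the op ran


@dataclass
class _Context:
    timeline: PatientTimeline
    variables: VariableState
    mode: str  # retrospective | prospective
    ontology: Optional[OntologyStore] = None
    families: Mapping[str, FamilyDialect] = field(default_factory=lambda: DEFAULT_FAMILIES)
    gender: GenderMapping = DEFAULT_GENDER
    clock: Optional[datetime] = None
    last: _ResultView = field(default_factory=_ResultView)

    def env(self) -> dict[str, Any]:
        return {**self.variables, "result": self.last}

    def resolve(self, value: Any) -> Any:
        """Resolve ``$name`` / ``$result.path`` references in op arguments."""
        if isinstance(value, str) and value.startswith("$"):
            path = value[1:]
            head, _, rest = path.partition(".")
            env = self.env()
            if head not in env:
                raise ExecutionError(f"unresolvable reference {value!r}")
            obj: Any = env[head]
            for part in rest.split(".") if rest else []:
                if obj is None:
                    return None
                obj = getattr(obj, part, None) if not isinstance(obj, Mapping) else obj.get(part)
            return obj
        return value

    def _time_bound(self, spec: Any) -> Optional[datetime]:
        if spec is None:
            return None
        if isinstance(spec, Mapping) and "months_before_pointer" in spec:
            anchor = self.timeline.effective_time()
            if anchor is None:
                return None
            return anchor - relativedelta(months=int(spec["months_before_pointer"]))
        if spec == "POINTER":
            return self.timeline.effective_time()
        if spec == "END_OF_RECORD":
            return None
        resolved = self.resolve(spec)
        if resolved is None or isinstance(resolved, datetime):
            return resolved
        return parse_timestamp(str(resolved))

    def window(self, spec: Any) -> Optional[SearchWindow]:
        if spec is None:
            return None
        if not isinstance(spec, Mapping):
            raise ExecutionError(f"window must be a mapping, got {spec!r}")
        return SearchWindow(self._time_bound(spec.get("lower")),
                            self._time_bound(spec.get("upper")))


def _as_timestamp(ctx: _Context, value: Any) -> Optional[datetime]:
    v = ctx.resolve(value)
    if v is None or isinstance(v, datetime):
        return v
    return parse_timestamp(str(v))


def _invoke(ctx: _Context, call: OperatorCall) -> Any:
    """Dispatch one operator call against the execution context."""
    name = call.op_name
    a = call.args
    if name.startswith("find_") and name[5:] in ctx.families:
        return find_events(
            ctx.timeline, family=name[5:], code=str(ctx.resolve(a["code"])),
            families=ctx.families,
        )
    if name == "find_coded_event":
        return find_events(
            ctx.timeline,
            family=a.get("family"),
            code=ctx.resolve(a.get("code")),
            codes=[ctx.resolve(c) for c in a["codes"]] if "codes" in a else None,
            window=ctx.window(a.get("window")),
            pointer_mode=PointerMode(a.get("pointer_mode", "STRICT")),
            families=ctx.families,
        )
    if name == "find_coded_event_vs":
        if ctx.ontology is None:
            raise ExecutionError("find_coded_event_vs needs an ontology store")
        from .operators import find_coded_event_vs

        return find_coded_event_vs(
            ctx.timeline,
            ctx.ontology,
            a.get("family"),
            a["value_set_concept"],
            rel_type=a.get("rel_type", "is_member"),
            depth=a.get("depth", "ALL"),
            window=ctx.window(a.get("window")),
            pointer_mode=PointerMode(a.get("pointer_mode", "STRICT")),
            families=ctx.families,
        )
    if name == "patient_is_male":
        return patient_is_male(ctx.timeline, ctx.gender)
    if name == "jump_to_last_ehr_event":
        return jump_to_last_ehr_event(ctx.timeline)
    if name == "jump_forward_months":
        return jump_forward_months(ctx.timeline, int(ctx.resolve(a["n"])))
    if name == "set_pointer_to_timestamp":
        t = _as_timestamp(ctx, a["t"])
        if t is None:
            raise ExecutionError("set_pointer_to_timestamp got a null timestamp")
        return set_pointer_to_timestamp(ctx.timeline, t)
    if name == "assign_value_to_variable":
        value = ctx.resolve(a["value"])
        ctx.variables.assign(str(a["var"]), value)
        return value
    if name == "increase_counter_variable":
        from .operators import increase_counter_variable

        return increase_counter_variable(
            ctx.variables, str(a["var"]), float(ctx.resolve(a.get("increment", 1)))
        )
    if name == "evaluate_two_timestamps_difference_criterion":
        return evaluate_two_timestamps_difference_criterion(
            _as_timestamp(ctx, a["t1"]),
            _as_timestamp(ctx, a["t2"]),
            str(a["comparator"]),
            float(a["amount"]),
            str(a["unit"]),
        )
    if name == "get_event_property":
        result = ctx.resolve(a.get("result", "$result"))
        if isinstance(result, _ResultView):
            result = result.raw
        return get_event_property(result, str(a["prop"]))
    if name == "aggregate_events":
        events = ctx.resolve(a.get("events", "$result.matches")) or ()
        return aggregate_events(events, a.get("field_name", "value_num"),
                                a.get("stat", "AVG"))
    raise ExecutionError(f"operator {name!r} cannot be invoked from a scenario node")


def _listen_spec_from_node(node: Node) -> ListenSpec:
    """Derive the event pattern a trigger/listen node waits for from its
    first (find-shaped) operator call."""
    for call in node.op_calls:
        a = call.args
        if call.op_name.startswith("find_") and call.op_name != "find_coded_event_vs":
            family = a.get("family")
            if family is None and call.op_name not in ("find_coded_event",):
                family = call.op_name[5:]
            code = a.get("code")
            return ListenSpec(family=family, code=None if code is None else str(code),
                              description=node.label)
        if call.op_name == "find_coded_event_vs":
            return ListenSpec(
                family=a.get("family"),
                value_set_concept=a["value_set_concept"],
                rel_type=a.get("rel_type", "is_member"),
                description=node.label,
            )
    raise ScenarioError(
        f"node {node.id!r} of kind {node.node_kind.value!r} has no find-shaped "
        "operator call to derive an event pattern from"
    )


def _parse_action_label(label: str) -> tuple[str, str]:
    head, sep, rest = label.partition(":")
    if sep and head.strip() in ACTION_KINDS:
        return head.strip(), rest.strip()
    return "generate_alert", label


def _summarize(e: Event) -> str:
    bits = [e.ev_time.isoformat(sep=" "), e.event_type.desc or e.event_type.code or ""]
    for f in ("event_subtype", "observation", "coded_value", "terminology2"):
        c = getattr(e, f)
        if c is not None:
            bits.append(c.code or c.desc or "")
    if e.value_num is not None:
        bits.append(str(e.value_num))
    return "|".join(bits)


def _describe_pointer(p: Position) -> str:
    if p.kind is PositionKind.AT_EVENT:
        return f"AT_EVENT[{p.index}]"
    if p.kind is PositionKind.AT_TIME:
        return f"AT_TIME[{p.time.isoformat(sep=' ')}]"
    return p.kind.value


# ---------------------------------------------------------------------------
# Single-instance execution (shared by both modes)


@dataclass
class _Stepper:
    scenario: Scenario
    ctx: _Context
    trace: ExecutionTrace
    loop_cap: int = DEFAULT_LOOP_CAP
    visits: int = 0
    sink: Optional[Callable[[ActionRecord], None]] = None

    def emission_time(self) -> Optional[datetime]:
        if self.ctx.mode == "prospective":
            return self.ctx.clock
        return self.ctx.timeline.effective_time()

    def visit(self, node: Node) -> Outcome:
        self.visits += 1
        if self.visits > self.loop_cap:
            raise ExecutionError(
                f"loop cap of {self.loop_cap} node visits exceeded at node {node.id!r}"
            )
        outcome = Outcome.SATISFIED
        if node.node_kind is NodeKind.CONCLUSION:
            self.trace.conclusions.append(
                ConclusionRecord(node.label or node.id, node.id, self.emission_time())
            )
        elif node.node_kind is NodeKind.ACTION:
            kind, payload = _parse_action_label(node.label or node.id)
            record = ActionRecord(
                action_kind=kind,
                payload=payload or node.id,
                target="report" if self.ctx.mode == "retrospective" else "sinks",
                emitted_at=self.emission_time(),
                patient_id=self.trace.patient_id,
                node_id=node.id,
            )
            self.trace.actions.append(record)
            if self.sink is not None and self.ctx.mode == "prospective":
                self.sink(record)
        elif node.node_kind is NodeKind.SUBFLOW:
            sub = self.scenario.subprocess(node.subflow_ref)
            outcome = self._run_subflow(sub)
        else:
            for call in node.op_calls:
                result = _invoke(self.ctx, call)
                self.ctx.last = _ResultView(result)
                if call.result_var is not None:
                    self.ctx.variables.assign(call.result_var, result)
            if node.op_calls:
                truth = self.ctx.last.truth
                outcome = Outcome.SATISFIED if truth else Outcome.FAILED
        self.trace.visited.append(
            NodeVisit(
                node_id=node.id,
                outcome=outcome.value,
                matched_events=tuple(
                    _summarize(e) for e in (
                        self.ctx.last.raw.matches
                        if isinstance(self.ctx.last.raw, FindResult)
                        else ()
                    )
                ),
                pointer_after=_describe_pointer(self.ctx.timeline.pointer),
            )
        )
        self.trace.variable_history.append((node.id, dict(self.ctx.variables)))
        return outcome

    def _run_subflow(self, sub: Scenario) -> Outcome:
        # subflows share the caller's variable state, timeline and trace
        saved = self.scenario
        self.scenario = replace(sub, subprocesses=saved.subprocesses)
        try:
            node: Optional[Node] = sub.start_node()
            while node is not None:
                self.visit(node)
                node = self.next_node(node)
        finally:
            self.scenario = saved
        return Outcome.SATISFIED

    def next_node(self, node: Node) -> Optional[Node]:
        """First transition whose condition holds, in declared order; null
        conditions are logged and fall through to OTHERWISE."""
        fallback: Optional[Transition] = None
        env = self.ctx.env()
        for t in self.scenario.outgoing(node.id):
            if t.otherwise:
                fallback = t
                continue
            if t.condition is None:
                return self.scenario.node(t.to_id)
            # a null condition (missing data) is never taken; it falls
            # through toward OTHERWISE
            if t.condition.evaluate(env) is True:
                return self.scenario.node(t.to_id)
        if fallback is not None:
            return self.scenario.node(fallback.to_id)
        return None


# ---------------------------------------------------------------------------
# Retrospective execution


def run_retrospective(
    scenario: Scenario,
    timelines: Mapping[str, PatientTimeline],
    cohort: Optional[Iterable[str]] = None,
    ontology: Optional[OntologyStore] = None,
    families: Mapping[str, FamilyDialect] = DEFAULT_FAMILIES,
    gender: GenderMapping = DEFAULT_GENDER,
    loop_cap: int = DEFAULT_LOOP_CAP,
) -> RunOutput:
    """Execute a scenario over complete historical timelines, one patient
    at a time; returns a map ``patient_id -> ExecutionTrace``.

    Conclusions and actions are only documented in the traces (the report
    sink); nothing is delivered.  Trigger and listen nodes, if present,
    execute as retrospective searches.  A patient whose execution exceeds
    the loop cap gets an error trace; the run continues for the others.
    """
    findings = validate(scenario)
    if findings:
        raise ScenarioError("scenario does not validate: " + "; ".join(map(str, findings)))
    out = RunOutput()
    cohort_ids = sorted(set(cohort)) if cohort is not None else sorted(timelines)
    for pid in cohort_ids:
        if pid not in timelines:
            out.missing_patients.append(pid)
            continue
        timeline = replace(timelines[pid], pointer=Position.before_first())
        trace = _run_single(scenario, timeline, ontology, families, gender, loop_cap)
        out[pid] = trace
        for v in trace.visited:
            out.log.append(
                f"patient={pid} node={v.node_id} outcome={v.outcome} "
                f"pointer={v.pointer_after} matched={len(v.matched_events)}"
            )
    if out.missing_patients:
        warnings.warn(
            f"{len(out.missing_patients)} cohort patient(s) have no timeline: "
            + ", ".join(out.missing_patients[:5]),
            stacklevel=2,
        )
    return out


def _initial_state(scenario: Scenario) -> VariableState:
    return VariableState(
        (v.name for v in scenario.variables),
        {v.name: v.initial for v in scenario.variables if v.initial is not None},
    )


def _run_single(
    scenario: Scenario,
    timeline: PatientTimeline,
    ontology: Optional[OntologyStore],
    families: Mapping[str, FamilyDialect],
    gender: GenderMapping,
    loop_cap: int,
) -> ExecutionTrace:
    ctx = _Context(timeline=timeline, variables=_initial_state(scenario),
                   mode="retrospective", ontology=ontology, families=families, gender=gender)
    trace = ExecutionTrace(timeline.patient_id, scenario.id)
    stepper = _Stepper(scenario, ctx, trace, loop_cap)
    try:
        node: Optional[Node] = scenario.start_node()
        while node is not None:
            stepper.visit(node)
            node = stepper.next_node(node)
    except ExecutionError as exc:
        trace.error = str(exc)
    trace.variables = dict(ctx.variables)
    return trace


# ---------------------------------------------------------------------------
# Retro -> prospective translation


@dataclass(frozen=True)
class TranslationMarkers:
    """Which nodes flip during retro->prospective translation.

    ``trigger_nodes``: background nodes whose event becomes the scenario
    trigger.  ``listen_nodes``: background nodes that wait for the event
    instead of searching for it.  ``action_nodes``: conclusion node id ->
    action kind.  Translation is marker-driven because intent (which steps
    are future-oriented) is the author's call, not derivable from the
    graph.
    """

    trigger_nodes: frozenset[str] = frozenset()
    listen_nodes: frozenset[str] = frozenset()
    action_nodes: Mapping[str, str] = field(default_factory=dict)


def read_markers(source: Union[str, Any]) -> TranslationMarkers:
    if isinstance(source, str):
        with open(source, "r", encoding="utf-8") as fh:
            return read_markers(fh)
    data = yaml.safe_load(source) or {}
    return TranslationMarkers(
        frozenset(data.get("trigger") or ()),
        frozenset(data.get("listen") or ()),
        dict(data.get("actions") or {}),
    )


def write_markers(markers: TranslationMarkers, dest: Union[str, Any, None] = None) -> str:
    text = yaml.safe_dump(
        {
            "trigger": sorted(markers.trigger_nodes),
            "listen": sorted(markers.listen_nodes),
            "actions": dict(markers.action_nodes),
        },
        sort_keys=False,
    )
    if isinstance(dest, str):
        with open(dest, "w", encoding="utf-8") as fh:
            fh.write(text)
    elif dest is not None:
        dest.write(text)
    return text


def translate_retro_to_prospective(
    scenario: Scenario, markers: TranslationMarkers
) -> Scenario:
    """Flip marked background nodes to trigger/listen nodes and mapped
    conclusion nodes to action nodes; everything else — graph shape,
    operator bindings, variables — is preserved.  Unmarked background
    nodes keep querying the past portion of the record at run time.
    """
    if any(n.node_kind in (NodeKind.LISTEN, NodeKind.ACTION) for n in scenario.nodes):
        warnings.warn(
            "scenario already contains listen/action nodes; such logic cannot be "
            "fully tested retrospectively unless decomposed into sub-scenarios",
            stacklevel=2,
        )
    nodes = []
    for n in scenario.nodes:
        if n.id in markers.trigger_nodes:
            _listen_spec_from_node(n)  # validates an event pattern exists
            nodes.append(replace(n, node_kind=NodeKind.TRIGGER))
        elif n.id in markers.listen_nodes:
            _listen_spec_from_node(n)
            nodes.append(replace(n, node_kind=NodeKind.LISTEN))
        elif n.id in markers.action_nodes:
            if n.node_kind is not NodeKind.CONCLUSION:
                raise ScenarioError(
                    f"action marker on node {n.id!r}, which is {n.node_kind.value}, "
                    "not a conclusion"
                )
            kind = markers.action_nodes[n.id]
            if kind not in ACTION_KINDS:
                raise ScenarioError(f"unknown action kind {kind!r} for node {n.id!r}")
            nodes.append(
                replace(n, node_kind=NodeKind.ACTION, label=f"{kind}: {n.label or n.id}")
            )
        else:
            nodes.append(n)
    return replace(scenario, id=f"{scenario.id}_prospective", nodes=tuple(nodes))


def revert_translation(scenario: Scenario, markers: TranslationMarkers) -> Scenario:
    """Inverse of translation for marker round-trips: trigger/listen nodes
    revert to background, action nodes to conclusion with their original
    labels."""
    nodes = []
    for n in scenario.nodes:
        if n.id in markers.trigger_nodes or n.id in markers.listen_nodes:
            nodes.append(replace(n, node_kind=NodeKind.BACKGROUND))
        elif n.id in markers.action_nodes:
            _, payload = _parse_action_label(n.label)
            nodes.append(replace(n, node_kind=NodeKind.CONCLUSION, label=payload))
        else:
            nodes.append(n)
    base_id = scenario.id[: -len("_prospective")] if scenario.id.endswith("_prospective") else scenario.id
    return replace(scenario, id=base_id, nodes=tuple(nodes))


# ---------------------------------------------------------------------------
# Prospective execution (event replay)


class InstanceState(str, Enum):
    RUNNING = "RUNNING"
    PAUSED_AT_LISTEN = "PAUSED_AT_LISTEN"
    COMPLETED = "COMPLETED"
    EXPIRED = "EXPIRED"


@dataclass
class ScenarioInstance:
    patient_id: str
    scenario_id: str
    state: InstanceState
    created_at: datetime
    trace: ExecutionTrace
    paused_node: Optional[str] = None
    paused_at: Optional[datetime] = None
    resumed_at: Optional[datetime] = None
    variables: Optional[VariableState] = None


@dataclass
class ProspectiveRun:
    instances: list[ScenarioInstance]
    actions: list[ActionRecord]
    log: list[str]

    def traces(self) -> dict[str, ExecutionTrace]:
        """Per-patient trace of the (first) instance per patient."""
        out: dict[str, ExecutionTrace] = {}
        for inst in self.instances:
            out.setdefault(inst.patient_id, inst.trace)
        return out


class ReplayContext:
    """Listener registry used while replaying an event stream."""

    mode = "prospective"

    def __init__(self) -> None:
        self.trigger_specs: list[tuple[Node, ListenSpec]] = []
        self.relevant: list[tuple[ScenarioInstance, Node, ListenSpec]] = []

    def register_trigger(self, spec: ListenSpec, node: Optional[Node] = None) -> None:
        self.trigger_specs.append((node, spec))

    def register_relevant(
        self, spec: ListenSpec, instance: Optional[ScenarioInstance] = None,
        node: Optional[Node] = None,
    ) -> None:
        self.relevant.append((instance, node, spec))


def run_prospective(
    scenario: Scenario,
    event_stream: Iterable[Event],
    ontology: Optional[OntologyStore] = None,
    sinks: Optional[Mapping[str, Callable[[ActionRecord], None]]] = None,
    cohort: Optional[Iterable[str]] = None,
    families: Mapping[str, FamilyDialect] = DEFAULT_FAMILIES,
    gender: GenderMapping = DEFAULT_GENDER,
    loop_cap: int = DEFAULT_LOOP_CAP,
    duplicate_triggers: str = "coalesce",
) -> ProspectiveRun:
    """Replay a time-ordered event feed through a prospective scenario.

    Each event is first offered to the listen patterns of paused instances
    of its patient (one resume per delivery), then to the scenario's
    trigger patterns.  With the default ``coalesce`` policy a patient gets
    at most one instance per scenario; ``multiply`` creates one per
    matching trigger event.  Action records go to every configured sink
    and are always collected on the run itself.
    """
    findings = validate(scenario)
    if findings:
        raise ScenarioError("scenario does not validate: " + "; ".join(map(str, findings)))
    trigger_nodes = [n for n in scenario.nodes if n.node_kind is NodeKind.TRIGGER]
    if not trigger_nodes:
        raise ScenarioError("prospective execution needs at least one trigger node")
    if duplicate_triggers not in ("coalesce", "multiply"):
        raise ValueError("duplicate_triggers must be 'coalesce' or 'multiply'")

    replay = ReplayContext()
    for node in trigger_nodes:
        replay.register_trigger(_listen_spec_from_node(node), node)

    cohort_set = set(cohort) if cohort is not None else None
    run = ProspectiveRun([], [], [])
    sinks = dict(sinks or {})

    def emit(record: ActionRecord) -> None:
        run.actions.append(record)
        for sink in sinks.values():
            sink(record)

    per_patient: dict[str, list[Event]] = {}
    steppers: dict[int, _Stepper] = {}
    triggered: set[str] = set()  # patients with an instance (coalesce policy)

    for event in event_stream:
        if not isinstance(event, Event):
            run.log.append(f"dropped malformed stream item: {event!r}")
            continue
        if cohort_set is not None and event.patient_id not in cohort_set:
            run.log.append(f"event for unknown patient {event.patient_id!r} ignored")
            continue
        bucket = per_patient.setdefault(event.patient_id, [])
        bucket.append(event)
        clock = event.ev_time

        # 1. offer to paused instances of this patient
        for entry in list(replay.relevant):
            inst, node, spec = entry
            if inst.patient_id != event.patient_id:
                continue
            if inst.state is not InstanceState.PAUSED_AT_LISTEN:
                replay.relevant.remove(entry)
                continue
            if not spec.matches(event, ontology, families):
                continue
            replay.relevant.remove(entry)
            _resume(inst, node, event, bucket, clock, scenario, steppers, replay, run,
                    loop_cap, emit)

        # 2. offer to trigger patterns
        if duplicate_triggers == "coalesce" and event.patient_id in triggered:
            continue
        for node, spec in replay.trigger_specs:
            if spec.matches(event, ontology, families):
                triggered.add(event.patient_id)
                _start_instance(scenario, node, event, bucket, clock, ontology,
                                families, gender, steppers, replay, run, loop_cap, emit)
                break
    return run


def _timeline_from(bucket: Sequence[Event], patient_id: str) -> PatientTimeline:
    return PatientTimeline(
        patient_id, tuple(sorted(bucket, key=lambda e: e.sort_key))
    )


def _advance(
    inst: ScenarioInstance,
    stepper: _Stepper,
    node: Optional[Node],
    replay: ReplayContext,
    run: ProspectiveRun,
) -> None:
    """Run an instance forward until it completes or pauses at a listen node."""
    try:
        while node is not None:
            if node.node_kind is NodeKind.LISTEN:
                inst.state = InstanceState.PAUSED_AT_LISTEN
                inst.paused_node = node.id
                inst.paused_at = stepper.ctx.clock
                replay.register_relevant(_listen_spec_from_node(node), inst, node)
                run.log.append(
                    f"patient={inst.patient_id} instance paused at listen node {node.id}"
                )
                return
            stepper.visit(node)
            run.log.append(
                f"patient={inst.patient_id} node={node.id} "
                f"outcome={stepper.trace.visited[-1].outcome}"
            )
            node = stepper.next_node(node)
    except ExecutionError as exc:
        stepper.trace.error = str(exc)
    inst.state = InstanceState.COMPLETED
    stepper.trace.variables = dict(stepper.ctx.variables)


def _start_instance(
    scenario: Scenario,
    trigger_node: Node,
    event: Event,
    bucket: Sequence[Event],
    clock: datetime,
    ontology: Optional[OntologyStore],
    families: Mapping[str, FamilyDialect],
    gender: GenderMapping,
    steppers: dict[int, _Stepper],
    replay: ReplayContext,
    run: ProspectiveRun,
    loop_cap: int,
    emit: Callable[[ActionRecord], None],
) -> None:
    timeline = _timeline_from(bucket, event.patient_id)
    idx = timeline.events.index(event)
    timeline.pointer = Position.at_event(idx)
    ctx = _Context(timeline=timeline, variables=_initial_state(scenario),
                   mode="prospective", ontology=ontology, families=families,
                   gender=gender, clock=clock)
    ctx.last = _ResultView(FindResult.of([event], timeline.pointer))
    trace = ExecutionTrace(event.patient_id, scenario.id)
    inst = ScenarioInstance(
        patient_id=event.patient_id, scenario_id=scenario.id,
        state=InstanceState.RUNNING, created_at=clock, trace=trace,
    )
    inst.variables = ctx.variables
    stepper = _Stepper(scenario, ctx, trace, loop_cap, sink=emit)
    steppers[id(inst)] = stepper
    run.instances.append(inst)
    run.log.append(f"patient={event.patient_id} instance created by trigger "
                   f"node {trigger_node.id}")
    # the trigger event is the node's match: record the visit, then run
    # any non-find ops the trigger node carries beyond its pattern
    for call in trigger_node.op_calls[1:]:
        result = _invoke(ctx, call)
        ctx.last = _ResultView(result)
        if call.result_var is not None:
            ctx.variables.assign(call.result_var, result)
    if trigger_node.op_calls and trigger_node.op_calls[0].result_var is not None:
        ctx.variables.assign(trigger_node.op_calls[0].result_var,
                             FindResult.of([event], timeline.pointer))
    stepper.trace.visited.append(
        NodeVisit(trigger_node.id, Outcome.SATISFIED.value,
                  (_summarize(event),), _describe_pointer(timeline.pointer))
    )
    stepper.trace.variable_history.append((trigger_node.id, dict(ctx.variables)))
    _advance(inst, stepper, stepper.next_node(trigger_node), replay, run)


def _resume(
    inst: ScenarioInstance,
    listen_node: Node,
    event: Event,
    bucket: Sequence[Event],
    clock: datetime,
    scenario: Scenario,
    steppers: dict[int, _Stepper],
    replay: ReplayContext,
    run: ProspectiveRun,
    loop_cap: int,
    emit: Callable[[ActionRecord], None],
) -> None:
    stepper = steppers[id(inst)]
    timeline = _timeline_from(bucket, event.patient_id)
    idx = timeline.events.index(event)
    timeline.pointer = Position.at_event(idx)
    stepper.ctx.timeline = timeline
    stepper.ctx.clock = clock
    stepper.ctx.last = _ResultView(FindResult.of([event], timeline.pointer))
    inst.state = InstanceState.RUNNING
    inst.resumed_at = clock
    inst.paused_node = None
    if listen_node.op_calls and listen_node.op_calls[0].result_var is not None:
        stepper.ctx.variables.assign(
            listen_node.op_calls[0].result_var, stepper.ctx.last.raw
        )
    stepper.trace.visited.append(
        NodeVisit(listen_node.id, Outcome.SATISFIED.value,
                  (_summarize(event),), _describe_pointer(timeline.pointer))
    )
    stepper.trace.variable_history.append((listen_node.id, dict(stepper.ctx.variables)))
    run.log.append(f"patient={inst.patient_id} instance resumed at node {listen_node.id}")
    _advance(inst, stepper, stepper.next_node(listen_node), replay, run)
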