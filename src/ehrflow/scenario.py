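"""Executable scenario model: a typed flowchart over patient timelines.

A *scenario* is a directed graph of typed nodes — trigger, background,
analytical, listen, action, conclusion (plus dummy-start and subflow
helpers) — joined by transitions whose conditions are small boolean
expressions.  Operator calls hang off the nodes; variables declared on the
process pass information between steps.  The same scenario representation
is executed retrospectively over complete records and prospectively over
live event streams.

Two serializations are supported and round-trip through the same model: a
native structured-text (YAML) dialect, and a subset of the XPDL 1.0
workflow-process vocabulary (Package, WorkflowProcess, Activity, Transition
with Condition, Application, Participant, DataField).  Node kinds and
operator bindings ride in XPDL extended attributes under names this package
defines; graphics coordinates and other vendor extensions are ignored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from enum import Enum
from typing import Any, Mapping, Optional, TextIO, Union

import networkx as nx
import yaml
from lxml import etree

from .expressions import Expression, ExpressionError, parse_expression
from .operators import LEVEL_ORDER, REGISTRY, OperatorCall

__all__ = [
    "NodeKind",
    "Node",
    "Transition",
    "VariableDecl",
    "Scenario",
    "ScenarioError",
    "Finding",
    "validate",
    "read_native",
    "write_native",
    "read_xpdl",
    "write_xpdl",
    "scenario_graph",
    "isomorphic",
]

XPDL_NS = "http://www.wfmc.org/2002/XPDL1.0"
NATIVE_DIALECT_VERSION = 1

VAR_TYPES = ("boolean", "number", "text", "timestamp", "event_set")

_XPDL_BASIC_TYPE = {
    "boolean": "BOOLEAN",
    "number": "FLOAT",
    "text": "STRING",
    "timestamp": "DATETIME",
    "event_set": "STRING",
}


class ScenarioError(ValueError):
    pass


class NodeKind(str, Enum):
    TRIGGER = "trigger"
    BACKGROUND = "background"
    ANALYTICAL = "analytical"
    LISTEN = "listen"
    ACTION = "action"
    CONCLUSION = "conclusion"
    DUMMY_START = "dummy_start"
    SUBFLOW = "subflow"


@dataclass(frozen=True)
class Node:
    id: str
    node_kind: NodeKind
    label: str = ""
    op_calls: tuple[OperatorCall, ...] = ()
    subflow_ref: Optional[str] = None


@dataclass(frozen=True)
class Transition:
    from_id: str
    to_id: str
    condition: Optional[Expression] = None  # None + not otherwise = unconditional
    otherwise: bool = False
    declared_order: int = 0


@dataclass(frozen=True)
class VariableDecl:
    name: str
    var_type: str = "text"
    initial: Any = None

    def __post_init__(self) -> None:
        if self.var_type not in VAR_TYPES:
            raise ScenarioError(f"unknown variable type: {self.var_type!r}")


@dataclass(frozen=True)
class Scenario:
    """One workflow process definition plus any subprocesses."""

    id: str
    nodes: tuple[Node, ...] = ()
    transitions: tuple[Transition, ...] = ()
    variables: tuple[VariableDecl, ...] = ()
    participants: tuple[str, ...] = ()
    subprocesses: tuple["Scenario", ...] = ()
    usage_level: str = "ultimate"

    def node(self, node_id: str) -> Node:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(node_id)

    def node_ids(self) -> list[str]:
        return [n.id for n in self.nodes]

    def outgoing(self, node_id: str) -> list[Transition]:
        """Outgoing transitions in declared evaluation order, OTHERWISE last."""
        out = [t for t in self.transitions if t.from_id == node_id]
        return sorted(out, key=lambda t: (t.otherwise, t.declared_order))

    def start_nodes(self) -> list[Node]:
        targets = {t.to_id for t in self.transitions}
        return [n for n in self.nodes if n.id not in targets]

    def start_node(self) -> Node:
        starts = self.start_nodes()
        if len(starts) != 1:
            raise ScenarioError(
                f"scenario {self.id!r} has {len(starts)} start nodes: "
                f"{[n.id for n in starts]}"
            )
        return starts[0]

    def has_loops(self) -> bool:
        g = scenario_graph(self)
        return not nx.is_directed_acyclic_graph(g)

    def subprocess(self, scenario_id: str) -> "Scenario":
        for s in self.subprocesses:
            if s.id == scenario_id:
                return s
        raise KeyError(scenario_id)


@dataclass(frozen=True)
class Finding:
    code: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.code}] {self.message}"


def scenario_graph(scenario: Scenario) -> nx.DiGraph:
    """The scenario as a directed graph with node-kind attributes."""
    g = nx.DiGraph()
    for n in scenario.nodes:
        g.add_node(n.id, kind=n.node_kind.value)
    for t in scenario.transitions:
        g.add_edge(t.from_id, t.to_id, otherwise=t.otherwise)
    return g


def isomorphic(a: Scenario, b: Scenario) -> bool:
    """Graph isomorphism respecting node kinds (labels and ids may differ)."""
    return nx.is_isomorphic(
        scenario_graph(a),
        scenario_graph(b),
        node_match=lambda x, y: x.get("kind") == y.get("kind"),
    )


def validate(scenario: Scenario) -> list[Finding]:
    """Check all structural invariants; an empty list means valid.

    A single start node fanning out through condition-guarded transitions
    (the dummy-start pattern for multiple logical entry points) validates
    cleanly; genuinely multiple start nodes do not.
    """
    findings: list[Finding] = []
    ids = scenario.node_ids()
    if not ids:
        findings.append(Finding("empty", "scenario has no nodes"))
        return findings
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        findings.append(Finding("duplicate-node", f"duplicate node ids: {dupes}"))

    id_set = set(ids)
    for t in scenario.transitions:
        for end in (t.from_id, t.to_id):
            if end not in id_set:
                findings.append(
                    Finding("dangling-transition", f"transition endpoint {end!r} is not a node")
                )

    starts = scenario.start_nodes()
    if len(starts) == 0:
        findings.append(Finding("no-start", "no start node (every node has an incoming edge)"))
    elif len(starts) > 1:
        findings.append(
            Finding(
                "multiple-start",
                "multiple start nodes: " + ", ".join(sorted(n.id for n in starts)),
            )
        )
    else:
        g = scenario_graph(scenario)
        reachable = {starts[0].id} | nx.descendants(g, starts[0].id)
        for n in scenario.nodes:
            if n.id not in reachable:
                findings.append(Finding("unreachable", f"node {n.id!r} unreachable from start"))

    names = [v.name for v in scenario.variables]
    if len(set(names)) != len(names):
        findings.append(Finding("duplicate-variable", "variable names are not unique"))

    for n in scenario.nodes:
        others = [t for t in scenario.transitions if t.from_id == n.id and t.otherwise]
        if len(others) > 1:
            findings.append(
                Finding("multiple-otherwise", f"node {n.id!r} has {len(others)} OTHERWISE edges")
            )
        if n.node_kind is NodeKind.SUBFLOW:
            if n.subflow_ref is None:
                findings.append(Finding("subflow-ref", f"subflow node {n.id!r} lacks a target"))
            elif n.subflow_ref not in {s.id for s in scenario.subprocesses}:
                findings.append(
                    Finding("subflow-ref", f"subflow node {n.id!r} references unknown "
                            f"process {n.subflow_ref!r}")
                )
        for call in n.op_calls:
            spec = REGISTRY.get(call.op_name)
            if spec is None:
                findings.append(
                    Finding("unknown-operator", f"node {n.id!r} calls unregistered "
                            f"operator {call.op_name!r}")
                )
                continue
            if LEVEL_ORDER[spec.level] > LEVEL_ORDER.get(scenario.usage_level, 2):
                findings.append(
                    Finding(
                        "level-violation",
                        f"node {n.id!r}: operator {call.op_name!r} is {spec.level}-level "
                        f"but the scenario declares {scenario.usage_level!r}",
                    )
                )
            unknown = set(call.args) - set(spec.params)
            if unknown:
                findings.append(
                    Finding(
                        "bad-arguments",
                        f"node {n.id!r}: operator {call.op_name!r} got unknown "
                        f"argument(s) {sorted(unknown)}",
                    )
                )

    declared = set(names) | {"result"}
    for t in scenario.transitions:
        if t.condition is not None:
            undeclared = t.condition.names() - declared
            if undeclared:
                findings.append(
                    Finding(
                        "undeclared-in-condition",
                        f"condition {t.condition.text!r} references undeclared "
                        f"name(s) {sorted(undeclared)}",
                    )
                )

    for sub in scenario.subprocesses:
        findings.extend(
            Finding(f.code, f"subprocess {sub.id!r}: {f.message}") for f in validate(sub)
        )
    return findings


# ---------------------------------------------------------------------------
# Native structured-text dialect (YAML, versioned header)


def _call_to_mapping(call: OperatorCall) -> dict:
    out: dict[str, Any] = {"op": call.op_name}
    if call.args:
        out["args"] = dict(call.args)
    if call.result_var is not None:
        out["result_var"] = call.result_var
    return out


def _call_from_mapping(m: Mapping) -> OperatorCall:
    if "op" not in m:
        raise ScenarioError(f"operator call needs an 'op' key: {m!r}")
    return OperatorCall(m["op"], dict(m.get("args") or {}), m.get("result_var"))


def _scenario_to_mapping(s: Scenario, top: bool = True) -> dict:
    out: dict[str, Any] = {}
    if top:
        out["scenario_dialect"] = NATIVE_DIALECT_VERSION
    out["id"] = s.id
    if s.usage_level != "ultimate":
        out["usage_level"] = s.usage_level
    if s.participants:
        out["participants"] = list(s.participants)
    if s.variables:
        out["variables"] = [
            {
                "name": v.name,
                "type": v.var_type,
                **({"initial": v.initial} if v.initial is not None else {}),
            }
            for v in s.variables
        ]
    nodes = []
    for n in s.nodes:
        m: dict[str, Any] = {"id": n.id, "kind": n.node_kind.value}
        if n.label:
            m["label"] = n.label
        if n.op_calls:
            m["ops"] = [_call_to_mapping(c) for c in n.op_calls]
        if n.subflow_ref is not None:
            m["subflow"] = n.subflow_ref
        nodes.append(m)
    out["nodes"] = nodes
    trans = []
    for t in s.transitions:
        m = {"from": t.from_id, "to": t.to_id, "order": t.declared_order}
        if t.otherwise:
            m["otherwise"] = True
        elif t.condition is not None:
            m["condition"] = t.condition.text
        trans.append(m)
    out["transitions"] = trans
    if s.subprocesses:
        out["subprocesses"] = [_scenario_to_mapping(p, top=False) for p in s.subprocesses]
    return out


def _scenario_from_mapping(m: Mapping) -> Scenario:
    if "id" not in m or "nodes" not in m:
        raise ScenarioError("scenario mapping needs 'id' and 'nodes'")
    nodes = []
    for nm in m["nodes"] or []:
        try:
            kind = NodeKind(nm["kind"])
        except (KeyError, ValueError) as exc:
            raise ScenarioError(f"bad node kind in {nm!r}") from exc
        nodes.append(
            Node(
                id=str(nm["id"]),
                node_kind=kind,
                label=nm.get("label", ""),
                op_calls=tuple(_call_from_mapping(c) for c in nm.get("ops") or []),
                subflow_ref=nm.get("subflow"),
            )
        )
    transitions = []
    for i, tm in enumerate(m.get("transitions") or []):
        cond_text = tm.get("condition")
        try:
            cond = parse_expression(cond_text) if cond_text is not None else None
        except ExpressionError as exc:
            raise ScenarioError(f"cannot parse condition {cond_text!r}: {exc}") from exc
        transitions.append(
            Transition(
                from_id=str(tm["from"]),
                to_id=str(tm["to"]),
                condition=cond,
                otherwise=bool(tm.get("otherwise", False)),
                declared_order=int(tm.get("order", i)),
            )
        )
    variables = tuple(
        VariableDecl(vm["name"], vm.get("type", "text"), vm.get("initial"))
        for vm in m.get("variables") or []
    )
    return Scenario(
        id=str(m["id"]),
        nodes=tuple(nodes),
        transitions=tuple(transitions),
        variables=variables,
        participants=tuple(m.get("participants") or ()),
        subprocesses=tuple(_scenario_from_mapping(p) for p in m.get("subprocesses") or []),
        usage_level=m.get("usage_level", "ultimate"),
    )


def read_native(source: Union[str, TextIO]) -> Scenario:
    """Read the native structured-text scenario dialect."""
    if isinstance(source, str):
        with open(source, "r", encoding="utf-8") as fh:
            return read_native(fh)
    data = yaml.safe_load(source)
    if not isinstance(data, dict):
        raise ScenarioError("native scenario file must hold a mapping")
    version = data.get("scenario_dialect")
    if version != NATIVE_DIALECT_VERSION:
        raise ScenarioError(
            f"unsupported scenario_dialect header: {version!r} "
            f"(expected {NATIVE_DIALECT_VERSION})"
        )
    return _scenario_from_mapping(data)


def write_native(scenario: Scenario, dest: Union[str, TextIO, None] = None) -> str:
    """Write the native dialect; returns the text (and writes it if *dest*
    is given).  ``read_native(write_native(s)) == s``."""
    text = yaml.safe_dump(_scenario_to_mapping(scenario), sort_keys=False, allow_unicode=True)
    if isinstance(dest, str):
        with open(dest, "w", encoding="utf-8") as fh:
            fh.write(text)
    elif dest is not None:
        dest.write(text)
    return text


# ---------------------------------------------------------------------------
# XPDL 1.0 subset

_EXT_NODE_KIND = "ehrflow.NodeKind"
_EXT_OP_CALL = "ehrflow.OperatorCall"
_EXT_SUBFLOW = "ehrflow.SubflowRef"
_EXT_ORDER = "ehrflow.DeclaredOrder"
_EXT_VAR_TYPE = "ehrflow.VarType"
_EXT_USAGE_LEVEL = "ehrflow.UsageLevel"


def _q(tag: str) -> str:
    return f"{{{XPDL_NS}}}{tag}"


def _ext_attrs(parent: etree._Element, pairs: list[tuple[str, str]]) -> None:
    if not pairs:
        return
    holder = etree.SubElement(parent, _q("ExtendedAttributes"))
    for name, value in pairs:
        etree.SubElement(holder, _q("ExtendedAttribute"), Name=name, Value=value)


def _read_ext_attrs(el: etree._Element) -> list[tuple[str, str]]:
    out = []
    for holder in el.findall(_q("ExtendedAttributes")):
        for ext in holder.findall(_q("ExtendedAttribute")):
            out.append((ext.get("Name"), ext.get("Value")))
    return out


def write_xpdl(scenario: Scenario, dest: Union[str, TextIO, None] = None) -> str:
    """Serialize to the XPDL 1.0 subset.

    Every operator used anywhere in the package is declared once as an
    Application; node kinds, operator bindings (JSON-encoded), declared
    transition order and variable types travel as extended attributes.
    """
    pkg = etree.Element(_q("Package"), Id=f"{scenario.id}_pkg", Name=scenario.id,
                        nsmap={None: XPDL_NS})
    used_ops = sorted(
        {
            c.op_name
            for s in (scenario, *scenario.subprocesses)
            for n in s.nodes
            for c in n.op_calls
        }
    )
    apps = etree.SubElement(pkg, _q("Applications"))
    for op in used_ops:
        app = etree.SubElement(apps, _q("Application"), Id=op)
        spec = REGISTRY.get(op)
        if spec is not None:
            etree.SubElement(app, _q("Description")).text = spec.summary
    procs = etree.SubElement(pkg, _q("WorkflowProcesses"))
    for s in (scenario, *scenario.subprocesses):
        _write_process(procs, s)
    text = etree.tostring(pkg, pretty_print=True, xml_declaration=True, encoding="UTF-8").decode()
    if isinstance(dest, str):
        with open(dest, "w", encoding="utf-8") as fh:
            fh.write(text)
    elif dest is not None:
        dest.write(text)
    return text


def _write_process(parent: etree._Element, s: Scenario) -> None:
    proc = etree.SubElement(parent, _q("WorkflowProcess"), Id=s.id, Name=s.id)
    _ext_attrs(proc, [(_EXT_USAGE_LEVEL, s.usage_level)])
    if s.participants:
        parts = etree.SubElement(proc, _q("Participants"))
        for p in s.participants:
            part = etree.SubElement(parts, _q("Participant"), Id=p)
            ptype = etree.SubElement(part, _q("ParticipantType"))
            ptype.set("Type", "ROLE")
    if s.variables:
        fields = etree.SubElement(proc, _q("DataFields"))
        for v in s.variables:
            df = etree.SubElement(fields, _q("DataField"), Id=v.name)
            dt = etree.SubElement(df, _q("DataType"))
            etree.SubElement(dt, _q("BasicType"), Type=_XPDL_BASIC_TYPE[v.var_type])
            if v.initial is not None:
                etree.SubElement(df, _q("InitialValue")).text = json.dumps(v.initial)
            _ext_attrs(df, [(_EXT_VAR_TYPE, v.var_type)])
    acts = etree.SubElement(proc, _q("Activities"))
    for n in s.nodes:
        act = etree.SubElement(acts, _q("Activity"), Id=n.id, Name=n.label or n.id)
        pairs = [(_EXT_NODE_KIND, n.node_kind.value)]
        for call in n.op_calls:
            pairs.append(
                (
                    _EXT_OP_CALL,
                    json.dumps(
                        {
                            "op": call.op_name,
                            "args": dict(call.args),
                            "result_var": call.result_var,
                        },
                        sort_keys=True,
                    ),
                )
            )
        if n.subflow_ref is not None:
            pairs.append((_EXT_SUBFLOW, n.subflow_ref))
        _ext_attrs(act, pairs)
    trans = etree.SubElement(proc, _q("Transitions"))
    for i, t in enumerate(s.transitions):
        tr = etree.SubElement(
            trans, _q("Transition"), Id=f"{t.from_id}__{t.to_id}__{i}",
            From=t.from_id, To=t.to_id,
        )
        if t.otherwise:
            etree.SubElement(tr, _q("Condition"), Type="OTHERWISE")
        elif t.condition is not None:
            cond = etree.SubElement(tr, _q("Condition"), Type="CONDITION")
            cond.text = t.condition.text
        _ext_attrs(tr, [(_EXT_ORDER, str(t.declared_order))])


def read_xpdl(source: Union[str, bytes, TextIO]) -> Scenario:
    """Parse the XPDL 1.0 subset back into a Scenario.

    The first workflow process in the package is the scenario; any further
    processes load as subprocesses so subflow references resolve.  Unknown
    application ids, multiple start nodes and unparseable conditions are
    errors.
    """
    if isinstance(source, str) and source.lstrip().startswith("<"):
        root = etree.fromstring(source.encode())
    elif isinstance(source, bytes):
        root = etree.fromstring(source)
    elif isinstance(source, str):
        root = etree.parse(source).getroot()
    else:
        root = etree.parse(source).getroot()
    if root.tag != _q("Package"):
        raise ScenarioError(f"root element is {root.tag!r}, expected an XPDL Package")

    declared_apps = {
        app.get("Id")
        for apps in root.findall(_q("Applications"))
        for app in apps.findall(_q("Application"))
    }
    unknown = declared_apps - set(REGISTRY)
    if unknown:
        raise ScenarioError(f"unknown application id(s): {sorted(unknown)}")

    processes = [
        _read_process(proc, declared_apps)
        for procs in root.findall(_q("WorkflowProcesses"))
        for proc in procs.findall(_q("WorkflowProcess"))
    ]
    if not processes:
        raise ScenarioError("package contains no workflow process")
    main = processes[0]
    scenario = replace(main, subprocesses=tuple(processes[1:]))
    errors = [
        f
        for f in validate(scenario)
        if f.code in ("multiple-start", "no-start", "dangling-transition", "unknown-operator")
    ]
    if errors:
        raise ScenarioError("; ".join(str(f) for f in errors))
    return scenario


def _read_process(proc: etree._Element, declared_apps: set) -> Scenario:
    ext = dict(_read_ext_attrs(proc))
    participants = tuple(
        p.get("Id")
        for parts in proc.findall(_q("Participants"))
        for p in parts.findall(_q("Participant"))
    )
    variables = []
    for fields in proc.findall(_q("DataFields")):
        for df in fields.findall(_q("DataField")):
            dfext = dict(_read_ext_attrs(df))
            var_type = dfext.get(_EXT_VAR_TYPE)
            if var_type is None:
                basic = df.find(f"{_q('DataType')}/{_q('BasicType')}")
                reverse = {v: k for k, v in _XPDL_BASIC_TYPE.items()}
                var_type = reverse.get(basic.get("Type"), "text") if basic is not None else "text"
            init_el = df.find(_q("InitialValue"))
            initial = json.loads(init_el.text) if init_el is not None and init_el.text else None
            variables.append(VariableDecl(df.get("Id"), var_type, initial))
    nodes = []
    for acts in proc.findall(_q("Activities")):
        for act in acts.findall(_q("Activity")):
            pairs = _read_ext_attrs(act)
            attrs = dict(pairs)
            kind_text = attrs.get(_EXT_NODE_KIND, "analytical")
            try:
                kind = NodeKind(kind_text)
            except ValueError as exc:
                raise ScenarioError(f"activity {act.get('Id')!r}: bad node kind "
                                    f"{kind_text!r}") from exc
            calls = []
            for name, value in pairs:
                if name != _EXT_OP_CALL:
                    continue
                data = json.loads(value)
                if data["op"] not in REGISTRY and data["op"] not in declared_apps:
                    raise ScenarioError(
                        f"activity {act.get('Id')!r} binds unknown application {data['op']!r}"
                    )
                calls.append(OperatorCall(data["op"], data.get("args") or {},
                                          data.get("result_var")))
            nodes.append(
                Node(
                    id=act.get("Id"),
                    node_kind=kind,
                    label=act.get("Name") or "",
                    op_calls=tuple(calls),
                    subflow_ref=attrs.get(_EXT_SUBFLOW),
                )
            )
    transitions = []
    for trs in proc.findall(_q("Transitions")):
        for i, tr in enumerate(trs.findall(_q("Transition"))):
            ext_tr = dict(_read_ext_attrs(tr))
            cond_el = tr.find(_q("Condition"))
            otherwise = cond_el is not None and cond_el.get("Type") == "OTHERWISE"
            cond = None
            if cond_el is not None and not otherwise and (cond_el.text or "").strip():
                try:
                    cond = parse_expression(cond_el.text.strip())
                except ExpressionError as exc:
                    raise ScenarioError(
                        f"cannot parse condition {cond_el.text!r}: {exc}"
                    ) from exc
            transitions.append(
                Transition(
                    from_id=tr.get("From"),
                    to_id=tr.get("To"),
                    condition=cond,
                    otherwise=otherwise,
                    declared_order=int(ext_tr.get(_EXT_ORDER, i)),
                )
            )
    return Scenario(
        id=proc.get("Id"),
        nodes=tuple(nodes),
        transitions=tuple(transitions),
        variables=tuple(variables),
        participants=participants,
        usage_level=ext.get(_EXT_USAGE_LEVEL, "ultimate"),
    )
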