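"""Operator library invoked from scenario nodes, in three usage levels.

Scenario flowcharts keep their logic in the graph; everything that touches
patient data goes through a small registry of modular operators.  The
registry is tiered so that simple problems stay simple:

* **simple** — one find operator per event-type family (nine families),
  each taking a single code and returning only found/not-found.  All simple
  finds run in *strict pointer mode*: they scan strictly after the current
  position pointer, move it to the match on success and leave it untouched
  on failure.  Pointer repositioning is available through jump operations.
* **advanced** — a generic coded-event find with arbitrary time windows and
  full result sets (events, counts, properties), variable assignment and
  counters, a two-timestamp temporal criterion, and tabular export.
* **ultimate** — aggregates over result sets, ontology-backed value-set
  finds, and the trigger/listen registrations used by prospective runs.

A higher level can always use everything below it.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from enum import Enum
from typing import Any, Callable, Iterable, Mapping, Optional, Sequence, TextIO, Union

from dateutil.relativedelta import relativedelta

from .events import Event, PatientTimeline, Position
from .ontology import Depth, OntologyStore

__all__ = [
    "OperatorCall",
    "FindResult",
    "SearchWindow",
    "PointerMode",
    "FamilyDialect",
    "DEFAULT_FAMILIES",
    "GenderMapping",
    "DEFAULT_GENDER",
    "AggregateResult",
    "ListenSpec",
    "ModeError",
    "RegistryError",
    "OperatorSpec",
    "REGISTRY",
    "registry_manifest",
    "level_totals",
    "find_events",
    "find_coded_event",
    "find_coded_event_vs",
    "simple_find",
    "patient_is_male",
    "VariableState",
    "assign_value_to_variable",
    "increase_counter_variable",
    "evaluate_two_timestamps_difference_criterion",
    "aggregate_events",
    "hf_export",
    "set_pointer_to_timestamp",
    "get_event_property",
    "trigger_event_listener",
    "relevant_event_listener",
]


class RegistryError(KeyError):
    pass


class ModeError(RuntimeError):
    """Listener registration attempted outside prospective mode."""


class PointerMode(str, Enum):
    STRICT = "STRICT"
    CUSTOM = "CUSTOM"


@dataclass(frozen=True)
class SearchWindow:
    """Absolute time bounds for a find; ``None`` means unbounded on that
    side (``upper=None`` reads to end of record)."""

    lower: Optional[datetime] = None
    upper: Optional[datetime] = None

    def __post_init__(self) -> None:
        if self.lower is not None and self.upper is not None and self.lower > self.upper:
            raise ValueError("window lower bound exceeds upper bound")

    def contains(self, t: datetime) -> bool:
        if self.lower is not None and t < self.lower:
            return False
        if self.upper is not None and t > self.upper:
            return False
        return True


@dataclass(frozen=True)
class FindResult:
    """Outcome of an event search.

    Simple-level callers read only ``found``; advanced callers get the full
    chronological match set, its count and the pointer after the call.
    """

    found: bool
    matches: tuple[Event, ...]
    pointer_after: Position
    first_match: Optional[Event] = None
    count: int = 0

    @staticmethod
    def of(matches: Sequence[Event], pointer_after: Position) -> "FindResult":
        matches = tuple(matches)
        return FindResult(
            found=bool(matches),
            matches=matches,
            pointer_after=pointer_after,
            first_match=matches[0] if matches else None,
            count=len(matches),
        )


# ---------------------------------------------------------------------------
# Event-family dialect: which event types belong to each family and which
# coded field carries the code that family is searched by.  The printed
# chart example shows codes landing in different columns per family (lab
# results code the observation, procedures the terminology2 column), so the
# mapping is configuration, not convention.


@dataclass(frozen=True)
class FamilyDialect:
    event_types: tuple[str, ...]  # accepted event_type codes/descriptions
    match_field: str  # Event field holding the family's designated code


DEFAULT_FAMILIES: dict[str, FamilyDialect] = {
    "diagnosis": FamilyDialect(("Diagnosis (ICD)", "ICD-9-CM Diseases"), "terminology2"),
    "lab_result": FamilyDialect(("Lab", "Standard Lab Data"), "observation"),
    "visit": FamilyDialect(("Appointment",), "event_subtype"),
    "procedure": FamilyDialect(
        ("Procedure (CPT)", "CPT-4", "ICD-9-CM Procedures"), "terminology2"
    ),
    "prescription": FamilyDialect(("Prescription",), "terminology2"),
    "vital_sign": FamilyDialect(("Vital signs",), "observation"),
    "textual_report": FamilyDialect(("Textual report", "Clinical Text Data"), "coded_value"),
    "order": FamilyDialect(("Order", "Patient Order"), "coded_value"),
    "microbiology": FamilyDialect(("Microbiology",), "observation"),
}


def _event_in_family(e: Event, dialect: FamilyDialect) -> bool:
    return any(e.event_type.matches(t) for t in dialect.event_types)


def _code_matches(e: Event, dialect: FamilyDialect, codes: frozenset[str]) -> bool:
    coded = getattr(e, dialect.match_field)
    return coded is not None and any(coded.matches(c) for c in codes)


def _bare(ccd: str) -> str:
    return ccd.split(":", 1)[1] if ":" in ccd else ccd


# ---------------------------------------------------------------------------
# Core search


def find_events(
    timeline: PatientTimeline,
    family: Optional[str] = None,
    code: Optional[str] = None,
    codes: Optional[Iterable[str]] = None,
    predicate: Optional[Callable[[Event], bool]] = None,
    window: Optional[SearchWindow] = None,
    pointer_mode: PointerMode = PointerMode.STRICT,
    families: Mapping[str, FamilyDialect] = DEFAULT_FAMILIES,
) -> FindResult:
    """Search a timeline for coded events; the one primitive behind every
    find operator.

    In ``STRICT`` mode the scan starts strictly after the current pointer
    and, on success, the pointer moves to the first match; on failure it
    stays put.  In ``CUSTOM`` mode the pointer is never touched and only
    the *window* restricts the scan.  Matches are returned in chronological
    order with all event properties.
    """
    if family is not None and family not in families:
        raise RegistryError(f"unknown event-type family: {family!r}")
    dialect = families[family] if family is not None else None
    code_set = frozenset(
        ([code] if code is not None else []) + list(codes or [])
    ) or None

    if pointer_mode is PointerMode.STRICT:
        indices: Iterable[int] = timeline.searchable_indices()
    else:
        indices = range(len(timeline.events))

    matches: list[Event] = []
    first_idx: Optional[int] = None
    for i in indices:
        e = timeline.events[i]
        if window is not None and not window.contains(e.ev_time):
            continue
        if dialect is not None and not _event_in_family(e, dialect):
            continue
        if code_set is not None:
            if dialect is not None:
                if not _code_matches(e, dialect, code_set):
                    continue
            elif not _any_field_matches(e, code_set):
                continue
        if predicate is not None and not predicate(e):
            continue
        if first_idx is None:
            first_idx = i
        matches.append(e)

    pointer_after = timeline.pointer
    if pointer_mode is PointerMode.STRICT and first_idx is not None:
        pointer_after = Position.at_event(first_idx)
        timeline.pointer = pointer_after
    return FindResult.of(matches, pointer_after)


def _any_field_matches(e: Event, codes: frozenset[str]) -> bool:
    for f in ("event_type", "event_subtype", "observation", "coded_value", "flag", "terminology2"):
        coded = getattr(e, f)
        if coded is not None and any(coded.matches(c) for c in codes):
            return True
    return False


# -- simple level -----------------------------------------------------------

SIMPLE_FAMILIES: tuple[str, ...] = tuple(DEFAULT_FAMILIES)


def simple_find(
    timeline: PatientTimeline,
    family: str,
    code: str,
    families: Mapping[str, FamilyDialect] = DEFAULT_FAMILIES,
) -> bool:
    """Strict-pointer, found/not-found search within one event family."""
    if not code:
        raise ValueError("code must be non-empty")
    return find_events(timeline, family=family, code=code, families=families).found


def _make_family_finder(family: str) -> Callable[..., bool]:
    def finder(
        timeline: PatientTimeline,
        code: str,
        families: Mapping[str, FamilyDialect] = DEFAULT_FAMILIES,
    ) -> bool:
        return simple_find(timeline, family, code, families)

    finder.__name__ = f"find_{family}"
    finder.__doc__ = (
        f"Strict-pointer search for a {family.replace('_', ' ')} event with the"
        " given code; returns found/not-found and advances the pointer on success."
    )
    return finder


find_diagnosis = _make_family_finder("diagnosis")
find_lab_result = _make_family_finder("lab_result")
find_visit = _make_family_finder("visit")
find_procedure = _make_family_finder("procedure")
find_prescription = _make_family_finder("prescription")
find_vital_sign = _make_family_finder("vital_sign")
find_textual_report = _make_family_finder("textual_report")
find_order = _make_family_finder("order")
find_microbiology = _make_family_finder("microbiology")


@dataclass(frozen=True)
class GenderMapping:
    """Where to look for the gender observation in a record."""

    event_types: tuple[str, ...] = ("Demographics",)
    observation: str = "Gender"
    male_values: tuple[str, ...] = ("Male", "M")
    female_values: tuple[str, ...] = ("Female", "F")


DEFAULT_GENDER = GenderMapping()


def patient_is_male(
    timeline: PatientTimeline, mapping: GenderMapping = DEFAULT_GENDER
) -> Optional[bool]:
    """True if male, False if female, None if no gender information.

    A demographic lookup, not a chart search: the whole record is scanned
    and the current position pointer is not moved.
    """
    for e in timeline.events:
        if not any(e.event_type.matches(t) for t in mapping.event_types):
            continue
        if e.observation is None or not e.observation.matches(mapping.observation):
            continue
        if e.coded_value is None:
            continue
        if any(e.coded_value.matches(v) for v in mapping.male_values):
            return True
        if any(e.coded_value.matches(v) for v in mapping.female_values):
            return False
    return None


# -- advanced level ---------------------------------------------------------


def find_coded_event(
    timeline: PatientTimeline,
    family: Optional[str] = None,
    code: Optional[str] = None,
    codes: Optional[Iterable[str]] = None,
    predicate: Optional[Callable[[Event], bool]] = None,
    window: Optional[SearchWindow] = None,
    pointer_mode: Union[PointerMode, str] = PointerMode.STRICT,
    families: Mapping[str, FamilyDialect] = DEFAULT_FAMILIES,
) -> FindResult:
    """Generalised event find: arbitrary time windows, full result sets and
    counts, strict or custom pointer mode."""
    return find_events(
        timeline,
        family=family,
        code=code,
        codes=codes,
        predicate=predicate,
        window=window,
        pointer_mode=PointerMode(pointer_mode),
        families=families,
    )


class VariableState(dict):
    """Scenario variable bindings; assignment is restricted to declared
    names so typos fail loudly instead of forking silent state."""

    def __init__(self, declared: Iterable[str], initial: Optional[Mapping[str, Any]] = None):
        super().__init__()
        self.declared = frozenset(declared)
        for k, v in (initial or {}).items():
            self.assign(k, v)

    def assign(self, name: str, value: Any) -> None:
        if name not in self.declared:
            raise KeyError(f"variable {name!r} is not declared")
        self[name] = value


def assign_value_to_variable(state: VariableState, var: str, value: Any) -> Any:
    """Bind *value* to a declared scenario variable; later nodes and
    transition conditions see the update (inter-step parameter passing)."""
    state.assign(var, value)
    return value


def increase_counter_variable(state: VariableState, var: str, increment: float = 1) -> float:
    """Add *increment* (default 1) to a numeric variable, treating an unset
    variable as 0."""
    if var not in state.declared:
        raise KeyError(f"variable {var!r} is not declared")
    value = (state.get(var) or 0) + increment
    state.assign(var, value)
    return value


_COMPARATORS: dict[str, Callable[[Any, Any], bool]] = {
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
    "==": lambda a, b: a == b,
    "!=": lambda a, b: a != b,
}

_EXACT_UNITS = {"hours": timedelta(hours=1), "days": timedelta(days=1)}
_CALENDAR_UNITS = ("months", "years")


def evaluate_two_timestamps_difference_criterion(
    t1: Optional[datetime],
    t2: Optional[datetime],
    comparator: str,
    amount: float,
    unit: str,
) -> Optional[bool]:
    """Does the elapsed time t2 − t1 satisfy ``comparator amount unit``?

    Hours and days compare exactly; months and years follow the calendar
    (``<= 6 months`` means t2 is no later than t1 advanced six calendar
    months, day-of-month clamped).  A null timestamp yields null, which
    conditions treat as not satisfied.
    """
    if comparator not in _COMPARATORS:
        raise ValueError(f"unknown comparator: {comparator!r}")
    if t1 is None or t2 is None:
        return None
    if unit in _EXACT_UNITS:
        elapsed = (t2 - t1) / _EXACT_UNITS[unit]
        return _COMPARATORS[comparator](elapsed, amount)
    if unit in _CALENDAR_UNITS:
        if amount != int(amount):
            raise ValueError(f"calendar unit {unit!r} needs a whole-number amount")
        boundary = t1 + relativedelta(**{unit: int(amount)})
        # elapsed cmp amount  <=>  t2 cmp boundary (calendar advance is monotone)
        return _COMPARATORS[comparator](t2, boundary)
    raise ValueError(f"unknown unit: {unit!r} (use hours, days, months, years)")


def hf_export(
    traces: Mapping[str, Any],
    columns: Sequence[str],
    dest: TextIO,
) -> None:
    """Write one CSV row per patient with the requested variable and
    conclusion columns (RFC-4180-style quoting).

    Column names address final variable values; the special column
    ``conclusions`` joins conclusion labels with ``|``.
    """
    w = csv.writer(dest, lineterminator="\n")
    w.writerow(["patient_id", *columns])
    for pid in traces:
        trace = traces[pid]
        row: list[str] = [pid]
        for c in columns:
            if c == "conclusions":
                row.append("|".join(r.label for r in trace.conclusions))
            elif c in trace.variables:
                v = trace.variables[c]
                row.append("" if v is None else str(v))
            else:
                raise KeyError(f"unknown export column: {c!r}")
        w.writerow(row)


def set_pointer_to_timestamp(timeline: PatientTimeline, t: datetime) -> Position:
    """Reposition the pointer to an arbitrary timestamp (typically one held
    in a scenario variable), so later strict finds start there."""
    pos = Position.at_time(t)
    timeline.pointer = pos
    return pos


def get_event_property(result: FindResult, prop: str) -> Any:
    """Read a property path off the first matched event of a find result,
    e.g. ``ev_time``, ``value_num`` or ``terminology2.code``."""
    if result.first_match is None:
        return None
    obj: Any = result.first_match
    for part in prop.split("."):
        if obj is None:
            return None
        if not hasattr(obj, part):
            raise AttributeError(f"event has no property {prop!r}")
        obj = getattr(obj, part)
    return obj


# -- ultimate level ---------------------------------------------------------


@dataclass(frozen=True)
class AggregateResult:
    value: Optional[float]
    n_used: int
    n_excluded: int  # events whose field was null

    def __float__(self) -> float:
        return float(self.value)


def aggregate_events(
    matches: Iterable[Event], field_name: str = "value_num", stat: str = "AVG"
) -> AggregateResult:
    """Arithmetic mean or sum of a numeric event field over a result set.

    Events with a null field are excluded and their count reported; an
    empty usable set yields a null value with a warning.
    """
    if stat not in ("AVG", "SUM"):
        raise ValueError(f"stat must be AVG or SUM, got {stat!r}")
    values, excluded = [], 0
    for e in matches:
        v = getattr(e, field_name)
        if v is None:
            excluded += 1
        else:
            values.append(float(v))
    if not values:
        warnings.warn("aggregate over empty result set yields null", stacklevel=2)
        return AggregateResult(None, 0, excluded)
    total = sum(values)
    return AggregateResult(total if stat == "SUM" else total / len(values), len(values), excluded)


def find_coded_event_vs(
    timeline: PatientTimeline,
    store: OntologyStore,
    family: Optional[str],
    value_set_concept: str,
    rel_type: str = "is_member",
    depth: Union[Depth, str] = Depth.ALL,
    window: Optional[SearchWindow] = None,
    pointer_mode: Union[PointerMode, str] = PointerMode.STRICT,
    families: Mapping[str, FamilyDialect] = DEFAULT_FAMILIES,
) -> FindResult:
    """Find events whose code belongs to an ontology-derived value set.

    The concept's descendants via *rel_type* (all or first-degree) are
    expanded to a code set; namespaced concept codes also match their bare
    terminology codes as stored on events.
    """
    members = store.descendants(value_set_concept, rel_type, Depth(depth))
    codes: set[str] = set()
    for ccd in members:
        codes.add(ccd)
        codes.add(_bare(ccd))
    if not codes:
        # empty value set matches nothing, honestly
        return FindResult.of((), timeline.pointer)
    return find_events(
        timeline,
        family=family,
        codes=codes,
        window=window,
        pointer_mode=PointerMode(pointer_mode),
        families=families,
    )


@dataclass(frozen=True)
class ListenSpec:
    """Event pattern a listener waits for (same event model as finds)."""

    family: Optional[str] = None
    code: Optional[str] = None
    value_set_concept: Optional[str] = None
    rel_type: str = "is_member"
    depth: Depth = Depth.ALL
    description: str = ""

    def codes(self, store: Optional[OntologyStore]) -> Optional[frozenset[str]]:
        out: set[str] = set()
        if self.code is not None:
            out.add(self.code)
        if self.value_set_concept is not None:
            if store is None:
                raise ValueError("value-set listen spec needs an ontology store")
            for ccd in store.descendants(self.value_set_concept, self.rel_type, self.depth):
                out.update((ccd, _bare(ccd)))
        return frozenset(out) if out else None

    def matches(
        self,
        event: Event,
        store: Optional[OntologyStore] = None,
        families: Mapping[str, FamilyDialect] = DEFAULT_FAMILIES,
    ) -> bool:
        if self.family is not None:
            if self.family not in families:
                raise RegistryError(f"unknown event-type family: {self.family!r}")
            dialect = families[self.family]
            if not _event_in_family(event, dialect):
                return False
            codes = self.codes(store)
            return codes is None or _code_matches(event, dialect, codes)
        codes = self.codes(store)
        return codes is None or _any_field_matches(event, codes)


def trigger_event_listener(context: Any, spec: ListenSpec) -> None:
    """Register a scenario-instantiating listener with a prospective
    execution context; a matching event starts a new instance."""
    if getattr(context, "mode", None) != "prospective":
        raise ModeError("trigger listeners can only be registered in prospective mode")
    context.register_trigger(spec)


def relevant_event_listener(context: Any, spec: ListenSpec) -> None:
    """Register a resuming listener: a matching event wakes the paused
    instance that registered it."""
    if getattr(context, "mode", None) != "prospective":
        raise ModeError("relevant listeners can only be registered in prospective mode")
    context.register_relevant(spec)


# ---------------------------------------------------------------------------
# Registry


@dataclass(frozen=True)
class OperatorCall:
    """One operator invocation bound to a scenario node.

    ``args`` values may be literals or references: strings beginning with
    ``$`` resolve against scenario variables and the node's last result
    (``"$fracture_date"``, ``"$result.first_match.ev_time"``).
    """

    op_name: str
    args: Mapping[str, Any] = field(default_factory=dict)
    result_var: Optional[str] = None


@dataclass(frozen=True)
class OperatorSpec:
    name: str
    level: str  # simple | advanced | ultimate
    category: str  # find_family | utility | variable | temporal | export | aggregate | listener | find
    func: Callable
    summary: str
    params: tuple[str, ...]


LEVEL_ORDER = {"simple": 0, "advanced": 1, "ultimate": 2}


def _spec(name, level, category, func, summary, params) -> tuple[str, OperatorSpec]:
    return name, OperatorSpec(name, level, category, func, summary, tuple(params))


REGISTRY: dict[str, OperatorSpec] = dict(
    [
        # simple: the nine per-family find operators
        *[
            _spec(
                f"find_{fam}",
                "simple",
                "find_family",
                globals()[f"find_{fam}"],
                f"found/not-found strict search for a {fam.replace('_', ' ')} event by code",
                ("code",),
            )
            for fam in SIMPLE_FAMILIES
        ],
        # simple utilities (outside the nine-family count)
        _spec(
            "patient_is_male",
            "simple",
            "utility",
            patient_is_male,
            "tri-state gender lookup; does not move the pointer",
            (),
        ),
        _spec(
            "jump_to_last_ehr_event",
            "simple",
            "utility",
            None,
            "move the pointer onto the final record event",
            (),
        ),
        _spec(
            "jump_forward_months",
            "simple",
            "utility",
            None,
            "advance the pointer by n calendar months",
            ("n",),
        ),
        # advanced (seven)
        _spec(
            "find_coded_event",
            "advanced",
            "find",
            find_coded_event,
            "windowed find with result sets, counts and strict/custom pointer modes",
            ("family", "code", "codes", "window", "pointer_mode"),
        ),
        _spec(
            "assign_value_to_variable",
            "advanced",
            "variable",
            assign_value_to_variable,
            "bind a value to a declared scenario variable",
            ("var", "value"),
        ),
        _spec(
            "increase_counter_variable",
            "advanced",
            "variable",
            increase_counter_variable,
            "increment a numeric scenario variable",
            ("var", "increment"),
        ),
        _spec(
            "evaluate_two_timestamps_difference_criterion",
            "advanced",
            "temporal",
            evaluate_two_timestamps_difference_criterion,
            "compare the elapsed time between two timestamps against a criterion",
            ("t1", "t2", "comparator", "amount", "unit"),
        ),
        _spec(
            "hf_export",
            "advanced",
            "export",
            hf_export,
            "CSV export of per-patient variables and conclusions",
            ("columns",),
        ),
        _spec(
            "set_pointer_to_timestamp",
            "advanced",
            "utility",
            set_pointer_to_timestamp,
            "reposition the pointer to an arbitrary timestamp",
            ("t",),
        ),
        _spec(
            "get_event_property",
            "advanced",
            "utility",
            get_event_property,
            "read a property of the first matched event of a find result",
            ("prop",),
        ),
        # ultimate (four new)
        _spec(
            "aggregate_events",
            "ultimate",
            "aggregate",
            aggregate_events,
            "average or sum of a numeric field over a result set",
            ("field_name", "stat"),
        ),
        _spec(
            "find_coded_event_vs",
            "ultimate",
            "find",
            find_coded_event_vs,
            "windowed find whose code match is an ontology value-set expansion",
            ("family", "value_set_concept", "rel_type", "depth", "window", "pointer_mode"),
        ),
        _spec(
            "trigger_event_listener",
            "ultimate",
            "listener",
            trigger_event_listener,
            "register an instance-creating event listener (prospective mode)",
            ("spec",),
        ),
        _spec(
            "relevant_event_listener",
            "ultimate",
            "listener",
            relevant_event_listener,
            "register an instance-resuming event listener (prospective mode)",
            ("spec",),
        ),
    ]
)


def registry_manifest() -> list[dict[str, Any]]:
    """Machine-readable operator manifest (name, level, category, params,
    summary) for scenario validation and documentation."""
    return [
        {
            "name": s.name,
            "level": s.level,
            "category": s.category,
            "params": list(s.params),
            "summary": s.summary,
        }
        for s in REGISTRY.values()
    ]


def level_totals() -> dict[str, int]:
    """Published operator counts per usage level: the nine simple
    per-family finds, the seven advanced operators, the four operators the
    ultimate level adds."""
    return {
        "simple": sum(
            1 for s in REGISTRY.values() if s.level == "simple" and s.category == "find_family"
        ),
        "advanced": sum(1 for s in REGISTRY.values() if s.level == "advanced"),
        "ultimate": sum(1 for s in REGISTRY.values() if s.level == "ultimate"),
    }
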