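"""Concept store with typed relationships and value-set expansion.

The store holds coded concepts from several terminologies at once (ICD-9-CM,
CPT, local lab codes, drug lists ...), so concept codes are namespaced as
``"<terminology>:<code>"``.  Relationships are typed (``is_a``,
``is_member``, ``has_indication`` ...) and a concept may have multiple
parents via the same or different relationship types — e.g. a depression
diagnosis code can sit under a psychiatric-disorder concept *and* belong to
a quality-measure value set.  Scenario operators use the descendant closure
of ``is_a`` (drug classes) and ``is_member`` (flat value sets) to match
whole families of codes with a single concept.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, TextIO, Union

import networkx as nx

__all__ = [
    "Concept",
    "Relationship",
    "OntologyStore",
    "OntologyError",
    "CycleError",
    "UnknownConceptError",
    "Depth",
    "load_ontology",
]


class OntologyError(ValueError):
    pass


class CycleError(OntologyError):
    def __init__(self, rel_type: str, cycle: list[str]):
        super().__init__(f"cycle in '{rel_type}' relationships: {' -> '.join(cycle)}")
        self.rel_type = rel_type
        self.cycle = cycle


class UnknownConceptError(KeyError):
    pass


class Depth(str, Enum):
    ALL = "ALL"
    FIRST_DEGREE = "FIRST_DEGREE"


@dataclass(frozen=True)
class Concept:
    ccd: str
    description: str = ""


@dataclass(frozen=True)
class Relationship:
    child: str
    parent: str
    rel_type: str


@dataclass
class OntologyStore:
    """Queryable concept store.

    ``children[rel_type][parent]`` lists direct children (inverse edges), in
    load order.  Construction validates referential integrity and rejects
    cycles within each relationship type, so closures always terminate.
    """

    concepts: dict[str, Concept] = field(default_factory=dict)
    relationships: list[Relationship] = field(default_factory=list)
    children: dict[str, dict[str, list[str]]] = field(default_factory=dict, repr=False)

    @staticmethod
    def build(
        concepts: Iterable[Concept], relationships: Iterable[Relationship]
    ) -> "OntologyStore":
        store = OntologyStore()
        for c in concepts:
            if c.ccd in store.concepts:
                raise OntologyError(f"duplicate concept code: {c.ccd}")
            store.concepts[c.ccd] = c
        dangling = []
        for r in relationships:
            if r.child not in store.concepts or r.parent not in store.concepts:
                dangling.append(r)
                continue
            store.relationships.append(r)
            store.children.setdefault(r.rel_type, {}).setdefault(r.parent, []).append(
                r.child
            )
        if dangling:
            names = ", ".join(f"{r.child}->{r.parent} [{r.rel_type}]" for r in dangling)
            raise OntologyError(f"relationships with undeclared endpoints: {names}")
        for rel_type in store.children:
            g = nx.DiGraph(
                (r.child, r.parent) for r in store.relationships if r.rel_type == rel_type
            )
            try:
                cycle = nx.find_cycle(g)
            except nx.NetworkXNoCycle:
                continue
            raise CycleError(rel_type, [a for a, _ in cycle] + [cycle[-1][1]])
        return store

    def _require(self, ccd: str) -> None:
        if ccd not in self.concepts:
            raise UnknownConceptError(ccd)

    def descendants(
        self, root: str, rel_type: str = "is_a", depth: Depth = Depth.ALL
    ) -> set[str]:
        """Codes below *root* via *rel_type*: one step for ``FIRST_DEGREE``,
        the transitive closure for ``ALL``.  The root itself is excluded;
        callers that want root-plus-descendants union it in explicitly."""
        self._require(root)
        kids = self.children.get(rel_type, {})
        if depth is Depth.FIRST_DEGREE:
            return set(kids.get(root, ()))
        out: set[str] = set()
        stack = list(kids.get(root, ()))
        while stack:
            c = stack.pop()
            if c not in out:
                out.add(c)
                stack.extend(kids.get(c, ()))
        return out

    def expand_value_set(self, set_concept: str, rel_type: str = "is_member") -> set[str]:
        """All codes belonging to a named value set, transitively."""
        return self.descendants(set_concept, rel_type, Depth.ALL)


def _read_table(source: Union[str, TextIO], columns: tuple[str, ...]) -> list[dict]:
    if isinstance(source, str):
        with open(source, "r", encoding="utf-8", newline="") as fh:
            return _read_table(fh, columns)
    first = source.readline()
    delim = "\t" if first.count("\t") >= first.count(",") else ","
    header = [h.strip() for h in next(csv.reader([first], delimiter=delim))]
    missing = set(columns) - set(header)
    if missing:
        raise OntologyError(f"missing column(s): {', '.join(sorted(missing))}")
    rows = []
    for row in csv.DictReader(source, fieldnames=header, delimiter=delim):
        if any((row.get(c) or "").strip() for c in columns):
            rows.append({c: (row.get(c) or "").strip() for c in header})
    return rows


def load_ontology(
    concepts: Union[str, TextIO], relationships: Union[str, TextIO]
) -> OntologyStore:
    """Load a store from two delimited files.

    The concepts file has columns ``ccd, description``; the relationships
    file ``child_ccd, parent_ccd, rel_type``.  Dangling endpoints and
    within-type cycles are load errors.
    """
    cons = [
        Concept(r["ccd"], r.get("description", ""))
        for r in _read_table(concepts, ("ccd",))
    ]
    rels = [
        Relationship(r["child_ccd"], r["parent_ccd"], r["rel_type"])
        for r in _read_table(relationships, ("child_ccd", "parent_ccd", "rel_type"))
    ]
    return OntologyStore.build(cons, rels)
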