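"""Cohort reports over execution traces.

Three views, mirroring the review workflow after a retrospective test run:
the *summary report* answers "how many cohort patients satisfied a given
step, branch or condition"; the *detailed report* is patient-centred and
reproduces each trace node by node with the exact events investigated; the
*individual patient view* lists every event of one patient.  Reports are
pure functions of traces and timelines — building a report never
re-executes a scenario.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from .engine import ExecutionTrace, RunOutput
from .events import PatientTimeline, _CODED_FIELDS, DEFAULT_COLUMNS, _fmt_time

__all__ = ["SummaryReport", "build_summary", "build_detailed", "build_ipv"]


@dataclass
class SummaryReport:
    """Cohort-level counts and percentages.

    Percentages are reported against two labelled denominators: the
    executed cohort (``pct_of_cohort``) and, per node, the patients that
    actually reached the node (``pct_of_reached``).  Patients missing from
    the timeline set are counted separately and are not in either
    denominator.
    """

    scenario_id: str
    cohort_size: int
    n_missing: int
    n_errors: int
    nodes: pd.DataFrame  # node_id, reached, satisfied, failed, pct_of_cohort, pct_of_reached
    branches: pd.DataFrame  # from_node, to_node, routed, pct_of_reached
    conclusions: pd.DataFrame  # label, count, pct_of_cohort

    @property
    def intervention_fraction(self) -> float:
        """Fraction of the executed cohort with at least one conclusion or
        action — the 'what percentage of the testing cohort has an
        alert generated' figure reviewed before deployment."""
        if self.cohort_size == 0:
            return 0.0
        return self.n_concluded / self.cohort_size

    n_concluded: int = 0


def _pct(num: int, denom: int) -> float:
    return round(100.0 * num / denom, 2) if denom else 0.0


def build_summary(
    traces: Mapping[str, ExecutionTrace], scenario_id: Optional[str] = None
) -> SummaryReport:
    """Aggregate per-node, per-branch and per-conclusion counts over a
    cohort of execution traces.  An empty trace map yields an empty-cohort
    report, not an error."""
    cohort = len(traces)
    node_reached: dict[str, int] = {}
    node_sat: dict[str, int] = {}
    node_fail: dict[str, int] = {}
    branch: dict[tuple[str, str], int] = {}
    conclusion_counts: dict[str, int] = {}
    n_concluded = 0
    n_errors = 0
    sid = scenario_id
    for pid in sorted(traces):
        t = traces[pid]
        sid = sid or t.scenario_id
        if t.error:
            n_errors += 1
        # loops count a patient once per node; a node satisfies for a
        # patient if any of its visits did, so every count stays <= cohort
        outcomes: dict[str, str] = {}
        for v in t.visited:
            prev = outcomes.get(v.node_id)
            if prev != "SATISFIED" and v.outcome in ("SATISFIED", "FAILED"):
                outcomes[v.node_id] = v.outcome
            elif prev is None:
                outcomes[v.node_id] = v.outcome
        for nid, outcome in outcomes.items():
            node_reached[nid] = node_reached.get(nid, 0) + 1
            if outcome == "SATISFIED":
                node_sat[nid] = node_sat.get(nid, 0) + 1
            elif outcome == "FAILED":
                node_fail[nid] = node_fail.get(nid, 0) + 1
        for a, b in zip(t.visited, t.visited[1:]):
            key = (a.node_id, b.node_id)
            branch[key] = branch.get(key, 0) + 1
        labels = set(t.conclusion_labels())
        if labels:
            n_concluded += 1
        for label in labels:
            conclusion_counts[label] = conclusion_counts.get(label, 0) + 1

    nodes = pd.DataFrame(
        [
            {
                "node_id": nid,
                "reached": node_reached[nid],
                "satisfied": node_sat.get(nid, 0),
                "failed": node_fail.get(nid, 0),
                "pct_of_cohort": _pct(node_reached[nid], cohort),
                "pct_of_reached": 100.0,
            }
            for nid in sorted(node_reached)
        ],
        columns=["node_id", "reached", "satisfied", "failed", "pct_of_cohort", "pct_of_reached"],
    )
    branches = pd.DataFrame(
        [
            {
                "from_node": a,
                "to_node": b,
                "routed": n,
                "pct_of_reached": _pct(n, node_reached.get(a, 0)),
            }
            for (a, b), n in sorted(branch.items())
        ],
        columns=["from_node", "to_node", "routed", "pct_of_reached"],
    )
    conclusions = pd.DataFrame(
        [
            {"label": label, "count": n, "pct_of_cohort": _pct(n, cohort)}
            for label, n in sorted(conclusion_counts.items())
        ],
        columns=["label", "count", "pct_of_cohort"],
    )
    n_missing = len(traces.missing_patients) if isinstance(traces, RunOutput) else 0
    return SummaryReport(
        scenario_id=sid or "",
        cohort_size=cohort,
        n_missing=n_missing,
        n_errors=n_errors,
        nodes=nodes,
        branches=branches,
        conclusions=conclusions,
        n_concluded=n_concluded,
    )


def build_detailed(
    traces: Mapping[str, ExecutionTrace], patient_ids: Optional[Iterable[str]] = None
) -> pd.DataFrame:
    """Node-by-node rows for selected patients with the exact values,
    timestamps and codes of every event the scenario investigated."""
    ids = sorted(patient_ids) if patient_ids is not None else sorted(traces)
    unknown = [p for p in ids if p not in traces]
    if unknown:
        raise KeyError(f"no trace for patient(s): {unknown}")
    rows = []
    for pid in ids:
        t = traces[pid]
        for step, v in enumerate(t.visited, start=1):
            rows.append(
                {
                    "patient_id": pid,
                    "step": step,
                    "node_id": v.node_id,
                    "outcome": v.outcome,
                    "n_matched": len(v.matched_events),
                    "matched_events": "; ".join(v.matched_events),
                    "pointer_after": v.pointer_after,
                }
            )
        for c in t.conclusions:
            rows.append(
                {
                    "patient_id": pid,
                    "step": len(t.visited) + 1,
                    "node_id": c.node_id,
                    "outcome": "CONCLUSION",
                    "n_matched": 0,
                    "matched_events": c.label,
                    "pointer_after": "",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "step", "node_id", "outcome",
            "n_matched", "matched_events", "pointer_after",
        ],
    )


def build_ipv(timeline: PatientTimeline) -> pd.DataFrame:
    """Individual patient view: every event of one patient, chronological,
    with all schema columns; one row per timeline event."""
    rows = []
    for e in timeline.events:
        row = {
            "patient_id": e.patient_id,
            "ev_time": _fmt_time(e.ev_time),
            "val_num": e.value_num,
            "val_text": e.value_text,
            "sequence_id": e.sequence_id,
        }
        for fname, (ccol, dcol) in _CODED_FIELDS.items():
            coded = getattr(e, fname)
            row[ccol] = coded.code if coded else None
            row[dcol] = coded.desc if coded else None
        rows.append(row)
    return pd.DataFrame(rows, columns=list(DEFAULT_COLUMNS))
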