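"""Engine: retrospective runs, translation, prospective replay lifecycle."""

from __future__ import annotations

from dataclasses import replace
from datetime import datetime, timedelta

import pytest

from ehrflow.engine import (
    InstanceState,
    TranslationMarkers,
    read_markers,
    revert_translation,
    run_prospective,
    run_retrospective,
    translate_retro_to_prospective,
    write_markers,
)
from ehrflow.events import Coded, Event, build_timelines
from ehrflow.expressions import parse_expression
from ehrflow.operators import OperatorCall
from ehrflow.scenario import (
    Node,
    NodeKind,
    Scenario,
    ScenarioError,
    Transition,
    isomorphic,
    validate,
)
from ehrflow.synth import (
    BMD_PROCEDURE_CODE,
    CONCLUSION_LABEL,
    FRACTURE_CODES,
    OSTEOPOROSIS_DRUGS,
)


def _patient(pid, birth_year, female, fracture_age=None, bmd_offset_days=None,
             drug_offset_days=None):
    """Hand-built synthetic patient for the osteoporosis logic."""
    birth = datetime(birth_year, 6, 1)
    events = [
        Event(pid, birth, Coded(desc="Birth event")),
        Event(pid, birth, Coded(desc="Demographics"), observation=Coded(desc="Gender"),
              coded_value=Coded(desc="Female" if female else "Male")),
    ]
    frac_time = None
    if fracture_age is not None:
        frac_time = birth + timedelta(days=int(fracture_age * 365.25))
        code, desc = FRACTURE_CODES[0]
        events.append(Event(pid, frac_time, Coded(desc="Diagnosis (ICD)"),
                            terminology2=Coded(code, desc)))
    if bmd_offset_days is not None:
        events.append(Event(pid, frac_time + timedelta(days=bmd_offset_days),
                            Coded(desc="Procedure (CPT)"),
                            terminology2=Coded(*BMD_PROCEDURE_CODE)))
    if drug_offset_days is not None:
        code, desc = OSTEOPOROSIS_DRUGS[0]
        events.append(Event(pid, frac_time + timedelta(days=drug_offset_days),
                            Coded(desc="Prescription"), terminology2=Coded(code, desc)))
    events.sort(key=lambda e: e.ev_time)
    return [replace(e, sequence_id=i) for i, e in enumerate(events)]


class TestRetrospective:
    def test_table1_patient_exits_at_fracture_step(self, osteo, store, table1):
        """The worked-example record holds no fracture diagnosis, so the
        scenario fails its first step and produces no conclusion."""
        traces = run_retrospective(osteo.retro, {"T1": table1}, ontology=store)
        t = traces["T1"]
        assert [v.node_id for v in t.visited] == ["s_fracture"]
        assert t.visited[0].outcome == "FAILED"
        assert t.conclusions == []

    def test_planted_positive_patient_reaches_conclusion(self, osteo, store):
        tls = build_timelines(_patient("P1", 1935, True, fracture_age=67))
        t = run_retrospective(osteo.retro, tls, ontology=store)["P1"]
        assert t.conclusion_labels() == (CONCLUSION_LABEL,)
        assert [v.outcome for v in t.visited][:1] == ["SATISFIED"]

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(female=False, fracture_age=67),  # male
            dict(female=True, fracture_age=60),  # too young at fracture
            dict(female=True, fracture_age=67, bmd_offset_days=-200),  # prior BMD
            dict(female=True, fracture_age=67, drug_offset_days=-300),  # prior drug
            dict(female=True),  # no fracture at all
        ],
    )
    def test_pattern_breakers_produce_no_conclusion(self, osteo, store, kwargs):
        tls = build_timelines(_patient("P1", 1935, **kwargs))
        t = run_retrospective(osteo.retro, tls, ontology=store)["P1"]
        assert t.conclusion_labels() == ()

    def test_post_fracture_bmd_does_not_block(self, osteo, store):
        """The density-test check is bounded by the fracture date, so a
        later test cannot retro-actively excuse the missed screening."""
        tls = build_timelines(_patient("P1", 1935, True, fracture_age=67,
                                       bmd_offset_days=+200))
        t = run_retrospective(osteo.retro, tls, ontology=store)["P1"]
        assert t.conclusion_labels() == (CONCLUSION_LABEL,)

    def test_empty_cohort_yields_empty_trace_map(self, osteo, store):
        assert dict(run_retrospective(osteo.retro, {}, ontology=store)) == {}

    def test_missing_cohort_patients_reported(self, osteo, store, table1):
        with pytest.warns(UserWarning, match="no timeline"):
            out = run_retrospective(osteo.retro, {"T1": table1}, cohort=["T1", "ghost"],
                                    ontology=store)
        assert out.missing_patients == ["ghost"]
        assert set(out) == {"T1"}

    def test_invalid_scenario_rejected(self, store):
        bad = Scenario("bad")
        with pytest.raises(ScenarioError):
            run_retrospective(bad, {})

    def test_repeat_runs_are_byte_identical(self, osteo, store, cohort_timelines):
        a = run_retrospective(osteo.retro, cohort_timelines, ontology=store)
        b = run_retrospective(osteo.retro, cohort_timelines, ontology=store)
        assert repr(sorted(a.items())) == repr(sorted(b.items()))
        assert a.log == b.log

    def test_loop_cap_recorded_per_patient_run_continues(self, table1):
        from ehrflow.scenario import VariableDecl

        looper = Scenario(
            "loop",
            (
                Node("start", NodeKind.DUMMY_START),
                Node("a", NodeKind.ANALYTICAL,
                     op_calls=(OperatorCall("increase_counter_variable", {"var": "n"}),)),
                Node("b", NodeKind.ANALYTICAL),
                Node("end", NodeKind.CONCLUSION, "done"),
            ),
            (
                Transition("start", "a", None, False, 1),
                Transition("a", "b", None, False, 1),
                Transition("b", "a", parse_expression("n < 100"), False, 1),
                Transition("b", "end", None, True, 2),
            ),
            variables=(VariableDecl("n", "number", 0),),
        )
        out = run_retrospective(looper, {"T1": table1, "T2": table1}, loop_cap=20)
        assert all(out[p].error and "loop cap" in out[p].error for p in ("T1", "T2"))

    def test_bounded_loop_terminates_and_concludes(self, table1):
        from ehrflow.scenario import VariableDecl

        looper = Scenario(
            "loop",
            (
                Node("start", NodeKind.DUMMY_START),
                Node("a", NodeKind.ANALYTICAL,
                     op_calls=(OperatorCall("increase_counter_variable", {"var": "n"}),)),
                Node("end", NodeKind.CONCLUSION, "done"),
            ),
            (
                Transition("start", "a", None, False, 1),
                Transition("a", "a", parse_expression("n < 5"), False, 1),
                Transition("a", "end", None, True, 2),
            ),
            variables=(VariableDecl("n", "number", 0),),
        )
        t = run_retrospective(looper, {"T1": table1})["T1"]
        assert t.error is None
        assert t.variables["n"] == 5
        assert t.conclusion_labels() == ("done",)


class TestTranslation:
    def test_marked_nodes_flip_kinds_shape_preserved(self, osteo):
        pros = translate_retro_to_prospective(osteo.retro, osteo.markers)
        kinds = {n.id: n.node_kind for n in pros.nodes}
        assert kinds["s_fracture"] is NodeKind.TRIGGER
        assert kinds["s_conclude"] is NodeKind.ACTION
        assert kinds["s_bmd"] is NodeKind.BACKGROUND  # unmarked stays
        assert len(pros.nodes) == len(osteo.retro.nodes)
        assert len(pros.transitions) == len(osteo.retro.transitions)

    def test_no_markers_is_identity_up_to_node_kinds(self, osteo):
        pros = translate_retro_to_prospective(osteo.retro, TranslationMarkers())
        assert [n.node_kind for n in pros.nodes] == [n.node_kind for n in osteo.retro.nodes]
        assert isomorphic(pros, osteo.retro)

    def test_round_trip_restores_original_graph(self, osteo):
        pros = translate_retro_to_prospective(osteo.retro, osteo.markers)
        back = revert_translation(pros, osteo.markers)
        assert back == osteo.retro

    def test_prospective_fixture_is_translation_plus_score_branch(self, osteo):
        pros = translate_retro_to_prospective(osteo.retro, osteo.markers)
        stripped = replace(
            osteo.prospective,
            nodes=tuple(n for n in osteo.prospective.nodes if n.id != "s_score"),
            transitions=tuple(
                t for t in osteo.prospective.transitions
                if "s_score" not in (t.from_id, t.to_id)
            ),
        )
        assert isomorphic(pros, stripped)
        assert not isomorphic(pros, osteo.prospective)

    def test_action_marker_on_non_conclusion_rejected(self, osteo):
        with pytest.raises(ScenarioError, match="not a conclusion"):
            translate_retro_to_prospective(
                osteo.retro, TranslationMarkers(action_nodes={"s_bmd": "generate_alert"})
            )

    def test_translating_mixed_scenario_warns(self, osteo):
        pros = translate_retro_to_prospective(osteo.retro, osteo.markers)
        with pytest.warns(UserWarning, match="cannot be fully tested"):
            translate_retro_to_prospective(pros, TranslationMarkers())

    def test_marker_file_round_trip(self, osteo, tmp_path):
        path = str(tmp_path / "markers.yaml")
        write_markers(osteo.markers, path)
        back = read_markers(path)
        assert back == osteo.markers


class TestProspective:
    def _trigger_scenario(self):
        return Scenario(
            "appt",
            (
                Node("t", NodeKind.TRIGGER, "appointment scheduled",
                     (OperatorCall("find_coded_event", {"family": "visit", "code": "OV"}),)),
                Node("act", NodeKind.ACTION, "generate_alert: visit due"),
            ),
            (Transition("t", "act", parse_expression("result.found")),),
        )

    @staticmethod
    def _visit(pid, day):
        return Event(pid, datetime(2012, 3, day), Coded(desc="Appointment"),
                     event_subtype=Coded("OV", "Office visit"))

    def test_matching_trigger_event_creates_one_instance(self):
        run = run_prospective(self._trigger_scenario(), [self._visit("P1", 5)])
        assert len(run.instances) == 1
        assert run.instances[0].state is InstanceState.COMPLETED
        assert [a.payload for a in run.actions] == ["visit due"]
        assert run.actions[0].emitted_at == datetime(2012, 3, 5)

    def test_no_matching_event_no_instances(self):
        lab = Event("P1", datetime(2012, 3, 5), Coded(desc="Lab"),
                    observation=Coded("x", "x"))
        run = run_prospective(self._trigger_scenario(), [lab])
        assert run.instances == [] and run.actions == []

    def test_coalesce_policy_single_instance_per_patient(self):
        events = [self._visit("P1", d) for d in (3, 10, 20)]
        run = run_prospective(self._trigger_scenario(), events)
        assert len(run.instances) == 1

    def test_multiply_policy_one_instance_per_trigger(self):
        events = [self._visit("P1", d) for d in (3, 10, 20)]
        run = run_prospective(self._trigger_scenario(), events,
                              duplicate_triggers="multiply")
        assert len(run.instances) == 3

    def test_scenario_without_trigger_rejected(self, osteo):
        with pytest.raises(ScenarioError, match="trigger"):
            run_prospective(osteo.retro, [])

    def test_listen_node_pauses_then_resumes_and_completes(self):
        scn = Scenario(
            "surgery",
            (
                Node("t", NodeKind.TRIGGER, "operative report filed",
                     (OperatorCall("find_coded_event",
                                   {"code": "Operative Report"}),)),
                Node("wait", NodeKind.LISTEN, "wait for discharge",
                     (OperatorCall("find_coded_event", {"code": "Discharged"}),)),
                Node("act", NodeKind.ACTION, "send_email: follow-up after discharge"),
            ),
            (
                Transition("t", "wait", parse_expression("result.found"), False, 1),
                Transition("wait", "act", parse_expression("result.found"), False, 1),
            ),
        )
        op = Event("P1", datetime(2012, 5, 1), Coded(desc="Clinical Text Data"),
                   coded_value=Coded(desc="Operative Report"))
        discharge = Event("P1", datetime(2012, 5, 9), Coded(desc="Discharged"))
        run = run_prospective(scn, [op])
        assert run.instances[0].state is InstanceState.PAUSED_AT_LISTEN
        assert run.instances[0].paused_node == "wait"
        run2 = run_prospective(scn, [op, discharge])
        inst = run2.instances[0]
        assert inst.state is InstanceState.COMPLETED
        assert inst.resumed_at == datetime(2012, 5, 9)
        assert [a.action_kind for a in run2.actions] == ["send_email"]

    def test_interleaved_patients_are_isolated(self):
        """Permuting the interleaving of two patients' events (keeping
        per-patient order) changes no outcome."""
        events_a = [self._visit("A", d) for d in (2, 9)]
        events_b = [self._visit("B", d) for d in (5,)]
        merged = [events_a[0], events_b[0], events_a[1]]
        flipped = [events_b[0], events_a[0], events_a[1]]
        r1 = run_prospective(self._trigger_scenario(), merged,
                             duplicate_triggers="multiply")
        r2 = run_prospective(self._trigger_scenario(), flipped,
                             duplicate_triggers="multiply")
        by_patient = lambda r: {
            p: [a.payload for a in r.actions if a.patient_id == p] for p in "AB"
        }
        assert by_patient(r1) == by_patient(r2)

    def test_event_outside_cohort_logged_not_executed(self):
        run = run_prospective(self._trigger_scenario(), [self._visit("X", 2)],
                              cohort=["P1"])
        assert run.instances == []
        assert any("unknown patient" in line for line in run.log)

    def test_malformed_stream_item_dropped_with_log(self):
        run = run_prospective(self._trigger_scenario(), ["not-an-event"])
        assert run.instances == []
        assert any("malformed" in line for line in run.log)


class TestModeEquivalence:
    def test_full_replay_matches_retrospective_conclusions(
        self, osteo, store, cohort_events, cohort_timelines
    ):
        """The seamless-switch property: replaying each complete timeline
        prospectively yields the same per-patient conclusion set as the
        retrospective run of the same logic."""
        retro = run_retrospective(osteo.retro, cohort_timelines, ontology=store)
        pros_scn = translate_retro_to_prospective(osteo.retro, osteo.markers)
        stream = sorted(cohort_events, key=lambda e: (e.ev_time, e.patient_id,
                                                      e.sequence_id))
        run = run_prospective(pros_scn, stream, ontology=store)
        pros_traces = run.traces()
        for pid in cohort_timelines:
            expected = set(retro[pid].conclusion_labels())
            got = set(pros_traces[pid].conclusion_labels()) if pid in pros_traces else set()
            assert got == expected, pid

    def test_planted_positive_fires_in_both_modes(self, osteo, store):
        events = _patient("P9", 1930, True, fracture_age=70)
        retro = run_retrospective(osteo.retro, build_timelines(events), ontology=store)
        assert retro["P9"].conclusion_labels() == (CONCLUSION_LABEL,)
        pros_scn = translate_retro_to_prospective(osteo.retro, osteo.markers)
        run = run_prospective(pros_scn, events, ontology=store)
        assert [a.payload for a in run.actions] == [CONCLUSION_LABEL]
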