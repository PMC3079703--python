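"""Operator library: strict/custom pointer search semantics, variables,
temporal criteria, aggregates, value-set finds, listeners, registry."""

from __future__ import annotations

import io
from datetime import datetime, timedelta

import numpy as np
import pytest

from ehrflow.events import (
    Coded,
    Event,
    PatientTimeline,
    Position,
    PositionKind,
    build_timelines,
)
from ehrflow.ontology import Depth
from ehrflow.operators import (
    DEFAULT_FAMILIES,
    FindResult,
    ListenSpec,
    ModeError,
    PointerMode,
    RegistryError,
    SearchWindow,
    VariableState,
    aggregate_events,
    assign_value_to_variable,
    evaluate_two_timestamps_difference_criterion as ts_criterion,
    find_coded_event,
    find_coded_event_vs,
    hf_export,
    increase_counter_variable,
    level_totals,
    patient_is_male,
    registry_manifest,
    relevant_event_listener,
    simple_find,
    trigger_event_listener,
)


def _lab(pid, t, code, desc, vn=None, seq=0):
    return Event(pid, t, Coded(desc="Lab"), observation=Coded(code, desc),
                 value_num=vn, sequence_id=seq)


def _dx(pid, t, code, seq=0):
    return Event(pid, t, Coded(desc="Diagnosis (ICD)"),
                 terminology2=Coded(code, code), sequence_id=seq)


# ---------------------------------------------------------------------------
# Independent full-scan oracle: filter every event of the record by family
# type label, designated code field, window and pointer region, in order.


def naive_find(timeline, family, code, window=None, strict=True):
    dialect = DEFAULT_FAMILIES[family] if family else None
    if strict:
        p = timeline.pointer
        if p.kind is PositionKind.BEFORE_FIRST:
            allowed = set(range(len(timeline.events)))
        elif p.kind is PositionKind.AFTER_LAST:
            allowed = set()
        elif p.kind is PositionKind.AT_EVENT:
            allowed = set(range(p.index + 1, len(timeline.events)))
        else:
            allowed = {
                i for i, e in enumerate(timeline.events) if e.ev_time >= p.time
            }
    else:
        allowed = set(range(len(timeline.events)))
    out = []
    for i, e in enumerate(timeline.events):
        if i not in allowed:
            continue
        if window is not None and not window.contains(e.ev_time):
            continue
        if dialect is not None:
            if not any(e.event_type.matches(t) for t in dialect.event_types):
                continue
            coded = getattr(e, dialect.match_field)
            if code is not None and (coded is None or not coded.matches(code)):
                continue
        elif code is not None:
            hit = False
            for f in ("event_type", "event_subtype", "observation", "coded_value",
                      "flag", "terminology2"):
                c = getattr(e, f)
                if c is not None and c.matches(code):
                    hit = True
            if not hit:
                continue
        out.append(e)
    return out


class TestSimpleFinds:
    def test_cholesterol_worked_example(self, table1):
        found = simple_find(table1, "lab_result", "Cholesterol, Plasma Quant.")
        assert found is True
        p = table1.pointer
        assert p.kind is PositionKind.AT_EVENT
        matched = table1.events[p.index]
        assert matched.value_num == 327
        assert matched.flag.desc == "Higher Than Normal"
        assert matched.ev_time == datetime(2046, 4, 23, 15, 23)

    def test_find_after_last_event_fails_pointer_unchanged(self, table1):
        table1.pointer = Position.at_event(13)
        before = table1.pointer
        assert simple_find(table1, "lab_result", "Cholesterol, Plasma Quant.") is False
        assert table1.pointer == before

    def test_follow_up_found_only_after_pointer(self):
        t0 = datetime(2005, 1, 1)
        events = [
            _lab("P1", t0, "LDL", "LDL cholesterol", 190, 0),
            Event("P1", t0 + timedelta(days=30), Coded(desc="Prescription"),
                  terminology2=Coded("statin", "statin"), sequence_id=0),
            _lab("P1", t0 + timedelta(days=200), "LDL", "LDL cholesterol", 120, 0),
        ]
        tl = build_timelines(events)["P1"]
        # establish therapy onset, then look for the follow-up test
        assert simple_find(tl, "prescription", "statin")
        assert simple_find(tl, "lab_result", "LDL") is True
        # no further follow-up beyond that one
        assert simple_find(tl, "lab_result", "LDL") is False

    def test_unknown_family_is_registry_error(self, table1):
        with pytest.raises(RegistryError):
            simple_find(table1, "genomics", "x")

    def test_empty_code_rejected(self, table1):
        with pytest.raises(ValueError):
            simple_find(table1, "lab_result", "")


class TestPatientIsMale:
    def _gender(self, value):
        return Event("P1", datetime(2000, 1, 1), Coded(desc="Demographics"),
                     observation=Coded(desc="Gender"), coded_value=Coded(desc=value))

    def test_female_record_returns_false(self):
        tl = build_timelines([self._gender("Female")])["P1"]
        assert patient_is_male(tl) is False

    def test_male_record_returns_true(self):
        tl = build_timelines([self._gender("Male")])["P1"]
        assert patient_is_male(tl) is True

    def test_record_without_gender_returns_null(self, table1):
        assert patient_is_male(table1) is None

    def test_empty_timeline_returns_null(self):
        assert patient_is_male(PatientTimeline("P1")) is None

    def test_lookup_does_not_move_pointer(self):
        tl = build_timelines([self._gender("Female"), _lab("P1", datetime(2001, 1, 1),
                                                           "x", "x")])["P1"]
        before = tl.pointer
        patient_is_male(tl)
        assert tl.pointer == before


class TestAdvancedFind:
    def test_count_in_window_supports_branching(self):
        t0 = datetime(2010, 6, 1)
        events = [_dx("P1", t0 + timedelta(days=30 * i), "V56.0", seq=i) for i in range(5)]
        tl = build_timelines(events)["P1"]
        tl.pointer = Position.at_time(t0 + timedelta(days=365))
        window = SearchWindow(t0 + timedelta(days=365) - timedelta(days=365), None)
        r = find_coded_event(tl, "diagnosis", "V56.0", window=window,
                             pointer_mode=PointerMode.CUSTOM)
        assert r.count == 5 and r.count > 3
        assert [e for e in r.matches] == naive_find(tl, "diagnosis", "V56.0",
                                                    window, strict=False)

    def test_window_excluding_everything(self, table1):
        w = SearchWindow(datetime(1800, 1, 1), datetime(1900, 1, 1))
        before = table1.pointer
        r = find_coded_event(table1, "lab_result", None, window=w,
                             pointer_mode=PointerMode.CUSTOM)
        assert r.found is False and r.count == 0 and table1.pointer == before

    def test_fentanyl_injection_worked_example(self, table1):
        r = find_coded_event(table1, "procedure", "J3010",
                             pointer_mode=PointerMode.CUSTOM)
        assert r.count == 1
        assert r.first_match.value_num == 2
        assert r.first_match.terminology2.desc == "Inj, fentanyl citrate"

    def test_invalid_window_is_argument_error(self):
        with pytest.raises(ValueError):
            SearchWindow(datetime(2010, 1, 1), datetime(2000, 1, 1))

    def test_strict_mode_moves_pointer_to_first_match(self, table1):
        r = find_coded_event(table1, "procedure", "8363")
        assert r.found and table1.pointer == r.pointer_after
        assert table1.events[table1.pointer.index].terminology2.code == "8363"

    def test_failed_find_is_fully_transparent(self, table1):
        table1.pointer = Position.at_event(3)
        before_events = table1.events
        before_pointer = table1.pointer
        r = find_coded_event(table1, "diagnosis", "no-such-code")
        assert not r.found
        assert table1.events is before_events and table1.pointer == before_pointer


class TestOracleEquivalence:
    """Every find operator equals the naive full-scan filter."""

    FAMILIES = ("lab_result", "diagnosis", "prescription", "procedure")
    CODES = ("A1", "B2", "C3", "D4")

    def _random_timeline(self, rng, n):
        t0 = datetime(2000, 1, 1)
        events = []
        for i in range(n):
            fam = self.FAMILIES[rng.integers(0, len(self.FAMILIES))]
            code = self.CODES[rng.integers(0, len(self.CODES))]
            t = t0 + timedelta(days=int(rng.integers(0, 1000)))
            ev_type = {"lab_result": "Lab", "diagnosis": "Diagnosis (ICD)",
                       "prescription": "Prescription", "procedure": "Procedure (CPT)"}[fam]
            kw = {}
            if fam == "lab_result":
                kw["observation"] = Coded(code, code)
            else:
                kw["terminology2"] = Coded(code, code)
            events.append(Event("P1", t, Coded(desc=ev_type), sequence_id=i % 3, **kw))
        if not events:
            return PatientTimeline("P1")
        return build_timelines(events)["P1"]

    @pytest.mark.parametrize("strict", [True, False])
    def test_matches_naive_scan(self, strict):
        rng = np.random.default_rng(42)
        for _ in range(150):
            tl = self._random_timeline(rng, int(rng.integers(0, 25)))
            fam = self.FAMILIES[rng.integers(0, len(self.FAMILIES))]
            code = self.CODES[rng.integers(0, len(self.CODES))]
            if len(tl.events) and rng.random() < 0.5:
                tl.pointer = Position.at_event(int(rng.integers(0, len(tl.events))))
            window = None
            if rng.random() < 0.5:
                lo = datetime(2000, 1, 1) + timedelta(days=int(rng.integers(0, 900)))
                window = SearchWindow(lo, lo + timedelta(days=int(rng.integers(0, 400))))
            mode = PointerMode.STRICT if strict else PointerMode.CUSTOM
            expected = naive_find(tl, fam, code, window, strict=strict)
            got = find_coded_event(tl, fam, code, window=window, pointer_mode=mode)
            assert list(got.matches) == expected
            assert got.found is bool(expected) and got.count == len(expected)

    def test_simple_level_is_advanced_with_default_window(self, table1):
        """Level containment: a simple find is the advanced call with the
        default window, projected to its found flag."""
        import copy

        a, b = copy.deepcopy(table1), copy.deepcopy(table1)
        for code in ("Cholesterol, Plasma Quant.", "Epithelial Cells, Urine", "nope"):
            sf = simple_find(a, "lab_result", code)
            af = find_coded_event(b, "lab_result", code)
            assert sf == af.found
            assert a.pointer == b.pointer


class TestVariables:
    def test_counter_three_increments(self):
        state = VariableState(["n"])
        for _ in range(3):
            increase_counter_variable(state, "n")
        assert state["n"] == 3

    def test_assign_undeclared_is_error(self):
        with pytest.raises(KeyError):
            assign_value_to_variable(VariableState(["a"]), "b", 1)

    def test_assignment_visible_to_later_reads(self):
        state = VariableState(["onset"])
        assign_value_to_variable(state, "onset", datetime(2005, 5, 5))
        assert state["onset"] == datetime(2005, 5, 5)


class TestTemporalCriterion:
    def test_naloxone_icu_within_six_hours(self):
        t = datetime(2010, 3, 1, 8, 0)
        assert ts_criterion(t, t + timedelta(hours=5), "<=", 6, "hours") is True
        assert ts_criterion(t, t + timedelta(hours=7), "<=", 6, "hours") is False

    def test_equal_timestamps_ge_zero_days(self):
        t = datetime(2010, 3, 1)
        assert ts_criterion(t, t, ">=", 0, "days") is True

    def test_200_days_vs_6_calendar_months(self):
        # calendar oracle: 2010-01-15 + 6 calendar months = 2010-07-15,
        # which is 181 days later; 200 days exceeds that boundary
        t1 = datetime(2010, 1, 15)
        t2 = t1 + timedelta(days=200)
        assert (t2 - datetime(2010, 7, 15)).days == 19
        assert ts_criterion(t1, t2, "<=", 6, "months") is False
        assert ts_criterion(t1, t1 + timedelta(days=150), "<=", 6, "months") is True

    def test_calendar_clamp_at_month_end(self):
        # Jan 31 + 1 calendar month clamps to Feb 28
        assert ts_criterion(datetime(2009, 1, 31), datetime(2009, 2, 28),
                            "<=", 1, "months") is True

    def test_null_timestamp_yields_null(self):
        assert ts_criterion(None, datetime(2010, 1, 1), "<=", 6, "hours") is None

    def test_bad_unit_and_comparator(self):
        t = datetime(2010, 1, 1)
        with pytest.raises(ValueError):
            ts_criterion(t, t, "<=", 1, "fortnights")
        with pytest.raises(ValueError):
            ts_criterion(t, t, "~", 1, "days")


class TestAggregates:
    def _labs(self, values):
        return [
            _lab("P1", datetime(2010, 1, 1) + timedelta(days=i), "SBP",
                 "Systolic BP", v, i)
            for i, v in enumerate(values)
        ]

    def test_average(self):
        assert aggregate_events(self._labs([120, 130, 140])).value == 130

    def test_sum_of_single_value(self):
        assert aggregate_events(self._labs([97]), stat="SUM").value == 97

    def test_fifty_values_match_brute_force_mean(self):
        rng = np.random.default_rng(5)
        values = [round(float(v), 1) for v in rng.normal(135, 15, size=50)]
        result = aggregate_events(self._labs(values))
        assert result.value == pytest.approx(sum(values) / 50)
        assert result.n_used == 50

    def test_null_fields_excluded_and_counted(self):
        events = self._labs([100, 120]) + self._labs([None])
        r = aggregate_events(events)
        assert r.value == 110 and r.n_excluded == 1

    def test_empty_set_is_null_with_warning(self):
        with pytest.warns(UserWarning):
            assert aggregate_events([]).value is None


class TestValueSetFind:
    def test_drug_class_matches_member_prescription(self, store):
        ev = Event("P1", datetime(2010, 1, 1), Coded(desc="Prescription"),
                   terminology2=Coded("exenatide", "exenatide injection"))
        tl = build_timelines([ev])["P1"]
        r = find_coded_event_vs(tl, store, "prescription", "RX:incretin_mimetic", "is_a")
        assert r.found and r.first_match.terminology2.code == "exenatide"

    def test_empty_value_set_finds_nothing(self, store, table1):
        from ehrflow.ontology import Concept, OntologyStore

        s = OntologyStore.build([Concept("VS:none")], [])
        assert find_coded_event_vs(table1, s, None, "VS:none").found is False

    def test_first_degree_misses_grandchildren_coded_events(self):
        from ehrflow.ontology import Concept, OntologyStore, Relationship

        s = OntologyStore.build(
            [Concept("top"), Concept("mid"), Concept("leaf")],
            [Relationship("mid", "top", "is_a"), Relationship("leaf", "mid", "is_a")],
        )
        ev = Event("P1", datetime(2010, 1, 1), Coded(desc="Prescription"),
                   terminology2=Coded("leaf", "leaf drug"))
        tl = build_timelines([ev])["P1"]
        assert find_coded_event_vs(tl, s, "prescription", "top", "is_a",
                                   depth=Depth.FIRST_DEGREE).found is False
        assert find_coded_event_vs(tl, s, "prescription", "top", "is_a",
                                   depth=Depth.ALL).found is True


class TestListeners:
    def test_registration_outside_prospective_mode_is_error(self):
        class RetroContext:
            mode = "retrospective"

        with pytest.raises(ModeError):
            trigger_event_listener(RetroContext(), ListenSpec(family="visit"))
        with pytest.raises(ModeError):
            relevant_event_listener(RetroContext(), ListenSpec(family="visit"))

    def test_spec_matches_family_and_code(self):
        spec = ListenSpec(family="visit", code="OV")
        visit = Event("P1", datetime(2010, 1, 1), Coded(desc="Appointment"),
                      event_subtype=Coded("OV", "Office visit"))
        lab = _lab("P1", datetime(2010, 1, 1), "x", "x")
        assert spec.matches(visit) and not spec.matches(lab)


class TestRegistry:
    def test_published_level_totals(self):
        assert level_totals() == {"simple": 9, "advanced": 7, "ultimate": 4}

    def test_manifest_is_machine_readable_and_complete(self):
        manifest = registry_manifest()
        names = {m["name"] for m in manifest}
        assert {"find_diagnosis", "find_lab_result", "find_visit",
                "find_coded_event", "aggregate_events"} <= names
        assert all({"name", "level", "category", "params", "summary"} <= set(m)
                   for m in manifest)

    def test_nine_distinct_find_families(self):
        fams = [m for m in registry_manifest()
                if m["level"] == "simple" and m["category"] == "find_family"]
        assert len(fams) == 9 and len({m["name"] for m in fams}) == 9


class TestExport:
    def test_export_shape_and_quoting(self):
        class T:
            def __init__(self, variables, conclusions):
                self.variables = variables
                self.conclusions = conclusions

        class C:
            def __init__(self, label):
                self.label = label

        traces = {
            "P1": T({"a": 1, "b": "x,y"}, [C("risk")]),
            "P2": T({"a": None, "b": "z"}, []),
        }
        buf = io.StringIO()
        hf_export(traces, ["a", "b", "conclusions"], buf)
        lines = buf.getvalue().splitlines()
        assert lines[0] == "patient_id,a,b,conclusions"
        assert lines[1] == 'P1,1,"x,y",risk'
        assert lines[2] == "P2,,z,"

    def test_unknown_column_is_error(self):
        class T:
            variables = {}
            conclusions = ()

        with pytest.raises(KeyError):
            hf_export({"P1": T()}, ["ghost"], io.StringIO())

    def test_empty_cohort_writes_header_only(self):
        buf = io.StringIO()
        hf_export({}, ["a"], buf)
        assert buf.getvalue() == "patient_id,a\n"
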