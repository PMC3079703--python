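"""Fixtures and a seeded synthetic-cohort generator.

Everything in the package is testable without any external data: this
module encodes the printed worked-example patient record, the osteoporosis
screening scenario in its retrospective and prospective forms, a small
illustrative ontology (drug classes and diagnostic value sets — not
clinical assets), and a reproducible generator of chronological coded
event streams with plantable clinical patterns at exact prevalences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Mapping, Optional, Sequence

import numpy as np

from .engine import TranslationMarkers, translate_retro_to_prospective
from .events import Coded, Event, PatientTimeline, build_timelines
from .ontology import Concept, OntologyStore, Relationship
from .operators import OperatorCall
from .scenario import Node, NodeKind, Scenario, Transition, VariableDecl
from .expressions import parse_expression

__all__ = [
    "fixture_table1",
    "fixture_ontology",
    "fixture_osteoporosis",
    "OsteoporosisFixture",
    "CohortConfig",
    "PatternInjection",
    "ConfigError",
    "generate_cohort",
    "FRACTURE_CODES",
    "OSTEOPOROSIS_DRUGS",
    "BMD_PROCEDURE_CODE",
    "BMD_SCORE_OBSERVATION",
]


# ---------------------------------------------------------------------------
# Worked-example patient (the printed 14-event chart)


def _t(text: str) -> datetime:
    return datetime.fromisoformat(text)


def fixture_table1(patient_id: str = "T1") -> PatientTimeline:
    """The printed example patient: 14 events from a birth event in 1990
    through a rotator-cuff repair admission to an ICU discharge, with the
    printed timestamps, types, codes and values."""
    rows: list[dict] = [
        dict(t="1990-01-01 00:00:00", ty="Birth event"),
        dict(t="2046-04-23 00:00:00", ty="Length of Stay", vn=3),
        dict(t="2046-04-23 00:00:00", ty="ICD-9-CM Diseases",
             t2=("72610", "ROTATOR CUFF SYND NOS")),
        dict(t="2046-04-23 00:00:00", ty="ICD-9-CM Procedures",
             t2=("8363", "ROTATOR CUFF REPAIR")),
        dict(t="2046-04-23 00:00:00", ty="CPT-4", vn=2, t2=("J3010", "Inj, fentanyl citrate")),
        dict(t="2046-04-23 00:00:00", ty="CPT-4", t2=("29999", "ARTHROSCOPY OF JOINT")),
        dict(t="2046-04-23 15:01:00", ty="Clinical Text Data", cv="Operative Report"),
        dict(t="2046-04-23 15:23:00", ty="Standard Lab Data", sub="Lipid Profile",
             obs="Cholesterol, Plasma Quant.", flg="Higher Than Normal", vn=327),
        dict(t="2046-04-23 15:21:00", ty="Standard Lab Data", sub="Urine Mi-croscopics",
             obs="Epithelial Cells, Urine", cv="Occasional"),
        dict(t="2046-05-11 13:21:50", ty="Problem Event", sub="Diagnosis", cv="Hyperlipidemia"),
        dict(t="2046-08-12 11:12:13", ty="Patient Order", sub="Pharmacy order",
             cv="Meperidine Hcl, 50 Mg/Ml, Ampul"),
        dict(t="2047-01-18 10:55:01", ty="Nurse Note",
             t2=("203.1.10.3.1.10.1.0", "PURPOSEFUL MOVEMENT")),
        dict(t="2047-01-18 15:23:30", ty="Inpatient Drug",
             t2=("3513816", "ELECTROLYTES (NUTRILYTE) 42.9 ML, VIAL")),
        dict(t="2047-01-19 11:02:02", ty="Discharged", t2=("43", "ICU")),
    ]
    events = []
    for i, r in enumerate(rows):
        events.append(
            Event(
                patient_id=patient_id,
                ev_time=_t(r["t"]),
                event_type=Coded(desc=r["ty"]),
                event_subtype=Coded(desc=r["sub"]) if "sub" in r else None,
                observation=Coded(desc=r["obs"]) if "obs" in r else None,
                coded_value=Coded(desc=r["cv"]) if "cv" in r else None,
                flag=Coded(desc=r["flg"]) if "flg" in r else None,
                value_num=float(r["vn"]) if "vn" in r else None,
                terminology2=Coded(*r["t2"]) if "t2" in r else None,
                sequence_id=i,
            )
        )
    return build_timelines(events)[patient_id]


# ---------------------------------------------------------------------------
# Illustrative ontology (drug classes and diagnostic value sets)

FRACTURE_CODES: tuple[tuple[str, str], ...] = (
    ("820.8", "FRACTURE NECK OF FEMUR NOS"),
    ("812.0", "FRACTURE UPPER HUMERUS, CLOSED"),
    ("813.42", "FRACTURE DISTAL RADIUS, CLOSED"),
)
OSTEOPOROSIS_DRUGS: tuple[tuple[str, str], ...] = (
    ("alendronate", "alendronate sodium tablet"),
    ("risedronate", "risedronate sodium tablet"),
    ("raloxifene", "raloxifene hydrochloride tablet"),
)
BMD_PROCEDURE_CODE = ("76977", "BONE MINERAL DENSITY STUDY")
BMD_SCORE_OBSERVATION = "BMD T-score"

_INCRETIN_MIMETICS = ("exenatide", "liraglutide", "taspoglutide")
_AMM_A_CODES = ("296.2", "296.3", "298.0", "311")  # major-depression diagnostic codes


def fixture_ontology_tables() -> tuple[list[Concept], list[Relationship]]:
    concepts = [
        Concept("VS:fracture_dx", "fracture diagnoses value set"),
        Concept("RX:osteoporosis_prevention", "osteoporosis prevention drugs"),
        Concept("RX:incretin_mimetic", "incretin mimetics drug class"),
        Concept("RX:beta_blocker", "beta blockers drug class"),
        Concept("RX:atenolol", "atenolol tablet"),
        Concept("DX:hypertension", "essential hypertension"),
        Concept("VS:AMM-A", "antidepressant medication management, table A"),
    ]
    rels = []
    for code, desc in FRACTURE_CODES:
        concepts.append(Concept(f"ICD9:{code}", desc))
        rels.append(Relationship(f"ICD9:{code}", "VS:fracture_dx", "is_member"))
    for code, desc in OSTEOPOROSIS_DRUGS:
        concepts.append(Concept(f"RX:{code}", desc))
        rels.append(Relationship(f"RX:{code}", "RX:osteoporosis_prevention", "is_a"))
    for code in _INCRETIN_MIMETICS:
        concepts.append(Concept(f"RX:{code}", f"{code} injection"))
        rels.append(Relationship(f"RX:{code}", "RX:incretin_mimetic", "is_a"))
    rels.append(Relationship("RX:atenolol", "RX:beta_blocker", "is_a"))
    rels.append(Relationship("RX:atenolol", "DX:hypertension", "has_indication"))
    for code in _AMM_A_CODES:
        concepts.append(Concept(f"ICD9:{code}", f"depression diagnosis {code}"))
        rels.append(Relationship(f"ICD9:{code}", "VS:AMM-A", "is_member"))
    return concepts, rels


def fixture_ontology() -> OntologyStore:
    """Small bundled concept store: fracture and depression value sets,
    osteoporosis-prevention / incretin-mimetic / beta-blocker drug classes.
    Illustrative codes, not clinical assets."""
    return OntologyStore.build(*fixture_ontology_tables())


# ---------------------------------------------------------------------------
# Osteoporosis screening scenario (retro + prospective forms)

CONCLUSION_LABEL = "increased fracture risk"


@dataclass(frozen=True)
class OsteoporosisFixture:
    retro: Scenario
    prospective: Scenario
    markers: TranslationMarkers


def _call(op: str, result_var: Optional[str] = None, **args) -> OperatorCall:
    return OperatorCall(op, args, result_var)


def fixture_osteoporosis() -> OsteoporosisFixture:
    """Osteoporosis case-finding logic: women with a fracture after age 65
    who never had a bone-density test nor an osteoporosis prevention drug
    before the fracture are concluded to be at increased fracture risk.

    The prospective form is the marker translation of the retrospective
    form (fracture step becomes the trigger, the conclusion becomes an
    alert action) extended with one branch for a site that records
    structured density scores: a present density test no longer ends the
    scenario if the T-score still indicates action.
    """
    variables = (
        VariableDecl("birth_date", "timestamp"),
        VariableDecl("fracture_date", "timestamp"),
        VariableDecl("age_ok", "boolean"),
        VariableDecl("is_male", "boolean"),
    )
    nodes = (
        Node("s_fracture", NodeKind.BACKGROUND, "fracture diagnosis",
             (_call("find_coded_event_vs", family="diagnosis",
                    value_set_concept="VS:fracture_dx", rel_type="is_member"),)),
        Node("s_fracture_date", NodeKind.ANALYTICAL, "remember fracture date",
             (_call("assign_value_to_variable", var="fracture_date",
                    value="$result.first_match.ev_time"),)),
        Node("s_birth", NodeKind.BACKGROUND, "establish date of birth",
             (_call("find_coded_event", code="Birth event", pointer_mode="CUSTOM"),
              _call("assign_value_to_variable", var="birth_date",
                    value="$result.first_match.ev_time"))),
        Node("s_age", NodeKind.ANALYTICAL, "fracture after age 65",
             (_call("evaluate_two_timestamps_difference_criterion",
                    result_var="age_ok", t1="$birth_date", t2="$fracture_date",
                    comparator=">=", amount=65, unit="years"),)),
        Node("s_female", NodeKind.ANALYTICAL, "ensure female gender",
             (_call("patient_is_male", result_var="is_male"),)),
        Node("s_bmd", NodeKind.BACKGROUND, "bone mineral density test",
             (_call("find_coded_event", family="procedure",
                    code=BMD_PROCEDURE_CODE[0], pointer_mode="CUSTOM",
                    window={"upper": "$fracture_date"}),)),
        Node("s_drug", NodeKind.BACKGROUND, "osteoporosis prevention drug",
             (_call("find_coded_event_vs", family="prescription",
                    value_set_concept="RX:osteoporosis_prevention", rel_type="is_a",
                    pointer_mode="CUSTOM", window={"upper": "$fracture_date"}),)),
        Node("s_conclude", NodeKind.CONCLUSION, CONCLUSION_LABEL),
    )
    # only the branches that make the scenario proceed are modelled;
    # a failing step simply ends the execution without a conclusion
    transitions = (
        Transition("s_fracture", "s_fracture_date", parse_expression("result.found"), False, 1),
        Transition("s_fracture_date", "s_birth", None, False, 1),
        Transition("s_birth", "s_age", parse_expression("birth_date != null"), False, 1),
        Transition("s_age", "s_female", parse_expression("age_ok"), False, 1),
        Transition("s_female", "s_bmd", parse_expression("is_male == false"), False, 1),
        Transition("s_bmd", "s_drug", parse_expression("result.count == 0"), False, 1),
        Transition("s_drug", "s_conclude", parse_expression("result.count == 0"), False, 1),
    )
    retro = Scenario(
        id="osteoporosis_retro",
        nodes=nodes,
        transitions=transitions,
        variables=variables,
        participants=("requestor", "knowledge_engineer"),
    )
    markers = TranslationMarkers(
        trigger_nodes=frozenset({"s_fracture"}),
        action_nodes={"s_conclude": "generate_alert"},
    )
    base = translate_retro_to_prospective(retro, markers)
    score_node = Node(
        "s_score", NodeKind.BACKGROUND, "structured density score",
        (_call("find_coded_event", code=BMD_SCORE_OBSERVATION, pointer_mode="CUSTOM",
               window={"upper": "$fracture_date"}),),
    )
    prospective = Scenario(
        id="osteoporosis_prospective",
        nodes=base.nodes + (score_node,),
        transitions=tuple(base.transitions) + (
            Transition("s_bmd", "s_score", parse_expression("result.count > 0"), False, 2),
            Transition("s_score", "s_drug",
                       parse_expression("result.value_num <= -2.5"), False, 1),
        ),
        variables=base.variables,
        participants=base.participants,
    )
    return OsteoporosisFixture(retro, prospective, markers)


# ---------------------------------------------------------------------------
# Cohort generator


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PatternInjection:
    """A clinical pattern planted into a known fraction of the cohort.

    With ``deterministic`` assignment exactly ``round(prevalence * n)``
    patients carry the pattern (chosen by a seeded permutation), so cohort
    reports can be checked against the planted truth exactly; the
    probabilistic mode draws carriers i.i.d. instead.
    """

    name: str
    prevalence: float
    deterministic: bool = True


#: mean events per patient per year over the active record window
DEFAULT_RATES: Mapping[str, float] = {
    "lab_result": 4.0,
    "diagnosis": 2.0,
    "procedure": 1.0,
    "prescription": 1.5,
    "visit": 3.0,
}

DEFAULT_VOCABULARIES: Mapping[str, Sequence[tuple[str, str]]] = {
    "lab_result": (("2160-0", "Creatinine, Serum"), ("2093-3", "Cholesterol, Total"),
                   ("718-7", "Hemoglobin")),
    "diagnosis": (("401.9", "ESSENTIAL HYPERTENSION NOS"), ("250.00", "DIABETES MELLITUS II"),
                  ("272.4", "HYPERLIPIDEMIA NEC/NOS")),
    "procedure": (("93000", "ELECTROCARDIOGRAM"), ("71020", "CHEST X-RAY")),
    "prescription": (("lisinopril", "lisinopril tablet"), ("metformin", "metformin tablet")),
    "visit": (("OV", "Office visit"), ("PHONE", "Telephone encounter")),
}

#: (mean, sd) of value_num per lab observation code
DEFAULT_NUMERIC: Mapping[str, tuple[float, float]] = {
    "2160-0": (1.0, 0.3),
    "2093-3": (195.0, 35.0),
    "718-7": (13.5, 1.5),
}

_FAMILY_EVENT_TYPE = {
    "lab_result": "Lab",
    "diagnosis": "Diagnosis (ICD)",
    "procedure": "Procedure (CPT)",
    "prescription": "Prescription",
    "visit": "Appointment",
}


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a generated cohort.

    The defaults describe a screening-age population: births 1920-1960, a
    ten-year active record starting at age 60, and modest per-family event
    rates.  Patterns are planted at exact prevalence by default.
    """

    n_patients: int = 100
    seed: int = 0
    birth_year_range: tuple[int, int] = (1920, 1960)
    record_start_age: int = 60
    record_years: int = 18
    rates: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_RATES))
    vocabularies: Mapping[str, Sequence[tuple[str, str]]] = field(
        default_factory=lambda: dict(DEFAULT_VOCABULARIES)
    )
    numeric_distributions: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_NUMERIC)
    )
    patterns: tuple[PatternInjection, ...] = (
        PatternInjection("fracture_risk", 0.3),
    )

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        if any(r < 0 for r in self.rates.values()):
            raise ConfigError("event rates must be >= 0")
        names = [p.name for p in self.patterns]
        if len(set(names)) != len(names):
            raise ConfigError(f"duplicate pattern injections: {names}")
        for p in self.patterns:
            if not 0.0 <= p.prevalence <= 1.0:
                raise ConfigError(f"pattern {p.name!r}: prevalence outside [0, 1]")
        if sum(p.prevalence for p in self.patterns) > 1.0 + 1e-9:
            raise ConfigError("pattern prevalences exceed 1: patients cannot carry "
                              "contradictory patterns")
        unknown = [p.name for p in self.patterns if p.name != "fracture_risk"]
        if unknown:
            raise ConfigError(f"unknown pattern name(s): {unknown}")


def _coded_event(pid: str, t: datetime, family: str, code: str, desc: str,
                 value_num: Optional[float] = None) -> Event:
    ev_type = Coded(desc=_FAMILY_EVENT_TYPE[family])
    if family == "lab_result":
        return Event(pid, t, ev_type, observation=Coded(code, desc), value_num=value_num)
    if family == "visit":
        return Event(pid, t, ev_type, event_subtype=Coded(code, desc))
    return Event(pid, t, ev_type, terminology2=Coded(code, desc), value_num=value_num)


def generate_cohort(config: Optional[CohortConfig] = None) -> list[Event]:
    """Generate a seeded synthetic cohort of chronological coded events.

    Every patient gets a birth event, a gender demographic event at birth,
    and background events per family at the configured rates over the
    active record window.  Pattern carriers additionally satisfy the
    pattern's full clinical definition; non-carriers are guaranteed to
    break it in at least one randomly chosen element.  Identical
    ``(config, seed)`` yields byte-identical output.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    fracture_pattern = next((p for p in config.patterns if p.name == "fracture_risk"), None)

    n = config.n_patients
    carriers = np.zeros(n, dtype=bool)
    if fracture_pattern is not None and n:
        if fracture_pattern.deterministic:
            k = int(round(fracture_pattern.prevalence * n))
            carriers[rng.permutation(n)[:k]] = True
        else:
            carriers = rng.random(n) < fracture_pattern.prevalence

    events: list[Event] = []
    y0, y1 = config.birth_year_range
    for i in range(n):
        pid = f"P{i:04d}"
        birth = datetime(int(rng.integers(y0, y1 + 1)), int(rng.integers(1, 13)),
                         int(rng.integers(1, 29)))
        window_start = birth + timedelta(days=365 * config.record_start_age)
        window_days = 365 * config.record_years
        pevents: list[Event] = [
            Event(pid, birth, Coded(desc="Birth event")),
        ]

        is_carrier = bool(carriers[i])
        breaker = None
        if fracture_pattern is not None and not is_carrier:
            breaker = ("no_fracture", "male", "too_young", "bmd_before", "drug_before")[
                int(rng.integers(0, 5))
            ]
        if is_carrier:
            female = True
        elif breaker == "male":
            female = False
        else:
            female = bool(rng.random() < 0.5)
        pevents.append(
            Event(pid, birth, Coded(desc="Demographics"),
                  observation=Coded(desc="Gender"),
                  coded_value=Coded(desc="Female" if female else "Male"))
        )

        # background noise per family
        for family, rate in config.rates.items():
            vocab = config.vocabularies.get(family, ())
            if not vocab:
                continue
            count = int(rng.poisson(rate * config.record_years))
            for _ in range(count):
                t = window_start + timedelta(
                    days=float(rng.uniform(0, window_days)),
                    minutes=int(rng.integers(0, 24 * 60)),
                )
                code, desc = vocab[int(rng.integers(0, len(vocab)))]
                vn = None
                if code in config.numeric_distributions:
                    mean, sd = config.numeric_distributions[code]
                    vn = round(float(rng.normal(mean, sd)), 1)
                pevents.append(_coded_event(pid, t, family, code, desc, vn))

        if fracture_pattern is not None and (is_carrier or breaker not in (None, "no_fracture")):
            if breaker == "too_young":
                frac_age_years = float(rng.uniform(50, 63))
            else:
                frac_age_years = float(rng.uniform(66, 75))
            frac_time = birth + timedelta(days=frac_age_years * 365.25)
            code, desc = FRACTURE_CODES[int(rng.integers(0, len(FRACTURE_CODES)))]
            pevents.append(_coded_event(pid, frac_time, "diagnosis", code, desc))
            if breaker == "bmd_before":
                t = frac_time - timedelta(days=float(rng.uniform(180, 1000)))
                pevents.append(_coded_event(pid, t, "procedure", *BMD_PROCEDURE_CODE))
            if breaker == "drug_before":
                t = frac_time - timedelta(days=float(rng.uniform(180, 1000)))
                code, desc = OSTEOPOROSIS_DRUGS[int(rng.integers(0, len(OSTEOPOROSIS_DRUGS)))]
                pevents.append(_coded_event(pid, t, "prescription", code, desc))
            if is_carrier and rng.random() < 0.3:
                # post-fracture density test: exercises the pre-fracture window
                t = frac_time + timedelta(days=float(rng.uniform(30, 365)))
                pevents.append(_coded_event(pid, t, "procedure", *BMD_PROCEDURE_CODE))

        pevents.sort(key=lambda e: e.ev_time)
        events.extend(replace(e, sequence_id=j) for j, e in enumerate(pevents))
    return events
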