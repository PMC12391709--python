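"""Rule-based trigger evaluation over hospitalization records.

The shipped default rule set holds the 24 validated triggers (7 laboratory,
6 antidote, 8 symptom, 3 treatment); user rule sets of the same condition
shapes run unchanged. Conventions:

* every printed threshold is a strict inequality, exactly as worded;
* at most one hit per (patient, trigger) per admission — the counting unit
  behind per-trigger positives and the overall PPV denominator;
* baseline-ratio rules compare against the first in-stay measurement;
* evaluation is order-independent and deterministic.
"""

from __future__ import annotations

import datetime as dt
import enum
from pathlib import Path
from typing import Literal, Optional, Union

import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from .records import (
    Analyte,
    DrugDictionary,
    HospitalizationRecord,
    InterventionKind,
    Sex,
    SymptomVocabulary,
    default_drug_dictionary,
    default_symptom_vocabulary,
)

__all__ = [
    "TriggerCategory",
    "TriggerRule",
    "TriggerHit",
    "ScreeningResult",
    "RulesetError",
    "load_ruleset",
    "default_ruleset",
    "evaluate_trigger",
    "evaluate_lab_trigger",
    "evaluate_exposure_trigger",
    "evaluate_event_trigger",
    "screen_cohort",
]


class TriggerCategory(str, enum.Enum):
    laboratory = "laboratory"
    antidote = "antidote"
    symptom = "symptom"
    treatment = "treatment"


class RulesetError(ValueError):
    """Invalid rule-set configuration (unknown shape, duplicate id, bad strata)."""


class Stratum(BaseModel):
    """An age(/sex) band with its own bound, e.g. the hemoglobin rule's bands."""

    age_min: float
    age_max: Optional[float] = None  # None = unbounded above; bands are [min, max)
    sex: Optional[Sex] = None
    bound: float

    def applies(self, age: float, sex: Sex) -> bool:
        if self.sex is not None and sex != self.sex:
            return False
        upper_ok = self.age_max is None or age < self.age_max
        return self.age_min <= age and upper_ok


class ThresholdCondition(BaseModel):
    shape: Literal["threshold"] = "threshold"
    analyte: Analyte
    comparator: Literal["<", ">"]
    bound: Optional[float] = None
    strata: Optional[list[Stratum]] = None

    @model_validator(mode="after")
    def _one_bound_source(self) -> "ThresholdCondition":
        if (self.bound is None) == (self.strata is None):
            raise ValueError("threshold needs exactly one of bound / strata")
        return self

    def bound_for(self, age: float, sex: Sex) -> Optional[float]:
        if self.strata is None:
            return self.bound
        for st in self.strata:
            if st.applies(age, sex):
                return st.bound
        return None  # age outside every band: rule not evaluated


class CompositeCondition(BaseModel):
    shape: Literal["composite"] = "composite"
    op: Literal["any", "all"]
    parts: list[Union["ThresholdCondition", "CompositeCondition"]]


class BaselineRatioCondition(BaseModel):
    """Any listed analyte rising strictly above ratio x its first in-stay value."""

    shape: Literal["baseline_ratio"] = "baseline_ratio"
    analytes: list[Analyte]
    ratio: float = Field(gt=0)


class ExposureCondition(BaseModel):
    shape: Literal["exposure"] = "exposure"
    drug_class: str


class SymptomCondition(BaseModel):
    shape: Literal["symptom"] = "symptom"
    group: str


class InterventionCondition(BaseModel):
    shape: Literal["intervention"] = "intervention"
    kind: InterventionKind


class AbruptCessationCondition(BaseModel):
    shape: Literal["abrupt_cessation"] = "abrupt_cessation"


Condition = Union[
    ThresholdCondition,
    CompositeCondition,
    BaselineRatioCondition,
    ExposureCondition,
    SymptomCondition,
    InterventionCondition,
    AbruptCessationCondition,
]

CompositeCondition.model_rebuild()


class TriggerRule(BaseModel):
    trigger_id: str
    category: TriggerCategory
    description: str = ""
    condition: Condition = Field(discriminator="shape")


class TriggerHit(BaseModel):
    """One firing of a trigger for one admission (deduplicated per patient)."""

    patient_id: str
    trigger_id: str
    evidence: list[str]  # "lab:i" / "med:i" / "event:i" / "intervention:i"
    first_satisfied_at: dt.datetime


class ScreeningResult(BaseModel):
    hits: list[TriggerHit]
    per_patient_flag: dict[str, bool]

    @property
    def n_instances(self) -> int:
        return len(self.hits)

    def positives_per_trigger(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for hit in self.hits:
            counts[hit.trigger_id] = counts.get(hit.trigger_id, 0) + 1
        return counts

    def trigger_counts_per_patient(self) -> dict[str, int]:
        counts = {pid: 0 for pid in self.per_patient_flag}
        for hit in self.hits:
            counts[hit.patient_id] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "patient_id": h.patient_id,
                "trigger_id": h.trigger_id,
                "evidence": ";".join(h.evidence),
                "first_satisfied_at": h.first_satisfied_at.isoformat(),
            }
            for h in self.hits
        ]
        return pd.DataFrame(rows, columns=["patient_id", "trigger_id", "evidence", "first_satisfied_at"])


# ---------------------------------------------------------------------------
# Rule-set loading


def _build_condition(raw: dict, uln: dict[str, float]) -> Condition:
    shape = raw.get("shape")
    if shape == "threshold":
        raw = dict(raw)
        mult = raw.pop("uln_multiple", None)
        if mult is not None:
            analyte = raw["analyte"]
            if analyte not in uln:
                raise RulesetError(f"threshold on {analyte} uses uln_multiple but no ULN is configured")
            raw["bound"] = float(mult) * float(uln[analyte])
        return ThresholdCondition(**raw)
    if shape == "composite":
        return CompositeCondition(
            op=raw["op"], parts=[_build_condition(p, uln) for p in raw["parts"]]
        )
    builders = {
        "baseline_ratio": BaselineRatioCondition,
        "exposure": ExposureCondition,
        "symptom": SymptomCondition,
        "intervention": InterventionCondition,
        "abrupt_cessation": AbruptCessationCondition,
    }
    if shape not in builders:
        raise RulesetError(f"unknown condition shape {shape!r}")
    return builders[shape](**{k: v for k, v in raw.items() if k != "shape"})


def _validate_strata(rule: TriggerRule) -> None:
    cond = rule.condition
    if not isinstance(cond, ThresholdCondition) or cond.strata is None:
        return
    # non-overlap within each sex slice, coverage from the lowest band upward
    for sex in Sex:
        bands = sorted(
            (s for s in cond.strata if s.sex in (None, sex)), key=lambda s: s.age_min
        )
        prev_max: Optional[float] = None
        for band in bands:
            if prev_max is not None:
                if band.age_min < prev_max:
                    raise RulesetError(f"{rule.trigger_id}: overlapping strata for {sex.value}")
                if band.age_min > prev_max:
                    raise RulesetError(
                        f"{rule.trigger_id}: gap in strata coverage for {sex.value} "
                        f"at age {prev_max}"
                    )
            prev_max = band.age_max
        if bands and bands[-1].age_max is not None:
            raise RulesetError(f"{rule.trigger_id}: strata for {sex.value} do not cover old age")


def load_ruleset(config: str | Path | dict) -> list[TriggerRule]:
    """Parse a YAML/JSON rule-set config into validated rules.

    The shipped default encodes the 24 validated triggers; adding a 25th rule
    of any supported shape requires no engine change.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            data = yaml.safe_load(fh)
    else:
        data = config
    uln = {k: float(v) for k, v in (data.get("uln") or {}).items()}
    rules: list[TriggerRule] = []
    seen: set[str] = set()
    for raw in data["triggers"]:
        try:
            rule = TriggerRule(
                trigger_id=raw["id"],
                category=raw["category"],
                description=raw.get("description", ""),
                condition=_build_condition(raw["condition"], uln),
            )
        except (KeyError, ValueError) as exc:
            raise RulesetError(f"invalid rule {raw.get('id', '?')}: {exc}") from exc
        if rule.trigger_id in seen:
            raise RulesetError(f"duplicate trigger_id {rule.trigger_id!r}")
        seen.add(rule.trigger_id)
        _validate_strata(rule)
        rules.append(rule)
    return rules


def default_ruleset() -> list[TriggerRule]:
    from .records import _data_path

    return load_ruleset(_data_path("triggers_default.yaml"))


# ---------------------------------------------------------------------------
# Evaluation

_SatisfiedBy = tuple[dt.datetime, list[str]]  # (when satisfied, evidence refs)


def _eval_threshold(
    cond: ThresholdCondition, record: HospitalizationRecord
) -> Optional[_SatisfiedBy]:
    bound = cond.bound_for(record.age_at_admission, record.sex)
    if bound is None:
        return None
    best: Optional[_SatisfiedBy] = None
    for i, lab in enumerate(record.labs):
        if lab.analyte != cond.analyte:
            continue
        ok = lab.value > bound if cond.comparator == ">" else lab.value < bound
        if ok and (best is None or lab.timestamp < best[0]):
            best = (lab.timestamp, [f"lab:{i}"])
    return best


def _eval_composite(
    cond: CompositeCondition, record: HospitalizationRecord
) -> Optional[_SatisfiedBy]:
    results = []
    for part in cond.parts:
        if isinstance(part, ThresholdCondition):
            res = _eval_threshold(part, record)
        else:
            res = _eval_composite(part, record)
        results.append(res)
    if cond.op == "any":
        satisfied = [r for r in results if r is not None]
        if not satisfied:
            return None
        return min(satisfied, key=lambda r: r[0])
    # all: every part satisfied; condition holds once the last one is
    if any(r is None for r in results):
        return None
    when = max(r[0] for r in results)  # type: ignore[index]
    evidence = [ref for r in results for ref in r[1]]  # type: ignore[index]
    return (when, evidence)


def _eval_baseline_ratio(
    cond: BaselineRatioCondition, record: HospitalizationRecord
) -> Optional[_SatisfiedBy]:
    best: Optional[_SatisfiedBy] = None
    for analyte in cond.analytes:
        series = sorted(
            ((lab.timestamp, lab.value, i) for i, lab in enumerate(record.labs) if lab.analyte == analyte),
            key=lambda t: t[0],
        )
        if len(series) < 2:
            continue
        base_ts, base_val, base_i = series[0]
        if base_val <= 0:
            continue  # a zero baseline makes the ratio meaningless
        for ts, val, i in series[1:]:
            if val > cond.ratio * base_val and (best is None or ts < best[0]):
                best = (ts, [f"lab:{base_i}", f"lab:{i}"])
    return best


def evaluate_lab_trigger(
    rule: TriggerRule, record: HospitalizationRecord
) -> Optional[TriggerHit]:
    """Evaluate a threshold / composite / baseline-ratio rule.

    Missing analytes simply produce no hit; strict inequalities throughout,
    so a value exactly at the bound never fires.
    """
    cond = rule.condition
    if isinstance(cond, ThresholdCondition):
        res = _eval_threshold(cond, record)
    elif isinstance(cond, CompositeCondition):
        res = _eval_composite(cond, record)
    elif isinstance(cond, BaselineRatioCondition):
        res = _eval_baseline_ratio(cond, record)
    else:
        raise TypeError(f"{rule.trigger_id} is not a laboratory rule")
    if res is None:
        return None
    when, evidence = res
    return TriggerHit(
        patient_id=record.patient_id,
        trigger_id=rule.trigger_id,
        evidence=evidence,
        first_satisfied_at=when,
    )


def evaluate_exposure_trigger(
    rule: TriggerRule,
    record: HospitalizationRecord,
    dictionary: DrugDictionary | None = None,
) -> Optional[TriggerHit]:
    """Hit iff any non-target medication resolves to the rule's drug class."""
    cond = rule.condition
    if not isinstance(cond, ExposureCondition):
        raise TypeError(f"{rule.trigger_id} is not an exposure rule")
    dictionary = dictionary or default_drug_dictionary()
    best: Optional[_SatisfiedBy] = None
    for i, med in enumerate(record.medications):
        if med.is_target_pah_drug:
            continue
        cls = dictionary.lookup(med.drug_name)
        if cls == DrugDictionary.OTHER and med.drug_class:
            cls = med.drug_class  # already resolved upstream
        if cls == cond.drug_class and (best is None or med.start < best[0]):
            best = (med.start, [f"med:{i}"])
    if best is None:
        return None
    return TriggerHit(
        patient_id=record.patient_id,
        trigger_id=rule.trigger_id,
        evidence=best[1],
        first_satisfied_at=best[0],
    )


def evaluate_event_trigger(
    rule: TriggerRule,
    record: HospitalizationRecord,
    vocabulary: SymptomVocabulary | None = None,
) -> Optional[TriggerHit]:
    """Symptom-set, intervention-kind, and abrupt-cessation rules."""
    cond = rule.condition
    best: Optional[_SatisfiedBy] = None
    if isinstance(cond, SymptomCondition):
        vocab = vocabulary or default_symptom_vocabulary()
        for i, ev in enumerate(record.events):
            if vocab.group_of(ev.term) == cond.group and (best is None or ev.timestamp < best[0]):
                best = (ev.timestamp, [f"event:{i}"])
    elif isinstance(cond, InterventionCondition):
        for i, iv in enumerate(record.interventions):
            if iv.kind == cond.kind and (best is None or iv.timestamp < best[0]):
                best = (iv.timestamp, [f"intervention:{i}"])
    elif isinstance(cond, AbruptCessationCondition):
        for i, med in enumerate(record.medications):
            if med.is_target_pah_drug and med.stopped_abruptly and (
                best is None or med.stop < best[0]
            ):
                best = (med.stop, [f"med:{i}"])
    else:
        raise TypeError(f"{rule.trigger_id} is not an event rule")
    if best is None:
        return None
    return TriggerHit(
        patient_id=record.patient_id,
        trigger_id=rule.trigger_id,
        evidence=best[1],
        first_satisfied_at=best[0],
    )


def evaluate_trigger(
    rule: TriggerRule,
    record: HospitalizationRecord,
    dictionary: DrugDictionary | None = None,
    vocabulary: SymptomVocabulary | None = None,
) -> Optional[TriggerHit]:
    cond = rule.condition
    if isinstance(cond, (ThresholdCondition, CompositeCondition, BaselineRatioCondition)):
        return evaluate_lab_trigger(rule, record)
    if isinstance(cond, ExposureCondition):
        return evaluate_exposure_trigger(rule, record, dictionary)
    return evaluate_event_trigger(rule, record, vocabulary)


def screen_cohort(
    records: list[HospitalizationRecord],
    ruleset: list[TriggerRule] | None = None,
    dictionary: DrugDictionary | None = None,
    vocabulary: SymptomVocabulary | None = None,
) -> ScreeningResult:
    """Evaluate every rule against every admission.

    Deterministic and order-independent; at most one hit per (patient,
    trigger); a patient is flagged iff at least one rule fires.
    """
    ruleset = ruleset if ruleset is not None else default_ruleset()
    dictionary = dictionary or default_drug_dictionary()
    vocabulary = vocabulary or default_symptom_vocabulary()
    hits: list[TriggerHit] = []
    flags: dict[str, bool] = {}
    for record in sorted(records, key=lambda r: r.patient_id):
        patient_hits = []
        for rule in ruleset:
            hit = evaluate_trigger(rule, record, dictionary, vocabulary)
            if hit is not None:
                patient_hits.append(hit)
        hits.extend(sorted(patient_hits, key=lambda h: h.trigger_id))
        flags[record.patient_id] = bool(patient_hits)
    return ScreeningResult(hits=hits, per_patient_flag=flags)
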