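"""Cohort data model: hospitalization records, controlled vocabularies, and I/O.

One cohort is five tabular streams keyed by ``patient_id``: patients, lab
observations, medication exposures, clinical events, and interventions.
Units are fixed per analyte; the reader rejects rows whose units column
disagrees rather than converting (silent unit conversion is the classic
pharmacovigilance bug). Dates are ISO-8601; length of stay counts calendar
days with a floor of one day, per the cohort's >=24 h inclusion criterion.
"""

from __future__ import annotations

import datetime as dt
import enum
import json
import re
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "Analyte",
    "ANALYTE_UNITS",
    "Sex",
    "InterventionKind",
    "LabObservation",
    "MedicationExposure",
    "ClinicalEvent",
    "InterventionEvent",
    "HospitalizationRecord",
    "DrugDictionary",
    "SymptomVocabulary",
    "CohortParseError",
    "ReferentialIntegrityError",
    "default_drug_dictionary",
    "default_symptom_vocabulary",
    "length_of_stay",
    "read_cohort",
    "write_cohort",
    "read_cohort_jsonl",
    "write_cohort_jsonl",
]

MIN_AGE_YEARS = 28.0 / 365.0  # inclusion: age > 28 days


class Sex(str, enum.Enum):
    male = "male"
    female = "female"


class Analyte(str, enum.Enum):
    eosinophils_abs = "eosinophils_abs"
    platelets = "platelets"
    leukocytes = "leukocytes"
    alt = "alt"
    ast = "ast"
    total_bilirubin = "total_bilirubin"
    alp = "alp"
    bun = "bun"
    creatinine = "creatinine"
    hemoglobin = "hemoglobin"
    sodium = "sodium"


#: Fixed unit per analyte; readers reject rows that disagree.
ANALYTE_UNITS: dict[Analyte, str] = {
    Analyte.eosinophils_abs: "10^9/L",
    Analyte.platelets: "10^9/L",
    Analyte.leukocytes: "10^9/L",
    Analyte.alt: "U/L",
    Analyte.ast: "U/L",
    Analyte.total_bilirubin: "umol/L",
    Analyte.alp: "U/L",
    Analyte.bun: "mmol/L",
    Analyte.creatinine: "umol/L",
    Analyte.hemoglobin: "g/L",
    Analyte.sodium: "mmol/L",
}


class InterventionKind(str, enum.Enum):
    icu_transfer = "icu_transfer"
    salvage = "salvage"


class CohortParseError(ValueError):
    """A cohort table row violates the documented schema."""


class ReferentialIntegrityError(CohortParseError):
    """A stream row references a patient_id absent from the patients table."""


class LabObservation(BaseModel):
    analyte: Analyte
    value: float = Field(ge=0)
    timestamp: dt.datetime

    @property
    def unit(self) -> str:
        return ANALYTE_UNITS[self.analyte]


class MedicationExposure(BaseModel):
    drug_name: str
    drug_class: str
    start: dt.datetime
    stop: dt.datetime
    is_target_pah_drug: bool = False
    stopped_abruptly: bool = False

    @model_validator(mode="after")
    def _check_span(self) -> "MedicationExposure":
        if self.start > self.stop:
            raise ValueError(f"medication {self.drug_name}: start after stop")
        if self.is_target_pah_drug and (self.stop - self.start) < dt.timedelta(hours=24):
            raise ValueError(
                f"target drug {self.drug_name}: exposure must be >=24 h (inclusion criterion)"
            )
        return self


class ClinicalEvent(BaseModel):
    """A coded symptom observation; terms live in the symptom vocabulary."""

    term: str
    timestamp: dt.datetime

    @field_validator("term")
    @classmethod
    def _normalize(cls, v: str) -> str:
        return _normalize_token(v)


class InterventionEvent(BaseModel):
    kind: InterventionKind
    timestamp: dt.datetime


class HospitalizationRecord(BaseModel):
    patient_id: str
    age_at_admission: float = Field(gt=MIN_AGE_YEARS)
    sex: Sex
    admission_date: dt.date
    discharge_date: dt.date
    n_comorbidities: int = Field(ge=0)
    n_prior_hospitalizations: int = Field(ge=1)  # current admission counts as 1
    target_drug_classes: frozenset[str]
    labs: list[LabObservation] = Field(default_factory=list)
    medications: list[MedicationExposure] = Field(default_factory=list)
    events: list[ClinicalEvent] = Field(default_factory=list)
    interventions: list[InterventionEvent] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check_invariants(self) -> "HospitalizationRecord":
        if self.discharge_date < self.admission_date:
            raise ValueError(
                f"{self.patient_id}: discharge {self.discharge_date} precedes "
                f"admission {self.admission_date}"
            )
        if not self.target_drug_classes:
            raise ValueError(f"{self.patient_id}: at least one targeted drug class required")
        for lab in self.labs:
            d = lab.timestamp.date()
            if not (self.admission_date <= d <= self.discharge_date):
                raise ValueError(
                    f"{self.patient_id}: lab {lab.analyte.value} at {lab.timestamp} "
                    "outside the stay"
                )
        return self


def length_of_stay(record: HospitalizationRecord) -> int:
    """Calendar days between admission and discharge, floored at 1.

    A same-day admission/discharge still counts one patient-day (stays are
    >=24 h by inclusion); this is the denominator unit of the
    per-1,000-patient-day ADE rate.
    """
    return max(1, (record.discharge_date - record.admission_date).days)


# ---------------------------------------------------------------------------
# Controlled vocabularies


def _normalize_token(name: str) -> str:
    """Lowercase, trim, collapse internal whitespace; spaces -> underscores."""
    return re.sub(r"\s+", "_", name.strip().lower())


class DrugDictionary:
    """Maps normalized drug names to drug-class identifiers.

    Every known name maps to exactly one class; unknown names resolve to
    ``"other"``, never to a trigger class. Target PAH drugs carry class ids
    prefixed ``pah_``.
    """

    OTHER = "other"

    def __init__(self, class_to_names: dict[str, list[str]]):
        self._name_to_class: dict[str, str] = {}
        for cls_id, names in class_to_names.items():
            for name in names:
                key = _normalize_token(name)
                prev = self._name_to_class.get(key)
                if prev is not None and prev != cls_id:
                    raise ValueError(f"drug {name!r} mapped to both {prev} and {cls_id}")
                self._name_to_class[key] = cls_id
        self._classes = sorted(class_to_names)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DrugDictionary":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(data["classes"])

    @property
    def classes(self) -> list[str]:
        return list(self._classes)

    @property
    def target_classes(self) -> list[str]:
        return [c for c in self._classes if self.is_target_class(c)]

    @staticmethod
    def is_target_class(cls_id: str) -> bool:
        return cls_id.startswith("pah_")

    def lookup(self, drug_name: str) -> str:
        return self._name_to_class.get(_normalize_token(drug_name), self.OTHER)

    def names_in_class(self, cls_id: str) -> list[str]:
        return sorted(n for n, c in self._name_to_class.items() if c == cls_id)


class SymptomVocabulary:
    """Flat list of canonical symptom codes with synonym aliases.

    Each code belongs to one symptom-trigger group (S1-S8 in the shipped
    file); aliases map free-text variants onto canonical codes.
    """

    def __init__(self, term_to_group: dict[str, str], aliases: dict[str, str] | None = None):
        self._term_to_group = {_normalize_token(t): g for t, g in term_to_group.items()}
        self._aliases = {}
        for alias, target in (aliases or {}).items():
            target_n = _normalize_token(target)
            if target_n not in self._term_to_group:
                raise ValueError(f"alias {alias!r} points to unknown term {target!r}")
            self._aliases[_normalize_token(alias)] = target_n

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SymptomVocabulary":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(data["terms"], data.get("aliases"))

    def normalize(self, term: str) -> Optional[str]:
        """Canonical code for a raw term, or None if unknown."""
        key = _normalize_token(term)
        if key in self._term_to_group:
            return key
        return self._aliases.get(key)

    def __contains__(self, term: str) -> bool:
        return self.normalize(term) is not None

    def group_of(self, term: str) -> Optional[str]:
        code = self.normalize(term)
        return None if code is None else self._term_to_group[code]

    def terms_in_group(self, group: str) -> list[str]:
        return sorted(t for t, g in self._term_to_group.items() if g == group)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("pahgtt").joinpath("data", name)))


@lru_cache(maxsize=1)
def default_drug_dictionary() -> DrugDictionary:
    return DrugDictionary.from_yaml(_data_path("drug_dictionary.yaml"))


@lru_cache(maxsize=1)
def default_symptom_vocabulary() -> SymptomVocabulary:
    return SymptomVocabulary.from_yaml(_data_path("symptom_vocabulary.yaml"))


# ---------------------------------------------------------------------------
# Cohort I/O (five CSV streams or one JSON-lines file)

PATIENT_COLUMNS = [
    "patient_id",
    "age_at_admission",
    "sex",
    "admission_date",
    "discharge_date",
    "n_comorbidities",
    "n_prior_hospitalizations",
    "target_drug_classes",
]
LAB_COLUMNS = ["patient_id", "analyte", "value", "unit", "timestamp"]
MEDICATION_COLUMNS = [
    "patient_id",
    "drug_name",
    "drug_class",
    "start",
    "stop",
    "is_target_pah_drug",
    "stopped_abruptly",
]
EVENT_COLUMNS = ["patient_id", "term", "timestamp"]
INTERVENTION_COLUMNS = ["patient_id", "kind", "timestamp"]

_STREAM_FILES = {
    "patients": "patients.csv",
    "labs": "labs.csv",
    "medications": "medications.csv",
    "events": "events.csv",
    "interventions": "interventions.csv",
}


def _read_stream(directory: Path, stream: str, columns: list[str]) -> pd.DataFrame:
    path = directory / _STREAM_FILES[stream]
    if not path.exists():
        raise CohortParseError(f"missing cohort file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise CohortParseError(f"{path}: missing columns {missing}")
    return df


def _row_err(fname: str, idx: int, field: str, msg: str) -> CohortParseError:
    return CohortParseError(f"{fname} row {idx} field {field!r}: {msg}")


def read_cohort(
    directory: str | Path,
    vocabulary: SymptomVocabulary | None = None,
) -> list[HospitalizationRecord]:
    """Read and validate a cohort from its five CSV streams.

    Raises :class:`CohortParseError` naming file/row/field on schema
    violations, and :class:`ReferentialIntegrityError` for stream rows whose
    patient_id is absent from patients.csv. Event terms are normalized
    against the symptom vocabulary (shipped default unless given); unknown
    terms are rejected.
    """
    directory = Path(directory)
    vocab = vocabulary or default_symptom_vocabulary()

    patients = _read_stream(directory, "patients", PATIENT_COLUMNS)
    labs = _read_stream(directory, "labs", LAB_COLUMNS)
    meds = _read_stream(directory, "medications", MEDICATION_COLUMNS)
    events = _read_stream(directory, "events", EVENT_COLUMNS)
    interventions = _read_stream(directory, "interventions", INTERVENTION_COLUMNS)

    known_ids = set(patients["patient_id"])
    streams: dict[str, dict[str, list]] = {
        s: {pid: [] for pid in known_ids} for s in ("labs", "medications", "events", "interventions")
    }

    for idx, row in labs.iterrows():
        pid = row["patient_id"]
        if pid not in known_ids:
            raise ReferentialIntegrityError(
                f"labs.csv row {idx}: patient_id {pid!r} not in patients.csv"
            )
        try:
            analyte = Analyte(row["analyte"])
        except ValueError:
            raise _row_err("labs.csv", idx, "analyte", f"unknown analyte {row['analyte']!r}")
        expected_unit = ANALYTE_UNITS[analyte]
        if row["unit"] != expected_unit:
            raise _row_err(
                "labs.csv", idx, "unit",
                f"{row['unit']!r} disagrees with fixed unit {expected_unit!r} "
                f"for {analyte.value} (no silent conversion)",
            )
        try:
            obs = LabObservation(
                analyte=analyte,
                value=float(row["value"]),
                timestamp=dt.datetime.fromisoformat(row["timestamp"]),
            )
        except (ValueError, TypeError) as exc:
            raise _row_err("labs.csv", idx, "value/timestamp", str(exc))
        streams["labs"][pid].append(obs)

    for idx, row in meds.iterrows():
        pid = row["patient_id"]
        if pid not in known_ids:
            raise ReferentialIntegrityError(
                f"medications.csv row {idx}: patient_id {pid!r} not in patients.csv"
            )
        try:
            exp = MedicationExposure(
                drug_name=row["drug_name"],
                drug_class=row["drug_class"],
                start=dt.datetime.fromisoformat(row["start"]),
                stop=dt.datetime.fromisoformat(row["stop"]),
                is_target_pah_drug=_parse_bool(row["is_target_pah_drug"]),
                stopped_abruptly=_parse_bool(row["stopped_abruptly"]),
            )
        except (ValueError, TypeError) as exc:
            raise _row_err("medications.csv", idx, "span/flags", str(exc))
        streams["medications"][pid].append(exp)

    for idx, row in events.iterrows():
        pid = row["patient_id"]
        if pid not in known_ids:
            raise ReferentialIntegrityError(
                f"events.csv row {idx}: patient_id {pid!r} not in patients.csv"
            )
        code = vocab.normalize(row["term"])
        if code is None:
            raise _row_err("events.csv", idx, "term", f"{row['term']!r} not in symptom vocabulary")
        streams["events"][pid].append(
            ClinicalEvent(term=code, timestamp=dt.datetime.fromisoformat(row["timestamp"]))
        )

    for idx, row in interventions.iterrows():
        pid = row["patient_id"]
        if pid not in known_ids:
            raise ReferentialIntegrityError(
                f"interventions.csv row {idx}: patient_id {pid!r} not in patients.csv"
            )
        try:
            kind = InterventionKind(row["kind"])
        except ValueError:
            raise _row_err("interventions.csv", idx, "kind", f"unknown kind {row['kind']!r}")
        streams["interventions"][pid].append(
            InterventionEvent(kind=kind, timestamp=dt.datetime.fromisoformat(row["timestamp"]))
        )

    records = []
    for idx, row in patients.iterrows():
        pid = row["patient_id"]
        try:
            rec = HospitalizationRecord(
                patient_id=pid,
                age_at_admission=float(row["age_at_admission"]),
                sex=Sex(row["sex"]),
                admission_date=dt.date.fromisoformat(row["admission_date"]),
                discharge_date=dt.date.fromisoformat(row["discharge_date"]),
                n_comorbidities=int(row["n_comorbidities"]),
                n_prior_hospitalizations=int(row["n_prior_hospitalizations"]),
                target_drug_classes=frozenset(
                    t for t in row["target_drug_classes"].split(";") if t
                ),
                labs=sorted(streams["labs"][pid], key=lambda o: o.timestamp),
                medications=sorted(streams["medications"][pid], key=lambda m: m.start),
                events=sorted(streams["events"][pid], key=lambda e: e.timestamp),
                interventions=sorted(streams["interventions"][pid], key=lambda i: i.timestamp),
            )
        except (ValueError, TypeError) as exc:
            raise _row_err("patients.csv", idx, "record", str(exc))
        records.append(rec)
    records.sort(key=lambda r: r.patient_id)
    return records


def _parse_bool(raw: str) -> bool:
    val = str(raw).strip().lower()
    if val in ("true", "1", "yes"):
        return True
    if val in ("false", "0", "no", ""):
        return False
    raise ValueError(f"not a boolean: {raw!r}")


def write_cohort(records: Iterable[HospitalizationRecord], directory: str | Path) -> None:
    """Write the five CSV streams with stable column order; lossless round-trip."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    prow, lrow, mrow, erow, irow = [], [], [], [], []
    for rec in sorted(records, key=lambda r: r.patient_id):
        prow.append(
            {
                "patient_id": rec.patient_id,
                "age_at_admission": repr(rec.age_at_admission),
                "sex": rec.sex.value,
                "admission_date": rec.admission_date.isoformat(),
                "discharge_date": rec.discharge_date.isoformat(),
                "n_comorbidities": rec.n_comorbidities,
                "n_prior_hospitalizations": rec.n_prior_hospitalizations,
                "target_drug_classes": ";".join(sorted(rec.target_drug_classes)),
            }
        )
        for lab in rec.labs:
            lrow.append(
                {
                    "patient_id": rec.patient_id,
                    "analyte": lab.analyte.value,
                    "value": repr(lab.value),
                    "unit": lab.unit,
                    "timestamp": lab.timestamp.isoformat(),
                }
            )
        for med in rec.medications:
            mrow.append(
                {
                    "patient_id": rec.patient_id,
                    "drug_name": med.drug_name,
                    "drug_class": med.drug_class,
                    "start": med.start.isoformat(),
                    "stop": med.stop.isoformat(),
                    "is_target_pah_drug": med.is_target_pah_drug,
                    "stopped_abruptly": med.stopped_abruptly,
                }
            )
        for ev in rec.events:
            erow.append(
                {"patient_id": rec.patient_id, "term": ev.term, "timestamp": ev.timestamp.isoformat()}
            )
        for iv in rec.interventions:
            irow.append(
                {
                    "patient_id": rec.patient_id,
                    "kind": iv.kind.value,
                    "timestamp": iv.timestamp.isoformat(),
                }
            )
    for rows, columns, stream in (
        (prow, PATIENT_COLUMNS, "patients"),
        (lrow, LAB_COLUMNS, "labs"),
        (mrow, MEDICATION_COLUMNS, "medications"),
        (erow, EVENT_COLUMNS, "events"),
        (irow, INTERVENTION_COLUMNS, "interventions"),
    ):
        pd.DataFrame(rows, columns=columns).to_csv(directory / _STREAM_FILES[stream], index=False)


def write_cohort_jsonl(records: Iterable[HospitalizationRecord], path: str | Path) -> None:
    """One JSON object per record, nested streams inline."""
    with open(path, "w") as fh:
        for rec in sorted(records, key=lambda r: r.patient_id):
            payload = rec.model_dump(mode="json")
            payload["target_drug_classes"] = sorted(rec.target_drug_classes)
            fh.write(json.dumps(payload) + "\n")


def read_cohort_jsonl(path: str | Path) -> list[HospitalizationRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                records.append(HospitalizationRecord.model_validate(json.loads(line)))
    records.sort(key=lambda r: r.patient_id)
    return records
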