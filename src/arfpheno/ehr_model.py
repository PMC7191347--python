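"""Domain types and CSV readers/writers for eICU-style relational tables.

The phenotyping pipeline consumes five relational tables keyed by an ICU-stay
identifier, with all clinical timestamps expressed as integer minute offsets
from ICU admission (negative values denote pre-admission events):

* ``patient.csv``        — one row per ICU stay (demographics, severity, outcome)
* ``treatment.csv``      — hierarchical treatment-path strings
* ``medication.csv``     — drug administration rows (peri-intubation corroboration)
* ``nurse_charting.csv`` — structured nurse-chart rows; the oxygen-device rows
  carry a free-text device-detail field used for high-flow detection
* ``resp_charting.csv``  — respiratory-therapy chart rows

Readers validate rows against the type invariants below and collect row-level
diagnostics instead of silently coercing; ``read_tables(write_tables(x)) == x``
holds for all valid tables.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Source",
    "Modality",
    "PhenotypeCode",
    "ExclusionReason",
    "PatientStay",
    "VentRecord",
    "VentEvent",
    "PhenotypeLabel",
    "RowIssue",
    "EHRTables",
    "TableValidationError",
    "AGE_CENSOR_SENTINEL",
    "AGE_CENSOR_TOKEN",
    "read_tables",
    "write_tables",
]

#: Numeric stand-in for ages recorded with the censoring token "> 89".
#: 90 preserves the adult (>=18) inclusion filter and median arithmetic
#: without inventing an age distribution above the censoring point.
AGE_CENSOR_SENTINEL = 90
AGE_CENSOR_TOKEN = "> 89"


class Source(str, enum.Enum):
    """Table of origin of a ventilation-related record."""

    TREATMENT = "TREATMENT"
    MEDICATION = "MEDICATION"
    NURSE_CHART = "NURSE_CHART"
    RESP_CHART = "RESP_CHART"


class Modality(str, enum.Enum):
    """Ventilatory-support modality attributed to a single record.

    ``LOW_FLOW`` (supplemental oxygen below 15 L/min) never qualifies a stay
    for the cohort; ``NONE`` marks records unrelated to ventilation.
    """

    INVASIVE = "INVASIVE"
    NIPPV = "NIPPV"
    HFNI = "HFNI"
    LOW_FLOW = "LOW_FLOW"
    NONE = "NONE"


#: Modalities that qualify a stay for cohort inclusion.
VENT_MODALITIES = frozenset({Modality.INVASIVE, Modality.NIPPV, Modality.HFNI})

#: Noninvasive-ventilation family (pressure- or flow-based support).
NIV_MODALITIES = frozenset({Modality.NIPPV, Modality.HFNI})


class PhenotypeCode(str, enum.Enum):
    """The seven ventilation-therapy phenotypes plus the exclusion bucket."""

    P0_INVASIVE = "P0_INVASIVE"
    P1_NIPPV = "P1_NIPPV"
    P2_HFNI = "P2_HFNI"
    P3_NIPPV_FAILURE = "P3_NIPPV_FAILURE"
    P4_HFNI_FAILURE = "P4_HFNI_FAILURE"
    P5_INVASIVE_TO_NIPPV = "P5_INVASIVE_TO_NIPPV"
    P6_INVASIVE_TO_HFNI = "P6_INVASIVE_TO_HFNI"
    EXCLUDED = "EXCLUDED"


#: The included phenotypes, in decision-tree order.
PHENOTYPES: tuple[PhenotypeCode, ...] = tuple(
    c for c in PhenotypeCode if c is not PhenotypeCode.EXCLUDED
)


class ExclusionReason(str, enum.Enum):
    MINOR = "MINOR"
    READMISSION = "READMISSION"
    LOW_FLOW_ONLY = "LOW_FLOW_ONLY"
    NO_VENT_RECORDS = "NO_VENT_RECORDS"
    NO_TIMESTAMPS = "NO_TIMESTAMPS"
    SINGLE_RECORD_ONLY = "SINGLE_RECORD_ONLY"
    HFNI_WITHOUT_NIV = "HFNI_WITHOUT_NIV"
    UNCORROBORATED = "UNCORROBORATED"


@dataclass(frozen=True)
class PatientStay:
    """One ICU stay with the demographics the summary tables report."""

    patient_id: str
    stay_id: str
    unit_visit_number: int
    age_years: int
    gender: str
    ethnicity: str
    admission_diagnosis: str
    apache_score: int | None
    icu_los_days: float
    hospital_mortality: bool
    censored_age: bool = False

    def __post_init__(self) -> None:
        if self.unit_visit_number < 1:
            raise ValueError(f"unit_visit_number must be >= 1, got {self.unit_visit_number}")
        if self.age_years < 0:
            raise ValueError(f"age_years must be >= 0, got {self.age_years}")
        if self.icu_los_days < 0:
            raise ValueError(f"icu_los_days must be >= 0, got {self.icu_los_days}")


@dataclass(frozen=True)
class VentRecord:
    """One raw timestamped record suggesting a ventilation modality.

    ``offset_min`` is ``None`` when the source row carried no timestamp; such
    records cannot contribute to event sequencing and, if a stay has no
    timestamped ventilation records at all, trigger the NO_TIMESTAMPS
    exclusion downstream.
    """

    stay_id: str
    source: Source
    raw_term: str
    offset_min: int | None
    offset_end_min: int | None = None

    def __post_init__(self) -> None:
        if not self.raw_term:
            raise ValueError("raw_term must be non-empty")
        if (
            self.offset_end_min is not None
            and self.offset_min is not None
            and self.offset_end_min < self.offset_min
        ):
            raise ValueError("offset_end_min must be >= offset_min")


@dataclass
class VentEvent:
    """A consolidated per-stay, per-modality event.

    ``sources`` records which tables contributed, so corroboration rules can
    distinguish treatment-record evidence from nurse-chart evidence.
    """

    stay_id: str
    modality: Modality
    first_offset_min: int
    last_offset_min: int
    n_records: int
    corroborated: bool = False
    sources: frozenset[Source] = frozenset()

    def __post_init__(self) -> None:
        if self.first_offset_min > self.last_offset_min:
            raise ValueError("first_offset_min must be <= last_offset_min")
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")


@dataclass(frozen=True)
class PhenotypeLabel:
    stay_id: str
    code: PhenotypeCode
    exclusion_reason: ExclusionReason | None = None

    def __post_init__(self) -> None:
        if (self.code is PhenotypeCode.EXCLUDED) != (self.exclusion_reason is not None):
            raise ValueError("exclusion_reason present iff code is EXCLUDED")


@dataclass(frozen=True)
class RowIssue:
    """Row-level diagnostic raised while reading a table."""

    table: str
    row: int  # 0-based data-row index (header excluded)
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.table}[row {self.row}]: {self.message}"


class TableValidationError(ValueError):
    def __init__(self, issues: Sequence[RowIssue]):
        self.issues = list(issues)
        super().__init__("; ".join(str(i) for i in self.issues))


# ---------------------------------------------------------------------------
# table schemas
# ---------------------------------------------------------------------------

#: External CSV headers, in the order they are written.
CSV_COLUMNS: Mapping[str, tuple[str, ...]] = {
    "patient": (
        "patient_id",
        "stay_id",
        "unit_visit_number",
        "age",
        "gender",
        "ethnicity",
        "admission_diagnosis",
        "apache_score",
        "icu_los_days",
        "hospital_mortality",
    ),
    "treatment": ("stay_id", "treatment_string", "offset_min"),
    "medication": ("stay_id", "drug_name", "offset_min"),
    "nurse_charting": ("stay_id", "chart_category", "chart_value", "offset_min"),
    "resp_charting": ("stay_id", "chart_string", "offset_min"),
}

TABLE_FILES: Mapping[str, str] = {name: f"{name}.csv" for name in CSV_COLUMNS}

_RECORD_TERM_COLUMN = {
    "treatment": "treatment_string",
    "medication": "drug_name",
    "nurse_charting": "chart_value",
    "resp_charting": "chart_string",
}

_RECORD_SOURCE = {
    "treatment": Source.TREATMENT,
    "medication": Source.MEDICATION,
    "nurse_charting": Source.NURSE_CHART,
    "resp_charting": Source.RESP_CHART,
}


@dataclass
class EHRTables:
    """In-memory, validated form of the five relational tables.

    ``patient`` uses the internal columns ``age_years`` (int) and
    ``censored_age`` (bool) in place of the external free-form ``age`` column;
    record tables carry ``offset_min`` as nullable Int64.
    """

    patient: pd.DataFrame
    treatment: pd.DataFrame
    medication: pd.DataFrame
    nurse_charting: pd.DataFrame
    resp_charting: pd.DataFrame
    issues: list[RowIssue] = field(default_factory=list)

    def record_tables(self) -> dict[str, pd.DataFrame]:
        return {
            "treatment": self.treatment,
            "medication": self.medication,
            "nurse_charting": self.nurse_charting,
            "resp_charting": self.resp_charting,
        }

    def stays(self) -> list[PatientStay]:
        """Materialize the patient table as :class:`PatientStay` objects."""
        out = []
        for row in self.patient.itertuples(index=False):
            apache = None if pd.isna(row.apache_score) else int(row.apache_score)
            out.append(
                PatientStay(
                    patient_id=row.patient_id,
                    stay_id=row.stay_id,
                    unit_visit_number=int(row.unit_visit_number),
                    age_years=int(row.age_years),
                    gender=row.gender,
                    ethnicity=row.ethnicity,
                    admission_diagnosis=row.admission_diagnosis,
                    apache_score=apache,
                    icu_los_days=float(row.icu_los_days),
                    hospital_mortality=bool(row.hospital_mortality),
                    censored_age=bool(row.censored_age),
                )
            )
        return out

    def vent_source_records(self) -> list[VentRecord]:
        """Raw records from the tables that can evidence a ventilation modality.

        Medication rows are deliberately not included: they corroborate
        invasive ventilation but never define an event on their own.
        """
        records: list[VentRecord] = []
        for name in ("treatment", "nurse_charting", "resp_charting"):
            df = self.record_tables()[name]
            term_col = _RECORD_TERM_COLUMN[name]
            for row in df.itertuples(index=False):
                term = getattr(row, term_col)
                if not term:
                    continue
                offset = None if pd.isna(row.offset_min) else int(row.offset_min)
                records.append(
                    VentRecord(
                        stay_id=row.stay_id,
                        source=_RECORD_SOURCE[name],
                        raw_term=term,
                        offset_min=offset,
                    )
                )
        return records


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------


def _parse_offset(value: str, table: str, row: int, issues: list[RowIssue]):
    """Parse a minute offset; blank -> missing, fractional -> truncated."""
    text = value.strip()
    if text == "":
        return pd.NA, True
    try:
        return int(text), True
    except ValueError:
        pass
    try:
        f = float(text)
    except ValueError:
        issues.append(RowIssue(table, row, f"unparsable offset {value!r}"))
        return pd.NA, False
    truncated = int(f)  # toward zero: offsets are integral minutes
    issues.append(
        RowIssue(table, row, f"fractional offset {value!r} truncated to {truncated}")
    )
    return truncated, True


def _parse_bool(value: str) -> bool | None:
    v = value.strip().lower()
    if v in {"true", "1", "yes", "t", "y"}:
        return True
    if v in {"false", "0", "no", "f", "n"}:
        return False
    return None


def _parse_age(value: str):
    """Return (age_years, censored) or None if unparsable."""
    text = value.strip()
    if text.replace(" ", "") == AGE_CENSOR_TOKEN.replace(" ", ""):
        return AGE_CENSOR_SENTINEL, True
    try:
        age = int(text)
    except ValueError:
        return None
    if age < 0:
        return None
    return age, False


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def _require_columns(df: pd.DataFrame, table: str, required: Iterable[str]) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableValidationError(
            [RowIssue(table, -1, f"missing required column(s): {', '.join(missing)}")]
        )


def _empty_patient() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": pd.Series(dtype=str),
            "stay_id": pd.Series(dtype=str),
            "unit_visit_number": pd.Series(dtype="int64"),
            "age_years": pd.Series(dtype="int64"),
            "censored_age": pd.Series(dtype=bool),
            "gender": pd.Series(dtype=str),
            "ethnicity": pd.Series(dtype=str),
            "admission_diagnosis": pd.Series(dtype=str),
            "apache_score": pd.Series(dtype="Int64"),
            "icu_los_days": pd.Series(dtype="float64"),
            "hospital_mortality": pd.Series(dtype=bool),
        }
    )


def _empty_record_table(name: str) -> pd.DataFrame:
    cols: dict[str, pd.Series] = {}
    for col in CSV_COLUMNS[name]:
        if col == "offset_min":
            cols[col] = pd.Series(dtype="Int64")
        else:
            cols[col] = pd.Series(dtype=str)
    return pd.DataFrame(cols)


def _parse_patient(df: pd.DataFrame, issues: list[RowIssue]) -> pd.DataFrame:
    rows = []
    seen_stays: set[str] = set()
    for i, row in enumerate(df.to_dict("records")):
        ok = True
        stay_id = row["stay_id"].strip()
        if not stay_id:
            issues.append(RowIssue("patient", i, "empty stay_id"))
            continue
        if stay_id in seen_stays:
            issues.append(RowIssue("patient", i, f"duplicate stay_id {stay_id!r}"))
            continue

        parsed_age = _parse_age(row["age"])
        if parsed_age is None:
            issues.append(RowIssue("patient", i, f"unparsable age {row['age']!r}"))
            ok = False
        try:
            visit = int(row["unit_visit_number"])
            if visit < 1:
                raise ValueError
        except ValueError:
            issues.append(
                RowIssue("patient", i, f"invalid unit_visit_number {row['unit_visit_number']!r}")
            )
            ok = False
        apache_text = row["apache_score"].strip()
        apache: object = pd.NA
        if apache_text:
            try:
                apache = int(apache_text)
                if apache < 0:
                    raise ValueError
            except ValueError:
                issues.append(
                    RowIssue("patient", i, f"invalid apache_score {apache_text!r}")
                )
                ok = False
        try:
            los = float(row["icu_los_days"])
            if los < 0 or not np.isfinite(los):
                raise ValueError
        except ValueError:
            issues.append(
                RowIssue("patient", i, f"invalid icu_los_days {row['icu_los_days']!r}")
            )
            ok = False
        mortality = _parse_bool(row["hospital_mortality"])
        if mortality is None:
            issues.append(
                RowIssue(
                    "patient", i, f"invalid hospital_mortality {row['hospital_mortality']!r}"
                )
            )
            ok = False
        if not ok:
            continue
        age_years, censored = parsed_age  # type: ignore[misc]
        seen_stays.add(stay_id)
        rows.append(
            {
                "patient_id": row["patient_id"].strip(),
                "stay_id": stay_id,
                "unit_visit_number": visit,
                "age_years": age_years,
                "censored_age": censored,
                "gender": row["gender"],
                "ethnicity": row["ethnicity"],
                "admission_diagnosis": row["admission_diagnosis"],
                "apache_score": apache,
                "icu_los_days": los,
                "hospital_mortality": mortality,
            }
        )
    if not rows:
        return _empty_patient()
    out = pd.DataFrame(rows)
    out["apache_score"] = out["apache_score"].astype("Int64")
    return out.astype(
        {
            "unit_visit_number": "int64",
            "age_years": "int64",
            "censored_age": bool,
            "icu_los_days": "float64",
            "hospital_mortality": bool,
        }
    )


def _parse_record_table(name: str, df: pd.DataFrame, issues: list[RowIssue]) -> pd.DataFrame:
    term_col = _RECORD_TERM_COLUMN[name]
    rows = []
    for i, row in enumerate(df.to_dict("records")):
        stay_id = row["stay_id"].strip()
        if not stay_id:
            issues.append(RowIssue(name, i, "empty stay_id"))
            continue
        if not row[term_col]:
            issues.append(RowIssue(name, i, f"empty {term_col}"))
            continue
        offset, ok = _parse_offset(row["offset_min"], name, i, issues)
        if not ok:
            continue
        parsed = {col: row[col] for col in CSV_COLUMNS[name] if col != "offset_min"}
        parsed["stay_id"] = stay_id
        parsed["offset_min"] = offset
        rows.append(parsed)
    if not rows:
        return _empty_record_table(name)
    out = pd.DataFrame(rows, columns=list(CSV_COLUMNS[name]))
    out["offset_min"] = out["offset_min"].astype("Int64")
    return out


# ---------------------------------------------------------------------------
# public readers / writers
# ---------------------------------------------------------------------------


def read_tables(directory_path: str | Path, errors: str = "skip") -> EHRTables:
    """Read and validate the five CSV tables from *directory_path*.

    Parameters
    ----------
    directory_path
        Directory containing patient.csv, treatment.csv, medication.csv,
        nurse_charting.csv and resp_charting.csv.
    errors
        ``"skip"`` (default) drops invalid rows and collects them in
        ``EHRTables.issues``; ``"raise"`` raises :class:`TableValidationError`
        if any row is invalid.

    Raises
    ------
    FileNotFoundError
        If any required table file is absent (always fatal).
    TableValidationError
        Under ``errors="raise"``, or when a required column is missing.
    """
    if errors not in {"skip", "raise"}:
        raise ValueError(f"errors must be 'skip' or 'raise', got {errors!r}")
    directory = Path(directory_path)
    raw: dict[str, pd.DataFrame] = {}
    for name, filename in TABLE_FILES.items():
        path = directory / filename
        if not path.exists():
            raise FileNotFoundError(f"required table file not found: {path}")
        df = _read_csv(path)
        _require_columns(df, name, CSV_COLUMNS[name])
        raw[name] = df

    issues: list[RowIssue] = []
    patient = _parse_patient(raw["patient"], issues)
    record_tables = {
        name: _parse_record_table(name, raw[name], issues)
        for name in ("treatment", "medication", "nurse_charting", "resp_charting")
    }
    # fractional-offset truncations are warnings, not rejections
    rejections = [i for i in issues if "truncated" not in i.message]
    if errors == "raise" and rejections:
        raise TableValidationError(rejections)
    return EHRTables(patient=patient, issues=issues, **record_tables)


def write_tables(tables: EHRTables, directory_path: str | Path) -> Path:
    """Write *tables* back to the external CSV layout; inverse of read_tables.

    Censored ages are rendered with the ``"> 89"`` token, missing APACHE
    scores and offsets as empty fields.
    """
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)

    patient = tables.patient.copy()
    age = patient["age_years"].astype(object).astype(str)
    age[patient["censored_age"].astype(bool)] = AGE_CENSOR_TOKEN
    patient["age"] = age
    patient["apache_score"] = patient["apache_score"].astype(object).where(
        patient["apache_score"].notna(), ""
    )
    patient["hospital_mortality"] = patient["hospital_mortality"].map(
        {True: "True", False: "False"}
    )
    patient = patient[list(CSV_COLUMNS["patient"])]
    patient.to_csv(directory / TABLE_FILES["patient"], index=False)

    for name, df in tables.record_tables().items():
        out = df.copy()
        out["offset_min"] = out["offset_min"].astype(object).where(
            out["offset_min"].notna(), ""
        )
        out = out[list(CSV_COLUMNS[name])]
        out.to_csv(directory / TABLE_FILES[name], index=False)
    return directory


def tables_equal(a: EHRTables, b: EHRTables) -> bool:
    """Value equality of two table sets (ignores row-issue logs)."""
    try:
        pd.testing.assert_frame_equal(
            a.patient.reset_index(drop=True), b.patient.reset_index(drop=True)
        )
        for name in a.record_tables():
            pd.testing.assert_frame_equal(
                a.record_tables()[name].reset_index(drop=True),
                b.record_tables()[name].reset_index(drop=True),
            )
    except AssertionError:
        return False
    return True
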