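"""Synthetic tele-ICU cohort generator with known ground-truth phenotypes.

The real tele-ICU database behind this algorithm is access-controlled, so
the generator emits the same five-table relational schema with a record
stream per stay that realizes a requested phenotype by construction:

* P0 — repeated invasive treatment rows plus peri-intubation medications;
* P1 — repeated NIPPV treatment rows;
* P2 — repeated NIV-family treatment rows plus repeated nurse-chart
  oxygen-device rows spelling a high-flow variant;
* P3/P4 — the noninvasive block strictly before the invasive block;
* P5/P6 — the invasive block strictly before the noninvasive block.

Demographics are sampled to match configurable per-phenotype median/IQR
targets (truncated normal for age and APACHE, log-normal for ICU length of
stay) whose defaults are the published cohort's summary statistics.
A configurable fraction of stays (default 7.4%) starts ventilation before
ICU admission, i.e. with negative minute offsets.

Optional noise processes reproduce the charting-error modes seen in real
data: a single spurious record of a therapy the patient never received,
continued recording of the prior therapy after a switch, missing
corroborating medications, and extra NIV->invasive->NIV repeat sequences.
All randomness flows from one seed; a fixed seed gives byte-identical
output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .ehr_model import (
    AGE_CENSOR_SENTINEL,
    EHRTables,
    ExclusionReason,
    PhenotypeCode,
    PhenotypeLabel,
    PHENOTYPES,
    write_tables,
)

__all__ = [
    "DemographicTarget",
    "NoiseConfig",
    "GeneratorConfig",
    "DEFAULT_DEMOGRAPHICS",
    "DEFAULT_N_PER_PHENOTYPE",
    "generate_cohort",
    "truth_table",
    "read_truth",
]


@dataclass(frozen=True)
class DemographicTarget:
    """Per-phenotype marginal targets: (median, IQR) and proportions."""

    age: tuple[float, float]
    apache: tuple[float, float]
    los_days: tuple[float, float]
    mortality: float
    male: float
    # White, African American, Hispanic, Asian, Native American, Other/Unknown
    ethnicity: tuple[float, float, float, float, float, float]


ETHNICITIES = (
    "White",
    "African American",
    "Hispanic",
    "Asian",
    "Native American",
    "Other/Unknown",
)

#: Published per-phenotype summary statistics used as default targets.
DEFAULT_DEMOGRAPHICS: Mapping[PhenotypeCode, DemographicTarget] = {
    PhenotypeCode.P0_INVASIVE: DemographicTarget(
        age=(63.0, 21), apache=(69, 41), los_days=(3.23, 4.56),
        mortality=0.2083, male=0.5887,
        ethnicity=(78.74, 10.85, 3.28, 1.19, 0.92, 5.01),
    ),
    PhenotypeCode.P1_NIPPV: DemographicTarget(
        age=(70.0, 20), apache=(57, 29), los_days=(2.23, 3.07),
        mortality=0.1768, male=0.5014,
        ethnicity=(82.04, 11.30, 2.10, 1.20, 0.42, 2.94),
    ),
    PhenotypeCode.P2_HFNI: DemographicTarget(
        age=(72.0, 22), apache=(56, 28), los_days=(2.43, 2.59),
        mortality=0.1023, male=0.4983,
        ethnicity=(72.07, 8.97, 11.63, 0.86, 0.43, 6.03),
    ),
    PhenotypeCode.P3_NIPPV_FAILURE: DemographicTarget(
        age=(65.0, 22), apache=(75, 38), los_days=(7.48, 9.31),
        mortality=0.3405, male=0.5550,
        ethnicity=(78.69, 10.75, 4.02, 1.01, 0.88, 4.65),
    ),
    PhenotypeCode.P4_HFNI_FAILURE: DemographicTarget(
        age=(65.0, 23), apache=(72, 39), los_days=(6.68, 9.10),
        mortality=0.1682, male=0.5456,
        ethnicity=(68.36, 6.84, 16.69, 1.43, 0.32, 6.36),
    ),
    PhenotypeCode.P5_INVASIVE_TO_NIPPV: DemographicTarget(
        age=(66.0, 20), apache=(75, 39), los_days=(5.42, 6.28),
        mortality=0.2080, male=0.5439,
        ethnicity=(83.74, 6.50, 3.87, 0.31, 1.70, 3.87),
    ),
    PhenotypeCode.P6_INVASIVE_TO_HFNI: DemographicTarget(
        age=(67.5, 21), apache=(72, 35.5), los_days=(4.93, 5.04),
        mortality=0.1011, male=0.5745,
        ethnicity=(60.96, 5.35, 22.99, 1.10, 1.10, 8.56),
    ),
}

#: Published cohort sizes scaled down by 100 (minimum 2 per phenotype).
DEFAULT_N_PER_PHENOTYPE: Mapping[PhenotypeCode, int] = {
    PhenotypeCode.P0_INVASIVE: 168,
    PhenotypeCode.P1_NIPPV: 67,
    PhenotypeCode.P2_HFNI: 12,
    PhenotypeCode.P3_NIPPV_FAILURE: 16,
    PhenotypeCode.P4_HFNI_FAILURE: 6,
    PhenotypeCode.P5_INVASIVE_TO_NIPPV: 6,
    PhenotypeCode.P6_INVASIVE_TO_HFNI: 2,
}

DIAGNOSES = (
    "Sepsis, pulmonary",
    "CHF, congestive heart failure",
    "CABG alone, coronary artery bypass grafting",
    "Pneumonia, bacterial",
    "Emphysema/bronchitis (COPD exacerbation)",
    "Cardiac arrest (with or without respiratory arrest)",
)

#: Hierarchical treatment-path strings, as exported by tele-ICU systems.
INVASIVE_TREATMENT = (
    "pulmonary|ventilation and oxygenation|mechanical ventilation|intubation/ETT"
)
NIPPV_TREATMENT = (
    "pulmonary|ventilation and oxygenation|non-invasive ventilation|face mask"
)
NIV_TREATMENT = "pulmonary|ventilation and oxygenation|non-invasive ventilation"
LOW_FLOW_TREATMENT = (
    "pulmonary|ventilation and oxygenation|oxygen therapy (< 40%)|nasal cannula"
)
RESP_INVASIVE_VALUE = "Intubated/oral ETT"
OXYGEN_DEVICE_CATEGORY = "O2 Admin Device"
HFNI_CANONICAL = "high-flow nasal insufflation"
HFNI_VARIANTS = (
    "HFNC",
    "highflow n/c",
    "optiflow",
    "Optiflow 50L",
    "airvo",
    "Vapotherm",
    "high flow nasal cannula",
    "HiFlow n/c",
    "nc 40 lpm",
    "heated high flow",
)
LOW_FLOW_CHART_VALUE = "nasal cannula 2L"

PERI_INTUBATION_DRUGS = (
    "etomidate",
    "ketamine",
    "propofol",
    "succinylcholine",
    "rocuronium",
    "vecuronium",
    "cisatracurium",
    "midazolam infusion",
    "fentanyl infusion",
    "dexmedetomidine",
)

_NIV_PHENOTYPES = frozenset(
    {
        PhenotypeCode.P1_NIPPV,
        PhenotypeCode.P2_HFNI,
        PhenotypeCode.P3_NIPPV_FAILURE,
        PhenotypeCode.P4_HFNI_FAILURE,
        PhenotypeCode.P5_INVASIVE_TO_NIPPV,
        PhenotypeCode.P6_INVASIVE_TO_HFNI,
    }
)
_HFNI_PHENOTYPES = frozenset(
    {
        PhenotypeCode.P2_HFNI,
        PhenotypeCode.P4_HFNI_FAILURE,
        PhenotypeCode.P6_INVASIVE_TO_HFNI,
    }
)
_INVASIVE_PHENOTYPES = frozenset(
    {
        PhenotypeCode.P0_INVASIVE,
        PhenotypeCode.P3_NIPPV_FAILURE,
        PhenotypeCode.P4_HFNI_FAILURE,
        PhenotypeCode.P5_INVASIVE_TO_NIPPV,
        PhenotypeCode.P6_INVASIVE_TO_HFNI,
    }
)


@dataclass(frozen=True)
class NoiseConfig:
    """Recording-error processes, each applied per stay.

    p_spurious_single_record
        Probability of injecting exactly one record of a therapy the stay
        never received (the repeated-record rule should absorb it).
    p_continued_recording
        For stays with a therapy switch: probability of 1-3 extra rows of
        the prior therapy charted after the switch time.
    p_missing_medication
        Probability that an intubated stay's peri-intubation medication
        rows are absent (invasive evidence then lacks corroboration).
    p_hfni_variant_spelling
        Probability that a high-flow nurse-chart row uses a free-text
        spelling variant instead of the canonical device name.
    n_repeat_sequences
        Number of failure-phenotype stays given an extra NIV block after
        intubation (NIV -> invasive -> NIV repeat sequence).
    """

    p_spurious_single_record: float = 0.0
    p_continued_recording: float = 0.0
    p_missing_medication: float = 0.0
    p_hfni_variant_spelling: float = 0.5
    n_repeat_sequences: int = 0

    def __post_init__(self) -> None:
        for name in (
            "p_spurious_single_record",
            "p_continued_recording",
            "p_missing_medication",
            "p_hfni_variant_spelling",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.n_repeat_sequences < 0:
            raise ValueError("n_repeat_sequences must be >= 0")


@dataclass(frozen=True)
class GeneratorConfig:
    n_per_phenotype: Mapping[PhenotypeCode, int] = field(
        default_factory=lambda: dict(DEFAULT_N_PER_PHENOTYPE)
    )
    seed: int = 0
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    demographics: Mapping[PhenotypeCode, DemographicTarget] = field(
        default_factory=lambda: dict(DEFAULT_DEMOGRAPHICS)
    )
    #: fraction of stays whose ventilation starts before ICU admission
    pre_admission_fraction: float = 0.074
    #: excluded "distractor" stays, for end-to-end filter testing
    n_low_flow_only: int = 0
    n_minor: int = 0
    n_readmission: int = 0

    def __post_init__(self) -> None:
        for code, n in self.n_per_phenotype.items():
            if n < 0:
                raise ValueError(f"negative count for {code}")
        if not 0.0 <= self.pre_admission_fraction <= 1.0:
            raise ValueError("pre_admission_fraction must be in [0, 1]")


class InfeasibleConfigError(ValueError):
    """The requested cohort cannot realize its phenotypes."""


# ---------------------------------------------------------------------------
# marginal samplers
# ---------------------------------------------------------------------------


def _sigma_from_iqr(iqr: float) -> float:
    # normal quartiles sit at +/- 0.6745 sigma
    return iqr / (2 * 0.6745)


def _sample_truncnorm(
    rng: np.random.Generator, median: float, iqr: float, lo: float, hi: float
) -> float:
    sigma = max(_sigma_from_iqr(iqr), 1e-6)
    a, b = (lo - median) / sigma, (hi - median) / sigma
    return float(
        stats.truncnorm.rvs(a, b, loc=median, scale=sigma, random_state=rng)
    )


def _sample_lognormal_from_median_iqr(
    rng: np.random.Generator, median: float, iqr: float
) -> float:
    # lognormal quartiles are median * exp(+/- 0.6745 sigma), so
    # IQR = 2 * median * sinh(0.6745 sigma)
    sigma = math.asinh(iqr / (2 * median)) / 0.6745
    return float(median * math.exp(sigma * rng.standard_normal()))


# ---------------------------------------------------------------------------
# record-stream construction
# ---------------------------------------------------------------------------


def _block_offsets(
    rng: np.random.Generator, start: int, duration_min: int, n_rows: int
) -> list[int]:
    """n_rows sorted integer offsets in [start, start + duration], first at
    start (the block's first offset defines the therapy start)."""
    if n_rows == 1:
        return [start]
    extra = sorted(
        int(o) for o in rng.integers(1, max(duration_min, 2), size=n_rows - 1)
    )
    return [start] + [start + o for o in extra]


@dataclass
class _Rows:
    treatment: list[dict] = field(default_factory=list)
    medication: list[dict] = field(default_factory=list)
    nurse: list[dict] = field(default_factory=list)
    resp: list[dict] = field(default_factory=list)


def _add_invasive_block(
    rows: _Rows,
    rng: np.random.Generator,
    stay_id: str,
    start: int,
    noise: NoiseConfig,
) -> int:
    """Invasive treatment rows + resp-chart rows + medications; returns the
    block end offset."""
    duration = int(rng.integers(12 * 60, 5 * 24 * 60))
    n_rows = int(rng.integers(2, 5))
    for offset in _block_offsets(rng, start, duration, n_rows):
        rows.treatment.append(
            {"stay_id": stay_id, "treatment_string": INVASIVE_TREATMENT, "offset_min": offset}
        )
    for offset in _block_offsets(rng, start + int(rng.integers(10, 120)), duration, 2):
        rows.resp.append(
            {"stay_id": stay_id, "chart_string": RESP_INVASIVE_VALUE, "offset_min": offset}
        )
    if rng.random() >= noise.p_missing_medication:
        for drug in rng.choice(PERI_INTUBATION_DRUGS, size=2, replace=False):
            rows.medication.append(
                {
                    "stay_id": stay_id,
                    "drug_name": str(drug),
                    "offset_min": start + int(rng.integers(-15, 30)),
                }
            )
    return start + duration


def _add_nippv_block(
    rows: _Rows, rng: np.random.Generator, stay_id: str, start: int
) -> int:
    duration = int(rng.integers(4 * 60, 2 * 24 * 60))
    n_rows = int(rng.integers(2, 5))
    for offset in _block_offsets(rng, start, duration, n_rows):
        rows.treatment.append(
            {"stay_id": stay_id, "treatment_string": NIPPV_TREATMENT, "offset_min": offset}
        )
    return start + duration


def _add_hfni_block(
    rows: _Rows,
    rng: np.random.Generator,
    stay_id: str,
    start: int,
    noise: NoiseConfig,
) -> int:
    """NIV-family treatment rows plus repeated high-flow nurse-chart rows."""
    duration = int(rng.integers(4 * 60, 2 * 24 * 60))
    for offset in _block_offsets(rng, start, duration, int(rng.integers(2, 4))):
        rows.treatment.append(
            {"stay_id": stay_id, "treatment_string": NIV_TREATMENT, "offset_min": offset}
        )
    for offset in _block_offsets(rng, start, duration, int(rng.integers(2, 5))):
        if rng.random() < noise.p_hfni_variant_spelling:
            value = str(rng.choice(HFNI_VARIANTS))
        else:
            value = HFNI_CANONICAL
        rows.nurse.append(
            {
                "stay_id": stay_id,
                "chart_category": OXYGEN_DEVICE_CATEGORY,
                "chart_value": value,
                "offset_min": offset,
            }
        )
    return start + duration


def _niv_block(code: PhenotypeCode):
    return _add_hfni_block if code in _HFNI_PHENOTYPES else (
        lambda rows, rng, stay_id, start, noise: _add_nippv_block(
            rows, rng, stay_id, start
        )
    )


def _spurious_record(
    rows: _Rows, rng: np.random.Generator, stay_id: str, code: PhenotypeCode, at: int
) -> None:
    """Exactly one stray record of a therapy not on the stay's true path."""
    if code in (PhenotypeCode.P1_NIPPV, PhenotypeCode.P2_HFNI):
        rows.treatment.append(
            {"stay_id": stay_id, "treatment_string": INVASIVE_TREATMENT, "offset_min": at}
        )
    elif code is PhenotypeCode.P0_INVASIVE:
        rows.treatment.append(
            {"stay_id": stay_id, "treatment_string": NIPPV_TREATMENT, "offset_min": at}
        )
    elif code in (PhenotypeCode.P3_NIPPV_FAILURE, PhenotypeCode.P5_INVASIVE_TO_NIPPV):
        rows.nurse.append(
            {
                "stay_id": stay_id,
                "chart_category": OXYGEN_DEVICE_CATEGORY,
                "chart_value": "HFNC",
                "offset_min": at,
            }
        )
    else:  # HFNI failure / extubation stays: stray low-flow entry
        rows.nurse.append(
            {
                "stay_id": stay_id,
                "chart_category": OXYGEN_DEVICE_CATEGORY,
                "chart_value": LOW_FLOW_CHART_VALUE,
                "offset_min": at,
            }
        )


def _realize_phenotype(
    rows: _Rows,
    rng: np.random.Generator,
    stay_id: str,
    code: PhenotypeCode,
    noise: NoiseConfig,
    pre_admission: bool,
    repeat_sequence: bool,
) -> None:
    start = (
        -int(rng.integers(30, 720)) if pre_admission else int(rng.integers(0, 360))
    )
    gap = int(rng.integers(30, 720))
    niv_block = _niv_block(code)

    if code is PhenotypeCode.P0_INVASIVE:
        end = _add_invasive_block(rows, rng, stay_id, start, noise)
    elif code in (PhenotypeCode.P1_NIPPV, PhenotypeCode.P2_HFNI):
        end = niv_block(rows, rng, stay_id, start, noise)
    elif code in (PhenotypeCode.P3_NIPPV_FAILURE, PhenotypeCode.P4_HFNI_FAILURE):
        niv_end = niv_block(rows, rng, stay_id, start, noise)
        inv_start = niv_end + gap
        end = _add_invasive_block(rows, rng, stay_id, inv_start, noise)
        if rng.random() < noise.p_continued_recording:
            # prior NIV therapy keeps being charted after intubation
            for k in range(int(rng.integers(1, 4))):
                offset = inv_start + int(rng.integers(10, 600))
                rows.treatment.append(
                    {
                        "stay_id": stay_id,
                        "treatment_string": (
                            NIV_TREATMENT
                            if code is PhenotypeCode.P4_HFNI_FAILURE
                            else NIPPV_TREATMENT
                        ),
                        "offset_min": offset,
                    }
                )
        if repeat_sequence:
            # NIV attempted again after intubation
            niv_block(rows, rng, stay_id, end + gap, noise)
    else:  # P5 / P6: extubated to NIV
        inv_end = _add_invasive_block(rows, rng, stay_id, start, noise)
        niv_start = inv_end + gap
        end = niv_block(rows, rng, stay_id, niv_start, noise)
        if rng.random() < noise.p_continued_recording:
            for k in range(int(rng.integers(1, 4))):
                rows.resp.append(
                    {
                        "stay_id": stay_id,
                        "chart_string": RESP_INVASIVE_VALUE,
                        "offset_min": niv_start + int(rng.integers(10, 600)),
                    }
                )

    if rng.random() < noise.p_spurious_single_record:
        _spurious_record(
            rows, rng, stay_id, code, at=start + int(rng.integers(0, 600))
        )


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------


def _demographic_row(
    rng: np.random.Generator,
    patient_id: str,
    stay_id: str,
    target: DemographicTarget,
    unit_visit_number: int = 1,
    age_override: int | None = None,
) -> dict:
    if age_override is not None:
        age = age_override
    else:
        age = int(round(_sample_truncnorm(rng, *target.age, lo=18, hi=91)))
        age = min(age, AGE_CENSOR_SENTINEL)
    apache = int(round(_sample_truncnorm(rng, *target.apache, lo=0, hi=300)))
    los = round(_sample_lognormal_from_median_iqr(rng, *target.los_days), 2)
    eth_p = np.asarray(target.ethnicity, dtype=float)
    ethnicity = ETHNICITIES[int(rng.choice(len(ETHNICITIES), p=eth_p / eth_p.sum()))]
    return {
        "patient_id": patient_id,
        "stay_id": stay_id,
        "unit_visit_number": unit_visit_number,
        "age_years": age,
        "censored_age": age >= AGE_CENSOR_SENTINEL,
        "gender": "Male" if rng.random() < target.male else "Female",
        "ethnicity": ethnicity,
        "admission_diagnosis": str(rng.choice(DIAGNOSES)),
        "apache_score": apache,
        "icu_los_days": los,
        "hospital_mortality": bool(rng.random() < target.mortality),
    }


def generate_cohort(
    config: GeneratorConfig | None = None,
) -> tuple[EHRTables, list[PhenotypeLabel]]:
    """Generate the five tables plus ground-truth labels.

    Deterministic for a fixed config (byte-identical CSV output). Raises
    :class:`InfeasibleConfigError` for configs that cannot realize their
    phenotypes.
    """
    cfg = config or GeneratorConfig()
    unknown = set(cfg.n_per_phenotype) - set(PHENOTYPES)
    if unknown:
        raise InfeasibleConfigError(f"unknown phenotype code(s): {sorted(unknown)}")
    missing_demo = [
        c for c, n in cfg.n_per_phenotype.items() if n > 0 and c not in cfg.demographics
    ]
    if missing_demo:
        raise InfeasibleConfigError(
            f"no demographic targets configured for: {missing_demo}"
        )

    rng = np.random.default_rng(cfg.seed)
    rows = _Rows()
    patients: list[dict] = []
    truth: list[PhenotypeLabel] = []
    counter = 0

    repeat_budget = cfg.noise.n_repeat_sequences
    for code in PHENOTYPES:
        n = int(cfg.n_per_phenotype.get(code, 0))
        for i in range(n):
            counter += 1
            stay_id = f"S{counter:06d}"
            patient_id = f"P{counter:06d}"
            target = cfg.demographics[code]
            patients.append(_demographic_row(rng, patient_id, stay_id, target))
            repeat = False
            if repeat_budget > 0 and code in (
                PhenotypeCode.P3_NIPPV_FAILURE,
                PhenotypeCode.P4_HFNI_FAILURE,
            ):
                repeat = True
                repeat_budget -= 1
            _realize_phenotype(
                rows,
                rng,
                stay_id,
                code,
                cfg.noise,
                pre_admission=bool(rng.random() < cfg.pre_admission_fraction),
                repeat_sequence=repeat,
            )
            truth.append(PhenotypeLabel(stay_id=stay_id, code=code))

    default_target = DEFAULT_DEMOGRAPHICS[PhenotypeCode.P1_NIPPV]
    for _ in range(cfg.n_low_flow_only):
        counter += 1
        stay_id, patient_id = f"S{counter:06d}", f"P{counter:06d}"
        patients.append(_demographic_row(rng, patient_id, stay_id, default_target))
        for offset in _block_offsets(rng, int(rng.integers(0, 360)), 12 * 60, 3):
            rows.nurse.append(
                {
                    "stay_id": stay_id,
                    "chart_category": OXYGEN_DEVICE_CATEGORY,
                    "chart_value": LOW_FLOW_CHART_VALUE,
                    "offset_min": offset,
                }
            )
        truth.append(
            PhenotypeLabel(
                stay_id=stay_id,
                code=PhenotypeCode.EXCLUDED,
                exclusion_reason=ExclusionReason.LOW_FLOW_ONLY,
            )
        )
    for _ in range(cfg.n_minor):
        counter += 1
        stay_id, patient_id = f"S{counter:06d}", f"P{counter:06d}"
        patients.append(
            _demographic_row(
                rng, patient_id, stay_id, default_target, age_override=int(rng.integers(1, 18))
            )
        )
        _add_nippv_block(rows, rng, stay_id, int(rng.integers(0, 360)))
        truth.append(
            PhenotypeLabel(
                stay_id=stay_id,
                code=PhenotypeCode.EXCLUDED,
                exclusion_reason=ExclusionReason.MINOR,
            )
        )
    for _ in range(cfg.n_readmission):
        counter += 1
        stay_id, patient_id = f"S{counter:06d}", f"P{counter:06d}"
        patients.append(
            _demographic_row(
                rng, patient_id, stay_id, default_target, unit_visit_number=2
            )
        )
        _add_nippv_block(rows, rng, stay_id, int(rng.integers(0, 360)))
        truth.append(
            PhenotypeLabel(
                stay_id=stay_id,
                code=PhenotypeCode.EXCLUDED,
                exclusion_reason=ExclusionReason.READMISSION,
            )
        )

    tables = _assemble_tables(patients, rows)
    return tables, truth


def _assemble_tables(patients: list[dict], rows: _Rows) -> EHRTables:
    patient_cols = [
        "patient_id",
        "stay_id",
        "unit_visit_number",
        "age_years",
        "censored_age",
        "gender",
        "ethnicity",
        "admission_diagnosis",
        "apache_score",
        "icu_los_days",
        "hospital_mortality",
    ]
    patient = pd.DataFrame(patients, columns=patient_cols)
    patient = patient.astype(
        {
            "unit_visit_number": "int64",
            "age_years": "int64",
            "censored_age": bool,
            "apache_score": "Int64",
            "icu_los_days": "float64",
            "hospital_mortality": bool,
        }
    )

    def _records(data: list[dict], columns: list[str]) -> pd.DataFrame:
        df = pd.DataFrame(data, columns=columns)
        df["offset_min"] = df["offset_min"].astype("Int64")
        return df

    return EHRTables(
        patient=patient,
        treatment=_records(rows.treatment, ["stay_id", "treatment_string", "offset_min"]),
        medication=_records(rows.medication, ["stay_id", "drug_name", "offset_min"]),
        nurse_charting=_records(
            rows.nurse, ["stay_id", "chart_category", "chart_value", "offset_min"]
        ),
        resp_charting=_records(rows.resp, ["stay_id", "chart_string", "offset_min"]),
    )


# ---------------------------------------------------------------------------
# ground-truth table
# ---------------------------------------------------------------------------


def truth_table(truth: list[PhenotypeLabel], path: str | Path | None = None) -> pd.DataFrame:
    """(stay_id, true_code) frame; written to *path* as CSV when given."""
    df = pd.DataFrame(
        {
            "stay_id": [l.stay_id for l in truth],
            "true_code": [l.code.value for l in truth],
        }
    )
    if path is not None:
        df.to_csv(path, index=False)
    return df


def read_truth(path: str | Path) -> dict[str, PhenotypeCode]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return {
        row.stay_id: PhenotypeCode(row.true_code) for row in df.itertuples(index=False)
    }
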