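"""Inclusion/exclusion criteria for the acute-respiratory-failure cohort.

A stay enters the analyzable cohort iff the patient is an adult (>= 18
years), it is the first ICU stay of the hospitalization, and it carries at
least one timestamped record of invasive ventilation, NIPPV or HFNI.
Stays supported only by conventional low-flow oxygen, stays with no
ventilation-related records, and stays whose ventilation records all lack
timestamps are excluded, each under its own logged reason.

Exclusion reasons are assigned under a fixed precedence so every stay gets
exactly one label: MINOR > READMISSION > NO_VENT_RECORDS > LOW_FLOW_ONLY >
NO_TIMESTAMPS.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .ehr_model import (
    ExclusionReason,
    Modality,
    PatientStay,
    PhenotypeCode,
    PhenotypeLabel,
    VentRecord,
    VENT_MODALITIES,
)

__all__ = ["CohortSplit", "apply_inclusion_exclusion", "ADULT_AGE_YEARS"]

ADULT_AGE_YEARS = 18

#: Order in which exclusion reasons are tested; the first that applies wins.
_EXCLUSION_PRECEDENCE = (
    ExclusionReason.MINOR,
    ExclusionReason.READMISSION,
    ExclusionReason.NO_VENT_RECORDS,
    ExclusionReason.LOW_FLOW_ONLY,
    ExclusionReason.NO_TIMESTAMPS,
)


@dataclass
class CohortSplit:
    """Result of the inclusion/exclusion pass.

    ``included`` and ``excluded`` partition the input stays: every stay
    appears in exactly one of the two.
    """

    included: list[str]
    excluded: list[PhenotypeLabel]
    orphan_record_stays: list[str] = field(default_factory=list)

    def exclusion_counts(self) -> Counter:
        return Counter(label.exclusion_reason for label in self.excluded)

    def exclusions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stay_id": [l.stay_id for l in self.excluded],
                "reason": [l.exclusion_reason.value for l in self.excluded],
            }
        )


def _reasons_for(
    stay: PatientStay,
    modalities_with_ts: set[Modality],
    modalities_all: set[Modality],
    readmitted_patient: bool,
) -> list[ExclusionReason]:
    reasons = []
    if stay.age_years < ADULT_AGE_YEARS:
        reasons.append(ExclusionReason.MINOR)
    if stay.unit_visit_number > 1 or readmitted_patient:
        reasons.append(ExclusionReason.READMISSION)
    vent_all = modalities_all & VENT_MODALITIES
    if not vent_all:
        if Modality.LOW_FLOW in modalities_all:
            reasons.append(ExclusionReason.LOW_FLOW_ONLY)
        else:
            reasons.append(ExclusionReason.NO_VENT_RECORDS)
    elif not (modalities_with_ts & VENT_MODALITIES):
        reasons.append(ExclusionReason.NO_TIMESTAMPS)
    return reasons


def apply_inclusion_exclusion(
    stays: Sequence[PatientStay],
    classified_records: Iterable[tuple[VentRecord, Modality]],
    readmission_policy: str = "keep-first",
) -> CohortSplit:
    """Split stays into the included cohort and labeled exclusions.

    Parameters
    ----------
    stays
        All candidate ICU stays.
    classified_records
        (record, modality) pairs, already classified by the lexicon.
        Records referencing a stay absent from *stays* are dropped and the
        offending stay ids reported in ``orphan_record_stays``.
    readmission_policy
        ``"keep-first"`` (default) keeps unit visit 1 and excludes later
        visits; ``"drop-all"`` additionally excludes every stay of a patient
        who has any later visit in the table.
    """
    if readmission_policy not in {"keep-first", "drop-all"}:
        raise ValueError(f"unknown readmission_policy {readmission_policy!r}")

    known = {s.stay_id for s in stays}
    with_ts: dict[str, set[Modality]] = defaultdict(set)
    any_ts: dict[str, set[Modality]] = defaultdict(set)
    orphans: set[str] = set()
    for record, modality in classified_records:
        if record.stay_id not in known:
            orphans.add(record.stay_id)
            continue
        if modality is Modality.NONE:
            continue
        any_ts[record.stay_id].add(modality)
        if record.offset_min is not None:
            with_ts[record.stay_id].add(modality)

    readmitted_patients: set[str] = set()
    if readmission_policy == "drop-all":
        readmitted_patients = {
            s.patient_id for s in stays if s.unit_visit_number > 1
        }

    included: list[str] = []
    excluded: list[PhenotypeLabel] = []
    for stay in stays:
        reasons = _reasons_for(
            stay,
            with_ts.get(stay.stay_id, set()),
            any_ts.get(stay.stay_id, set()),
            stay.patient_id in readmitted_patients,
        )
        if not reasons:
            included.append(stay.stay_id)
            continue
        reason = min(reasons, key=_EXCLUSION_PRECEDENCE.index)
        excluded.append(
            PhenotypeLabel(
                stay_id=stay.stay_id,
                code=PhenotypeCode.EXCLUDED,
                exclusion_reason=reason,
            )
        )
    return CohortSplit(
        included=included, excluded=excluded, orphan_record_stays=sorted(orphans)
    )
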