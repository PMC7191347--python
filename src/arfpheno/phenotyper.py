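"""Event consolidation, corroboration rules and the phenotype decision tree.

Classified records are consolidated into one event per (stay, modality);
single-record events are discarded (a modality needs more than one record
to count, which suppresses spurious entries); invasive events are
corroborated against peri-intubation medications and high-flow events
against nurse-chart oxygen-device rows; finally a decision tree compares
the earliest invasive and noninvasive timestamps to emit one of seven
phenotypes per stay:

====  =====================================================
P0    invasive mechanical ventilation only
P1    NIPPV only
P2    HFNI only
P3    NIPPV failure (NIPPV before intubation)
P4    HFNI failure (HFNI before intubation)
P5    extubated to NIPPV (NIPPV after intubation)
P6    extubated to HFNI (HFNI after intubation)
====  =====================================================

Only the relative order of timestamps matters, so every label is invariant
to a constant shift of one stay's offsets. High-flow evidence lives in
nurse charts (there is no dedicated treatment code for it), and a stay is
routed to the HFNI branch only when it also carries an NIV-family
treatment event; high-flow charting without any NIV record is excluded.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cohort_filter import CohortSplit, apply_inclusion_exclusion
from .ehr_model import (
    EHRTables,
    ExclusionReason,
    Modality,
    PhenotypeCode,
    PhenotypeLabel,
    Source,
    VentEvent,
    VentRecord,
    NIV_MODALITIES,
)
from .term_lexicon import (
    Lexicon,
    classify_record_term,
    default_drug_lexicon,
    default_lexicon,
    normalize_hfni_variant,
)

__all__ = [
    "SequenceRelation",
    "PipelineConfig",
    "PipelineResult",
    "consolidate_events",
    "filter_repeated_records",
    "corroborate_invasive",
    "corroborate_hfni",
    "determine_sequence",
    "assign_phenotype",
    "classify_tables",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


class SequenceRelation:
    """Temporal relation between a stay's NIV and invasive events."""

    NIV_BEFORE_INVASIVE = "NIV_BEFORE_INVASIVE"
    NIV_AFTER_INVASIVE = "NIV_AFTER_INVASIVE"
    NIV_ONLY = "NIV_ONLY"
    INVASIVE_ONLY = "INVASIVE_ONLY"


#: substring used to recognize oxygen-device rows in nurse charts
OXYGEN_DEVICE_CATEGORY_TOKENS = ("o2 admin device", "o2 device", "oxygen device")


@dataclass
class PipelineConfig:
    """Tunable policies of the phenotyping pipeline.

    min_records
        A modality is accepted for a stay only with at least this many
        records (default 2: "more than one record").
    tie_rule
        Label when the earliest NIV and invasive timestamps coincide:
        ``"niv-first"`` (default — simultaneous charting is read as NIV
        attempted peri-intubation, i.e. a failure phenotype) or
        ``"invasive-first"``.
    uncorroborated_invasive_policy
        ``"retain"`` (default) keeps invasive events lacking medication
        corroboration, flagged; ``"exclude"`` drops the stay with reason
        UNCORROBORATED when its invasive evidence is uncorroborated.
    readmission_policy
        Passed through to the cohort filter (``"keep-first"``/``"drop-all"``).
    """

    min_records: int = 2
    tie_rule: str = "niv-first"
    uncorroborated_invasive_policy: str = "retain"
    readmission_policy: str = "keep-first"
    lexicon: Lexicon | None = None
    drug_lexicon: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.min_records < 1:
            raise ValueError("min_records must be >= 1")
        if self.tie_rule not in {"niv-first", "invasive-first"}:
            raise ValueError(f"unknown tie_rule {self.tie_rule!r}")
        if self.uncorroborated_invasive_policy not in {"retain", "exclude"}:
            raise ValueError(
                f"unknown uncorroborated_invasive_policy "
                f"{self.uncorroborated_invasive_policy!r}"
            )

    def resolved_lexicon(self) -> Lexicon:
        return self.lexicon if self.lexicon is not None else default_lexicon()

    def resolved_drugs(self) -> tuple[str, ...]:
        return (
            self.drug_lexicon
            if self.drug_lexicon is not None
            else default_drug_lexicon()
        )


# ---------------------------------------------------------------------------
# event construction
# ---------------------------------------------------------------------------


def consolidate_events(
    classified_records: Iterable[tuple[VentRecord, Modality]]
) -> list[VentEvent]:
    """One :class:`VentEvent` per (stay, modality) with first/last offsets.

    Records with modality NONE or without a timestamp are dropped (stays
    whose ventilation records all lack timestamps were already excluded
    upstream).
    """
    groups: dict[tuple[str, Modality], list[VentRecord]] = defaultdict(list)
    for record, modality in classified_records:
        if modality is Modality.NONE or record.offset_min is None:
            continue
        groups[(record.stay_id, modality)].append(record)
    events = []
    for (stay_id, modality), records in sorted(
        groups.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
    ):
        offsets = [r.offset_min for r in records]
        events.append(
            VentEvent(
                stay_id=stay_id,
                modality=modality,
                first_offset_min=min(offsets),
                last_offset_min=max(offsets),
                n_records=len(records),
                sources=frozenset(r.source for r in records),
            )
        )
    return events


def filter_repeated_records(
    events: Sequence[VentEvent], min_records: int = 2
) -> list[VentEvent]:
    """Drop events backed by fewer than *min_records* records.

    Requiring repeated records of each ventilation type suppresses single
    spurious entries that would otherwise misclassify a stay.
    """
    kept = []
    for event in events:
        if event.n_records >= min_records:
            kept.append(event)
        else:
            logger.debug(
                "dropping %s event for stay %s: %d record(s) < %d",
                event.modality.value,
                event.stay_id,
                event.n_records,
                min_records,
            )
    return kept


def corroborate_invasive(
    events: Sequence[VentEvent],
    medication_terms_by_stay: Mapping[str, Sequence[str]],
    drug_lexicon: Sequence[str] | None = None,
) -> list[VentEvent]:
    """Flag invasive events corroborated by peri-intubation medications.

    An invasive event is corroborated iff at least one of the stay's
    medication rows matches the drug lexicon (case-insensitive substring).
    Noninvasive events pass through unchanged.
    """
    drugs = tuple(drug_lexicon) if drug_lexicon is not None else default_drug_lexicon()
    out = []
    for event in events:
        if event.modality is Modality.INVASIVE:
            terms = medication_terms_by_stay.get(event.stay_id, ())
            event.corroborated = any(
                any(drug in term.lower() for drug in drugs) for term in terms
            )
        out.append(event)
    return out


def corroborate_hfni(
    events: Sequence[VentEvent],
) -> tuple[list[VentEvent], ExclusionReason | None]:
    """Enforce the high-flow evidence rule for one stay's events.

    High-flow nasal insufflation is charted, not ordered: an HFNI event
    (built from repeated nurse-chart oxygen-device rows) stands only when
    the stay also has an NIV-family event from treatment/respiratory
    records. HFNI evidence without any NIV record excludes the stay
    (HFNI_WITHOUT_NIV); with it, the HFNI event is marked corroborated.
    """
    hfni = next((e for e in events if e.modality is Modality.HFNI), None)
    if hfni is None:
        return list(events), None
    has_niv_family = any(
        e.modality is Modality.NIPPV for e in events
    )
    if not has_niv_family:
        return list(events), ExclusionReason.HFNI_WITHOUT_NIV
    hfni.corroborated = True
    return list(events), None


# ---------------------------------------------------------------------------
# sequencing and the decision tree
# ---------------------------------------------------------------------------


def determine_sequence(
    invasive: VentEvent | None,
    niv: VentEvent | None,
    tie_rule: str = "niv-first",
) -> str:
    """Order a stay's invasive and NIV events by earliest timestamp.

    NIV strictly before intubation is a failure of the noninvasive
    strategy; NIV strictly after is extubation to NIV. Coincident earliest
    timestamps follow *tie_rule* (default: treated as NIV first, since
    simultaneous charting usually reflects NIV attempted peri-intubation).
    """
    if invasive is None and niv is None:
        raise ValueError("determine_sequence requires at least one event")
    if invasive is None:
        return SequenceRelation.NIV_ONLY
    if niv is None:
        return SequenceRelation.INVASIVE_ONLY
    if niv.first_offset_min < invasive.first_offset_min:
        return SequenceRelation.NIV_BEFORE_INVASIVE
    if niv.first_offset_min > invasive.first_offset_min:
        return SequenceRelation.NIV_AFTER_INVASIVE
    return (
        SequenceRelation.NIV_BEFORE_INVASIVE
        if tie_rule == "niv-first"
        else SequenceRelation.NIV_AFTER_INVASIVE
    )


_TREE = {
    (SequenceRelation.INVASIVE_ONLY, False): PhenotypeCode.P0_INVASIVE,
    (SequenceRelation.NIV_ONLY, False): PhenotypeCode.P1_NIPPV,
    (SequenceRelation.NIV_ONLY, True): PhenotypeCode.P2_HFNI,
    (SequenceRelation.NIV_BEFORE_INVASIVE, False): PhenotypeCode.P3_NIPPV_FAILURE,
    (SequenceRelation.NIV_BEFORE_INVASIVE, True): PhenotypeCode.P4_HFNI_FAILURE,
    (SequenceRelation.NIV_AFTER_INVASIVE, False): PhenotypeCode.P5_INVASIVE_TO_NIPPV,
    (SequenceRelation.NIV_AFTER_INVASIVE, True): PhenotypeCode.P6_INVASIVE_TO_HFNI,
}


def assign_phenotype(
    stay_id: str,
    events: Sequence[VentEvent],
    tie_rule: str = "niv-first",
) -> PhenotypeLabel:
    """Run the decision tree on one stay's filtered, corroborated events.

    When both NIPPV and HFNI evidence exist, the HFNI branch takes
    precedence: in the source schema high-flow charting is a refinement of
    the NIV treatment path, so NIPPV-vs-HFNI crossover phenotypes are not
    emitted. Stays whose events were all filtered away are excluded as
    SINGLE_RECORD_ONLY.
    """
    invasive = next((e for e in events if e.modality is Modality.INVASIVE), None)
    hfni = next((e for e in events if e.modality is Modality.HFNI), None)
    nippv = next((e for e in events if e.modality is Modality.NIPPV), None)
    niv = hfni if hfni is not None else nippv
    if invasive is None and niv is None:
        return PhenotypeLabel(
            stay_id=stay_id,
            code=PhenotypeCode.EXCLUDED,
            exclusion_reason=ExclusionReason.SINGLE_RECORD_ONLY,
        )
    relation = determine_sequence(invasive, niv, tie_rule=tie_rule)
    code = _TREE[(relation, hfni is not None)]
    return PhenotypeLabel(stay_id=stay_id, code=code)


def count_transitions(
    classified_records: Sequence[tuple[VentRecord, Modality]]
) -> int:
    """Number of invasive<->NIV alternations in one stay's timestamped
    record stream (0 or 1 for clean courses; >1 flags repeated sequences)."""
    timeline = sorted(
        (
            (r.offset_min, m)
            for r, m in classified_records
            if r.offset_min is not None
            and m in (Modality.INVASIVE, Modality.NIPPV, Modality.HFNI)
        ),
        key=lambda t: t[0],
    )
    transitions = 0
    prev_family = None
    for _, modality in timeline:
        family = "INV" if modality is Modality.INVASIVE else "NIV"
        if prev_family is not None and family != prev_family:
            transitions += 1
        prev_family = family
    return transitions


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    labels: list[PhenotypeLabel]
    cohort: CohortSplit
    events_by_stay: dict[str, list[VentEvent]]
    n_transitions: dict[str, int]
    log: dict[str, object] = field(default_factory=dict)

    def label_counts(self) -> Counter:
        return Counter(label.code for label in self.labels)

    def labels_frame(self) -> pd.DataFrame:
        """phenotypes.csv layout: label, reason, per-modality first offsets,
        corroboration flags and transition count per stay."""
        rows = []
        for label in self.labels:
            events = {
                e.modality: e for e in self.events_by_stay.get(label.stay_id, [])
            }
            def _first(m: Modality):
                return events[m].first_offset_min if m in events else pd.NA
            rows.append(
                {
                    "stay_id": label.stay_id,
                    "code": label.code.value,
                    "exclusion_reason": (
                        label.exclusion_reason.value if label.exclusion_reason else ""
                    ),
                    "invasive_first_offset_min": _first(Modality.INVASIVE),
                    "nippv_first_offset_min": _first(Modality.NIPPV),
                    "hfni_first_offset_min": _first(Modality.HFNI),
                    "invasive_corroborated": (
                        events[Modality.INVASIVE].corroborated
                        if Modality.INVASIVE in events
                        else pd.NA
                    ),
                    "hfni_corroborated": (
                        events[Modality.HFNI].corroborated
                        if Modality.HFNI in events
                        else pd.NA
                    ),
                    "n_transitions": self.n_transitions.get(label.stay_id, 0),
                }
            )
        columns = [
            "stay_id",
            "code",
            "exclusion_reason",
            "invasive_first_offset_min",
            "nippv_first_offset_min",
            "hfni_first_offset_min",
            "invasive_corroborated",
            "hfni_corroborated",
            "n_transitions",
        ]
        return pd.DataFrame(rows, columns=columns)


def classify_tables(
    tables: EHRTables, lexicon: Lexicon | None = None
) -> list[tuple[VentRecord, Modality]]:
    """Classify every potentially ventilation-related record in *tables*.

    Treatment and respiratory-chart strings go through the lexicon.
    Nurse-chart rows are first screened by their category: oxygen-device
    rows run the free-text high-flow normalizer before falling back to the
    lexicon; all other nurse rows use the lexicon directly (airway-status
    entries such as "Intubated/oral ETT" still classify as invasive).
    """
    lex = lexicon if lexicon is not None else default_lexicon()
    classified: list[tuple[VentRecord, Modality]] = []

    def _offset(value) -> int | None:
        return None if pd.isna(value) else int(value)

    for row in tables.treatment.itertuples(index=False):
        if not row.treatment_string:
            continue
        record = VentRecord(
            row.stay_id, Source.TREATMENT, row.treatment_string, _offset(row.offset_min)
        )
        classified.append(
            (record, classify_record_term(record.raw_term, record.source, lex))
        )
    for row in tables.resp_charting.itertuples(index=False):
        if not row.chart_string:
            continue
        record = VentRecord(
            row.stay_id, Source.RESP_CHART, row.chart_string, _offset(row.offset_min)
        )
        classified.append(
            (record, classify_record_term(record.raw_term, record.source, lex))
        )
    for row in tables.nurse_charting.itertuples(index=False):
        if not row.chart_value:
            continue
        record = VentRecord(
            row.stay_id, Source.NURSE_CHART, row.chart_value, _offset(row.offset_min)
        )
        if _is_oxygen_device_category(row.chart_category) and normalize_hfni_variant(
            record.raw_term
        ):
            classified.append((record, Modality.HFNI))
            continue
        classified.append(
            (record, classify_record_term(record.raw_term, record.source, lex))
        )
    return classified


def _is_oxygen_device_category(category: str) -> bool:
    c = category.strip().lower()
    return any(token in c for token in OXYGEN_DEVICE_CATEGORY_TOKENS)


def run_pipeline(
    tables: EHRTables, config: PipelineConfig | None = None
) -> PipelineResult:
    """Classify, filter, consolidate, corroborate and label every stay.

    Deterministic; the returned label multiset is invariant to input row
    order. Output labels are sorted by stay id.
    """
    cfg = config or PipelineConfig()
    lexicon = cfg.resolved_lexicon()
    drugs = cfg.resolved_drugs()

    classified = classify_tables(tables, lexicon)
    stays = tables.stays()
    cohort = apply_inclusion_exclusion(
        stays, classified, readmission_policy=cfg.readmission_policy
    )

    by_stay: dict[str, list[tuple[VentRecord, Modality]]] = defaultdict(list)
    for record, modality in classified:
        by_stay[record.stay_id].append((record, modality))

    meds_by_stay: dict[str, list[str]] = defaultdict(list)
    for row in tables.medication.itertuples(index=False):
        meds_by_stay[row.stay_id].append(row.drug_name)

    labels: list[PhenotypeLabel] = list(cohort.excluded)
    events_by_stay: dict[str, list[VentEvent]] = {}
    n_transitions: dict[str, int] = {}

    for stay_id in cohort.included:
        stay_records = by_stay.get(stay_id, [])
        events = consolidate_events(stay_records)
        events = filter_repeated_records(events, min_records=cfg.min_records)
        events, hfni_exclusion = corroborate_hfni(events)
        if hfni_exclusion is not None:
            labels.append(
                PhenotypeLabel(
                    stay_id=stay_id,
                    code=PhenotypeCode.EXCLUDED,
                    exclusion_reason=hfni_exclusion,
                )
            )
            events_by_stay[stay_id] = events
            continue
        events = corroborate_invasive(events, meds_by_stay, drugs)
        if cfg.uncorroborated_invasive_policy == "exclude" and any(
            e.modality is Modality.INVASIVE and not e.corroborated for e in events
        ):
            labels.append(
                PhenotypeLabel(
                    stay_id=stay_id,
                    code=PhenotypeCode.EXCLUDED,
                    exclusion_reason=ExclusionReason.UNCORROBORATED,
                )
            )
            events_by_stay[stay_id] = events
            continue
        events_by_stay[stay_id] = events
        n_transitions[stay_id] = count_transitions(stay_records)
        labels.append(assign_phenotype(stay_id, events, tie_rule=cfg.tie_rule))

    labels.sort(key=lambda l: l.stay_id)
    counts = Counter(l.code.value for l in labels)
    log = {
        "n_stays": len(stays),
        "n_records_classified": len(classified),
        "n_included": len(cohort.included),
        "n_excluded_cohort": len(cohort.excluded),
        "orphan_record_stays": cohort.orphan_record_stays,
        "label_counts": dict(sorted(counts.items())),
        "n_multi_transition_stays": sum(
            1 for v in n_transitions.values() if v > 1
        ),
        "row_issues": [str(i) for i in tables.issues],
    }
    if log["orphan_record_stays"]:
        logger.warning(
            "records referenced %d stay id(s) absent from the patient table",
            len(log["orphan_record_stays"]),
        )
    return PipelineResult(
        labels=labels,
        cohort=cohort,
        events_by_stay=events_by_stay,
        n_transitions=n_transitions,
        log=log,
    )
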