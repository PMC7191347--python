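"""Event consolidation, corroboration, sequencing and the decision tree."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from arfpheno.ehr_model import (
    ExclusionReason,
    Modality,
    PhenotypeCode,
    Source,
    VentEvent,
    VentRecord,
)
from arfpheno.phenotyper import (
    SequenceRelation,
    assign_phenotype,
    consolidate_events,
    corroborate_hfni,
    corroborate_invasive,
    count_transitions,
    determine_sequence,
    filter_repeated_records,
)


def rec(stay_id, modality, offset, source=Source.TREATMENT, term="x"):
    return (VentRecord(stay_id, source, term, offset), modality)


def event(modality, first, last=None, n=2, stay_id="S1"):
    return VentEvent(
        stay_id=stay_id,
        modality=modality,
        first_offset_min=first,
        last_offset_min=first if last is None else last,
        n_records=n,
    )


class TestConsolidateEvents:
    def test_min_max_and_count(self):
        events = consolidate_events(
            [rec("S1", Modality.INVASIVE, 50), rec("S1", Modality.INVASIVE, 10)]
        )
        assert len(events) == 1
        e = events[0]
        assert (e.first_offset_min, e.last_offset_min, e.n_records) == (10, 50, 2)

    def test_single_negative_offset_record(self):
        (e,) = consolidate_events([rec("S1", Modality.NIPPV, -90)])
        assert (e.first_offset_min, e.last_offset_min, e.n_records) == (-90, -90, 1)

    def test_empty_input_gives_empty_output(self):
        assert consolidate_events([]) == []

    def test_none_modality_and_untimestamped_records_dropped(self):
        events = consolidate_events(
            [rec("S1", Modality.NONE, 5), rec("S1", Modality.NIPPV, None)]
        )
        assert events == []

    def test_source_tags_retained(self):
        (e,) = consolidate_events(
            [
                rec("S1", Modality.HFNI, 5, Source.NURSE_CHART),
                rec("S1", Modality.HFNI, 9, Source.TREATMENT),
            ]
        )
        assert e.sources == {Source.NURSE_CHART, Source.TREATMENT}


class TestFilterRepeatedRecords:
    def test_single_record_event_removed(self):
        assert filter_repeated_records([event(Modality.INVASIVE, 0, n=1)]) == []

    def test_two_record_event_retained_at_boundary(self):
        events = [event(Modality.NIPPV, 0, n=2)]
        assert filter_repeated_records(events) == events

    def test_empty_list(self):
        assert filter_repeated_records([]) == []

    def test_threshold_configurable(self):
        events = [event(Modality.NIPPV, 0, n=2)]
        assert filter_repeated_records(events, min_records=3) == []
        assert filter_repeated_records(events, min_records=1) == events


class TestCorroboration:
    def test_invasive_event_corroborated_by_drug_row(self):
        (e,) = corroborate_invasive(
            [event(Modality.INVASIVE, 0)], {"S1": ["Rocuronium 50mg IV"]}
        )
        assert e.corroborated

    def test_invasive_without_medications_flagged_but_retained(self):
        (e,) = corroborate_invasive([event(Modality.INVASIVE, 0)], {})
        assert not e.corroborated

    def test_medications_do_not_touch_nippv_events(self):
        (e,) = corroborate_invasive(
            [event(Modality.NIPPV, 0)], {"S1": ["rocuronium"]}
        )
        assert not e.corroborated

    def test_hfni_with_niv_family_event_corroborated(self):
        events = [event(Modality.HFNI, 20), event(Modality.NIPPV, 0)]
        out, exclusion = corroborate_hfni(events)
        assert exclusion is None
        assert next(e for e in out if e.modality is Modality.HFNI).corroborated

    def test_hfni_without_any_niv_record_excluded(self):
        out, exclusion = corroborate_hfni([event(Modality.HFNI, 20)])
        assert exclusion is ExclusionReason.HFNI_WITHOUT_NIV

    def test_no_hfni_event_passes_through(self):
        events = [event(Modality.INVASIVE, 0)]
        out, exclusion = corroborate_hfni(events)
        assert exclusion is None and out == events


class TestDetermineSequence:
    def test_worked_example_niv_minus_90_invasive_plus_30(self):
        """NIPPV charted 90 min before admission, intubation 30 min after:
        the noninvasive attempt preceded intubation, i.e. NIV failure."""
        relation = determine_sequence(
            invasive=event(Modality.INVASIVE, 30), niv=event(Modality.NIPPV, -90)
        )
        assert relation == SequenceRelation.NIV_BEFORE_INVASIVE

    def test_niv_after_invasive_is_extubation_to_niv(self):
        relation = determine_sequence(
            invasive=event(Modality.INVASIVE, 0), niv=event(Modality.NIPPV, 600)
        )
        assert relation == SequenceRelation.NIV_AFTER_INVASIVE

    def test_tie_defaults_to_niv_first(self):
        relation = determine_sequence(
            invasive=event(Modality.INVASIVE, 30), niv=event(Modality.NIPPV, 30)
        )
        assert relation == SequenceRelation.NIV_BEFORE_INVASIVE

    def test_tie_rule_configurable(self):
        relation = determine_sequence(
            invasive=event(Modality.INVASIVE, 30),
            niv=event(Modality.NIPPV, 30),
            tie_rule="invasive-first",
        )
        assert relation == SequenceRelation.NIV_AFTER_INVASIVE

    def test_single_argument_cases(self):
        assert (
            determine_sequence(event(Modality.INVASIVE, 0), None)
            == SequenceRelation.INVASIVE_ONLY
        )
        assert (
            determine_sequence(None, event(Modality.NIPPV, 0))
            == SequenceRelation.NIV_ONLY
        )

    def test_both_absent_is_contract_violation(self):
        with pytest.raises(ValueError):
            determine_sequence(None, None)


def oracle_phenotype(has_inv, has_nippv, has_hfni, inv_first, nippv_first, hfni_first):
    """Independent truth-table evaluation of the decision tree.

    Explicit enumeration of every modality subset; the NIV branch is HFNI
    whenever high-flow evidence exists, NIPPV otherwise; NIV at or before
    the invasive start is a failure phenotype, strictly after is
    extubation to NIV.
    """
    if not (has_inv or has_nippv or has_hfni):
        return ("EXCLUDED", "SINGLE_RECORD_ONLY")
    if has_inv and not has_nippv and not has_hfni:
        return "P0_INVASIVE"
    if not has_inv:
        return "P2_HFNI" if has_hfni else "P1_NIPPV"
    niv_first = hfni_first if has_hfni else nippv_first
    if niv_first <= inv_first:
        return "P4_HFNI_FAILURE" if has_hfni else "P3_NIPPV_FAILURE"
    return "P6_INVASIVE_TO_HFNI" if has_hfni else "P5_INVASIVE_TO_NIPPV"


class TestAssignPhenotype:
    def test_invasive_only_is_p0(self):
        label = assign_phenotype("S1", [event(Modality.INVASIVE, 0)])
        assert label.code is PhenotypeCode.P0_INVASIVE

    def test_worked_example_is_nippv_failure(self):
        label = assign_phenotype(
            "S1", [event(Modality.NIPPV, -90), event(Modality.INVASIVE, 30)]
        )
        assert label.code is PhenotypeCode.P3_NIPPV_FAILURE

    def test_hfni_after_invasive_is_extubated_to_hfni(self):
        events = [
            event(Modality.INVASIVE, 0),
            event(Modality.HFNI, 700),
            event(Modality.NIPPV, 690),
        ]
        label = assign_phenotype("S1", events)
        assert label.code is PhenotypeCode.P6_INVASIVE_TO_HFNI

    def test_no_events_excluded_as_single_record_only(self):
        label = assign_phenotype("S1", [])
        assert label.code is PhenotypeCode.EXCLUDED
        assert label.exclusion_reason is ExclusionReason.SINGLE_RECORD_ONLY

    def test_low_flow_events_alone_do_not_label(self):
        label = assign_phenotype("S1", [event(Modality.LOW_FLOW, 0)])
        assert label.exclusion_reason is ExclusionReason.SINGLE_RECORD_ONLY

    def test_agrees_with_truth_table_oracle_on_all_small_stays(self):
        """Enumerate every modality subset x every first-offset ordering
        (including ties) and compare with the independent oracle."""
        offsets = [-90, 0, 30, 30, 600]  # duplicated 30 covers ties
        n_checked = 0
        for has_inv, has_nippv, has_hfni in itertools.product([False, True], repeat=3):
            mods = []
            if has_inv:
                mods.append(Modality.INVASIVE)
            if has_nippv:
                mods.append(Modality.NIPPV)
            if has_hfni:
                mods.append(Modality.HFNI)
            for firsts in itertools.permutations(offsets, len(mods)):
                by = dict(zip(mods, firsts))
                events = [event(m, by[m]) for m in mods]
                label = assign_phenotype("S1", events)
                expected = oracle_phenotype(
                    has_inv,
                    has_nippv,
                    has_hfni,
                    by.get(Modality.INVASIVE, 0),
                    by.get(Modality.NIPPV, 0),
                    by.get(Modality.HFNI, 0),
                )
                if isinstance(expected, tuple):
                    assert label.code is PhenotypeCode.EXCLUDED
                    assert label.exclusion_reason is ExclusionReason.SINGLE_RECORD_ONLY
                else:
                    assert label.code.value == expected, (mods, by)
                n_checked += 1
        assert n_checked > 100

    @settings(max_examples=100, deadline=None)
    @given(
        shift=st.integers(-100_000, 100_000),
        nippv_first=st.integers(-1000, 1000),
        inv_first=st.integers(-1000, 1000),
    )
    def test_shift_invariance(self, shift, nippv_first, inv_first):
        """Adding a constant to all of a stay's offsets never changes its
        phenotype: only relative order matters."""
        base = [event(Modality.NIPPV, nippv_first), event(Modality.INVASIVE, inv_first)]
        shifted = [
            event(e.modality, e.first_offset_min + shift) for e in base
        ]
        assert assign_phenotype("S1", base).code is assign_phenotype("S1", shifted).code

    def test_alternating_sequence_classified_by_first_transition(self):
        """NIV -> intubation -> NIV again is a failure phenotype, not
        extubation to NIV: the first transition decides."""
        records = [
            rec("S1", Modality.NIPPV, -90),
            rec("S1", Modality.NIPPV, -60),
            rec("S1", Modality.INVASIVE, 30),
            rec("S1", Modality.INVASIVE, 100),
            rec("S1", Modality.NIPPV, 3000),
            rec("S1", Modality.NIPPV, 3100),
        ]
        events = filter_repeated_records(consolidate_events(records))
        assert assign_phenotype("S1", events).code is PhenotypeCode.P3_NIPPV_FAILURE
        assert count_transitions(records) == 2
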