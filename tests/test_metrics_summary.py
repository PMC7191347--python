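"""Descriptive statistics, failure rates, sampling, multiclass metrics."""

import math

import numpy as np
import pytest

from arfpheno import (
    PHENOTYPES,
    PhenotypeCode,
    PhenotypeLabel,
    compute_validation_metrics,
    failure_rates,
    phenotype_shares,
    sample_for_validation,
    summarize_cohort,
)
from arfpheno.ehr_model import ExclusionReason, PatientStay
from arfpheno.metrics_summary import MetricsError, percentage


def stay(stay_id, *, age=60, apache=70, los=3.0, dead=False, gender="Female"):
    return PatientStay(
        patient_id=f"pt-{stay_id}",
        stay_id=stay_id,
        unit_visit_number=1,
        age_years=age,
        gender=gender,
        ethnicity="White",
        admission_diagnosis="Sepsis, pulmonary",
        apache_score=apache,
        icu_los_days=los,
        hospital_mortality=dead,
    )


def label(stay_id, code):
    return PhenotypeLabel(stay_id=stay_id, code=code)


class TestSummarizeCohort:
    def test_shares_and_mortality_from_published_counts(self, table2_counts):
        shares = phenotype_shares(table2_counts)
        assert shares[PhenotypeCode.P0_INVASIVE] == 60.61
        assert shares[PhenotypeCode.P3_NIPPV_FAILURE] == 5.76
        assert percentage(3501, 16809) == 20.83

    def test_summary_counts_partition_the_cohort(self):
        stays = [stay(f"S{i}") for i in range(6)]
        labels = [
            label("S0", PhenotypeCode.P0_INVASIVE),
            label("S1", PhenotypeCode.P0_INVASIVE),
            label("S2", PhenotypeCode.P1_NIPPV),
            label("S3", PhenotypeCode.P3_NIPPV_FAILURE),
            PhenotypeLabel("S4", PhenotypeCode.EXCLUDED, exclusion_reason=ExclusionReason.MINOR),
            label("S5", PhenotypeCode.P2_HFNI),
        ]
        summary = summarize_cohort(stays, labels)
        assert summary.total == 5  # excluded stay not counted
        assert sum(s.n for s in summary.per_phenotype.values()) == summary.total
        pcts = [s.pct_of_total for s in summary.per_phenotype.values()]
        assert math.isclose(sum(pcts), 100.0, abs_tol=0.05)

    def test_median_iqr_linear_interpolation(self):
        stays = [stay(f"S{i}", age=a) for i, a in enumerate([50, 60, 70, 80])]
        labels = [label(s.stay_id, PhenotypeCode.P1_NIPPV) for s in stays]
        s = summarize_cohort(stays, labels).per_phenotype[PhenotypeCode.P1_NIPPV]
        assert s.age_median == 65.0
        assert s.age_iqr == 15.0  # Q3 72.5 - Q1 57.5

    def test_single_stay_cohort(self):
        summary = summarize_cohort(
            [stay("S1", dead=True)], [label("S1", PhenotypeCode.P2_HFNI)]
        )
        s = summary.per_phenotype[PhenotypeCode.P2_HFNI]
        assert (s.pct_of_total, s.age_iqr, s.mortality_pct) == (100.0, 0.0, 100.0)

    def test_empty_cohort_no_division_by_zero(self):
        summary = summarize_cohort([], [])
        assert summary.total == 0 and summary.per_phenotype == {}


class TestFailureRates:
    def test_published_rates_reproduced(self, table2_counts):
        rates = failure_rates(table2_counts)
        assert rates == {"NIPPV": 19.4, "HFNI": 34.6}

    def test_accepts_label_sequences(self):
        labels = [label(f"S{i}", PhenotypeCode.P1_NIPPV) for i in range(8)] + [
            label(f"F{i}", PhenotypeCode.P3_NIPPV_FAILURE) for i in range(2)
        ]
        assert failure_rates(labels)["NIPPV"] == 20.0

    def test_zero_numerator(self):
        rates = failure_rates({PhenotypeCode.P1_NIPPV: 10})
        assert rates["NIPPV"] == 0.0

    def test_zero_denominator_reported_missing(self):
        rates = failure_rates({PhenotypeCode.P0_INVASIVE: 10})
        assert rates["NIPPV"] is None and rates["HFNI"] is None


class TestSampleForValidation:
    def _labels(self, sizes):
        out = []
        for code, n in sizes.items():
            out.extend(label(f"{code.value}-{i}", code) for i in range(n))
        return out

    def test_ceiling_sample_sizes_per_class(self):
        labels = self._labels(
            {PhenotypeCode.P0_INVASIVE: 100, PhenotypeCode.P6_INVASIVE_TO_HFNI: 188}
        )
        sampled = sample_for_validation(labels, fraction=0.05, seed=0)
        by_class = {
            code: sum(1 for s in sampled if s.startswith(code.value))
            for code in (PhenotypeCode.P0_INVASIVE, PhenotypeCode.P6_INVASIVE_TO_HFNI)
        }
        assert by_class[PhenotypeCode.P0_INVASIVE] == 5  # ceil(5.0)
        assert by_class[PhenotypeCode.P6_INVASIVE_TO_HFNI] == 10  # ceil(9.4)

    def test_fraction_one_takes_everything(self):
        labels = self._labels({PhenotypeCode.P1_NIPPV: 7})
        assert sorted(sample_for_validation(labels, 1.0, seed=3)) == sorted(
            l.stay_id for l in labels
        )

    def test_deterministic_given_seed_and_no_duplicates(self):
        labels = self._labels({PhenotypeCode.P0_INVASIVE: 50, PhenotypeCode.P2_HFNI: 30})
        a = sample_for_validation(labels, 0.2, seed=11)
        b = sample_for_validation(labels, 0.2, seed=11)
        assert a == b and len(set(a)) == len(a)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            sample_for_validation([], 0.0, seed=1)


class TestComputeValidationMetrics:
    def test_identity_predictions_score_perfectly(self):
        truth = {f"S{i}": code for i, code in enumerate(PHENOTYPES)}
        report = compute_validation_metrics(truth, dict(truth))
        assert report.accuracy == 1.0
        assert all(
            v["precision"] == v["recall"] == v["f1"] == 1.0
            for v in report.per_class.values()
        )

    def test_three_class_toy_confusion_matches_hand_oracle(self):
        """Confusion [[2,1,0],[0,3,0],[1,0,3]]: hand-enumerated TP/FP/FN.

        class a: TP 2, FP 1, FN 1 -> P 2/3, R 2/3
        class b: TP 3, FP 1, FN 0 -> P 3/4, R 1
        class c: TP 3, FP 0, FN 1 -> P 1,   R 3/4
        accuracy 8/10; macro-P (2/3+3/4+1)/3; micro = accuracy.
        """
        codes = [
            PhenotypeCode.P0_INVASIVE,
            PhenotypeCode.P1_NIPPV,
            PhenotypeCode.P2_HFNI,
        ]
        confusion = [[2, 1, 0], [0, 3, 0], [1, 0, 3]]
        truth, pred = {}, {}
        k = 0
        for i, t in enumerate(codes):
            for j, p in enumerate(codes):
                for _ in range(confusion[i][j]):
                    truth[f"S{k}"] = t
                    pred[f"S{k}"] = p
                    k += 1
        report = compute_validation_metrics(truth, pred)
        assert report.accuracy == pytest.approx(0.8)
        pc = report.per_class
        assert pc[codes[0].value]["precision"] == pytest.approx(2 / 3)
        assert pc[codes[0].value]["recall"] == pytest.approx(2 / 3)
        assert pc[codes[1].value]["precision"] == pytest.approx(3 / 4)
        assert pc[codes[1].value]["recall"] == pytest.approx(1.0)
        assert pc[codes[2].value]["precision"] == pytest.approx(1.0)
        assert pc[codes[2].value]["recall"] == pytest.approx(3 / 4)
        assert report.macro_precision == pytest.approx((2 / 3 + 3 / 4 + 1) / 3)
        assert report.micro_precision == pytest.approx(0.8)
        assert report.confusion.tolist() == confusion

    def test_micro_precision_equals_micro_recall_equals_accuracy(self):
        rng = np.random.default_rng(42)
        codes = list(PHENOTYPES)
        truth = {f"S{i}": codes[rng.integers(len(codes))] for i in range(200)}
        pred = {
            s: (c if rng.random() < 0.7 else codes[rng.integers(len(codes))])
            for s, c in truth.items()
        }
        report = compute_validation_metrics(truth, pred)
        assert report.micro_precision == pytest.approx(report.accuracy, abs=1e-12)
        assert report.micro_recall == pytest.approx(report.accuracy, abs=1e-12)

    def test_weighted_averages_bounded_by_class_extremes(self):
        rng = np.random.default_rng(7)
        codes = [PhenotypeCode.P0_INVASIVE, PhenotypeCode.P1_NIPPV, PhenotypeCode.P3_NIPPV_FAILURE]
        truth = {f"S{i}": codes[rng.integers(3)] for i in range(100)}
        pred = {
            s: (c if rng.random() < 0.6 else codes[rng.integers(3)])
            for s, c in truth.items()
        }
        report = compute_validation_metrics(truth, pred)
        recalls = [v["recall"] for v in report.per_class.values()]
        assert min(recalls) - 1e-12 <= report.weighted_recall <= max(recalls) + 1e-12

    def test_degenerate_single_class_predictions(self):
        truth = {
            "S1": PhenotypeCode.P0_INVASIVE,
            "S2": PhenotypeCode.P0_INVASIVE,
            "S3": PhenotypeCode.P1_NIPPV,
        }
        pred = {s: PhenotypeCode.P0_INVASIVE for s in truth}
        with pytest.warns(UserWarning, match="never predicted"):
            report = compute_validation_metrics(truth, pred)
        assert report.per_class[PhenotypeCode.P0_INVASIVE.value]["recall"] == 1.0
        assert report.per_class[PhenotypeCode.P1_NIPPV.value]["recall"] == 0.0
        assert report.per_class[PhenotypeCode.P1_NIPPV.value]["precision"] == 0.0

    def test_id_mismatch_is_fatal_and_lists_offenders(self):
        with pytest.raises(MetricsError, match="S2"):
            compute_validation_metrics(
                {"S1": PhenotypeCode.P0_INVASIVE, "S2": PhenotypeCode.P1_NIPPV},
                {"S1": PhenotypeCode.P0_INVASIVE},
            )
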