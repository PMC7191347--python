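"""Cohort descriptive statistics and multiclass validation metrics.

Two reporting surfaces:

* :func:`summarize_cohort` / :func:`phenotype_shares` / :func:`failure_rates`
  — per-phenotype counts, shares, median/IQR demographics and mortality,
  plus the derived noninvasive-failure rates
  (NIPPV failure / (NIPPV-only + NIPPV failure), and likewise for HFNI).
* :func:`compute_validation_metrics` — accuracy, per-class precision/
  recall/F1 and the micro, macro and support-weighted averages against a
  reference labeling (e.g. manual chart review or generator ground truth).
  Micro and macro variants are both reported explicitly because a
  "weighted average" alone is ambiguous.

Medians and quartiles use linear interpolation; IQR = Q3 - Q1.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    precision_recall_fscore_support,
)

from .ehr_model import PhenotypeCode, PhenotypeLabel, PatientStay, PHENOTYPES

__all__ = [
    "CohortSummary",
    "MetricsReport",
    "MetricsError",
    "summarize_cohort",
    "phenotype_shares",
    "percentage",
    "failure_rates",
    "sample_for_validation",
    "compute_validation_metrics",
]


class MetricsError(ValueError):
    """Mismatched stay-id sets between truth and predictions."""


def percentage(numerator: float, denominator: float, ndigits: int = 2) -> float | None:
    """Percent value rounded to *ndigits*; None for a zero denominator."""
    if denominator == 0:
        return None
    return round(100.0 * numerator / denominator, ndigits)


def _median_iqr(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        return (math.nan, math.nan)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])  # linear interpolation
    return float(med), float(q3 - q1)


# ---------------------------------------------------------------------------
# descriptive statistics
# ---------------------------------------------------------------------------


@dataclass
class PhenotypeSummary:
    n: int
    pct_of_total: float | None
    age_median: float
    age_iqr: float
    apache_median: float
    apache_iqr: float
    los_median: float
    los_iqr: float
    male_n: int
    male_pct: float | None
    ethnicity_n: dict[str, int]
    mortality_n: int
    mortality_pct: float | None


@dataclass
class CohortSummary:
    total: int
    per_phenotype: dict[PhenotypeCode, PhenotypeSummary] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for code, s in self.per_phenotype.items():
            rows.append(
                {
                    "phenotype": code.value,
                    "n": s.n,
                    "pct_of_total": s.pct_of_total,
                    "age_median": s.age_median,
                    "age_iqr": s.age_iqr,
                    "apache_median": s.apache_median,
                    "apache_iqr": s.apache_iqr,
                    "los_median": s.los_median,
                    "los_iqr": s.los_iqr,
                    "male_n": s.male_n,
                    "male_pct": s.male_pct,
                    "mortality_n": s.mortality_n,
                    "mortality_pct": s.mortality_pct,
                }
            )
        return pd.DataFrame(rows)


def summarize_cohort(
    stays: Sequence[PatientStay], labels: Sequence[PhenotypeLabel]
) -> CohortSummary:
    """Per-phenotype descriptive statistics over the included cohort.

    Within-phenotype percentages (gender, mortality) use the phenotype's n
    as denominator; ``pct_of_total`` uses the included-cohort total.
    Excluded stays are ignored. Empty cohorts give an empty summary.
    """
    by_stay = {s.stay_id: s for s in stays}
    assigned: dict[PhenotypeCode, list[PatientStay]] = {c: [] for c in PHENOTYPES}
    for label in labels:
        if label.code is PhenotypeCode.EXCLUDED:
            continue
        stay = by_stay.get(label.stay_id)
        if stay is None:
            raise MetricsError(f"label references unknown stay {label.stay_id!r}")
        assigned[label.code].append(stay)

    total = sum(len(v) for v in assigned.values())
    summary = CohortSummary(total=total)
    for code, members in assigned.items():
        if not members:
            continue
        n = len(members)
        age_med, age_iqr = _median_iqr([s.age_years for s in members])
        apache_values = [s.apache_score for s in members if s.apache_score is not None]
        apache_med, apache_iqr = _median_iqr(apache_values)
        los_med, los_iqr = _median_iqr([s.icu_los_days for s in members])
        male_n = sum(1 for s in members if s.gender.strip().lower() == "male")
        mortality_n = sum(1 for s in members if s.hospital_mortality)
        ethnicity_n = dict(Counter(s.ethnicity for s in members))
        summary.per_phenotype[code] = PhenotypeSummary(
            n=n,
            pct_of_total=percentage(n, total),
            age_median=age_med,
            age_iqr=age_iqr,
            apache_median=apache_med,
            apache_iqr=apache_iqr,
            los_median=los_med,
            los_iqr=los_iqr,
            male_n=male_n,
            male_pct=percentage(male_n, n),
            ethnicity_n=ethnicity_n,
            mortality_n=mortality_n,
            mortality_pct=percentage(mortality_n, n),
        )
    return summary


def _as_counts(
    labels_or_counts: Sequence[PhenotypeLabel] | Mapping[PhenotypeCode, int]
) -> Counter:
    if isinstance(labels_or_counts, Mapping):
        return Counter(
            {PhenotypeCode(k): int(v) for k, v in labels_or_counts.items()}
        )
    counts: Counter = Counter()
    for label in labels_or_counts:
        if label.code is not PhenotypeCode.EXCLUDED:
            counts[label.code] += 1
    return counts


def phenotype_shares(
    labels_or_counts: Sequence[PhenotypeLabel] | Mapping[PhenotypeCode, int],
    ndigits: int = 2,
) -> dict[PhenotypeCode, float]:
    """Each phenotype's share of the included cohort, in percent."""
    counts = _as_counts(labels_or_counts)
    total = sum(counts.values())
    if total == 0:
        return {}
    return {
        code: percentage(counts[code], total, ndigits)
        for code in PHENOTYPES
        if counts[code]
    }


def failure_rates(
    labels_or_counts: Sequence[PhenotypeLabel] | Mapping[PhenotypeCode, int],
    ndigits: int = 1,
) -> dict[str, float | None]:
    """Noninvasive-strategy failure rates, in percent (1 decimal).

    NIPPV rate = n(NIPPV failure) / (n(NIPPV only) + n(NIPPV failure));
    HFNI rate likewise. A zero denominator yields None.
    """
    counts = _as_counts(labels_or_counts)
    nippv_initiated = (
        counts[PhenotypeCode.P1_NIPPV] + counts[PhenotypeCode.P3_NIPPV_FAILURE]
    )
    hfni_initiated = (
        counts[PhenotypeCode.P2_HFNI] + counts[PhenotypeCode.P4_HFNI_FAILURE]
    )
    return {
        "NIPPV": percentage(
            counts[PhenotypeCode.P3_NIPPV_FAILURE], nippv_initiated, ndigits
        ),
        "HFNI": percentage(
            counts[PhenotypeCode.P4_HFNI_FAILURE], hfni_initiated, ndigits
        ),
    }


# ---------------------------------------------------------------------------
# validation sampling and metrics
# ---------------------------------------------------------------------------


def sample_for_validation(
    labels: Sequence[PhenotypeLabel], fraction: float, seed: int
) -> list[str]:
    """Stratified validation sample: ceil(fraction * n) stays per phenotype.

    Deterministic for a fixed seed; empty classes contribute nothing.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    by_class: dict[PhenotypeCode, list[str]] = {}
    for label in labels:
        if label.code is not PhenotypeCode.EXCLUDED:
            by_class.setdefault(label.code, []).append(label.stay_id)
    sampled: list[str] = []
    for code in PHENOTYPES:
        ids = sorted(by_class.get(code, []))
        if not ids:
            continue
        k = math.ceil(fraction * len(ids))
        sampled.extend(
            str(s) for s in rng.choice(ids, size=k, replace=False)
        )
    return sampled


@dataclass
class MetricsReport:
    labels: list[str]
    confusion: np.ndarray
    support: dict[str, int]
    accuracy: float
    per_class: dict[str, dict[str, float]]
    micro_precision: float
    micro_recall: float
    micro_f1: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float

    def as_dict(self) -> dict:
        return {
            "labels": self.labels,
            "confusion": self.confusion.tolist(),
            "support": self.support,
            "accuracy": self.accuracy,
            "per_class": self.per_class,
            "micro": {
                "precision": self.micro_precision,
                "recall": self.micro_recall,
                "f1": self.micro_f1,
            },
            "macro": {
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f1": self.macro_f1,
            },
            "weighted": {
                "precision": self.weighted_precision,
                "recall": self.weighted_recall,
                "f1": self.weighted_f1,
            },
        }

    def confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.confusion,
            index=pd.Index(self.labels, name="truth"),
            columns=pd.Index(self.labels, name="predicted"),
        )


def _label_map(
    labels: Sequence[PhenotypeLabel] | Mapping[str, PhenotypeCode]
) -> dict[str, str]:
    if isinstance(labels, Mapping):
        return {str(k): PhenotypeCode(v).value for k, v in labels.items()}
    out: dict[str, str] = {}
    for label in labels:
        out[label.stay_id] = label.code.value
    return out


def compute_validation_metrics(
    truth: Sequence[PhenotypeLabel] | Mapping[str, PhenotypeCode],
    predicted: Sequence[PhenotypeLabel] | Mapping[str, PhenotypeCode],
) -> MetricsReport:
    """Multiclass metrics of *predicted* against *truth*.

    Standard definitions: per-class precision TP/(TP+FP), recall
    TP/(TP+FN), F1 their harmonic mean; micro-averages pool TP/FP/FN over
    classes (and equal accuracy for exhaustive single-label output, an
    invariant asserted on every report); macro-averages weight classes
    equally; weighted averages weight by true-class support. Classes with
    no predicted positives get precision 0 with a warning.
    """
    truth_map = _label_map(truth)
    pred_map = _label_map(predicted)
    if set(truth_map) != set(pred_map):
        only_truth = sorted(set(truth_map) - set(pred_map))[:10]
        only_pred = sorted(set(pred_map) - set(truth_map))[:10]
        raise MetricsError(
            "truth/prediction stay-id sets differ; "
            f"only in truth: {only_truth}; only in predictions: {only_pred}"
        )
    if not truth_map:
        raise MetricsError("cannot compute metrics on an empty label set")

    ids = sorted(truth_map)
    y_true = [truth_map[i] for i in ids]
    y_pred = [pred_map[i] for i in ids]
    label_order = sorted(set(y_true) | set(y_pred))

    empty_pred = sorted(set(y_true) - set(y_pred))
    if empty_pred:
        warnings.warn(
            f"classes never predicted (precision defined as 0): {empty_pred}",
            stacklevel=2,
        )

    cm = confusion_matrix(y_true, y_pred, labels=label_order)
    accuracy = float(accuracy_score(y_true, y_pred))
    p, r, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=label_order, zero_division=0
    )
    per_class = {
        lab: {
            "precision": float(p[i]),
            "recall": float(r[i]),
            "f1": float(f1[i]),
            "support": int(support[i]),
        }
        for i, lab in enumerate(label_order)
    }
    averages = {}
    for avg in ("micro", "macro", "weighted"):
        ap, ar, af1, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=label_order, average=avg, zero_division=0
        )
        averages[avg] = (float(ap), float(ar), float(af1))

    report = MetricsReport(
        labels=label_order,
        confusion=cm,
        support={lab: int(s) for lab, s in zip(label_order, support)},
        accuracy=accuracy,
        per_class=per_class,
        micro_precision=averages["micro"][0],
        micro_recall=averages["micro"][1],
        micro_f1=averages["micro"][2],
        macro_precision=averages["macro"][0],
        macro_recall=averages["macro"][1],
        macro_f1=averages["macro"][2],
        weighted_precision=averages["weighted"][0],
        weighted_recall=averages["weighted"][1],
        weighted_f1=averages["weighted"][2],
    )
    # exhaustive single-label classification: pooled precision = pooled
    # recall = accuracy; row sums of the confusion matrix = class supports
    assert math.isclose(report.micro_precision, accuracy, abs_tol=1e-12)
    assert math.isclose(report.micro_recall, accuracy, abs_tol=1e-12)
    assert (cm.sum(axis=1) == np.array([support[i] for i in range(len(label_order))])).all()
    return report
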