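"""Derived rates from published per-phenotype cohort counts.

Feeds the published counts of a 27,734-patient ventilation cohort into
the summary machinery: phenotype shares, noninvasive-failure rates and
the attrition flow are all arithmetic consequences of the counts, so
they make a compact end-to-end check of the reporting code.
"""

from arfpheno import PhenotypeCode, failure_rates, phenotype_shares
from arfpheno.metrics_summary import percentage

counts = {
    PhenotypeCode.P0_INVASIVE: 16_809,
    PhenotypeCode.P1_NIPPV: 6_653,
    PhenotypeCode.P2_HFNI: 1_202,
    PhenotypeCode.P3_NIPPV_FAILURE: 1_597,
    PhenotypeCode.P4_HFNI_FAILURE: 636,
    PhenotypeCode.P5_INVASIVE_TO_NIPPV: 649,
    PhenotypeCode.P6_INVASIVE_TO_HFNI: 188,
}

total = sum(counts.values())
print(f"included patients: {total} "
      f"(= 139,367 total - 31,366 readmissions - 80,267 low-flow/no support)")

print("\nphenotype shares (% of included cohort):")
for code, share in phenotype_shares(counts).items():
    print(f"  {code.value:22} {counts[code]:>7,}  ({share}%)")

rates = failure_rates(counts)
print(f"\nNIPPV failure rate: {rates['NIPPV']}%  "
      f"(= {counts[PhenotypeCode.P3_NIPPV_FAILURE]:,} of "
      f"{counts[PhenotypeCode.P1_NIPPV] + counts[PhenotypeCode.P3_NIPPV_FAILURE]:,} "
      "patients started on NIPPV)")
print(f"HFNI failure rate:  {rates['HFNI']}%  "
      f"(= {counts[PhenotypeCode.P4_HFNI_FAILURE]:,} of "
      f"{counts[PhenotypeCode.P2_HFNI] + counts[PhenotypeCode.P4_HFNI_FAILURE]:,} "
      "patients started on HFNI)")
print(f"hospital mortality within the invasive phenotype: "
      f"{percentage(3_501, counts[PhenotypeCode.P0_INVASIVE])}%")
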