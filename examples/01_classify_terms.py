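"""Classify raw chart strings into ventilation modalities.

Runs the default lexicon over a handful of strings of the kind found in
tele-ICU treatment and nurse-chart tables, then shows the free-text
high-flow normalizer on observed spelling variants.
"""

from arfpheno import Source, classify_record_term, default_lexicon, normalize_hfni_variant

lexicon = default_lexicon()

terms = [
    ("Intubated/oral ETT", Source.NURSE_CHART),
    ("pulmonary|ventilation and oxygenation|non-invasive ventilation|face mask", Source.TREATMENT),
    ("BiPAP", Source.RESP_CHART),
    ("high-flow nasal insufflation", Source.NURSE_CHART),
    ("nasal cannula 2L", Source.NURSE_CHART),
    ("nasal cannula 40L", Source.NURSE_CHART),
    ("heart rate 88", Source.NURSE_CHART),
]

print("lexicon classification (precedence INVASIVE > NIPPV > HFNI > LOW_FLOW):")
for term, source in terms:
    modality = classify_record_term(term, source, lexicon)
    print(f"  {term!r:75} -> {modality.value}")

print("\nfree-text high-flow variants (oxygen-device field of nurse charts):")
for text in ["HFNC", "highflow n/c", "optiflow", "Vapotherm", "nasal cannula 2L", "nc 40 lpm"]:
    print(f"  {text!r:20} -> is high-flow: {normalize_hfni_variant(text)}")

# A flow of >= 15 L/min through a nasal cannula counts as high-flow support;
# below that it is conventional low-flow oxygen, which never qualifies a
# stay for the cohort.
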