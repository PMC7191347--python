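# Default ventilation-term lexicon.
#
# Each entry maps a pattern to a modality. match_mode is SUBSTRING or EXACT
# (both case-insensitive by default); sources restricts an entry to specific
# record tables (TREATMENT, MEDICATION, NURSE_CHART, RESP_CHART) and defaults
# to all. When several entries match one string the highest-precedence
# modality wins: INVASIVE > NIPPV > HFNI > LOW_FLOW. This mirrors the
# hierarchical treatment-path strings of tele-ICU exports, where a specific
# device name is appended to a broader therapy path.
case_sensitive: false
entries:
  # --- invasive mechanical ventilation -----------------------------------
  - {pattern: "intub", match_mode: SUBSTRING, modality: INVASIVE}
  - {pattern: "endotracheal", match_mode: SUBSTRING, modality: INVASIVE}
  - {pattern: "oral ett", match_mode: SUBSTRING, modality: INVASIVE}
  - {pattern: "nasal ett", match_mode: SUBSTRING, modality: INVASIVE}
  - {pattern: "tracheostomy ventilation", match_mode: SUBSTRING, modality: INVASIVE}

  # --- noninvasive positive-pressure ventilation --------------------------
  - {pattern: "non-invasive ventilation", match_mode: SUBSTRING, modality: NIPPV}
  - {pattern: "noninvasive ventilation", match_mode: SUBSTRING, modality: NIPPV}
  - {pattern: "noninvasive positive pressure", match_mode: SUBSTRING, modality: NIPPV}
  - {pattern: "nippv", match_mode: SUBSTRING, modality: NIPPV}
  - {pattern: "bipap", match_mode: SUBSTRING, modality: NIPPV}
  - {pattern: "bi-pap", match_mode: SUBSTRING, modality: NIPPV}
  - {pattern: "cpap", match_mode: SUBSTRING, modality: NIPPV}
  - {pattern: "face mask ventilation", match_mode: SUBSTRING, modality: NIPPV}

  # --- high-flow nasal insufflation ---------------------------------------
  - {pattern: "hfni", match_mode: SUBSTRING, modality: HFNI}
  - {pattern: "hfnc", match_mode: SUBSTRING, modality: HFNI}
  - {pattern: "high flow", match_mode: SUBSTRING, modality: HFNI}
  - {pattern: "high-flow", match_mode: SUBSTRING, modality: HFNI}
  - {pattern: "highflow", match_mode: SUBSTRING, modality: HFNI}
  - {pattern: "hi flow", match_mode: SUBSTRING, modality: HFNI}
  - {pattern: "hiflow", match_mode: SUBSTRING, modality: HFNI}
  - {pattern: "nasal insufflation", match_mode: SUBSTRING, modality: HFNI}
  - {pattern: "optiflow", match_mode: SUBSTRING, modality: HFNI}
  - {pattern: "airvo", match_mode: SUBSTRING, modality: HFNI}
  - {pattern: "vapotherm", match_mode: SUBSTRING, modality: HFNI}

  # --- conventional low-flow oxygen (< 15 L/min) ---------------------------
  - {pattern: "nasal cannula", match_mode: SUBSTRING, modality: LOW_FLOW}
  - {pattern: "ventimask", match_mode: SUBSTRING, modality: LOW_FLOW}
  - {pattern: "venti-mask", match_mode: SUBSTRING, modality: LOW_FLOW}
  - {pattern: "venturi mask", match_mode: SUBSTRING, modality: LOW_FLOW}
  - {pattern: "nonrebreather", match_mode: SUBSTRING, modality: LOW_FLOW}
  - {pattern: "non-rebreather", match_mode: SUBSTRING, modality: LOW_FLOW}
  - {pattern: "nonrebreathing mask", match_mode: SUBSTRING, modality: LOW_FLOW}
  - {pattern: "simple mask", match_mode: SUBSTRING, modality: LOW_FLOW}
  - {pattern: "face tent", match_mode: SUBSTRING, modality: LOW_FLOW}
  - {pattern: "oxygen therapy", match_mode: SUBSTRING, modality: LOW_FLOW}
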