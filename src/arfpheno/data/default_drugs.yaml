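# Peri-intubation medication lexicon used to corroborate invasive
# mechanical ventilation: rapid-sequence-intubation agents, neuromuscular
# blockers, and continuous sedatives. Matched case-insensitively as
# substrings of medication.drug_name.
drugs:
  - etomidate
  - ketamine
  - propofol
  - succinylcholine
  - rocuronium
  - vecuronium
  - cisatracurium
  - midazolam infusion
  - fentanyl infusion
  - dexmedetomidine
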