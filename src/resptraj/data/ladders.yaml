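# Guideline-derived treatment-intensity ladders, keyed by canonical event
# labels ('+' joins loose combinations alphabetically; fixed-combination
# inhalers such as LABA-ICS are atomic tokens).
#
# These defaults encode the step structure of the GINA (asthma) and GOLD
# (COPD) guidelines at drug-class granularity.  They are data, not code:
# review and override them per study.  `levels` maps exact labels to a step;
# `contains_levels` assigns a step to any label containing the named class
# (checked only when the exact label is absent; the maximum applies).
asthma:
  levels:
    SABA: 1
    SAMA: 1
    SABA-SAMA: 1
    SABA+SAMA: 1
    ICS: 2
    LTRA: 2
    ICS+SABA: 2
    LTRA+SABA: 2
    LABA-ICS: 3
    ICS+LTRA: 3
    ICS+LABA: 3
    LABA-ICS+SABA: 3
    LABA-LAMA-ICS: 4
    LABA-ICS+LTRA: 4
    LABA-ICS+LAMA: 4
    ICS+LABA+LTRA: 4
  contains_levels:
    biologics: 5
    steroid_maintenance: 5
copd:
  levels:
    SABA: 1
    SAMA: 1
    SABA-SAMA: 1
    SABA+SAMA: 1
    LABA: 2
    LAMA: 2
    LABA+SABA: 2
    LAMA+SABA: 2
    LAMA+SAMA: 2
    LABA-LAMA: 3
    LABA+LAMA: 3
    LABA-ICS: 3
    ICS+LABA: 3
    LABA-LAMA-ICS: 4
    LABA-ICS+LAMA: 4
    ICS+LABA-LAMA: 4
    ICS+LABA+LAMA: 4
  contains_levels:
    PDE4: 5
    xanthines: 5
    steroid_maintenance: 5
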