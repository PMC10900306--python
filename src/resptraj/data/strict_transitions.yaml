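# Strict guideline transition sets: (first-line label, follow-up label)
# pairs accepted as conforming to a literal reading of the GINA / GOLD
# escalation and de-escalation recommendations at drug-class level.
#
# Guideline conformance computed from these sets is meaningful only after
# study-specific review: edit these files to your guideline reading before
# interpreting the numbers.
asthma:
  - [SABA, ICS]
  - [SABA, LABA-ICS]
  - [ICS, LABA-ICS]
  - [ICS, ICS+LTRA]
  - [LABA-ICS, LABA-LAMA-ICS]
  - [LABA-ICS, LABA-ICS+LTRA]
  - [LABA-ICS, ICS]
  - [LABA-LAMA-ICS, LABA-ICS]
  - [ICS+LTRA, ICS]
copd:
  - [SABA, LABA]
  - [SABA, LAMA]
  - [SAMA, LABA]
  - [SAMA, LAMA]
  - [SABA-SAMA, LABA]
  - [SABA-SAMA, LAMA]
  - [LABA, LABA-LAMA]
  - [LAMA, LABA-LAMA]
  - [LABA-LAMA, LABA-LAMA-ICS]
  - [LABA-ICS, LABA-LAMA-ICS]
  - [LABA-LAMA-ICS, LABA-LAMA]
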