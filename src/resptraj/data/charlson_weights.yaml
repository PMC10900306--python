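# Classic Charlson Comorbidity Index weights, keyed by the condition concept
# labels used in the condition_occurrence table.  Configurable per run.
myocardial_infarction: 1
heart_failure: 1
peripheral_vascular_disease: 1
cerebrovascular_disease: 1
dementia: 1
chronic_pulmonary_disease: 1
rheumatic_disease: 1
peptic_ulcer_disease: 1
mild_liver_disease: 1
diabetes_mellitus: 1
diabetes_with_complications: 2
hemiplegia: 2
renal_disease: 2
malignancy: 2
moderate_severe_liver_disease: 3
metastatic_solid_tumour: 6
aids: 6
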