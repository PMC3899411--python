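# Default underlying-cause categories for PD multiple-cause extrapolation.
# Each entry maps a category name to comma-separated ICD-10 block ranges;
# "other" is the implicit complement of the named categories.
ischemic_heart_disease: I20-I25
malignant_neoplasm: C00-C75
cerebrovascular_disease: I60-I69
pneumonia: J10-J18
parkinsons_disease: G20
other: ""
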