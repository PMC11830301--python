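# Default ICD-10 code sets for phenotype definition.
#
# psychotic_mdd follows the register definition F32.3/F33.3.  An alternative
# set including F32.2 (psychotic_mdd_f322: F32.2/F32.3) is shipped because
# some summaries describe psychotic MDD via the F32.2/F32.3 sub-codes; the
# default is NOT resolved silently -- pick explicitly via configuration.
mdd:
  icd10: [F32, F33]
psychotic_mdd:
  icd10: [F32.3, F33.3]
psychotic_mdd_f322:
  icd10: [F32.2, F32.3]
severe_nonpsychotic_mdd:
  icd10: [F32.2, F33.2]
bd:
  icd10: [F30, F31]
scz_sad:
  icd10: [F20, F25]
# psychotic disorders other than SCZ/SAD: F2x excluding F20 and F25
other_psychotic:
  icd10: [F21, F22, F23, F24, F28, F29]
all_psychotic:
  icd10: [F20, F21, F22, F23, F24, F25, F28, F29]
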