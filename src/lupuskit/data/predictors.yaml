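# Variant-effect predictor panel and raw-scale orientations.
# orientation: true  -> larger raw score means more damaging
#              false -> smaller (more negative) raw score means more damaging
orientation:
  DeepSequence: false   # delta-ELBO style; more negative = more damaging
  VARITY_R: true
  VARITY_ER: true
  ESM-1v: false         # masked-LM log-likelihood ratio; more negative = more damaging
  MetaRNN: true
  ClinPred: true
  REVEL: true
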