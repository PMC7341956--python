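# Accessory / regulator gene catalog used by the operon neighbourhood
# inventory. Categories are disjoint; symbols are matched case-insensitively
# after synonym normalisation (see symbol_synonyms).
categories:
  cofactor:           [nifX, nifE, nifN, nifB, nifV]   # FeMoco synthesis
  accessory:          [nifQ, nifZ, nifU, nifS, nifW]
  regulators:         [nifA, nifL]
  post_translational: [draG, draT, glnB]               # glnB = PII family
  Mo_transport:       [modA, modB]
  ROS:                [katG, rdrA, dfx]
  electron:           [rnfA, rnfB, rnfC, rnfD, rnfE, fixA, fixB]
# Case-insensitive synonym map applied before catalog/cluster matching.
symbol_synonyms:
  pii: glnB
  "anfh/nifh": anfH
  nifh-like: nifH
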