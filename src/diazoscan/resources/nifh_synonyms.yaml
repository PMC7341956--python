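# Per-system identifiers accepted as labels for the nitrogenase iron protein
# family (nifH and the alternative-nitrogenase H genes anfH/vnfH, which are
# nifH homologs). The annotation systems name the family differently; these
# sets are the configurable vocabulary the consensus caller matches against.
KO:
  - K02588   # nifH, nitrogenase iron protein
  - K22899   # anfH, Fe-only nitrogenase iron protein
  - K22897   # vnfH, V-nitrogenase iron protein
PFAM:
  - PF00142  # Fer4_NifH, 4Fe-4S iron sulfur cluster binding (NifH/frxC family)
COG:
  - COG1348  # NifH, nitrogenase subunit NifH
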