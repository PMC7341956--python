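# Pathway definitions for completeness scoring. The marker-gene lists are
# editable reconstructions assembled from standard references for each
# pathway; each entry notes its provenance. Completeness is
# |present| / |required| over the listed symbols.
pathways:
  chlorosome:
    name: Chlorosome and bacteriochlorophyll c/d biosynthesis
    provenance: >
      Core chlorosome envelope protein plus the bacteriochlorophyll c/d
      branch of the (bacterio)chlorophyll pathway as characterised in green
      sulfur bacteria; bciC (EC 3.1.1.100) is the chlorophyllide c-forming
      hydrolase step.
    genes: [csmA, csmB, csmC, bchK, bchU, bchV, bchQ, bchR, bchE, bchJ, bciB, bciC]
  rtca:
    name: Reductive tricarboxylic acid (rTCA) cycle
    provenance: >
      Key reversible TCA steps plus the three rTCA-diagnostic enzymes
      (ATP-citrate lyase, 2-oxoglutarate and pyruvate ferredoxin
      oxidoreductases).
    genes: [aclA, aclB, korA, korB, porA, porB, frdA, fumA, mdh, sucC, sucD]
  wood_ljungdahl:
    name: Wood-Ljungdahl (reductive acetyl-CoA) pathway
    provenance: >
      Carbonyl branch (CO dehydrogenase / acetyl-CoA synthase complex) and
      methyl branch (formate -> methyl-THF) marker genes.
    genes: [acsA, acsB, acsC, acsD, acsE, fhs, folD, metF, fdhA]
  sulfate_reduction:
    name: Dissimilatory sulfate reduction
    provenance: >
      dsrAB (dissimilatory sulfite reductase, reversible; alone it supports
      sulfide oxidation) plus the activation steps sat and aprAB needed for
      the full sulfate-reducing pathway.
    genes: [dsrA, dsrB, sat, aprA, aprB]
  methylotrophy:
    name: Methylotrophy (C1 oxidation)
    provenance: Particulate methane monooxygenase and methanol dehydrogenases.
    genes: [pmoA, mdh1, mxaF]
  rnf:
    name: Rnf complex (ferredoxin:NAD+ oxidoreductase)
    provenance: Membrane H+/Na+-translocating electron transfer complex.
    genes: [rnfA, rnfB, rnfC, rnfD, rnfE]
  ros_protection:
    name: Oxidative stress protection
    provenance: Catalase-peroxidase, rubrerythrin and desulfoferrodoxin.
    genes: [katG, rdrA, dfx]
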