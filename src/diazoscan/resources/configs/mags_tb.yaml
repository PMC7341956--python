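# MAG collection fixture: fifteen genomes carrying a complete, consensus-
# annotated Mo-nitrogenase (nifHDK) cluster -- four Chlorobi (two of which
# additionally carry an Fe-only retroelement cluster or a V cluster), one
# Acidobacteria, one Sulfurimonas, two Verrucomicrobia, two Methylococcales,
# three Deltaproteobacteria and two Betaproteobacteria -- plus five decoys:
# a conflicted three-system annotation, a partial cluster, a cluster split
# by a long gap, a below-threshold identity call, and a chlL-like gene with
# no true nitrogenase.
name: mags_tb
genome_length: 40000
genomes:
  - {id: chlorobi_I,        lineage: Chlorobi,           template: mo_delta}
  - {id: chlorobi_II,       lineage: Chlorobi,           template: mo_delta}
  - {id: chlorobi_III,      lineage: Chlorobi,           template: mo, extra_template: fe_only_retro}
  - {id: chlorobi_IV,       lineage: Chlorobi,           template: mo, extra_template: v}
  - {id: acidobacteria_I,   lineage: Acidobacteria,      template: mo_cofactor}
  - {id: sulfurimonas_I,    lineage: Sulfurimonas,       template: mo}
  - {id: verrucomicrobia_I, lineage: Verrucomicrobia,    template: mo_mod}
  - {id: verrucomicrobia_II, lineage: Verrucomicrobia,   template: mo_mod}
  - {id: methylococcales_I, lineage: Methylococcales,    template: mo_gamma, genome_length: 48000}
  - {id: methylococcales_II, lineage: Methylococcales,   template: mo_gamma, genome_length: 48000}
  - {id: geobacter_I,       lineage: Geobacter,          template: mo_cofactor}
  - {id: desulfobacterales_I, lineage: Desulfobacterales, template: mo_delta}
  - {id: desulfobacterales_II, lineage: Desulfobacterales, template: mo_delta}
  - {id: betaproteobacteria_I, lineage: Betaproteobacteria, template: mo_beta}
  - {id: betaproteobacteria_II, lineage: Betaproteobacteria, template: mo_beta}
  - {id: decoy_conflicted,  lineage: Chloroflexi,        template: mo, conflict_labels: true}
  - {id: decoy_partial,     lineage: Bacteroidetes,      template: mo_partial, nifh_identity: 93.0}
  - {id: decoy_split,       lineage: Planctomycetes,     template: mo_split, nifh_identity: 94.0}
  - {id: decoy_lowid,       lineage: Firmicutes,         template: mo, nifh_identity: 92.0}
  - {id: decoy_chll,        lineage: Cyanobacteria,      template: chll_only}
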