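# Three-year hypolimnion series fixture for the phylotype read-count
# filter: eight designed diazotroph groups accumulate 54-150 nifH reads
# each summed across the 24 samples, while a ninth minor taxon
# (Spirochaetia, 21 reads) stays at or below the 50-read threshold.
# Seasonal composition shifts from Proteobacteria-rich spring samples to
# Chlorobi-dominated summer samples within each year.
name: hypo_multiyear
library_size: 5000
read_length: 200
error_rate: 0.002
emit_reads: true
layers: [hypolimnion]
dates: [15MAY07, 01JUN07, 17JUN07, 03JUL07, 19JUL07, 04AUG07, 20AUG07, 10SEP07, 15MAY08, 01JUN08, 17JUN08, 03JUL08, 19JUL08, 04AUG08, 20AUG08, 10SEP08, 15MAY09, 01JUN09, 17JUN09, 03JUL09, 19JUL09, 04AUG09, 20AUG09, 10SEP09]
planted:
  hypolimnion:
    15MAY07: {Chlorobi: 1, Geobacter: 6, Desulfobacterales: 5, Methylococcales: 4, Acidobacteria: 3, Betaproteobacteria: 4, Verrucomicrobia: 3, Sulfurimonas: 4, Spirochaetia: 1}
    01JUN07: {Chlorobi: 2, Geobacter: 5, Desulfobacterales: 5, Methylococcales: 4, Acidobacteria: 3, Betaproteobacteria: 4, Verrucomicrobia: 3, Sulfurimonas: 3, Spirochaetia: 1}
    17JUN07: {Chlorobi: 6, Geobacter: 4, Desulfobacterales: 4, Methylococcales: 4, Acidobacteria: 3, Betaproteobacteria: 3, Verrucomicrobia: 3, Sulfurimonas: 3, Spirochaetia: 1}
    03JUL07: {Chlorobi: 9, Geobacter: 3, Desulfobacterales: 3, Methylococcales: 3, Acidobacteria: 3, Betaproteobacteria: 2, Verrucomicrobia: 2, Sulfurimonas: 2, Spirochaetia: 1}
    19JUL07: {Chlorobi: 11, Geobacter: 2, Desulfobacterales: 2, Methylococcales: 3, Acidobacteria: 3, Betaproteobacteria: 2, Verrucomicrobia: 2, Sulfurimonas: 2, Spirochaetia: 1}
    04AUG07: {Chlorobi: 10, Geobacter: 2, Desulfobacterales: 2, Methylococcales: 2, Acidobacteria: 3, Betaproteobacteria: 2, Verrucomicrobia: 2, Sulfurimonas: 2, Spirochaetia: 1}
    20AUG07: {Chlorobi: 8, Geobacter: 2, Desulfobacterales: 2, Methylococcales: 2, Acidobacteria: 2, Betaproteobacteria: 2, Verrucomicrobia: 2, Sulfurimonas: 1, Spirochaetia: 1}
    10SEP07: {Chlorobi: 3, Geobacter: 3, Desulfobacterales: 2, Methylococcales: 2, Acidobacteria: 2, Betaproteobacteria: 1, Verrucomicrobia: 2, Sulfurimonas: 1}
    15MAY08: {Chlorobi: 1, Geobacter: 6, Desulfobacterales: 5, Methylococcales: 4, Acidobacteria: 3, Betaproteobacteria: 4, Verrucomicrobia: 3, Sulfurimonas: 4, Spirochaetia: 1}
    01JUN08: {Chlorobi: 2, Geobacter: 5, Desulfobacterales: 5, Methylococcales: 4, Acidobacteria: 3, Betaproteobacteria: 4, Verrucomicrobia: 3, Sulfurimonas: 3, Spirochaetia: 1}
    17JUN08: {Chlorobi: 6, Geobacter: 4, Desulfobacterales: 4, Methylococcales: 4, Acidobacteria: 3, Betaproteobacteria: 3, Verrucomicrobia: 3, Sulfurimonas: 3, Spirochaetia: 1}
    03JUL08: {Chlorobi: 9, Geobacter: 3, Desulfobacterales: 3, Methylococcales: 3, Acidobacteria: 3, Betaproteobacteria: 2, Verrucomicrobia: 2, Sulfurimonas: 2, Spirochaetia: 1}
    19JUL08: {Chlorobi: 11, Geobacter: 2, Desulfobacterales: 2, Methylococcales: 3, Acidobacteria: 3, Betaproteobacteria: 2, Verrucomicrobia: 2, Sulfurimonas: 2, Spirochaetia: 1}
    04AUG08: {Chlorobi: 10, Geobacter: 2, Desulfobacterales: 2, Methylococcales: 2, Acidobacteria: 3, Betaproteobacteria: 2, Verrucomicrobia: 2, Sulfurimonas: 2, Spirochaetia: 1}
    20AUG08: {Chlorobi: 8, Geobacter: 2, Desulfobacterales: 2, Methylococcales: 2, Acidobacteria: 2, Betaproteobacteria: 2, Verrucomicrobia: 2, Sulfurimonas: 1, Spirochaetia: 1}
    10SEP08: {Chlorobi: 3, Geobacter: 3, Desulfobacterales: 2, Methylococcales: 2, Acidobacteria: 2, Betaproteobacteria: 1, Verrucomicrobia: 2, Sulfurimonas: 1}
    15MAY09: {Chlorobi: 1, Geobacter: 6, Desulfobacterales: 5, Methylococcales: 4, Acidobacteria: 3, Betaproteobacteria: 4, Verrucomicrobia: 3, Sulfurimonas: 4, Spirochaetia: 1}
    01JUN09: {Chlorobi: 2, Geobacter: 5, Desulfobacterales: 5, Methylococcales: 4, Acidobacteria: 3, Betaproteobacteria: 4, Verrucomicrobia: 3, Sulfurimonas: 3, Spirochaetia: 1}
    17JUN09: {Chlorobi: 6, Geobacter: 4, Desulfobacterales: 4, Methylococcales: 4, Acidobacteria: 3, Betaproteobacteria: 3, Verrucomicrobia: 3, Sulfurimonas: 3, Spirochaetia: 1}
    03JUL09: {Chlorobi: 9, Geobacter: 3, Desulfobacterales: 3, Methylococcales: 3, Acidobacteria: 3, Betaproteobacteria: 2, Verrucomicrobia: 2, Sulfurimonas: 2, Spirochaetia: 1}
    19JUL09: {Chlorobi: 11, Geobacter: 2, Desulfobacterales: 2, Methylococcales: 3, Acidobacteria: 3, Betaproteobacteria: 2, Verrucomicrobia: 2, Sulfurimonas: 2, Spirochaetia: 1}
    04AUG09: {Chlorobi: 10, Geobacter: 2, Desulfobacterales: 2, Methylococcales: 2, Acidobacteria: 3, Betaproteobacteria: 2, Verrucomicrobia: 2, Sulfurimonas: 2, Spirochaetia: 1}
    20AUG09: {Chlorobi: 8, Geobacter: 2, Desulfobacterales: 2, Methylococcales: 2, Acidobacteria: 2, Betaproteobacteria: 2, Verrucomicrobia: 2, Sulfurimonas: 1, Spirochaetia: 1}
    10SEP09: {Chlorobi: 3, Geobacter: 3, Desulfobacterales: 2, Methylococcales: 2, Acidobacteria: 2, Betaproteobacteria: 1, Verrucomicrobia: 2, Sulfurimonas: 1}
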