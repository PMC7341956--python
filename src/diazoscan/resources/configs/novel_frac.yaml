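# Novel-lineage fixture: four hypolimnion samples with ~500 nitrogenase
# reads each, of which 10 in total (~0.5%) come from a lineage absent from
# both reference tiers (its closest reference relative is an uncultured
# environmental nifH clone without taxonomy in tier 2).
name: novel_frac
library_size: 20000
read_length: 200
error_rate: 0.002
emit_reads: true
layers: [hypolimnion]
dates: [D1, D2, D3, D4]
planted:
  hypolimnion:
    D1: {Chlorobi: 300, Geobacter: 100, Methylococcales: 97}
    D2: {Chlorobi: 300, Geobacter: 100, Methylococcales: 97}
    D3: {Chlorobi: 300, Geobacter: 100, Methylococcales: 97}
    D4: {Chlorobi: 300, Geobacter: 100, Methylococcales: 97}
novel_planted:
  hypolimnion: {D1: 3, D2: 3, D3: 2, D4: 2}
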