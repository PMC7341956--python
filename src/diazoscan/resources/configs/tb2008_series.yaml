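# Two-layer 2008 season fixture: 8 dates x {epilimnion, hypolimnion} with
# the study's environmental table and explicit planted consensus-nifH read
# counts. The per-layer maximum of 3 planted reads in a 10,000-read library
# puts the per-sample nitrogenase frequency ceiling at 0.030% in both
# layers. Composition follows the seasonal narrative: Proteobacteria after
# spring mixing, Chlorobi under summer stratification. decoy_planted reads
# come from a chlL-like gene with conflicted annotations and must be
# excluded by the consensus filter.
name: tb2008_series
library_size: 10000
read_length: 200
error_rate: 0.002
emit_reads: true
layers: [epilimnion, hypolimnion]
dates: [29MAY08, 13JUN08, 24JUN08, 08JUL08, 22JUL08, 05AUG08, 19AUG08, 19SEP08]
env:
  - {date: 29MAY08, layer: epilimnion, TN_ppb: 575,  TP_ppb: 19,  TDN_ppb: 479,  TDP_ppb: 12}
  - {date: 13JUN08, layer: epilimnion, TN_ppb: 551,  TP_ppb: 23,  TDN_ppb: 447,  TDP_ppb: 11}
  - {date: 24JUN08, layer: epilimnion, TN_ppb: 629,  TP_ppb: 31,  TDN_ppb: 417,  TDP_ppb: 15}
  - {date: 08JUL08, layer: epilimnion, TN_ppb: 678,  TP_ppb: 134, TDN_ppb: 548,  TDP_ppb: 109}
  - {date: 22JUL08, layer: epilimnion, TN_ppb: 1187, TP_ppb: 61,  TDN_ppb: 1019, TDP_ppb: 38}
  - {date: 05AUG08, layer: epilimnion, TN_ppb: 758,  TP_ppb: 38,  TDN_ppb: 509,  TDP_ppb: 17}
  - {date: 19AUG08, layer: epilimnion, TN_ppb: 865,  TP_ppb: 46,  TDN_ppb: 585,  TDP_ppb: 22}
  - {date: 19SEP08, layer: epilimnion, TN_ppb: 679,  TP_ppb: 40,  TDN_ppb: null, TDP_ppb: null}
  - {date: 29MAY08, layer: hypolimnion, TN_ppb: 1049, TP_ppb: 43, TDN_ppb: 456,   TDP_ppb: 15}
  - {date: 13JUN08, layer: hypolimnion, TN_ppb: 1152, TP_ppb: 49, TDN_ppb: 987,   TDP_ppb: 35}
  - {date: 24JUN08, layer: hypolimnion, TN_ppb: 1140, TP_ppb: 53, TDN_ppb: 853,   TDP_ppb: 35}
  - {date: 08JUL08, layer: hypolimnion, TN_ppb: 1161, TP_ppb: 63, TDN_ppb: 999,   TDP_ppb: 42}
  - {date: 22JUL08, layer: hypolimnion, TN_ppb: 684,  TP_ppb: 36, TDN_ppb: 527,   TDP_ppb: 15}
  - {date: 05AUG08, layer: hypolimnion, TN_ppb: 1152, TP_ppb: 57, TDN_ppb: 895,   TDP_ppb: 34}
  - {date: 19AUG08, layer: hypolimnion, TN_ppb: 1117, TP_ppb: 65, TDN_ppb: 1024.5, TDP_ppb: 45}
  - {date: 19SEP08, layer: hypolimnion, TN_ppb: 1513, TP_ppb: 60, TDN_ppb: null,  TDP_ppb: null}
planted:
  epilimnion:
    29MAY08: {Betaproteobacteria: 1}
    13JUN08: {Chlorobi: 1}
    24JUN08: {Chlorobi: 1, Betaproteobacteria: 1}
    08JUL08: {}
    22JUL08: {Chlorobi: 2, Betaproteobacteria: 1}
    05AUG08: {Chlorobi: 2}
    19AUG08: {Chlorobi: 1, Betaproteobacteria: 1}
    19SEP08: {Chlorobi: 1}
  hypolimnion:
    29MAY08: {}
    13JUN08: {Geobacter: 1, Desulfobacterales: 1}
    24JUN08: {Methylococcales: 1, Geobacter: 1}
    08JUL08: {Chlorobi: 2, Sulfurimonas: 1}
    22JUL08: {Chlorobi: 1}
    05AUG08: {Chlorobi: 2, Acidobacteria: 1}
    19AUG08: {Chlorobi: 1, Verrucomicrobia: 1}
    19SEP08: {Chlorobi: 2}
decoy_planted:
  epilimnion: {29MAY08: 1, 24JUN08: 1, 22JUL08: 1}
  hypolimnion: {13JUN08: 1, 08JUL08: 1, 19AUG08: 1}
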