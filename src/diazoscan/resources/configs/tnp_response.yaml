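# Quadratic nutrient-response generator: per-sample expected nitrogenase
# frequency follows fmax * (1 - ((TN:TP - vertex)/width)^2) with binomial
# counting noise at a 10^6-read library, over a TN:TP design grid spanning
# the vertex. Counts-only mode: no read sequences are materialised.
name: tnp_response
library_size: 1000000
read_length: 200
error_rate: 0.0
emit_reads: false
mode: response
layers: [epilimnion, hypolimnion]
dates: []
ratios: [6, 8, 10, 12, 14, 16, 18, 20, 22, 24, 26, 28, 30, 32, 34]
tp_ppb: 50.0
response:
  vertex: 20.0
  width: 18.0
  fmax_pct: 0.03
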