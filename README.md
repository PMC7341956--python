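# diazoscan

Profiling potential nitrogen fixers (diazotrophs) in metagenomic data from
stratified lakes: from unassembled reads and annotated reference genomes to
nifH relative-abundance time series, phylotype composition, nitrogenase
operon architecture, and energy-metabolism pathway completeness.

Non-cyanobacterial diazotrophs in the dark, seasonally anoxic bottom waters
(hypolimnion) of humic lakes are easy to miss with PCR-based surveys.
`diazoscan` implements a direct-sequencing workflow for them:

1. **Read recruitment** — each metagenomic read is assigned to at most one
   reference nitrogenase gene by a deterministic ungapped seed-and-extend
   aligner (seeds of length *k* = 11 on both strands; match +1 / mismatch −2;
   Karlin–Altschul significance *E = K·m·n·e^(−λS)* with λ = 1.28,
   *K* = 0.46). A local MAG-derived tier is searched first, with fallback to
   a global reference tier; hits must satisfy *E* ≤ 10⁻²⁰ and identity ≥ 95%,
   and ties break by highest identity, then lowest e-value.
2. **Annotation consensus** — a gene counts as *nifH* only when all three
   annotation systems (KO, Pfam, COG) agree; if any system points to a
   different function the gene is *conflicted* and every read recruited to
   it is excluded. Nitrogenase-positive MAGs additionally need ≥ 95%
   supporting identity, and phylotypes are kept only when their
   series-summed read count exceeds 50.
3. **Abundance** — per-sample relative nitrogenase frequency
   (100 × hits / library size, in % of reads), taxon composition, TN:TP
   mass ratios, and a per-layer degree-2 least-squares fit of frequency
   against TN:TP with its turning point x\* = −b/(2a).
4. **Operon architecture** — nitrogenase gene clusters are detected by
   neighbourhood chaining (gap ≤ 2 kb, ≤ 2 intervening genes), typed as
   Mo (*nifHDK*), V (*vnfHGDK*) or Fe-only (*anfH* + *anfOKGD*),
   inventoried for accessory/regulator genes, and screened for
   retroelement signatures (reverse transcriptase + endopeptidase CDS with
   direct/inverted repeats flanking the cluster).
5. **Pathway completeness** — per-genome fractions of required marker genes
   for chlorosome biosynthesis, rTCA, Wood–Ljungdahl, dissimilatory sulfate
   reduction, methylotrophy, the Rnf complex and ROS protection, with
   explicit missing-gene reporting.

A first-class synthetic-data generator (`diazoscan.synthgen`) emulates the
two-layer multi-year lake study design — eight diazotroph phylotypes plus
background, seasonal composition shifts, a quadratic TN:TP response, and
planted nif/vnf/anf operons with retroelement features — and emits a truth
object with every dataset, so the entire pipeline is testable offline.

## Worked example

Run the packaged two-layer 2008 season fixture end to end:

```python
from diazoscan.pipeline import RunConfig, run_series

summary = run_series(RunConfig(config="tb2008_series", seed=1))
print(summary["max_frequency_pct"])
print(summary["total_nifh_hits"], summary["excluded_conflicted_hits"])
print(round(summary["fits"]["hypolimnion"]["vertex"], 2))
```

prints

```
{'epilimnion': 0.03, 'hypolimnion': 0.03}
27 6
18.95
```

meaning: across 16 samples (8 dates × 2 layers, 10,000 reads each) the
per-sample nitrogenase frequency peaks at 0.030% of the library in both
layers; 27 reads were retained as consensus nifH hits while 6 reads
recruiting to a conflicted chlL-like gene were excluded; and the
hypolimnion frequency–TN:TP quadratic turns over near a TN:TP ratio of 19.

The same pipeline is available from the shell:

```
diazoscan run --config tb2008_series --seed 1 --out out/
diazoscan simulate --config novel_frac --seed 1 --out sim/
diazoscan mags --seed 1
```

Subcommands `recruit`, `consensus`, `abundance`, `operon` and `pathways`
expose the individual stages on standard FASTA/GFF3/TSV inputs.

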