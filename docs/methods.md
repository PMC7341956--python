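# Methods

## Scope and model

`diazoscan` treats diazotroph profiling as a counting problem over
marker-gene read recruitment. The quantity of interest per sample is the
relative nitrogenase frequency, 100 × (reads assigned to consensus nifH
genes) / (library size), reported in percent of reads. Everything else —
phylotype composition, the nutrient response, operon typing, pathway
completeness — is derived from the same recruitment and annotation layers.

## Read recruitment

The built-in aligner is an ungapped seed-and-extend engine chosen for
determinism and offline testability; the backend is intentionally small and
fully specified so e-values are reproducible to the last bit:

- seeds: exact k-mers, k = 11, taken from both strands of the read and
  looked up in a per-tier subject index; alignments are reported on the
  subject's forward frame (merged reads are unoriented);
- scoring: match +1, mismatch −2; on each seeded diagonal the
  maximal-scoring contiguous segment is taken (a Kadane scan; ties resolve
  to the smallest start, then the smallest end, so results are
  order-independent);
- significance: Karlin–Altschul E = K·m·n·e^(−λS) with the ungapped DNA
  constants λ = 1.28, K = 0.46, where m is the read length and n the summed
  length of the subject genes in the searched tier (the simplest defensible
  effective database size). The exponent is evaluated in log space and
  clamped to ±745 so extreme scores yield a positive floor instead of
  underflowing to zero;
- cutoffs: E ≤ 10⁻²⁰ and identity ≥ 95%, applied identically in both tiers.
  The identity threshold is unified as ≥ 95.0 for reads and for MAG gene
  evidence; the boundary convention is configurable;
- tie-break: highest identity, then lowest e-value, then lexicographically
  smallest gene id — at most one assignment per read;
- tiering: the local (MAG-derived) tier is searched first; the global tier
  only when nothing passes locally. Reads shorter than k or containing
  ambiguous bases are skipped and counted in the summary.

Any alignment able to pass both cutoffs must contain an exact 11-mer (at
95% identity the longest exact run in an alignment long enough to clear the
e-value bar exceeds 11), so seeding loses no passing hits; the test suite
checks the engine against a seed-free brute-force enumerator on small
instances. A consequence of the e-value cutoff worth noting: very short
error-free reads (e.g. 2k bp) cannot reach E ≤ 10⁻²⁰, so the 100%-recall
property of planted reads holds at the generator's read length (200 bp),
not at arbitrarily short lengths.

The recruitment database holds nitrogenase-family gene sequences (plus
known confounders such as chlL/bchL-like genes) rather than whole genomes:
only nifH-family hits are ever counted, so recruiting against non-nif
genome regions would change nothing while dominating the runtime.

## Annotation consensus

A gene is consensus nifH only when KO, Pfam and COG all label it as a
nitrogenase iron protein (the shipped synonym sets include the alternative
nitrogenase H genes anfH/vnfH, which are nifH homologs). A gene with at
least one nifH label and at least one label pointing elsewhere is
conflicted, and all reads recruited to it are excluded — the
partition (retained / conflicted / non-nif) is checked to reconcile
exactly. Genes with incomplete label coverage whose present labels agree on
nifH are neither consensus nor conflicted: absence of a label is not "a
different function". MAGs are nitrogenase-positive when they contain at
least one consensus nifH gene with ≥ 95% supporting identity; phylotypes
are retained when their series-summed read count strictly exceeds 50
("exceeds", so 50 itself fails).

## Abundance and the nutrient response

TN:TP is the mass ratio of total nitrogen to total phosphorus (both in
ppb); rows with a missing nutrient get no ratio. The frequency–TN:TP
relationship is modelled as a degree-2 polynomial fitted by ordinary least
squares on the Vandermonde design, independently per layer; degree 2 is the
minimal model with a single turning point, which is the vertex
x\* = −b/(2a), a maximum when a < 0. Fits require ≥ 4 points and ≥ 3
distinct x values; |a| < 10⁻¹² is treated as effectively linear and the
vertex reported as undefined.

## Operon architecture

Cluster detection seeds at nitrogenase-family genes and chains catalog
genes (family + accessory/regulator catalog) while consecutive members are
≤ 2,000 bp apart with ≤ 2 intervening non-catalog genes. The distance rule
is a package default (configurable): nif neighbourhoods are near-contiguous
in practice, but no numeric chaining rule is standard in the literature. Strand agreement is reported,
never enforced — real nif neighbourhoods mix strands. Typing is a pure
function of the member symbol set: Mo needs nifH+nifD+nifK; Fe-only needs
anfH plus ≥ 3 of anfO/anfK/anfG/anfD; V needs vnfH plus ≥ 2 of
vnfG/vnfD/vnfK; otherwise partial. Symbols are normalised case-insensitively
through a shipped synonym table (e.g. PII ≡ glnB).

Repeat detection reports exact maximal repeats (≥ 20 bp, direct and
inverted) with one arm in the left flank ∪ cluster and the other in the
cluster ∪ right flank (flanks 5 kb, clipped at sequence ends); degenerate
repeats are out of scope. At these lengths chance repeats in background
sequence are vanishingly rare (~4 × 10⁸ candidate pairs × 4⁻²⁰ per 20 kb
region). A retroelement verdict requires a reverse-transcriptase CDS, an
endopeptidase CDS, and at least one repeat pair whose arms flank the
cluster span; an AAA-type ATPase is recorded as supporting evidence only —
this is the implementable reading of a "retrotransposon-like" neighbourhood,
since no quantitative published definition exists. Synteny between two
clusters is a greedy best-bidirectional matching on ungapped alignment
identity, expressed relative to the shorter gene so short chance matches
score near zero; pairs below 70% are dropped. Cluster comparisons are
emitted as machine-readable tables; figure rendering is out of scope.

## Pathway completeness

Each pathway is a set of required marker symbols in an editable YAML
resource; completeness is |present| / |required| and missing genes are
listed explicitly (narrative labels such as "incomplete" are avoided —
fractions are testable). The shipped lists are reconstructions assembled
for this package (chlorosome biosynthesis with 12 symbols including bciC,
rTCA, Wood–Ljungdahl, dissimilatory sulfate reduction, methylotrophy, rnf,
ROS protection), each carrying a provenance note, and can be overridden.

## Synthetic data generator

The generator emulates the study design the pipeline targets: a two-layer
(epilimnion/hypolimnion) seasonal series with eight diazotroph phylotypes
(Chlorobi, Acidobacteria, Beta-proteobacteria, Verrucomicrobia,
Sulfurimonas, Geobacter, Desulfobacterales, Methylococcales) plus a rare
ninth taxon and non-diazotroph background. Design choices:

- reads are fixed-length (default 200 bp, the typical merged-read length),
  substitution-only (default rate 0.002/bp), with uniform start positions
  inside source genes — the analysis is count-based, so indels and quality
  profiles would add no test value;
- background sequence is i.i.d. uniform A/C/G/T: the simplest null that
  cannot produce a chance 95%-identity hit at 200 bp;
- per-sample planted counts are explicit in the packaged configs; library
  sizes are free parameters of the design, and the packaged values —
  10,000 reads/sample for the two-layer season, 5,000 for the multi-year
  series, 20,000 for the novel-lineage fixture — are package choices, with
  planted ceilings set so the per-sample frequency maximum is 0.030% in
  both layers of the season fixture;
- the nutrient-response config draws per-sample nifH counts from a binomial
  around f(r) = f_max·(1 − ((r − 20)/18)²) on a TN:TP grid spanning 6–34,
  at a counts-only library of 10⁶ reads; binomial counting noise is the
  configured noise model;
- one tier-2 reference entry is an "uncultured environmental clone": full
  three-system nifH labels but no taxonomy, as in real reference
  collections. The novel-lineage gene is a 2%-diverged copy of it and is
  absent from both tiers, so its reads recruit as nifH but remain
  taxonomically unclassified;
- every dataset is accompanied by a truth object and is byte-identical
  under a fixed seed (per-stream generators are derived from the seed and
  stable name hashes).

What the generator does **not** emulate: indels and chimeras, realistic
error/quality profiles, GC heterogeneity and repeat families in background
genomes, assembly/binning artefacts, and inter-annual community drift
beyond the configured mixing matrices. Passing tests therefore demonstrate
the correctness of the counting, filtering and detection logic under the
stated read model — not robustness to real-data artefacts upstream of it.

## Problem sizes and numerical conventions

The packaged fixtures are sized for interactive runs on one CPU: the
two-layer season fixture processes 160,000 reads end to end in ~15 s, the
three-year hypolimnion series 120,000 reads, the novel-lineage fixture
80,000; the nutrient-response study runs 100 seeds in ~1 s (counts-only).
Ties everywhere are resolved deterministically (documented sort keys);
percentages are used for frequencies throughout and noted in every output
header; coordinates are 1-based inclusive end-to-end, with explicit
converters to 0-based half-open.

## Known limitations

- The aligner is ungapped; an indel-containing read aligns as its best
  ungapped segment and may fall below the identity/e-value bar.
- Protein-space (BLASTp-style) MAG evidence is modelled at the label level
  (per-gene identity evidence supplied with annotations), not recomputed
  from sequence.
- Pathway gene lists are curated defaults, not an authority; real analyses
  should review them per study system.
- The retroelement verdict is rule-based evidence integration, not mobile
  element classification.
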