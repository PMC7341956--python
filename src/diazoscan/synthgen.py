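"""Synthetic reference genomes, read libraries and sample series.

The generator emulates the study design the pipeline is built for: a small
stratified humic lake sampled in two layers (epilimnion / hypolimnion)
across a season, with roughly eight diazotroph phylotypes plus a
non-diazotroph background, seasonal composition shifts (Proteobacteria
after spring mixing, Chlorobi under summer stratification), a quadratic
response of nitrogenase gene frequency to the TN:TP ratio, and planted
nif/vnf/anf operons with accessory genes and retroelement features.

The read model is deliberately simple -- fixed-length reads, substitution
errors only, uniform start positions -- because the downstream analysis is
count-based; background sequence is i.i.d. uniform A/C/G/T, the simplest
null that cannot produce a chance 95%-identity hit at 200 bp. Every output
is deterministic in the seed, and a machine-readable truth object
accompanies every dataset.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io_formats import FeatureTable, GeneFeature
from .recruit import ReferenceTier, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: reserved planting keys that are not regular reference taxa
DECOY_KEY = "__decoy__"
NOVEL_KEY = "__novel__"

#: the eight main phylotype groups of the emulated hypolimnion community
DIAZOTROPH_TAXA = (
    "Chlorobi",
    "Acidobacteria",
    "Betaproteobacteria",
    "Verrucomicrobia",
    "Sulfurimonas",
    "Geobacter",
    "Desulfobacterales",
    "Methylococcales",
)
#: a genuine but rare diazotroph that stays below the phylotype filter
MINOR_TAXON = "Spirochaetia"
#: taxa whose reference genes live only in the global (tier 2) collection
TIER2_TAXA = ("Sulfurimonas",)

H_GENE_LENGTH = 900


class ConfigError(ValueError):
    pass


class SizingError(ValueError):
    pass


class IntegrityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# label vocabulary

#: symbol -> (KO, PFAM, COG) labels used by the synthetic annotator.
LABELS: dict[str, tuple[str, str, str]] = {
    "nifH": ("K02588", "PF00142", "COG1348"),
    "anfH": ("K22899", "PF00142", "COG1348"),
    "vnfH": ("K22897", "PF00142", "COG1348"),
    "nifD": ("K02586", "PF00148", "COG2710"),
    "nifK": ("K02591", "PF00148", "COG1429"),
    "anfD": ("K22896", "PF00148", "COG2710"),
    "anfK": ("K22898", "PF00148", "COG1429"),
    "anfG": ("K22900", "PF03139", "COG5420"),
    "anfO": ("K22901", "PF07065", "COG5421"),
    "vnfD": ("K22894", "PF00148", "COG2710"),
    "vnfK": ("K22895", "PF00148", "COG1429"),
    "vnfG": ("K22893", "PF03139", "COG5420"),
}

#: labels of a chlL/bchL-like decoy: two systems say nifH-family, COG points
#: to the protochlorophyllide reductase -- a conflicted annotation.
CONFLICT_LABELS = ("K02588", "PF00142", "COG2710")


def _generic_labels(symbol: str) -> tuple[str, str, str]:
    h = zlib.crc32(symbol.encode())
    return (
        f"K{10000 + h % 80000:05d}",
        f"PF{1000 + h % 9000:05d}",
        f"COG{2000 + h % 3000:04d}",
    )


def labels_for(symbol: str) -> tuple[str, str, str]:
    return LABELS.get(symbol, _generic_labels(symbol))


# ---------------------------------------------------------------------------
# sequence helpers

def derive_rng(seed: int, *tokens: str | int) -> np.random.Generator:
    """Deterministic child generator for a named stream under one seed."""
    extras = [zlib.crc32(str(t).encode()) for t in tokens]
    return np.random.default_rng(np.random.SeedSequence([int(seed), *extras]))


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=n, p=p)
    return _BASES[codes].tobytes().decode()


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitution-only mutation at the given per-base rate."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    idx = np.flatnonzero(hit)
    if idx.size:
        cur = np.searchsorted(_BASES, arr[idx])  # ACGT are sorted bytes
        arr[idx] = _BASES[(cur + rng.integers(1, 4, size=idx.size)) % 4]
    return arr.tobytes().decode()


def _substitute_n(seq: str, n_sub: int, rng: np.random.Generator) -> str:
    if n_sub <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    idx = rng.choice(arr.size, size=min(n_sub, arr.size), replace=False)
    cur = np.searchsorted(_BASES, arr[idx])
    arr[idx] = _BASES[(cur + rng.integers(1, 4, size=idx.size)) % 4]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class TaxonSpec:
    taxon_id: str
    lineage_label: str
    diazotroph: bool
    operon_template_id: str | None = None
    genome_length: int = 40_000

    def __post_init__(self) -> None:
        if self.diazotroph != (self.operon_template_id is not None):
            raise ConfigError(
                f"{self.taxon_id}: diazotroph flag and operon template must agree"
            )
        if self.genome_length < 20_000:
            raise ConfigError(f"{self.taxon_id}: genome_length must be >= 20,000 bp")


@dataclass(frozen=True)
class RepeatSpec:
    kind: str  # 'direct' or 'inverted'
    arm_length: int = 25
    left_offset: int = 300  # bp upstream of the cluster span for arm 1
    right_offset: int = 250  # bp downstream of the template span for arm 2


@dataclass(frozen=True)
class OperonTemplate:
    """Ordered gene layout of one nitrogenase cluster (plus companions)."""

    template_id: str
    genes: tuple[tuple[str, int, str, int], ...]  # (symbol, length, strand, gap_after)
    type_label: str  # Mo / V / Fe-only / partial
    accessory_symbols: frozenset[str] = frozenset()
    retroelement: bool = False
    repeats: tuple[RepeatSpec, ...] = ()

    def __post_init__(self) -> None:
        symbols = {g[0] for g in self.genes}
        required = {
            "Mo": {"nifH", "nifD", "nifK"},
            "Fe-only": {"anfH", "anfO", "anfK", "anfG", "anfD"},
            "V": {"vnfH", "vnfG", "vnfD", "vnfK"},
            "partial": set(),
        }[self.type_label]
        if not required <= symbols:
            raise ConfigError(
                f"template {self.template_id}: {self.type_label} requires {required}"
            )
        if self.retroelement and not self.repeats:
            raise ConfigError(
                f"template {self.template_id}: retroelement templates need repeat specs"
            )

    @property
    def span(self) -> int:
        return sum(length + gap for _, length, _, gap in self.genes)


_GL = {
    "nifH": 900, "anfH": 900, "vnfH": 900,
    "nifD": 1450, "anfD": 1450, "vnfD": 1450,
    "nifK": 1550, "anfK": 1550, "vnfK": 1550,
    "anfG": 350, "vnfG": 350, "anfO": 750,
    "nifB": 1000, "nifE": 1450, "nifN": 1400, "nifX": 450, "nifV": 1100,
    "nifQ": 600, "nifZ": 450, "nifU": 850, "nifS": 1150, "nifW": 350,
    "nifA": 1550, "nifL": 1400,
    "draG": 900, "draT": 850, "glnB": 350,
    "modA": 750, "modB": 700,
    "katG": 2150, "rdrA": 550, "dfx": 400,
    "rnfA": 600, "rnfB": 900, "rnfC": 1300, "rnfD": 950, "rnfE": 700,
    "RT": 1200, "endopeptidase": 700, "AAA-ATPase": 900, "chlL": 880,
}


def _genes(symbols: Sequence[str], gap: int = 60) -> tuple:
    out = []
    for i, sym in enumerate(symbols):
        strand = "+" if sym not in ("nifA", "nifL") else "-"
        out.append((sym, _GL.get(sym, 800), strand, gap))
    return tuple(out)


def _template(tid, symbols, type_label, retro=False, gaps=None, **kw):
    genes = list(_genes(symbols))
    if gaps:
        genes = [
            (s, ln, st, gaps.get(s, gp)) for (s, ln, st, gp) in genes
        ]
    return OperonTemplate(
        template_id=tid,
        genes=tuple(genes),
        type_label=type_label,
        retroelement=retro,
        repeats=(RepeatSpec("direct"), RepeatSpec("inverted", left_offset=150, right_offset=120))
        if retro
        else (),
        **kw,
    )


#: registry of packaged cluster layouts
TEMPLATES: dict[str, OperonTemplate] = {
    "mo": _template("mo", ["nifH", "nifD", "nifK"], "Mo"),
    "mo_cofactor": _template(
        "mo_cofactor", ["nifH", "nifD", "nifK", "nifB", "nifE", "nifN"], "Mo"
    ),
    "mo_gamma": _template(
        "mo_gamma",
        ["nifH", "nifD", "nifK", "nifE", "nifN", "nifB",
         "nifQ", "nifZ", "nifU", "nifS", "nifW", "nifA", "nifL",
         "rnfA", "rnfB", "rnfC", "rnfD", "rnfE"],
        "Mo",
    ),
    "mo_beta": _template(
        "mo_beta",
        ["nifH", "nifD", "nifK", "nifB", "nifE", "nifN",
         "nifQ", "nifZ", "nifW", "modA", "modB", "draG", "draT",
         "katG", "rdrA", "dfx"],
        "Mo",
    ),
    "mo_delta": _template(
        "mo_delta",
        ["nifH", "nifD", "nifK", "glnB", "draG", "draT",
         "rnfA", "rnfB", "rnfC", "rnfD", "rnfE"],
        "Mo",
    ),
    "mo_mod": _template(
        "mo_mod", ["nifH", "nifD", "nifK", "modA", "modB", "draG", "draT"], "Mo"
    ),
    "fe_only_retro": _template(
        "fe_only_retro",
        ["anfH", "anfO", "anfK", "anfG", "anfD", "RT", "endopeptidase", "AAA-ATPase"],
        "Fe-only",
        retro=True,
        gaps={"anfD": 400},
    ),
    "v": _template("v", ["vnfH", "vnfG", "vnfD", "vnfK"], "V"),
    "mo_partial": _template("mo_partial", ["nifH", "nifD"], "partial"),
    "mo_split": _template(
        "mo_split", ["nifH", "nifD", "nifK"], "Mo", gaps={"nifH": 12_000}
    ),
    "chll_only": _template("chll_only", ["chlL"], "partial"),
}

_PRODUCTS = {
    "RT": "reverse transcriptase",
    "endopeptidase": "retroelement endopeptidase",
    "AAA-ATPase": "AAA-type ATPase",
    "chlL": "nifH-like (chlL) protochlorophyllide reductase iron protein",
}

_HOUSEKEEPING = ("rpoB", "gyrA", "recA", "dnaK", "ftsZ", "secY")


@dataclass
class Genome:
    genome_id: str
    lineage: str
    sequence: str
    table: FeatureTable
    annotations: pd.DataFrame
    truth: dict

    @property
    def symbols(self) -> list[str]:
        return [f.product.split(" ")[0] if f.product else "" for f in self.table]


def build_genome(
    spec: TaxonSpec,
    template: OperonTemplate | Sequence[OperonTemplate] | None,
    seed: int,
    conflict_labels: bool = False,
    nifh_identity: float | None = None,
    gene_sequences: Mapping[str, str] | None = None,
) -> Genome:
    """Random background genome with the operon template(s) planted.

    Every planted gene receives three annotation labels; housekeeping decoy
    genes are scattered near the genome ends. The returned truth fragment
    records all planted coordinates and repeat arms.
    """
    templates: list[OperonTemplate] = []
    if template is not None:
        templates = list(template) if isinstance(template, (list, tuple)) else [template]
    total_span = sum(t.span for t in templates)
    if total_span >= spec.genome_length / 2:
        raise SizingError(
            f"{spec.taxon_id}: template span {total_span} exceeds half the genome"
        )

    rng = derive_rng(seed, "genome", spec.taxon_id)
    seq = np.frombuffer(random_dna(rng, spec.genome_length).encode(), np.uint8).copy()

    features: list[GeneFeature] = []
    ann_rows: list[dict] = []
    truth: dict = {"genome_id": spec.taxon_id, "clusters": [], "repeats": []}
    gene_counter = 0
    seen_ids: set[str] = set()

    def add_gene(symbol: str, pos0: int, length: int, strand: str,
                 labels: tuple[str, str, str], identity: float | None) -> GeneFeature:
        nonlocal gene_counter
        gene_counter += 1
        gene_id = f"{spec.taxon_id}_g{gene_counter:03d}"
        if gene_id in seen_ids:
            raise IntegrityError(f"duplicate gene id {gene_id}")
        seen_ids.add(gene_id)
        if gene_sequences and symbol in gene_sequences:
            gseq = gene_sequences[symbol]
            length = len(gseq)
        else:
            gseq = random_dna(rng, length)
        if strand == "-":
            gseq = revcomp(gseq)
        seq[pos0 : pos0 + length] = np.frombuffer(gseq.encode(), np.uint8)
        product = _PRODUCTS.get(symbol, symbol)
        feat = GeneFeature(
            gene_id=gene_id,
            scaffold_id=spec.taxon_id,
            start=pos0 + 1,
            end=pos0 + length,
            strand=strand,
            product=product,
            labels=dict(zip(("KO", "PFAM", "COG"), labels)),
        )
        features.append(feat)
        ann_rows.append(
            {
                "gene_id": gene_id,
                "symbol": symbol,
                "ko_label": labels[0],
                "pfam_label": labels[1],
                "cog_label": labels[2],
                "product": product,
                "identity_pct": identity if identity is not None else np.nan,
            }
        )
        return feat

    # housekeeping decoys near both genome ends
    cursor = 600
    for sym in _HOUSEKEEPING[:3]:
        add_gene(sym, cursor, 800, "+", labels_for(sym), None)
        cursor += 1100
    cursor = spec.genome_length - 3600
    for sym in _HOUSEKEEPING[3:]:
        add_gene(sym, cursor, 800, "-", labels_for(sym), None)
        cursor += 1100

    h_family = {"nifH", "anfH", "vnfH", "chlL"}
    nif_family = set(_GL) - {"RT", "endopeptidase", "AAA-ATPase", "chlL"}
    cursor = 5000
    for tmpl in templates:
        cluster_gene_ids = []
        first_start = cursor
        for symbol, length, strand, gap in tmpl.genes:
            labels = labels_for(symbol)
            if symbol == "chlL" or (conflict_labels and symbol in h_family):
                labels = CONFLICT_LABELS
            identity = None
            if symbol in nif_family or symbol == "chlL":
                identity = float(np.round(96.5 + rng.uniform(0, 3), 1))
                if nifh_identity is not None and (symbol in h_family):
                    identity = nifh_identity
            feat = add_gene(symbol, cursor, length, strand, labels, identity)
            cluster_gene_ids.append(feat.gene_id)
            cursor = feat.end + gap
        last_end = cursor
        truth["clusters"].append(
            {
                "template_id": tmpl.template_id,
                "type": tmpl.type_label,
                "gene_ids": cluster_gene_ids,
                "span": [first_start + 1, last_end],
            }
        )
        if tmpl.retroelement:
            for rspec in tmpl.repeats:
                arm = random_dna(rng, rspec.arm_length)
                p1 = first_start - rspec.left_offset - rspec.arm_length
                p2 = last_end + rspec.right_offset
                arm2 = arm if rspec.kind == "direct" else revcomp(arm)
                seq[p1 : p1 + rspec.arm_length] = np.frombuffer(arm.encode(), np.uint8)
                seq[p2 : p2 + rspec.arm_length] = np.frombuffer(arm2.encode(), np.uint8)
                _break_repeat_extension(seq, p1, p2, rspec.arm_length, rspec.kind)
                truth["repeats"].append(
                    {
                        "kind": rspec.kind,
                        "arm1": [p1 + 1, p1 + rspec.arm_length],
                        "arm2": [p2 + 1, p2 + rspec.arm_length],
                        "length": rspec.arm_length,
                    }
                )
        cursor += 4000
        if cursor > spec.genome_length - 4500:
            raise SizingError(f"{spec.taxon_id}: operon layout exceeds genome bounds")

    table = FeatureTable(
        scaffold_id=spec.taxon_id, length=spec.genome_length, features=features
    )
    annotations = pd.DataFrame(ann_rows)
    return Genome(
        genome_id=spec.taxon_id,
        lineage=spec.lineage_label,
        sequence=seq.tobytes().decode(),
        table=table,
        annotations=annotations,
        truth=truth,
    )


_COMP_CODE = {65: 84, 84: 65, 67: 71, 71: 67}


def _break_repeat_extension(seq: np.ndarray, p1: int, p2: int, length: int, kind: str) -> None:
    """Force mismatches just outside both planted arms so the detected
    maximal repeat has exactly the planted coordinates."""
    def differ(i: int, j: int, complement: bool) -> None:
        if not (0 <= i < seq.size and 0 <= j < seq.size):
            return
        target = _COMP_CODE[int(seq[j])] if complement else int(seq[j])
        if int(seq[i]) == target:
            choices = [b for b in (65, 67, 71, 84) if b != target]
            seq[i] = choices[0]

    if kind == "direct":
        differ(p1 - 1, p2 - 1, False)
        differ(p1 + length, p2 + length, False)
    else:
        # outward: seq[p1-1] vs comp(seq[p2+length]); inward: seq[p1+length]
        # vs comp(seq[p2-1])
        differ(p1 - 1, p2 + length, True)
        differ(p1 + length, p2 - 1, True)


# ---------------------------------------------------------------------------
# reference panel (recruitment database + its annotations)

class ReferencePanel:
    """Reference nitrogenase gene panel backing read recruitment.

    Tier 1 holds the local MAG-derived genes (plus a conflicted chlL-like
    decoy); tier 2 the global collection, including taxa missing from the
    local assembly and an uncultured environmental clone that carries full
    nifH labels but no taxonomy. A "novel lineage" gene diverged 2% from the
    environmental clone exists outside both tiers, for planting reads from
    a taxon the references do not contain.
    """

    DECOY_GENE = "bchL_decoy"
    ENV_CLONE = "env_nifH_clone_1"
    NOVEL = "novel_lineage"

    def __init__(self, seed: int):
        self.seed = int(seed)
        self.genes: dict[str, str] = {}
        self.taxon_of: dict[str, str | None] = {}
        tier1_ids, tier2_ids = [], []
        for taxon in (*DIAZOTROPH_TAXA, MINOR_TAXON):
            rng = derive_rng(self.seed, "panel", taxon)
            gene_id = f"{taxon}_nifH"
            self.genes[gene_id] = random_dna(rng, H_GENE_LENGTH)
            self.taxon_of[gene_id] = taxon
            (tier2_ids if taxon in TIER2_TAXA else tier1_ids).append(gene_id)
        rng = derive_rng(self.seed, "panel", self.DECOY_GENE)
        self.genes[self.DECOY_GENE] = random_dna(rng, _GL["chlL"])
        self.taxon_of[self.DECOY_GENE] = None
        tier1_ids.append(self.DECOY_GENE)
        rng = derive_rng(self.seed, "panel", self.ENV_CLONE)
        self.genes[self.ENV_CLONE] = random_dna(rng, H_GENE_LENGTH)
        self.taxon_of[self.ENV_CLONE] = None
        tier2_ids.append(self.ENV_CLONE)
        rng = derive_rng(self.seed, "panel", self.NOVEL)
        self.novel_gene = mutate(self.genes[self.ENV_CLONE], 0.02, rng)
        self._tier1_ids = tier1_ids
        self._tier2_ids = tier2_ids

    def tiers(self) -> list[ReferenceTier]:
        return [
            ReferenceTier(
                tier=1,
                genes={g: self.genes[g] for g in self._tier1_ids},
                taxa={g: self.taxon_of[g] for g in self._tier1_ids},
            ),
            ReferenceTier(
                tier=2,
                genes={g: self.genes[g] for g in self._tier2_ids},
                taxa={g: self.taxon_of[g] for g in self._tier2_ids},
            ),
        ]

    def annotations(self) -> pd.DataFrame:
        rows = []
        for gene_id in sorted(self.genes):
            if gene_id == self.DECOY_GENE:
                ko, pf, cog = CONFLICT_LABELS
            else:
                ko, pf, cog = labels_for("nifH")
            rows.append(
                {
                    "gene_id": gene_id,
                    "ko_label": ko,
                    "pfam_label": pf,
                    "cog_label": cog,
                }
            )
        return pd.DataFrame(rows)

    def read_source(self, key: str) -> str:
        if key == DECOY_KEY:
            return self.genes[self.DECOY_GENE]
        if key == NOVEL_KEY:
            return self.novel_gene
        gene_id = f"{key}_nifH"
        if gene_id not in self.genes:
            raise ConfigError(f"unknown planting taxon {key!r}")
        return self.genes[gene_id]


# ---------------------------------------------------------------------------
# series configuration

@dataclass
class SeriesConfig:
    name: str
    layers: list[str]
    dates: list[str]
    library_size: int
    read_length: int = 200
    error_rate: float = 0.002
    emit_reads: bool = True
    mode: str = "explicit"  # 'explicit' planted counts or quadratic 'response'
    planted: dict[str, dict[str, dict[str, int]]] = field(default_factory=dict)
    decoy_planted: dict[str, dict[str, int]] = field(default_factory=dict)
    novel_planted: dict[str, dict[str, int]] = field(default_factory=dict)
    env_rows: list[dict] = field(default_factory=list)
    ratios: list[float] = field(default_factory=list)
    tp_ppb: float = 50.0
    response: dict[str, float] = field(default_factory=dict)
    gc: float = 0.5

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ConfigError("library_size must be positive")
        if not 0 <= self.error_rate < 0.05:
            raise ConfigError("error_rate must be in [0, 0.05)")
        if self.mode not in ("explicit", "response"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "response":
            if not self.ratios or not self.response:
                raise ConfigError("response mode needs ratios and response parameters")
            if not self.dates:
                self.dates = [f"S{i + 1:02d}" for i in range(len(self.ratios))]
            if len(self.dates) != len(self.ratios):
                raise ConfigError("dates and ratios length mismatch")
        for section in (self.planted, self.decoy_planted, self.novel_planted):
            for layer in section:
                if layer not in self.layers:
                    raise ConfigError(f"planted layer {layer!r} not in layers")
                for date in section[layer]:
                    if date not in self.dates:
                        raise ConfigError(f"planted date {date!r} not in dates")
        total_nifh = 0
        total_novel = 0
        for layer in self.layers:
            for date in self.dates:
                planted = sum(self.planted.get(layer, {}).get(date, {}).values())
                decoy = self.decoy_planted.get(layer, {}).get(date, 0)
                novel = self.novel_planted.get(layer, {}).get(date, 0)
                if min(planted, decoy, novel, 0) < 0:
                    raise ConfigError("planted counts must be non-negative")
                if planted + decoy + novel > self.library_size:
                    raise ConfigError(
                        f"{layer}/{date}: planted reads exceed library_size"
                    )
                total_nifh += planted + novel
                total_novel += novel
        if total_nifh and not 0 <= total_novel / total_nifh <= 0.05:
            raise ConfigError("novel lineage fraction must be within [0, 0.05]")

    @classmethod
    def from_yaml(cls, source: str | Path) -> "SeriesConfig":
        """Load a config from a path or a packaged config name."""
        path = Path(source)
        if path.exists():
            raw = yaml.safe_load(path.read_text())
        else:
            res = importlib_resources.files("diazoscan.resources.configs") / f"{source}.yaml"
            try:
                raw = yaml.safe_load(res.read_text())
            except FileNotFoundError:
                raise ConfigError(f"no such config file or packaged config: {source}")
        return cls(
            name=raw["name"],
            layers=list(raw["layers"]),
            dates=list(raw.get("dates", [])),
            library_size=int(raw["library_size"]),
            read_length=int(raw.get("read_length", 200)),
            error_rate=float(raw.get("error_rate", 0.002)),
            emit_reads=bool(raw.get("emit_reads", True)),
            mode=str(raw.get("mode", "explicit")),
            planted=raw.get("planted", {}),
            decoy_planted=raw.get("decoy_planted", {}),
            novel_planted=raw.get("novel_planted", {}),
            env_rows=raw.get("env", []),
            ratios=[float(r) for r in raw.get("ratios", [])],
            tp_ppb=float(raw.get("tp_ppb", 50.0)),
            response={k: float(v) for k, v in raw.get("response", {}).items()},
        )


@dataclass
class SampleResult:
    sample_id: str
    date: str
    layer: str
    library_size: int
    reads: list[tuple[str, str]] | None
    truth_counts: dict[str, int]


@dataclass
class SeriesResult:
    config_name: str
    seed: int
    samples: list[SampleResult]
    env: pd.DataFrame
    truth: dict


def simulate_library(
    sample_id: str,
    planted: Mapping[str, int],
    library_size: int,
    read_length: int,
    error_rate: float,
    panel: ReferencePanel,
    rng: np.random.Generator,
    gc: float = 0.5,
) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """One read library: planted nitrogenase reads + i.i.d. background.

    Planted reads are uniform windows of their source gene with binomial
    substitution errors; read ids encode the truth key. Returns exactly
    ``library_size`` reads plus the truth count fragment.
    """
    n_planted = sum(planted.values())
    if n_planted > library_size:
        raise ConfigError(f"{sample_id}: planted reads exceed library size")
    reads: list[tuple[str, str]] = []
    idx = 0
    truth: dict[str, int] = {}
    for key in sorted(planted):
        count = planted[key]
        if count <= 0:
            continue
        truth[key] = count
        src = panel.read_source(key)
        if len(src) < read_length:
            raise ConfigError(f"source gene for {key} shorter than read length")
        for _ in range(count):
            start = int(rng.integers(0, len(src) - read_length + 1))
            window = src[start : start + read_length]
            n_sub = int(rng.binomial(read_length, error_rate))
            window = _substitute_n(window, n_sub, rng)
            if int(rng.integers(0, 2)):
                window = revcomp(window)
            idx += 1
            reads.append((f"{sample_id}_r{idx:06d}|src={key}", window))
    n_bg = library_size - n_planted
    if n_bg:
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        codes = rng.choice(4, size=n_bg * read_length, p=p).astype(np.uint8)
        blob = _BASES[codes].tobytes().decode()
        for i in range(n_bg):
            idx += 1
            reads.append(
                (f"{sample_id}_r{idx:06d}|src=bg", blob[i * read_length : (i + 1) * read_length])
            )
    return reads, truth


def _expected_fraction(ratio: float, response: Mapping[str, float]) -> float:
    """Quadratic nutrient response, as a fraction of the library (not %)."""
    v = response["vertex"]
    w = response["width"]
    fmax = response["fmax_pct"] / 100.0
    return max(fmax * (1.0 - ((ratio - v) / w) ** 2), 0.0)


def simulate_series(
    cfg: SeriesConfig, seed: int, panel: ReferencePanel | None = None
) -> SeriesResult:
    """Generate the full sample series (libraries, env table, truth)."""
    panel = panel or ReferencePanel(seed)
    samples: list[SampleResult] = []
    truth: dict = {"config": cfg.name, "seed": int(seed), "samples": {}}

    if cfg.mode == "response":
        env_rows = []
        for layer in cfg.layers:
            for date, ratio in zip(cfg.dates, cfg.ratios):
                env_rows.append(
                    {
                        "date": date,
                        "layer": layer,
                        "TN_ppb": ratio * cfg.tp_ppb,
                        "TP_ppb": cfg.tp_ppb,
                        "TDN_ppb": np.nan,
                        "TDP_ppb": np.nan,
                    }
                )
        env = pd.DataFrame(env_rows)
    else:
        env = pd.DataFrame(
            cfg.env_rows,
            columns=["date", "layer", "TN_ppb", "TP_ppb", "TDN_ppb", "TDP_ppb"],
        )
    if not env.empty:
        env["tn_tp_ratio"] = env["TN_ppb"] / env["TP_ppb"]

    for layer in cfg.layers:
        for i, date in enumerate(cfg.dates):
            sample_id = f"{layer[:3].upper()}_{date}"
            rng = derive_rng(seed, "library", cfg.name, sample_id)
            if cfg.mode == "response":
                frac = _expected_fraction(cfg.ratios[i], cfg.response)
                count = int(rng.binomial(cfg.library_size, frac))
                planted: dict[str, int] = {"Chlorobi": count}
            else:
                planted = dict(cfg.planted.get(layer, {}).get(date, {}))
                decoy = cfg.decoy_planted.get(layer, {}).get(date, 0)
                if decoy:
                    planted[DECOY_KEY] = decoy
                novel = cfg.novel_planted.get(layer, {}).get(date, 0)
                if novel:
                    planted[NOVEL_KEY] = novel
            if cfg.emit_reads:
                reads, truth_counts = simulate_library(
                    sample_id, planted, cfg.library_size, cfg.read_length,
                    cfg.error_rate, panel, rng, cfg.gc,
                )
            else:
                reads = None
                truth_counts = {k: v for k, v in planted.items() if v > 0}
            total = sum(truth_counts.values())
            if total > cfg.library_size:
                raise ConfigError(f"{sample_id}: planted counts exceed library size")
            samples.append(
                SampleResult(
                    sample_id=sample_id,
                    date=date,
                    layer=layer,
                    library_size=cfg.library_size,
                    reads=reads,
                    truth_counts=truth_counts,
                )
            )
            truth["samples"][sample_id] = dict(truth_counts)
    return SeriesResult(
        config_name=cfg.name, seed=int(seed), samples=samples, env=env, truth=truth
    )
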