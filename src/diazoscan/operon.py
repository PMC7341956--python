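"""Nitrogenase gene cluster detection, typing and neighbourhood analysis.

Clusters are seeded at nitrogenase-family genes (nif/vnf/anf symbols) and
grown by absorbing neighbouring family or catalog genes while consecutive
members are separated by at most ``gap_max`` bp with at most
``max_intervening`` non-catalog genes in between. Typing follows the
canonical cluster compositions: Mo-nitrogenase requires nifH+nifD+nifK,
Fe-only requires anfH plus at least three of anfO/anfK/anfG/anfD, and
V-nitrogenase requires vnfH plus at least two of vnfG/vnfD/vnfK; anything
else is partial. Strand agreement is reported but never enforced -- real
nif neighbourhoods mix strands.

Repeat detection reports exact maximal direct and inverted repeats around a
cluster; a retroelement verdict requires a reverse transcriptase, an
endopeptidase and at least one repeat pair spanning the cluster (an
AAA-type ATPase is recorded as supporting evidence only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from typing import Mapping, Sequence

import yaml

from .io_formats import FeatureTable, GeneFeature
from .recruit import AlignerParams, revcomp, seed_extend_align

NITROGENASE_FAMILY = {
    "nifH", "nifD", "nifK",
    "anfH", "anfO", "anfK", "anfG", "anfD",
    "vnfH", "vnfG", "vnfD", "vnfK",
}

MO_CORE = {"nifH", "nifD", "nifK"}
FE_ONLY_ANCHOR = "anfH"
FE_ONLY_REST = {"anfO", "anfK", "anfG", "anfD"}
V_ANCHOR = "vnfH"
V_REST = {"vnfG", "vnfD", "vnfK"}


class IntegrityError(ValueError):
    pass


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _load_catalog() -> tuple[dict[str, list[str]], dict[str, str]]:
    text = (
        importlib_resources.files("diazoscan.resources") / "accessory_catalog.yaml"
    ).read_text()
    raw = yaml.safe_load(text)
    return raw["categories"], {k.lower(): v for k, v in raw.get("symbol_synonyms", {}).items()}


_CATEGORIES, _SYNONYMS = _load_catalog()
_CANONICAL = {s.lower(): s for cat in _CATEGORIES.values() for s in cat}
_CANONICAL.update({s.lower(): s for s in NITROGENASE_FAMILY})
_CATALOG_SYMBOLS = set(_CANONICAL.values())


def normalize_symbol(symbol: str) -> str:
    """Case-insensitive symbol normalisation through the synonym table."""
    low = symbol.strip().lower()
    low = _SYNONYMS.get(low, low).lower() if low in _SYNONYMS else low
    return _CANONICAL.get(low, symbol.strip())


def feature_symbol(feature: GeneFeature) -> str:
    return normalize_symbol(feature.product)


def _is_family(feature: GeneFeature) -> bool:
    return feature_symbol(feature) in NITROGENASE_FAMILY


def _is_catalog(feature: GeneFeature) -> bool:
    sym = feature_symbol(feature)
    return sym in NITROGENASE_FAMILY or sym in _CATALOG_SYMBOLS


@dataclass
class OperonCluster:
    scaffold_id: str
    members: list[GeneFeature]  # ordered by start
    start: int
    end: int
    type_label: str
    strand_consensus: str  # '+', '-' or 'mixed'
    accessory: dict[str, list[str]] = field(default_factory=dict)

    @property
    def member_symbols(self) -> set[str]:
        return {feature_symbol(f) for f in self.members}

    @property
    def member_ids(self) -> list[str]:
        return [f.gene_id for f in self.members]


@dataclass(frozen=True)
class RepeatFeature:
    kind: str  # 'direct' or 'inverted'
    arm1: tuple[int, int]  # 1-based inclusive
    arm2: tuple[int, int]
    length: int


@dataclass(frozen=True)
class RetroelementCall:
    cluster_span: tuple[int, int]
    has_rt: bool
    has_endopeptidase: bool
    has_aaa_atpase: bool
    repeats: tuple[RepeatFeature, ...]
    verdict: bool


def classify_cluster(symbols: set[str] | Sequence[str]) -> str:
    """Type label from the member symbol set alone (pure function)."""
    syms = {normalize_symbol(s) for s in symbols}
    if MO_CORE <= syms:
        return "Mo"
    if FE_ONLY_ANCHOR in syms and len(FE_ONLY_REST & syms) >= 3:
        return "Fe-only"
    if V_ANCHOR in syms and len(V_REST & syms) >= 2:
        return "V"
    return "partial"


def _strand_consensus(members: Sequence[GeneFeature]) -> str:
    strands = {f.strand for f in members}
    return strands.pop() if len(strands) == 1 else "mixed"


def detect_nif_clusters(
    table: FeatureTable, gap_max: int = 2000, max_intervening: int = 2
) -> list[OperonCluster]:
    """Maximal non-overlapping nitrogenase gene clusters on one scaffold."""
    feats = table.features
    for prev, cur in zip(feats, feats[1:]):
        if cur.start < prev.start:
            raise IntegrityError("feature table is not sorted by start")

    catalog_idx = [i for i, f in enumerate(feats) if _is_catalog(f)]
    clusters: list[OperonCluster] = []
    chain: list[int] = []

    def flush() -> None:
        members = [feats[i] for i in chain]
        if members and any(_is_family(m) for m in members):
            symbols = {feature_symbol(m) for m in members}
            clusters.append(
                OperonCluster(
                    scaffold_id=table.scaffold_id,
                    members=members,
                    start=min(m.start for m in members),
                    end=max(m.end for m in members),
                    type_label=classify_cluster(symbols),
                    strand_consensus=_strand_consensus(members),
                )
            )
        chain.clear()

    for pos, i in enumerate(catalog_idx):
        if not chain:
            chain.append(i)
            continue
        j = chain[-1]
        gap = feats[i].start - feats[j].end
        intervening = sum(1 for t in range(j + 1, i) if not _is_catalog(feats[t]))
        if gap <= gap_max and intervening <= max_intervening:
            chain.append(i)
        else:
            flush()
            chain.append(i)
    flush()
    return clusters


def accessory_inventory(
    cluster: OperonCluster, table: FeatureTable, window: int = 10_000
) -> dict[str, list[str]]:
    """Catalog genes within *window* bp of the cluster span, by category
    (cluster members included)."""
    lo = cluster.start - window
    hi = cluster.end + window
    inventory: dict[str, list[str]] = {cat: [] for cat in _CATEGORIES}
    for f in table:
        if f.end < lo or f.start > hi:
            continue
        sym = feature_symbol(f)
        for cat, symbols in _CATEGORIES.items():
            if sym in symbols:
                inventory[cat].append(f.gene_id)
    cluster.accessory = inventory
    return inventory


def _maximal_repeats(
    seq: str, lo0: int, hi0: int, min_len: int, inverted: bool
) -> set[tuple[int, int, int]]:
    """Exact maximal repeats >= min_len within seq[lo0:hi0) (0-based).

    Returns {(start1, start2, length)} in 0-based absolute coordinates; for
    inverted repeats the second arm is the reverse complement of the first.
    """
    region = seq[lo0:hi0]
    n = len(region)
    if n < 2 * min_len:
        return set()
    other = revcomp(region) if inverted else region
    anchors: dict[str, list[int]] = {}
    for i in range(n - min_len + 1):
        anchors.setdefault(region[i : i + min_len], []).append(i)
    found: set[tuple[int, int, int]] = set()
    for i in range(n - min_len + 1):
        word = other[i : i + min_len]
        for j in anchors.get(word, ()):
            # position i in `other` maps back to region coordinates
            if inverted:
                # other[i:i+L] == revcomp(region)[i:i+L] corresponds to
                # region[n-i-L : n-i]
                p2 = n - i - min_len
            else:
                p2 = i
            p1 = j
            if p1 == p2 and not inverted:
                continue
            a, b = (p1, p2) if p1 <= p2 else (p2, p1)
            # extend maximally
            if inverted:
                # arm1 = region[a:a+L], arm2 = region[b:b+L] with
                # arm1 == revcomp(arm2); outward extension grows arm1 left /
                # arm2 right, inward extension grows arm1 right / arm2 left.
                length = min_len
                while a > 0 and b + length < n and region[a - 1] == _COMP[region[b + length]]:
                    a -= 1
                    length += 1
                while b - 1 >= a + length + 1 and region[a + length] == _COMP[region[b - 1]]:
                    b -= 1
                    length += 1
            else:
                length = min_len
                while a > 0 and b > 0 and region[a - 1] == region[b - 1]:
                    a -= 1
                    b -= 1
                    length += 1
                while (
                    a + length < n
                    and b + length < n
                    and region[a + length] == region[b + length]
                ):
                    length += 1
            if b >= a + length:  # arms must not overlap
                found.add((lo0 + a, lo0 + b, length))
    return found


def find_repeats(
    sequence: str,
    cluster_span: tuple[int, int],
    flank: int = 5000,
    min_len: int = 20,
) -> list[RepeatFeature]:
    """Exact maximal direct and inverted repeats around a cluster.

    One arm must lie in the left flank or cluster, the other in the cluster
    or right flank (1-based inclusive *cluster_span*); flanks are clipped to
    the sequence. Output is ordered by left arm start.
    """
    c_lo, c_hi = cluster_span  # 1-based inclusive
    lo0 = max(0, c_lo - 1 - flank)
    hi0 = min(len(sequence), c_hi + flank)
    c_lo0, c_hi0 = c_lo - 1, c_hi  # 0-based half-open cluster

    results: list[RepeatFeature] = []
    for inverted in (False, True):
        for p1, p2, length in _maximal_repeats(sequence, lo0, hi0, min_len, inverted):
            arm1 = (p1, p1 + length)  # 0-based half-open
            arm2 = (p2, p2 + length)
            left_ok = arm1[0] < c_hi0  # overlaps left flank or cluster
            right_ok = arm2[1] > c_lo0  # overlaps cluster or right flank
            if not (left_ok and right_ok):
                continue
            results.append(
                RepeatFeature(
                    kind="inverted" if inverted else "direct",
                    arm1=(arm1[0] + 1, arm1[1]),
                    arm2=(arm2[0] + 1, arm2[1]),
                    length=length,
                )
            )
    results.sort(key=lambda r: (r.arm1, r.arm2, r.kind))
    return results


_RT_WORDS = ("reverse transcriptase", "rt")
_ENDO_WORDS = ("endopeptidase",)
_AAA_WORDS = ("aaa",)


def _product_matches(product: str, words: tuple[str, ...]) -> bool:
    p = product.lower()
    return any(w in p for w in words)


def flag_retroelement(
    cluster: OperonCluster,
    table: FeatureTable,
    repeats: Sequence[RepeatFeature],
    window: int = 5000,
) -> RetroelementCall:
    """Retroelement verdict: RT + endopeptidase CDS near the cluster plus at
    least one repeat pair whose arms flank the cluster span."""
    lo = cluster.start - window
    hi = cluster.end + window
    nearby = [f for f in table if f.end >= lo and f.start <= hi]
    has_rt = any(_product_matches(f.product, _RT_WORDS) for f in nearby)
    has_endo = any(_product_matches(f.product, _ENDO_WORDS) for f in nearby)
    has_aaa = any(_product_matches(f.product, _AAA_WORDS) for f in nearby)
    spanning = [
        r
        for r in repeats
        if r.arm1[1] <= cluster.start and r.arm2[0] >= cluster.end
    ]
    verdict = has_rt and has_endo and bool(spanning)
    return RetroelementCall(
        cluster_span=(cluster.start, cluster.end),
        has_rt=has_rt,
        has_endopeptidase=has_endo,
        has_aaa_atpase=has_aaa,
        repeats=tuple(repeats),
        verdict=verdict,
    )


@dataclass(frozen=True)
class SyntenyPair:
    gene_a: str
    gene_b: str
    identity: float  # percent of the shorter gene covered by identical columns


def synteny_pairs(
    genes_a: Mapping[str, str],
    genes_b: Mapping[str, str],
    min_identity: float = 70.0,
    params: AlignerParams | None = None,
) -> list[SyntenyPair]:
    """Greedy best-bidirectional gene matching between two clusters.

    Pair identity is the identical-column count of the best ungapped local
    alignment expressed as a percent of the shorter gene, so short chance
    matches between unrelated genes score near zero. Each gene joins at
    most one pair; pairs below *min_identity* are dropped.
    """
    params = params or AlignerParams()
    scored: list[tuple[float, str, str]] = []
    for ga, sa in genes_a.items():
        for gb, sb in genes_b.items():
            aln = seed_extend_align(sa, sb, params, read_id=ga, subject_id=gb)
            if aln is None:
                continue
            ident = 100.0 * aln.matches / min(len(sa), len(sb))
            if ident >= min_identity:
                scored.append((ident, ga, gb))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[str] = set()
    used_b: set[str] = set()
    pairs: list[SyntenyPair] = []
    for ident, ga, gb in scored:
        if ga in used_a or gb in used_b:
            continue
        used_a.add(ga)
        used_b.add(gb)
        pairs.append(SyntenyPair(gene_a=ga, gene_b=gb, identity=ident))
    pairs.sort(key=lambda p: (p.gene_a, p.gene_b))
    return pairs
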