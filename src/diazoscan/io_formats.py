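"""Readers/writers for the formats the pipeline touches.

Coordinates are 1-based inclusive everywhere (GFF3 convention); helpers are
provided to convert to 0-based half-open Python slices and back. Only a single
strict GFF3 dialect (JGI-style ``ID=`` attributes, explicit strand) is
accepted -- anything else raises :class:`FormatError` rather than being
silently reinterpreted.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

logger = logging.getLogger(__name__)

LABEL_SYSTEMS = ("KO", "PFAM", "COG")

#: GFF3 feature types carried through to the feature table.
_KNOWN_TYPES = {"gene", "CDS"}


class FormatError(ValueError):
    """Raised on malformed or unsupported input files."""


class BoundsError(ValueError):
    """Raised when a feature exceeds its scaffold's sequence bounds."""


@dataclass(frozen=True)
class GeneFeature:
    """A located, stranded gene with labels from three annotation systems."""

    gene_id: str
    scaffold_id: str
    start: int  # 1-based, inclusive
    end: int  # inclusive, >= start
    strand: str  # '+' or '-'
    product: str = ""
    labels: Mapping[str, str] = field(default_factory=dict)
    partial: bool = False  # truncated at a contig edge; retained but flagged

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise FormatError(
                f"feature {self.gene_id}: invalid span {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(
                f"feature {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def slice(self) -> slice:
        """0-based half-open slice covering the feature."""
        return slice(self.start - 1, self.end)


def to_zero_based(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive span -> 0-based half-open span."""
    return start - 1, end


def to_one_based(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open span -> 1-based inclusive span."""
    return start0 + 1, end0


@dataclass
class FeatureTable:
    """Ordered gene features on one scaffold."""

    scaffold_id: str
    length: int
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = sorted(self.features, key=lambda f: (f.start, f.end, f.gene_id))
        seen: set[str] = set()
        for f in self.features:
            if f.scaffold_id != self.scaffold_id:
                raise FormatError(
                    f"feature {f.gene_id} on {f.scaffold_id} placed in table "
                    f"{self.scaffold_id}"
                )
            if f.gene_id in seen:
                raise FormatError(f"duplicate gene_id {f.gene_id}")
            seen.add(f.gene_id)
            if self.length and f.end > self.length:
                raise BoundsError(
                    f"feature {f.gene_id} ends at {f.end} beyond scaffold "
                    f"length {self.length}"
                )

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ``{id: uppercase sequence}`` map.

    Duplicate record ids and empty files are format errors.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def read_reads(path: str | Path) -> dict[str, str]:
    """Read a FASTA or FASTQ read library (qualities are ignored)."""
    fmt = "fastq" if str(path).endswith((".fastq", ".fq")) else "fasta"
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), fmt):
        if rec.id in records:
            raise FormatError(f"duplicate read id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise FormatError(f"no records in {path}")
    return records


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

_ATTR_RE = re.compile(r"([^=;]+)=([^;]*)")


def _parse_attributes(text: str) -> dict[str, str]:
    return {k.strip(): v.strip() for k, v in _ATTR_RE.findall(text)}


def read_gff3(
    path: str | Path, scaffold_lengths: Mapping[str, int] | None = None
) -> list[FeatureTable]:
    """Parse a strict JGI-style GFF3 file into per-scaffold feature tables.

    Rows must carry ``ID=`` attributes and an explicit strand; ``end < start``
    or a missing ID is a :class:`FormatError`. Feature types outside
    ``gene``/``CDS`` are skipped with a logged warning. ``##sequence-region``
    pragmas supply scaffold lengths unless *scaffold_lengths* overrides them.
    """
    lengths: dict[str, int] = dict(scaffold_lengths or {})
    by_scaffold: dict[str, list[GeneFeature]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    lengths.setdefault(parts[1], int(parts[3]))
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            seqid, _src, ftype, start_s, end_s, _score, strand, _phase, attrs = cols
            if ftype not in _KNOWN_TYPES:
                logger.warning("%s:%d: skipping feature type %r", path, lineno, ftype)
                continue
            start, end = int(start_s), int(end_s)
            if end < start:
                raise FormatError(f"{path}:{lineno}: end {end} < start {start}")
            if strand not in ("+", "-"):
                raise FormatError(
                    f"{path}:{lineno}: strandless features are unsupported (strand {strand!r})"
                )
            attr = _parse_attributes(attrs)
            if "ID" not in attr:
                raise FormatError(f"{path}:{lineno}: missing ID attribute")
            labels = {s: attr[s] for s in LABEL_SYSTEMS if s in attr}
            feat = GeneFeature(
                gene_id=attr["ID"],
                scaffold_id=seqid,
                start=start,
                end=end,
                strand=strand,
                product=attr.get("product", ""),
                labels=labels,
                partial=attr.get("partial", "") in ("1", "true", "True"),
            )
            if seqid not in by_scaffold:
                by_scaffold[seqid] = []
                order.append(seqid)
            by_scaffold[seqid].append(feat)
    return [
        FeatureTable(scaffold_id=s, length=lengths.get(s, 0), features=by_scaffold[s])
        for s in order
    ]


def write_gff3(tables: Iterable[FeatureTable], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for table in tables:
            if table.length:
                fh.write(f"##sequence-region {table.scaffold_id} 1 {table.length}\n")
            for f in table:
                attrs = [f"ID={f.gene_id}"]
                if f.product:
                    attrs.append(f"product={f.product}")
                for sysname in LABEL_SYSTEMS:
                    if sysname in f.labels:
                        attrs.append(f"{sysname}={f.labels[sysname]}")
                if f.partial:
                    attrs.append("partial=1")
                fh.write(
                    "\t".join(
                        [
                            f.scaffold_id,
                            "diazoscan",
                            "gene",
                            str(f.start),
                            str(f.end),
                            ".",
                            f.strand,
                            ".",
                            ";".join(attrs),
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# GenBank-like flat feature table
#
# A deliberately minimal flavour of the GenBank feature block: one LOCUS line,
# a FEATURES header, one `gene` entry per feature with `complement(a..b)`
# notation on the minus strand and /qualifiers for product and the three
# annotation systems. Parsing the emitted text reproduces the FeatureTable
# exactly (round-trip safe). Full GenBank grammar (ORIGIN blocks, joins) is
# out of scope.

_LOCATION_RE = re.compile(r"^(complement\()?(\d+)\.\.(\d+)(\))?$")


def gff_to_genbank_table(table: FeatureTable, sequence: str | None = None) -> str:
    """Render a FeatureTable as a GenBank-like flat feature listing."""
    length = table.length or (len(sequence) if sequence else 0)
    if sequence is not None:
        for f in table:
            if f.end > len(sequence):
                raise BoundsError(
                    f"feature {f.gene_id} ends at {f.end} beyond sequence "
                    f"length {len(sequence)}"
                )
    lines = [f"LOCUS       {table.scaffold_id} {length} bp DNA linear"]
    lines.append("FEATURES             Location/Qualifiers")
    for f in table:
        loc = f"{f.start}..{f.end}" if f.strand == "+" else f"complement({f.start}..{f.end})"
        lines.append(f"     gene            {loc}")
        lines.append(f'                     /locus_tag="{f.gene_id}"')
        if f.product:
            lines.append(f'                     /product="{f.product}"')
        for sysname in LABEL_SYSTEMS:
            if sysname in f.labels:
                lines.append(f'                     /{sysname}="{f.labels[sysname]}"')
        if f.partial:
            lines.append('                     /partial="1"')
    lines.append("//")
    return "\n".join(lines) + "\n"


def parse_genbank_table(text: str) -> FeatureTable:
    """Inverse of :func:`gff_to_genbank_table`."""
    scaffold_id = ""
    length = 0
    features: list[GeneFeature] = []
    current: dict | None = None

    def flush() -> None:
        nonlocal current
        if current is not None:
            features.append(
                GeneFeature(
                    gene_id=current["gene_id"],
                    scaffold_id=scaffold_id,
                    start=current["start"],
                    end=current["end"],
                    strand=current["strand"],
                    product=current.get("product", ""),
                    labels=current.get("labels", {}),
                    partial=current.get("partial", False),
                )
            )
            current = None

    for raw in text.splitlines():
        line = raw.strip()
        if not line or line == "//" or line == "FEATURES             Location/Qualifiers".strip():
            continue
        if raw.startswith("LOCUS"):
            parts = raw.split()
            scaffold_id = parts[1]
            length = int(parts[2])
            continue
        if raw.startswith("FEATURES"):
            continue
        if raw.startswith("     gene"):
            flush()
            loc = line.split()[-1]
            m = _LOCATION_RE.match(loc)
            if not m:
                raise FormatError(f"unparseable location {loc!r}")
            strand = "-" if m.group(1) else "+"
            current = {"start": int(m.group(2)), "end": int(m.group(3)), "strand": strand}
            continue
        if line.startswith("/") and current is not None:
            key, _, val = line[1:].partition("=")
            val = val.strip('"')
            if key == "locus_tag":
                current["gene_id"] = val
            elif key == "product":
                current["product"] = val
            elif key == "partial":
                current["partial"] = val in ("1", "true")
            elif key in LABEL_SYSTEMS:
                current.setdefault("labels", {})[key] = val
            continue
        raise FormatError(f"unexpected line in GenBank-like table: {raw!r}")
    flush()
    return FeatureTable(scaffold_id=scaffold_id, length=length, features=features)


def shift_feature(feature: GeneFeature, offset: int) -> GeneFeature:
    """Translate a feature along its scaffold by *offset* bp."""
    return replace(feature, start=feature.start + offset, end=feature.end + offset)
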