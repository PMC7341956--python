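"""Pathway completeness scoring from per-genome gene annotations.

Each pathway is a named set of required gene symbols (shipped as an editable
YAML resource); completeness is the fraction of required symbols present in
a genome's annotation, and the missing set is reported explicitly so
single-gene gaps (such as bciC in otherwise complete chlorosome pathways)
are visible. Narrative labels like "incomplete" are deliberately avoided in
favour of fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .operon import normalize_symbol


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PathwayDefinition:
    pathway_id: str
    name: str
    genes: frozenset[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ConfigError(f"pathway {self.pathway_id} has an empty gene set")


@dataclass(frozen=True)
class PathwayScore:
    genome_id: str
    pathway_id: str
    present: frozenset[str]
    missing: frozenset[str]

    @property
    def completeness(self) -> float:
        return len(self.present) / (len(self.present) + len(self.missing))


def load_definitions(path: str | Path | None = None) -> list[PathwayDefinition]:
    if path is None:
        text = (
            importlib_resources.files("diazoscan.resources") / "pathways.yaml"
        ).read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    defs = []
    for pid, entry in raw["pathways"].items():
        defs.append(
            PathwayDefinition(
                pathway_id=pid,
                name=entry.get("name", pid),
                genes=frozenset(normalize_symbol(g) for g in entry["genes"]),
                provenance=entry.get("provenance", "").strip(),
            )
        )
    return defs


def _symbol_set(annotations: Iterable[str] | pd.DataFrame) -> set[str]:
    if isinstance(annotations, pd.DataFrame):
        symbols = annotations["symbol"].astype(str)
    else:
        symbols = annotations
    return {normalize_symbol(s) for s in symbols}


def score_pathway(
    annotations: Iterable[str] | pd.DataFrame,
    definition: PathwayDefinition,
    genome_id: str = "genome",
) -> PathwayScore:
    """Set arithmetic: which required genes are present, which are missing."""
    present_all = _symbol_set(annotations)
    present = definition.genes & present_all
    return PathwayScore(
        genome_id=genome_id,
        pathway_id=definition.pathway_id,
        present=frozenset(present),
        missing=frozenset(definition.genes - present),
    )


def score_all(
    genomes: Mapping[str, Iterable[str] | pd.DataFrame],
    definitions: Iterable[PathwayDefinition] | None = None,
    reporting_threshold: float = 0.75,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Complete genome x pathway score matrix plus a per-genome summary of
    pathways at completeness >= *reporting_threshold*."""
    defs = list(definitions) if definitions is not None else load_definitions()
    if not genomes or not defs:
        raise ConfigError("need at least one genome and one pathway definition")
    rows = []
    summary: dict[str, list[str]] = {}
    for genome_id in sorted(genomes):
        summary[genome_id] = []
        for d in defs:
            score = score_pathway(genomes[genome_id], d, genome_id=genome_id)
            rows.append(
                {
                    "genome_id": genome_id,
                    "pathway_id": d.pathway_id,
                    "completeness": score.completeness,
                    "n_present": len(score.present),
                    "n_required": len(d.genes),
                    "missing": ",".join(sorted(score.missing)),
                }
            )
            if score.completeness >= reporting_threshold:
                summary[genome_id].append(d.pathway_id)
    return pd.DataFrame(rows), summary
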