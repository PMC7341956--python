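"""Three-system annotation consensus for nifH calling.

A gene counts as nifH only when KO, Pfam and COG all label it as a
nitrogenase iron protein (nifH family, which includes the alternative
nitrogenase H genes anfH and vnfH). A gene where at least one system says
nifH while another points to a different function is *conflicted*, and every
read recruited to it is excluded from the counts. Genes with incomplete
label coverage whose present labels all agree on nifH are neither consensus
nor conflicted (absence of a label is not "a different function").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .recruit import HitRecord

SYSTEMS = ("KO", "PFAM", "COG")

CONSENSUS_NIFH = "consensus_nifH"
CONFLICTED = "conflicted"
NON_NIF = "non_nif"


class IntegrityError(ValueError):
    pass


@dataclass(frozen=True)
class NifCall:
    gene_id: str
    status: str
    labels: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class PhylotypeCount:
    taxon: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise IntegrityError(f"negative count for {self.taxon}")


def load_nifh_synonyms() -> dict[str, set[str]]:
    """Per-system identifier sets recognised as nifH-family labels."""
    text = (
        importlib_resources.files("diazoscan.resources") / "nifh_synonyms.yaml"
    ).read_text()
    raw = yaml.safe_load(text)
    return {sys: {str(v) for v in vals} for sys, vals in raw.items()}


def _is_nifh(system: str, label: str, synonyms: Mapping[str, set[str]]) -> bool:
    return label in synonyms.get(system, set())


def call_nifh_genes(
    annotations: pd.DataFrame, synonyms: Mapping[str, set[str]] | None = None
) -> list[NifCall]:
    """Classify each annotated gene as consensus_nifH / conflicted / non_nif.

    *annotations* needs columns ``gene_id, ko_label, pfam_label, cog_label``;
    empty strings or NaN mean the system produced no label for the gene.
    """
    synonyms = synonyms or load_nifh_synonyms()
    calls: list[NifCall] = []
    for row in annotations.itertuples(index=False):
        labels = {}
        for system, col in zip(SYSTEMS, ("ko_label", "pfam_label", "cog_label")):
            val = getattr(row, col, None)
            if val is not None and not pd.isna(val) and str(val) != "":
                labels[system] = str(val)
        nifh_votes = [s for s, v in labels.items() if _is_nifh(s, v, synonyms)]
        other_votes = [s for s, v in labels.items() if not _is_nifh(s, v, synonyms)]
        if len(nifh_votes) == len(SYSTEMS):
            status = CONSENSUS_NIFH
        elif nifh_votes and other_votes:
            status = CONFLICTED
        else:
            status = NON_NIF
        calls.append(NifCall(gene_id=str(row.gene_id), status=status, labels=labels))
    return calls


def filter_conflicting_hits(
    hits: Sequence[HitRecord], calls: Iterable[NifCall]
) -> tuple[list[HitRecord], int, int]:
    """Partition hits into (retained consensus-nifH hits, n excluded
    conflicted, n non-nif). Retained + excluded + non-nif == input size."""
    status = {c.gene_id: c.status for c in calls}
    retained: list[HitRecord] = []
    excluded = 0
    non_nif = 0
    for h in hits:
        if h.gene_id not in status:
            raise IntegrityError(f"hit to unknown gene {h.gene_id}")
        s = status[h.gene_id]
        if s == CONSENSUS_NIFH:
            retained.append(h)
        elif s == CONFLICTED:
            excluded += 1
        else:
            non_nif += 1
    return retained, excluded, non_nif


def call_positive_mags(
    mag_annotations: Mapping[str, pd.DataFrame],
    identity_evidence: Mapping[str, Mapping[str, float]],
    identity_min: float = 95.0,
    synonyms: Mapping[str, set[str]] | None = None,
) -> list[str]:
    """MAG ids with at least one consensus nifH gene supported at >= 95% identity.

    *identity_evidence* maps mag_id -> gene_id -> percent identity of the
    gene against the reference nitrogenase set (the BLASTp-style evidence).
    """
    synonyms = synonyms or load_nifh_synonyms()
    positives = []
    for mag_id in sorted(mag_annotations):
        calls = call_nifh_genes(mag_annotations[mag_id], synonyms)
        evidence = identity_evidence.get(mag_id, {})
        for call in calls:
            if call.status != CONSENSUS_NIFH:
                continue
            if evidence.get(call.gene_id, 0.0) >= identity_min:
                positives.append(mag_id)
                break
    return positives


def select_phylotypes(
    counts: Iterable[PhylotypeCount], threshold: int = 50
) -> list[PhylotypeCount]:
    """Phylotypes whose series-summed nifH read count strictly exceeds the
    threshold, sorted by count descending (name ascending on ties)."""
    passing = [c for c in counts if c.count > threshold]
    return sorted(passing, key=lambda c: (-c.count, c.taxon))
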