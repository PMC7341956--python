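"""Unique assignment of metagenomic reads to reference nitrogenase genes.

The built-in engine is a deterministic ungapped seed-and-extend aligner:
exact ``seed_k``-mer seeds on both strands of the read select diagonals, and
on each seeded diagonal the maximal-scoring ungapped segment (match +1,
mismatch -2) is taken. Significance is expressed as a Karlin-Altschul
e-value ``E = K * m * n * exp(-lambda * S)`` with the ungapped DNA constants
lambda = 1.28, K = 0.46, where *m* is the read length and *n* the summed
length of the subject genes in the searched tier.

Recruitment searches a local reference tier first and falls back to a global
tier only when no alignment passes both cutoffs (e-value <= 1e-20 and
identity >= 95%). Among passing alignments the winner has the highest
identity, then the lowest e-value, then the lexicographically smallest gene
id, so every read receives at most one taxonomic assignment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: base -> 2-bit code; anything outside ACGT maps to 4 (never matches a
#: reference code, which is a base-5 number with all digits < 4).
_CODE_TABLE = np.full(256, 4, dtype=np.uint8)
for _b, _c in zip(b"ACGT", range(4)):
    _CODE_TABLE[_b] = _c


class ConfigError(ValueError):
    pass


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignerParams:
    seed_k: int = 11
    match: int = 1
    mismatch: int = -2
    lam: float = 1.28
    K: float = 0.46
    evalue_max: float = 1e-20
    identity_min: float = 95.0

    def __post_init__(self) -> None:
        if self.seed_k < 8:
            raise ConfigError("seed_k must be >= 8")
        if self.lam <= 0 or self.K <= 0:
            raise ConfigError("Karlin-Altschul constants must be positive")
        if self.evalue_max <= 0 or self.identity_min <= 0:
            raise ConfigError("thresholds must be positive")


@dataclass(frozen=True)
class Alignment:
    read_id: str
    subject_gene_id: str
    score: int
    aligned_length: int
    matches: int
    identity: float  # percent
    evalue: float
    m: int  # query length (bp)
    n: int  # effective database length (bp)
    strand: str  # strand of the read that aligned to the forward subject
    read_start: int  # 0-based, on the aligned orientation of the read
    subject_start: int  # 0-based on the subject


@dataclass(frozen=True)
class HitRecord:
    read_id: str
    gene_id: str
    taxon: str | None
    tier: int
    identity: float
    evalue: float
    score: int
    aligned_length: int


@dataclass
class ReferenceTier:
    """One reference gene set: tier 1 = local MAGs, tier 2 = global collection."""

    tier: int
    genes: dict[str, str]
    taxa: dict[str, str | None] = field(default_factory=dict)

    @cached_property
    def total_length(self) -> int:
        return sum(len(s) for s in self.genes.values())

    def seed_index(self, k: int) -> dict[bytes, list[tuple[str, int]]]:
        key = ("_index", k)
        cached = self.__dict__.get(key)
        if cached is None:
            index: dict[bytes, list[tuple[str, int]]] = {}
            for gene_id in sorted(self.genes):
                b = self.genes[gene_id].encode()
                for i in range(len(b) - k + 1):
                    index.setdefault(b[i : i + k], []).append((gene_id, i))
            self.__dict__[key] = cached = index
        return cached

    def kmer_codes(self, k: int) -> np.ndarray:
        """Sorted unique base-5 codes of all subject k-mers (for screening)."""
        key = ("_codes", k)
        cached = self.__dict__.get(key)
        if cached is None:
            chunks = []
            pow5 = 5 ** np.arange(k, dtype=np.uint64)
            for seq in self.genes.values():
                codes = _CODE_TABLE[np.frombuffer(seq.encode(), dtype=np.uint8)]
                if len(codes) >= k:
                    win = np.lib.stride_tricks.sliding_window_view(codes, k)
                    chunks.append(win.astype(np.uint64) @ pow5)
            cached = np.unique(np.concatenate(chunks)) if chunks else np.empty(0, np.uint64)
            self.__dict__[key] = cached
        return cached


def evalue(S: int, m: int, n: int, params: AlignerParams) -> float:
    """Karlin-Altschul expectation ``K * m * n * exp(-lambda * S)``.

    Computed in log space; the exponent is clamped so extreme scores return a
    positive subnormal floor instead of underflowing to an invalid zero.
    """
    if m <= 0 or n <= 0:
        raise ValueError("m and n must be positive")
    arg = math.log(params.K) + math.log(m) + math.log(n) - params.lam * S
    return math.exp(max(min(arg, 709.0), -745.0))


def _best_segment(eq: np.ndarray, match: int, mismatch: int) -> tuple[int, int, int, int]:
    """Maximal-scoring contiguous segment of a match/mismatch column vector.

    Ties break toward the smallest start, then the smallest end. Returns
    (score, start, end_inclusive, n_matches); score of an empty input is the
    sentinel (-inf-ish) tuple handled by callers.
    """
    best_s = -(10**9)
    best = (best_s, 0, -1)
    cur = 0
    cur_start = 0
    scores = np.where(eq, match, mismatch)
    for i, sc in enumerate(scores.tolist()):
        if cur < 0:
            cur = sc
            cur_start = i
        else:
            cur += sc
        if cur > best[0] or (cur == best[0] and (cur_start, i) < (best[1], best[2])):
            best = (cur, cur_start, i)
    s, a, b = best
    n_matches = int(eq[a : b + 1].sum()) if b >= a else 0
    return s, a, b, n_matches


def _diagonal_alignment(
    read_id: str,
    q: str,
    q_arr: np.ndarray,
    subject: str,
    s_arr: np.ndarray,
    diag: int,
    strand: str,
    params: AlignerParams,
    n_eff: int,
    m_len: int,
) -> Alignment | None:
    # overlap of the read (oriented as q) with the subject on diagonal
    # ``diag = subject_pos - read_pos``
    r0 = max(0, -diag)
    r1 = min(len(q), len(subject) - diag)
    if r1 - r0 <= 0:
        return None
    eq = q_arr[r0:r1] == s_arr[r0 + diag : r1 + diag]
    S, a, b, n_match = _best_segment(eq, params.match, params.mismatch)
    if b < a:
        return None
    length = b - a + 1
    return Alignment(
        read_id=read_id,
        subject_gene_id="",
        score=S,
        aligned_length=length,
        matches=n_match,
        identity=100.0 * n_match / length,
        evalue=evalue(S, m_len, n_eff, params),
        m=m_len,
        n=n_eff,
        strand=strand,
        read_start=r0 + a,
        subject_start=r0 + a + diag,
    )


def _align_rank(aln: Alignment) -> tuple:
    # deterministic within-subject ranking: best score first, then stable
    # positional order (strand '+' preferred)
    return (-aln.score, aln.subject_start, aln.read_start, 0 if aln.strand == "+" else 1)


def seed_extend_align(
    read: str,
    subject: str,
    params: AlignerParams | None = None,
    read_id: str = "read",
    subject_id: str = "subject",
    n_eff: int | None = None,
) -> Alignment | None:
    """Best ungapped alignment of one read against one subject, or None.

    Both strands of the read are seeded; the alignment is reported on the
    subject's forward frame. Returns None when read and subject share no
    exact ``seed_k``-mer.
    """
    params = params or AlignerParams()
    k = params.seed_k
    if len(read) < k or len(subject) < k:
        return None
    if set(read) - set("ACGT"):
        logger.warning("read %s contains ambiguous bases; skipped", read_id)
        return None
    n_eff = n_eff if n_eff is not None else len(subject)
    s_bytes = subject.encode()
    s_arr = np.frombuffer(s_bytes, dtype=np.uint8)
    subj_index: dict[bytes, list[int]] = {}
    for i in range(len(s_bytes) - k + 1):
        subj_index.setdefault(s_bytes[i : i + k], []).append(i)

    best: Alignment | None = None
    for strand, q in (("+", read), ("-", revcomp(read))):
        q_bytes = q.encode()
        q_arr = np.frombuffer(q_bytes, dtype=np.uint8)
        diags: set[int] = set()
        for i in range(len(q_bytes) - k + 1):
            for j in subj_index.get(q_bytes[i : i + k], ()):
                diags.add(j - i)
        for diag in sorted(diags):
            aln = _diagonal_alignment(
                read_id, q, q_arr, subject, s_arr, diag, strand, params, n_eff, len(read)
            )
            if aln is None:
                continue
            aln = Alignment(**{**aln.__dict__, "subject_gene_id": subject_id})
            if best is None or _align_rank(aln) < _align_rank(best):
                best = aln
    return best


def _passes(aln: Alignment, params: AlignerParams) -> bool:
    return aln.evalue <= params.evalue_max and aln.identity >= params.identity_min


# candidate map: (gene_id, read strand) -> set of diagonals with a seed
Candidates = dict[tuple[str, str], set[int]]


def _evaluate_candidates(
    read_id: str,
    oriented: Mapping[str, str],
    tiers: Sequence[ReferenceTier],
    per_tier: Sequence[Candidates],
    params: AlignerParams,
) -> HitRecord | None:
    """Extend seeded candidates tier by tier and emit at most one hit.

    Tier 1 is searched first; tier 2 only when no tier-1 alignment passes
    both cutoffs. The winning alignment has the highest identity, then the
    lowest e-value, then the smallest gene id.
    """
    m_len = len(oriented["+"])
    q_arrs = {s: np.frombuffer(q.encode(), dtype=np.uint8) for s, q in oriented.items()}
    for tier, cands in zip(tiers, per_tier):
        if not cands:
            continue
        n_eff = tier.total_length
        results: dict[str, Alignment] = {}
        for (gene_id, strand), diags in sorted(cands.items()):
            subject = tier.genes[gene_id]
            s_arr = np.frombuffer(subject.encode(), dtype=np.uint8)
            for diag in sorted(diags):
                aln = _diagonal_alignment(
                    read_id, oriented[strand], q_arrs[strand], subject, s_arr,
                    diag, strand, params, n_eff, m_len,
                )
                if aln is None:
                    continue
                aln = Alignment(**{**aln.__dict__, "subject_gene_id": gene_id})
                prev = results.get(gene_id)
                if prev is None or _align_rank(aln) < _align_rank(prev):
                    results[gene_id] = aln
        passing = [a for a in results.values() if _passes(a, params)]
        if not passing:
            continue
        best = min(passing, key=lambda a: (-a.identity, a.evalue, a.subject_gene_id))
        return HitRecord(
            read_id=read_id,
            gene_id=best.subject_gene_id,
            taxon=tier.taxa.get(best.subject_gene_id),
            tier=tier.tier,
            identity=best.identity,
            evalue=best.evalue,
            score=best.score,
            aligned_length=best.aligned_length,
        )
    return None


def _scan_candidates(
    oriented: Mapping[str, str], tiers: Sequence[ReferenceTier], k: int
) -> list[Candidates]:
    per_tier: list[Candidates] = [dict() for _ in tiers]
    indexes = [t.seed_index(k) for t in tiers]
    for strand, q in oriented.items():
        b = q.encode()
        for i in range(len(b) - k + 1):
            word = b[i : i + k]
            for cands, index in zip(per_tier, indexes):
                for gene_id, j in index.get(word, ()):
                    cands.setdefault((gene_id, strand), set()).add(j - i)
    return per_tier


def recruit_read(
    read_id: str,
    read: str,
    tiers: Sequence[ReferenceTier],
    params: AlignerParams | None = None,
) -> HitRecord | None:
    """Assign one read to at most one reference gene (tiered fallback,
    highest-identity / lowest-e-value / smallest-gene-id tie-break)."""
    params = params or AlignerParams()
    if not tiers:
        raise ConfigError("at least one reference tier is required")
    if len(read) < params.seed_k:
        return None
    if set(read) - set("ACGT"):
        logger.warning("read %s contains ambiguous bases; skipped", read_id)
        return None
    oriented = {"+": read, "-": revcomp(read)}
    per_tier = _scan_candidates(oriented, tiers, params.seed_k)
    return _evaluate_candidates(read_id, oriented, tiers, per_tier, params)


@dataclass
class RecruitSummary:
    library_size: int
    n_hits: int
    hits_per_tier: dict[int, int]
    skipped_short: int
    skipped_ambiguous: int


def _screen_seed_positions(
    reads: list[str], db_codes: np.ndarray, k: int, chunk: int = 4096
) -> dict[int, list[tuple[str, int]]]:
    """Vectorised seed pre-screen over the whole library.

    Returns ``{read index: [(strand, position in the oriented read), ...]}``
    for every read sharing at least one exact k-mer (either strand) with the
    reference database. Exact: a read with no shared seed cannot align, and
    every shared seed position is reported.
    """
    found: dict[int, list[tuple[str, int]]] = {}
    if db_codes.size == 0 or not reads:
        return found
    pow5 = 5 ** np.arange(k, dtype=np.uint64)
    for lo in range(0, len(reads), chunk):
        batch = reads[lo : lo + chunk]
        maxlen = max(len(r) for r in batch)
        if maxlen < k:
            continue
        mat = np.full((len(batch), maxlen), 4, dtype=np.uint8)
        for i, r in enumerate(batch):
            mat[i, : len(r)] = _CODE_TABLE[np.frombuffer(r.encode(), dtype=np.uint8)]
        rc = np.where(mat < 4, 3 - mat, 4)[:, ::-1]
        for strand, m in (("+", mat), ("-", rc)):
            win = np.lib.stride_tricks.sliding_window_view(m, k, axis=1)
            codes = win.astype(np.uint64) @ pow5
            idx = np.searchsorted(db_codes, codes)
            idx[idx >= db_codes.size] = 0
            hit = db_codes[idx] == codes
            for row, col in zip(*np.nonzero(hit)):
                ridx = lo + int(row)
                # reversed rows place the oriented read at the row's tail
                offset = maxlen - len(batch[int(row)]) if strand == "-" else 0
                pos = int(col) - offset
                if pos >= 0:
                    found.setdefault(ridx, []).append((strand, pos))
    return found


def recruit_library(
    reads: Mapping[str, str] | Iterable[tuple[str, str]],
    tiers: Sequence[ReferenceTier],
    params: AlignerParams | None = None,
) -> tuple[list[HitRecord], RecruitSummary]:
    """Recruit every read in a library; returns hits plus a reconciling summary."""
    params = params or AlignerParams()
    if not tiers:
        raise ConfigError("at least one reference tier is required")
    items = list(reads.items()) if isinstance(reads, Mapping) else list(reads)
    if not items:
        raise ConfigError("empty read library")
    k = params.seed_k
    skipped_short = sum(1 for _, s in items if len(s) < k)
    skipped_ambiguous = sum(
        1 for _, s in items if len(s) >= k and set(s) - set("ACGT")
    )
    all_codes = np.unique(np.concatenate([t.kmer_codes(k) for t in tiers]))
    seed_map = _screen_seed_positions([s for _, s in items], all_codes, k)
    indexes = [t.seed_index(k) for t in tiers]
    hits: list[HitRecord] = []
    for ridx in sorted(seed_map):
        read_id, seq = items[ridx]
        if len(seq) < k or set(seq) - set("ACGT"):
            continue  # counted above
        oriented = {"+": seq, "-": revcomp(seq)}
        per_tier: list[Candidates] = [dict() for _ in tiers]
        for strand, pos in seed_map[ridx]:
            word = oriented[strand][pos : pos + k].encode()
            for cands, index in zip(per_tier, indexes):
                for gene_id, j in index.get(word, ()):
                    cands.setdefault((gene_id, strand), set()).add(j - pos)
        hit = _evaluate_candidates(read_id, oriented, tiers, per_tier, params)
        if hit is not None:
            hits.append(hit)
    per_tier: dict[int, int] = {t.tier: 0 for t in tiers}
    for h in hits:
        per_tier[h.tier] += 1
    return hits, RecruitSummary(
        library_size=len(items),
        n_hits=len(hits),
        hits_per_tier=per_tier,
        skipped_short=skipped_short,
        skipped_ambiguous=skipped_ambiguous,
    )


def hits_to_dataframe(hits: Sequence[HitRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "read_id": h.read_id,
                "gene_id": h.gene_id,
                "taxon": h.taxon if h.taxon is not None else "",
                "tier": h.tier,
                "identity": h.identity,
                "evalue": h.evalue,
            }
            for h in hits
        ],
        columns=["read_id", "gene_id", "taxon", "tier", "identity", "evalue"],
    )
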