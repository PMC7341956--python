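"""Aligner, e-value and tiered recruitment behaviour.

Includes a brute-force oracle that enumerates every read-subject offset on
both strands with prefix-sum segment scoring (no seeding, no Kadane scan)
and applies the same thresholds and tie-breaks; on small instances the
production engine must agree with it exactly.
"""

import math

import numpy as np
import pytest

from diazoscan.recruit import (
    AlignerParams,
    ConfigError,
    HitRecord,
    ReferenceTier,
    evalue,
    recruit_library,
    recruit_read,
    revcomp,
    seed_extend_align,
)

from conftest import random_dna


# ---------------------------------------------------------------------------
# e-value

def test_evalue_matches_closed_form():
    p = AlignerParams()
    got = evalue(50, 100, 10**6, p)
    expect = 0.46 * 100 * 1e6 * math.exp(-1.28 * 50)
    assert got == pytest.approx(expect, rel=1e-9)
    assert got == pytest.approx(7.4e-21, rel=0.01)


def test_evalue_monotone_decreasing_in_score():
    p = AlignerParams()
    vals = [evalue(S, 200, 10**4, p) for S in range(0, 120)]
    assert all(a > b for a, b in zip(vals, vals[1:]))
    assert vals[0] == pytest.approx(0.46 * 200 * 1e4, rel=1e-9)  # S = 0 limit


# ---------------------------------------------------------------------------
# seed-and-extend engine

def test_exact_substring_scores_full_length(rng):
    subject = random_dna(rng, 400)
    read = subject[100:200]
    aln = seed_extend_align(read, subject)
    assert aln is not None
    assert aln.score == 100 and aln.identity == 100.0 and aln.aligned_length == 100


def test_single_interior_mismatch_hand_score(rng):
    subject = random_dna(rng, 400)
    read = list(subject[100:200])
    read[50] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[50]]
    aln = seed_extend_align("".join(read), subject)
    assert aln.score == 99 * 1 + 1 * (-2) == 97
    assert aln.identity == pytest.approx(99.0)
    assert aln.aligned_length == 100


def test_no_shared_seed_returns_none():
    read = "ACGT" * 10
    subject = "TTTTTTTTTTTTGGGGGGGGGGGGCCCCAACCAA" * 4
    assert seed_extend_align(read, subject) is None


def test_reverse_strand_read_is_found(rng):
    subject = random_dna(rng, 300)
    read = revcomp(subject[50:150])
    aln = seed_extend_align(read, subject)
    assert aln is not None and aln.identity == 100.0 and aln.strand == "-"
    assert aln.subject_start == 50


# ---------------------------------------------------------------------------
# recruit_read: thresholds, tie-breaks, tier fallback

def _mutate_at(seq: str, positions, table={"A": "C", "C": "G", "G": "T", "T": "A"}):
    out = list(seq)
    for p in positions:
        out[p] = table[out[p]]
    return "".join(out)


def test_higher_identity_wins(rng):
    read = random_dna(rng, 200)
    sub97 = _mutate_at(read, range(3, 200, 67))  # 3 mismatches -> 98.5%
    sub96 = _mutate_at(read, range(5, 200, 25))  # 8 mismatches -> 96%
    tier = ReferenceTier(1, {"a96": sub96, "b97": sub97}, {"a96": "X", "b97": "Y"})
    hit = recruit_read("r", read, [tier])
    assert hit.gene_id == "b97" and hit.taxon == "Y"


def test_equal_identity_lower_evalue_wins(rng):
    read = random_dna(rng, 200)
    # both subjects contain the read region exactly (identity 100), but the
    # longer embedded copy yields a higher score and hence a lower e-value
    short_host = random_dna(rng, 40) + read[:100] + random_dna(rng, 40)
    long_host = random_dna(rng, 40) + read[:180] + random_dna(rng, 40)
    tier = ReferenceTier(1, {"a_short": short_host, "b_long": long_host}, {})
    hit = recruit_read("r", read, [tier])
    assert hit.gene_id == "b_long"


def test_tier2_fallback_sets_tier(rng):
    read = random_dna(rng, 200)
    tier1 = ReferenceTier(1, {"g1": random_dna(rng, 300)}, {"g1": "A"})
    tier2 = ReferenceTier(2, {"g2": random_dna(rng, 50) + read + random_dna(rng, 50)}, {"g2": "B"})
    hit = recruit_read("r", read, [tier1, tier2])
    assert hit.tier == 2 and hit.taxon == "B"


def test_identity_below_cutoff_is_rejected(rng):
    read = random_dna(rng, 200)
    sub = _mutate_at(read, range(9, 200, 18))  # 11 mismatches -> 94.5%
    tier = ReferenceTier(1, {"g": sub}, {})
    assert recruit_read("r", read, [tier]) is None


def test_empty_tiers_is_config_error():
    with pytest.raises(ConfigError):
        recruit_read("r", "ACGT" * 50, [])


def test_ambiguous_and_short_reads_skipped(rng):
    tier = ReferenceTier(1, {"g": random_dna(rng, 300)}, {})
    assert recruit_read("r", "ACGTN" * 40, [tier]) is None
    assert recruit_read("r", "ACGTACGT", [tier]) is None


# ---------------------------------------------------------------------------
# library-level behaviour

def _library_with_plants(rng, n_bg=300, n_planted=5):
    gene = random_dna(rng, 900)
    tier = ReferenceTier(1, {"nifH_x": gene}, {"nifH_x": "T"})
    reads = []
    for i in range(n_planted):
        s = int(rng.integers(0, 700))
        reads.append((f"plant{i}", gene[s : s + 200]))
    for i in range(n_bg):
        reads.append((f"bg{i}", random_dna(rng, 200)))
    return reads, tier


def test_planted_reads_all_recovered_background_none(rng):
    reads, tier = _library_with_plants(rng)
    hits, summary = recruit_library(reads, [tier])
    assert len(hits) == 5
    assert {h.read_id for h in hits} == {f"plant{i}" for i in range(5)}
    assert all(h.gene_id == "nifH_x" for h in hits)
    assert summary.library_size == 305 and summary.n_hits == 5


def test_doubling_library_doubles_hits(rng):
    reads, tier = _library_with_plants(rng)
    hits1, _ = recruit_library(reads, [tier])
    doubled = reads + [(f"{rid}_copy", seq) for rid, seq in reads]
    hits2, _ = recruit_library(doubled, [tier])
    assert len(hits2) == 2 * len(hits1)


def test_unique_assignment_no_read_twice(rng):
    reads, tier = _library_with_plants(rng, n_bg=100, n_planted=20)
    hits, _ = recruit_library(reads, [tier])
    ids = [h.read_id for h in hits]
    assert len(ids) == len(set(ids)) <= len(reads)


def test_threshold_relaxation_never_loses_hits(rng):
    gene = random_dna(rng, 900)
    tier = ReferenceTier(1, {"g": gene}, {})
    reads = []
    for i in range(60):
        s = int(rng.integers(0, 700))
        window = gene[s : s + 200]
        n_mut = int(rng.integers(0, 20))
        reads.append((f"r{i}", _mutate_at(window, rng.choice(200, n_mut, replace=False))))
    strict = AlignerParams()
    n_strict = len(recruit_library(reads, [tier], strict)[0])
    for relaxed in (
        AlignerParams(evalue_max=1e-5),
        AlignerParams(identity_min=80.0),
        AlignerParams(evalue_max=1e-5, identity_min=80.0),
    ):
        assert len(recruit_library(reads, [tier], relaxed)[0]) >= n_strict


def test_full_recall_of_error_free_subject_reads(panel, rng):
    tiers = panel.tiers()
    reads = []
    for taxon in ("Chlorobi", "Geobacter", "Sulfurimonas"):
        gene = panel.read_source(taxon)
        for i in range(20):
            s = int(rng.integers(0, len(gene) - 200 + 1))
            reads.append((f"{taxon}_{i}", gene[s : s + 200]))
    hits, _ = recruit_library(reads, tiers)
    assert len(hits) == len(reads)
    for h in hits:
        assert h.identity == 100.0
        assert h.read_id.startswith(h.taxon)


def test_recruit_library_deterministic(rng):
    reads, tier = _library_with_plants(rng)
    h1, _ = recruit_library(reads, [tier])
    h2, _ = recruit_library(reads, [tier])
    assert h1 == h2


# ---------------------------------------------------------------------------
# brute-force oracle equivalence

def _oracle_best_on_diagonal(q, subject, diag, match=1, mismatch=-2):
    r0 = max(0, -diag)
    r1 = min(len(q), len(subject) - diag)
    if r1 - r0 <= 0:
        return None
    qa = np.frombuffer(q[r0:r1].encode(), np.uint8)
    sa = np.frombuffer(subject[r0 + diag : r1 + diag].encode(), np.uint8)
    eq = qa == sa
    sc = np.where(eq, match, mismatch)
    c = np.concatenate([[0], np.cumsum(sc)])
    cm = np.concatenate([[0], np.cumsum(eq.astype(int))])
    L = len(sc)
    ii, jj = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
    S = c[jj + 1] - c[ii]
    S[jj < ii] = -(10**9)
    best = int(S.max())
    i, j = min(map(tuple, np.argwhere(S == best)))
    matches = int(cm[j + 1] - cm[i])
    length = j - i + 1
    return {
        "score": best,
        "matches": matches,
        "length": length,
        "identity": 100.0 * matches / length,
        "read_start": r0 + i,
        "subject_start": r0 + i + diag,
    }


def _oracle_recruit(read_id, read, tiers, params):
    """Exhaustive reference scorer: every offset, both strands, no seeding."""
    if len(read) < params.seed_k or set(read) - set("ACGT"):
        return None
    for tier in tiers:
        n_eff = tier.total_length
        per_gene = {}
        for gene_id in sorted(tier.genes):
            subject = tier.genes[gene_id]
            best = None
            for srank, (strand, q) in enumerate((("+", read), ("-", revcomp(read)))):
                for diag in range(-(len(q) - 1), len(subject)):
                    seg = _oracle_best_on_diagonal(q, subject, diag, params.match, params.mismatch)
                    if seg is None:
                        continue
                    rank = (-seg["score"], seg["subject_start"], seg["read_start"], srank)
                    if best is None or rank < best[0]:
                        best = (rank, seg)
            if best is not None:
                per_gene[gene_id] = best[1]
        passing = []
        for gene_id, seg in per_gene.items():
            E = evalue(seg["score"], len(read), n_eff, params)
            if E <= params.evalue_max and seg["identity"] >= params.identity_min:
                passing.append((-seg["identity"], E, gene_id, seg))
        if passing:
            ident_neg, E, gene_id, seg = min(passing, key=lambda t: t[:3])
            return HitRecord(
                read_id=read_id,
                gene_id=gene_id,
                taxon=tier.taxa.get(gene_id),
                tier=tier.tier,
                identity=seg["identity"],
                evalue=E,
                score=seg["score"],
                aligned_length=seg["length"],
            )
    return None


@pytest.mark.parametrize("instance_seed", [7, 19, 42])
def test_recruit_read_equals_brute_force_oracle(instance_seed):
    rng = np.random.default_rng(instance_seed)
    params = AlignerParams()
    genes = {f"g{i:02d}": random_dna(rng, int(rng.integers(60, 150))) for i in range(8)}
    taxa = {g: f"tax{i}" for i, g in enumerate(sorted(genes))}
    items = sorted(genes.items())
    tiers = [
        ReferenceTier(1, dict(items[:5]), taxa),
        ReferenceTier(2, dict(items[5:]), taxa),
    ]
    reads = []
    for i in range(36):
        gid = items[int(rng.integers(0, len(items)))][0]
        src = genes[gid]
        length = int(rng.integers(44, min(61, len(src) + 1)))
        s = int(rng.integers(0, len(src) - length + 1))
        window = src[s : s + length]
        n_mut = int(rng.integers(0, 3))
        window = _mutate_at(window, rng.choice(length, n_mut, replace=False))
        if rng.integers(0, 2):
            window = revcomp(window)
        reads.append((f"read{i}", window))
    reads += [(f"rand{i}", random_dna(rng, 50)) for i in range(10)]
    reads.append(("short", "ACGTACG"))
    for read_id, seq in reads:
        got = recruit_read(read_id, seq, tiers, params)
        want = _oracle_recruit(read_id, seq, tiers, params)
        if want is None:
            assert got is None, read_id
        else:
            assert got is not None, read_id
            assert (got.gene_id, got.tier) == (want.gene_id, want.tier), read_id
            assert got.score == want.score and got.identity == pytest.approx(want.identity)
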