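"""Cluster detection, typing, accessory inventory, repeats and synteny."""

import pytest

from diazoscan.io_formats import FeatureTable, GeneFeature
from diazoscan.operon import (
    IntegrityError,
    classify_cluster,
    detect_nif_clusters,
    accessory_inventory,
    find_repeats,
    flag_retroelement,
    normalize_symbol,
    synteny_pairs,
)
from diazoscan.recruit import revcomp
from diazoscan.synthgen import TEMPLATES, TaxonSpec, build_genome

from conftest import random_dna


def _table(genes, scaffold="scf", length=100_000):
    feats = []
    for i, (sym, start, end, strand) in enumerate(genes):
        feats.append(
            GeneFeature(f"g{i:02d}", scaffold, start, end, strand, product=sym)
        )
    return FeatureTable(scaffold, length, feats)


def test_contiguous_nifhdk_is_one_cluster():
    table = _table([("nifH", 1000, 1900, "+"), ("nifD", 1950, 3400, "+"), ("nifK", 3450, 5000, "+")])
    (cluster,) = detect_nif_clusters(table)
    assert len(cluster.members) == 3 and cluster.type_label == "Mo"
    assert (cluster.start, cluster.end) == (1000, 5000)
    assert cluster.strand_consensus == "+"


def test_long_gap_splits_clusters():
    table = _table([("nifH", 1000, 1900, "+"), ("nifD", 12000, 13450, "+"), ("nifK", 13500, 15050, "+")])
    clusters = detect_nif_clusters(table)
    assert len(clusters) == 2
    assert [c.type_label for c in clusters] == ["partial", "partial"]


def test_intervening_gene_budget():
    genes = [("nifH", 1000, 1900, "+")]
    for i in range(3):  # three non-catalog genes between nifH and nifD
        genes.append((f"hyp{i}", 1950 + i * 100, 2000 + i * 100, "+"))
    genes.append(("nifD", 2400, 3850, "+"))
    clusters = detect_nif_clusters(_table(genes))
    assert len(clusters) == 2  # budget of 2 intervening genes exceeded


def test_no_family_genes_no_clusters():
    table = _table([("rpoB", 100, 900, "+"), ("modA", 2000, 2700, "+")])
    assert detect_nif_clusters(table) == []


def test_unsorted_table_is_integrity_error():
    table = _table([("nifH", 1000, 1900, "+"), ("nifD", 2000, 3400, "+")])
    table.features = list(reversed(table.features))  # violate sort invariant
    with pytest.raises(IntegrityError):
        detect_nif_clusters(table)


@pytest.mark.parametrize(
    "symbols,expected",
    [
        ({"nifH", "nifD", "nifK"}, "Mo"),
        ({"anfH", "anfO", "anfK", "anfG", "anfD"}, "Fe-only"),
        ({"vnfH", "vnfG", "vnfD", "vnfK"}, "V"),
        ({"nifH", "nifD"}, "partial"),
        ({"anfH", "anfO"}, "partial"),
        ({"NIFH", "nifd", "NifK"}, "Mo"),  # case-insensitive normalisation
    ],
)
def test_classify_cluster_is_pure_symbol_function(symbols, expected):
    assert classify_cluster(symbols) == expected
    assert classify_cluster(sorted(symbols)) == expected  # order-independent


def test_symbol_synonyms():
    assert normalize_symbol("PII") == "glnB"
    assert normalize_symbol("pii") == "glnB"
    assert normalize_symbol("anfH/nifH") == "anfH"


def test_accessory_inventory_from_gamma_template():
    spec = TaxonSpec("mx", "Methylococcales", True, "mo_gamma", genome_length=48_000)
    g = build_genome(spec, TEMPLATES["mo_gamma"], seed=13)
    (cluster,) = detect_nif_clusters(g.table)
    inv = accessory_inventory(cluster, g.table)
    syms = {gid: sym for gid, sym in zip(g.annotations.gene_id, g.annotations.symbol)}
    assert {syms[g] for g in inv["accessory"]} == {"nifQ", "nifZ", "nifU", "nifS", "nifW"}
    assert {syms[g] for g in inv["regulators"]} == {"nifA", "nifL"}
    assert {syms[g] for g in inv["electron"]} == {"rnfA", "rnfB", "rnfC", "rnfD", "rnfE"}


def test_accessory_inventory_mo_transport_and_bare_cluster():
    spec = TaxonSpec("v1", "Verrucomicrobia", True, "mo_mod")
    g = build_genome(spec, TEMPLATES["mo_mod"], seed=13)
    (cluster,) = detect_nif_clusters(g.table)
    inv = accessory_inventory(cluster, g.table)
    assert len(inv["Mo_transport"]) == 2
    bare = _table([("nifH", 1000, 1900, "+"), ("nifD", 1950, 3400, "+"), ("nifK", 3450, 5000, "+")])
    (c2,) = detect_nif_clusters(bare)
    inv2 = accessory_inventory(c2, bare)
    assert all(not v for v in inv2.values())


# ---------------------------------------------------------------------------
# repeats

def _retro_genome(seed=7):
    spec = TaxonSpec("chl", "Chlorobi", True, "fe_only_retro")
    return build_genome(spec, TEMPLATES["fe_only_retro"], seed=seed)


def test_planted_repeats_found_at_exact_coordinates():
    g = _retro_genome()
    (cluster,) = detect_nif_clusters(g.table)
    found = find_repeats(g.sequence, (cluster.start, cluster.end))
    by_kind = {r.kind: r for r in found}
    for truth in g.truth["repeats"]:
        det = by_kind[truth["kind"]]
        assert [list(det.arm1), list(det.arm2)] == [truth["arm1"], truth["arm2"]]
        assert det.length == truth["length"]


def test_random_sequence_has_no_chance_repeats(rng):
    for _ in range(30):
        seq = random_dna(rng, 20_000)
        assert find_repeats(seq, (8_000, 12_000)) == []


def test_find_repeats_reverse_complement_invariant():
    g = _retro_genome()
    (cluster,) = detect_nif_clusters(g.table)
    fwd = find_repeats(g.sequence, (cluster.start, cluster.end))
    n = len(g.sequence)
    rc_seq = revcomp(g.sequence)
    rc_span = (n - cluster.end + 1, n - cluster.start + 1)
    rev = find_repeats(rc_seq, rc_span)
    assert sorted(r.kind for r in fwd) == sorted(r.kind for r in rev)

    def mapped(interval):
        s, e = interval
        return (n - e + 1, n - s + 1)

    fwd_arms = {(r.kind, mapped(r.arm2), mapped(r.arm1)) for r in fwd}
    rev_arms = {(r.kind, r.arm1, r.arm2) for r in rev}
    assert fwd_arms == rev_arms


def test_retroelement_verdict_requires_all_evidence():
    g = _retro_genome()
    clusters = detect_nif_clusters(g.table)
    (cluster,) = clusters
    repeats = find_repeats(g.sequence, (cluster.start, cluster.end))
    call = flag_retroelement(cluster, g.table, repeats)
    assert call.verdict and call.has_rt and call.has_endopeptidase and call.has_aaa_atpase

    # necessary-condition removal: drop the RT coding region
    no_rt = FeatureTable(
        g.table.scaffold_id,
        g.table.length,
        [f for f in g.table if "transcriptase" not in f.product],
    )
    assert not flag_retroelement(cluster, no_rt, repeats).verdict
    # repeats alone, no CDS evidence at all
    empty = FeatureTable(g.table.scaffold_id, g.table.length, [])
    cluster_copy = detect_nif_clusters(g.table)[0]
    assert not flag_retroelement(cluster_copy, empty, repeats).verdict


def test_cluster_detection_translation_invariant():
    base = [("nifH", 1000, 1900, "+"), ("nifD", 1950, 3400, "-"), ("nifK", 3450, 5000, "+")]
    (c0,) = detect_nif_clusters(_table(base))
    shift = 7_777
    shifted = [(s, a + shift, b + shift, st) for s, a, b, st in base]
    (c1,) = detect_nif_clusters(_table(shifted))
    assert (c1.start, c1.end) == (c0.start + shift, c0.end + shift)
    assert c0.strand_consensus == c1.strand_consensus == "mixed"


# ---------------------------------------------------------------------------
# synteny

def test_identical_clusters_pair_fully(rng):
    genes = {f"g{i}": random_dna(rng, 600) for i in range(4)}
    other = {f"h{i}": genes[f"g{i}"] for i in range(4)}
    pairs = synteny_pairs(genes, other)
    assert len(pairs) == 4
    assert all(p.identity == pytest.approx(100.0) for p in pairs)


def test_synteny_order_invariant(rng):
    genes = {f"g{i}": random_dna(rng, 500) for i in range(3)}
    other = {f"h{i}": genes[f"g{i}"] for i in range(3)}
    reversed_other = dict(reversed(list(other.items())))
    a = synteny_pairs(genes, other)
    b = synteny_pairs(genes, reversed_other)
    assert {(p.gene_a, p.gene_b) for p in a} == {(p.gene_a, p.gene_b) for p in b}


def test_unrelated_genes_yield_no_pairs(rng):
    a = {f"a{i}": random_dna(rng, 700) for i in range(3)}
    b = {f"b{i}": random_dna(rng, 700) for i in range(3)}
    assert synteny_pairs(a, b) == []
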