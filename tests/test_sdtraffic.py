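"""SD detection, bSD/iSD classing, parental resolution and direction counts."""

import numpy as np
import pytest

from asmcompare.seqio import Assembly
from asmcompare.sdtraffic import (SDCopy, SDPair, categorize_direction,
                                  classify_sd, find_many_to_one,
                                  genes_in_derived, resolve_parent,
                                  source_export_table)
from conftest import make_block

_ROTATE = {65: 67, 67: 71, 71: 84, 84: 65}


def _seq(n, seed):
    rng = np.random.default_rng(seed)
    return bytes(rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n))


def _mutated(seq, n_subs, seed):
    rng = np.random.default_rng(seed)
    out = bytearray(seq)
    for pos in rng.choice(len(seq), size=n_subs, replace=False):
        out[pos] = _ROTATE[out[pos]]
    return bytes(out)


# ---------------------------------------------------------------------------
# many-to-one detection


def test_two_copies_on_one_anchor_make_a_pair():
    raw = [make_block("chr1", 0, 1500, "anchor", 1000, 2500),
           make_block("chr5", 0, 1500, "anchor", 1000, 2500)]
    (pair,) = find_many_to_one(raw)
    assert {pair.copy1.chrom, pair.copy2.chrom} == {"chr1", "chr5"}
    assert (pair.anchor_start, pair.anchor_end) == (1000, 2500)


def test_short_blocks_never_pair():
    raw = [make_block("chr1", 0, 900, "anchor", 0, 900),
           make_block("chr5", 0, 900, "anchor", 0, 900)]
    assert find_many_to_one(raw) == []


def test_insufficient_anchor_overlap_rejected():
    """500 of 1500 bp shared on the anchor side fails the 0.8 rule."""
    raw = [make_block("chr1", 0, 1500, "anchor", 0, 1500),
           make_block("chr5", 0, 1500, "anchor", 1000, 2500)]
    assert find_many_to_one(raw) == []


def test_three_copy_family_gives_all_pairs_one_family_id():
    raw = [make_block(c, 0, 2000, "anchor", 0, 2000)
           for c in ("chr1", "chr2", "chr3")]
    pairs = find_many_to_one(raw)
    assert len(pairs) == 3  # C(3, 2)
    assert len({p.family_id for p in pairs}) == 1


def test_intra_chromosomal_tandem_family_excluded_by_default():
    raw = [make_block("c", 0, 2000, "c", 0, 2000),
           make_block("c", 2000, 4000, "c", 0, 2000)]
    assert find_many_to_one(raw) == []
    assert len(find_many_to_one(raw, inter_chromosomal_only=False)) == 1


def test_copy_loci_trimmed_to_shared_anchor_window():
    """A long flank-merged block only contributes its anchor-matched part."""
    raw = [make_block("chr1", 0, 50_000, "anchor", 0, 50_000),
           make_block("chr5", 100, 2100, "anchor", 10_000, 12_000)]
    (pair,) = find_many_to_one(raw)
    copies = {p.chrom: (p.start, p.end) for p in pair.copies()}
    assert copies["chr1"] == (10_000, 12_000)
    assert copies["chr5"] == (100, 2100)


# ---------------------------------------------------------------------------
# bSD / iSD classification


def _chains():
    # one long chain covering chr1[0, 200k), another covering chr2[0, 100k)
    return [
        make_block("chr1", 0, 200_000, "b1", 0, 200_000,
                   chain_id=0, chain_span=200_000),
        make_block("chr2", 0, 100_000, "b2", 0, 100_000,
                   chain_id=1, chain_span=100_000),
    ]


def _pair(c1, c2):
    return SDPair(1, SDCopy(*c1), SDCopy(*c2), "anchor", 0, 2000,
                  copy_side="query")


def test_copies_deep_inside_chains_are_internal():
    pair = classify_sd(_pair(("chr1", 50_000, 60_000), ("chr2", 40_000, 50_000)),
                       _chains())
    assert pair.sd_class == "iSD"
    assert pair.copy1.chain_span == 200_000
    assert pair.copy2.chain_span == 100_000


def test_copy_near_chain_end_is_boundary():
    pair = classify_sd(_pair(("chr1", 50_000, 60_000), ("chr2", 97_800, 99_800)),
                       _chains())
    assert pair.sd_class == "bSD"  # 200 bp from the chain end


def test_copy_outside_all_chains_is_boundary():
    pair = classify_sd(_pair(("chr1", 50_000, 60_000), ("chr9", 0, 2000)),
                       _chains())
    assert pair.sd_class == "bSD"
    assert pair.copy2.chain_span == 0


# ---------------------------------------------------------------------------
# parental resolution


def test_isd_longer_synteny_chain_wins():
    pair = classify_sd(_pair(("chr1", 50_000, 60_000), ("chr2", 40_000, 50_000)),
                       _chains())
    resolved = resolve_parent(pair, Assembly({}, x_name="chrX"),
                              Assembly({}, x_name="chrX"))
    assert resolved.parental == "copy1"
    assert resolved.direction == "A>A"


def _identity_fixture(n1_subs, n2_subs):
    """Copies differing from a 2 kb anchor by the given substitution counts.

    2000 bp: 40 subs -> identity 0.98, 140 -> 0.93, 220 -> 0.89, 240 -> 0.88.
    """
    anchor = _seq(2000, 31)
    copy1 = _mutated(anchor, n1_subs, 32)
    copy2 = _mutated(anchor, n2_subs, 33)
    copy_asm = Assembly({"chr1": copy1, "chr5": copy2}, x_name="chrX")
    anchor_asm = Assembly({"anchor": anchor}, x_name="chrX")
    pair = SDPair(1, SDCopy("chr1", 0, 2000), SDCopy("chr5", 0, 2000),
                  "anchor", 0, 2000, copy_side="query", sd_class="bSD")
    return pair, copy_asm, anchor_asm


def test_bsd_higher_identity_wins():
    pair, copy_asm, anchor_asm = _identity_fixture(40, 140)   # 0.98 vs 0.93
    resolved = resolve_parent(pair, copy_asm, anchor_asm)
    assert resolved.copy1.identity_vs_anchor == pytest.approx(0.98, abs=0.003)
    assert resolved.copy2.identity_vs_anchor == pytest.approx(0.93, abs=0.005)
    assert resolved.parental == "copy1" and resolved.direction == "A>A"


def test_bsd_below_threshold_stays_unresolved():
    pair, copy_asm, anchor_asm = _identity_fixture(220, 240)  # 0.89 vs 0.88
    resolved = resolve_parent(pair, copy_asm, anchor_asm)
    assert resolved.copy1.identity_vs_anchor < 0.90
    assert resolved.parental == "unresolved"
    assert resolved.direction == "unresolved"


def test_bsd_missing_sequence_warns_not_crashes(caplog):
    pair = SDPair(1, SDCopy("nope", 0, 2000), SDCopy("chr5", 0, 2000),
                  "anchor", 0, 2000, copy_side="query", sd_class="bSD")
    with caplog.at_level("WARNING"):
        resolved = resolve_parent(pair, Assembly({"chr5": _seq(2000, 1)}),
                                  Assembly({"anchor": _seq(2000, 2)}))
    assert resolved.parental == "unresolved"
    assert "unresolved" in caplog.text


def test_direction_follows_parent_and_derived_chromosome_classes():
    chains = [
        make_block("chrX", 0, 200_000, "bX", 0, 200_000,
                   chain_id=0, chain_span=200_000),
        make_block("chr3", 0, 100_000, "b3", 0, 100_000,
                   chain_id=1, chain_span=100_000),
    ]
    pair = classify_sd(_pair(("chrX", 50_000, 60_000), ("chr3", 40_000, 50_000)),
                       chains)
    resolved = resolve_parent(pair, Assembly({}, x_name="chrX"),
                              Assembly({}, x_name="chrX"))
    assert resolved.direction == "X>A"


# ---------------------------------------------------------------------------
# direction counting and gene lists


def _resolved_pair(fam, parent, derived, direction):
    pair = SDPair(fam, SDCopy(*parent), SDCopy(*derived), "anchor", 0, 2000)
    pair.parental, pair.direction = "copy1", direction
    return pair


def test_direction_counts_on_derived_chromosome_and_conserve():
    lengths = {"chr2": 100_000, "chr3": 90_000, "chr7": 80_000, "chrX": 70_000}
    pairs = [
        _resolved_pair(1, ("chrX", 0, 2000), ("chr3", 0, 2000), "X>A"),
        _resolved_pair(2, ("chr2", 0, 2000), ("chr7", 0, 2000), "A>A"),
        _resolved_pair(3, ("chr2", 9000, 11_000), ("chrX", 0, 2000), "A>X"),
        SDPair(4, SDCopy("chr2", 0, 2000), SDCopy("chr3", 5000, 7000),
               "anchor", 0, 2000),  # unresolved
    ]
    table, summary = categorize_direction(pairs, lengths, "chrX")
    assert table.loc["chr3", "X>A"] == 1
    assert table.loc["chr7", "A>A"] == 1
    assert table.loc["chrX", "A>X"] == 1
    assert summary == {"A>A": 1, "A>X": 1, "X>A": 1, "unresolved": 1, "other": 0}
    assert sum(summary.values()) == len(pairs)

    exports = source_export_table(pairs, lengths, "chrX")
    assert exports.loc["chrX", "exports_into_autosomes"] == 1  # the X>A pair
    assert exports.loc["chr2", "exports_into_autosomes"] == 1  # the A>A pair


def test_genes_in_derived_copies():
    pairs = [_resolved_pair(1, ("chrX", 0, 2000), ("chr3", 1000, 3000), "X>A")]
    genes = [
        ("chr3", 1500, 1800, "inside"),
        ("chr3", 2900, 4000, "straddles"),
        ("chr3", 5000, 6000, "outside"),
        ("chrX", 100, 300, "on_parent"),
    ]
    lists = genes_in_derived(pairs, genes)
    assert lists == {1: ["inside", "straddles"]}


def test_genes_on_unknown_chromosome_skipped_with_warning(caplog):
    pairs = [_resolved_pair(1, ("chrX", 0, 2000), ("chr3", 1000, 3000), "X>A")]
    with caplog.at_level("WARNING"):
        lists = genes_in_derived(pairs, [("chrZ", 0, 10_000, "ghost")],
                                 known_chroms={"chr3", "chrX"})
    assert lists == {1: []}
    assert "unknown chromosome" in caplog.text


def test_empty_annotation_gives_empty_lists():
    pairs = [_resolved_pair(1, ("chrX", 0, 2000), ("chr3", 1000, 3000), "X>A")]
    assert genes_in_derived(pairs, []) == {1: []}
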