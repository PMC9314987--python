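"""SV classification oracles: hand-built chains, simulator truth, filters."""

import pandas as pd
import pytest

from asmcompare.alignkit import align_pair
from asmcompare.scoring import score_svs
from asmcompare.simgenome import SimConfig, simulate_pair
from asmcompare.svclass import (StructuralVariant, classify_svs,
                                count_by_chromosome, filter_svs, write_sv_tsv,
                                write_sv_vcf)
from asmcompare.synteny import one_to_one_map
from conftest import make_block


def _chain(*blocks):
    return one_to_one_map(list(blocks))


def test_query_only_gap_is_deletion():
    chains = _chain(make_block("c", 0, 10_000, "c", 0, 10_000),
                    make_block("c", 13_000, 20_000, "c", 10_000, 17_000))
    (sv,) = classify_svs(chains, [])
    assert sv.sv_type == "DEL"
    assert (sv.a_start, sv.a_end) == (10_000, 13_000)
    assert sv.length == 3000 and sv.b_start == sv.b_end


def test_target_only_gap_is_insertion():
    chains = _chain(make_block("c", 0, 10_000, "c", 0, 10_000),
                    make_block("c", 10_000, 17_000, "c", 14_000, 21_000))
    (sv,) = classify_svs(chains, [])
    assert sv.sv_type == "INS" and sv.length == 4000
    assert sv.a_start == sv.a_end == 10_000


def test_double_gap_splits_into_del_plus_ins():
    chains = _chain(make_block("c", 0, 10_000, "c", 0, 10_000),
                    make_block("c", 15_000, 22_000, "c", 12_000, 19_000))
    svs = classify_svs(chains, [])
    assert sorted((s.sv_type, s.length) for s in svs) == [("DEL", 5000),
                                                          ("INS", 2000)]


def test_equal_gaps_are_unaligned_patches_not_svs():
    chains = _chain(make_block("c", 0, 10_000, "c", 0, 10_000),
                    make_block("c", 12_000, 20_000, "c", 12_000, 20_000))
    assert classify_svs(chains, []) == []


def test_minus_chain_between_plus_chains_is_inversion():
    chains = _chain(make_block("c", 0, 10_000, "c", 0, 10_000),
                    make_block("c", 10_000, 20_000, "c", 10_000, 20_000, strand="-"),
                    make_block("c", 20_000, 30_000, "c", 20_000, 30_000))
    (sv,) = classify_svs(chains, [])
    assert sv.sv_type == "INV" and sv.length == 10_000
    assert (sv.a_start, sv.a_end) == (10_000, 20_000)


def test_many_to_one_same_chromosome_is_duplication():
    raw = [make_block("c", 5000, 8000, "c", 5000, 8000),
           make_block("c", 5000, 8000, "c", 8000, 11_000)]
    svs = classify_svs([], raw)
    assert [s.sv_type for s in svs] == ["DUP"]
    assert (svs[0].a_start, svs[0].a_end) == (5000, 8000)
    assert (svs[0].b_start, svs[0].b_end) == (8000, 11_000)


def test_inter_chromosomal_chain_skipped_with_warning(caplog):
    chains = _chain(make_block("q", 0, 5000, "t", 0, 5000),
                    make_block("q", 6000, 11_000, "t", 5000, 10_000))
    with caplog.at_level("WARNING"):
        assert classify_svs(chains, []) == []
    assert "inter-chromosomal" in caplog.text


def test_simulated_truth_recovered_exactly_at_zero_divergence():
    config = SimConfig(
        seed=21,
        chrom_lengths={"chr1": 800_000, "chr2": 800_000, "chr3": 800_000},
        x_name="chrX",
        sv_rates={"DEL": 3, "INS": 2, "DUP": 2, "INV": 2},
        sv_length_range=(1000, 15_000),
        background_divergence=0.0, ngap_count=0,
    )
    pair, truth = simulate_pair(config)
    unique_blocks, multi_blocks = align_pair(pair.a, pair.b)
    called = filter_svs(classify_svs(one_to_one_map(unique_blocks), multi_blocks))
    result = score_svs(truth, called)
    assert result.precision == 1.0 and result.recall == 1.0
    # types and chromosomes agree event for event
    assert sorted((t.kind, t.chrom) for t in truth) == \
        sorted((c.sv_type, c.chrom) for c in called)


def test_filter_length_boundary_and_continuity():
    short = StructuralVariant("DEL", "c", 0, 999, 0, 0)
    exact = StructuralVariant("DEL", "c", 0, 1000, 0, 0)
    gapped = StructuralVariant("DEL", "c", 0, 5000, 0, 0, continuous=False)
    kept = filter_svs([short, exact, gapped])
    assert kept == [exact]
    assert filter_svs([gapped], require_continuous=False) == [gapped]


def test_filter_partitions_and_is_idempotent():
    svs = [StructuralVariant("DEL", "c", 0, n, 0, 0) for n in
           (500, 999, 1000, 1001, 40_000)]
    kept = filter_svs(svs)
    assert len(kept) + sum(1 for s in svs if s.length < 1000) == len(svs)
    assert filter_svs(kept) == kept


def test_continuous_flag_reflects_n_runs():
    chains = _chain(make_block("c", 0, 10_000, "c", 0, 10_000),
                    make_block("c", 13_000, 20_000, "c", 10_000, 17_000))
    (sv,) = classify_svs(chains, [], ngaps_a={"c": [(11_000, 11_200)]})
    assert sv.sv_type == "DEL" and not sv.continuous
    assert filter_svs([sv]) == []


def test_count_table_tallies_and_conserves():
    svs = [StructuralVariant("DEL", "chr1", i * 3000, i * 3000 + 2000, 0, 0)
           for i in range(3)]
    svs.append(StructuralVariant("INV", "chrX", 0, 5000, 0, 5000))
    table = count_by_chromosome(svs, {"chr1": 1_000_000, "chr2": 900_000,
                                      "chrX": 800_000}, x_name="chrX")
    assert table.loc["chr1", "DEL"] == 3
    assert table.loc["chrX", "INV"] == 1
    assert table[["DEL", "INS", "DUP", "INV"]].to_numpy().sum() == len(svs)
    assert table.loc["chrX", "is_x"] and not table.loc["chr1", "is_x"]


def test_count_table_empty_and_unknown_chromosome():
    table = count_by_chromosome([], {"chr1": 1000}, x_name=None)
    assert table[["DEL", "INS", "DUP", "INV"]].to_numpy().sum() == 0
    with pytest.raises(ValueError, match="unknown chromosome"):
        count_by_chromosome([StructuralVariant("DEL", "nope", 0, 2000, 0, 0)],
                            {"chr1": 1000})


def test_exports_parse_back(tmp_path):
    svs = [StructuralVariant("DEL", "chr1", 100, 2100, 100, 100),
           StructuralVariant("INS", "chr1", 5000, 5000, 5000, 8000)]
    write_sv_tsv(svs, tmp_path / "svs.tsv")
    frame = pd.read_csv(tmp_path / "svs.tsv", sep="\t")
    assert list(frame["type"]) == ["DEL", "INS"]
    assert list(frame["length"]) == [2000, 3000]
    write_sv_vcf(svs, tmp_path / "svs.vcf", {"chr1": 10_000})
    lines = [l for l in (tmp_path / "svs.vcf").read_text().splitlines()
             if not l.startswith("#")]
    assert len(lines) == 2
    assert lines[0].split("\t")[1] == "101"  # 1-based POS
    assert "SVTYPE=DEL" in lines[0] and "<DEL>" in lines[0]
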