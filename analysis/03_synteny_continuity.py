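"""One-to-one synteny map and continuity statistics for the SV condition.

Reports how many reference N-gaps fall in orthologous regions and how many
the other assembly spans with clean sequence, plus the per-chromosome
gapless-length ratio l_r (assembly b over assembly a).
"""

from analysis_config import DATA, RESULTS

from asmcompare.alignkit import read_paf, write_paf
from asmcompare.seqio import read_fasta
from asmcompare.synteny import (gap_fill_stats, gapless_length_ratio,
                                one_to_one_map)


def main() -> None:
    a = read_fasta(DATA / "sv_assembly_a.fasta", x_name="chrX")
    b = read_fasta(DATA / "sv_assembly_b.fasta", x_name="chrX")
    blocks = read_paf(RESULTS / "sv_alignment_unique.paf")
    chains = one_to_one_map(blocks)
    write_paf(chains, RESULTS / "sv_synteny.paf", a.lengths(), b.lengths())
    n_chains = len({c.chain_id for c in chains})
    print(f"one-to-one map: {len(chains)} blocks in {n_chains} chains")

    report = gap_fill_stats(a.all_ngaps(), b, chains)
    report.to_frame().to_csv(RESULTS / "sv_gap_fill.tsv", sep="\t", index=False)
    print(f"N-gaps in orthologous regions: {report.total}; "
          f"spanned by assembly b: {report.filled} "
          f"({100 * report.fill_rate:.1f}%)")

    ratios = gapless_length_ratio(a, b)
    ratios.to_csv(RESULTS / "sv_length_ratio.tsv", sep="\t", index=False)
    print("gapless length ratios (b / a):")
    print(ratios.to_string(index=False))


if __name__ == "__main__":
    main()
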