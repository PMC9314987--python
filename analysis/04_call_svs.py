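"""Structural-variant catalogue for the SV condition, scored against truth.

Classifies DEL/INS/DUP/INV from the synteny chains, applies the >=1 kb and
continuity filters, tallies counts per chromosome, and reports precision
and recall against the planted truth.
"""

from analysis_config import DATA, RESULTS

from asmcompare.alignkit import read_paf
from asmcompare.scoring import score_svs
from asmcompare.seqio import read_fasta
from asmcompare.simgenome import read_truth
from asmcompare.svclass import (classify_svs, count_by_chromosome, filter_svs,
                                write_sv_tsv, write_sv_vcf)
from asmcompare.synteny import one_to_one_map


def main() -> None:
    a = read_fasta(DATA / "sv_assembly_a.fasta", x_name="chrX")
    b = read_fasta(DATA / "sv_assembly_b.fasta", x_name="chrX")
    truth = read_truth(DATA / "sv_truth.tsv")
    chains = one_to_one_map(read_paf(RESULTS / "sv_alignment_unique.paf"))
    multi_blocks = read_paf(RESULTS / "sv_alignment_multi.paf")

    svs = filter_svs(classify_svs(chains, multi_blocks, a.all_ngaps(),
                                  b.all_ngaps()))
    write_sv_tsv(svs, RESULTS / "sv_calls.tsv")
    write_sv_vcf(svs, RESULTS / "sv_calls.vcf", a.lengths())

    table = count_by_chromosome(svs, a.lengths(), "chrX")
    table.to_csv(RESULTS / "sv_counts.tsv", sep="\t")
    print(table.to_string())

    result = score_svs(truth, svs)
    print(f"recovered {result.n_matched}/{result.n_truth} planted SVs "
          f"(recall {result.recall:.3f}) with {result.n_called} calls "
          f"(precision {result.precision:.3f})")


if __name__ == "__main__":
    main()
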