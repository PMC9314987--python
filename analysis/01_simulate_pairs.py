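"""Generate the two simulated assembly pairs that drive the analysis.

Writes FASTA pairs and truth tables under results/data/.  Everything
downstream is reproducible from the seeds in analysis_config.
"""

from analysis_config import DATA, sd_condition, sv_condition

from asmcompare.seqio import write_fasta
from asmcompare.simgenome import simulate_pair, write_truth


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    for label, config in [("sv", sv_condition()), ("sd", sd_condition())]:
        pair, truth = simulate_pair(config)
        write_fasta(pair.a, DATA / f"{label}_assembly_a.fasta")
        write_fasta(pair.b, DATA / f"{label}_assembly_b.fasta")
        write_truth(truth, DATA / f"{label}_truth.tsv")
        n_sv = sum(1 for t in truth if t.kind != "SD")
        n_sd = len(truth) - n_sv
        print(f"{label} condition: {sum(pair.a.lengths().values()):,} bp over "
              f"{len(pair.a.chroms)} chromosomes; planted {n_sv} SVs, {n_sd} SDs "
              f"-> {DATA}")


if __name__ == "__main__":
    main()
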