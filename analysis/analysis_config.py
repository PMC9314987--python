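"""Shared study conditions for the numbered analysis scripts.

Two simulated comparisons drive the whole analysis:

* the SV condition: three 1 Mb chromosomes, 30 planted rearrangements of
  1-20 kb at background divergence 0.001, four planted N-gap runs;
* the SD condition: a four-chromosome genome (autosomes bracketing the X in
  length) carrying 12 segmental duplications split evenly across the
  A>A / A>X / X>A directions, derived copies at 2% extra divergence.
"""

from pathlib import Path

from asmcompare.simgenome import SimConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA = RESULTS / "data"

SV_SEED = 11
SD_SEED = 7


def sv_condition(seed: int = SV_SEED) -> SimConfig:
    return SimConfig(
        seed=seed,
        chrom_lengths={"chr1": 1_000_000, "chr2": 1_000_000, "chr3": 1_000_000},
        x_name="chrX",
        sv_rates={"DEL": 3, "INS": 3, "DUP": 2, "INV": 2},
        sv_length_range=(1000, 20_000),
        background_divergence=0.001,
        ngap_count=4,
    )


def sd_condition(seed: int = SD_SEED) -> SimConfig:
    return SimConfig(
        seed=seed,
        sv_rates={},
        sd_counts={"A>A": 4, "A>X": 4, "X>A": 4},
        derived_extra_divergence=0.02,
        ngap_count=0,
    )
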