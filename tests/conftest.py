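"""Shared fixtures: small simulated assembly pairs, reused across modules."""

from __future__ import annotations

import numpy as np
import pytest

from asmcompare.alignkit import AlignmentBlock
from asmcompare.simgenome import SimConfig, simulate_pair
from asmcompare.synteny import SyntenyBlock


def make_block(qn, qs, qe, tn, ts, te, strand="+", identity=1.0,
               chain_id=None, chain_span=0):
    """A hand-built alignment (or synteny) block with a chosen identity."""
    length = max(qe - qs, te - ts)
    matches = int(round(identity * length))
    if chain_id is None:
        return AlignmentBlock(qn, qs, qe, tn, ts, te, strand, matches, length)
    return SyntenyBlock(qn, qs, qe, tn, ts, te, strand, matches, length,
                        chain_id=chain_id, chain_span=chain_span)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_260_927)


@pytest.fixture(scope="session")
def sv_pair():
    """A 3 x 1 Mb pair with 30 planted SVs >= 1 kb at background 0.001."""
    config = SimConfig(
        seed=11,
        chrom_lengths={"chr1": 1_000_000, "chr2": 1_000_000, "chr3": 1_000_000},
        x_name="chrX",
        sv_rates={"DEL": 3, "INS": 3, "DUP": 2, "INV": 2},
        sv_length_range=(1000, 20_000),
        background_divergence=0.001,
        ngap_count=4,
    )
    return simulate_pair(config)


@pytest.fixture(scope="session")
def sd_pair():
    """The SD study condition: 12 planted SDs split across the 3 directions."""
    config = SimConfig(
        seed=7,
        sv_rates={},
        sd_counts={"A>A": 4, "A>X": 4, "X>A": 4},
        ngap_count=0,
    )
    return simulate_pair(config)


@pytest.fixture(scope="session")
def clean_pair():
    """Zero divergence, no events: the identity case."""
    config = SimConfig(
        seed=3,
        chrom_lengths={"chr1": 120_000, "chr2": 90_000},
        x_name="chrX",
        sv_rates={},
        background_divergence=0.0,
        ngap_count=0,
    )
    return simulate_pair(config)
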