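"""One-to-one orthologous mapping and assembly-continuity statistics.

The one-to-one map keeps, among alignment blocks that overlap substantially
on either assembly, only the best-scoring one, then strings the survivors
into collinear, strand-consistent synteny chains.  Chains are what the SV
classifier walks; their total aligned length ("synteny length") is what the
segmental-duplication stage uses to tell parental from derived copies.

Continuity statistics follow the gap-filling question asked of a new
assembly: which N-runs of the reference-like assembly sit inside orthologous
regions, and how many of them does the other assembly span with uninterrupted
sequence.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignkit import AlignmentBlock
from .seqio import Assembly

logger = logging.getLogger(__name__)

DEFAULT_MIN_IDENTITY = 0.90   # the one-to-one orthology threshold
DEFAULT_OVERLAP_FRAC = 0.5    # of the shorter block, on either assembly
DEFAULT_MAX_CHAIN_GAP = 100_000  # bp; larger gaps end a chain
FLANK = 1_000                 # bp; how much context defines "orthologous region"


@dataclass
class SyntenyBlock(AlignmentBlock):
    """An alignment block annotated with its collinear chain."""

    chain_id: int = -1
    chain_span: int = 0       # sum of block lengths over the chain


# ---------------------------------------------------------------------------
# one-to-one resolution and chaining


def _overlap(s1: int, e1: int, s2: int, e2: int) -> int:
    return max(0, min(e1, e2) - max(s1, s2))


def one_to_one_map(
    blocks: list[AlignmentBlock],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    overlap_frac: float = DEFAULT_OVERLAP_FRAC,
    max_chain_gap: int = DEFAULT_MAX_CHAIN_GAP,
) -> list[SyntenyBlock]:
    """Resolve overlapping blocks to a one-to-one map and chain it.

    Blocks below ``min_identity`` are dropped.  Where two blocks overlap by
    at least ``overlap_frac`` of the shorter one on either assembly, the
    higher-scoring block wins (matches, then block length, then target name).
    Survivors are greedily chained into collinear same-strand runs; a chain
    ends at a strand flip, a gap beyond ``max_chain_gap``, or wherever a
    block of another chain interposes on either assembly.
    """
    for b in blocks:
        b.validate()
    candidates = [b for b in blocks if b.identity >= min_identity]
    candidates.sort(key=lambda b: (-b.matches, -b.block_length, b.target_name,
                                   b.query_name, b.query_start, b.target_start))

    kept: list[AlignmentBlock] = []
    by_query: dict[str, list[AlignmentBlock]] = {}
    by_target: dict[str, list[AlignmentBlock]] = {}
    for cand in candidates:
        conflict = False
        for other in by_query.get(cand.query_name, ()):
            ov = _overlap(cand.query_start, cand.query_end,
                          other.query_start, other.query_end)
            if ov >= overlap_frac * min(cand.query_span, other.query_span):
                conflict = True
                break
        if not conflict:
            for other in by_target.get(cand.target_name, ()):
                ov = _overlap(cand.target_start, cand.target_end,
                              other.target_start, other.target_end)
                if ov >= overlap_frac * min(cand.target_span, other.target_span):
                    conflict = True
                    break
        if conflict:
            continue
        kept.append(cand)
        by_query.setdefault(cand.query_name, []).append(cand)
        by_target.setdefault(cand.target_name, []).append(cand)

    return _chain(kept, max_chain_gap)


def _chain(kept: list[AlignmentBlock], max_chain_gap: int) -> list[SyntenyBlock]:
    # interval centres per assembly side, for the interposition test
    q_centres: dict[str, list[float]] = {}
    t_centres: dict[str, list[float]] = {}
    for b in kept:
        q_centres.setdefault(b.query_name, []).append((b.query_start + b.query_end) / 2)
        t_centres.setdefault(b.target_name, []).append((b.target_start + b.target_end) / 2)
    for v in q_centres.values():
        v.sort()
    for v in t_centres.values():
        v.sort()

    def interposed(centres: list[float], lo: float, hi: float) -> bool:
        if hi <= lo:
            return False
        i = bisect.bisect_right(centres, lo)
        return i < len(centres) and centres[i] < hi

    groups: dict[tuple[str, str, str], list[AlignmentBlock]] = {}
    for b in kept:
        groups.setdefault((b.query_name, b.target_name, b.strand), []).append(b)

    out: list[SyntenyBlock] = []
    chain_id = 0
    for (qn, tn, strand), blist in sorted(groups.items()):
        blist.sort(key=lambda b: b.query_start)
        chains: list[list[AlignmentBlock]] = []
        for b in blist:
            linked = False
            if chains:
                prev = chains[-1][-1]
                q_gap = b.query_start - prev.query_end
                if strand == "+":
                    t_gap = b.target_start - prev.target_end
                    collinear = b.target_start >= prev.target_start
                else:
                    t_gap = prev.target_start - b.target_end
                    collinear = b.target_end <= prev.target_end
                if (collinear and q_gap <= max_chain_gap and t_gap <= max_chain_gap
                        and t_gap >= -max_chain_gap
                        and not interposed(q_centres[qn], prev.query_end, b.query_start)
                        and not interposed(
                            t_centres[tn],
                            *((prev.target_end, b.target_start) if strand == "+"
                              else (b.target_end, prev.target_start)))):
                    chains[-1].append(b)
                    linked = True
            if not linked:
                chains.append([b])
        for chain in chains:
            span = sum(b.block_length for b in chain)
            for b in chain:
                out.append(SyntenyBlock(
                    b.query_name, b.query_start, b.query_end,
                    b.target_name, b.target_start, b.target_end,
                    b.strand, b.matches, b.block_length, dict(b.tags),
                    chain_id=chain_id, chain_span=span,
                ))
            chain_id += 1
    out.sort(key=lambda b: (b.query_name, b.query_start))
    return out


# ---------------------------------------------------------------------------
# continuity statistics


@dataclass
class GapFillReport:
    """Per-chromosome gap counts in orthologous regions, and how many filled."""

    per_chrom: dict[str, tuple[int, int]] = field(default_factory=dict)  # (total, filled)

    @property
    def total(self) -> int:
        return sum(t for t, _ in self.per_chrom.values())

    @property
    def filled(self) -> int:
        return sum(f for _, f in self.per_chrom.values())

    @property
    def fill_rate(self) -> float:
        return self.filled / self.total if self.total else float("nan")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [(c, t, f) for c, (t, f) in sorted(self.per_chrom.items())],
            columns=["chrom", "gaps_in_orthologous_regions", "filled"],
        )
        return df


def _containing_block(blocks: list[SyntenyBlock], starts: list[int],
                      lo: int, hi: int) -> SyntenyBlock | None:
    """The block whose query interval fully contains [lo, hi), if any."""
    i = bisect.bisect_right(starts, lo) - 1
    if i >= 0:
        b = blocks[i]
        if b.query_start <= lo and hi <= b.query_end:
            return b
    return None


def _project(b: SyntenyBlock, q_pos: int) -> int:
    """Project a query position through a gap-free block."""
    if b.strand == "+":
        return b.target_start + (q_pos - b.query_start)
    return b.target_end - (q_pos - b.query_start)


def gap_fill_stats(
    a_gaps: dict[str, list[tuple[int, int]]],
    assembly_b: Assembly,
    synteny: list[SyntenyBlock],
    flank: int = FLANK,
) -> GapFillReport:
    """Count reference N-gaps in orthologous regions and those spanned by b.

    A gap enters the denominator only when 1 kb of flank on each side lies
    inside a one-to-one block.  It counts as filled when both flanks project
    onto the same chromosome and chain of ``b`` and the implied spanning
    interval contains no N.
    """
    by_chrom: dict[str, list[SyntenyBlock]] = {}
    for b in synteny:
        by_chrom.setdefault(b.query_name, []).append(b)
    starts = {c: [b.query_start for b in v] for c, v in by_chrom.items()}

    report = GapFillReport()
    for chrom, gaps in a_gaps.items():
        total = filled = 0
        blocks = by_chrom.get(chrom, [])
        if blocks:
            for (gs, ge) in gaps:
                left = _containing_block(blocks, starts[chrom], gs - flank, gs)
                right = _containing_block(blocks, starts[chrom], ge, ge + flank)
                if left is None or right is None:
                    continue  # outside orthologous regions
                total += 1
                if left.target_name != right.target_name or \
                        left.chain_id != right.chain_id:
                    continue
                p1, p2 = _project(left, gs), _project(right, ge)
                lo, hi = min(p1, p2), max(p1, p2)
                span = assembly_b.chroms[left.target_name][lo:hi]
                if b"N" not in span and b"n" not in span:
                    filled += 1
        if total:
            report.per_chrom[chrom] = (total, filled)
    return report


def gapless_length_ratio(assembly_a: Assembly, assembly_b: Assembly) -> pd.DataFrame:
    """Per-chromosome ratio of non-N lengths, b over a.

    Chromosomes present in only one assembly, or entirely N in ``a``, are
    reported with a missing ratio rather than raising.
    """
    rows = []
    for chrom in assembly_a.chroms:
        a_len = assembly_a.gapless_length(chrom)
        if chrom not in assembly_b.chroms:
            logger.warning("chromosome %s missing from assembly b", chrom)
            rows.append((chrom, a_len, np.nan, np.nan))
            continue
        b_len = assembly_b.gapless_length(chrom)
        if a_len == 0:
            logger.warning("chromosome %s is entirely N in assembly a", chrom)
            rows.append((chrom, a_len, b_len, np.nan))
            continue
        rows.append((chrom, a_len, b_len, b_len / a_len))
    for chrom in assembly_b.chroms:
        if chrom not in assembly_a.chroms:
            logger.warning("chromosome %s missing from assembly a", chrom)
            rows.append((chrom, np.nan, assembly_b.gapless_length(chrom), np.nan))
    return pd.DataFrame(rows, columns=["chrom", "a_gapless", "b_gapless", "l_r"])
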