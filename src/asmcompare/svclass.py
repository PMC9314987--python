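"""Structural-variant classification from the one-to-one synteny map.

Within each collinear chain, coordinate gaps between consecutive blocks are
read as indels: sequence present only in the reference-like assembly ``a``
is a deletion (DEL), sequence present only in ``b`` an insertion (INS), and
simultaneous gaps on both sides are split into one DEL plus one INS.  A
minus-strand chain on an otherwise plus chromosome is an inversion (INV).
Duplications (DUP) come from the permissive alignment: one ``a`` interval
covered by two or more disjoint ``b`` intervals on the same chromosome.

Polarity follows the reference-like assembly: DEL means present in ``a``,
absent in ``b``.  Gaps equal on both sides are unaligned substitution
patches, not SVs, and are skipped.  Events overlapping a DUP call are
suppressed, since the duplication explains the alignment hole it leaves in
the unique-anchor map.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .alignkit import AlignmentBlock
from .synteny import SyntenyBlock

logger = logging.getLogger(__name__)

SV_TYPES = ("DEL", "INS", "DUP", "INV")
DEFAULT_MIN_LEN = 1000   # "short SVs" below 1 kb are discarded
INDEL_TOL = 50           # bp; coordinate slack below the small-variant scale
DUP_OVERLAP_FRAC = 0.8   # reciprocal overlap grouping copies of one locus


@dataclass
class StructuralVariant:
    """A typed intra-chromosomal event with intervals in both assemblies."""

    sv_type: str
    chrom: str
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    continuous: bool = True

    @property
    def length(self) -> int:
        return max(self.a_end - self.a_start, self.b_end - self.b_start)

    def validate(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type}")
        if self.length <= 0:
            raise ValueError(f"non-positive SV length: {self}")
        if self.sv_type == "DEL" and self.b_end != self.b_start:
            raise ValueError("DEL must have a zero-length b interval")
        if self.sv_type == "INS" and self.a_end != self.a_start:
            raise ValueError("INS must have a zero-length a interval")
        if self.sv_type == "INV" and (
                self.a_end <= self.a_start or self.b_end <= self.b_start):
            raise ValueError("INV needs positive length on both sides")


def _overlaps_any(sorted_ivs: list[tuple[int, int]], start: int, end: int) -> bool:
    if start >= end:
        return False
    for s, e in sorted_ivs:
        if s >= end:
            break
        if e > start:
            return True
    return False


def _n_free(ngaps: dict[str, list[tuple[int, int]]] | None,
            chrom: str, start: int, end: int) -> bool:
    if ngaps is None or start >= end:
        return True
    return not _overlaps_any(sorted(ngaps.get(chrom, [])), start, end)


# ---------------------------------------------------------------------------
# classification


def _dup_events(raw_blocks: list[AlignmentBlock], indel_tol: int
                ) -> tuple[list[StructuralVariant], dict[str, list[tuple[int, int]]],
                           dict[str, list[tuple[int, int]]]]:
    """Intra-chromosomal duplications from many-to-one raw alignments."""
    same_chrom = [b for b in raw_blocks if b.query_name == b.target_name]
    by_chrom: dict[str, list[AlignmentBlock]] = {}
    for b in same_chrom:
        by_chrom.setdefault(b.query_name, []).append(b)

    events: list[StructuralVariant] = []
    a_env: dict[str, list[tuple[int, int]]] = {}
    b_env: dict[str, list[tuple[int, int]]] = {}
    for chrom, blist in by_chrom.items():
        blist.sort(key=lambda b: b.query_start)
        used = [False] * len(blist)
        for i, bi in enumerate(blist):
            if used[i]:
                continue
            family = [i]
            for j in range(i + 1, len(blist)):
                bj = blist[j]
                if bj.query_start >= bi.query_end:
                    break
                ov = min(bi.query_end, bj.query_end) - bj.query_start
                if ov >= DUP_OVERLAP_FRAC * min(bi.query_span, bj.query_span):
                    family.append(j)
            if len(family) < 2:
                continue
            members = [blist[j] for j in family]
            # require disjoint target intervals (distinct copies)
            members.sort(key=lambda b: b.target_start)
            distinct = [members[0]]
            for m in members[1:]:
                if m.target_start >= distinct[-1].target_end - indel_tol:
                    distinct.append(m)
            if len(distinct) < 2:
                continue
            for j in family:
                used[j] = True
            # the copy sitting on the main diagonal is the locus itself;
            # every other copy is duplicated material
            def self_overlap(b: AlignmentBlock) -> int:
                return max(0, min(b.query_end, b.target_end)
                           - max(b.query_start, b.target_start))
            distinct.sort(key=self_overlap, reverse=True)
            origin, copies = distinct[0], distinct[1:]
            for c in copies:
                events.append(StructuralVariant(
                    "DUP", chrom, c.query_start, c.query_end,
                    c.target_start, c.target_end,
                ))
            # suppression envelopes cover the duplicated locus only: the
            # copies' own intervals plus the origin's matching stretch —
            # never the origin block's full extent, which may run far into
            # unrelated flanking alignment
            lo_a = min(c.query_start for c in copies)
            hi_a = max(c.query_end for c in copies)
            b_ivs = [(c.target_start, c.target_end) for c in copies]
            if origin.strand == "+":
                off = origin.target_start - origin.query_start
                b_ivs.append((lo_a + off, hi_a + off))
            else:
                b_ivs.append((origin.target_start, origin.target_end))
            a_env.setdefault(chrom, []).append((lo_a, hi_a))
            for lo_b, hi_b in b_ivs:
                b_env.setdefault(chrom, []).append((lo_b, hi_b))
    return events, a_env, b_env


def classify_svs(
    chains: list[SyntenyBlock],
    raw_blocks: list[AlignmentBlock],
    ngaps_a: dict[str, list[tuple[int, int]]] | None = None,
    ngaps_b: dict[str, list[tuple[int, int]]] | None = None,
    indel_tol: int = INDEL_TOL,
) -> list[StructuralVariant]:
    """Classify DEL/INS/DUP/INV between two name-matched assemblies.

    ``chains`` is the one-to-one synteny map; ``raw_blocks`` the permissive
    alignment used for duplication detection.  Each event carries
    ``continuous=True`` iff its intervals are N-free on both assemblies.
    """
    dups, dup_a_env, dup_b_env = _dup_events(raw_blocks, indel_tol)

    by_chain: dict[int, list[SyntenyBlock]] = {}
    for b in chains:
        by_chain.setdefault(b.chain_id, []).append(b)

    events: list[StructuralVariant] = []
    for chain in by_chain.values():
        chain.sort(key=lambda b: b.query_start)
        first = chain[0]
        if first.query_name != first.target_name:
            logger.warning(
                "chain %s spans %s->%s; inter-chromosomal events are not SVs, skipping",
                first.chain_id, first.query_name, first.target_name)
            continue
        chrom = first.query_name
        if first.strand == "-":
            events.append(StructuralVariant(
                "INV", chrom,
                min(b.query_start for b in chain), max(b.query_end for b in chain),
                min(b.target_start for b in chain), max(b.target_end for b in chain),
            ))
            continue
        for prev, cur in zip(chain, chain[1:]):
            a_gap = cur.query_start - prev.query_end
            b_gap = cur.target_start - prev.target_end
            if a_gap < -indel_tol or b_gap < -indel_tol:
                continue
            a_gap, b_gap = max(a_gap, 0), max(b_gap, 0)
            if a_gap > indel_tol and b_gap <= indel_tol:
                events.append(StructuralVariant(
                    "DEL", chrom, prev.query_end, cur.query_start,
                    prev.target_end, prev.target_end))
            elif b_gap > indel_tol and a_gap <= indel_tol:
                events.append(StructuralVariant(
                    "INS", chrom, prev.query_end, prev.query_end,
                    prev.target_end, cur.target_start))
            elif a_gap > indel_tol and b_gap > indel_tol:
                if abs(a_gap - b_gap) <= indel_tol:
                    continue  # unaligned substitution patch, not an SV
                events.append(StructuralVariant(
                    "DEL", chrom, prev.query_end, cur.query_start,
                    prev.target_end, prev.target_end))
                events.append(StructuralVariant(
                    "INS", chrom, prev.query_end, prev.query_end,
                    prev.target_end, cur.target_start))

    # indel calls explained by a duplication are artefacts of the unique-
    # anchor map and are dropped in favour of the DUP event
    dup_a_sorted = {c: sorted(v) for c, v in dup_a_env.items()}
    dup_b_sorted = {c: sorted(v) for c, v in dup_b_env.items()}
    cleaned = []
    for ev in events:
        pad = indel_tol
        in_dup = (
            _overlaps_any(dup_a_sorted.get(ev.chrom, []),
                          ev.a_start - pad, ev.a_end + pad)
            or _overlaps_any(dup_b_sorted.get(ev.chrom, []),
                             ev.b_start - pad, ev.b_end + pad)
        )
        if not in_dup:
            cleaned.append(ev)
    events = cleaned + dups

    for ev in events:
        ev.continuous = (
            _n_free(ngaps_a, ev.chrom, ev.a_start, ev.a_end)
            and _n_free(ngaps_b, ev.chrom, ev.b_start, ev.b_end)
        )
        ev.validate()
    events.sort(key=lambda e: (e.chrom, e.a_start, e.sv_type))
    return events


def filter_svs(
    svs: list[StructuralVariant],
    min_len: int = DEFAULT_MIN_LEN,
    require_continuous: bool = True,
) -> list[StructuralVariant]:
    """Keep events of at least ``min_len`` bp (and N-free ones if required)."""
    return [
        sv for sv in svs
        if sv.length >= min_len and (sv.continuous or not require_continuous)
    ]


def count_by_chromosome(
    svs: list[StructuralVariant],
    chrom_lengths: dict[str, int],
    x_name: str | None = None,
) -> pd.DataFrame:
    """Per-chromosome SV tally: one row per chromosome, one column per type."""
    table = pd.DataFrame(
        0, index=pd.Index(chrom_lengths, name="chrom"), columns=list(SV_TYPES)
    )
    for sv in svs:
        if sv.chrom not in table.index:
            raise ValueError(f"SV on unknown chromosome {sv.chrom}")
        table.loc[sv.chrom, sv.sv_type] += 1
    table.insert(0, "length", [chrom_lengths[c] for c in table.index])
    table.insert(1, "is_x", [c == x_name for c in table.index])
    return table


# ---------------------------------------------------------------------------
# export


def write_sv_tsv(svs: list[StructuralVariant], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["chrom", "a_start", "a_end", "b_start", "b_end",
                    "type", "length", "continuous"])
        for sv in svs:
            w.writerow([sv.chrom, sv.a_start, sv.a_end, sv.b_start, sv.b_end,
                        sv.sv_type, sv.length, int(sv.continuous)])


def write_sv_vcf(svs: list[StructuralVariant], path: str | Path,
                 chrom_lengths: dict[str, int] | None = None) -> None:
    """Symbolic-ALT VCF export (1-based positions per the VCF spec)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
        fh.write('##ALT=<ID=INS,Description="Insertion">\n')
        fh.write('##ALT=<ID=DUP,Description="Duplication">\n')
        fh.write('##ALT=<ID=INV,Description="Inversion">\n')
        for chrom, length in (chrom_lengths or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, sv in enumerate(svs, 1):
            pos = sv.a_start + 1 if sv.a_end > sv.a_start else max(sv.a_start, 1)
            end = max(sv.a_end, pos)
            svlen = sv.length if sv.sv_type != "DEL" else -sv.length
            fh.write(
                f"{sv.chrom}\t{pos}\tsv{i}\tN\t<{sv.sv_type}>\t.\tPASS\t"
                f"SVTYPE={sv.sv_type};END={end};SVLEN={svlen}\n"
            )
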