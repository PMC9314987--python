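"""Whole-genome local alignment for low-divergence assembly pairs.

The aligner anchors on exact k-mer matches and chains them along diagonals
into gap-free blocks, which is adequate when the two assemblies differ by
point substitutions plus large planted rearrangements.  Two anchor policies
are exposed:

* ``max_occ=1`` (default): anchors must be unique in both assemblies.
  Repeated sequence drops out and is recovered later as many-to-one
  alignments by the segmental-duplication stage.
* ``max_occ>1``: k-mers occurring up to ``max_occ`` times on each side are
  paired in all combinations, so two copies of a duplication each produce a
  block onto their common locus in the other assembly.

Block identity is a gap-free column comparison over the chained span: the
two spans are compared position by position (reverse-complemented for minus
blocks) and identity = matching columns / block length.  PAF is the only
interchange format, so externally produced alignments (minimap2, MashMap)
can be substituted for the built-in aligner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np

from .seqio import Assembly, encode, revcomp

DEFAULT_K = 21
DEFAULT_MIN_BLOCK = 1000     # bp; the segmental-duplication unit
DEFAULT_GAP_TOL = 100        # bp of tolerated diagonal drift within a block
DEFAULT_MAX_ANCHOR_GAP = 200  # bp between consecutive anchors within a block


@dataclass
class AlignmentBlock:
    """One gapless chained local alignment between the two assemblies.

    Query coordinates are always on the + strand per PAF convention; a minus
    block pairs the query interval with the reverse complement of the target
    interval.
    """

    query_name: str
    query_start: int
    query_end: int
    target_name: str
    target_start: int
    target_end: int
    strand: str              # "+" or "-"
    matches: int
    block_length: int
    tags: dict[str, str] = field(default_factory=dict)

    @property
    def identity(self) -> float:
        return self.matches / self.block_length if self.block_length else 0.0

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start

    def validate(self) -> None:
        if self.query_start >= self.query_end or self.target_start >= self.target_end:
            raise ValueError(f"degenerate block interval: {self}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not 0 <= self.matches <= self.block_length:
            raise ValueError(f"matches/block_length inconsistent: {self}")
        if self.block_length < min(self.query_span, self.target_span):
            raise ValueError(f"block_length below aligned span: {self}")


# ---------------------------------------------------------------------------
# k-mer machinery


def _kmer_values(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(canonical value, forward-is-canonical flag, validity) per window."""
    n = codes.size - k + 1
    if n <= 0:
        empty = np.empty(0, dtype=np.uint64)
        return empty, np.empty(0, bool), np.empty(0, bool)
    safe = np.where(codes < 4, codes, 0).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    for i in range(k):
        fwd |= safe[i:i + n] << np.uint64(2 * (k - 1 - i))
        rev |= (np.uint64(3) - safe[i:i + n]) << np.uint64(2 * i)
    bad = (codes == 4).astype(np.int32)
    cs = np.concatenate([[0], np.cumsum(bad)])
    valid = (cs[k:] - cs[:-k]) == 0
    fwd_is_canon = fwd <= rev
    return np.where(fwd_is_canon, fwd, rev), fwd_is_canon, valid


def _genome_kmers(assembly: Assembly, k: int):
    """Per-assembly k-mer table, sorted by canonical value."""
    vals, canon, gpos = [], [], []
    offsets, names = [], []
    off = 0
    for name, seq in assembly.chroms.items():
        codes = encode(seq)
        v, c, ok = _kmer_values(codes, k)
        idx = np.flatnonzero(ok)
        vals.append(v[idx])
        canon.append(c[idx])
        gpos.append(idx.astype(np.int64) + off)
        offsets.append(off)
        names.append(name)
        off += len(seq)
    v = np.concatenate(vals) if vals else np.empty(0, np.uint64)
    c = np.concatenate(canon) if canon else np.empty(0, bool)
    p = np.concatenate(gpos) if gpos else np.empty(0, np.int64)
    order = np.argsort(v)
    return v[order], c[order], p[order], np.array(offsets + [off], np.int64), names


def _paired_anchors(tables_a, tables_b, max_occ: int):
    """All (a, b) anchor pairs sharing a canonical k-mer, occ <= max_occ per side.

    Also returns each pair's occurrence count on both sides, so the strict
    unique-anchor subset can be taken without re-joining.
    """
    av, ac, ap = tables_a[:3]
    bv, bc, bp = tables_b[:3]
    a_start = np.flatnonzero(np.concatenate([[True], av[1:] != av[:-1]])) \
        if av.size else np.empty(0, np.int64)
    b_start = np.flatnonzero(np.concatenate([[True], bv[1:] != bv[:-1]])) \
        if bv.size else np.empty(0, np.int64)
    a_count = np.diff(np.append(a_start, av.size))
    b_count = np.diff(np.append(b_start, bv.size))
    common, ia, ib = np.intersect1d(av[a_start], bv[b_start],
                                    assume_unique=True, return_indices=True)
    if common.size == 0:
        z = np.empty(0, np.int64)
        return z, z, np.empty(0, bool), z, z
    na, nb = a_count[ia], b_count[ib]
    sa, sb = a_start[ia], b_start[ib]
    keep = (na <= max_occ) & (nb <= max_occ)
    na, nb, sa, sb = na[keep], nb[keep], sa[keep], sb[keep]
    m = na * nb
    cum = np.concatenate([[0], np.cumsum(m)])
    total = int(cum[-1])
    g = np.repeat(np.arange(na.size), m)
    t = np.arange(total) - cum[g]
    a_sel = sa[g] + t // nb[g]
    b_sel = sb[g] + t % nb[g]
    same = ac[a_sel] == bc[b_sel]
    return ap[a_sel], bp[b_sel], same, na[g], nb[g]


def _to_chrom(gpos: np.ndarray, offsets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ci = np.searchsorted(offsets, gpos, side="right") - 1
    return ci, gpos - offsets[ci]


def _check_k(assembly_a: Assembly, assembly_b: Assembly, k: int) -> bool:
    """Validate k against both assemblies; False means nothing to align."""
    if k < 11:
        raise ValueError("k must be >= 11 to keep anchors specific")
    lengths = [len(s) for s in assembly_a.chroms.values()] + \
              [len(s) for s in assembly_b.chroms.values()]
    if not lengths or min(lengths) == 0:
        return False
    if k > min(lengths):
        raise ValueError(f"k={k} exceeds the shortest chromosome ({min(lengths)} bp)")
    return True


def _chain_blocks(assembly_a, assembly_b, tables_a, tables_b, anchors,
                  k, min_block, gap_tol, max_anchor_gap) -> list[AlignmentBlock]:
    a_pos, b_pos, same_strand = anchors
    if a_pos.size == 0:
        return []
    aoff, anames = tables_a[3], tables_a[4]
    boff, bnames = tables_b[3], tables_b[4]

    a_ci, a_local = _to_chrom(a_pos, aoff)
    b_ci, b_local = _to_chrom(b_pos, boff)
    strand_code = same_strand.astype(np.int8)  # 1 = plus, 0 = minus
    # plus anchors share b - a; minus anchors share a + b (anti-diagonal)
    diag = np.where(same_strand, b_local - a_local, b_local + a_local)

    # sort by (a_chrom, b_chrom, strand, diagonal, a position): anchors of one
    # gap-free block are then contiguous, and parallel repeat copies (same
    # chromosome pair, distant diagonals) never interleave.  One composite
    # int64 key sorts faster than a 5-key lexsort.
    span = int(aoff[-1] + boff[-1]) + 1
    n_pairs = (len(anames) + 1) * (len(bnames) + 1) * 2
    if n_pairs * 2 * span * span < 2**62:
        pair_id = (a_ci.astype(np.int64) * (len(bnames) + 1) + b_ci) * 2 + strand_code
        key = (pair_id * (2 * span) + (diag + span)) * span + a_local
        order = np.argsort(key)
    else:
        order = np.lexsort((a_local, diag, strand_code, b_ci, a_ci))
    a_ci, b_ci = a_ci[order], b_ci[order]
    a_local, b_local = a_local[order], b_local[order]
    strand_code, diag = strand_code[order], diag[order]

    split = np.ones(a_ci.size, bool)
    split[1:] = (
        (np.diff(a_ci) != 0) | (np.diff(b_ci) != 0)
        | (np.diff(strand_code) != 0) | (np.diff(diag) > gap_tol)
        | (np.abs(np.diff(a_local)) > max_anchor_gap)
    )
    bounds = np.append(np.flatnonzero(split), a_ci.size)

    blocks: list[AlignmentBlock] = []
    for gi in range(bounds.size - 1):
        lo, hi = bounds[gi], bounds[gi + 1]
        ca, cb = a_local[lo:hi], b_local[lo:hi]
        qs, qe = int(ca.min()), int(ca.max()) + k
        ts, te = int(cb.min()), int(cb.max()) + k
        if min(qe - qs, te - ts) < min_block:
            continue
        qname = anames[a_ci[lo]]
        tname = bnames[b_ci[lo]]
        blocks.append(_score_block(
            assembly_a.chroms[qname], assembly_b.chroms[tname],
            qname, qs, qe, tname, ts, te,
            "+" if strand_code[lo] == 1 else "-",
        ))
    blocks.sort(key=lambda b: (b.query_name, b.query_start, b.target_name,
                               b.target_start, b.strand))
    return blocks


def anchor_chain_align(
    assembly_a: Assembly,
    assembly_b: Assembly,
    k: int = DEFAULT_K,
    min_block: int = DEFAULT_MIN_BLOCK,
    gap_tol: int = DEFAULT_GAP_TOL,
    max_anchor_gap: int = DEFAULT_MAX_ANCHOR_GAP,
    max_occ: int = 1,
) -> list[AlignmentBlock]:
    """Anchor-and-chain alignment of assembly_a (query) onto assembly_b (target).

    Blocks are maximal runs of co-diagonal k-mer anchors; a chain is split
    wherever the anchor diagonal jumps by more than ``gap_tol``, the strand
    flips, or consecutive anchors are more than ``max_anchor_gap`` apart.
    Reported blocks are at least ``min_block`` long and carry an identity
    computed by direct column comparison of the two spans.
    """
    if not _check_k(assembly_a, assembly_b, k):
        return []
    tables_a = _genome_kmers(assembly_a, k)
    tables_b = _genome_kmers(assembly_b, k)
    ap, bp, same, _, _ = _paired_anchors(tables_a, tables_b, max_occ)
    return _chain_blocks(assembly_a, assembly_b, tables_a, tables_b,
                         (ap, bp, same), k, min_block, gap_tol, max_anchor_gap)


def align_pair(
    assembly_a: Assembly,
    assembly_b: Assembly,
    k: int = DEFAULT_K,
    min_block: int = DEFAULT_MIN_BLOCK,
    gap_tol: int = DEFAULT_GAP_TOL,
    max_anchor_gap: int = DEFAULT_MAX_ANCHOR_GAP,
    max_occ_multi: int = 4,
) -> tuple[list[AlignmentBlock], list[AlignmentBlock]]:
    """Both anchor policies over one shared k-mer scan.

    Returns ``(unique_blocks, multi_blocks)``: the unique-anchor alignment
    feeding the one-to-one synteny map, and the permissive alignment (k-mer
    occurrence up to ``max_occ_multi`` per side) in which repeated loci show
    up as many-to-one blocks for duplication detection.
    """
    if not _check_k(assembly_a, assembly_b, k):
        return [], []
    tables_a = _genome_kmers(assembly_a, k)
    tables_b = _genome_kmers(assembly_b, k)
    ap, bp, same, occ_a, occ_b = _paired_anchors(tables_a, tables_b, max_occ_multi)
    multi = _chain_blocks(assembly_a, assembly_b, tables_a, tables_b,
                          (ap, bp, same), k, min_block, gap_tol, max_anchor_gap)
    uniq = (occ_a == 1) & (occ_b == 1)
    unique = _chain_blocks(assembly_a, assembly_b, tables_a, tables_b,
                           (ap[uniq], bp[uniq], same[uniq]),
                           k, min_block, gap_tol, max_anchor_gap)
    return unique, multi


def _score_block(qseq: bytes, tseq: bytes, qname: str, qs: int, qe: int,
                 tname: str, ts: int, te: int, strand: str) -> AlignmentBlock:
    q = np.frombuffer(qseq[qs:qe], dtype=np.uint8)
    tpart = tseq[ts:te]
    if strand == "-":
        tpart = revcomp(tpart)
    t = np.frombuffer(tpart, dtype=np.uint8)
    n = min(q.size, t.size)
    matches = int(np.count_nonzero(q[:n] == t[:n]))
    block_length = max(q.size, t.size)
    return AlignmentBlock(qname, qs, qe, tname, ts, te, strand, matches, block_length)


# ---------------------------------------------------------------------------
# pairwise identity


def pairwise_identity(seq1: bytes | str, seq2: bytes | str) -> float:
    """Global-alignment identity under unit match/mismatch/gap scoring.

    Computed as ``1 - d / max(len1, len2)`` where ``d`` is the global
    (Needleman-Wunsch) edit distance; this equals matches over alignment
    columns whenever indels fall on one side only, and is symmetric in its
    arguments.
    """
    if isinstance(seq1, bytes):
        seq1 = seq1.decode()
    if isinstance(seq2, bytes):
        seq2 = seq2.decode()
    if not seq1 or not seq2:
        raise ValueError("pairwise_identity requires two non-empty sequences")
    d = edlib.align(seq1, seq2, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(seq1), len(seq2))


# ---------------------------------------------------------------------------
# PAF I/O


def write_paf(blocks: list[AlignmentBlock], path: str | Path,
              query_lengths: dict[str, int] | None = None,
              target_lengths: dict[str, int] | None = None) -> None:
    query_lengths = query_lengths or {}
    target_lengths = target_lengths or {}
    with open(path, "w") as fh:
        for b in blocks:
            fields = [
                b.query_name, query_lengths.get(b.query_name, b.query_end),
                b.query_start, b.query_end, b.strand,
                b.target_name, target_lengths.get(b.target_name, b.target_end),
                b.target_start, b.target_end,
                b.matches, b.block_length, 255,
            ]
            tags = [f"{k}:{v}" for k, v in b.tags.items()]
            fh.write("\t".join(map(str, fields + tags)) + "\n")


def read_paf(path: str | Path) -> list[AlignmentBlock]:
    blocks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(f"{path}:{lineno}: PAF line has {len(parts)} columns, needs 12")
            try:
                block = AlignmentBlock(
                    query_name=parts[0], query_start=int(parts[2]),
                    query_end=int(parts[3]), strand=parts[4],
                    target_name=parts[5], target_start=int(parts[7]),
                    target_end=int(parts[8]), matches=int(parts[9]),
                    block_length=int(parts[10]),
                    tags=dict(t.split(":", 1) for t in parts[12:]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed PAF line ({exc})") from exc
            try:
                block.validate()
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: invalid alignment ({exc})") from exc
            blocks.append(block)
    return blocks
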