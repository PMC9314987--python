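"""Segmental-duplication detection and parental/derived direction calling.

A segmental duplication (SD) shows up in a whole-genome comparison as a
many-to-one alignment: two loci of one assembly (the *copies*) covering a
single locus of the other (the *anchor*).  Which copy is parental is decided
by two rules, switched on whether a copy sits at a synteny-chain boundary:

* internal SD (iSD): the parental copy lies in the longer synteny chain —
  a derived insertion lands in younger, shorter-chained surroundings;
* boundary SD (bSD): the copy with the higher global-alignment identity to
  the anchor is parental (above the orthology threshold of 0.90), because
  orthologues are closer than paralogues.

The parental copy's chromosome class (X vs autosome) then categorises the
duplication direction: A>A, A>X or X>A, counted on the derived copy's
chromosome.  An excess of X>A events is the signature of gene traffic out
of the X expected under meiotic sex chromosome inactivation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .alignkit import AlignmentBlock, pairwise_identity
from .seqio import Assembly, revcomp
from .synteny import SyntenyBlock

logger = logging.getLogger(__name__)

DEFAULT_MIN_SD_LEN = 1000          # bp; alignments over 1 kb count as SDs
DEFAULT_MIN_RECIPROCAL_OVERLAP = 0.8
DEFAULT_BOUNDARY_TOL = 1000        # bp from a chain end that makes a bSD
IDENTITY_THRESHOLD = 0.90          # the winner of the bSD rule must clear this

DIRECTIONS = ("A>A", "A>X", "X>A")


@dataclass
class SDCopy:
    chrom: str
    start: int
    end: int
    strand: str = "+"
    identity_vs_anchor: float | None = None
    chain_span: int = 0

    @property
    def span(self) -> int:
        return self.end - self.start

    def locus(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class SDPair:
    """Two same-assembly copies aligned onto one locus of the other assembly."""

    family_id: int
    copy1: SDCopy
    copy2: SDCopy
    anchor_chrom: str
    anchor_start: int
    anchor_end: int
    copy_side: str = "query"       # which alignment side the copies live on
    sd_class: str = ""             # bSD / iSD
    parental: str = "unresolved"   # copy1 / copy2 / unresolved
    direction: str = "unresolved"

    @property
    def length(self) -> int:
        return min(self.copy1.span, self.copy2.span)

    def copies(self) -> tuple[SDCopy, SDCopy]:
        return (self.copy1, self.copy2)

    def parental_copy(self) -> SDCopy | None:
        return {"copy1": self.copy1, "copy2": self.copy2}.get(self.parental)

    def derived_copy(self) -> SDCopy | None:
        return {"copy1": self.copy2, "copy2": self.copy1}.get(self.parental)

    def derived_locus(self) -> tuple[str, int, int]:
        derived = self.derived_copy()
        if derived is None:
            raise ValueError("parental copy not resolved")
        return derived.locus()


def _reciprocal_overlap(s1, e1, s2, e2) -> float:
    ov = min(e1, e2) - max(s1, s2)
    return ov / max(min(e1 - s1, e2 - s2), 1) if ov > 0 else 0.0


# ---------------------------------------------------------------------------
# detection


def _oriented(block: AlignmentBlock, copy_side: str):
    """(copy locus, anchor locus) view of a block."""
    if copy_side == "query":
        return ((block.query_name, block.query_start, block.query_end),
                (block.target_name, block.target_start, block.target_end))
    return ((block.target_name, block.target_start, block.target_end),
            (block.query_name, block.query_start, block.query_end))


def _trim_to_anchor(copy: tuple[str, int, int], anchor: tuple[str, int, int],
                    strand: str, lo: int, hi: int) -> tuple[str, int, int]:
    """Project an anchor sub-interval [lo, hi) onto the copy side of a block.

    Blocks are gap-free chains, so the projection is a simple offset; on a
    minus block the ends swap.
    """
    _, a_s, a_e = anchor
    off_lo, off_hi = lo - a_s, a_e - hi
    c_chrom, c_s, c_e = copy
    if strand == "+":
        s, e = c_s + off_lo, c_e - off_hi
    else:
        s, e = c_s + off_hi, c_e - off_lo
    return (c_chrom, max(s, c_s), min(e, c_e))


def find_many_to_one(
    raw_blocks: list[AlignmentBlock],
    min_len: int = DEFAULT_MIN_SD_LEN,
    min_reciprocal_overlap: float = DEFAULT_MIN_RECIPROCAL_OVERLAP,
    copy_side: str = "query",
    inter_chromosomal_only: bool = True,
) -> list[SDPair]:
    """Group many-to-one alignments into candidate SD pairs.

    Every two blocks whose anchor intervals overlap by at least
    ``min_reciprocal_overlap`` of the shorter one are trimmed to their
    shared anchor window; if the trimmed copy loci are distinct and at least
    ``min_len`` long they form an SD pair.  Pairs touching a common copy
    locus share a family id, so an n-copy family carries C(n, 2) pairs.
    Intra-chromosomal tandem families (both copies and the anchor on one
    chromosome) are the DUP class of the SV catalogue and are excluded by
    default.
    """
    if copy_side not in ("query", "target"):
        raise ValueError("copy_side must be 'query' or 'target'")
    entries = []
    for b in raw_blocks:
        copy, anchor = _oriented(b, copy_side)
        if min(copy[2] - copy[1], anchor[2] - anchor[1]) >= min_len:
            entries.append((copy, anchor, b.strand))

    by_anchor: dict[str, list] = {}
    for entry in entries:
        by_anchor.setdefault(entry[1][0], []).append(entry)

    raw_pairs: list[SDPair] = []
    for anchor_chrom, elist in sorted(by_anchor.items()):
        elist.sort(key=lambda e: e[1][1])
        for i, (ci, ai, si) in enumerate(elist):
            for j in range(i + 1, len(elist)):
                cj, aj, sj = elist[j]
                if aj[1] >= ai[2]:
                    break
                lo, hi = max(ai[1], aj[1]), min(ai[2], aj[2])
                if hi - lo < min_len or hi - lo < min_reciprocal_overlap * min(
                        ai[2] - ai[1], aj[2] - aj[1]):
                    continue
                t1 = _trim_to_anchor(ci, ai, si, lo, hi)
                t2 = _trim_to_anchor(cj, aj, sj, lo, hi)
                if min(t1[2] - t1[1], t2[2] - t2[1]) < min_len:
                    continue
                if t1[0] == t2[0] and _reciprocal_overlap(
                        t1[1], t1[2], t2[1], t2[2]) >= 0.5:
                    continue  # the same locus seen twice, not two copies
                if inter_chromosomal_only and t1[0] == t2[0] == anchor_chrom:
                    continue
                raw_pairs.append(SDPair(
                    family_id=0,
                    copy1=SDCopy(*t1, strand=si),
                    copy2=SDCopy(*t2, strand=sj),
                    anchor_chrom=anchor_chrom, anchor_start=lo, anchor_end=hi,
                    copy_side=copy_side,
                ))
    return _assign_families(_dedup_pairs(raw_pairs))


def _same_locus(c1: SDCopy, c2: SDCopy) -> bool:
    return c1.chrom == c2.chrom and _reciprocal_overlap(
        c1.start, c1.end, c2.start, c2.end) >= 0.5


def _dedup_pairs(pairs: list[SDPair]) -> list[SDPair]:
    """Collapse pairs describing the same two copies.

    The same duplication is often seen through several overlapping anchor
    windows (and, when both assemblies carry both copies, through two
    mirrored anchors); keep the widest view of each copy pair.
    """
    pairs = sorted(pairs, key=lambda p: -p.length)
    kept: list[SDPair] = []
    for p in pairs:
        c = sorted(p.copies(), key=lambda x: (x.chrom, x.start))
        if not any(
            _same_locus(c[0], d[0]) and _same_locus(c[1], d[1])
            for q in kept
            for d in [sorted(q.copies(), key=lambda x: (x.chrom, x.start))]
        ):
            kept.append(p)
    return kept


def _assign_families(pairs: list[SDPair]) -> list[SDPair]:
    """Connected components over shared copy loci define SD families."""
    parent = list(range(len(pairs)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(pairs)):
        for j in range(i + 1, len(pairs)):
            if any(_same_locus(ci, cj)
                   for ci in pairs[i].copies() for cj in pairs[j].copies()):
                parent[find(i)] = find(j)
    roots: dict[int, int] = {}
    for i, p in enumerate(pairs):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots) + 1
        p.family_id = roots[r]
    pairs.sort(key=lambda p: (p.family_id, p.anchor_chrom, p.anchor_start))
    return pairs


# ---------------------------------------------------------------------------
# bSD/iSD classification and parental resolution


def _copy_side_interval(b: SyntenyBlock, copy_side: str) -> tuple[str, int, int]:
    if copy_side == "query":
        return (b.query_name, b.query_start, b.query_end)
    return (b.target_name, b.target_start, b.target_end)


def classify_sd(
    pair: SDPair,
    chains: list[SyntenyBlock],
    boundary_tol: int = DEFAULT_BOUNDARY_TOL,
) -> SDPair:
    """Attach sd_class (bSD/iSD) and per-copy chain spans.

    A copy not covered by any one-to-one chain, or lying within
    ``boundary_tol`` of its enclosing chain's end (or beyond it), marks the
    pair as boundary-derived.
    """
    spans: dict[int, int] = {}
    envelopes: dict[str, dict[int, tuple[int, int]]] = {}
    cover: dict[str, dict[int, list[tuple[int, int]]]] = {}
    for b in chains:
        chrom, s, e = _copy_side_interval(b, pair.copy_side)
        spans[b.chain_id] = b.chain_span
        env = envelopes.setdefault(chrom, {})
        lo, hi = env.get(b.chain_id, (s, e))
        env[b.chain_id] = (min(lo, s), max(hi, e))
        cover.setdefault(chrom, {}).setdefault(b.chain_id, []).append((s, e))

    any_boundary = False
    for copy in pair.copies():
        best_chain, best_cov = None, 0
        for chain_id, ivs in cover.get(copy.chrom, {}).items():
            cov = sum(max(0, min(copy.end, e) - max(copy.start, s)) for s, e in ivs)
            if cov > best_cov:
                best_chain, best_cov = chain_id, cov
        if best_chain is None or best_cov < 0.5 * copy.span:
            copy.chain_span = 0
            any_boundary = True
            continue
        copy.chain_span = spans[best_chain]
        env_lo, env_hi = envelopes[copy.chrom][best_chain]
        if (copy.start - env_lo < boundary_tol
                or env_hi - copy.end < boundary_tol):
            any_boundary = True
    pair.sd_class = "bSD" if any_boundary else "iSD"
    return pair


def _copy_sequence(copy: SDCopy, assembly: Assembly) -> bytes:
    seq = assembly.chroms[copy.chrom][copy.start:copy.end]
    return revcomp(seq) if copy.strand == "-" else seq


def resolve_parent(
    pair: SDPair,
    copy_assembly: Assembly,
    anchor_assembly: Assembly,
    identity_threshold: float = IDENTITY_THRESHOLD,
) -> SDPair:
    """Decide the parental copy and the duplication direction.

    iSD pairs use the synteny-length rule (larger chain span is parental);
    equal spans fall back to the identity rule.  bSD pairs use identity of
    each copy against the anchor sequence; the winner must exceed the
    orthology threshold, otherwise the pair stays unresolved.
    """
    winner = ""
    if pair.sd_class == "iSD" and pair.copy1.chain_span != pair.copy2.chain_span:
        winner = "copy1" if pair.copy1.chain_span > pair.copy2.chain_span else "copy2"
    else:
        try:
            anchor_seq = anchor_assembly.chroms[pair.anchor_chrom][
                pair.anchor_start:pair.anchor_end]
            id1 = pairwise_identity(_copy_sequence(pair.copy1, copy_assembly),
                                    anchor_seq)
            id2 = pairwise_identity(_copy_sequence(pair.copy2, copy_assembly),
                                    anchor_seq)
        except (KeyError, ValueError) as exc:
            logger.warning("family %d: cannot score identities (%s); unresolved",
                           pair.family_id, exc)
            pair.parental = pair.direction = "unresolved"
            return pair
        pair.copy1.identity_vs_anchor = id1
        pair.copy2.identity_vs_anchor = id2
        if id1 != id2 and max(id1, id2) > identity_threshold:
            winner = "copy1" if id1 > id2 else "copy2"

    if not winner:
        pair.parental = pair.direction = "unresolved"
        return pair
    pair.parental = winner
    parent, derived = pair.parental_copy(), pair.derived_copy()
    x = copy_assembly.x_name
    pclass = "X" if parent.chrom == x else "A"
    dclass = "X" if derived.chrom == x else "A"
    pair.direction = f"{pclass}>{dclass}"
    return pair


# ---------------------------------------------------------------------------
# direction counts and gene lists


def categorize_direction(
    pairs: list[SDPair],
    chrom_lengths: dict[str, int],
    x_name: str,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Count resolved SD pairs per direction on the derived copy's chromosome.

    Returns the per-chromosome table plus a genome-wide summary including
    the unresolved tally; the summary always conserves the pair total.
    """
    table = pd.DataFrame(
        0, index=pd.Index(chrom_lengths, name="chrom"), columns=list(DIRECTIONS)
    )
    summary = {d: 0 for d in DIRECTIONS}
    summary["unresolved"] = 0
    summary["other"] = 0
    for p in pairs:
        if p.parental == "unresolved":
            summary["unresolved"] += 1
            continue
        if p.direction not in DIRECTIONS:
            summary["other"] += 1
            continue
        summary[p.direction] += 1
        chrom = p.derived_copy().chrom
        if chrom in table.index:
            table.loc[chrom, p.direction] += 1
    table.insert(0, "length", [chrom_lengths[c] for c in table.index])
    table.insert(1, "is_x", [c == x_name for c in table.index])
    return table, summary


def remove_sd_insertions(svs, pairs: list[SDPair], tol: int = 200,
                         min_len: int = DEFAULT_MIN_SD_LEN):
    """Drop SV calls that are really SD derived-copy insertions.

    A boundary-type derived copy exists in only one assembly, so the SV
    walk sees it as a large insertion; it belongs to the SD catalogue, and
    keeping it in both would double-count the event across the two
    analyses.  ``svs`` are filtered on their b-side intervals against the
    derived loci of resolved pairs.
    """
    derived = []
    for p in pairs:
        if p.parental != "unresolved":
            derived.append(p.derived_locus())
    out = []
    for sv in svs:
        hits = [
            (start, end) for chrom, start, end in derived
            if chrom == sv.chrom
            and min(end, sv.b_end + tol) - max(start, sv.b_start - tol)
            > 0.5 * (end - start)
        ]
        if not hits:
            out.append(sv)
            continue
        if sv.sv_type == "INS":
            # an adjacent genuine insertion may have fused with the derived
            # copies into one call: subtract them and keep the largest
            # unexplained piece, if it is still of SV size
            pieces = [(sv.b_start, sv.b_end)]
            for start, end in sorted(hits):
                nxt = []
                for lo, hi in pieces:
                    if start - lo > 0:
                        nxt.append((lo, min(start, hi)))
                    if hi - end > 0:
                        nxt.append((max(end, lo), hi))
                pieces = nxt
            pieces = [(lo, hi) for lo, hi in pieces if hi - lo >= min_len]
            if pieces:
                lo, hi = max(pieces, key=lambda iv: iv[1] - iv[0])
                if hi - lo < sv.b_end - sv.b_start:
                    sv.b_start, sv.b_end = lo, hi
                    out.append(sv)
    return out


def source_export_table(
    pairs: list[SDPair],
    chrom_lengths: dict[str, int],
    x_name: str,
) -> pd.DataFrame:
    """Counts of SDs exported *into autosomes*, by parental chromosome.

    Autosome rows collect A>A pairs, the X row collects X>A pairs; this is
    the table behind the "is X an excessive source" regression, where the
    autosomes define the linear model and the X is tested as an outlier.
    """
    table = pd.DataFrame(
        0, index=pd.Index(chrom_lengths, name="chrom"),
        columns=["exports_into_autosomes"],
    )
    for p in pairs:
        if p.parental == "unresolved" or p.direction not in ("A>A", "X>A"):
            continue
        parent = p.parental_copy().chrom
        if parent in table.index:
            table.loc[parent, "exports_into_autosomes"] += 1
    table.insert(0, "length", [chrom_lengths[c] for c in table.index])
    table.insert(1, "is_x", [c == x_name for c in table.index])
    return table


def read_genes(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Gene spans from BED (0-based) or GFF3 (1-based 'gene' features)."""
    path = Path(path)
    genes = []
    if path.suffix.lower() in (".gff", ".gff3"):
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != "gene":
                    continue
                attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
                name = attrs.get("ID", attrs.get("Name", f"{f[0]}:{f[3]}"))
                genes.append((f[0], int(f[3]) - 1, int(f[4]), name))
    else:
        with open(path) as fh:
            for line in fh:
                if line.startswith(("#", "track")) or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                name = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}"
                genes.append((f[0], int(f[1]), int(f[2]), name))
    return genes


def genes_in_derived(
    pairs: list[SDPair],
    genes: list[tuple[str, int, int, str]],
    known_chroms: set[str] | None = None,
) -> dict[int, list[str]]:
    """Sorted, deduplicated gene ids intersecting each pair's derived copy."""
    out: dict[int, list[str]] = {}
    for p in pairs:
        derived = p.derived_copy()
        if derived is None:
            continue
        hits = set()
        for chrom, start, end, name in genes:
            if known_chroms is not None and chrom not in known_chroms:
                logger.warning("gene %s on unknown chromosome %s; skipped",
                               name, chrom)
                continue
            if chrom == derived.chrom and start < derived.end and derived.start < end:
                hits.add(name)
        out[p.family_id] = sorted(hits)
    return out


def write_sd_tsv(pairs: list[SDPair], path: str | Path) -> None:
    rows = []
    for p in pairs:
        rows.append({
            "family_id": p.family_id,
            "copy1": f"{p.copy1.chrom}:{p.copy1.start}-{p.copy1.end}",
            "copy2": f"{p.copy2.chrom}:{p.copy2.start}-{p.copy2.end}",
            "anchor": f"{p.anchor_chrom}:{p.anchor_start}-{p.anchor_end}",
            "length": p.length,
            "sd_class": p.sd_class,
            "parental": p.parental,
            "identity1": "" if p.copy1.identity_vs_anchor is None
                         else f"{p.copy1.identity_vs_anchor:.4f}",
            "identity2": "" if p.copy2.identity_vs_anchor is None
                         else f"{p.copy2.identity_vs_anchor:.4f}",
            "chain_span1": p.copy1.chain_span,
            "chain_span2": p.copy2.chain_span,
            "direction": p.direction,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
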