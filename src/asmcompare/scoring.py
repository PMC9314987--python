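"""Scoring of called events against the simulator's truth tables.

Matching is deliberately coordinate-tolerant: a called event matches a truth
record of the same type and chromosome when the intervals agree by
reciprocal overlap (interval events) or by breakpoint distance and length
(insertions).  Each truth record can absorb at most one call and vice versa
(greedy one-to-one matching).
"""

from __future__ import annotations

from dataclasses import dataclass

from .sdtraffic import SDPair
from .simgenome import TruthRecord
from .svclass import StructuralVariant

POS_TOL = 200          # bp breakpoint slack for point events
MIN_RECIP_OVERLAP = 0.5
MIN_LEN_RATIO = 0.7


@dataclass
class MatchResult:
    n_truth: int
    n_called: int
    n_matched: int

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_truth if self.n_truth else 1.0

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_called if self.n_called else 1.0


def _reciprocal_overlap(s1: int, e1: int, s2: int, e2: int) -> float:
    ov = min(e1, e2) - max(s1, s2)
    if ov <= 0:
        return 0.0
    return ov / max(min(e1 - s1, e2 - s2), 1)


def _sv_matches(truth: TruthRecord, call: StructuralVariant) -> bool:
    if truth.kind != call.sv_type or truth.chrom != call.chrom:
        return False
    if truth.kind == "INS":
        return (abs(call.a_start - truth.start) <= POS_TOL
                and min(call.length, truth.length)
                / max(call.length, truth.length) >= MIN_LEN_RATIO)
    return _reciprocal_overlap(truth.start, truth.end, call.a_start,
                               call.a_end) >= MIN_RECIP_OVERLAP


def score_svs(truth: list[TruthRecord],
              called: list[StructuralVariant]) -> MatchResult:
    """Precision/recall of SV calls at the given truth records."""
    truth = [t for t in truth if t.kind in ("DEL", "INS", "DUP", "INV")]
    taken = [False] * len(called)
    matched = 0
    for t in truth:
        for i, c in enumerate(called):
            if not taken[i] and _sv_matches(t, c):
                taken[i] = True
                matched += 1
                break
    return MatchResult(len(truth), len(called), matched)


def score_sd_directions(truth: list[TruthRecord],
                        pairs: list[SDPair]) -> tuple[int, int, int]:
    """(n_truth, n_resolved_matches, n_correct) for SD direction calls.

    A detected pair matches a truth SD when its derived copy overlaps the
    truth derived locus (b coordinates) reciprocally by at least half.
    Returns the number of truth SDs, how many matched a resolved pair, and
    how many of those carried the correct direction.
    """
    sd_truth = [t for t in truth if t.kind == "SD"]
    n_resolved = n_correct = 0
    taken = [False] * len(pairs)
    for t in sd_truth:
        chrom, ds, de = t.derived_interval()
        for i, p in enumerate(pairs):
            if taken[i] or p.parental == "unresolved":
                continue
            d_chrom, d_start, d_end = p.derived_locus()
            if d_chrom != chrom:
                continue
            if _reciprocal_overlap(ds, de, d_start, d_end) >= MIN_RECIP_OVERLAP:
                taken[i] = True
                n_resolved += 1
                if p.direction == t.direction:
                    n_correct += 1
                break
    return len(sd_truth), n_resolved, n_correct
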