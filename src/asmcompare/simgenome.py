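"""Simulated assembly pairs with planted rearrangements and known truth.

The generator produces two related assemblies the way a reference genome and
a de novo assembly of a close relative would look: shared chromosomes with a
low background substitution rate, N-gap runs confined to the reference-like
assembly ``a``, and planted structural events — deletions, insertions,
duplications, inversions, and inter-chromosomal segmental duplications (SDs)
with a known parental copy and an elevated mutation load on the derived copy.

Coordinate conventions
----------------------
All truth coordinates are 0-based half-open.  SV parent loci are expressed in
``a`` coordinates; derived loci (the inserted/duplicated material) in ``b``
coordinates.  Internal-type SD copies (placed before the two assemblies
diverge, so present in both) additionally carry their ``a``-side derived
locus.

Event semantics
---------------
DEL removes a segment from ``b``; INS materialises novel sequence in ``b``;
DUP overwrites the downstream half of its window with a tandem copy of the
upstream half (length-neutral); INV reverse-complements in place.  SD events
copy a parent segment onto another chromosome: boundary-type (bSD) copies are
inserted into ``b`` only, next to a planted rearrangement breakpoint or a
chromosome end; internal-type (iSD) copies are inserted into the shared
ancestor so both assemblies inherit them mid-synteny.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqio import Assembly, AssemblyPair, decode

SV_TYPES = ("DEL", "INS", "DUP", "INV")
SD_DIRECTIONS = ("A>A", "A>X", "X>A")

# default per-Mb event rates, proportioned like an assembly-to-assembly SV
# catalog of a wild/domestic pig pair (DEL-heavy, few DUP/INV)
DEFAULT_SV_RATES = {"DEL": 0.58, "INS": 0.33, "DUP": 0.08, "INV": 0.08}

_MARGIN = 2000      # bp between planted features: enough that the spacer
                    # between two events still anchors its own alignment block
_EDGE_MARGIN = 2000  # bp of clearance from chromosome ends
_MAX_TRIES = 500


class SimulationError(ValueError):
    """Raised when the requested events cannot be placed."""


@dataclass
class SimConfig:
    """Study conditions for one simulated assembly pair."""

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 700_000, "chr2": 550_000,
                                 "chrX": 500_000, "chr3": 380_000}
    )
    x_name: str = "chrX"
    background_divergence: float = 0.001
    sv_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SV_RATES))
    sv_length_range: tuple[int, int] = (200, 50_000)
    sd_counts: dict[str, int] = field(default_factory=lambda: {"A>A": 0, "A>X": 0, "X>A": 0})
    sd_length_range: tuple[int, int] = (2_000, 8_000)
    derived_extra_divergence: float = 0.02
    sd_boundary_fraction: float = 0.5
    ngap_count: int = 0
    ngap_length_range: tuple[int, int] = (500, 3_000)

    def validate(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("chrom_lengths is empty")
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        for rng_ in (self.sv_length_range, self.sd_length_range, self.ngap_length_range):
            if rng_[0] <= 0 or rng_[1] < rng_[0]:
                raise ValueError(f"invalid length range {rng_}")
        if self.sd_length_range[0] < 1_000:
            raise ValueError("sd_length_range minimum must be >= 1000 bp")
        if not 0 <= self.background_divergence <= self.derived_extra_divergence:
            raise ValueError(
                "background_divergence must lie in [0, derived_extra_divergence]"
            )
        for t in self.sv_rates:
            if t not in SV_TYPES:
                raise ValueError(f"unknown SV type {t}")
        for d in self.sd_counts:
            if d not in SD_DIRECTIONS:
                raise ValueError(f"unknown SD direction {d}")
        if self.x_name not in self.chrom_lengths and any(self.sd_counts.values()):
            raise ValueError("x_name must name a simulated chromosome when SDs are planted")


@dataclass
class TruthRecord:
    """Ground truth for one planted event."""

    event_id: str
    kind: str                     # DEL / INS / DUP / INV / SD
    chrom: str                    # parent locus, assembly-a coordinates
    start: int
    end: int
    length: int
    direction: str = ""           # SD only: A>A / A>X / X>A
    boundary: bool = False        # SD only: bSD fixture (True) vs iSD (False)
    b_chrom: str = ""             # derived locus, assembly-b coordinates
    b_start: int = -1
    b_end: int = -1
    derived_a_start: int = -1     # iSD only: derived locus in a coordinates
    derived_a_end: int = -1

    def parent_interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def derived_interval(self) -> tuple[str, int, int]:
        return (self.b_chrom, self.b_start, self.b_end)


# ---------------------------------------------------------------------------
# internal helpers


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute bases at the given per-bp rate; never a silent substitution."""
    if rate <= 0 or codes.size == 0:
        return codes.copy()
    out = codes.copy()
    hit = np.flatnonzero(rng.random(codes.size) < rate)
    if hit.size:
        out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return out


class _Registry:
    """Per-chromosome intervals already claimed by planted features."""

    def __init__(self) -> None:
        self._iv: dict[str, list[list[int]]] = {}

    def blocked(self, chrom: str, start: int, end: int, margin: int = _MARGIN) -> bool:
        for s, e in self._iv.get(chrom, ()):
            if start - margin < e and s < end + margin:
                return True
        return False

    def claim(self, chrom: str, start: int, end: int) -> None:
        self._iv.setdefault(chrom, []).append([start, end])

    def shift(self, chrom: str, at: int, delta: int) -> None:
        for iv in self._iv.get(chrom, ()):
            if iv[0] >= at:
                iv[0] += delta
                iv[1] += delta


def _place_interval(
    rng: np.random.Generator,
    registry: _Registry,
    chrom: str,
    chrom_len: int,
    length: int,
    edge: int = _EDGE_MARGIN,
) -> int:
    lo, hi = edge, chrom_len - edge - length
    if hi < lo:
        raise SimulationError(
            f"genome too small for requested events: {length} bp on {chrom}"
        )
    for _ in range(_MAX_TRIES):
        start = int(rng.integers(lo, hi + 1))
        if not registry.blocked(chrom, start, start + length):
            registry.claim(chrom, start, start + length)
            return start
    raise SimulationError("genome too small for requested events (placement failed)")


def _pick_chrom(rng: np.random.Generator, lengths: dict[str, int]) -> str:
    names = list(lengths)
    w = np.array([lengths[n] for n in names], dtype=float)
    return names[int(rng.choice(len(names), p=w / w.sum()))]


@dataclass
class _Planned:
    kind: str      # DEL / INS / DUP / INV / BSD
    chrom: str
    start: int
    end: int       # a-interval consumed (INS and BSD: start == end)
    payload: np.ndarray | None = None   # inserted codes for INS / BSD
    truth: TruthRecord | None = None


# ---------------------------------------------------------------------------
# main entry point


def simulate_pair(config: SimConfig) -> tuple[AssemblyPair, list[TruthRecord]]:
    """Generate a reproducible assembly pair plus the truth table.

    Identical configs give byte-identical assemblies and truth records.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    # fixed spawn order keeps each event class on its own stream, so adding
    # SDs does not move SV placements (and vice versa)
    rng_base, rng_isd, rng_ngap, rng_sv, rng_bsd, rng_bg = (
        np.random.default_rng(c) for c in ss.spawn(6)
    )

    base: dict[str, np.ndarray] = {
        name: rng_base.integers(0, 4, size=length).astype(np.uint8)
        for name, length in config.chrom_lengths.items()
    }
    registry = _Registry()
    truth: list[TruthRecord] = []
    planned: list[_Planned] = []
    counter = 0

    def next_id(prefix: str) -> str:
        nonlocal counter
        counter += 1
        return f"{prefix}{counter:04d}"

    autosomes = [c for c in config.chrom_lengths if c != config.x_name]

    def direction_chroms(direction: str, rng: np.random.Generator,
                         internal: bool) -> tuple[str, str]:
        if direction == "A>X":
            parents, targets = autosomes, [config.x_name]
        elif direction == "X>A":
            parents, targets = [config.x_name], autosomes
        else:
            parents, targets = autosomes, autosomes
        pairs = [
            (p, t) for p in parents for t in targets
            if p != t and (not internal or len(base[p]) > 1.05 * len(base[t]))
        ]
        if not pairs:
            raise SimulationError(
                f"chromosome lengths cannot host an "
                f"{'internal' if internal else 'boundary'} {direction} SD"
            )
        return pairs[int(rng.integers(len(pairs)))]

    # --- internal-type SDs: inserted into the shared ancestor -------------
    sd_plan: list[tuple[str, bool]] = []
    for direction in SD_DIRECTIONS:
        n = int(config.sd_counts.get(direction, 0))
        n_boundary = int(round(n * config.sd_boundary_fraction))
        sd_plan += [(direction, True)] * n_boundary
        sd_plan += [(direction, False)] * (n - n_boundary)

    for direction, is_boundary in sd_plan:
        if is_boundary:
            continue
        length = int(rng_isd.integers(config.sd_length_range[0],
                                      config.sd_length_range[1] + 1))
        parent_chrom, target_chrom = direction_chroms(direction, rng_isd, internal=True)
        p_start = _place_interval(rng_isd, registry, parent_chrom,
                                  len(base[parent_chrom]), length)
        derived = _mutate(base[parent_chrom][p_start:p_start + length],
                          config.derived_extra_divergence, rng_isd)
        d_pos = _place_interval(rng_isd, registry, target_chrom,
                                len(base[target_chrom]), 0)
        base[target_chrom] = np.concatenate(
            [base[target_chrom][:d_pos], derived, base[target_chrom][d_pos:]]
        )
        registry.shift(target_chrom, d_pos + 1, length)
        registry.claim(target_chrom, d_pos, d_pos + length)
        # insertions move everything downstream on the target chromosome,
        # including loci of SDs planted earlier
        for rec in truth:
            if rec.chrom == target_chrom and rec.start >= d_pos:
                rec.start += length
                rec.end += length
            if rec.b_chrom == target_chrom and rec.derived_a_start >= d_pos:
                rec.derived_a_start += length
                rec.derived_a_end += length
        truth.append(TruthRecord(
            event_id=next_id("sd"), kind="SD", chrom=parent_chrom,
            start=p_start, end=p_start + length, length=length,
            direction=direction, boundary=False,
            b_chrom=target_chrom, derived_a_start=d_pos, derived_a_end=d_pos + length,
        ))

    # base is now final: assembly-a coordinates are fixed from here on

    # --- N-gap runs (reference-like assembly only) ------------------------
    ngap_intervals: dict[str, list[tuple[int, int]]] = {}
    for _ in range(config.ngap_count):
        length = int(rng_ngap.integers(config.ngap_length_range[0],
                                       config.ngap_length_range[1] + 1))
        chrom = _pick_chrom(rng_ngap, {c: len(s) for c, s in base.items()})
        start = _place_interval(rng_ngap, registry, chrom, len(base[chrom]), length)
        ngap_intervals.setdefault(chrom, []).append((start, start + length))

    # --- intra-chromosomal SVs -------------------------------------------
    total_mb = sum(len(s) for s in base.values()) / 1e6
    chrom_lengths_now = {c: len(s) for c, s in base.items()}
    for sv_type in SV_TYPES:
        n_events = int(round(config.sv_rates.get(sv_type, 0.0) * total_mb))
        for _ in range(n_events):
            length = int(rng_sv.integers(config.sv_length_range[0],
                                         config.sv_length_range[1] + 1))
            chrom = _pick_chrom(rng_sv, chrom_lengths_now)
            span = 2 * length if sv_type == "DUP" else (0 if sv_type == "INS" else length)
            start = _place_interval(rng_sv, registry, chrom, len(base[chrom]), span)
            payload = None
            if sv_type == "INS":
                payload = rng_sv.integers(0, 4, size=length).astype(np.uint8)
            rec = TruthRecord(
                event_id=next_id(sv_type.lower()), kind=sv_type, chrom=chrom,
                start=start, end=start + (length if sv_type != "INS" else 0),
                length=length, b_chrom=chrom,
            )
            truth.append(rec)
            planned.append(_Planned(sv_type if sv_type != "DUP" else "DUP",
                                    chrom, start, start + span, payload, rec))

    # --- boundary-type SDs: inserted into assembly b only -----------------
    for direction, is_boundary in sd_plan:
        if not is_boundary:
            continue
        length = int(rng_bsd.integers(config.sd_length_range[0],
                                      config.sd_length_range[1] + 1))
        parent_chrom, target_chrom = direction_chroms(direction, rng_bsd, internal=False)
        p_start = _place_interval(rng_bsd, registry, parent_chrom,
                                  len(base[parent_chrom]), length)
        derived = _mutate(base[parent_chrom][p_start:p_start + length],
                          config.derived_extra_divergence, rng_bsd)
        q = _boundary_insertion_point(rng_bsd, registry, planned, target_chrom,
                                      len(base[target_chrom]))
        registry.claim(target_chrom, q, q)
        rec = TruthRecord(
            event_id=next_id("sd"), kind="SD", chrom=parent_chrom,
            start=p_start, end=p_start + length, length=length,
            direction=direction, boundary=True, b_chrom=target_chrom,
        )
        truth.append(rec)
        planned.append(_Planned("BSD", target_chrom, q, q, derived, rec))

    # --- materialise the two assemblies -----------------------------------
    a_chroms: dict[str, bytes] = {}
    b_chroms: dict[str, bytes] = {}
    for chrom, codes in base.items():
        a_codes = codes.copy()
        for s, e in ngap_intervals.get(chrom, ()):
            a_codes[s:e] = 4  # N
        a_chroms[chrom] = decode(a_codes)

        b_codes = _mutate(codes, config.background_divergence, rng_bg)
        events = sorted((p for p in planned if p.chrom == chrom),
                        key=lambda p: p.start)
        b_chroms[chrom] = _apply_events(b_codes, events)
        _fill_b_coordinates(chrom, events, truth)

    a = Assembly(a_chroms, name="asm_a", x_name=config.x_name)
    b = Assembly(b_chroms, name="asm_b", x_name=config.x_name)
    return AssemblyPair(a, b, x_name=config.x_name), truth


def _boundary_insertion_point(
    rng: np.random.Generator,
    registry: _Registry,
    planned: list[_Planned],
    chrom: str,
    chrom_len: int,
) -> int:
    """A b-only insertion point abutting a synteny break.

    Prefer a spot within 500 bp of an already-planted rearrangement
    breakpoint on the target chromosome; otherwise sit within 500 bp of the
    chromosome end, which is a chain end by construction.
    """
    breakpoints = [p.end for p in planned if p.chrom == chrom and p.kind != "BSD"]
    rng.shuffle(breakpoints)
    for bp in breakpoints:
        for _ in range(20):
            q = bp + int(rng.integers(1, 501))
            if q < chrom_len and not registry.blocked(chrom, q, q, margin=0):
                return q
    for _ in range(_MAX_TRIES):
        q = chrom_len - int(rng.integers(1, 501))
        if q > 0 and not registry.blocked(chrom, q, q, margin=0):
            return q
    raise SimulationError("genome too small for requested events (bSD placement)")


def _apply_events(codes: np.ndarray, events: list[_Planned]) -> bytes:
    parts: list[np.ndarray] = []
    pos = 0
    for ev in events:
        parts.append(codes[pos:ev.start])
        if ev.kind == "DEL":
            pass
        elif ev.kind in ("INS", "BSD"):
            parts.append(ev.payload)
        elif ev.kind == "DUP":
            half = (ev.end - ev.start) // 2
            unit = codes[ev.start:ev.start + half]
            parts.append(unit)
            parts.append(unit.copy())
        elif ev.kind == "INV":
            parts.append(3 - codes[ev.start:ev.end][::-1])
        pos = ev.end
    parts.append(codes[pos:])
    return decode(np.concatenate(parts) if parts else codes)


def _fill_b_coordinates(chrom: str, events: list[_Planned],
                        truth: list[TruthRecord]) -> None:
    """Project a-coordinates through the event list to fill b-side loci."""

    def project(a_pos: int) -> int:
        delta = 0
        for ev in events:
            if ev.start >= a_pos:
                break
            if ev.kind == "DEL":
                delta -= min(ev.end, a_pos) - ev.start
            elif ev.kind in ("INS", "BSD"):
                delta += len(ev.payload)
        return a_pos + delta

    for ev in events:
        rec = ev.truth
        if rec is None:
            continue
        if ev.kind == "DEL":
            rec.b_start = rec.b_end = project(ev.start)
        elif ev.kind == "INS":
            rec.b_start = project(ev.start)
            rec.b_end = rec.b_start + rec.length
        elif ev.kind == "DUP":
            half = (ev.end - ev.start) // 2
            rec.b_start = project(ev.start) + half
            rec.b_end = rec.b_start + half
        elif ev.kind == "INV":
            rec.b_start = project(ev.start)
            rec.b_end = rec.b_start + rec.length
        elif ev.kind == "BSD":
            rec.b_start = project(ev.start)
            rec.b_end = rec.b_start + rec.length
    # iSD records live on this chromosome if their derived a-locus does
    for rec in truth:
        if rec.kind == "SD" and not rec.boundary and rec.b_chrom == chrom \
                and rec.b_start < 0:
            rec.b_start = project(rec.derived_a_start)
            rec.b_end = rec.b_start + rec.length


# ---------------------------------------------------------------------------
# truth table I/O

_TRUTH_COLUMNS = [
    "chrom", "start", "end", "event_id", "kind", "direction", "role",
    "length", "boundary", "b_chrom", "b_start", "b_end",
]


def write_truth(records: list[TruthRecord], path: str | Path) -> None:
    """BED-like TSV; SD events emit two rows (parent, derived) per event."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_TRUTH_COLUMNS)
        for rec in records:
            w.writerow([
                rec.chrom, rec.start, rec.end, rec.event_id, rec.kind,
                rec.direction, "parent", rec.length, int(rec.boundary),
                rec.b_chrom, rec.b_start, rec.b_end,
            ])
            if rec.kind == "SD":
                d_chrom = rec.b_chrom
                d_start = rec.derived_a_start if not rec.boundary else rec.b_start
                d_end = rec.derived_a_end if not rec.boundary else rec.b_end
                w.writerow([
                    d_chrom, d_start, d_end, rec.event_id, rec.kind,
                    rec.direction, "derived", rec.length, int(rec.boundary),
                    rec.b_chrom, rec.b_start, rec.b_end,
                ])


def read_truth(path: str | Path) -> list[TruthRecord]:
    records: dict[str, TruthRecord] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != _TRUTH_COLUMNS:
            raise ValueError(f"unexpected truth table header in {path}")
        for row in reader:
            if row["role"] == "derived":
                rec = records[row["event_id"]]
                if not rec.boundary:
                    rec.derived_a_start = int(row["start"])
                    rec.derived_a_end = int(row["end"])
                continue
            records[row["event_id"]] = TruthRecord(
                event_id=row["event_id"], kind=row["kind"], chrom=row["chrom"],
                start=int(row["start"]), end=int(row["end"]),
                length=int(row["length"]), direction=row["direction"],
                boundary=bool(int(row["boundary"])), b_chrom=row["b_chrom"],
                b_start=int(row["b_start"]), b_end=int(row["b_end"]),
            )
    return list(records.values())
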