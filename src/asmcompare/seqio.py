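"""FASTA-backed assembly containers.

Sequences are held in memory as upper-case ASCII bytes; coordinates are
0-based half-open throughout the package.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# byte code table: A/C/G/T -> 0..3, anything else (incl. N) -> 4
CODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    CODE[_c] = _i
    CODE[_c + 32] = _i  # lower case
BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def revcomp(seq: bytes) -> bytes:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: bytes) -> np.ndarray:
    """Map a byte sequence onto the 0..4 numeric alphabet."""
    return CODE[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> bytes:
    """Inverse of :func:`encode`; code 4 renders as ``N``."""
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[codes].tobytes()


def n_runs(seq: bytes) -> list[tuple[int, int]]:
    """Maximal runs of N/n as 0-based half-open intervals."""
    isn = encode(seq) == 4
    if not isn.any():
        return []
    d = np.diff(isn.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if isn[0]:
        starts.insert(0, 0)
    if isn[-1]:
        ends.append(len(isn))
    return list(zip(starts, ends))


@dataclass
class Assembly:
    """A named genome: ordered chromosomes plus the sex-chromosome label."""

    chroms: dict[str, bytes]
    name: str = "assembly"
    x_name: str | None = None
    _ngap_cache: dict[str, list[tuple[int, int]]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.chroms = {k: bytes(v).upper() for k, v in self.chroms.items()}

    def lengths(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.chroms.items()}

    def ngaps(self, chrom: str) -> list[tuple[int, int]]:
        if chrom not in self._ngap_cache:
            self._ngap_cache[chrom] = n_runs(self.chroms[chrom])
        return self._ngap_cache[chrom]

    def all_ngaps(self) -> dict[str, list[tuple[int, int]]]:
        return {c: self.ngaps(c) for c in self.chroms}

    def gapless_length(self, chrom: str) -> int:
        return len(self.chroms[chrom]) - sum(e - s for s, e in self.ngaps(chrom))

    def is_x(self, chrom: str) -> bool:
        return chrom == self.x_name


@dataclass
class AssemblyPair:
    """Two related assemblies sharing chromosome names.

    ``a`` plays the reference-like role (it may carry N-gaps); ``b`` is the
    derived assembly produced by the simulator or supplied by the user.
    """

    a: Assembly
    b: Assembly
    x_name: str | None = None

    def __post_init__(self) -> None:
        if self.x_name is not None:
            self.a.x_name = self.x_name
            self.b.x_name = self.x_name


def read_fasta(path: str | Path, name: str | None = None, x_name: str | None = None) -> Assembly:
    chroms: dict[str, bytes] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        chroms[rec.id] = bytes(rec.seq)
    if not chroms:
        raise ValueError(f"no sequences found in {path}")
    return Assembly(chroms, name=name or Path(path).stem, x_name=x_name)


def write_fasta(assembly: Assembly, path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq.decode()), id=chrom, description="")
        for chrom, seq in assembly.chroms.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def fasta_bytes(assembly: Assembly, width: int = 60) -> bytes:
    buf = io.StringIO()
    records = [
        SeqRecord(Seq(seq.decode()), id=chrom, description="")
        for chrom, seq in assembly.chroms.items()
    ]
    SeqIO.FastaIO.FastaWriter(buf, wrap=width).write_file(records)
    return buf.getvalue().encode()
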