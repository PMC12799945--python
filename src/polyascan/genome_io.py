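"""Genome sequence and interval I/O.

All coordinates are 0-based, half-open, matching BED. A cleavage site is a
1-bp interval; the biological "51st nucleotide" of a 101-nt window is internal
index 50. Conversions to 1-based conventions happen only at I/O boundaries
(there are none: FASTA is positionless and BED is already 0-based).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome.

    ``strand`` is ``'+'``, ``'-'`` or ``None`` (unstranded records, e.g.
    BED3). Poly(A) cleavage sites are represented as 1-bp intervals whose
    ``start`` is the cleavage base.
    """

    chrom: str
    start: int
    end: int
    strand: Optional[str] = None
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in (None, "+", "-"):
            raise FormatError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class Genome:
    """Uppercase nucleotide sequences keyed by chromosome name."""

    sequences: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, chrom: str) -> str:
        try:
            return self.sequences[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __iter__(self) -> Iterator[str]:
        return iter(self.sequences)

    @property
    def chroms(self) -> list[str]:
        return list(self.sequences)

    def length(self, chrom: str) -> int:
        return len(self[chrom])

    def items(self):
        return self.sequences.items()


def _validate_sequence(seq: str, name: str) -> str:
    seq = seq.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise FormatError(
            f"record {name!r} contains characters outside ACGTN: {sorted(bad)}"
        )
    return seq


def read_fasta(path: str | Path) -> Genome:
    """Load a (multi-record) FASTA file into a :class:`Genome`.

    Sequences are uppercased; characters outside ``ACGTN`` are rejected.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    sequences: dict[str, str] = {}
    for rec in records:
        if rec.id in sequences:
            raise FormatError(f"duplicate FASTA record {rec.id!r}")
        sequences[rec.id] = _validate_sequence(str(rec.seq), rec.id)
    return Genome(sequences)


def write_fasta(genome: Genome, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Parse BED3+ into intervals, preserving file order.

    Name (col 4) and strand (col 6) are kept when present; score (col 5)
    is ignored. ``start >= end`` is a format error.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else None
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, strand=strand, name=name)
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED6 (name '.', score 0 placeholders)."""
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            strand = iv.strand if iv.strand is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{strand}\n")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the ACGTN alphabet (N maps to N)."""
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"cannot complement characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def extract_window(
    genome: Genome, chrom: str, center: int, flank: int
) -> Optional[str]:
    """Return the ``2*flank + 1`` nt window centered on ``center``.

    Returns ``None`` when the window would cross a chromosome boundary
    (windows are never padded). ``flank=50`` gives the standard 101-nt
    cleavage-site window.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    seq = genome[chrom]
    if center - flank < 0 or center + flank + 1 > len(seq):
        return None
    return seq[center - flank : center + flank + 1]
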