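"""Shared genomic primitives: contigs, intervals, and DNA string helpers.

Coordinates are 1-based inclusive throughout the package, matching the
hg19-style positions used in breakpoint reports. Each contig carries an
``offset`` so that a small in-memory contig can present genome-scale
coordinates: local base ``i`` (1-based) has genome coordinate ``offset + i``.
Conversion to 0-based half-open happens only at BED export.
"""

from __future__ import annotations

from dataclasses import dataclass

DNA_ALPHABET = frozenset("ACGT")

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMP)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMP)


@dataclass
class Contig:
    """A named DNA sequence anchored at a genome-scale coordinate offset.

    ``offset`` is fixed for the contig's lifetime; local base i (1-based)
    has genome coordinate ``offset + i``.
    """

    name: str
    sequence: str
    offset: int = 0

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"contig {self.name!r}: empty sequence")
        if not set(self.sequence) <= DNA_ALPHABET:
            bad = sorted(set(self.sequence) - DNA_ALPHABET)
            raise ValueError(f"contig {self.name!r}: non-ACGT characters {bad}")
        if self.offset < 0:
            raise ValueError(f"contig {self.name!r}: negative offset")

    def __len__(self) -> int:
        return len(self.sequence)

    # -- coordinate conversion -------------------------------------------
    def to_genome(self, local_pos: int) -> int:
        """Genome coordinate of 1-based local position."""
        if not 1 <= local_pos <= len(self.sequence):
            raise ValueError(
                f"local position {local_pos} outside contig {self.name!r}"
            )
        return self.offset + local_pos

    def to_local(self, genome_pos: int) -> int:
        """1-based local position of a genome coordinate."""
        local = genome_pos - self.offset
        if not 1 <= local <= len(self.sequence):
            raise ValueError(
                f"genome position {genome_pos} outside contig {self.name!r}"
            )
        return local

    def fetch(self, start: int, end: int) -> str:
        """Subsequence by 1-based inclusive genome coordinates."""
        i, j = self.to_local(start), self.to_local(end)
        if i > j:
            raise ValueError("start > end")
        return self.sequence[i - 1 : j]


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive interval on a named contig."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.end
            and other.start <= self.end
        )

    def to_bed(self) -> tuple[str, int, int]:
        """0-based half-open (contig, start, end) for BED export."""
        return (self.contig, self.start - 1, self.end)


def longest_common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def suffix_prefix_overlap(left: str, right: str) -> int:
    """Maximal k such that the last k bases of ``left`` equal the first k
    bases of ``right`` (microhomology convention)."""
    best = 0
    for k in range(1, min(len(left), len(right)) + 1):
        if left[-k:] == right[:k]:
            best = k
    return best
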