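"""Genomic coordinate primitives shared by every stage of the pipeline.

Coordinates are 1-based and inclusive at both ends throughout the package,
matching the notation used in breakpoint reports (``chr1:18163342–18163563``).
BED-style 0-based half-open coordinates are converted exactly once, at the
file boundary (see :mod:`abtmap.io`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping

EN_DASH = "–"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based, fully closed span on a named chromosome.

    ``width`` counts both endpoints: chr1:100–199 covers 100 bases.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end ({self.end}) < start ({self.start}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be +, - or ., got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, chrom: str, position: int) -> bool:
        return chrom == self.chrom and self.start <= position <= self.end

    def shared_bases(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        lo = max(self.start, other.start)
        hi = min(self.end, other.end)
        return max(0, hi - lo + 1)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}{EN_DASH}{self.end}"


@dataclass(frozen=True)
class Breakpoint:
    """A single 1-based position, tagged with which flank stays on the derivative."""

    chrom: str
    position: int
    side: str = "upstream"  # "upstream": bases <= position retained; "downstream": >= retained

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.side not in ("upstream", "downstream"):
            raise ValueError(f"side must be upstream/downstream, got {self.side!r}")


def interval_width(ivl: GenomicInterval) -> int:
    """Width in bp of a closed interval (end − start + 1)."""
    return ivl.width


def overlap_fraction(a: GenomicInterval, b: GenomicInterval, mode: str = "of_a") -> float:
    """Fraction of overlap between two intervals.

    ``of_a``: shared bases / width(a).  ``reciprocal``: the smaller of the two
    one-sided fractions.  Intervals on different chromosomes share nothing.
    """
    if mode not in ("of_a", "reciprocal"):
        raise ValueError(f"mode must be 'of_a' or 'reciprocal', got {mode!r}")
    shared = a.shared_bases(b)
    if shared == 0:
        return 0.0
    if mode == "of_a":
        return shared / a.width
    return min(shared / a.width, shared / b.width)


_INTERVAL_RE = re.compile(
    rf"^\s*([\w.]+):([\d,]+)\s*[-{EN_DASH}]\s*([\d,]+)\s*$"
)


def parse_interval(text: str, strand: str = ".") -> GenomicInterval:
    """Parse ``chrom:start-end`` (hyphen or en-dash) into a GenomicInterval."""
    m = _INTERVAL_RE.match(text)
    if not m:
        raise ValueError(f"cannot parse genomic interval from {text!r}")
    chrom, s, e = m.group(1), m.group(2), m.group(3)
    start, end = int(s.replace(",", "")), int(e.replace(",", ""))
    if end < start:
        raise ValueError(f"end < start in {text!r}")
    return GenomicInterval(chrom, start, end, strand)


def format_interval(ivl: GenomicInterval) -> str:
    """Render an interval in report notation (en-dash separated)."""
    return str(ivl)


class Genome:
    """An ordered set of named nucleotide sequences over {A,C,G,T,N}."""

    def __init__(self, sequences: Mapping[str, str]):
        if not sequences:
            raise ValueError("genome needs at least one chromosome")
        self._seqs: Dict[str, str] = {}
        for name, seq in sequences.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} has an empty sequence")
            up = seq.upper()
            if set(up) - set("ACGTN"):
                bad = sorted(set(up) - set("ACGTN"))
                raise ValueError(f"chromosome {name!r} has non-ACGTN bases: {bad}")
            self._seqs[name] = up

    @property
    def chromosomes(self) -> list[str]:
        return list(self._seqs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def sequence(self, chrom: str) -> str:
        return self._seqs[chrom]

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def total_length(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of the closed interval [start, end], 1-based."""
        if start < 1 or end > len(self._seqs[chrom]) or end < start:
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside chromosome "
                f"(length {len(self._seqs[chrom])})"
            )
        return self._seqs[chrom][start - 1 : end]

    def rank(self, chrom: str) -> int:
        """Declaration order of a chromosome, used for deterministic sorting."""
        return self.chromosomes.index(chrom)


@dataclass
class FeatureRecord:
    """A typed annotation: gene, exon, repeat, CNE, or known-SV catalogue entry."""

    interval: GenomicInterval
    kind: str
    name: str
    attributes: Dict[str, object] = field(default_factory=dict)

    KINDS = ("gene", "exon", "repeat", "CNE", "known_sv")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "gene":
            exons = self.attributes.get("exons")
            if not exons:
                raise ValueError(f"gene {self.name!r} needs a non-empty exon list")
            starts = [e.start for e in exons]
            if starts != sorted(starts):
                raise ValueError(f"gene {self.name!r} exons must be sorted by start")
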