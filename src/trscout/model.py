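"""Shared domain types.

Coordinates are 0-based half-open everywhere inside the package; SAM's
1-based POS is converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

# CIGAR operations that consume the read / the reference
_READ_OPS = frozenset("M=XIS")
_REF_OPS = frozenset("M=XDN")
_ALN_OPS = frozenset("M=X")


@dataclass
class AlignmentRecord:
    """One read-to-reference alignment with a parsed CIGAR.

    ``read_seq`` is the sequence as stored in the SAM record, i.e. already
    reverse-complemented onto the reference strand for minus-strand
    alignments. Hard-clipped records may carry ``read_seq=None``; their
    clip lengths are still set so split-alignment geometry works.
    """

    read_id: str
    ref_name: str
    ref_start: int
    strand: str
    mapq: int
    cigar: list[tuple[str, int]]
    read_seq: Optional[str]
    is_supplementary: bool = False
    left_clip: int = 0
    right_clip: int = 0

    def __post_init__(self) -> None:
        lc = rc = 0
        ops = self.cigar
        if ops:
            i = 0
            while i < len(ops) and ops[i][0] in "SH":
                lc += ops[i][1]
                i += 1
            j = len(ops) - 1
            while j >= i and ops[j][0] in "SH":
                rc += ops[j][1]
                j -= 1
        self.left_clip = lc
        self.right_clip = rc

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(n for op, n in self.cigar if op in _REF_OPS)

    @property
    def aligned_read_len(self) -> int:
        """Read bases consumed by non-clip operations (M/=/X/I)."""
        return sum(n for op, n in self.cigar if op in "M=XI")

    @property
    def read_len(self) -> int:
        """Full read length including clips (hard clips counted)."""
        return self.left_clip + self.aligned_read_len + self.right_clip

    def read_interval(self) -> tuple[int, int]:
        """Aligned interval in original-read coordinates (strand-aware)."""
        if self.strand == "+":
            start = self.left_clip
        else:
            start = self.right_clip
        return start, start + self.aligned_read_len


@dataclass
class RepeatHit:
    """A tandem-repeat tract detected within a query sequence."""

    motif: str  # canonical form
    start: int
    end: int
    purity: float
    score: float

    @property
    def copy_number(self) -> float:
        return (self.end - self.start) / len(self.motif)


@dataclass
class TRLocus:
    """A reference tandem-repeat locus (0-based half-open)."""

    chrom: str
    start: int
    end: int
    motifs: list[str]
    source: str = "annotation"  # or "scan"
    support_events: int = 0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"locus {self.chrom}:{self.start}-{self.end}: start must be < end"
            )

    @property
    def ref_len(self) -> int:
        return self.end - self.start


@dataclass
class InsertionEvent:
    """A candidate insertion from one read (CIGAR- or split-derived)."""

    read_id: str
    ref_name: str
    ref_pos: int  # 0-based insertion anchor (first reference base after it)
    ins_seq: str
    source: str  # "cigar" | "split"
    read_span: tuple[int, int]

    def __len__(self) -> int:
        return len(self.ins_seq)


@dataclass
class ReadCall:
    """Per-read repeat measurement at one locus."""

    locus: TRLocus
    read_id: str
    repeat_size: int
    copy_number: float
    read_tract_start: int
    method: str  # "spanning" | "rescued"


@dataclass
class Allele:
    size: float  # median repeat size (bp) of member reads
    copy_number: float  # median copy number of member reads
    support: int
    members: list[str] = field(default_factory=list)


@dataclass
class Genotype:
    locus: TRLocus
    alleles: list[Allele]
    total_reads: int
    calls: list[ReadCall] = field(default_factory=list)

    def allele_sizes(self) -> list[float]:
        return [a.size for a in self.alleles]


@dataclass
class MatchResult:
    """Outcome of comparing a called genotype with truth allele sizes."""

    locus: TRLocus
    truth_alleles: list[float]
    called_alleles: list[float]
    flags: list[bool]
    classification: str  # both_match | one_match | no_match
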