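"""Core genomic domain types.

Coordinates are 0-based half-open internally; GTF I/O converts at the
boundary (1-based inclusive on disk).
"""

from __future__ import annotations

from dataclasses import dataclass, field

STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware interval on a named sequence, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start >= self.end:
            raise ValueError(f"start must be < end, got [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TranscriptModel:
    """One transcript: an ordered set of non-overlapping exons on one strand."""

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"transcript {self.transcript_id} spans multiple chroms/strands"
            )
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"transcript {self.transcript_id} has overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand


@dataclass
class GeneModel:
    """A gene: one or more transcripts sharing chrom and strand."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        for t in self.transcripts:
            if t.chrom != self.chrom or t.strand != self.strand:
                raise ValueError(
                    f"transcript {t.transcript_id} of gene {self.gene_id} "
                    f"is on {t.chrom}{t.strand}, expected {self.chrom}{self.strand}"
                )


@dataclass
class CountingBin:
    """A maximal disjoint exonic interval supported by a fixed transcript set.

    The unit of exon-level quantification: within one gene, bins partition the
    exonic bases and every base of a bin lies in an exon of exactly the
    transcripts in ``supporting_transcripts``.
    """

    gene_id: str
    bin_id: str
    interval: GenomicInterval
    supporting_transcripts: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.supporting_transcripts:
            raise ValueError(f"bin {self.bin_id} has no supporting transcripts")
        self.supporting_transcripts = frozenset(self.supporting_transcripts)
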