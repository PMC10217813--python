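"""Core genomic data structures.

Coordinates are 0-based half-open internally; GTF I/O converts to and from
the 1-based closed convention at the boundary (see :mod:`seedcerna.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Sequence

VALID_STRANDS = ("+", "-")


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded interval on a chromosome, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Positional overlap, ignoring strand."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int:
        """Minimal distance in bp between the two intervals; 0 if overlapping."""
        if self.chrom != other.chrom:
            raise ValueError("gap undefined across chromosomes")
        if self.overlaps(other):
            return 0
        return max(self.start, other.start) - min(self.end, other.end)


@dataclass
class TranscriptModel:
    """A multi-exon transcript; exons sorted, non-overlapping, one strand."""

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        self.exons = tuple(sorted(self.exons, key=lambda e: e.start))
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(f"{self.transcript_id}: exons span chroms/strands")
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @cached_property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out


@dataclass
class GeneModel:
    """A gene with one or more transcripts and a biotype."""

    gene_id: str
    transcripts: list[TranscriptModel] = field(default_factory=list)
    biotype: str = "protein_coding"

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        start = min(t.span.start for t in self.transcripts)
        end = max(t.span.end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)

    def exons(self) -> list[GenomicInterval]:
        return [e for t in self.transcripts for e in t.exons]

    def introns(self) -> list[GenomicInterval]:
        return [i for t in self.transcripts for i in t.introns()]


def transcripts_of(genes: Iterable[GeneModel]) -> list[TranscriptModel]:
    return [t for g in genes for t in g.transcripts]


def coding_genes(genes: Sequence[GeneModel]) -> list[GeneModel]:
    return [g for g in genes if g.biotype == "protein_coding"]
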