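"""lncRNA candidate filtering, positional classification and summaries.

The basic screen keeps transcripts with spliced length >= 200 nt, >= 2
exons, and a maximum FPKM over samples >= 0.1 (the most permissive reading
of an expression gate applied across many libraries). Surviving non-coding
transcripts are then classified relative to protein-coding annotation into
lincRNA / antisense / intronic / sense classes with an explicit precedence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .coding import CodingPotential
from .models import GeneModel, TranscriptModel, coding_genes

CLASSES = ("lincRNA", "antisense", "intronic", "sense")


@dataclass
class LncRNARecord:
    transcript: TranscriptModel
    position_class: str
    coding: CodingPotential | None = None
    fpkm: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.position_class not in CLASSES:
            raise ValueError(f"unknown class {self.position_class!r}")


def basic_filter(
    transcripts: Sequence[TranscriptModel],
    fpkm: pd.DataFrame,
    min_len: int = 200,
    min_exons: int = 2,
    min_fpkm: float = 0.1,
) -> list[TranscriptModel]:
    """Length / exon-count / expression screen; order of survivors is stable."""
    missing = [t.transcript_id for t in transcripts if t.transcript_id not in fpkm.index]
    if missing:
        raise KeyError(f"transcripts missing from FPKM matrix: {missing[:5]}")
    kept = []
    for t in transcripts:
        if t.spliced_length < min_len or t.n_exons < min_exons:
            continue
        if fpkm.loc[t.transcript_id].max() < min_fpkm:
            continue
        kept.append(t)
    return kept


class GeneIndex:
    """Per-chromosome interval trees over coding gene spans and exons."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = coding_genes(genes)
        self._span: dict[str, IntervalTree] = {}
        self._exon: dict[str, IntervalTree] = {}
        for g in self.genes:
            span = g.span
            self._span.setdefault(g.chrom, IntervalTree()).addi(span.start, span.end, g)
            for e in g.exons():
                self._exon.setdefault(g.chrom, IntervalTree()).addi(e.start, e.end, g)

    def span_hits(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        tree = self._span.get(chrom)
        return [iv.data for iv in tree.overlap(start, end)] if tree else []

    def exon_hits(self, chrom: str, start: int, end: int) -> list[tuple[int, int, GeneModel]]:
        tree = self._exon.get(chrom)
        return [(iv.begin, iv.end, iv.data) for iv in tree.overlap(start, end)] if tree else []

    @property
    def chroms(self) -> set[str]:
        return set(self._span)


def classify_position(lnc: TranscriptModel, index: GeneIndex) -> str:
    """Assign one positional class with precedence sense > antisense > intronic > lincRNA.

    sense/antisense: some lncRNA exon overlaps a coding exon on the same /
    opposite strand. intronic: the lncRNA span lies fully inside an intron of
    a coding gene (either strand) with no exonic overlap. lincRNA: no overlap
    with any coding gene span; partial span overlap without exonic overlap
    also falls back to lincRNA.
    """
    if lnc.chrom not in index.chroms:
        warnings.warn(
            f"{lnc.transcript_id}: chromosome {lnc.chrom} absent from gene index; "
            "classifying as lincRNA",
            stacklevel=2,
        )
        return "lincRNA"
    same, opposite = False, False
    for e in lnc.exons:
        for _, _, gene in index.exon_hits(lnc.chrom, e.start, e.end):
            if gene.strand == lnc.strand:
                same = True
            else:
                opposite = True
    if same:
        return "sense"
    if opposite:
        return "antisense"
    span = lnc.span
    for gene in index.span_hits(lnc.chrom, span.start, span.end):
        for intron in gene.introns():
            if intron.start <= span.start and span.end <= intron.end:
                return "intronic"
    return "lincRNA"


def class_percentages(counts: Mapping[str, int], ndigits: int = 1) -> dict[str, float]:
    """Percentage of each class, 100 x count / total, rounded."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty class counts")
    return {k: round(100.0 * v / total, ndigits) for k, v in counts.items()}


@dataclass
class LncRNASummary:
    n_total: int
    class_counts: dict[str, int]
    class_percent: dict[str, float]
    exon_histogram: dict[int, int]
    pct_two_exons: float
    median_length: float
    pct_orf_below_125: float
    max_exons: int = field(default=0)


def summarize_lncrna_set(records: Sequence[LncRNARecord]) -> LncRNASummary:
    """Class counts/percentages, exon histogram, median spliced length and
    the fraction of longest ORFs shorter than 125 nt."""
    if not records:
        raise ValueError("empty lncRNA set")
    counts = {c: 0 for c in CLASSES}
    for r in records:
        counts[r.position_class] += 1
    exon_counts = [r.transcript.n_exons for r in records]
    hist: dict[int, int] = {}
    for n in exon_counts:
        hist[n] = hist.get(n, 0) + 1
    lengths = [r.transcript.spliced_length for r in records]
    orf_lens = [r.coding.orf_len for r in records if r.coding is not None]
    pct_small_orf = (
        round(100.0 * sum(o < 125 for o in orf_lens) / len(orf_lens), 2)
        if orf_lens
        else float("nan")
    )
    return LncRNASummary(
        n_total=len(records),
        class_counts=counts,
        class_percent=class_percentages(counts),
        exon_histogram=dict(sorted(hist.items())),
        pct_two_exons=round(100.0 * hist.get(2, 0) / len(records), 2),
        median_length=float(np.median(lengths)),
        pct_orf_below_125=pct_small_orf,
        max_exons=max(exon_counts),
    )
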