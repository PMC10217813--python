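"""Readers and writers for GTF, FASTA and the pipeline's TSV tables.

GTF features are written 1-based closed with ``gene_id``/``transcript_id``
attributes (plus ``gene_biotype`` on gene lines); parsing goes through
gffutils' attribute grammar so quoting/escaping follows the GTF dialect.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

from .models import GeneModel, GenomicInterval, TranscriptModel


# ---------------------------------------------------------------------------
# GTF

def write_gtf(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene/transcript/exon features, 1-based closed coordinates."""
    Path(path).write_text(gtf_string(genes))


def gtf_string(genes: Iterable[GeneModel]) -> str:
    lines = []
    for g in genes:
        span = g.span
        attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
        lines.append(_gtf_line(g.chrom, "gene", span, g.strand, attrs))
        for t in g.transcripts:
            tattrs = f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'
            lines.append(_gtf_line(t.chrom, "transcript", t.span, t.strand, tattrs))
            for e in t.exons:
                lines.append(_gtf_line(t.chrom, "exon", e, t.strand, tattrs))
    return "\n".join(lines) + "\n"


def _gtf_line(chrom: str, kind: str, iv: GenomicInterval, strand: str, attrs: str) -> str:
    # 0-based half-open -> 1-based closed
    return "\t".join(
        [chrom, "seedcerna", kind, str(iv.start + 1), str(iv.end), ".", strand, ".", attrs]
    )


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Parse a GTF back into gene models (exon features define structure)."""
    biotypes: dict[str, str] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    tx_gene: dict[str, str] = {}
    order: list[str] = []
    for raw in Path(path).read_text().splitlines():
        if not raw or raw.startswith("#"):
            continue
        feat = feature_from_line(raw, dialect=None)
        gid = feat.attributes.get("gene_id", [None])[0]
        if feat.featuretype == "gene":
            biotypes[gid] = feat.attributes.get("gene_biotype", ["protein_coding"])[0]
            order.append(gid)
        elif feat.featuretype == "exon":
            tid = feat.attributes["transcript_id"][0]
            tx_gene[tid] = gid
            exons.setdefault(tid, []).append(
                GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
            )
    genes: dict[str, GeneModel] = {}
    for tid, ivs in exons.items():
        gid = tx_gene[tid]
        gene = genes.setdefault(
            gid, GeneModel(gid, [], biotypes.get(gid, "protein_coding"))
        )
        gene.transcripts.append(TranscriptModel(tid, gid, tuple(ivs)))
    ordered = [genes[g] for g in order if g in genes]
    leftover = [g for gid, g in genes.items() if gid not in set(order)]
    return ordered + leftover


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# TSV tables

def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError("negative values in counts table")
    return df


def read_design(path: str | Path) -> pd.DataFrame:
    """Sample design: index = sample id; columns variety, timepoint, replicate."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    required = {"variety", "timepoint", "replicate"}
    if not required.issubset(df.columns):
        raise ValueError(f"design table needs columns {sorted(required)}")
    return df


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
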