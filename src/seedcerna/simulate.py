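"""Synthetic seed-development transcriptome fixtures with full ground truth.

The generator emulates a two-variety (oil "M" vs fiber "H") by
four-timepoint (5/10/20/30 days after flowering) bulk RNA-seq design on a
single miniature chromosome: protein-coding gene models, lncRNA transcripts
placed to realize each positional class by construction, transcript and
mature-miRNA sequences, negative-binomial counts with planted fold changes,
and a planted ceRNA motif (one lincRNA, one six-member miRNA family and a
block of mRNAs, wired so the lncRNA and mRNAs fall while the family rises
between the first and last timepoints). Everything is seeded and
byte-reproducible, and a truth table records labels for every feature so
each downstream stage can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as sio
from .cerna import MiRNA
from .coding import STOP_CODONS, find_longest_orf
from .models import GeneModel, GenomicInterval, TranscriptModel

CHROM = "chr1"
_NT = "ACGT"
_CODONS = [a + b + c for a in _NT for b in _NT for c in _NT]
_SENSE_CODONS = [c for c in _CODONS if c not in STOP_CODONS]
# fixed codon-usage bias for coding ORFs: GC3-rich codons favoured, giving
# coding sequence a hexamer and codon-position signature absent from the
# uniform background used for non-coding transcripts
_CODON_WEIGHTS = np.array([3.0 if c[2] in "GC" else 1.0 for c in _SENSE_CODONS])
_CODON_WEIGHTS /= _CODON_WEIGHTS.sum()

_DNA_COMPLEMENT = str.maketrans("ACGTU", "TGCAA")


def reverse_complement_dna(seq: str) -> str:
    """Reverse complement, DNA alphabet out (U treated as A's partner)."""
    return seq.upper().translate(_DNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SimConfig:
    """Study-design and noise parameters for one synthetic dataset."""

    seed: int = 42
    n_genes: int = 80
    n_lnc_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"lincRNA": 6, "antisense": 4, "intronic": 4, "sense": 4}
    )
    n_far_linc: int = 2  # lincRNAs placed beyond the cis window from any gene
    n_mirnas: int = 30
    module_family_size: int = 6
    module_n_mrnas: int = 15
    timepoints: tuple[int, ...] = (5, 10, 20, 30)
    varieties: tuple[str, ...] = ("M", "H")
    replicates: int = 3
    nb_mean_range: tuple[float, float] = (20.0, 300.0)
    nb_dispersion: float = 0.05  # mean of the gene-wise gamma dispersion
    planted_fc: float = 4.0  # fold change between first and last timepoint
    de_fraction: float = 0.1  # non-module features that drift, per variety
    planted_failures: tuple[str, ...] = ("too_short", "single_exon", "low_expression")
    intergenic_gap: int = 15_000
    cis_window: int = 100_000
    mirna_length: int = 21
    max_lnc_orf: int = 150  # longest complete ORF allowed in a lncRNA

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates per condition for testable DE")
        if self.module_family_size <= 5:
            raise ValueError("planted family must exceed the shared-miRNA gate (> 5)")
        if self.module_n_mrnas < 5:
            raise ValueError("planted module needs >= 5 mRNAs")


@dataclass
class SimTruth:
    """Ground-truth labels, planted effects and site coordinates."""

    table: pd.DataFrame  # per-feature labels and true log2FCs
    sites: pd.DataFrame  # mirna_id, target_id, start (planted target sites)
    module_lnc: str = ""
    module_mrnas: tuple[str, ...] = ()
    module_mirnas: tuple[str, ...] = ()


@dataclass
class SimulatedDataset:
    config: SimConfig
    genes: list[GeneModel]
    sequences: dict[str, str]  # transcript id -> DNA sequence
    mirnas: list[MiRNA]
    counts: pd.DataFrame
    design: pd.DataFrame
    truth: SimTruth


# ---------------------------------------------------------------------------
# Gene and lncRNA placement

def gen_gene_models(config: SimConfig) -> tuple[list[GeneModel], pd.DataFrame]:
    """Place coding genes and lncRNA transcripts on one chromosome.

    Returns the gene models plus a skeleton truth table (labels and
    positional classes; expression truth is added by :func:`gen_counts`).
    Every lncRNA class is realized by construction: antisense/sense lncRNAs
    overlap an internal coding exon of a host gene on the opposite/same
    strand, intronic lncRNAs sit inside an enlarged first intron, and
    lincRNAs sit mid-gap between genes (a configurable number beyond the
    cis window from every gene).
    """
    rng = np.random.default_rng([config.seed, 0])
    n_per = dict(config.n_lnc_per_class)
    need_hosts = n_per.get("antisense", 0) + n_per.get("sense", 0) + n_per.get("intronic", 0)
    if need_hosts > config.n_genes:
        raise ValueError(
            f"cannot place {need_hosts} gene-associated lncRNAs on {config.n_genes} genes"
        )
    n_linc = n_per.get("lincRNA", 0)
    if n_linc > max(config.n_genes - 1, 0) + config.n_far_linc:
        raise ValueError("not enough intergenic gaps for the requested lincRNAs")

    genes: list[GeneModel] = []
    cursor = 10_000
    for i in range(config.n_genes):
        gid = f"GENE{i + 1:04d}"
        strand = "+" if i % 2 == 0 else "-"
        n_exons = int(rng.integers(3, 6))
        exons = []
        pos = cursor
        for e in range(n_exons):
            elen = int(rng.integers(250, 420))
            exons.append(GenomicInterval(CHROM, pos, pos + elen, strand))
            if e < n_exons - 1:
                ilen = 2500 if e == 0 else int(rng.integers(300, 800))
                pos = pos + elen + ilen
            else:
                pos = pos + elen
        tx = TranscriptModel(f"{gid}.t1", gid, tuple(exons))
        genes.append(GeneModel(gid, [tx], "protein_coding"))
        cursor = pos + config.intergenic_gap

    rows: list[dict] = []
    for g in genes:
        rows.append(
            {
                "feature_id": g.transcripts[0].transcript_id,
                "kind": "mRNA",
                "coding": "coding",
                "class": "",
                "flag": "ok",
            }
        )

    lnc_genes: list[GeneModel] = []
    counter = 0

    def add_lnc(exons: list[GenomicInterval], cls: str, flag: str = "ok") -> str:
        nonlocal counter
        counter += 1
        tid = f"LNC{counter:04d}.1"
        gid = f"LNCG{counter:04d}"
        lnc_genes.append(GeneModel(gid, [TranscriptModel(tid, gid, tuple(exons))], "lncRNA"))
        rows.append(
            {"feature_id": tid, "kind": "lncRNA", "coding": "noncoding", "class": cls, "flag": flag}
        )
        return tid

    host_iter = iter(genes)

    for _ in range(n_per.get("antisense", 0)):
        host = next(host_iter)
        ce = host.transcripts[0].exons[1]
        strand = "-" if host.strand == "+" else "+"
        e1 = GenomicInterval(CHROM, ce.start + 20, ce.start + 20 + int(rng.integers(150, 220)), strand)
        gap = int(rng.integers(150, 300))
        e2len = int(rng.integers(200, 500))
        e2 = GenomicInterval(CHROM, e1.end + gap, e1.end + gap + e2len, strand)
        add_lnc([e1, e2], "antisense")

    for _ in range(n_per.get("sense", 0)):
        host = next(host_iter)
        ce = host.transcripts[0].exons[1]
        strand = host.strand
        e1 = GenomicInterval(CHROM, ce.start + 20, ce.start + 20 + int(rng.integers(150, 220)), strand)
        gap = int(rng.integers(150, 300))
        e2len = int(rng.integers(200, 500))
        e2 = GenomicInterval(CHROM, e1.end + gap, e1.end + gap + e2len, strand)
        add_lnc([e1, e2], "sense")

    for j in range(n_per.get("intronic", 0)):
        host = next(host_iter)
        intron = host.transcripts[0].introns()[0]
        strand = host.strand if j % 2 == 0 else ("-" if host.strand == "+" else "+")
        e1len = int(rng.integers(150, 350))
        e2len = int(rng.integers(150, 350))
        gap = 200
        if 100 + e1len + gap + e2len + 100 > len(intron):
            raise ValueError("host intron too small for intronic lncRNA placement")
        e1 = GenomicInterval(CHROM, intron.start + 100, intron.start + 100 + e1len, strand)
        e2 = GenomicInterval(CHROM, e1.end + gap, e1.end + gap + e2len, strand)
        add_lnc([e1, e2], "intronic")

    n_far = min(config.n_far_linc, n_linc)
    n_near = n_linc - n_far
    last_end = genes[-1].span.end
    for j in range(n_near):
        left = genes[j].span.end
        mid = left + config.intergenic_gap // 2
        strand = "+" if j % 2 == 0 else "-"
        e1len = int(rng.integers(200, 500))
        e2len = int(rng.integers(200, 500))
        e1 = GenomicInterval(CHROM, mid, mid + e1len, strand)
        e2 = GenomicInterval(CHROM, e1.end + 250, e1.end + 250 + e2len, strand)
        add_lnc([e1, e2], "lincRNA")
    far_cursor = last_end + config.cis_window + 50_000
    for j in range(n_far):
        strand = "+" if j % 2 == 0 else "-"
        e1len = int(rng.integers(200, 500))
        e2len = int(rng.integers(200, 500))
        e1 = GenomicInterval(CHROM, far_cursor, far_cursor + e1len, strand)
        e2 = GenomicInterval(CHROM, e1.end + 250, e1.end + 250 + e2len, strand)
        add_lnc([e1, e2], "lincRNA", flag="far")
        far_cursor = e2.end + 10_000

    fail_cursor = far_cursor + 20_000
    for kind in config.planted_failures:
        if kind == "too_short":
            e = GenomicInterval(CHROM, fail_cursor, fail_cursor + 150, "+")
            add_lnc([e], "lincRNA", flag="too_short")
        elif kind == "single_exon":
            e = GenomicInterval(CHROM, fail_cursor, fail_cursor + 400, "+")
            add_lnc([e], "lincRNA", flag="single_exon")
        elif kind == "low_expression":
            e1 = GenomicInterval(CHROM, fail_cursor, fail_cursor + 300, "+")
            e2 = GenomicInterval(CHROM, e1.end + 200, e1.end + 500, "+")
            add_lnc([e1, e2], "lincRNA", flag="low_expression")
        else:
            raise ValueError(f"unknown planted failure {kind!r}")
        fail_cursor += 5_000

    truth = pd.DataFrame(rows).set_index("feature_id")
    return genes + lnc_genes, truth


# ---------------------------------------------------------------------------
# Sequences

# non-coding and untranslated sequence is AT-rich, as in plant genomes;
# coding ORFs are GC3-biased, so composition and codon structure both
# separate the two populations (as they do in real transcriptomes)
_NONCODING_P = (0.30, 0.20, 0.20, 0.30)  # A, C, G, T


def _random_seq(rng: np.random.Generator, n: int, p=_NONCODING_P) -> str:
    return "".join(rng.choice(list(_NT), size=n, p=p))


def _coding_orf(rng: np.random.Generator, n_codons: int) -> str:
    codons = rng.choice(_SENSE_CODONS, size=n_codons - 2, p=_CODON_WEIGHTS)
    stop = STOP_CODONS[int(rng.integers(0, 3))]
    return "ATG" + "".join(codons) + stop


def _break_orfs(
    seq: str, rng: np.random.Generator, max_orf: int, protected: Sequence[tuple[int, int]] = ()
) -> str:
    """Mutate in-frame codons to stops until no complete ORF reaches max_orf."""
    s = list(seq)
    for _ in range(400):
        hit = find_longest_orf("".join(s))
        if hit.length < max_orf:
            return "".join(s)
        # candidate in-frame codon starts within the ORF, avoiding protected spans
        starts = [
            hit.offset + 3 * k
            for k in range(1, hit.length // 3 - 1)
            if not any(a < hit.offset + 3 * k + 3 and hit.offset + 3 * k < b for a, b in protected)
        ]
        if not starts:
            raise ValueError("cannot break ORF without touching a protected site")
        pos = starts[int(rng.integers(0, len(starts)))]
        s[pos : pos + 3] = STOP_CODONS[int(rng.integers(0, 3))]
    raise RuntimeError("ORF breaking did not converge")


def gen_sequences(
    genes: Sequence[GeneModel], truth: pd.DataFrame, config: SimConfig
) -> tuple[dict[str, str], list[MiRNA], SimTruth]:
    """Transcript and mature-miRNA sequences with planted target sites.

    Coding transcripts carry one long biased-codon ORF (>= 300 nt including
    the stop) between UTRs; non-coding transcripts are uniform-random with
    every complete ORF broken below ``config.max_lnc_orf``. The planted
    family shares one mature sequence across ``module_family_size`` distinct
    ids; its sites are embedded as exact reverse complements in the module
    lincRNA and in the 3' UTR of each module mRNA. Decoy miRNAs get sparse
    single sites so candidate pairs below the shared-miRNA gate exist.
    """
    rng = np.random.default_rng([config.seed, 1])
    fam_seq = "".join(rng.choice(list("ACGU"), size=config.mirna_length))
    mirnas = [
        MiRNA(f"miR156L-{i + 1}", "miR156L", fam_seq) for i in range(config.module_family_size)
    ]
    n_decoys = config.n_mirnas - config.module_family_size
    if n_decoys < 0:
        raise ValueError("n_mirnas must be >= module_family_size")
    for d in range(n_decoys):
        while True:
            seq = "".join(rng.choice(list("ACGU"), size=config.mirna_length))
            if seq != fam_seq:
                break
        mid = f"miR-dec-{d + 1:02d}"
        mirnas.append(MiRNA(mid, mid, seq))

    coding_ids = [fid for fid in truth.index if truth.loc[fid, "kind"] == "mRNA"]
    lnc_ids = [fid for fid in truth.index if truth.loc[fid, "kind"] == "lncRNA"]
    if len(coding_ids) < config.module_n_mrnas:
        raise ValueError("not enough coding genes for the planted module")
    module_mrnas = tuple(coding_ids[: config.module_n_mrnas])
    near_lincs = [
        fid
        for fid in lnc_ids
        if truth.loc[fid, "class"] == "lincRNA" and truth.loc[fid, "flag"] == "ok"
    ]
    module_lnc = near_lincs[0] if near_lincs else (lnc_ids[0] if lnc_ids else "")
    fam_site_dna = reverse_complement_dna(fam_seq)

    tx_by_id = {t.transcript_id: t for g in genes for t in g.transcripts}
    sequences: dict[str, str] = {}
    site_rows: list[dict] = []

    def plant(seq: str, tid: str, pos: int, mirna_id: str, site: str) -> str:
        if pos < 0 or pos + len(site) > len(seq):
            raise ValueError(f"{tid}: transcript too short for planted site")
        site_rows.append({"mirna_id": mirna_id, "target_id": tid, "start": pos})
        return seq[:pos] + site + seq[pos + len(site) :]

    decoy_iter = 0
    non_module_coding = [fid for fid in coding_ids if fid not in module_mrnas]
    decoy_sites: dict[str, list[str]] = {fid: [] for fid in non_module_coding}
    for d in range(n_decoys):
        target = non_module_coding[decoy_iter % len(non_module_coding)]
        decoy_sites[target].append(mirnas[config.module_family_size + d].mirna_id)
        decoy_iter += 1

    for tid in coding_ids:
        L = tx_by_id[tid].spliced_length
        utr3 = 60
        utr5 = 60
        orf_len = ((L - utr5 - utr3) // 3) * 3
        if orf_len < 303:
            raise ValueError(f"{tid}: spliced length {L} too short for a >= 300 nt ORF")
        utr3 = L - utr5 - orf_len
        seq = _random_seq(rng, utr5) + _coding_orf(rng, orf_len // 3) + _random_seq(rng, utr3)
        if tid in module_mrnas:
            pos = L - utr3 + 5
            for m in mirnas[: config.module_family_size]:
                # family members share the sequence, hence one physical site
                site_rows.append({"mirna_id": m.mirna_id, "target_id": tid, "start": pos})
            seq = seq[:pos] + fam_site_dna + seq[pos + len(fam_site_dna) :]
        for mid in decoy_sites.get(tid, []):
            dseq = reverse_complement_dna(next(m.sequence for m in mirnas if m.mirna_id == mid))
            pos = L - utr3 + 5
            seq = plant(seq, tid, pos, mid, dseq)
        sequences[tid] = seq

    for tid in lnc_ids:
        L = tx_by_id[tid].spliced_length
        seq = _break_orfs(_random_seq(rng, L), rng, config.max_lnc_orf)
        if tid == module_lnc:
            pos = max(0, L // 2 - config.mirna_length)
            protected = [(pos, pos + len(fam_site_dna))]
            for m in mirnas[: config.module_family_size]:
                site_rows.append({"mirna_id": m.mirna_id, "target_id": tid, "start": pos})
            seq = seq[:pos] + fam_site_dna + seq[pos + len(fam_site_dna) :]
            if n_decoys > 0:
                # one decoy also hits the sponge, creating a sub-threshold pair
                dpos = pos + config.mirna_length + 10
                dm = mirnas[config.module_family_size]
                dsite = reverse_complement_dna(dm.sequence)
                protected.append((dpos, dpos + len(dsite)))
                seq = plant(seq, tid, dpos, dm.mirna_id, dsite)
            if find_longest_orf(seq).length >= 300:
                seq = _break_orfs(seq, rng, 300, protected=protected)
        sequences[tid] = seq

    sites = pd.DataFrame(site_rows, columns=["mirna_id", "target_id", "start"])
    truth_obj = SimTruth(
        table=truth,
        sites=sites,
        module_lnc=module_lnc,
        module_mrnas=module_mrnas,
        module_mirnas=tuple(m.mirna_id for m in mirnas[: config.module_family_size]),
    )
    return sequences, mirnas, truth_obj


# ---------------------------------------------------------------------------
# Counts

def sample_names(config: SimConfig) -> list[str]:
    return [
        f"{v}{t}_r{r + 1}"
        for v in config.varieties
        for t in config.timepoints
        for r in range(config.replicates)
    ]


def gen_counts(
    truth: SimTruth, mirnas: Sequence[MiRNA], config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Negative-binomial counts with planted timepoint trends.

    Each feature draws a baseline mean (log-uniform over ``nb_mean_range``)
    and a gene-wise dispersion from a gamma around ``nb_dispersion``.
    Drifting features move geometrically across the four timepoints so the
    first-vs-last contrast realizes the full planted fold change; the
    planted module drifts down (lncRNA, mRNAs) or up (family miRNAs) in the
    oil variety. True per-variety log2FCs (last over first timepoint) are
    written back into the truth table.
    """
    rng = np.random.default_rng([config.seed, 2])
    table = truth.table.copy()
    mirna_ids = [m.mirna_id for m in mirnas]
    features = list(table.index) + mirna_ids
    kinds = {fid: table.loc[fid, "kind"] for fid in table.index}
    for m in mirna_ids:
        kinds[m] = "miRNA"

    fc = float(config.planted_fc)
    n_tp = len(config.timepoints)
    module = set(truth.module_mrnas) | {truth.module_lnc} | set(truth.module_mirnas)

    base = {}
    disp = {}
    direction: dict[str, dict[str, float]] = {}
    lo, hi = config.nb_mean_range
    for fid in features:
        base[fid] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        disp[fid] = float(rng.gamma(8.0, config.nb_dispersion / 8.0))
        direction[fid] = {v: 0.0 for v in config.varieties}
        if fid in module:
            base[fid] = float(rng.uniform(150.0, 300.0))
            d = 1.0 if fid in truth.module_mirnas else -1.0
            direction[fid][config.varieties[0]] = d
        elif kinds[fid] == "lncRNA" and table.loc[fid, "flag"] == "low_expression":
            base[fid] = 0.0  # silent: fails the FPKM gate deterministically
        else:
            for v in config.varieties:
                if rng.random() < config.de_fraction:
                    direction[fid][v] = 1.0 if rng.random() < 0.5 else -1.0

    cols = sample_names(config)
    mat = np.zeros((len(features), len(cols)), dtype=int)
    for j, col in enumerate(cols):
        v = col[0]
        tp = int(col[1:].split("_")[0])
        stage = config.timepoints.index(tp)
        for i, fid in enumerate(features):
            mean = base[fid] * fc ** (direction[fid][v] * stage / (n_tp - 1))
            alpha = disp[fid]
            n = 1.0 / alpha
            p = n / (n + mean)
            mat[i, j] = rng.negative_binomial(n, p)
    counts = pd.DataFrame(mat, index=pd.Index(features, name="feature_id"), columns=cols)

    design = pd.DataFrame(
        [
            {
                "sample": col,
                "variety": col[0],
                "timepoint": int(col[1:].split("_")[0]),
                "replicate": int(col.split("_r")[1]),
            }
            for col in cols
        ]
    ).set_index("sample")

    for m in mirna_ids:
        table.loc[m, ["kind", "coding", "class", "flag"]] = ["miRNA", "", "", "ok"]
    for v in config.varieties:
        table[f"lfc_{v}"] = [direction[fid][v] * np.log2(fc) for fid in table.index]
    table["module_role"] = ""
    table.loc[[truth.module_lnc], "module_role"] = "lncRNA"
    table.loc[list(truth.module_mrnas), "module_role"] = "mRNA"
    table.loc[list(truth.module_mirnas), "module_role"] = "miRNA"
    out_truth = replace(truth, table=table)
    return counts, design, out_truth


# ---------------------------------------------------------------------------
# Orchestration

def simulate(config: SimConfig | None = None) -> SimulatedDataset:
    """Run all generation stages for one config."""
    config = config or SimConfig()
    genes, skeleton = gen_gene_models(config)
    sequences, mirnas, truth = gen_sequences(genes, skeleton, config)
    counts, design, truth = gen_counts(truth, mirnas, config)
    return SimulatedDataset(config, genes, sequences, mirnas, counts, design, truth)


FIXTURE_FILES = (
    "models.gtf",
    "transcripts.fa",
    "mirnas.fa",
    "counts.tsv",
    "design.tsv",
    "truth.tsv",
)


def write_fixture(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the six fixture files; all re-readable by the pipeline readers."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / name for name in FIXTURE_FILES}
    sio.write_gtf(dataset.genes, paths["models.gtf"])
    sio.write_fasta(dataset.sequences, paths["transcripts.fa"])
    sio.write_fasta({m.mirna_id: m.sequence for m in dataset.mirnas}, paths["mirnas.fa"])
    sio.write_tsv(dataset.counts, paths["counts.tsv"])
    sio.write_tsv(dataset.design, paths["design.tsv"])
    truth = dataset.truth.table.copy()
    site_strings = {
        tid: ";".join(f"{r.mirna_id}@{r.start}" for r in grp.itertuples())
        for tid, grp in dataset.truth.sites.groupby("target_id")
    }
    truth["sites"] = [site_strings.get(fid, "") for fid in truth.index]
    family = {m.mirna_id: m.family for m in dataset.mirnas}
    truth["family"] = [family.get(fid, "") for fid in truth.index]
    sio.write_tsv(truth, paths["truth.tsv"])
    return paths
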