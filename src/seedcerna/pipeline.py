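"""End-to-end orchestration: identify -> DE -> cis/scan -> ceRNA -> network.

Contrasts are oriented later-timepoint over earlier, so a transcript that
falls between 5 and 30 days after flowering has a negative log2FC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .cerna import (
    MiRNA,
    ScanParams,
    build_network,
    cerna_pairs,
    cis_targets,
    export_network,
    negative_regulation_filter,
    node_counts,
    scan_all,
    targets_by,
)
from .coding import (
    dinucleotide_shuffle,
    find_longest_orf,
    fickett_score,
    hexamer_score,
    score_transcript,
    train_combiner,
    train_hexamer_table,
)
from .diffexp import de_screen, fold_increase, fpkm, nb_test
from .lncrna import (
    GeneIndex,
    LncRNARecord,
    LncRNASummary,
    basic_filter,
    classify_position,
    summarize_lncrna_set,
)
from .models import GeneModel, coding_genes, transcripts_of


@dataclass
class PipelineConfig:
    """All stage thresholds; defaults are the published screening gates."""

    min_len: int = 200
    min_exons: int = 2
    min_fpkm: float = 0.1
    orf_cutoff: int = 300
    fickett_cutoff: float = 0.95
    hexamer_cutoff: float = 0.0
    combiner_threshold: float = 0.5
    cis_window: int = 100_000
    scan: ScanParams = field(default_factory=ScanParams)
    min_shared: int = 6  # "more than 5" shared miRNAs, read strictly
    p_max: float = 0.01
    fdr_max: float = 0.01
    lnc_screen_mode: str = "lnc_fdr05"
    cerna_variety: str = "M"
    cerna_timepoints: tuple[int, int] = (5, 30)
    contrast_timepoints: tuple[int, ...] = (10, 20, 30)  # each vs the first timepoint
    seed: int = 42

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        scan = data.pop("scan", None)
        cfg = cls(**data)
        if scan:
            cfg.scan = ScanParams(**scan)
        return cfg


@dataclass
class StageCount:
    stage: str
    n_input: int
    n_surviving: int
    reasons: dict[str, int] = field(default_factory=dict)

    @property
    def n_dropped(self) -> int:
        return self.n_input - self.n_surviving


@dataclass
class RunReport:
    stages: list[StageCount]
    lnc_summary: LncRNASummary | None
    de_tallies: dict[str, dict[str, int]]  # contrast label -> {up, down, total}
    fold_table: dict[str, float]  # variety -> fold increase first->last contrast
    network_nodes: dict[str, int]
    network_edges: int
    n_cis_pairs: int
    n_cerna_pairs: int


def de_tally(calls: Mapping[str, pd.Series] | pd.Series) -> dict:
    """Up/down/total tallies (and shared/specific sets across contrasts).

    With a single call Series, returns {up, down, total}. With a mapping of
    contrast label -> calls, additionally returns per-contrast significant
    id sets, their intersection ("shared") and per-contrast exclusives
    ("specific").
    """
    if isinstance(calls, pd.Series):
        up = int((calls == "up").sum())
        down = int((calls == "down").sum())
        return {"up": up, "down": down, "total": up + down}
    per = {}
    sig_sets = {}
    for label, series in calls.items():
        per[label] = de_tally(series)
        sig_sets[label] = set(series.index[series != "ns"])
    shared = set.intersection(*sig_sets.values()) if sig_sets else set()
    specific = {
        label: ids - set.union(*(s for k, s in sig_sets.items() if k != label), set())
        if len(sig_sets) > 1
        else ids
        for label, ids in sig_sets.items()
    }
    return {"per_contrast": per, "sets": sig_sets, "shared": shared, "specific": specific}


@dataclass
class FixturePaths:
    gtf: Path
    transcripts_fa: Path
    mirnas_fa: Path
    counts: Path
    design: Path

    @classmethod
    def in_dir(cls, d: str | Path) -> "FixturePaths":
        d = Path(d)
        return cls(
            d / "models.gtf",
            d / "transcripts.fa",
            d / "mirnas.fa",
            d / "counts.tsv",
            d / "design.tsv",
        )


def _samples_for(design: pd.DataFrame, variety: str, timepoint: int) -> list[str]:
    mask = (design["variety"] == variety) & (design["timepoint"] == timepoint)
    return list(design.index[mask])


def run_pipeline(
    paths: FixturePaths | str | Path,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    mirna_families: Mapping[str, str] | None = None,
) -> tuple[RunReport, dict]:
    """Run every stage on one fixture directory.

    Returns the report plus a dict of intermediate artifacts (lncRNA
    records, DE tables, pairs, network). When ``outdir`` is given, stage
    outputs are written there (TSV tables, SIF/GraphML/TSV network,
    markdown report).
    """
    config = config or PipelineConfig()
    if not isinstance(paths, FixturePaths):
        paths = FixturePaths.in_dir(paths)
    genes = sio.read_gtf(paths.gtf)
    seqs = sio.read_fasta(paths.transcripts_fa)
    mirna_seqs = sio.read_fasta(paths.mirnas_fa)
    fams = mirna_families or {}
    mirnas = [MiRNA(mid, fams.get(mid, mid), s) for mid, s in mirna_seqs.items()]
    counts = sio.read_counts(paths.counts)
    design = sio.read_design(paths.design)

    transcripts = transcripts_of(genes)
    tx_ids = [t.transcript_id for t in transcripts]
    missing = [tid for tid in tx_ids if tid not in counts.index]
    if missing:
        raise KeyError(f"identify stage: transcripts without counts: {missing[:5]}")
    counts_tx = counts.loc[tx_ids]
    mirna_ids = [m for m in counts.index if m not in set(tx_ids)]
    counts_mirna = counts.loc[mirna_ids]
    lengths = pd.Series({t.transcript_id: t.spliced_length for t in transcripts})
    fpkm_tx = fpkm(counts_tx, lengths, counts_tx.sum(axis=0))

    stages: list[StageCount] = []

    # --- stage 1: basic screen -------------------------------------------
    survivors = basic_filter(
        transcripts, fpkm_tx, config.min_len, config.min_exons, config.min_fpkm
    )
    reasons: dict[str, int] = {"length": 0, "exons": 0, "fpkm": 0}
    for t in transcripts:
        if t.spliced_length < config.min_len:
            reasons["length"] += 1
        elif t.n_exons < config.min_exons:
            reasons["exons"] += 1
        elif fpkm_tx.loc[t.transcript_id].max() < config.min_fpkm:
            reasons["fpkm"] += 1
    stages.append(StageCount("basic_filter", len(transcripts), len(survivors), reasons))

    # --- stage 2: coding-potential consensus ------------------------------
    # the coding model is trained on annotated coding transcripts; the
    # non-coding background on dinucleotide-preserving shuffles of the whole
    # candidate pool, so it matches the candidates' composition while
    # destroying codon structure
    rng = np.random.default_rng([config.seed, 97])
    potentials = {}
    lnc_candidates = []
    if survivors:
        coding_ref = [seqs[t.transcript_id] for g in coding_genes(genes) for t in g.transcripts]
        shuffled_ref = [dinucleotide_shuffle(seqs[t.transcript_id], rng) for t in survivors]
        table = train_hexamer_table(coding_ref, shuffled_ref)
        X, y = [], []
        for s in coding_ref:
            X.append([find_longest_orf(s).length, fickett_score(s), hexamer_score(s, table)])
            y.append(1)
        for s in shuffled_ref:
            X.append([find_longest_orf(s).length, fickett_score(s), hexamer_score(s, table)])
            y.append(0)
        combiner = train_combiner(np.array(X), np.array(y), config.combiner_threshold)
        for t in survivors:
            cp = score_transcript(
                seqs[t.transcript_id],
                table,
                combiner,
                config.orf_cutoff,
                config.fickett_cutoff,
                config.hexamer_cutoff,
            )
            potentials[t.transcript_id] = cp
            if cp.consensus_noncoding:
                lnc_candidates.append(t)
    stages.append(
        StageCount(
            "coding_screen",
            len(survivors),
            len(lnc_candidates),
            {"coding": len(survivors) - len(lnc_candidates)},
        )
    )

    # --- stage 3: positional classification -------------------------------
    index = GeneIndex(genes)
    records = [
        LncRNARecord(
            t,
            classify_position(t, index),
            potentials[t.transcript_id],
            fpkm_tx.loc[t.transcript_id].to_numpy(),
        )
        for t in lnc_candidates
    ]
    summary = summarize_lncrna_set(records) if records else None
    lnc_ids = [r.transcript.transcript_id for r in records]

    # --- stage 4: differential expression ---------------------------------
    t0 = min(design["timepoint"])
    de_tables: dict[str, pd.DataFrame] = {}
    lnc_calls: dict[str, pd.Series] = {}
    for variety in sorted(design["variety"].unique()):
        for tp in config.contrast_timepoints:
            label = f"{variety}{t0}:{variety}{tp}"
            ga = _samples_for(design, variety, t0)
            gb = _samples_for(design, variety, tp)
            if not ga or not gb:
                raise ValueError(f"contrast {label}: design levels missing")
            de_tables[label] = nb_test(counts_tx, ga, gb)
            if lnc_ids:
                lnc_calls[label] = de_screen(de_tables[label].loc[lnc_ids], config.lnc_screen_mode)

    tallies = {label: de_tally(c) for label, c in lnc_calls.items()}
    fold_table = {}
    first_tp, last_tp = config.contrast_timepoints[0], config.contrast_timepoints[-1]
    for variety in sorted(design["variety"].unique()):
        a = tallies.get(f"{variety}{t0}:{variety}{first_tp}", {}).get("total", 0)
        b = tallies.get(f"{variety}{t0}:{variety}{last_tp}", {}).get("total", 0)
        if a > 0:
            fold_table[variety] = fold_increase(a, b)

    # --- stage 5: cis targets ---------------------------------------------
    cis = cis_targets([r.transcript for r in records], genes, config.cis_window)

    # --- stage 6: ceRNA network -------------------------------------------
    v = config.cerna_variety
    tp_a, tp_b = config.cerna_timepoints
    label = f"{v}{tp_a}:{v}{tp_b}"
    ga = _samples_for(design, v, tp_a)
    gb = _samples_for(design, v, tp_b)
    de_tx = nb_test(counts_tx, ga, gb)
    de_mirna = nb_test(counts_mirna, ga, gb) if len(counts_mirna) >= 1 else pd.DataFrame()
    coding_tx_ids = [
        t.transcript_id for g in coding_genes(genes) for t in g.transcripts
    ]
    lnc_cerna_calls = (
        de_screen(de_tx.loc[lnc_ids], "cerna_fdr01") if lnc_ids else pd.Series(dtype=object)
    )
    mrna_cerna_calls = de_screen(de_tx.loc[coding_tx_ids], "cerna_fdr01")
    mirna_calls = de_screen(de_mirna, "mirna") if len(de_mirna) else pd.Series(dtype=object)

    de_lnc_ids = list(lnc_cerna_calls.index[lnc_cerna_calls != "ns"])
    de_mrna_ids = list(mrna_cerna_calls.index[mrna_cerna_calls != "ns"])
    hits_lnc = scan_all(mirnas, {i: seqs[i] for i in de_lnc_ids}, config.scan)
    hits_mrna = scan_all(mirnas, {i: seqs[i] for i in de_mrna_ids}, config.scan)
    universe = len(mirnas)
    pairs = cerna_pairs(
        targets_by(hits_lnc),
        targets_by(hits_mrna),
        universe,
        config.min_shared,
        config.p_max,
        config.fdr_max,
    )
    n_tested = len(pairs)
    calls_all = pd.concat([lnc_cerna_calls, mrna_cerna_calls, mirna_calls]).to_dict()
    screened = negative_regulation_filter(pairs, calls_all, config.min_shared)
    stages.append(
        StageCount(
            "cerna_screen", n_tested, len(screened), {"regulation": n_tested - len(screened)}
        )
    )
    network = build_network(screened, calls_all)

    report = RunReport(
        stages=stages,
        lnc_summary=summary,
        de_tallies=tallies,
        fold_table=fold_table,
        network_nodes=node_counts(network),
        network_edges=network.number_of_edges(),
        n_cis_pairs=len(cis),
        n_cerna_pairs=len(screened),
    )
    artifacts = {
        "records": records,
        "potentials": potentials,
        "de_tables": de_tables,
        "de_cerna": de_tx,
        "de_mirna": de_mirna,
        "lnc_calls": lnc_calls,
        "cerna_calls": calls_all,
        "cis_pairs": cis,
        "pairs": screened,
        "pairs_pregate": pairs,
        "network": network,
        "cerna_contrast": label,
    }
    if outdir is not None:
        _write_outputs(Path(outdir), report, artifacts)
    return report, artifacts


def _write_outputs(outdir: Path, report: RunReport, artifacts: dict) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    recs = artifacts["records"]
    lnc_df = pd.DataFrame(
        {
            "transcript_id": [r.transcript.transcript_id for r in recs],
            "class": [r.position_class for r in recs],
            "length": [r.transcript.spliced_length for r in recs],
            "n_exons": [r.transcript.n_exons for r in recs],
            "orf_len": [r.coding.orf_len for r in recs],
            "fickett": [r.coding.fickett for r in recs],
            "hexamer": [r.coding.hexamer for r in recs],
            "combined": [r.coding.combined for r in recs],
        }
    ).set_index("transcript_id")
    sio.write_tsv(lnc_df, outdir / "lncrnas.tsv")
    for label, table in artifacts["de_tables"].items():
        sio.write_tsv(table, outdir / f"de_{label.replace(':', '_vs_')}.tsv")
    pairs_df = pd.DataFrame(
        [
            {
                "lnc_id": p.lnc_id,
                "mrna_id": p.mrna_id,
                "k": p.k,
                "n_lnc": p.n_lnc,
                "n_mrna": p.n_mrna,
                "universe": p.universe,
                "pvalue": p.pvalue,
                "fdr": p.fdr,
                "shared": ";".join(sorted(p.shared)),
            }
            for p in artifacts["pairs"]
        ],
        columns=[
            "lnc_id", "mrna_id", "k", "n_lnc", "n_mrna", "universe", "pvalue", "fdr", "shared",
        ],
    )
    pairs_df.to_csv(outdir / "cerna_pairs.tsv", sep="\t", index=False)
    cis_df = pd.DataFrame(
        [{"lnc_id": c.lnc_id, "gene_id": c.gene_id, "distance": c.distance}
         for c in artifacts["cis_pairs"]],
        columns=["lnc_id", "gene_id", "distance"],
    )
    cis_df.to_csv(outdir / "cis_pairs.tsv", sep="\t", index=False)
    net = artifacts["network"]
    export_network(net, outdir / "network.sif", "sif")
    export_network(net, outdir / "network.graphml", "graphml")
    export_network(net, outdir / "network_nodes.tsv", "tsv")
    render_report(report, outdir, fmt="md")
    render_report(report, outdir, fmt="tsv")


def render_report(report: RunReport, outdir: str | Path, fmt: str = "md") -> Path:
    """Write the run report as markdown or TSV with a stable field order."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if fmt == "tsv":
        rows = []
        for s in report.stages:
            rows.append({"section": "stage", "key": s.stage, "value": f"{s.n_input}->{s.n_surviving}"})
        if report.lnc_summary:
            for cls, n in sorted(report.lnc_summary.class_counts.items()):
                rows.append({"section": "class_count", "key": cls, "value": n})
            for cls, p in sorted(report.lnc_summary.class_percent.items()):
                rows.append({"section": "class_percent", "key": cls, "value": p})
            rows.append({"section": "summary", "key": "median_length",
                         "value": report.lnc_summary.median_length})
        for label, t in sorted(report.de_tallies.items()):
            for k in ("up", "down", "total"):
                rows.append({"section": "de_tally", "key": f"{label}.{k}", "value": t[k]})
        for v, f in sorted(report.fold_table.items()):
            rows.append({"section": "fold_increase", "key": v, "value": f})
        for kind, n in sorted(report.network_nodes.items()):
            rows.append({"section": "network", "key": kind, "value": n})
        rows.append({"section": "network", "key": "edges", "value": report.network_edges})
        path = outdir / "report.tsv"
        pd.DataFrame(rows, columns=["section", "key", "value"]).to_csv(path, sep="\t", index=False)
        return path
    if fmt != "md":
        raise ValueError(f"unknown report format {fmt!r}")
    lines = ["# Pipeline report", "", "## Stage record counts", ""]
    lines.append("| stage | input | surviving | dropped |")
    lines.append("|---|---|---|---|")
    for s in report.stages:
        lines.append(f"| {s.stage} | {s.n_input} | {s.n_surviving} | {s.n_dropped} |")
    if report.lnc_summary:
        sm = report.lnc_summary
        lines += ["", "## lncRNA classes", "", "| class | count | percent |", "|---|---|---|"]
        for cls in sorted(sm.class_counts):
            lines.append(f"| {cls} | {sm.class_counts[cls]} | {sm.class_percent[cls]} |")
        lines.append(f"| total | {sm.n_total} | 100.0 |")
        lines += [
            "",
            f"Median spliced length: {sm.median_length} nt; "
            f"{sm.pct_two_exons}% with 2 exons; "
            f"{sm.pct_orf_below_125}% of ORFs < 125 nt.",
        ]
    lines += ["", "## Differential expression", ""]
    lines.append("| contrast | up | down | total |")
    lines.append("|---|---|---|---|")
    for label, t in sorted(report.de_tallies.items()):
        lines.append(f"| {label} | {t['up']} | {t['down']} | {t['total']} |")
    for v, f in sorted(report.fold_table.items()):
        lines.append(f"\nVariety {v}: {f}-fold increase in DE lncRNAs across the series.")
    lines += ["", "## ceRNA network", ""]
    for kind, n in sorted(report.network_nodes.items()):
        lines.append(f"- {kind}: {n}")
    lines.append(f"- edges: {report.network_edges}")
    lines.append(f"- surviving lncRNA-mRNA pairs: {report.n_cerna_pairs}")
    lines.append(f"- cis pairs: {report.n_cis_pairs}")
    path = outdir / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path
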