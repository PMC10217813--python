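"""ceRNA network inference: cis targets, miRNA target scanning, shared-miRNA
hypergeometric pairing, negative-regulation screening and network export.

The target scanner slides the reverse-complemented mature miRNA along the
transcript and scores each site with plant-style penalties: mismatch 1.0,
G:U wobble 0.5, single-nucleotide target bulge 1.0, each doubled when it
falls at miRNA positions 2-13 (counted from the miRNA 5' end). Sites with a
total penalty <= cutoff (default 4.0) are reported; at most one bulge per
site is considered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_fdr
from .models import GeneModel, TranscriptModel

_RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class MiRNA:
    """A mature plant miRNA (RNA alphabet, typically 19-24 nt)."""

    mirna_id: str
    family: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        object.__setattr__(self, "sequence", seq)
        if set(seq) - set("ACGU"):
            raise ValueError(f"{self.mirna_id}: non-RNA characters in mature sequence")


@dataclass(frozen=True)
class TargetHit:
    mirna_id: str
    target_id: str
    start: int  # 0-based position on the transcript
    penalty: float
    bulge_pos: int | None = None  # miRNA position 5' of the target bulge, if any


@dataclass(frozen=True)
class CisPair:
    lnc_id: str
    gene_id: str
    distance: int  # bp between spans; 0 if overlapping


@dataclass
class CeRNAPair:
    lnc_id: str
    mrna_id: str
    shared: frozenset[str]
    n_lnc: int  # miRNAs targeting the lncRNA
    n_mrna: int  # miRNAs targeting the mRNA
    universe: int
    pvalue: float
    fdr: float = float("nan")

    @property
    def k(self) -> int:
        return len(self.shared)


def cis_targets(
    lncrnas: Sequence[TranscriptModel],
    genes: Sequence[GeneModel],
    window: int = 100_000,
) -> list[CisPair]:
    """Protein-coding genes within ``window`` bp (inclusive) of each lncRNA span."""
    pairs = []
    for lnc in lncrnas:
        span = lnc.span
        for g in genes:
            if g.biotype != "protein_coding" or g.chrom != span.chrom:
                continue
            d = span.gap_to(g.span)
            if d <= window:
                pairs.append(CisPair(lnc.transcript_id, g.gene_id, d))
    return pairs


@dataclass
class ScanParams:
    mismatch: float = 1.0
    gu_wobble: float = 0.5
    bulge: float = 1.0
    seed_start: int = 2  # doubled-penalty region, miRNA positions (1-based)
    seed_end: int = 13
    cutoff: float = 4.0


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}


def _penalty_matrix(params: ScanParams) -> np.ndarray:
    """P[m, t]: penalty for pairing miRNA base m with target base t.

    Row/column order A, C, G, U plus a fifth target column for N (infinite,
    so N-containing alignments never qualify).
    """
    P = np.full((4, 5), params.mismatch)
    for i, m in enumerate("ACGU"):
        for j, t in enumerate("ACGU"):
            if _RNA_COMPLEMENT[m] == t:
                P[i, j] = 0.0
            elif (m == "G" and t == "U") or (m == "U" and t == "G"):
                P[i, j] = params.gu_wobble
    P[:, 4] = np.inf
    return P


def mirna_target_scan(
    mirna: MiRNA, target_id: str, transcript_seq: str, params: ScanParams | None = None
) -> list[TargetHit]:
    """All target sites for one miRNA on one transcript with penalty <= cutoff.

    At each transcript position the ungapped alignment and every
    single-nucleotide target-bulge alignment (at most one bulge per site)
    are scored; the best variant is reported when it passes the cutoff.

    A site occupies the miRNA length in target nucleotides (one more with a
    bulge); the miRNA 5' end pairs with the 3' end of the site, so miRNA
    position p (1-based from the 5' end) faces transcript index
    ``start + L - p`` (ungapped). A bulge after miRNA position j leaves one
    target base unpaired and shifts the 5'-proximal pairs outward by one.
    """
    params = params or ScanParams()
    mseq = mirna.sequence
    L = len(mseq)
    t = transcript_seq.upper().replace("T", "U")
    if set(t) - set("ACGUN"):
        raise ValueError(f"{target_id}: non-nucleotide characters")
    n = len(t)
    if n < L:
        return []
    P = _penalty_matrix(params)
    weights = np.array(
        [2.0 if params.seed_start <= p <= params.seed_end else 1.0 for p in range(1, L + 1)]
    )
    midx = np.array([_BASE_INDEX[c] for c in mseq])
    tidx = np.array([_BASE_INDEX[c] for c in t])
    Pw = P[midx] * weights[:, None]  # (L, 5): row p-1 = weighted penalties per target base

    n_sites = n - L + 1
    # B[p-1, i]: ungapped term, miRNA pos p vs transcript index i + L - p
    # A[p-1, i]: bulged-5'-side term, miRNA pos p vs transcript index i + L - p + 1
    B = np.empty((L, n_sites))
    A = np.empty((L, n_sites))
    for p in range(1, L + 1):
        B[p - 1] = Pw[p - 1, tidx[L - p : L - p + n_sites]]
        shifted = tidx[L - p + 1 : L - p + 1 + n_sites]
        A[p - 1, : len(shifted)] = Pw[p - 1, shifted]
        A[p - 1, len(shifted) :] = np.inf  # bulge would run off the 3' end
    score_nb = B.sum(axis=0)
    best = score_nb.copy()
    best_bulge = np.full(n_sites, -1)
    prefA = np.cumsum(A, axis=0)
    prefB = np.cumsum(B, axis=0)
    totB = prefB[-1]
    for j in range(1, L):  # bulge after miRNA position j
        bulge_pen = params.bulge * (2.0 if params.seed_start <= j <= params.seed_end else 1.0)
        with np.errstate(invalid="ignore"):
            s = prefA[j - 1] + (totB - prefB[j - 1]) + bulge_pen
        s[n_sites - 1] = np.inf  # bulged site needs L + 1 target bases
        improved = s < best
        best[improved] = s[improved]
        best_bulge[improved] = j
    hits = []
    for i in np.nonzero(best <= params.cutoff)[0]:
        bp = int(best_bulge[i])
        hits.append(
            TargetHit(mirna.mirna_id, target_id, int(i), float(best[i]), bp if bp > 0 else None)
        )
    return hits


def scan_all(
    mirnas: Sequence[MiRNA],
    transcripts: Mapping[str, str],
    params: ScanParams | None = None,
) -> pd.DataFrame:
    """Scan every miRNA against every transcript; tidy hits table."""
    rows = []
    for m in mirnas:
        for tid, seq in transcripts.items():
            for h in mirna_target_scan(m, tid, seq, params):
                rows.append((h.mirna_id, h.target_id, h.start, h.penalty))
    return pd.DataFrame(rows, columns=["mirna_id", "target_id", "start", "penalty"])


def hypergeom_upper(M: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k), X ~ Hypergeometric(M population, K marked, n drawn)."""
    if not (0 <= k <= min(K, n) <= M) or K > M or n > M:
        raise ValueError(f"inconsistent hypergeometric arguments M={M} K={K} n={n} k={k}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, M, K, n))


def targets_by(hits: pd.DataFrame) -> dict[str, set[str]]:
    """target_id -> set of miRNA ids hitting it."""
    out: dict[str, set[str]] = {}
    for mirna_id, target_id in zip(hits["mirna_id"], hits["target_id"]):
        out.setdefault(target_id, set()).add(mirna_id)
    return out


def cerna_pairs(
    lnc_targets: Mapping[str, set[str]],
    mrna_targets: Mapping[str, set[str]],
    universe: int,
    min_shared: int = 6,
    p_max: float = 0.01,
    fdr_max: float = 0.01,
) -> list[CeRNAPair]:
    """Shared-miRNA hypergeometric pairing of lncRNAs and mRNAs.

    Pairs sharing more than 5 miRNAs (k >= ``min_shared``) are tested; BH
    correction runs across all tested pairs and survivors need p < ``p_max``
    and FDR < ``fdr_max``. miRNA ids count as distinct even when family
    members share one mature sequence.
    """
    if universe <= 0:
        raise ValueError("empty miRNA universe")
    tested: list[CeRNAPair] = []
    for lnc_id in sorted(lnc_targets):
        lset = lnc_targets[lnc_id]
        for mrna_id in sorted(mrna_targets):
            mset = mrna_targets[mrna_id]
            shared = lset & mset
            if len(shared) < min_shared:
                continue
            p = hypergeom_upper(universe, len(mset), len(lset), len(shared))
            tested.append(
                CeRNAPair(lnc_id, mrna_id, frozenset(shared), len(lset), len(mset), universe, p)
            )
    if not tested:
        return []
    fdrs = bh_fdr([pair.pvalue for pair in tested])
    out = []
    for pair, fdr in zip(tested, fdrs):
        pair.fdr = float(fdr)
        if pair.pvalue < p_max and pair.fdr < fdr_max:
            out.append(pair)
    return out


def negative_regulation_filter(
    pairs: Sequence[CeRNAPair],
    de_calls: Mapping[str, str],
    min_shared: int = 6,
) -> list[CeRNAPair]:
    """Keep pairs whose lncRNA and mRNA move together while their shared
    miRNAs move the opposite way.

    Shared sets are pruned to significant, opposite-signed miRNAs and the
    shared-count gate is re-checked afterwards.
    """
    kept = []
    for pair in pairs:
        for fid in (pair.lnc_id, pair.mrna_id, *sorted(pair.shared)):
            if fid not in de_calls:
                raise KeyError(f"no DE call for feature {fid!r}")
        lnc_call = de_calls[pair.lnc_id]
        mrna_call = de_calls[pair.mrna_id]
        if lnc_call == "ns" or lnc_call != mrna_call:
            continue
        anti = "down" if lnc_call == "up" else "up"
        pruned = frozenset(m for m in pair.shared if de_calls[m] == anti)
        if len(pruned) < min_shared:
            continue
        kept.append(
            CeRNAPair(
                pair.lnc_id,
                pair.mrna_id,
                pruned,
                pair.n_lnc,
                pair.n_mrna,
                pair.universe,
                pair.pvalue,
                pair.fdr,
            )
        )
    return kept


# ---------------------------------------------------------------------------
# Network assembly and export

NODE_KINDS = ("lncRNA", "miRNA", "mRNA")
EDGE_KINDS = ("miRNA-lncRNA", "miRNA-mRNA", "lncRNA-mRNA")


def build_network(
    pairs: Sequence[CeRNAPair], de_calls: Mapping[str, str] | None = None
) -> nx.Graph:
    """Tripartite ceRNA graph: sponge edges plus shared-miRNA targeting edges."""
    g = nx.Graph()
    calls = de_calls or {}
    for pair in pairs:
        g.add_node(pair.lnc_id, kind="lncRNA", regulation=calls.get(pair.lnc_id, "na"))
        g.add_node(pair.mrna_id, kind="mRNA", regulation=calls.get(pair.mrna_id, "na"))
        g.add_edge(pair.lnc_id, pair.mrna_id, kind="lncRNA-mRNA", pvalue=pair.pvalue)
        for m in sorted(pair.shared):
            g.add_node(m, kind="miRNA", regulation=calls.get(m, "na"))
            g.add_edge(m, pair.lnc_id, kind="miRNA-lncRNA")
            g.add_edge(m, pair.mrna_id, kind="miRNA-mRNA")
    return g


def node_counts(g: nx.Graph) -> dict[str, int]:
    out = {k: 0 for k in NODE_KINDS}
    for _, data in g.nodes(data=True):
        out[data["kind"]] += 1
    return out


def export_network(g: nx.Graph, path: str | Path, fmt: str) -> None:
    """Write the network as SIF, GraphML or a node-attribute TSV (sorted)."""
    path = Path(path)
    if fmt == "sif":
        lines = []
        for a, b, data in g.edges(data=True):
            x, y = sorted((a, b))
            lines.append(f"{x}\t{data['kind']}\t{y}")
        path.write_text("\n".join(sorted(lines)) + ("\n" if lines else ""))
    elif fmt == "graphml":
        h = nx.Graph()
        h.add_nodes_from(sorted(g.nodes(data=True)))
        h.add_edges_from(sorted((min(a, b), max(a, b), d) for a, b, d in g.edges(data=True)))
        nx.write_graphml(h, str(path))
    elif fmt == "tsv":
        rows = [
            {"node": n, "kind": d["kind"], "regulation": d.get("regulation", "na")}
            for n, d in sorted(g.nodes(data=True))
        ]
        pd.DataFrame(rows, columns=["node", "kind", "regulation"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_sif(path: str | Path) -> nx.Graph:
    g = nx.Graph()
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        a, kind, b = line.split("\t")
        g.add_edge(a, b, kind=kind)
    return g


def annotate_targets(
    pairs: Iterable[CisPair] | Iterable[CeRNAPair],
    annotation: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Left-join gene annotation terms onto pairs; return (table, term counts).

    ``annotation`` needs columns ``gene_id`` and ``term``; genes without an
    entry stay in the table with a missing term.
    """
    if not {"gene_id", "term"}.issubset(annotation.columns):
        raise ValueError("annotation table needs columns gene_id, term")
    rows = []
    for p in pairs:
        gene = p.gene_id if isinstance(p, CisPair) else p.mrna_id
        other = p.lnc_id
        rows.append({"lnc_id": other, "gene_id": gene})
    table = pd.DataFrame(rows, columns=["lnc_id", "gene_id"])
    joined = table.merge(annotation, on="gene_id", how="left")
    counts = joined["term"].value_counts()
    return joined, counts
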