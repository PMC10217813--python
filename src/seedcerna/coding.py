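"""Coding-potential scoring for transcript sequences.

Four independent verdicts are computed per transcript — an ORF-length rule,
the Fickett TESTCODE statistic, an in-frame hexamer log-likelihood ratio,
and a logistic combiner over the three features — and a transcript is called
non-coding only when *all* verdicts agree (intersection semantics), mirroring
the consensus logic used when multiple coding-potential tools are combined.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

STOP_CODONS = ("TAA", "TAG", "TGA")
_NT = "ACGT"

# Fickett (1982) TESTCODE lookup tables, as propagated by the CPAT lineage
# of tools.  Position parameter = max/(min+1) of the three codon-position
# counts of a base; content parameter = base fraction.  Each parameter is
# binned against the threshold list (first threshold <= value wins) and the
# looked-up probability is weighted and summed over the eight terms.
_POSITION_PROB = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_PARA = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]
_CONTENT_PROB = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29],
    "T": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_PARA = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0]


def _clean(seq: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return s


@dataclass(frozen=True)
class OrfHit:
    """Longest complete open reading frame on the sense strand."""

    length: int  # nt, stop codon included; 0 when no complete ORF
    frame: int  # 0, 1 or 2 (undefined content when length == 0)
    offset: int  # 0-based start of the ATG


def find_longest_orf(seq: str) -> OrfHit:
    """Longest ATG..stop span (stop included) on the sense strand.

    Ties are broken by the smaller start offset, then lower frame index.
    Returns length 0 when no in-frame stop completes any ORF.
    """
    s = _clean(seq)
    best = OrfHit(0, 0, 0)
    for frame in range(3):
        open_atg = -1
        for i in range(frame, len(s) - 2, 3):
            codon = s[i : i + 3]
            if open_atg < 0 and codon == "ATG":
                open_atg = i
            elif open_atg >= 0 and codon in STOP_CODONS:
                length = i + 3 - open_atg
                if length > best.length or (
                    length == best.length
                    and best.length > 0
                    and (open_atg, frame) < (best.offset, best.frame)
                ):
                    best = OrfHit(length, frame, open_atg)
                open_atg = -1
    return best


def fickett_score(seq: str) -> float:
    """Fickett TESTCODE statistic (unitless, roughly 0.2-1.6).

    Higher values indicate codon-position base asymmetry and composition
    typical of protein-coding sequence.
    """
    s = _clean(seq).replace("N", "")
    if not s:
        return 0.0
    total = len(s)
    score = 0.0
    for base in _NT:
        counts = [s[p::3].count(base) for p in range(3)]
        position = max(counts) / (min(counts) + 1)
        content = s.count(base) / total
        score += _lookup(position, _POSITION_PARA, _POSITION_PROB[base]) * _POSITION_WEIGHT[base]
        score += _lookup(content, _CONTENT_PARA, _CONTENT_PROB[base]) * _CONTENT_WEIGHT[base]
    return score


def _lookup(value: float, thresholds: Sequence[float], probs: Sequence[float]) -> float:
    for thr, p in zip(thresholds, probs):
        if value >= thr:
            return p
    return probs[-1]


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving exact dinucleotide counts (Altschul-Erikson).

    Builds the dinucleotide transition multigraph, fixes a random last-exit
    edge per vertex forming a tree into the terminal base, shuffles the
    remaining edges, and reads off an Eulerian walk.
    """
    s = _clean(seq)
    if len(s) < 3:
        return s
    edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    vertices = list(edges)
    last = s[-1]
    for _ in range(10_000):
        last_exit = {}
        for v in vertices:
            if v == last:
                continue
            last_exit[v] = edges[v][int(rng.integers(0, len(edges[v])))]
        if _reaches_last(last_exit, last):
            break
    else:  # pragma: no cover - astronomically unlikely for nucleotide data
        raise RuntimeError("failed to sample a valid Eulerian ordering")
    shuffled: dict[str, list[str]] = {}
    for v in vertices:
        pool = list(edges[v])
        if v in last_exit:
            pool.remove(last_exit[v])
        order = list(rng.permutation(len(pool)))
        pool = [pool[i] for i in order]
        if v in last_exit:
            pool.append(last_exit[v])
        shuffled[v] = pool
    out = [s[0]]
    ptr = {v: 0 for v in vertices}
    cur = s[0]
    for _ in range(len(s) - 1):
        nxt = shuffled[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def _reaches_last(last_exit: Mapping[str, str], last: str) -> bool:
    for v in last_exit:
        seen = {v}
        cur = v
        while cur != last and cur in last_exit:
            cur = last_exit[cur]
            if cur in seen:
                return False
            seen.add(cur)
        if cur != last:
            return False
    return True


# ---------------------------------------------------------------------------
# Hexamer usage

def all_hexamers() -> list[str]:
    return ["".join(p) for p in itertools.product(_NT, repeat=6)]


def train_hexamer_table(
    coding_seqs: Iterable[str],
    noncoding_seqs: Iterable[str],
    pseudocount: float = 1.0,
) -> dict[str, float]:
    """Per-hexamer log2(coding frequency / non-coding frequency), in bits.

    Coding sequences are counted in the frame of their longest ORF,
    non-coding sequences in frame 0; both step by 3 nt so only in-frame
    (codon-pair) hexamers contribute.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    hexamers = all_hexamers()
    idx = {h: i for i, h in enumerate(hexamers)}
    counts = np.full((2, len(hexamers)), pseudocount)
    for row, seqs in ((0, coding_seqs), (1, noncoding_seqs)):
        for seq in seqs:
            s = _clean(seq)
            frame = find_longest_orf(s).frame if row == 0 else 0
            for i in range(frame, len(s) - 5, 3):
                j = idx.get(s[i : i + 6])
                if j is not None:
                    counts[row, j] += 1
    freq = counts / counts.sum(axis=1, keepdims=True)
    ratios = np.log2(freq[0] / freq[1])
    return dict(zip(hexamers, ratios))


def hexamer_score(seq: str, table: Mapping[str, float]) -> float:
    """Mean log2 likelihood ratio (bits/hexamer) over in-frame hexamers.

    The frame is that of the longest ORF (frame 0 when the sequence has no
    complete ORF); hexamers step by 3. Returns 0.0 when the sequence yields
    no scoreable hexamer.
    """
    if not table:
        raise ValueError("empty hexamer table")
    s = _clean(seq)
    frame = find_longest_orf(s).frame
    vals = []
    for i in range(frame, len(s) - 5, 3):
        hexamer = s[i : i + 6]
        if hexamer in table:
            vals.append(table[hexamer])
    return float(np.mean(vals)) if vals else 0.0


# ---------------------------------------------------------------------------
# Combiner and consensus

class CodingCombiner:
    """Logistic model over (orf_len, fickett, hexamer) coding features."""

    def __init__(self, threshold: float = 0.5):
        self.threshold = threshold
        self._model: LogisticRegression | None = None

    @staticmethod
    def features(seq: str, table: Mapping[str, float]) -> np.ndarray:
        return np.array(
            [find_longest_orf(seq).length, fickett_score(seq), hexamer_score(seq, table)]
        )

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CodingCombiner":
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("combiner needs both coding and non-coding examples")
        self._model = LogisticRegression(max_iter=2000)
        self._model.fit(np.asarray(X, dtype=float), y)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """P(coding) per row."""
        if self._model is None:
            raise RuntimeError("combiner not fitted")
        return self._model.predict_proba(np.asarray(X, dtype=float))[:, 1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X) >= self.threshold


def train_combiner(X: np.ndarray, y: np.ndarray, threshold: float = 0.5) -> CodingCombiner:
    """Fit the logistic combiner on labelled feature rows (1 = coding)."""
    return CodingCombiner(threshold).fit(X, y)


def consensus_noncoding(verdicts: Sequence[bool]) -> bool:
    """True iff every scorer calls the transcript non-coding (intersection)."""
    if len(verdicts) == 0:
        raise ValueError("no verdicts supplied")
    return all(bool(v) for v in verdicts)


@dataclass
class CodingPotential:
    """Combined coding-potential summary for one transcript."""

    orf_len: int
    fickett: float
    hexamer: float
    combined: float
    verdicts: tuple[bool, ...]  # True = non-coding, per scorer

    def __post_init__(self) -> None:
        if self.orf_len < 0 or (self.orf_len > 0 and self.orf_len % 3 != 0):
            raise ValueError("orf_len must be >= 0 and a codon multiple when > 0")

    @property
    def consensus_noncoding(self) -> bool:
        return consensus_noncoding(self.verdicts)


def score_transcript(
    seq: str,
    table: Mapping[str, float],
    combiner: CodingCombiner,
    orf_cutoff: int = 300,
    fickett_cutoff: float = 0.95,
    hexamer_cutoff: float = 0.0,
) -> CodingPotential:
    """Score one transcript with the four in-repo verdicts.

    Each verdict is True when that scorer deems the transcript non-coding:
    longest ORF < ``orf_cutoff`` nt (this rule also stands in for a protein
    domain search: transcripts without a substantial ORF cannot carry one),
    Fickett < ``fickett_cutoff``, hexamer bias < ``hexamer_cutoff`` bits,
    combiner P(coding) < its threshold.
    """
    orf = find_longest_orf(seq)
    fick = fickett_score(seq)
    hexa = hexamer_score(seq, table)
    prob = float(combiner.predict_proba(np.array([[orf.length, fick, hexa]]))[0])
    verdicts = (
        orf.length < orf_cutoff,
        fick < fickett_cutoff,
        hexa < hexamer_cutoff,
        prob < combiner.threshold,
    )
    return CodingPotential(orf.length, fick, hexa, prob, verdicts)
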