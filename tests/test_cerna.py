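"""cis windows, miRNA target scan, hypergeometric pairing and the network."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from seedcerna.cerna import (
    CeRNAPair,
    CisPair,
    MiRNA,
    ScanParams,
    annotate_targets,
    build_network,
    cerna_pairs,
    cis_targets,
    export_network,
    hypergeom_upper,
    mirna_target_scan,
    negative_regulation_filter,
    node_counts,
    read_sif,
    targets_by,
)
from seedcerna.models import GeneModel, GenomicInterval, TranscriptModel
from seedcerna.simulate import reverse_complement_dna


def tx(tid, start, end, strand="+"):
    return TranscriptModel(tid, tid, (GenomicInterval("chr1", start, end, strand),))


def gene(gid, start, end, strand="+"):
    return GeneModel(gid, [tx(f"{gid}.t", start, end, strand)], "protein_coding")


class TestCisTargets:
    @pytest.mark.parametrize(
        "gap,paired", [(99_999, True), (100_000, True), (100_001, False)]
    )
    def test_window_boundary_inclusive(self, gap, paired):
        lnc = tx("l", 0, 500)
        g = gene("g", 500 + gap, 500 + gap + 1000)
        pairs = cis_targets([lnc], [g])
        assert bool(pairs) is paired
        if paired:
            assert pairs[0].distance == gap

    def test_overlap_distance_zero_and_strand_agnostic(self):
        lnc = tx("l", 100, 700, "+")
        g = gene("g", 600, 2000, "-")
        pairs = cis_targets([lnc], [g])
        assert pairs[0].distance == 0


MIRNA = MiRNA("mir", "fam", "UGACAGAAGAGAGUGAGCACA")  # 21 nt


def scan_oracle(mirna, target_dna, params=None):
    """Exhaustive enumeration of ungapped and single-bulge alignments."""
    params = params or ScanParams()
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    m = mirna.sequence
    L = len(m)
    t = target_dna.upper().replace("T", "U")
    out = {}
    for start in range(len(t) - L + 1):
        variants = []

        def pair_pen(mb, tb):
            if comp[mb] == tb:
                return 0.0
            if (mb == "G" and tb == "U") or (mb == "U" and tb == "G"):
                return params.gu_wobble
            return params.mismatch

        # ungapped: miRNA position p faces t[start + L - p]
        s = 0.0
        for p in range(1, L + 1):
            pen = pair_pen(m[p - 1], t[start + L - p])
            if params.seed_start <= p <= params.seed_end:
                pen *= 2
            s += pen
        variants.append(s)
        # one target bulge after miRNA position j
        if start + L < len(t):
            for j in range(1, L):
                s = params.bulge * (2 if params.seed_start <= j <= params.seed_end else 1)
                for p in range(1, L + 1):
                    ti = start + L - p + (1 if p <= j else 0)
                    pen = pair_pen(m[p - 1], t[ti])
                    if params.seed_start <= p <= params.seed_end:
                        pen *= 2
                    s += pen
                variants.append(s)
        best = min(variants)
        if best <= params.cutoff:
            out[start] = best
    return out


class TestTargetScan:
    def test_perfect_site_scores_zero(self):
        site = reverse_complement_dna(MIRNA.sequence)
        hits = mirna_target_scan(MIRNA, "t", "ACGT" * 10 + site + "ACGT" * 10)
        exact = {h.start: h.penalty for h in hits}
        assert exact[40] == 0.0

    def test_single_mismatch_in_doubled_region_scores_two(self):
        site = list(reverse_complement_dna(MIRNA.sequence))
        site[21 - 10] = {"A": "C", "C": "A", "G": "A", "T": "C"}[site[21 - 10]]
        hits = mirna_target_scan(MIRNA, "t", "AAAA" + "".join(site) + "AAAA")
        assert {h.start: h.penalty for h in hits}[4] == 2.0

    def test_gu_wobble_outside_doubled_region_scores_half(self):
        m = MiRNA("m", "f", "UGACAGAAGAGAGUGAGGACA")  # G at position 18
        site = list(reverse_complement_dna(m.sequence))
        site[21 - 18] = "T"  # G:U instead of G:C
        hits = mirna_target_scan(m, "t", "AAAA" + "".join(site) + "AAAA")
        assert {h.start: h.penalty for h in hits}[4] == 0.5

    def test_mirna_longer_than_transcript_gives_no_hits(self):
        assert mirna_target_scan(MIRNA, "t", "ACGT") == []

    def test_matches_exhaustive_oracle_on_planted_and_random_sequences(self):
        rng = np.random.default_rng(23)
        site = reverse_complement_dna(MIRNA.sequence)
        for trial in range(30):
            n = int(rng.integers(40, 90))
            t = list(rng.choice(list("ACGT"), size=n))
            if trial % 2 == 0:  # plant a (possibly mutated) site
                pos = int(rng.integers(0, n - len(site)))
                mutated = list(site)
                for _ in range(int(rng.integers(0, 4))):
                    k = int(rng.integers(0, len(site)))
                    mutated[k] = "ACGT"[int(rng.integers(0, 4))]
                t[pos : pos + len(site)] = mutated
            seq = "".join(t)
            got = {h.start: h.penalty for h in mirna_target_scan(MIRNA, "t", seq)}
            assert got == pytest.approx(scan_oracle(MIRNA, seq))


class TestHypergeometric:
    def test_worked_example(self):
        assert hypergeom_upper(10, 4, 5, 3) == pytest.approx(66 / 252, abs=1e-12)

    def test_certain_events(self):
        assert hypergeom_upper(10, 4, 5, 0) == 1.0
        assert hypergeom_upper(5, 5, 3, 3) == pytest.approx(1.0, abs=1e-12)

    def test_inconsistent_arguments_error(self):
        with pytest.raises(ValueError):
            hypergeom_upper(5, 6, 3, 1)
        with pytest.raises(ValueError):
            hypergeom_upper(10, 4, 5, 5)

    def test_monotone_nonincreasing_in_k(self):
        for M, K, n in [(20, 8, 10), (25, 12, 6)]:
            ps = [hypergeom_upper(M, K, n, k) for k in range(0, min(K, n) + 1)]
            assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_exact_agreement_with_enumeration_small_universe(self):
        for M in range(1, 13):
            for K in range(M + 1):
                for n in range(M + 1):
                    for k in range(min(K, n) + 1):
                        num = sum(
                            math.comb(K, i) * math.comb(M - K, n - i)
                            for i in range(k, min(K, n) + 1)
                        )
                        expect = num / math.comb(M, n)
                        assert hypergeom_upper(M, K, n, k) == pytest.approx(
                            expect, abs=1e-12
                        ), (M, K, n, k)


class TestCeRNAPairs:
    def test_shared_gate_is_strict_more_than_five(self):
        lnc = {"L": {f"m{i}" for i in range(5)}}
        mrna = {"G": {f"m{i}" for i in range(5)}}
        assert cerna_pairs(lnc, mrna, universe=30) == []

    def test_pair_with_weak_p_is_excluded(self):
        # k = 6 but both target sets nearly exhaust the universe
        lnc = {"L": {f"m{i}" for i in range(7)}}
        mrna = {"G": {f"m{i}" for i in range(6)} | {"m8"}}
        pairs = cerna_pairs(lnc, mrna, universe=8, p_max=0.01)
        assert pairs == []

    def test_enriched_pair_survives_with_statistics(self):
        shared = {f"m{i}" for i in range(6)}
        pairs = cerna_pairs({"L": shared}, {"G": shared}, universe=30)
        (p,) = pairs
        assert p.k == 6 and p.shared == frozenset(shared)
        assert p.pvalue == pytest.approx(1 / math.comb(30, 6))
        assert p.fdr == p.pvalue

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            cerna_pairs({}, {}, universe=0)


class TestNegativeRegulation:
    def make_pair(self, shared):
        return CeRNAPair("L", "G", frozenset(shared), 7, 7, 30, 1e-5, 1e-5)

    def test_concordant_pair_with_opposing_mirnas_kept(self):
        shared = [f"m{i}" for i in range(6)]
        calls = {"L": "down", "G": "down", **{m: "up" for m in shared}}
        kept = negative_regulation_filter([self.make_pair(shared)], calls)
        assert len(kept) == 1 and kept[0].k == 6

    def test_discordant_lnc_mrna_dropped(self):
        shared = [f"m{i}" for i in range(6)]
        calls = {"L": "up", "G": "down", **{m: "up" for m in shared}}
        assert negative_regulation_filter([self.make_pair(shared)], calls) == []

    def test_pruning_below_gate_drops_pair(self):
        shared = [f"m{i}" for i in range(6)]
        calls = {"L": "down", "G": "down", **{m: "up" for m in shared[:5]}, "m5": "ns"}
        assert negative_regulation_filter([self.make_pair(shared)], calls) == []

    def test_missing_call_errors_with_feature_name(self):
        shared = [f"m{i}" for i in range(6)]
        calls = {"L": "down", "G": "down", **{m: "up" for m in shared[:-1]}}
        with pytest.raises(KeyError, match="m5"):
            negative_regulation_filter([self.make_pair(shared)], calls)


class TestNetwork:
    def planted(self):
        shared = frozenset(f"m{i}" for i in range(6))
        return [
            CeRNAPair("L", f"G{j}", shared, 6, 6, 30, 1e-6, 1e-6) for j in range(15)
        ]

    def test_planted_module_node_counts(self):
        g = build_network(self.planted())
        assert node_counts(g) == {"lncRNA": 1, "miRNA": 6, "mRNA": 15}

    def test_empty_pairs_give_valid_empty_exports(self, tmp_path):
        g = build_network([])
        for fmt, name in [("sif", "n.sif"), ("graphml", "n.graphml"), ("tsv", "n.tsv")]:
            export_network(g, tmp_path / name, fmt)
        assert (tmp_path / "n.sif").read_text() == ""
        assert "node\tkind" in (tmp_path / "n.tsv").read_text()

    def test_sif_round_trip_preserves_nodes_and_edges(self, tmp_path):
        g = build_network(self.planted())
        export_network(g, tmp_path / "n.sif", "sif")
        back = read_sif(tmp_path / "n.sif")
        assert set(back.nodes) == set(g.nodes)
        assert {frozenset(e) for e in back.edges} == {frozenset(e) for e in g.edges}

    def test_graphml_round_trip(self, tmp_path):
        g = build_network(self.planted())
        export_network(g, tmp_path / "n.graphml", "graphml")
        back = nx.read_graphml(tmp_path / "n.graphml")
        assert set(back.nodes) == set(g.nodes)
        assert back.number_of_edges() == g.number_of_edges()

    def test_unknown_format_errors(self, tmp_path):
        with pytest.raises(ValueError):
            export_network(build_network([]), tmp_path / "x", "dot")

    def test_network_is_tripartite_by_edge_kind(self):
        g = build_network(self.planted())
        for a, b, data in g.edges(data=True):
            kinds = {g.nodes[a]["kind"], g.nodes[b]["kind"]}
            expect = set(data["kind"].split("-"))
            assert kinds == expect


class TestAnnotateTargets:
    def test_term_counts(self):
        pairs = [CisPair("L", g, 0) for g in ("g1", "g2", "g3")]
        ann = pd.DataFrame(
            {"gene_id": ["g1", "g2", "g3"], "term": ["lipid", "lipid", "transport"]}
        )
        joined, counts = annotate_targets(pairs, ann)
        assert counts["lipid"] == 2
        assert counts.sum() == len(joined.dropna())

    def test_empty_annotation(self):
        pairs = [CisPair("L", "g1", 0)]
        ann = pd.DataFrame({"gene_id": [], "term": []})
        joined, counts = annotate_targets(pairs, ann)
        assert joined["term"].isna().all() and len(counts) == 0

    def test_malformed_table_errors(self):
        with pytest.raises(ValueError):
            annotate_targets([], pd.DataFrame({"gene": []}))


def test_targets_by_groups_hits():
    hits = pd.DataFrame(
        {"mirna_id": ["m1", "m2", "m1"], "target_id": ["t1", "t1", "t2"]}
    )
    assert targets_by(hits) == {"t1": {"m1", "m2"}, "t2": {"m1"}}
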