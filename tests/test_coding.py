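"""Coding-potential scorers against independent oracles and known examples."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedcerna.coding import (
    CodingCombiner,
    consensus_noncoding,
    dinucleotide_shuffle,
    fickett_score,
    find_longest_orf,
    hexamer_score,
    train_combiner,
    train_hexamer_table,
)

# ---------------------------------------------------------------------------
# ORF finder


def orf_oracle(seq):
    """Brute force: every ATG, first downstream in-frame stop."""
    s = seq.upper().replace("U", "T")
    best = 0
    stops = {"TAA", "TAG", "TGA"}
    for i in range(len(s) - 2):
        if s[i : i + 3] != "ATG":
            continue
        for j in range(i + 3, len(s) - 2, 3):
            if s[j : j + 3] in stops:
                best = max(best, j + 3 - i)
                break
    return best


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("ATGAAATAG", 9),
        ("ATGAAA", 0),  # no stop, no complete ORF
        ("CCATGTAGC", 6),
        ("", 0),
        ("ATGATGAAATAA", 12),  # nested start: earliest ATG wins
        ("atgaaaTAG", 9),  # case-insensitive
        ("AUGAAAUAG", 9),  # RNA alphabet
    ],
)
def test_longest_orf_examples(seq, expected):
    assert find_longest_orf(seq).length == expected


def test_longest_orf_matches_bruteforce_on_random_sequences():
    rng = np.random.default_rng(5)
    for _ in range(200):
        n = int(rng.integers(0, 400))
        seq = "".join(rng.choice(list("ACGT"), size=n))
        assert find_longest_orf(seq).length == orf_oracle(seq), seq


def test_orf_length_is_codon_multiple_and_within_bounds():
    rng = np.random.default_rng(6)
    for _ in range(100):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        hit = find_longest_orf(seq)
        assert hit.length % 3 == 0
        assert 0 <= hit.length <= 300


def test_orf_rejects_bad_alphabet():
    with pytest.raises(ValueError):
        find_longest_orf("ATGXXXTAG")


# ---------------------------------------------------------------------------
# Fickett TESTCODE — independent oracle carries its own copy of the
# published lookup tables and bins by explicit iteration.

_ORACLE_POS = {
    "A": ([1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0],
          [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22], 0.26),
    "C": ([1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0],
          [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23], 0.18),
    "G": ([1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0],
          [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08], 0.31),
    "T": ([1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0],
          [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09], 0.33),
}
_ORACLE_CONTENT = {
    "A": ([0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0],
          [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21], 0.11),
    "C": ([0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0],
          [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31], 0.12),
    "G": ([0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0],
          [0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29], 0.15),
    "T": ([0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0],
          [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58], 0.14),
}


def fickett_oracle(seq):
    s = seq.upper()
    total = len(s)
    out = 0.0
    for base in "ACGT":
        c0 = s[0::3].count(base)
        c1 = s[1::3].count(base)
        c2 = s[2::3].count(base)
        position = max(c0, c1, c2) / (min(c0, c1, c2) + 1)
        content = s.count(base) / total
        thr, probs, w = _ORACLE_POS[base]
        val = probs[-1]
        for t, p in zip(thr, probs):
            if position >= t:
                val = p
                break
        out += val * w
        thr, probs, w = _ORACLE_CONTENT[base]
        val = probs[-1]
        for t, p in zip(thr, probs):
            if content >= t:
                val = p
                break
        out += val * w
    return out


def test_fickett_matches_oracle_on_fixed_and_random_sequences():
    rng = np.random.default_rng(11)
    fixed = "".join(rng.choice(list("ACGT"), size=300))
    assert fickett_score(fixed) == pytest.approx(fickett_oracle(fixed), abs=1e-12)
    for _ in range(50):
        n = int(rng.integers(30, 600))
        s = "".join(rng.choice(list("ACGT"), size=n))
        assert fickett_score(s) == pytest.approx(fickett_oracle(s), abs=1e-12)


def test_fickett_deterministic_and_rejects_bad_input():
    s = "ACGT" * 60
    assert fickett_score(s) == fickett_score(s)
    with pytest.raises(ValueError):
        fickett_score("ACGT$")


def test_fickett_separates_coding_from_dinucleotide_shuffles(dataset):
    """Coding ORFs should out-score composition-matched shuffles on average."""
    rng = np.random.default_rng(1)
    truth = dataset.truth.table
    coding = [
        dataset.sequences[t] for t in truth.index[truth["coding"] == "coding"][:50]
    ]
    real = np.mean([fickett_score(s) for s in coding])
    shuf = np.mean([fickett_score(dinucleotide_shuffle(s, rng)) for s in coding])
    assert real > shuf


# ---------------------------------------------------------------------------
# Hexamer score


def test_hexamer_equal_tables_score_zero():
    table = {h: 0.0 for h in ("ACGTAC", "AAAAAA")}
    flat = dict.fromkeys(
        ["".join(p) for p in __import__("itertools").product("ACGT", repeat=6)], 0.0
    )
    assert hexamer_score("ACGTACGTACGTACGT", flat) == 0.0


def test_hexamer_single_entry_example():
    # 12 x A: in-frame hexamers at offsets 0, 3, 6, each worth 1 bit
    assert hexamer_score("A" * 12, {"AAAAAA": np.log2(0.02 / 0.01)}) == pytest.approx(1.0)


def test_hexamer_invariant_to_short_trailing_bases():
    table = train_hexamer_table(["ATG" + "GCT" * 40 + "TAA"], ["ATATATAT" * 20])
    s = "ATG" + "GCTGAAGCT" * 10 + "TAA"
    base = hexamer_score(s, table)
    assert hexamer_score(s + "GC", table) == pytest.approx(base)


def test_hexamer_empty_table_errors():
    with pytest.raises(ValueError):
        hexamer_score("ACGTACGTACGT", {})


def test_hexamer_separates_generated_coding_from_noncoding(dataset):
    truth = dataset.truth.table
    coding = [dataset.sequences[t] for t in truth.index[truth["coding"] == "coding"]]
    noncoding = [dataset.sequences[t] for t in truth.index[truth["coding"] == "noncoding"]]
    table = train_hexamer_table(coding[:40], noncoding[:10])
    held_coding = [hexamer_score(s, table) for s in coding[40:60]]
    held_non = [hexamer_score(s, table) for s in noncoding[10:]]
    assert min(held_coding) > max(held_non)


# ---------------------------------------------------------------------------
# Combiner and consensus


def _features(seqs, table):
    return np.array(
        [[find_longest_orf(s).length, fickett_score(s), hexamer_score(s, table)] for s in seqs]
    )


def test_combiner_recovers_labels_on_synthetic_transcripts():
    """Held-out accuracy >= 0.9 on generator output (seed 7, 200 per side)."""
    from seedcerna.simulate import SimConfig, gen_gene_models, gen_sequences

    cfg = SimConfig(
        seed=7,
        n_genes=200,
        n_lnc_per_class={"lincRNA": 50, "antisense": 50, "intronic": 50, "sense": 50},
        n_far_linc=0,
        planted_failures=(),
        module_n_mrnas=5,
    )
    genes, skeleton = gen_gene_models(cfg)
    seqs, _, truth = gen_sequences(genes, skeleton, cfg)
    t = truth.table
    coding = [seqs[i] for i in t.index[t["coding"] == "coding"]]
    noncoding = [seqs[i] for i in t.index[t["coding"] == "noncoding"]]
    table = train_hexamer_table(coding[:100], noncoding[:100])
    X = np.vstack([_features(coding[:100], table), _features(noncoding[:100], table)])
    y = np.array([1] * 100 + [0] * 100)
    model = train_combiner(X, y)
    X_test = np.vstack([_features(coding[100:200], table), _features(noncoding[100:200], table)])
    y_test = np.array([1] * 100 + [0] * 100)
    acc = ((model.predict_proba(X_test) >= 0.5) == y_test).mean()
    assert acc >= 0.9


def test_combiner_perfect_separation_and_null_labels():
    rng = np.random.default_rng(8)
    X = np.concatenate([rng.normal(0, 1, 50), rng.normal(10, 1, 50)]).reshape(-1, 1)
    X = np.hstack([X, np.zeros_like(X), np.zeros_like(X)])
    y = np.array([0] * 50 + [1] * 50)
    model = train_combiner(X, y)
    assert ((model.predict_proba(X) >= 0.5) == y).mean() == 1.0
    yperm = rng.permutation(y)
    null_acc = ((train_combiner(X, yperm).predict_proba(X) >= 0.5) == yperm).mean()
    assert abs(null_acc - 0.5) <= 0.15


def test_combiner_single_class_errors():
    X = np.zeros((10, 3))
    with pytest.raises(ValueError):
        train_combiner(X, np.ones(10))


@pytest.mark.parametrize(
    "verdicts,expected",
    [([True, True, True, True], True), ([True, True, True, False], False), ([True], True)],
)
def test_consensus_is_intersection(verdicts, expected):
    assert consensus_noncoding(verdicts) is expected


def test_consensus_empty_errors():
    with pytest.raises(ValueError):
        consensus_noncoding([])


def test_consensus_on_overlapping_tool_sets():
    """Four screens of sizes 4236/7344/11272/10218 with a planted common core
    of 2350 ids intersect to exactly that core."""
    rng = np.random.default_rng(99)
    core = {f"core{i}" for i in range(2350)}
    sizes = [4236, 7344, 11272, 10218]
    pools = [{f"s{j}_extra{i}" for i in range(sizes[j] - 2350)} for j in range(4)]
    tool_sets = [core | pools[j] for j in range(4)]
    assert [len(s) for s in tool_sets] == sizes
    universe = set().union(*tool_sets)
    passed = {
        tid for tid in universe if consensus_noncoding([tid in s for s in tool_sets])
    }
    assert passed == core and len(passed) == 2350


# ---------------------------------------------------------------------------
# Dinucleotide shuffle


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=3, max_size=200), st.integers(0, 1000))
def test_dinucleotide_shuffle_preserves_dinucleotide_counts(seq, seed):
    rng = np.random.default_rng(seed)
    out = dinucleotide_shuffle(seq, rng)

    def counts(s):
        d = {}
        for a, b in zip(s, s[1:]):
            d[a + b] = d.get(a + b, 0) + 1
        return d

    assert len(out) == len(seq)
    assert counts(out) == counts(seq)
    assert out[0] == seq[0] and out[-1] == seq[-1]
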