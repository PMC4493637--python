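"""AF / CKSAAP / KNN encodings against brute-force oracles and invariants."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from oryzaphos.encodings import (
    AA_INDEX,
    EncodingSpec,
    SimilarityMatrix,
    encode_af,
    encode_cksaap,
    encode_combined,
    encode_fragments,
    encode_knn,
    k_from_fraction,
    knn_distance,
    normalize_blosum62,
)
from oryzaphos.errors import ConfigError, DataError
from oryzaphos.synthetic import generate, strong_signal_spec
from tests.conftest import random_fragment


def cksaap_oracle(sequence, k_max):
    """Exhaustive pair-enumeration reference for CKSAAP."""
    out = np.zeros(400 * (k_max + 1))
    for k in range(k_max + 1):
        counts = {}
        total = 0
        for i in range(len(sequence) - k - 1):
            a, b = sequence[i], sequence[i + k + 1]
            if a in AA_INDEX and b in AA_INDEX:
                counts[(a, b)] = counts.get((a, b), 0) + 1
                total += 1
        for (a, b), c in counts.items():
            out[400 * k + AA_INDEX[a] * 20 + AA_INDEX[b]] = c / total
    return out


class TestAF:
    def test_homopolymer(self):
        v = encode_af("A" * 25)
        assert v[AA_INDEX["A"]] == 1.0
        assert v.sum() == 1.0

    def test_mixed_counts(self):
        v = encode_af("A" * 13 + "S" * 12)
        assert v[AA_INDEX["A"]] == pytest.approx(13 / 25)
        assert v[AA_INDEX["S"]] == pytest.approx(12 / 25)

    def test_pads_and_wildcards_excluded_from_denominator(self):
        v = encode_af("--" + "A" * 10 + "S" + "X" + "A" * 11)
        assert v[AA_INDEX["A"]] == pytest.approx(21 / 22)
        assert v.sum() == pytest.approx(1.0)

    def test_all_pads_rejected(self):
        with pytest.raises(DataError):
            encode_af("-" * 25)

    def test_sums_to_one_for_padfree(self, rng):
        for _ in range(5):
            frag = random_fragment(rng)
            assert encode_af(frag).sum() == pytest.approx(1.0)


class TestCKSAAP:
    def test_toy_homopolymer(self):
        v = encode_cksaap("AAAAA", k_max=0)
        assert v[AA_INDEX["A"] * 20 + AA_INDEX["A"]] == 1.0
        assert v.sum() == 1.0

    def test_toy_asa(self):
        v = encode_cksaap("ASA", k_max=1)
        a, s = AA_INDEX["A"], AA_INDEX["S"]
        assert v[a * 20 + s] == pytest.approx(0.5)
        assert v[s * 20 + a] == pytest.approx(0.5)
        assert v[400 + a * 20 + a] == pytest.approx(1.0)

    def test_full_dimension(self):
        assert encode_cksaap("A" * 25, k_max=5).size == 2400

    def test_matches_enumeration_oracle(self, rng):
        for pads in (0, 3):
            for _ in range(5):
                frag = random_fragment(rng, pads=pads)
                np.testing.assert_allclose(
                    encode_cksaap(frag, 5), cksaap_oracle(frag.sequence, 5), atol=1e-12
                )

    def test_blocks_sum_to_one_without_pads(self, rng):
        frag = random_fragment(rng)
        v = encode_cksaap(frag, 5)
        for k in range(6):
            assert v[400 * k : 400 * (k + 1)].sum() == pytest.approx(1.0)

    def test_extreme_padding_gives_zero_block(self, caplog):
        with caplog.at_level("WARNING"):
            v = encode_cksaap("AS", k_max=3)
        assert v[400 * 2 :].sum() == 0.0


class TestSimilarityMatrix:
    def test_normalization_is_tight_and_symmetric(self):
        sim = normalize_blosum62()
        assert np.allclose(sim.values, sim.values.T)
        assert sim.values.min() == 0.0
        assert sim.values.max() == 1.0

    def test_monotone_in_raw_blosum(self):
        sim = normalize_blosum62()
        raw = substitution_matrices.load("BLOSUM62")
        pairs = [("A", "A"), ("W", "W"), ("A", "W"), ("L", "I"), ("C", "C")]
        for a1, b1 in pairs:
            for a2, b2 in pairs:
                if raw[a1, b1] > raw[a2, b2]:
                    assert sim.lookup(a1, b1) > sim.lookup(a2, b2)

    def test_rejects_invalid_matrices(self):
        with pytest.raises(ConfigError):
            SimilarityMatrix(np.zeros((19, 19)))
        bad = np.zeros((20, 20))
        bad[0, 1] = 0.5
        with pytest.raises(ConfigError, match="symmetric"):
            SimilarityMatrix(bad)


class TestKnnDistance:
    def test_symmetry(self, rng):
        sim = normalize_blosum62()
        f1, f2 = random_fragment(rng), random_fragment(rng)
        assert knn_distance(f1, f2, sim) == pytest.approx(knn_distance(f2, f1, sim))

    def test_zero_at_max_similarity(self):
        # W-W is the top-scoring BLOSUM62 pair, so sim = 1 at every position
        sim = normalize_blosum62()
        assert knn_distance("W" * 25, "W" * 25, sim) == pytest.approx(0.0)

    def test_hand_computed_three_positions(self):
        sim = normalize_blosum62()
        d = knn_distance("AST", "ATS", sim)
        expected = 1 - (sim.lookup("A", "A") + sim.lookup("S", "T") + sim.lookup("T", "S")) / 3
        assert d == pytest.approx(expected)

    def test_pads_skipped(self):
        sim = normalize_blosum62()
        assert knn_distance("-AS", "TAS", sim) == pytest.approx(
            1 - (sim.lookup("A", "A") + sim.lookup("S", "S")) / 2
        )

    def test_incomparable_raises(self):
        sim = normalize_blosum62()
        with pytest.raises(DataError, match="incomparable"):
            knn_distance("---", "AAA", sim)


def knn_oracle(query, pos_refs, neg_refs, fractions, sim, cap=100.0):
    """Brute-force all-pairs KNN ratio features."""
    d_pos = [knn_distance(query, r, sim) for r in pos_refs]
    d_neg = [knn_distance(query, r, sim) for r in neg_refs]
    feats = []
    for f in fractions:
        kp = max(1, int(np.floor(f * len(d_pos) + 0.5)))
        kn = max(1, int(np.floor(f * len(d_neg) + 0.5)))
        mp = np.mean(sorted(d_pos)[:kp])
        mn = np.mean(sorted(d_neg)[:kn])
        feats.append(cap if mp == 0 and mn > 0 else (1.0 if mp == mn == 0 else mn / mp))
    return np.array(feats)


class TestKnnEncoding:
    def test_identical_reference_sets_give_unit_ratios(self, rng):
        refs = [random_fragment(rng, pid=f"r{i}") for i in range(6)]
        query = random_fragment(rng, pid="q")
        feats = encode_knn(query, refs, refs)
        np.testing.assert_allclose(feats, np.ones(7))

    def test_default_fraction_count_is_seven(self, rng):
        refs_p = [random_fragment(rng, pid=f"p{i}") for i in range(5)]
        refs_n = [random_fragment(rng, pid=f"n{i}") for i in range(5)]
        assert encode_knn(random_fragment(rng, pid="q"), refs_p, refs_n).size == 7

    def test_matches_bruteforce_oracle(self, rng):
        sim = normalize_blosum62()
        refs_p = [random_fragment(rng, pid=f"p{i}") for i in range(5)]
        refs_n = [random_fragment(rng, pid=f"n{i}") for i in range(5)]
        query = random_fragment(rng, pid="q")
        fractions = (0.2, 0.5, 1.0)
        got = encode_knn(query, refs_p, refs_n, fractions=fractions, sim=sim)
        want = knn_oracle(query, refs_p, refs_n, fractions, sim)
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_exclude_self_removes_query_from_references(self, rng):
        sim = normalize_blosum62()
        refs_p = [random_fragment(rng, pid=f"p{i}") for i in range(5)]
        refs_n = [random_fragment(rng, pid=f"n{i}") for i in range(5)]
        query = refs_p[0]
        with_self = encode_knn(query, refs_p, refs_n, fractions=(0.2,), sim=sim)
        without = encode_knn(query, refs_p, refs_n, fractions=(0.2,), sim=sim, exclude_self=True)
        oracle = knn_oracle(query, refs_p[1:], refs_n, (0.2,), sim)
        assert with_self[0] != without[0]
        np.testing.assert_allclose(without, oracle, atol=1e-12)

    def test_k_from_fraction_rounds_half_away_with_floor_one(self):
        assert k_from_fraction(0.001, 100) == 1
        assert k_from_fraction(0.05, 100) == 5
        assert k_from_fraction(0.005, 500) == 3  # 2.5 rounds up
        assert k_from_fraction(0.1, 4) == 1

    def test_planted_signal_direction(self):
        # positives generated from a distinct composition: each ratio feature
        # should on average be larger for positives than negatives
        pos, neg = generate(strong_signal_spec(n_pos=40, n_neg=40, seed=2))
        spec = EncodingSpec("KNN")
        Xp = encode_fragments(pos, spec, positive_refs=pos, negative_refs=neg, exclude_self=True)
        Xn = encode_fragments(neg, spec, positive_refs=pos, negative_refs=neg, exclude_self=True)
        assert np.all(Xp.mean(axis=0) > Xn.mean(axis=0))


class TestCombinedSchemes:
    @pytest.mark.parametrize(
        "scheme,dim",
        [("AF", 20), ("KNN", 7), ("CKSAAP", 2400), ("AF-KNN", 27),
         ("AF-CKSAAP", 2420), ("CKSAAP-KNN", 2407)],
    )
    def test_pre_selection_dimensions(self, scheme, dim):
        assert EncodingSpec(scheme).dimension == dim

    def test_af_block_of_combined_equals_encode_af(self, rng):
        frag = random_fragment(rng)
        combined = encode_combined(frag, EncodingSpec("AF-CKSAAP"))
        np.testing.assert_array_equal(combined[:20], encode_af(frag))

    def test_layout_identifiers_cover_blocks(self):
        layout = EncodingSpec("AF-KNN").feature_layout()
        assert layout[0] == "AF:A"
        assert layout[20].startswith("KNN:f0.001")
        assert len(layout) == 27

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ConfigError):
            EncodingSpec("ONEHOT")

    def test_encoding_purity(self, rng):
        frag = random_fragment(rng)
        spec = EncodingSpec("AF-CKSAAP")
        np.testing.assert_array_equal(
            encode_combined(frag, spec), encode_combined(frag, spec)
        )
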