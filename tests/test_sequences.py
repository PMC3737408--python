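"""Sequence diversity: identity, histograms, pruning, alignment vs DP oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chewspace import (
    Msa,
    align_pair,
    msa_identity_histogram,
    pairwise_identity,
    per_residue_similarity,
    prune_redundant,
)
from chewspace.sequences import AMINO_ACIDS, load_substitution_matrix

NEG = float("-inf")


def affine_nw_score(a, b, matrix, gap_open, gap_extend, free_end_gaps=True):
    """Independent Gotoh dynamic-programming oracle (score only).

    A gap of length L costs ``gap_open + (L-1) * gap_extend``; terminal gaps
    are free when ``free_end_gaps``.
    """
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in b (consuming a)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in a (consuming b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = 0.0 if free_end_gaps else -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Iy[0, j] = 0.0 if free_end_gaps else -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i, j] = s + max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            Ix[i, j] = max(
                M[i - 1, j] - gap_open,
                Ix[i - 1, j] - gap_extend,
                Iy[i - 1, j] - gap_open,
            )
            Iy[i, j] = max(
                M[i, j - 1] - gap_open,
                Iy[i, j - 1] - gap_extend,
                Ix[i, j - 1] - gap_open,
            )
    best = np.maximum(np.maximum(M, Ix), Iy)
    if not free_end_gaps:
        return best[n, m]
    return max(best[n, :].max(), best[:, m].max())


class TestPairwiseIdentity:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("ACDEFG", "ACDEFG", 100.0),
            ("ACDEFG", "ACDKFG", 100 * 5 / 6),
            ("A-CD", "AEC-", 100.0),  # shared non-gap columns {A, C} only
            ("AAAA", "CCCC", 0.0),
        ],
    )
    def test_hand_counted_cases(self, a, b, expected):
        assert pairwise_identity(a, b) == pytest.approx(expected)

    def test_all_gap_overlap_is_an_error(self):
        with pytest.raises(ValueError, match="non-gap"):
            pairwise_identity("A--", "-CC")

    @given(
        st.tuples(
            st.text(alphabet=AMINO_ACIDS + "-", min_size=3, max_size=20),
            st.text(alphabet=AMINO_ACIDS + "-", min_size=3, max_size=20),
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_symmetry(self, pair):
        a, b = pair
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        try:
            forward = pairwise_identity(a, b)
        except ValueError:
            return
        assert forward == pytest.approx(pairwise_identity(b, a))


class TestHistogram:
    def test_identical_sequences_land_in_top_bin(self):
        msa = Msa(tuple((f"s{i}", "ACDEFGHIKL") for i in range(5)))
        hist = msa_identity_histogram(msa)
        assert hist.counts[99] == 10 and hist.n_pairs == 10

    def test_hand_binned_toy(self):
        # identities: (s1,s2)=2/4, (s1,s3)=3/4, (s2,s3)=3/4
        msa = Msa((("s1", "ACDE"), ("s2", "ACKL"), ("s3", "ACDL")))
        hist = msa_identity_histogram(msa)
        assert hist.counts[50] == 1 and hist.counts[75] == 2
        assert hist.n_pairs == 3

    def test_pair_conservation_and_reorder_invariance(self):
        rng = np.random.default_rng(5)
        records = tuple(
            (f"s{i}", "".join(rng.choice(list(AMINO_ACIDS), 12))) for i in range(7)
        )
        hist = msa_identity_histogram(Msa(records))
        assert hist.n_pairs == 7 * 6 // 2
        shuffled = tuple(records[i] for i in rng.permutation(7))
        assert np.array_equal(
            hist.counts, msa_identity_histogram(Msa(shuffled)).counts
        )


class TestPruning:
    def test_mutually_identical_keep_one(self):
        msa = Msa(tuple((f"s{i}", "ACDEFGHIKL") for i in range(4)))
        kept, removed = prune_redundant(msa)
        assert len(kept) == 1 and removed == ["s1", "s2", "s3"]

    def test_diverse_set_fully_kept(self):
        msa = Msa((("s1", "AAAAAAAAAA"), ("s2", "CCCCCCCCCC"), ("s3", "DDDDDDDDDD")))
        kept, removed = prune_redundant(msa)
        assert len(kept) == 3 and removed == []

    def test_greedy_input_order_rule(self):
        s1 = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY"
        s2 = s1[:-1] + "W"  # 99% of s1
        s3 = s1[:50] + "W" * 50  # about half identical
        kept, removed = prune_redundant(Msa((("s1", s1), ("s2", s2), ("s3", s3))))
        assert kept.ids == ["s1", "s3"] and removed == ["s2"]

    def test_no_kept_pair_reaches_threshold(self):
        rng = np.random.default_rng(0)
        base = rng.choice(list(AMINO_ACIDS), 50)
        records = []
        for i in range(10):
            seq = base.copy()
            k = rng.integers(0, 6)
            for p in rng.permutation(50)[:k]:
                seq[p] = rng.choice(list(AMINO_ACIDS))
            records.append((f"s{i}", "".join(seq)))
        kept, _ = prune_redundant(Msa(tuple(records)), threshold=95.0)
        seqs = [s for _, s in kept.records]
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                assert pairwise_identity(seqs[i], seqs[j]) < 95.0


class TestAlignPair:
    def test_self_alignment_scores_diagonal_sum(self):
        seq = "MKVLAWYEDH"
        matrix = load_substitution_matrix("BLOSUM62")
        aln = align_pair(seq, seq)
        assert "-" not in aln.aligned_a + aln.aligned_b
        assert aln.score == sum(matrix[c, c] for c in seq)

    def test_textbook_pair_matches_dp_oracle(self):
        matrix = load_substitution_matrix("BLOSUM62")
        expected = affine_nw_score("HEAGAWGHEE", "PAWHEAE", matrix, 7, 1)
        aln = align_pair("HEAGAWGHEE", "PAWHEAE")
        assert aln.score == expected
        assert aln.aligned_a.replace("-", "") == "HEAGAWGHEE"
        assert aln.aligned_b.replace("-", "") == "PAWHEAE"

    @given(
        st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=12),
        st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=12),
    )
    @settings(max_examples=60, deadline=None)
    def test_score_matches_dp_oracle_on_short_sequences(self, a, b):
        matrix = load_substitution_matrix("BLOSUM62")
        assert align_pair(a, b).score == affine_nw_score(a, b, matrix, 7, 1)

    def test_unknown_letter_rejected_but_x_is_neutral(self):
        with pytest.raises(ValueError, match="unknown"):
            align_pair("ACDO", "ACD")
        aln = align_pair("ACXD", "ACXD")
        matrix = load_substitution_matrix("BLOSUM62")
        expected = matrix["A", "A"] + matrix["C", "C"] + 0.0 + matrix["D", "D"]
        assert aln.score == expected


class TestPerResidueSimilarity:
    def test_identical_sequences_score_matrix_diagonal(self):
        matrix = load_substitution_matrix("BLOSUM62")
        aln = align_pair("MKWY", "MKWY")
        scores = per_residue_similarity(aln)
        assert scores.tolist() == [matrix[c, c] for c in "MKWY"]

    def test_gap_partner_gets_matrix_minimum(self):
        from chewspace.sequences import AlignmentResult

        aln = AlignmentResult("MKWY", "MK-Y", 0.0, "BLOSUM62", 7, 1)
        matrix = load_substitution_matrix("BLOSUM62")
        scores = per_residue_similarity(aln)
        assert scores[2] == float(np.min(np.asarray(matrix)))
        assert len(scores) == 4

    def test_hand_scored_toy_alignment(self):
        from chewspace.sequences import AlignmentResult

        matrix = load_substitution_matrix("BLOSUM62")
        aln = AlignmentResult("MAWD", "MVWE", 0.0, "BLOSUM62", 7, 1)
        expected = [
            matrix["M", "M"],
            matrix["A", "V"],
            matrix["W", "W"],
            matrix["D", "E"],
        ]
        assert per_residue_similarity(aln).tolist() == expected
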