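import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helpers_oracle import exhaustive_local_score, oracle_local_score
from ptmtransfer.alignment import (
    AlignmentError,
    SearchParams,
    SequenceDatabase,
    SubstitutionMatrix,
    batch_local_scores,
    best_hit,
    evalue,
    karlin_k,
    karlin_lambda,
    search,
    smith_waterman,
    _encode,
)

BL62 = SubstitutionMatrix.blosum62()
AA = "ACDEFGHIKLMNPQRSTWYV"


def engine_scores(a, b, gap_open=11, gap_extend=1):
    """Score the same pair through both internal scoring paths."""
    s_trace = smith_waterman(a, b, BL62, gap_open, gap_extend).raw_score
    s_batch = int(
        batch_local_scores(a, np.stack([_encode(b)]), BL62, gap_open, gap_extend)[0]
    )
    return s_trace, s_batch


class TestSmithWaterman:
    def test_oracle_agrees_with_exhaustive_enumeration_on_tiny_strings(self):
        # validates the oracle itself before it is trusted as a reference
        rng = np.random.default_rng(1)
        for _ in range(40):
            a = "".join(rng.choice(list(AA), size=rng.integers(1, 5)))
            b = "".join(rng.choice(list(AA), size=rng.integers(1, 5)))
            assert oracle_local_score(a, b, BL62.score, 11, 1) == \
                exhaustive_local_score(a, b, BL62.score, 11, 1)

    def test_engine_matches_brute_force_oracle_on_random_pairs(self):
        rng = np.random.default_rng(2)
        for _ in range(60):
            a = "".join(rng.choice(list(AA), size=rng.integers(1, 9)))
            b = "".join(rng.choice(list(AA), size=rng.integers(1, 9)))
            expected = oracle_local_score(a, b, BL62.score, 11, 1)
            s_trace, s_batch = engine_scores(a, b)
            assert s_trace == expected
            assert s_batch == expected

    def test_self_alignment_score_is_diagonal_sum(self):
        hit = smith_waterman("PELICAN", "PELICAN", BL62)
        assert hit.raw_score == sum(BL62.score(c, c) for c in "PELICAN")
        assert hit.pair_map == tuple((i, i) for i in range(1, 8))

    def test_no_positive_pair_gives_empty_alignment(self):
        hit = smith_waterman("AAAA", "CCCC", BL62)
        assert hit.raw_score == 0
        assert hit.pair_map == ()

    def test_padded_window_aligns_on_real_residues_only(self):
        hit = smith_waterman("MKSAPK", "XXMKS", BL62)
        assert hit.query_range == (1, 3)
        assert hit.subject_range == (3, 5)
        assert hit.raw_score == sum(BL62.score(c, c) for c in "MKS")

    def test_empty_sequence_errors(self):
        with pytest.raises(AlignmentError):
            smith_waterman("", "MK", BL62)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        a=st.text(alphabet=AA, min_size=1, max_size=12),
        b=st.text(alphabet=AA, min_size=1, max_size=12),
    )
    def test_score_symmetry(self, a, b):
        assert smith_waterman(a, b, BL62).raw_score == smith_waterman(b, a, BL62).raw_score


class TestKarlinStatistics:
    def test_toy_matrix_lambda_has_closed_form(self):
        # +1/-1 on a uniform 4-letter alphabet: (1/4)e^l + (3/4)e^-l = 1
        # => e^l = 3 => l = ln 3
        mat = SubstitutionMatrix.from_match_mismatch(1, -1, alphabet="ABCD")
        assert mat.karlin_lambda == pytest.approx(math.log(3), rel=1e-9)

    @pytest.mark.parametrize("mat", [BL62,
                                     SubstitutionMatrix.from_match_mismatch(1, -1, "ABCD"),
                                     SubstitutionMatrix.from_match_mismatch(2, -3, "ACGT")])
    def test_lambda_satisfies_root_equation(self, mat):
        scores = mat._score_grid()
        p = mat._prob_vector()
        residual = float((np.outer(p, p) * np.exp(mat.karlin_lambda * scores)).sum()) - 1.0
        assert abs(residual) < 1e-9

    def test_all_negative_scores_reject_lambda(self):
        scores = np.full((4, 4), -1.0)
        probs = np.full(4, 0.25)
        with pytest.raises(AlignmentError):
            karlin_lambda(scores, probs)

    def test_positive_expected_score_rejects_lambda(self):
        scores = np.ones((4, 4))
        probs = np.full(4, 0.25)
        with pytest.raises(AlignmentError):
            karlin_lambda(scores, probs)

    def test_k_is_positive_finite_and_deterministic(self):
        k1 = karlin_k(BL62._score_grid(), BL62._prob_vector(), BL62.karlin_lambda)
        k2 = karlin_k(BL62._score_grid(), BL62._prob_vector(), BL62.karlin_lambda)
        assert 0 < k1 < 1
        assert k1 == k2

    def test_evalue_closed_form_identities(self):
        lam, K = 0.3, 0.1
        assert evalue(0, 10, 100, lam, K) == pytest.approx(K * 10 * 100)
        assert evalue(50, 10, 200, lam, K) == pytest.approx(2 * evalue(50, 10, 100, lam, K))
        ratio = evalue(57, 10, 100, lam, K) / evalue(50, 10, 100, lam, K)
        assert ratio == pytest.approx(math.exp(-lam * 7))


class TestSearchContract:
    def test_identical_sequence_is_top_hit(self):
        db = SequenceDatabase("d", [
            ("other", "WWWWHHHHWWWW"),
            ("self", "MKSAPKLMNPQR"),
            ("junk", "GGGGGGGGGGGG"),
        ])
        hits = search("MKSAPKLMNPQR", db, SearchParams())
        assert best_hit(hits).subject_id == "self"

    def test_cutoff_below_every_hit_gives_empty_list(self):
        db = SequenceDatabase("d", [("s", "MKSAPK")])
        hits = search("MKSAPK", db, SearchParams(evalue_cutoff=1e-30))
        assert hits == []

    def test_equal_hits_truncate_to_lexicographically_smallest_subjects(self):
        seq = "MKSAPKLMNPQRW"
        db = SequenceDatabase("d", [(f"d{i}", seq) for i in (3, 1, 5, 2, 4)])
        hits = search(seq, db, SearchParams(max_target_seqs=3))
        assert [h.subject_id for h in hits] == ["d1", "d2", "d3"]

    def test_decoy_grows_evalues_but_not_raw_scores(self):
        entries = [("a", "MKSAPKLMNPQR"), ("b", "MKSAPKWWNPQR")]
        small = SequenceDatabase("small", list(entries))
        big = SequenceDatabase("big", entries + [("decoy", "G" * 200)])
        params = SearchParams()
        h_small = {h.subject_id: h for h in search("MKSAPKLMNPQR", small, params)}
        h_big = {h.subject_id: h for h in search("MKSAPKLMNPQR", big, params)}
        for sid in h_small:
            assert h_big[sid].raw_score == h_small[sid].raw_score
            assert h_big[sid].evalue > h_small[sid].evalue

    def test_search_is_deterministic(self):
        rng = np.random.default_rng(3)
        entries = [
            (f"s{i}", "".join(rng.choice(list(AA), size=30))) for i in range(10)
        ]
        db = SequenceDatabase("d", entries)
        q = "".join(rng.choice(list(AA), size=25))
        assert search(q, db, SearchParams()) == search(q, db, SearchParams())

    def test_empty_database_is_an_error(self):
        with pytest.raises(AlignmentError):
            SequenceDatabase("d", [])

    def test_best_hit_of_empty_list_is_none(self):
        assert best_hit([]) is None


class TestParamsAndMatrixValidation:
    def test_gap_and_cutoff_invariants(self):
        with pytest.raises(AlignmentError):
            SearchParams(gap_open=5, gap_extend=6)
        with pytest.raises(AlignmentError):
            SearchParams(evalue_cutoff=0)

    def test_positive_expected_score_matrix_rejected(self):
        with pytest.raises(AlignmentError):
            SubstitutionMatrix.from_match_mismatch(5, 1, alphabet="ABCD")

    def test_x_column_of_blosum62_never_positive(self):
        assert all(BL62.score("X", a) <= 0 for a in AA + "X")
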