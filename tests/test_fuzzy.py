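"""Levenshtein distance, similarity ratios, and unit matching.

The distance implementation is checked against an independent brute-force
oracle that transcribes the textbook recursive definition (base cases
Lev(V, eps) = |V|, Lev(eps, W) = |W|; deletion/insertion/substitution each
cost 1), exhaustively for short strings and against edlib for longer random
ones.
"""

import itertools

import edlib
import pytest
from hypothesis import given, settings, strategies as st

from ehrclean.fuzzy import (
    MatchResult,
    indel_distance,
    levenshtein,
    match_unit,
    similarity_ratio,
)


def lev_oracle(a: str, b: str) -> int:
    """Direct memoized transcription of the recursive definition."""
    memo = {}

    def rec(i: int, j: int) -> int:
        if i == 0 or j == 0:
            return max(i, j)
        if (i, j) in memo:
            return memo[(i, j)]
        d = min(
            rec(i - 1, j) + 1,            # deletion
            rec(i, j - 1) + 1,            # insertion
            rec(i - 1, j - 1) + (a[i - 1] != b[j - 1]),  # substitution / copy
        )
        memo[(i, j)] = d
        return d

    return rec(len(a), len(b))


def indel_oracle(a: str, b: str) -> int:
    """len(a) + len(b) - 2*LCS(a, b), with LCS by dynamic programming."""
    m, n = len(a), len(b)
    dp = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(m):
        for j in range(n):
            dp[i + 1][j + 1] = (
                dp[i][j] + 1 if a[i] == b[j] else max(dp[i][j + 1], dp[i + 1][j])
            )
    return m + n - 2 * dp[m][n]


def all_strings(alphabet: str, max_len: int):
    for k in range(max_len + 1):
        for tup in itertools.product(alphabet, repeat=k):
            yield "".join(tup)


class TestLevenshtein:
    @pytest.mark.parametrize(
        "a, b, expected",
        [("abc", "abc", 0), ("ab", "", 2), ("", "ab", 2), ("kitten", "sitting", 3)],
    )
    def test_known_distances(self, a, b, expected):
        assert levenshtein(a, b) == expected

    def test_kitten_sitting_matches_bruteforce(self):
        assert lev_oracle("kitten", "sitting") == 3

    def test_exhaustive_against_recursive_definition(self):
        """DP distance equals the recursive definition for every pair of
        strings of length <= 6 over a 3-letter alphabet (unordered pairs;
        symmetry is asserted separately)."""
        strings = list(all_strings("abc", 6))
        assert len(strings) == 1093
        for i, a in enumerate(strings):
            for b in strings[i:]:
                assert levenshtein(a, b) == lev_oracle(a, b)

    @given(
        st.text(alphabet="abcdefg/L%", max_size=12),
        st.text(alphabet="abcdefg/L%", max_size=12),
    )
    @settings(max_examples=1000, deadline=None, derandomize=True)
    def test_random_pairs_against_edlib(self, a, b):
        if a and b:  # edlib rejects empty queries
            assert levenshtein(a, b) == edlib.align(a, b, task="distance")["editDistance"]
        assert levenshtein(a, b) == lev_oracle(a, b)

    @given(
        st.text(alphabet="abcd", max_size=8),
        st.text(alphabet="abcd", max_size=8),
        st.text(alphabet="abcd", max_size=8),
    )
    @settings(max_examples=500, deadline=None, derandomize=True)
    def test_is_a_metric(self, a, b, c):
        assert levenshtein(a, b) == levenshtein(b, a)
        assert (levenshtein(a, b) == 0) == (a == b)
        assert levenshtein(a, c) <= levenshtein(a, b) + levenshtein(b, c)

    @given(st.text(alphabet="abcd", max_size=10), st.text(alphabet="abcd", max_size=10))
    @settings(max_examples=500, deadline=None, derandomize=True)
    def test_indel_distance_equals_lcs_form(self, a, b):
        assert indel_distance(a, b) == indel_oracle(a, b)


class TestSimilarityRatio:
    def test_unit_check_scores_default_method(self):
        """The worked unit-check scores: 0.71 and 0.75 at 2 dp."""
        assert round(similarity_ratio("106/L", "X10exp6/L"), 2) == 0.71
        assert round(similarity_ratio("mmol/LsOms", "mmol/L"), 2) == 0.75

    def test_printed_formula_differs_on_the_same_pairs(self):
        """1 - Lev/max(|V|,|W|): 1 - 4/9 = 0.56 and 1 - 4/10 = 0.60."""
        assert round(similarity_ratio("106/L", "X10exp6/L", "printed_formula"), 2) == 0.56
        assert similarity_ratio("mmol/LsOms", "mmol/L", "printed_formula") == pytest.approx(0.6)

    @pytest.mark.parametrize("method", ["matching_blocks", "printed_formula"])
    def test_identical_strings_score_one(self, method):
        assert similarity_ratio("mmol/L", "mmol/L", method) == 1.0
        assert similarity_ratio("", "", method) == 1.0

    @pytest.mark.parametrize("method", ["matching_blocks", "printed_formula"])
    @given(
        a=st.text(alphabet="abcL/", max_size=10),
        b=st.text(alphabet="abcL/", max_size=10),
    )
    @settings(max_examples=400, deadline=None, derandomize=True)
    def test_bounded_symmetric_one_iff_equal(self, method, a, b):
        r = similarity_ratio(a, b, method)
        assert 0.0 <= r <= 1.0
        assert r == similarity_ratio(b, a, method)
        assert (r == 1.0) == (a == b)

    def test_methods_agree_on_pure_indel_edits(self):
        """With no substitutions and equal-length strings the two
        normalizations coincide (e.g. identical strings, or a pure
        insertion against the empty string)."""
        assert similarity_ratio("ab", "ab") == similarity_ratio("ab", "ab", "printed_formula")
        assert similarity_ratio("", "abcd") == similarity_ratio("", "abcd", "printed_formula") == 0.0

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            similarity_ratio("a", "b", "soundex")


class TestMatchUnit:
    CANDIDATES = ["mg/dL", "mmol/L", "mg/L"]

    def test_typo_repaired_to_closest_unit(self):
        result = match_unit("mmol/LsOms", self.CANDIDATES, threshold=0.5)
        assert result.accepted
        assert result.best_candidate == "mmol/L"
        assert result.ratio == 0.75

    def test_exact_match_keeps_unit_unchanged(self):
        result = match_unit("mmol/L", self.CANDIDATES, threshold=0.5)
        assert result == MatchResult("mmol/L", "mmol/L", 1.0, True, "matching_blocks")

    def test_case_insensitive_exact_match(self):
        result = match_unit("MMOL/l", self.CANDIDATES)
        assert result.accepted and result.ratio == 1.0
        assert result.best_candidate == "mmol/L"

    def test_gibberish_rejected_but_audited(self):
        result = match_unit("zzz", ["mmol/L", "mg/dL"], threshold=0.5)
        assert not result.accepted
        assert result.ratio < 0.5
        assert result.best_candidate is not None

    def test_threshold_zero_always_accepts(self):
        assert match_unit("qqqq", self.CANDIDATES, threshold=0.0).accepted

    def test_threshold_one_accepts_only_exact(self):
        assert match_unit("mg/dL", self.CANDIDATES, threshold=1.0).accepted
        assert not match_unit("mg/dl1", self.CANDIDATES, threshold=1.0).accepted

    def test_tie_broken_by_plain_distance_then_candidate_order(self):
        # "ax" vs candidates "ay"/"az": identical ratio and distance, the
        # earlier candidate (the standard unit slot) wins.
        result = match_unit("ax", ["ay", "az"], threshold=0.0)
        assert result.best_candidate == "ay"

    def test_empty_candidates_error(self):
        with pytest.raises(ValueError, match="empty"):
            match_unit("mg/dL", [], threshold=0.5)
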