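import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcrsimnet import similarity as ts
from tcrsimnet.clonotype import Clonotype

from oracles import brute_force_components, dp_levenshtein

AA = "ACDEFGHIKLMNPQRSTVWY"
aa_strings = st.text(alphabet=AA, min_size=0, max_size=30)


def make_ct(cid, cdr3a, cdr3b, size=2, sample="S1", group="AD"):
    return Clonotype(
        clonotype_id=cid,
        cdr3a=cdr3a,
        cdr3b=cdr3b,
        member_cells=[(sample, f"{cid}-{i}") for i in range(size)],
        groups={group},
    )


class TestLevenshteinDistance:
    @pytest.mark.parametrize("a,b,d", [
        ("", "", 0),
        ("", "ABC", 3),
        ("ABC", "", 3),
        ("kitten", "sitting", 3),  # frozen from the DP oracle
        ("CASSF", "CASTF", 1),
        ("AB", "ABCD", 2),
    ])
    def test_known_values(self, a, b, d):
        assert ts.levenshtein_distance(a, b) == d
        assert dp_levenshtein(a, b) == d  # oracle agrees on the frozen values

    def test_identity(self):
        for s in ["", "A", "CASSLGQAYEQYF"]:
            assert ts.levenshtein_distance(s, s) == 0

    @given(aa_strings, aa_strings)
    @settings(max_examples=200, deadline=None)
    def test_matches_dp_oracle(self, a, b):
        assert ts.levenshtein_distance(a, b) == dp_levenshtein(a, b)

    @given(aa_strings, aa_strings)
    @settings(max_examples=100, deadline=None)
    def test_symmetric(self, a, b):
        assert ts.levenshtein_distance(a, b) == ts.levenshtein_distance(b, a)

    @given(aa_strings, aa_strings, aa_strings)
    @settings(max_examples=100, deadline=None)
    def test_triangle_inequality(self, a, b, c):
        assert ts.levenshtein_distance(a, c) <= (
            ts.levenshtein_distance(a, b) + ts.levenshtein_distance(b, c)
        )

    @given(aa_strings, aa_strings)
    @settings(max_examples=100, deadline=None)
    def test_zero_iff_equal(self, a, b):
        assert (ts.levenshtein_distance(a, b) == 0) == (a == b)


class TestLsim:
    def test_identical_is_one(self):
        assert ts.lsim("CASSLGQAYEQYF", "CASSLGQAYEQYF") == 1.0

    def test_single_letter_substitution(self):
        assert ts.lsim("A", "B") == 0.0

    @pytest.mark.parametrize("a,b,score", [("CASSF", "CASTF", 0.8), ("AB", "ABCD", 0.5)])
    def test_derived_values(self, a, b, score):
        assert ts.lsim(a, b) == pytest.approx(score)

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            ts.lsim("", "")

    def test_one_empty(self):
        assert ts.lsim("", "ABC") == 0.0

    @given(aa_strings, aa_strings)
    @settings(max_examples=200, deadline=None)
    def test_bounded_symmetric_and_one_iff_equal(self, a, b):
        if not a and not b:
            return
        s = ts.lsim(a, b)
        assert 0.0 <= s <= 1.0
        assert s == ts.lsim(b, a)
        assert (s == 1.0) == (a == b)


class TestPairwiseLsim:
    def _three(self):
        return [
            make_ct("ct0", "CAVRDNYQLIW", "CASSLGQAYEQYF"),
            make_ct("ct1", "CAVRDNYQLIW", "CASSLGQAYEQYF"),
            make_ct("ct2", "CAVRDNYQLIW", "CASSETQYF"),
        ]

    def test_identical_pair_scores_one_in_all_modes(self):
        cts = self._three()[:2]
        for mode in (ts.CONCAT_AB, ts.PER_CHAIN_MEAN, ts.BETA_ONLY):
            matrix = ts.pairwise_lsim(cts, mode)
            assert matrix.get("ct0", "ct1") == 1.0

    def test_per_chain_mean_hand_computed(self):
        cts = self._three()
        matrix = ts.pairwise_lsim(cts, ts.PER_CHAIN_MEAN)
        expected = (1.0 + ts.lsim("CASSLGQAYEQYF", "CASSETQYF")) / 2.0
        assert matrix.get("ct0", "ct2") == pytest.approx(expected)

    def test_concat_matches_single_string_lsim(self):
        cts = self._three()
        matrix = ts.pairwise_lsim(cts, ts.CONCAT_AB)
        expected = ts.lsim(
            "CAVRDNYQLIW" + "CASSLGQAYEQYF", "CAVRDNYQLIW" + "CASSETQYF"
        )
        assert matrix.get("ct0", "ct2") == pytest.approx(expected)

    def test_pair_count(self):
        rng = random.Random(5)
        cts = [
            make_ct(f"ct{i}", "C" + "".join(rng.choices(AA, k=10)) + "F",
                    "C" + "".join(rng.choices(AA, k=10)) + "F")
            for i in range(7)
        ]
        matrix = ts.pairwise_lsim(cts)
        assert len(matrix.scores) == 7 * 6 // 2

    def test_diagonal_and_symmetry(self):
        cts = self._three()
        matrix = ts.pairwise_lsim(cts)
        assert matrix.get("ct1", "ct1") == 1.0
        assert matrix.get("ct0", "ct2") == matrix.get("ct2", "ct0")

    def test_missing_alpha_is_config_error(self):
        cts = [make_ct("ct0", None, "CASSETQYF"), make_ct("ct1", None, "CASSLGQAYEQYF")]
        with pytest.raises(ValueError, match="cdr3a"):
            ts.pairwise_lsim(cts, ts.CONCAT_AB)
        ts.pairwise_lsim(cts, ts.BETA_ONLY)  # fine

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            ts.pairwise_lsim([make_ct("ct0", "CAV", "CASS")])

    def test_long_frame_round_trip(self):
        cts = self._three()
        matrix = ts.pairwise_lsim(cts)
        back = ts.SimilarityMatrix.from_long_frame(matrix.to_long_frame())
        for i in ("ct0", "ct1", "ct2"):
            for j in ("ct0", "ct1", "ct2"):
                assert back.get(i, j) == pytest.approx(matrix.get(i, j))

    def test_square_frame_symmetric_unit_diagonal(self):
        matrix = ts.pairwise_lsim(self._three())
        square = matrix.to_square_frame()
        assert np.allclose(square.values, square.values.T)
        assert np.allclose(np.diag(square.values), 1.0)


class TestDistribution:
    def test_point_mass_at_one(self):
        cts = [make_ct(f"ct{i}", "CAVRDNYQLIW", "CASSLGQAYEQYF", sample=f"S{i}") for i in range(4)]
        matrix = ts.pairwise_lsim(cts)
        dist = ts.lsim_distribution(matrix)
        assert dist["mean"] == 1.0
        assert dist["fraction_above_0.8"] == 1.0

    def test_bimodal_with_planted_near_duplicates(self):
        rng = random.Random(9)
        # two tight planted groups + scattered background
        cts = []
        for g, (a, b) in enumerate([("CAVRDNYQLIWGS", "CASSIRSAYEQF"), ("CAGQTGANNLFFG", "CASRPDRGLYTF")]):
            for i in range(4):
                chars = list(a)
                chars[5] = AA[(AA.index(chars[5]) + i) % 20]
                cts.append(make_ct(f"g{g}v{i}", "".join(chars), b))
        matrix = ts.pairwise_lsim(cts)
        dist = ts.lsim_distribution(matrix, bin_width=0.1)
        counts = dist["counts"]
        # within-group pairs near 1, cross-group pairs far below: mass in
        # both the top bin region and a distinctly lower region
        assert sum(counts[-2:]) == 2 * (4 * 3 // 2)
        assert sum(counts[:6]) == 4 * 4

    def test_empty_matrix_rejected(self):
        matrix = ts.SimilarityMatrix(["ct0"], np.array([]), ts.CONCAT_AB)
        with pytest.raises(ValueError):
            ts.lsim_distribution(matrix)


class TestThresholdClusters:
    def _matrix(self, ids, score_map):
        n = len(ids)
        scores = np.zeros(n * (n - 1) // 2)
        k = 0
        for i in range(n):
            for j in range(i + 1, n):
                scores[k] = score_map.get((ids[i], ids[j]), score_map.get((ids[j], ids[i]), 0.1))
                k += 1
        return ts.SimilarityMatrix(list(ids), scores, ts.CONCAT_AB)

    def test_pair_above_threshold(self):
        matrix = self._matrix(["A", "B"], {("A", "B"): 0.85})
        (cluster,) = ts.threshold_clusters(matrix, 0.8)
        assert cluster.members == ["A", "B"]
        assert cluster.min_lsim == pytest.approx(0.85)

    def test_strict_inequality_at_threshold(self):
        matrix = self._matrix(["A", "B"], {("A", "B"): 0.80})
        assert ts.threshold_clusters(matrix, 0.8) == []

    def test_transitive_component(self):
        matrix = self._matrix(
            ["A", "B", "C"], {("A", "B"): 0.85, ("B", "C"): 0.82, ("A", "C"): 0.40}
        )
        (cluster,) = ts.threshold_clusters(matrix, 0.8)
        assert cluster.members == ["A", "B", "C"]

    def test_matches_brute_force_components(self):
        rng = random.Random(21)
        ids = [f"ct{i}" for i in range(12)]
        score_map = {}
        for i in range(12):
            for j in range(i + 1, 12):
                score_map[(ids[i], ids[j])] = rng.random()
        matrix = self._matrix(ids, score_map)
        tau = 0.7
        edges = [
            (i, j)
            for i in range(12)
            for j in range(i + 1, 12)
            if score_map[(ids[i], ids[j])] > tau
        ]
        expected = {
            frozenset(ids[i] for i in comp)
            for comp in brute_force_components(12, edges)
            if len(comp) >= 2
        }
        got = {frozenset(c.members) for c in ts.threshold_clusters(matrix, tau)}
        assert got == expected

    def test_sorted_by_size_then_lexicographic(self):
        matrix = self._matrix(
            ["A", "B", "X", "Y", "Z"],
            {("X", "Y"): 0.9, ("Y", "Z"): 0.9, ("A", "B"): 0.9},
        )
        clusters = ts.threshold_clusters(matrix, 0.8)
        assert [c.members for c in clusters] == [["X", "Y", "Z"], ["A", "B"]]

    def test_refinement_under_higher_tau(self):
        rng = random.Random(33)
        ids = [f"ct{i}" for i in range(15)]
        score_map = {}
        for i in range(15):
            for j in range(i + 1, 15):
                score_map[(ids[i], ids[j])] = rng.random()
        matrix = self._matrix(ids, score_map)
        low = ts.threshold_clusters(matrix, 0.5)
        high = ts.threshold_clusters(matrix, 0.75)
        low_sets = [set(c.members) for c in low]
        for cluster in high:
            assert any(set(cluster.members) <= s for s in low_sets)

    def test_tau_bounds(self):
        matrix = self._matrix(["A", "B"], {})
        for bad in (0.0, 1.0, -0.5):
            with pytest.raises(ValueError):
                ts.threshold_clusters(matrix, bad)
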