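"""p-distance, pairwise alignment and annealed subset selection."""

from itertools import combinations

import numpy as np
import pytest

from coiminer import repselect
from coiminer.repselect import (
    AnnealSchedule,
    DistanceMatrix,
    anneal_select,
    p_distance,
    pairwise_align,
    subset_objective,
)


class TestPDistance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("ACGT", "ACGT", 0.0),
            ("AAAA", "TTTT", 1.0),
            ("ACG-", "ACGT", 0.0),   # gap columns excluded
            ("AC-T", "AGT-", 0.5),   # 2 comparable columns, 1 difference
            ("----", "ACGT", 0.0),   # no comparable columns
            ("acgt", "ACGT", 0.0),   # case-insensitive
        ],
    )
    def test_gap_excluded_proportion(self, a, b, expected):
        assert p_distance(a, b) == expected

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            p_distance("ACG", "ACGT")

    def test_symmetry_and_self_distance(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            s = "".join(rng.choice(list("ACGT-"), size=30))
            t = "".join(rng.choice(list("ACGT-"), size=30))
            assert p_distance(s, t) == p_distance(t, s)
            assert p_distance(s, s) == 0.0


def brute_force_alignment_score(a, b, match=1.0, mismatch=-1.0, gap=-2.0):
    """Independent optimum by exhaustive recursion (tiny inputs only)."""
    def rec(i, j):
        if i == len(a) and j == len(b):
            return 0.0
        best = -np.inf
        if i < len(a) and j < len(b):
            sub = match if a[i] == b[j] else mismatch
            best = max(best, sub + rec(i + 1, j + 1))
        if i < len(a):
            best = max(best, gap + rec(i + 1, j))
        if j < len(b):
            best = max(best, gap + rec(i, j + 1))
        return best
    return rec(0, 0)


def alignment_score(aligned_a, aligned_b, match=1.0, mismatch=-1.0, gap=-2.0):
    score = 0.0
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" or y == "-":
            score += gap
        else:
            score += match if x == y else mismatch
    return score


class TestPairwiseAlign:
    def test_identical_sequences_unchanged(self):
        assert pairwise_align("ACGT", "ACGT") == ("ACGT", "ACGT")

    def test_single_column_outscores_double_gap(self):
        assert pairwise_align("A", "T") == ("A", "T")

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            pairwise_align("", "ACGT")

    def test_gap_insertion_and_p_distance(self):
        aligned_a, aligned_b = pairwise_align("ACGT", "AGT")
        assert len(aligned_a) == len(aligned_b) == 4
        assert aligned_b.count("-") == 1
        assert p_distance(aligned_a, aligned_b) == 0.0

    def test_optimal_on_all_short_pairs(self):
        # exhaustive-enumeration oracle over every pair up to length 4
        rng = np.random.default_rng(5)
        for _ in range(30):
            a = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 5)))
            b = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 5)))
            aligned = pairwise_align(a, b)
            assert alignment_score(*aligned) == pytest.approx(
                brute_force_alignment_score(a, b)
            )

    def test_deterministic(self):
        assert pairwise_align("ACGTAC", "AGTC") == pairwise_align("ACGTAC", "AGTC")


def random_matrix(n, seed):
    rng = np.random.default_rng(seed)
    d = rng.uniform(0, 1, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    return DistanceMatrix(ids=[f"s{i}" for i in range(n)], d=d)


class TestSubsetObjective:
    def test_sum_and_maximin_modes(self):
        m = DistanceMatrix(
            ids=["a", "b", "c"],
            d=np.array([[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]]),
        )
        assert subset_objective(["a", "b", "c"], m, "sum") == pytest.approx(1.5)
        assert subset_objective(["a", "b", "c"], m, "maximin") == pytest.approx(0.5)

    def test_singleton_and_duplicates_rejected(self):
        m = random_matrix(4, 0)
        with pytest.raises(ValueError):
            subset_objective(["s0"], m)
        with pytest.raises(ValueError):
            subset_objective(["s0", "s0"], m)


def independent_best_objective(m, k, mode="sum"):
    """Plain-python enumeration oracle, independent of the package path."""
    best = -1.0
    for combo in combinations(range(len(m.ids)), k):
        pairs = [m.d[i][j] for i, j in combinations(combo, 2)]
        obj = sum(pairs) if mode == "sum" else min(pairs)
        best = max(best, obj)
    return best


class TestAnnealSelect:
    def test_population_equal_to_k_returned_whole(self):
        m = random_matrix(4, 1)
        subset, trace = anneal_select(m, 4)
        assert sorted(subset) == sorted(m.ids)
        assert trace[-1] == pytest.approx(subset_objective(subset, m, "sum"))

    def test_k_larger_than_population_raises(self):
        with pytest.raises(ValueError):
            anneal_select(random_matrix(4, 1), 5)

    def test_same_seed_same_result(self):
        m = random_matrix(10, 2)
        sched = AnnealSchedule(seed=42)
        assert anneal_select(m, 3, sched) == anneal_select(m, 3, sched)

    def test_beats_random_subset(self):
        m = random_matrix(12, 3)
        rng = np.random.default_rng(0)
        random_subset = list(rng.choice(m.ids, size=4, replace=False))
        chosen, _ = anneal_select(m, 4, AnnealSchedule(seed=0))
        assert subset_objective(chosen, m) >= subset_objective(random_subset, m)

    @pytest.mark.parametrize("mode", ["sum", "maximin"])
    def test_reaches_brute_force_optimum_small(self, mode):
        for seed in range(5):
            m = random_matrix(8, seed)
            chosen, _ = anneal_select(m, 3, AnnealSchedule(seed=seed), mode)
            assert subset_objective(chosen, m, mode) == pytest.approx(
                independent_best_objective(m, 3, mode)
            )

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            AnnealSchedule(t_start=1.0, t_end=2.0)
        with pytest.raises(ValueError):
            AnnealSchedule(cooling=1.5)


class TestDistanceMatrix:
    def test_from_sequences_symmetric_zero_diagonal(self):
        m = DistanceMatrix.from_sequences(
            [("a", "ACGTACGT"), ("b", "ACGTTCGT"), ("c", "TTTTACGT")]
        )
        assert np.allclose(m.d, m.d.T)
        assert np.all(np.diag(m.d) == 0)
        assert m.d[0, 1] > 0

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(ids=["a", "b"], d=np.array([[0, 0.2], [0.3, 0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(ids=["a", "b"], d=np.array([[0, 2.0], [2.0, 0]]))
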