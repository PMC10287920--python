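import itertools

import numpy as np
import pytest

from snapcluster import (
    Partition,
    ValidationError,
    align_to_consensus,
    ari,
    consensus_objective,
    hard_euclidean_consensus,
    membership_matrix,
)


def _p(labels, k=None):
    labels = np.asarray(labels)
    return Partition(labels=labels, k=int(labels.max()) if k is None else k)


def _brute_force_objective(candidate: np.ndarray, bases: list[np.ndarray], k: int) -> int:
    """Independent oracle: permutation minimum by exhaustive enumeration."""
    total = 0
    for b in bases:
        best = None
        for perm in itertools.permutations(range(1, k + 1)):
            mapped = np.array([perm[v - 1] for v in b])
            d = 2 * int((mapped != candidate).sum())
            best = d if best is None else min(best, d)
        total += best
    return total


def _global_optimum(bases: list[np.ndarray], n: int, k: int) -> int:
    best = None
    for cand in itertools.product(range(1, k + 1), repeat=n):
        obj = _brute_force_objective(np.array(cand), bases, k)
        best = obj if best is None else min(best, obj)
    return best


class TestMembershipMatrix:
    def test_worked_example(self):
        m = membership_matrix(_p([1, 2, 1], k=2))
        np.testing.assert_array_equal(m, [[1, 0], [0, 1], [1, 0]])

    def test_row_sums_one_column_sums_class_sizes(self, rng):
        labels = rng.integers(1, 4, size=20)
        p = _p(labels, k=3)
        m = membership_matrix(p)
        assert (m.sum(axis=1) == 1).all()
        for j in range(3):
            assert m[:, j].sum() == (labels == j + 1).sum()


class TestAlign:
    def test_swapped_labels_restored(self):
        cons = _p([1, 1, 2, 2])
        base = _p([2, 2, 1, 1])
        aligned = align_to_consensus(base, cons)
        np.testing.assert_array_equal(aligned.labels, cons.labels)

    def test_identity_when_equal(self):
        p = _p([1, 2, 3, 1])
        aligned = align_to_consensus(p, p)
        np.testing.assert_array_equal(aligned.labels, p.labels)

    def test_matches_exhaustive_permutation_search(self, rng):
        k = 3
        for _ in range(20):
            base = _p(rng.integers(1, k + 1, size=8), k=k)
            cons = _p(rng.integers(1, k + 1, size=8), k=k)
            aligned = align_to_consensus(base, cons)
            agreement = int((aligned.labels == cons.labels).sum())
            best = max(
                int(
                    (
                        np.array([perm[v - 1] for v in base.labels])
                        == cons.labels
                    ).sum()
                )
                for perm in itertools.permutations(range(1, k + 1))
            )
            assert agreement == best

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            align_to_consensus(_p([1, 2]), _p([1, 2, 1]))


class TestObjective:
    def test_zero_when_candidate_equals_bases(self):
        p = _p([1, 2, 1, 2])
        assert consensus_objective(p, [p, p, p]) == 0.0

    def test_single_cell_disagreement_costs_two(self):
        cand = _p([1, 1, 2, 2])
        base = _p([1, 2, 2, 2], k=2)
        assert consensus_objective(cand, [base]) == 2.0

    def test_invariant_to_base_relabeling(self, rng):
        cand = _p(rng.integers(1, 4, size=10), k=3)
        base = rng.integers(1, 4, size=10)
        perm = {1: 3, 2: 1, 3: 2}
        relabeled = np.array([perm[v] for v in base])
        assert consensus_objective(cand, [_p(base, k=3)]) == consensus_objective(
            cand, [_p(relabeled, k=3)]
        )

    def test_empty_bases_rejected(self):
        with pytest.raises(ValidationError):
            consensus_objective(_p([1, 2]), [])


class TestFixedPoint:
    def test_identical_bases_returned_directly(self):
        p = _p([1, 2, 1, 2, 2])
        res = hard_euclidean_consensus([p, p, p], k=2, seed=0)
        assert res.objective == 0.0
        assert ari(res.partition.labels, p.labels) == pytest.approx(1.0)
        assert res.converged

    def test_label_permuted_copies_recovered(self):
        base = np.array([1, 1, 2, 2, 3, 3])
        perms = [{1: 2, 2: 3, 3: 1}, {1: 3, 2: 1, 3: 2}, {1: 1, 2: 2, 3: 3}]
        bases = [_p(np.array([p[v] for v in base]), k=3) for p in perms]
        res = hard_euclidean_consensus(bases, k=3, seed=0)
        assert res.objective == 0.0
        assert ari(res.partition.labels, base) == pytest.approx(1.0)

    def test_matches_brute_force_global_optimum_small(self, rng):
        n, k = 6, 2
        bases_arr = [rng.integers(1, k + 1, size=n) for _ in range(3)]
        bases = [_p(b, k=k) for b in bases_arr]
        res = hard_euclidean_consensus(bases, k=k, n_restarts=20, seed=1)
        assert res.objective == _global_optimum(bases_arr, n, k)

    def test_objective_traces_non_increasing(self, rng):
        for seed in range(5):
            bases = [
                _p(rng.integers(1, 4, size=15), k=3) for _ in range(4)
            ]
            res = hard_euclidean_consensus(bases, k=3, n_restarts=5, seed=seed)
            for trace in res.objective_traces:
                assert all(a >= b for a, b in zip(trace, trace[1:]))

    def test_consensus_no_worse_than_any_base(self, rng):
        bases = [_p(rng.integers(1, 4, size=20), k=3) for _ in range(5)]
        res = hard_euclidean_consensus(bases, k=3, n_restarts=5, seed=3)
        for b in bases:
            assert res.objective <= consensus_objective(b, bases)

    def test_class_permutation_equivariance(self, rng):
        # structured bases (noisy copies of one partition) have a unique
        # optimum, so the consensus must be identical up to relabeling
        truth = np.repeat([1, 2, 3], 8)
        bases_arr = []
        for i in range(3):  # disjoint corruptions: every cell keeps a 2-of-3 majority
            noisy = truth.copy()
            noisy[2 * i] = noisy[2 * i] % 3 + 1
            noisy[2 * i + 1] = noisy[2 * i + 1] % 3 + 1
            bases_arr.append(noisy)
        perm = {1: 2, 2: 3, 3: 1}
        bases = [_p(b, k=3) for b in bases_arr]
        permuted = [_p(np.array([perm[v] for v in b]), k=3) for b in bases_arr]
        r1 = hard_euclidean_consensus(bases, k=3, seed=5)
        r2 = hard_euclidean_consensus(permuted, k=3, seed=5)
        assert r1.objective == r2.objective
        assert ari(r1.partition.labels, r2.partition.labels) == pytest.approx(1.0)

    def test_random_bases_permutation_gives_equal_objective(self, rng):
        # with tied optima the partitions may differ, but never the objective
        bases_arr = [rng.integers(1, 4, size=12) for _ in range(4)]
        perm = {1: 2, 2: 3, 3: 1}
        bases = [_p(b, k=3) for b in bases_arr]
        permuted = [_p(np.array([perm[v] for v in b]), k=3) for b in bases_arr]
        r1 = hard_euclidean_consensus(bases, k=3, seed=5)
        r2 = hard_euclidean_consensus(permuted, k=3, seed=5)
        assert r1.objective == r2.objective

    def test_result_objective_is_recomputable(self, rng):
        bases = [_p(rng.integers(1, 3, size=10), k=2) for _ in range(3)]
        res = hard_euclidean_consensus(bases, k=2, seed=0)
        assert res.objective == consensus_objective(res.partition, bases)

    def test_empty_bases_rejected(self):
        with pytest.raises(ValidationError):
            hard_euclidean_consensus([], k=2, seed=0)
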