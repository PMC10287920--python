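"""Hard least-squares Euclidean consensus of an ensemble of partitions.

The consensus partition minimizes, over hard candidate partitions R,

    sum_b  min_perm  || M(R) - M(perm(base_b)) ||_F^2,

where M(.) is the binary cells x k membership matrix and the inner minimum
runs over class permutations. For hard partitions the permutation-matched
squared Frobenius distance equals twice the number of cells on which the
aligned labels disagree, so the objective is a (permutation-invariant)
misclassification count. It is minimized by fixed-point iteration:
align every base to the current candidate by optimal assignment on the
k x k contingency table (Hungarian algorithm), reassign each cell to the
majority class among aligned bases, and repeat until the labels stabilize.
Each restart's objective trace is non-increasing; the best restart wins.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import linear_sum_assignment

from ._errors import ValidationError
from .clustering import Partition

__all__ = [
    "ConsensusResult",
    "membership_matrix",
    "align_to_consensus",
    "consensus_objective",
    "hard_euclidean_consensus",
]


@dataclasses.dataclass
class ConsensusResult:
    partition: Partition
    objective: float
    n_iterations: int
    restarts_used: int
    converged: bool
    objective_traces: list[list[float]] = dataclasses.field(default_factory=list)


def membership_matrix(p: Partition) -> np.ndarray:
    """Binary cells x k matrix with exactly one 1 per row."""
    m = np.zeros((p.n_cells, p.k), dtype=int)
    m[np.arange(p.n_cells), p.labels - 1] = 1
    return m


def _contingency(a: np.ndarray, b: np.ndarray, k: int) -> np.ndarray:
    """k x k contingency table of two 1-based label vectors (padded to k)."""
    table = np.zeros((k, k), dtype=int)
    np.add.at(table, (a - 1, b - 1), 1)
    return table


def _optimal_mapping(base: Partition, consensus: Partition, k: int) -> np.ndarray:
    """Permutation mapping base classes -> consensus classes maximizing agreement."""
    table = _contingency(base.labels, consensus.labels, k)
    rows, cols = linear_sum_assignment(-table)
    mapping = np.empty(k, dtype=int)
    mapping[rows] = cols
    return mapping


def align_to_consensus(base: Partition, consensus: Partition) -> Partition:
    """Relabel ``base`` by the class permutation that maximizes agreement
    with ``consensus`` (exact optimal assignment on the contingency table)."""
    if base.n_cells != consensus.n_cells:
        raise ValidationError("partitions have different lengths")
    k = max(base.k, consensus.k)
    mapping = _optimal_mapping(base, consensus, k)
    return Partition(labels=mapping[base.labels - 1] + 1, k=k)


def _misassignment(base: Partition, candidate: Partition, k: int) -> int:
    """Cells where the optimally aligned base disagrees with the candidate."""
    table = _contingency(base.labels, candidate.labels, k)
    rows, cols = linear_sum_assignment(-table)
    return int(base.n_cells - table[rows, cols].sum())


def consensus_objective(candidate: Partition, bases: list[Partition]) -> float:
    """Total permutation-matched squared Euclidean membership distance.

    For hard partitions this equals 2x the total number of aligned-label
    disagreements over all bases.
    """
    if not bases:
        raise ValidationError("no base partitions")
    for b in bases:
        if b.n_cells != candidate.n_cells:
            raise ValidationError("base partition length mismatch")
    k = max([candidate.k] + [b.k for b in bases])
    cand = Partition(labels=candidate.labels, k=k)
    return float(2 * sum(_misassignment(b, cand, k) for b in bases))


def _vote_step(aligned: list[Partition], k: int) -> np.ndarray:
    """Majority vote per cell over aligned bases; ties -> lowest class index."""
    n = aligned[0].n_cells
    votes = np.zeros((n, k), dtype=int)
    rows = np.arange(n)
    for p in aligned:
        votes[rows, p.labels - 1] += 1
    return votes.argmax(axis=1) + 1  # argmax breaks ties at the lowest index


def hard_euclidean_consensus(
    bases: list[Partition],
    k: int,
    n_restarts: int = 5,
    max_iter: int = 100,
    seed: int = 0,
) -> ConsensusResult:
    """Fixed-point consensus over ``bases``, best of ``n_restarts`` starts.

    Restart 1 starts from the base with the lowest objective against all
    others; further restarts start from seeded uniform-random partitions.
    """
    if not bases:
        raise ValidationError("no base partitions")
    n = bases[0].n_cells
    for b in bases:
        if b.n_cells != n:
            raise ValidationError("base partitions have different lengths")
    if k < 1:
        raise ValidationError("k must be >= 1")
    if n_restarts < 1 or max_iter < 1:
        raise ValidationError("n_restarts and max_iter must be >= 1")

    kmax = max([k] + [b.k for b in bases])
    padded = [Partition(labels=b.labels, k=kmax) for b in bases]
    rng = np.random.default_rng(seed)

    best: tuple[float, Partition, int, bool] | None = None
    traces: list[list[float]] = []
    for restart in range(n_restarts):
        if restart == 0:
            objs = [consensus_objective(b, padded) for b in padded]
            candidate = padded[int(np.argmin(objs))]
            candidate = Partition(labels=candidate.labels.copy(), k=kmax)
        else:
            candidate = Partition(labels=rng.integers(1, k + 1, size=n), k=kmax)

        trace: list[float] = []
        converged = False
        iters = 0
        for _ in range(max_iter):
            iters += 1
            aligned = [align_to_consensus(b, candidate) for b in padded]
            new_labels = _vote_step(aligned, kmax)
            new_candidate = Partition(labels=new_labels, k=kmax)
            trace.append(consensus_objective(new_candidate, padded))
            if np.array_equal(new_labels, candidate.labels):
                converged = True
                candidate = new_candidate
                break
            candidate = new_candidate
        traces.append(trace)
        obj = trace[-1]
        if best is None or obj < best[0]:
            best = (obj, candidate, iters, converged)

    assert best is not None
    obj, candidate, iters, converged = best
    final = candidate.compact()
    return ConsensusResult(
        partition=final,
        objective=consensus_objective(final, padded),
        n_iterations=iters,
        restarts_used=n_restarts,
        converged=converged,
        objective_traces=traces,
    )
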