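"""Community structure of the group-average functional network.

Communities are found by maximising Newman-Girvan weighted modularity with
the Louvain algorithm. Because Louvain is stochastic, the decomposition is
repeated many times and the runs are summarised in an agreement matrix
(co-assignment frequency per node pair); iterating Louvain on the
thresholded agreement matrix until every run returns the same partition
yields the consensus partition (Lancichinetti-Fortunato scheme).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .errors import ConvergenceError, InputError
from .netbuild import ConnectivityMatrix, _as_array

__all__ = ["Partition", "modularity", "louvain", "agreement", "consensus"]


@dataclass
class Partition:
    """Node-to-community assignment with its modularity score.

    ``assignment`` holds 1-based integer labels, canonicalised so that
    communities are numbered by descending size (ties broken by smallest
    member node index).
    """

    assignment: np.ndarray
    q: float

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)

    @property
    def n_communities(self) -> int:
        return len(np.unique(self.assignment))

    def communities(self) -> dict[int, np.ndarray]:
        return {c: np.flatnonzero(self.assignment == c)
                for c in np.unique(self.assignment)}

    def sizes(self) -> dict[int, int]:
        labels, counts = np.unique(self.assignment, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


def canonical_labels(assignment: Sequence[int]) -> np.ndarray:
    """Renumber labels 1..K by descending community size, ties by first member."""
    assignment = np.asarray(assignment)
    labels = np.unique(assignment)
    order = sorted(labels,
                   key=lambda c: (-int(np.sum(assignment == c)),
                                  int(np.argmax(assignment == c))))
    remap = {old: new for new, old in enumerate(order, start=1)}
    return np.array([remap[a] for a in assignment], dtype=int)


def modularity(matrix, assignment: Sequence[int], gamma: float = 1.0) -> float:
    """Newman-Girvan weighted modularity of a partition.

    Q = sum_ij [A_ij/(2W) - gamma * k_i k_j / (2W)^2] * delta(c_i, c_j),
    with W the total edge weight (each undirected edge counted once) and
    k_i the weighted degree.
    """
    a = _as_array(matrix)
    if np.any(a < 0):
        raise InputError("modularity requires nonnegative weights")
    assignment = np.asarray(assignment)
    if assignment.shape[0] != a.shape[0]:
        raise InputError("assignment length does not match matrix size")
    two_w = a.sum()
    if two_w <= 0:
        raise InputError("modularity is undefined for a zero-weight graph")
    k = a.sum(axis=1)
    same = assignment[:, None] == assignment[None, :]
    return float(((a / two_w - gamma * np.outer(k, k) / two_w**2) * same).sum())


def louvain(matrix, gamma: float = 1.0, seed: int | None = None) -> Partition:
    """One Louvain run (seeded sweep order) returning a canonical Partition.

    The returned q is the modularity of the final assignment and is never
    below the trivial one-community partition's (which is exactly 0).
    """
    a = _as_array(matrix)
    if np.any(a < 0):
        raise InputError("louvain requires nonnegative weights")
    if a.sum() <= 0:
        raise InputError("louvain is undefined for a zero-weight graph")
    g = nx.from_numpy_array(a)
    communities = nx.community.louvain_communities(
        g, weight="weight", resolution=gamma, seed=seed)
    assignment = np.empty(a.shape[0], dtype=int)
    for label, nodes in enumerate(communities, start=1):
        for node in nodes:
            assignment[node] = label
    assignment = canonical_labels(assignment)
    q = modularity(a, assignment, gamma=gamma)
    if q < 0:  # never worse than the all-in-one partition
        assignment = np.ones(a.shape[0], dtype=int)
        q = 0.0
    return Partition(assignment, q)


def agreement(partitions: Sequence[Partition | Sequence[int]]) -> np.ndarray:
    """Co-assignment frequency matrix over a set of partitions of one node set."""
    if len(partitions) == 0:
        raise InputError("agreement needs at least one partition")
    arrays = [np.asarray(p.assignment if isinstance(p, Partition) else p)
              for p in partitions]
    n = arrays[0].shape[0]
    if any(a.shape[0] != n for a in arrays):
        raise InputError("partitions are over different node sets")
    acc = np.zeros((n, n))
    for a in arrays:
        acc += a[:, None] == a[None, :]
    acc /= len(arrays)
    np.fill_diagonal(acc, 1.0)
    return acc


def _all_identical(partitions: list[Partition]) -> bool:
    first = partitions[0].assignment
    return all(np.array_equal(p.assignment, first) for p in partitions[1:])


def consensus(agreement_matrix: np.ndarray, tau: float = 0.5, reps: int = 1000,
              seed: int | None = None, max_iter: int = 20,
              gamma: float = 1.0,
              modularity_matrix=None) -> Partition:
    """Consensus partition of an agreement matrix.

    Iterates: zero agreement entries below ``tau``, run Louvain ``reps``
    times on the thresholded matrix, rebuild the agreement — until every
    run returns the same partition (agreement entries all 0 or 1) or
    ``max_iter`` is reached. The returned q is the modularity of the stable
    partition on ``modularity_matrix`` when given (typically the thresholded
    group-average functional network), else on the input agreement matrix.
    """
    a = np.asarray(agreement_matrix, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise InputError("agreement matrix must be square")
    if np.any(a < 0) or np.any(a > 1):
        raise InputError("agreement entries must lie in [0, 1]")
    ss = np.random.SeedSequence(seed)
    current = a.copy()
    final: Partition | None = None
    for _ in range(max_iter):
        thresholded = current.copy()
        thresholded[thresholded < tau] = 0.0
        np.fill_diagonal(thresholded, 0.0)
        if thresholded.sum() == 0:
            # every pair below tau: all-singleton partition is the fixed point
            final = Partition(np.arange(1, a.shape[0] + 1), 0.0)
            break
        child_seeds = [int(s.generate_state(1)[0]) % (2**31) for s in ss.spawn(reps)]
        runs = [louvain(thresholded, gamma=gamma, seed=s) for s in child_seeds]
        if _all_identical(runs):
            final = runs[0]
            break
        current = agreement(runs)
    if final is None:
        raise ConvergenceError(
            f"consensus did not stabilise in {max_iter} iterations; "
            "consider a higher tau")
    q_source = modularity_matrix if modularity_matrix is not None else a
    q = modularity(q_source, final.assignment, gamma=gamma)
    return Partition(canonical_labels(final.assignment), q)
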