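"""Shared search-tree machinery for the branch-and-bound PDP solvers.

Every solver explores the same solution tree.  A node at level ``k`` is a
pair ``(X, Dres)``: a partial point set ``X`` of ``k + 2`` coordinates and
the residual distance pool ``Dres = D \\ ΔX`` (an invariant that holds at
every node of the tree and is what makes nodes with equal ``X``
interchangeable).  The root is ``X = {0, width}``, ``Dres = D \\ {width}``.

A node expands into at most two children: the largest residual distance
``y = max(Dres)`` must be realised by a point at coordinate ``y`` or at
``width - y``, and a candidate survives only if its distances to all placed
points are available in the residual pool (the bounding condition
``Δ(y, X) ⊆ Dres``).  A child whose residual pool is empty is a complete
solution.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Iterator, Optional

from .multisets import (
    DistanceMultiset,
    PDPError,
    PDPInstance,
    delta_set,
)


class LimitExceeded(PDPError):
    """A solver hit a configured resource limit before exhausting the tree.

    The ``result`` attribute carries the partial SolutionSet accumulated so
    far, with ``stats.complete = False``.
    """

    def __init__(self, message: str, result: Optional["SolutionSet"] = None):
        super().__init__(message)
        self.result = result


@dataclass(frozen=True)
class SolverLimits:
    """Optional resource caps; ``None`` means unlimited.

    max_nodes     cap on total node expansions
    max_frontier  cap on the size of any single BFS frontier (BFS solvers)
    max_seconds   wall-clock cap
    """

    max_nodes: Optional[int] = None
    max_frontier: Optional[int] = None
    max_seconds: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("max_nodes", "max_frontier", "max_seconds"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when finite, got {v}")


UNLIMITED = SolverLimits()


@dataclass
class SolveStats:
    """Search-effort instrumentation.

    Effort is reported as node counts and frontier sizes rather than
    wall-clock time or OS memory, so runs are comparable across machines.
    ``nodes_per_level[k]`` counts nodes processed at tree level k (the root
    is level 0); ``peak_frontier`` is the largest number of nodes held
    simultaneously; ``dedup_hits`` counts children discarded because an
    equal partial point set was already present at their level.
    """

    algorithm: str
    nodes_per_level: dict[int, int] = field(default_factory=dict)
    total_nodes: int = 0
    peak_frontier: int = 0
    dedup_hits: int = 0
    levels_completed: int = 0
    complete: bool = True

    def count_node(self, level: int) -> None:
        self.nodes_per_level[level] = self.nodes_per_level.get(level, 0) + 1
        self.total_nodes += 1

    def observe_frontier(self, size: int) -> None:
        if size > self.peak_frontier:
            self.peak_frontier = size


@dataclass
class SolutionSet:
    """All distinct point sets X with ΔX = D, plus search statistics.

    Solutions are stored as ascending tuples of coordinates, sorted
    lexicographically; every member is verified against the instance before
    being reported.
    """

    solutions: list[tuple[int, ...]]
    stats: SolveStats

    def __contains__(self, X) -> bool:
        return tuple(sorted(X)) in set(self.solutions)

    def __len__(self) -> int:
        return len(self.solutions)


@dataclass
class SearchNode:
    """A subproblem (X, Dres) at one level of the solution tree."""

    level: int
    X: tuple[int, ...]  # ascending coordinates, len == level + 2
    Dres: DistanceMultiset

    def is_solution(self) -> bool:
        return len(self.Dres) == 0


def make_root(instance: PDPInstance) -> SearchNode:
    """Root node: X = {0, width}, Dres = D \\ {width}."""
    width = instance.width
    return SearchNode(
        level=0,
        X=(0, width),
        Dres=instance.D.difference(DistanceMultiset([width])),
    )


def expand(node: SearchNode, width: int) -> Iterator[SearchNode]:
    """Yield the (at most two) feasible children of a node.

    The y-candidate is yielded before the (width - y)-candidate; when the
    two coincide (y == width - y) a single child is produced, since both
    branches would be the identical state.
    """
    dres = node.Dres
    y = dres.max()
    candidates = (y,) if y == width - y else (y, width - y)
    X = node.X
    for cand in candidates:
        # bounding condition: Δ(cand, X) ⊆ Dres, checked incrementally
        # against a working copy of the residual counts
        counts = dict(dres._counts)  # noqa: SLF001 - hot path within the package
        ok = True
        for x in X:
            d = abs(cand - x)
            c = counts.get(d, 0)
            if c == 0:
                ok = False
                break
            if c == 1:
                del counts[d]
            else:
                counts[d] = c - 1
        if not ok:
            continue
        assert cand not in X, "candidate duplicates an existing point"
        child_D = DistanceMultiset.__new__(DistanceMultiset)
        child_D._counts = counts
        child_D._size = len(dres) - len(X)
        yield SearchNode(level=node.level + 1, X=_insert(X, cand), Dres=child_D)


def _insert(X: tuple[int, ...], y: int) -> tuple[int, ...]:
    """Insert y into the ascending tuple X, keeping order."""
    for i, x in enumerate(X):
        if y < x:
            return X[:i] + (y,) + X[i:]
    return X + (y,)


def check_node_invariant(node: SearchNode, instance: PDPInstance) -> None:
    """Assert Dres = D \\ ΔX, the defining invariant of every tree node."""
    expected = instance.D.difference(delta_set(node.X))
    if node.Dres != expected:
        raise AssertionError(
            f"node invariant violated at level {node.level}: X={node.X}"
        )


class _Deadline:
    """Tracks max_seconds / max_nodes limits for a running solve."""

    def __init__(self, limits: SolverLimits):
        self.limits = limits
        self.start = time.monotonic()

    def check(self, stats: SolveStats) -> Optional[str]:
        lim = self.limits
        if lim.max_nodes is not None and stats.total_nodes > lim.max_nodes:
            return f"node budget exceeded ({stats.total_nodes} > {lim.max_nodes})"
        if lim.max_seconds is not None and time.monotonic() - self.start > lim.max_seconds:
            return f"time budget exceeded (> {lim.max_seconds}s)"
        return None


def verify_solution(X: tuple[int, ...], instance: PDPInstance) -> bool:
    """True iff ΔX equals the instance multiset exactly."""
    return delta_set(X) == instance.D


def finalize(
    solutions: list[tuple[int, ...]],
    stats: SolveStats,
    instance: PDPInstance,
) -> SolutionSet:
    """Deduplicate, verify and sort solutions into a SolutionSet."""
    distinct = sorted(set(solutions))
    for X in distinct:
        if not verify_solution(X, instance):
            raise AssertionError(f"reported solution {X} does not reproduce D")
    return SolutionSet(solutions=distinct, stats=stats)
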