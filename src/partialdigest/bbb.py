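"""Breadth-first PDP solver with within-level duplicate elimination (BBb).

The solution tree is expanded level by level.  Because every node satisfies
Dres = D \\ ΔX, two nodes at the same level with equal partial point sets X
are fully identical subproblems, so only the first is kept — the
deduplication that makes breadth-first search dramatically faster than the
depth-first baseline on inputs with many coincident distances.

The frontier is deduplicated with a per-level hash table keyed on the
ascending coordinate tuple X alone (Dres is determined by X, so it is
excluded from the key); the observable behaviour matches a list-membership
test on the partial point sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

from .multisets import PDPInstance
from .search import (
    LimitExceeded,
    SearchNode,
    SolutionSet,
    SolveStats,
    SolverLimits,
    UNLIMITED,
    _Deadline,
    check_node_invariant,
    expand,
    finalize,
    make_root,
)


@dataclass
class LevelFrontier:
    """All nodes of one level of the solution tree, in insertion order."""

    level: int
    entries: list[SearchNode] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)


def generate_next_level(
    frontier: LevelFrontier,
    instance: PDPInstance,
    limits: SolverLimits = UNLIMITED,
    solutions: Optional[list[tuple[int, ...]]] = None,
    stats: Optional[SolveStats] = None,
    deadline: Optional[_Deadline] = None,
    check_invariants: bool = False,
    node_hook: Optional[Callable[[SearchNode], None]] = None,
) -> LevelFrontier:
    """Expand one BFS level into the next, deduplicating children.

    Entries whose residual pool is empty are complete solutions: they are
    appended to ``solutions`` instead of being expanded.  Every other entry
    contributes at most two children; a child is added to the next frontier
    only if no node with the same partial point set is already there.
    """
    if solutions is None:
        solutions = []
    if stats is None:
        stats = SolveStats(algorithm="bbb")
    if deadline is None:
        deadline = _Deadline(limits)

    width = instance.width
    next_entries: list[SearchNode] = []
    seen: dict[tuple[int, ...], SearchNode] = {}

    for node in frontier.entries:
        stats.count_node(node.level)
        if check_invariants:
            check_node_invariant(node, instance)
        if node_hook is not None:
            node_hook(node)
        msg = deadline.check(stats)
        if msg is not None:
            partial = finalize(solutions, stats, instance)
            partial.stats.complete = False
            raise LimitExceeded(msg, result=partial)
        if node.is_solution():
            solutions.append(node.X)
            continue
        for child in expand(node, width):
            kept = seen.get(child.X)
            if kept is not None:
                if check_invariants and kept.Dres != child.Dres:
                    raise AssertionError(
                        "duplicate partial point sets with unequal residual "
                        f"pools at level {child.level}: X={child.X}"
                    )
                stats.dedup_hits += 1
                continue
            seen[child.X] = child
            next_entries.append(child)
            if limits.max_frontier is not None and len(next_entries) > limits.max_frontier:
                partial = finalize(solutions, stats, instance)
                partial.stats.complete = False
                raise LimitExceeded(
                    f"frontier budget exceeded ({len(next_entries)} > "
                    f"{limits.max_frontier}) at level {frontier.level + 1}",
                    result=partial,
                )

    stats.levels_completed = frontier.level + 1
    stats.observe_frontier(len(next_entries))
    return LevelFrontier(level=frontier.level + 1, entries=next_entries)


def solve_bbb(
    instance: PDPInstance,
    limits: SolverLimits = UNLIMITED,
    check_invariants: bool = False,
    node_hook: Optional[Callable[[SearchNode], None]] = None,
) -> SolutionSet:
    """Solve a PDP instance breadth-first with per-level deduplication.

    Returns every distinct solution; raises :class:`LimitExceeded` (with
    the partial result attached) if a node, frontier or time budget is hit.
    """
    stats = SolveStats(algorithm="bbb")
    deadline = _Deadline(limits)
    solutions: list[tuple[int, ...]] = []

    frontier = LevelFrontier(level=0, entries=[make_root(instance)])
    stats.observe_frontier(1)
    while frontier.entries:
        frontier = generate_next_level(
            frontier,
            instance,
            limits=limits,
            solutions=solutions,
            stats=stats,
            deadline=deadline,
            check_invariants=check_invariants,
            node_hook=node_hook,
        )

    return finalize(solutions, stats, instance)
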