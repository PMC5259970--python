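"""Depth-first branch-and-bound PDP solver (the classical baseline).

This is the Skiena-style "place the largest unexplained distance" search:
starting from X = {0, width}, repeatedly take y = max(Dres) and try to
place a point at coordinate y or at width - y, pruning candidates whose
distances to the placed points are not all present in the residual pool.
The traversal is depth-first (y-branch before the width - y branch) and
performs no subproblem deduplication, so identical subtrees reached along
different paths are each explored in full — the behaviour the breadth-first
solvers improve on.  The final reported solution set is deduplicated.

The recursion is realised with an explicit stack: restriction maps with
thousands of sites would otherwise exceed the interpreter call-stack depth.
"""

from __future__ import annotations

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


def solve_bbd(
    instance: PDPInstance,
    limits: SolverLimits = UNLIMITED,
    check_invariants: bool = False,
    node_hook: Optional[Callable[[SearchNode], None]] = None,
) -> SolutionSet:
    """Exhaustively solve a PDP instance by depth-first branch and bound.

    Parameters
    ----------
    instance
        A validated instance (see :func:`partialdigest.validate_instance`).
    limits
        Optional caps on nodes expanded / wall-clock time; hitting one
        raises :class:`LimitExceeded` carrying the partial result.
    check_invariants
        When true, assert Dres = D \\ ΔX at every node (slow; for tests).
    node_hook
        Optional callback invoked with every processed node.

    Returns
    -------
    SolutionSet
        Every distinct point set X with ΔX = D, search stats attached.
    """
    stats = SolveStats(algorithm="bbd")
    deadline = _Deadline(limits)
    solutions: list[tuple[int, ...]] = []

    root = make_root(instance)
    if instance.n == 2:
        # the root already places both extreme points
        stats.count_node(0)
        stats.observe_frontier(1)
        return finalize([root.X], stats, instance)

    stack = [root]
    width = instance.width
    while stack:
        stats.observe_frontier(len(stack))
        node = stack.pop()
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
        # push in reverse so the y-branch is explored first
        for child in reversed(list(expand(node, width))):
            stack.append(child)

    return finalize(solutions, stats, instance)
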