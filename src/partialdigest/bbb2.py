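"""Two-stage breadth-first PDP solver with memory-balanced split (BBb2).

Pure breadth-first search holds an entire level in memory at once, and the
widest level of the worst-case solution tree for n points has ~2^n nodes.
BBb2 caps this by splitting the search at a level α: stage 1 runs the
deduplicating breadth-first solver down to level α; stage 2 then expands
each level-α node as an independent breadth-first search to completion,
freeing each subtree's frontier before starting the next.  The worst-case
number of simultaneously held nodes is then 2^α + 2^(n-α) (times the O(n²)
per-node payload), minimised by choosing α near n/2.

``find_alpha_m`` computes the minimising split level with exact integer
arithmetic — for maps with thousands of sites, 2^n vastly exceeds any
float, so the memory scores are compared as big integers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

from .bbb import LevelFrontier, generate_next_level
from .multisets import PDPInstance, points_from_pair_count
from .search import (
    SearchNode,
    SolutionSet,
    SolveStats,
    SolverLimits,
    UNLIMITED,
    _Deadline,
    finalize,
    make_root,
)


@dataclass(frozen=True)
class AlphaPlan:
    """The chosen split level and its worst-case memory score.

    m_min is exactly n²(2^alpha_m + 2^(n-alpha_m)).
    """

    n: int
    alpha_m: int
    m_min: int


def find_alpha_m(N: int) -> AlphaPlan:
    """Choose the split level minimising worst-case memory n²(2^α + 2^(n-α)).

    N is the instance size |D|; n is recovered from n(n-1)/2 = N.  The scan
    runs α = 1..n, keeping the first α attaining each strict improvement,
    so ties resolve to the smaller split level (n/2 for even n, (n-1)/2 for
    odd n).
    """
    n = points_from_pair_count(N)
    alpha_m = 1
    m_min = n * n * (2**1 + 2 ** (n - 1))
    for alpha in range(2, n + 1):
        m = n * n * (2**alpha + 2 ** (n - alpha))
        if m < m_min:
            m_min = m
            alpha_m = alpha
    return AlphaPlan(n=n, alpha_m=alpha_m, m_min=m_min)


def solve_bbb2(
    instance: PDPInstance,
    limits: SolverLimits = UNLIMITED,
    alpha: Optional[int] = None,
    check_invariants: bool = False,
    node_hook: Optional[Callable[[SearchNode], None]] = None,
) -> SolutionSet:
    """Solve a PDP instance with the two-stage breadth-first strategy.

    Parameters
    ----------
    instance
        A validated instance.
    alpha
        Split level override; defaults to ``find_alpha_m(N).alpha_m``.
    check_invariants, node_hook, limits
        As for the other solvers.

    Notes
    -----
    Duplicate subproblems are removed within stage 1 and within each
    stage-2 subtree, but not across subtrees; solutions reached through
    different subtrees are therefore deduplicated once more before being
    reported.  ``stats.peak_frontier`` counts the largest number of nodes
    resident at once: during stage 2 that is the retained level-α frontier
    plus the current subtree's frontier.
    """
    if alpha is None:
        alpha = find_alpha_m(instance.N).alpha_m
    if alpha < 1:
        raise ValueError(f"alpha must be >= 1, got {alpha}")

    stats = SolveStats(algorithm="bbb2")
    deadline = _Deadline(limits)
    solutions: list[tuple[int, ...]] = []

    # stage 1: breadth-first with dedup down to level alpha (or exhaustion)
    frontier = LevelFrontier(level=0, entries=[make_root(instance)])
    stats.observe_frontier(1)
    while frontier.entries and frontier.level < alpha:
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

    # stage 2: expand each surviving level-alpha node independently
    retained = len(frontier.entries)
    for seed_node in frontier.entries:
        sub = LevelFrontier(level=seed_node.level, entries=[seed_node])
        while sub.entries:
            sub = generate_next_level(
                sub,
                instance,
                limits=limits,
                solutions=solutions,
                stats=stats,
                deadline=deadline,
                check_invariants=check_invariants,
                node_hook=node_hook,
            )
            stats.observe_frontier(retained + len(sub.entries))

    return finalize(solutions, stats, instance)
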