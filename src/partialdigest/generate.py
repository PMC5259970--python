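"""Synthetic PDP instance generators.

Two families, mirroring the standard benchmarks for partial-digest solvers:

* **Random instances (RD)** — the average case.  n points are scattered
  uniformly in [0, M]: the set X is {0} plus n-1 distinct integers drawn
  without replacement from 1..M, and the instance is D = ΔX.  Anchoring at
  0 makes round-trip checks exact, since solver output is itself anchored
  at 0 (the problem is translation-invariant).

* **Zhang instances (ZD)** — the adversarial worst case.  Five arithmetic
  blocks of n coordinates each are packed symmetrically into an interval
  so that huge numbers of distance coincidences arise; depth-first
  branch-and-bound is forced into exponentially many identical subtrees,
  while the deduplicating breadth-first solvers collapse them.  The
  classical construction lives in the real unit interval; here the
  interval is scaled to an integer width W with an integer spacing ε
  satisfying 12·n·ε < W, which keeps all five blocks (plus the endpoints)
  pairwise disjoint.

Both generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .multisets import DistanceMultiset, PDPError, delta_set


class InfeasibleParams(PDPError):
    """Generator parameters cannot yield a valid instance."""


@dataclass(frozen=True)
class RandomInstanceParams:
    """Average-case generator parameters.

    n     number of points (>= 2)
    M     maximum coordinate; benchmark practice sets M = n*q with
          q in {10, 100, 1000, 10000} (small q => many coincident
          distances, the regime where deduplication pays off)
    seed  RNG seed
    """

    n: int
    M: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InfeasibleParams(f"need n >= 2, got {self.n}")
        if self.M < self.n - 1:
            raise InfeasibleParams(
                f"M = {self.M} leaves no room for {self.n - 1} distinct "
                f"positive coordinates"
            )


def generate_random_instance(
    params: RandomInstanceParams,
) -> tuple[tuple[int, ...], DistanceMultiset]:
    """Draw X = {0} ∪ (n-1 distinct integers from 1..M); return (X, ΔX)."""
    rng = random.Random(params.seed)
    body = rng.sample(range(1, params.M + 1), params.n - 1)
    X = tuple(sorted([0, *body]))
    return X, delta_set(X)


@dataclass(frozen=True)
class ZhangInstanceParams:
    """Worst-case generator parameters.

    n      block size; the generated point set has exactly 5n + 2 points
    scale  integer width W of the scaled unit interval (default 1000 per
           point: W = (5n + 2) * 1000)
    eps    integer block spacing ε; must satisfy 0 < 12·n·ε < W
           (default: the largest ε meeting the bound)
    seed   seed for the random left/right split of the middle block
    """

    n: int
    scale: int = 0
    eps: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InfeasibleParams(f"need n >= 1, got {self.n}")
        if self.scale == 0:
            object.__setattr__(self, "scale", (5 * self.n + 2) * 1000)
        if self.eps == 0:
            object.__setattr__(self, "eps", max(1, (self.scale - 1) // (12 * self.n)))
        if not 0 < 12 * self.n * self.eps < self.scale:
            raise InfeasibleParams(
                f"need 0 < 12*n*eps < scale, got 12*{self.n}*{self.eps} "
                f"vs scale {self.scale}"
            )


def generate_zhang_instance(
    params: ZhangInstanceParams,
) -> tuple[tuple[int, ...], DistanceMultiset]:
    """Build a 5n+2-point adversarial instance; return (A, ΔA).

    With W the scaled interval width and ε the spacing, the blocks are

        A1 = {W - iε : i = 1..n}          (just below the right end)
        A2 = {iε : i = 1..n}              (just above the left end)
        A3 = {(n+i)ε : i = 1..n}          (middle block, see below)
        A4 = {(2n+i)ε : i = 1..n}
        A5 = {W - iε : i = 2n+1..3n}

    Each middle-block coordinate a ∈ A3 is kept as-is or reflected to
    W - a by a seeded fair coin — every such left/right split produces the
    same difficulty, which is exactly what makes these instances hard: the
    distance multiset cannot tell the choices apart locally.  The returned
    point set is A1 ∪ A2 ∪ A4 ∪ A5 ∪ (split A3) ∪ {0, W}.
    """
    n, W, eps = params.n, params.scale, params.eps
    rng = random.Random(params.seed)

    a1 = [W - i * eps for i in range(n, 0, -1)]
    a2 = [i * eps for i in range(1, n + 1)]
    a3 = [(n + i) * eps for i in range(1, n + 1)]
    a4 = [(2 * n + i) * eps for i in range(1, n + 1)]
    a5 = [W - i * eps for i in range(3 * n, 2 * n, -1)]

    middle = [a if rng.random() < 0.5 else W - a for a in a3]

    points = {0, W, *a1, *a2, *a4, *a5, *middle}
    if len(points) != 5 * n + 2:
        raise InfeasibleParams(
            f"blocks are not pairwise disjoint for n={n}, scale={W}, "
            f"eps={eps}: got {len(points)} distinct points, expected {5 * n + 2}"
        )
    A = tuple(sorted(points))
    return A, delta_set(A)
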