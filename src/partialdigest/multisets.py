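"""Exact integer multiset algebra for distance sets.

The partial digest problem (PDP) asks: given the multiset ``D`` of all
``n(n-1)/2`` pairwise distances between ``n`` points on a line, reconstruct
every point set ``X`` with difference set ``ΔX = D``.  Everything in the
solvers reduces to a handful of exact operations on integer multisets —
difference, disjoint union, the single-point difference operator
``Δ(y, X)`` and the all-pairs operator ``ΔX`` — which live here,
together with instance validation.

Multisets are represented as a mapping ``distance -> multiplicity`` with
exact integer arithmetic, so difference/union are O(1) per distinct value
and equality is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping


class PDPError(Exception):
    """Base class for all errors raised by this package."""


class NonTriangularSize(PDPError):
    """The multiset size is not n(n-1)/2 for any integer n >= 2."""


class NonPositiveDistance(PDPError):
    """An instance distance is zero or negative."""


class DistanceMultiset:
    """A multiset of non-negative integer distances.

    Stores a ``value -> multiplicity`` mapping.  Instances are treated as
    immutable by all public code paths; operations return new multisets.
    Equality is exact equality of the count mappings.
    """

    __slots__ = ("_counts", "_size")

    def __init__(self, elements: Iterable[int] = ()):
        counts: dict[int, int] = {}
        size = 0
        for x in elements:
            if not isinstance(x, int) or isinstance(x, bool):
                raise TypeError(f"distances must be integers, got {x!r}")
            if x < 0:
                raise ValueError(f"distances must be >= 0, got {x}")
            counts[x] = counts.get(x, 0) + 1
            size += 1
        self._counts = counts
        self._size = size

    @classmethod
    def from_counts(cls, counts: Mapping[int, int]) -> "DistanceMultiset":
        """Build directly from a value -> multiplicity mapping."""
        ms = cls.__new__(cls)
        clean: dict[int, int] = {}
        size = 0
        for x, c in counts.items():
            if not isinstance(x, int) or isinstance(x, bool):
                raise TypeError(f"distances must be integers, got {x!r}")
            if x < 0:
                raise ValueError(f"distances must be >= 0, got {x}")
            if not isinstance(c, int) or c < 1:
                raise ValueError(f"multiplicity of {x} must be a positive integer, got {c!r}")
            clean[x] = c
            size += c
        ms._counts = clean
        ms._size = size
        return ms

    # -- inspection ---------------------------------------------------------

    @property
    def counts(self) -> Mapping[int, int]:
        return dict(self._counts)

    def count(self, x: int) -> int:
        """Multiplicity C(D, x); 0 when x is absent."""
        return self._counts.get(x, 0)

    def __len__(self) -> int:
        return self._size

    def __bool__(self) -> bool:
        return self._size > 0

    def __contains__(self, x: int) -> bool:
        return x in self._counts

    def __iter__(self) -> Iterator[int]:
        """Iterate elements with multiplicity, in ascending order."""
        for x in sorted(self._counts):
            for _ in range(self._counts[x]):
                yield x

    def max(self) -> int:
        if not self._counts:
            raise ValueError("max() of empty multiset")
        return max(self._counts)

    def to_sorted_list(self) -> list[int]:
        return list(self)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DistanceMultiset):
            return NotImplemented
        return self._counts == other._counts

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __repr__(self) -> str:
        if self._size <= 30:
            return f"DistanceMultiset({self.to_sorted_list()})"
        return f"DistanceMultiset(<{self._size} elements>)"

    # -- algebra ------------------------------------------------------------

    def difference(self, other: "DistanceMultiset") -> "DistanceMultiset":
        """Multiset difference D \\ L with counts clamped at zero.

        The result contains x with multiplicity max(C(D,x) - C(L,x), 0);
        L need not be a sub-multiset of D.
        """
        counts: dict[int, int] = {}
        size = 0
        ocounts = other._counts
        for x, c in self._counts.items():
            r = c - ocounts.get(x, 0)
            if r > 0:
                counts[x] = r
                size += r
        ms = DistanceMultiset.__new__(DistanceMultiset)
        ms._counts = counts
        ms._size = size
        return ms

    def disjoint_union(self, other: "DistanceMultiset") -> "DistanceMultiset":
        """Multiset sum D ∪+ L: multiplicities add."""
        counts = dict(self._counts)
        for x, c in other._counts.items():
            counts[x] = counts.get(x, 0) + c
        ms = DistanceMultiset.__new__(DistanceMultiset)
        ms._counts = counts
        ms._size = self._size + other._size
        return ms

    def is_submultiset(self, other: "DistanceMultiset") -> bool:
        """True iff C(self, x) <= C(other, x) for every x."""
        ocounts = other._counts
        for x, c in self._counts.items():
            if c > ocounts.get(x, 0):
                return False
        return True


def multiset_difference(D: DistanceMultiset, L: DistanceMultiset) -> DistanceMultiset:
    """D \\ L (counts clamp at zero)."""
    return D.difference(L)


def disjoint_union(D: DistanceMultiset, L: DistanceMultiset) -> DistanceMultiset:
    """D ∪+ L (counts add)."""
    return D.disjoint_union(L)


def is_submultiset(L: DistanceMultiset, D: DistanceMultiset) -> bool:
    """True iff L ⊆ D as multisets."""
    return L.is_submultiset(D)


def delta_point(y: int, X: Iterable[int]) -> DistanceMultiset:
    """Δ(y, X) = {|y - x| : x in X}, with multiplicity.

    May contain 0 when y is itself a point of X; the solvers never place a
    duplicate point, so a 0 can never survive the feasibility test against a
    residual pool of positive distances.
    """
    if y < 0:
        raise ValueError("y must be >= 0")
    return DistanceMultiset(abs(y - x) for x in X)


def delta_set(X: Iterable[int]) -> DistanceMultiset:
    """ΔX: the multiset of all |x_j - x_i| over unordered pairs of X.

    X must contain pairwise-distinct non-negative integers; the result has
    exactly |X|(|X|-1)/2 elements counted with multiplicity.
    """
    pts = sorted(X)
    if len(set(pts)) != len(pts):
        raise ValueError("point set contains duplicate coordinates")
    counts: dict[int, int] = {}
    n = len(pts)
    for i in range(n):
        xi = pts[i]
        for j in range(i + 1, n):
            d = pts[j] - xi
            counts[d] = counts.get(d, 0) + 1
    ms = DistanceMultiset.__new__(DistanceMultiset)
    ms._counts = counts
    ms._size = n * (n - 1) // 2
    return ms


@dataclass(frozen=True)
class PDPInstance:
    """A validated PDP instance.

    Attributes
    ----------
    D : DistanceMultiset
        The input distance multiset.
    N : int
        ``len(D)``, necessarily triangular: N = n(n-1)/2.
    n : int
        The number of points any solution must have.
    width : int
        max(D); the distance between the two extreme points, i.e. the
        molecule length in the restriction-mapping reading of the problem.
    """

    D: DistanceMultiset
    N: int
    n: int
    width: int


def points_from_pair_count(N: int) -> int:
    """Invert N = n(n-1)/2 exactly, raising NonTriangularSize otherwise.

    Uses integer arithmetic (math.isqrt) so that very large N — e.g. the
    1,999,000 fragments of a 2000-site digest — cannot be mis-rounded.
    """
    if N < 1:
        raise NonTriangularSize(f"multiset size must be >= 1, got {N}")
    # n = (1 + sqrt(1 + 8N)) / 2, then verify exactly
    s = math.isqrt(1 + 8 * N)
    n = (1 + s) // 2
    for cand in (n - 1, n, n + 1):
        if cand >= 2 and cand * (cand - 1) // 2 == N:
            return cand
    raise NonTriangularSize(f"{N} is not n(n-1)/2 for any integer n >= 2")


def validate_instance(D: DistanceMultiset) -> PDPInstance:
    """Check that D is a well-formed PDP input and derive (N, n, width).

    Raises NonPositiveDistance if any element is <= 0 and NonTriangularSize
    if |D| is not a triangular number.
    """
    if len(D) == 0:
        raise NonTriangularSize("empty multiset is not a PDP instance")
    if 0 in D:
        raise NonPositiveDistance("instance distances must be positive (found 0)")
    N = len(D)
    n = points_from_pair_count(N)
    return PDPInstance(D=D, N=N, n=n, width=D.max())
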