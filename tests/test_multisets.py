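"""Multiset algebra: worked examples plus algebraic property tests."""

from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

from partialdigest import (
    DistanceMultiset,
    NonPositiveDistance,
    NonTriangularSize,
    delta_point,
    delta_set,
    disjoint_union,
    is_submultiset,
    multiset_difference,
    points_from_pair_count,
    validate_instance,
)
from partialdigest.datasets import LUCIFERASE_TAQI_D, WORKED_EXAMPLE_D


def ms(*xs: int) -> DistanceMultiset:
    return DistanceMultiset(xs)


small_multisets = st.lists(st.integers(min_value=0, max_value=12), max_size=12).map(
    DistanceMultiset
)


class TestDifference:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (WORKED_EXAMPLE_D, (10,), (1, 2, 2, 3, 5, 6, 7, 8, 8)),
            (WORKED_EXAMPLE_D, (), WORKED_EXAMPLE_D),
            (WORKED_EXAMPLE_D, WORKED_EXAMPLE_D, ()),
            ((2, 2, 3), (2, 5), (2, 3)),
        ],
    )
    def test_examples(self, a, b, expected):
        assert multiset_difference(ms(*a), ms(*b)) == ms(*expected)

    def test_counts_clamp_at_zero(self):
        # subtracting more copies than present removes the value entirely
        assert multiset_difference(ms(4), ms(4, 4, 4)) == ms()

    @given(small_multisets, small_multisets, small_multisets)
    @settings(max_examples=200, derandomize=True)
    def test_difference_of_union_associates(self, D, L, Z):
        """(D \\ L) \\ Z = D \\ (L ∪+ Z), checked against a Counter model."""
        lhs = multiset_difference(multiset_difference(D, L), Z)
        rhs = multiset_difference(D, disjoint_union(L, Z))
        assert lhs == rhs
        model = Counter(dict(D.counts))
        model.subtract(Counter(dict(L.counts)))
        model.subtract(Counter(dict(Z.counts)))
        assert dict(lhs.counts) == {x: c for x, c in model.items() if c > 0}


class TestUnion:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((), (7,), (7,)),
            ((2,), (2,), (2, 2)),
            ((1, 3), (3, 5), (1, 3, 3, 5)),
        ],
    )
    def test_examples(self, a, b, expected):
        assert disjoint_union(ms(*a), ms(*b)) == ms(*expected)


class TestDeltaOperators:
    @pytest.mark.parametrize(
        "y, X, expected",
        [
            (8, (0, 10), (2, 8)),
            (5, (5,), (0,)),
            (0, (0, 2, 8, 10), (0, 2, 8, 10)),
        ],
    )
    def test_delta_point(self, y, X, expected):
        assert delta_point(y, X) == ms(*expected)

    @pytest.mark.parametrize(
        "X, expected",
        [
            ((0, 2, 7, 8, 10), WORKED_EXAMPLE_D),
            ((0, 30, 975, 984, 1277, 1377, 1839, 2009), LUCIFERASE_TAQI_D),
            ((0, 42), (42,)),
        ],
    )
    def test_delta_set(self, X, expected):
        assert delta_set(X) == ms(*expected)

    def test_delta_set_rejects_duplicates(self):
        with pytest.raises(ValueError):
            delta_set((0, 3, 3))

    @given(st.sets(st.integers(min_value=0, max_value=200), min_size=1, max_size=10))
    @settings(max_examples=200, derandomize=True)
    def test_delta_set_properties(self, pts):
        X = sorted(pts)
        D = delta_set(X)
        n = len(X)
        assert len(D) == n * (n - 1) // 2
        # reflection invariance: the difference multiset cannot tell a set
        # from its mirror image
        c = max(X)
        assert delta_set([c - x for x in X]) == D
        # pairwise form equals the union of per-point difference sets,
        # each unordered pair contributed exactly once
        acc = DistanceMultiset()
        for i in range(n):
            acc = disjoint_union(acc, delta_point(X[i], X[i + 1 :]))
        assert acc == D


class TestSubmultiset:
    @pytest.mark.parametrize(
        "L, D, expected",
        [
            ((2, 8), (1, 2, 2, 3, 5, 6, 7, 8, 8), True),
            ((0, 1), (1, 1), False),
            ((), (9, 9), True),
            ((2, 2, 2), (2, 2), False),
        ],
    )
    def test_examples(self, L, D, expected):
        assert is_submultiset(ms(*L), ms(*D)) is expected


class TestValidateInstance:
    @pytest.mark.parametrize("N, n", [(1, 2), (3, 3), (10, 5), (28, 8), (1_999_000, 2000)])
    def test_triangular_inversion(self, N, n):
        assert points_from_pair_count(N) == n

    @pytest.mark.parametrize("N", [2, 4, 7, 11, 100])
    def test_non_triangular_rejected(self, N):
        with pytest.raises(NonTriangularSize):
            points_from_pair_count(N)

    def test_validate_worked_example(self, worked_example_D):
        inst = validate_instance(worked_example_D)
        assert (inst.N, inst.n, inst.width) == (10, 5, 10)

    def test_zero_distance_rejected(self):
        with pytest.raises(NonPositiveDistance):
            validate_instance(ms(0, 1, 2))

    def test_empty_rejected(self):
        with pytest.raises(NonTriangularSize):
            validate_instance(ms())
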