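"""Shared fixtures and the brute-force reference solver used as an oracle."""

from __future__ import annotations

import itertools

import pytest

from partialdigest import DistanceMultiset, delta_set, validate_instance
from partialdigest.datasets import luciferase_taqi, worked_example


def brute_force_solutions(D: DistanceMultiset) -> list[tuple[int, ...]]:
    """Enumerate every solution by exhaustive subset search.

    Any solution is anchored at 0, contains width = max(D), and all its
    other coordinates must themselves appear in D (each is a distance to
    the point at 0).  So it suffices to try every (n-2)-subset of the
    distinct interior values of D.  Exponential — intended for n <= 7.
    """
    inst = validate_instance(D)
    interior = [v for v in sorted(set(D.counts)) if 0 < v < inst.width]
    sols = []
    for combo in itertools.combinations(interior, inst.n - 2):
        X = (0, *combo, inst.width)
        if delta_set(X) == D:
            sols.append(X)
    return sorted(sols)


@pytest.fixture
def worked_example_D() -> DistanceMultiset:
    return worked_example()


@pytest.fixture
def luciferase_D() -> DistanceMultiset:
    return luciferase_taqi()
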