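"""Small published reference instances used as fixtures and smoke tests."""

from __future__ import annotations

from .multisets import DistanceMultiset

#: Classic 5-point worked example: the digest of the site map {0,2,7,8,10}.
#: Its two solutions, {0,2,7,8,10} and {0,2,3,8,10}, are mirror images of
#: each other about the midpoint of the interval.
WORKED_EXAMPLE_D = (1, 2, 2, 3, 5, 6, 7, 8, 8, 10)
WORKED_EXAMPLE_SOLUTIONS = ((0, 2, 3, 8, 10), (0, 2, 7, 8, 10))

#: TaqI (TCGA) partial digest of the 2009 bp luciferase gene: the 28
#: fragment lengths of the 8-point map with internal sites at
#: 30, 975, 984, 1277, 1377 and 1839.
LUCIFERASE_TAQI_D = (
    9, 30, 100, 170, 293, 302, 393, 402, 462, 562, 632, 732, 855, 864,
    945, 954, 975, 984, 1025, 1034, 1247, 1277, 1347, 1377, 1809, 1839,
    1979, 2009,
)
LUCIFERASE_LENGTH = 2009
LUCIFERASE_TAQI_SITES = (30, 975, 984, 1277, 1377, 1839)
LUCIFERASE_SOLUTIONS = (
    (0, 30, 975, 984, 1277, 1377, 1839, 2009),
    (0, 170, 632, 732, 1025, 1034, 1979, 2009),
)


def worked_example() -> DistanceMultiset:
    """The 10-element worked-example distance multiset."""
    return DistanceMultiset(WORKED_EXAMPLE_D)


def luciferase_taqi() -> DistanceMultiset:
    """The 28-element luciferase TaqI fragment-length multiset."""
    return DistanceMultiset(LUCIFERASE_TAQI_D)
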