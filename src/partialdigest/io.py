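"""Plain-text input/output for distance multisets and solution sets.

Multiset files are whitespace-separated integers (multiplicity by
repetition); lines whose first non-blank character is ``#`` are comments.
Solution files hold one solution per line as ascending space-separated
coordinates, sorted lexicographically so the three solvers' outputs are
byte-comparable, with optional search statistics appended as comments.
"""

from __future__ import annotations

from pathlib import Path
from typing import TextIO

from .multisets import DistanceMultiset, PDPError
from .search import SolutionSet


class ParseError(PDPError):
    """A token in a multiset file is not an integer."""


class EmptyInput(PDPError):
    """A multiset file contains no values."""


def parse_multiset_text(text: str, source: str = "<string>") -> DistanceMultiset:
    """Parse a whitespace-separated integer multiset from a string."""
    values: list[int] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        for tok in stripped.split():
            try:
                values.append(int(tok))
            except ValueError:
                raise ParseError(
                    f"{source}:{lineno}: non-integer token {tok!r}"
                ) from None
    if not values:
        raise EmptyInput(f"{source}: no values found")
    if any(v < 0 for v in values):
        raise ParseError(f"{source}: negative distance in input")
    return DistanceMultiset(values)


def parse_multiset_file(path: str | Path) -> DistanceMultiset:
    """Read a multiset file; see module docstring for the format."""
    path = Path(path)
    return parse_multiset_text(path.read_text(), source=str(path))


def write_multiset(D: DistanceMultiset, path: str | Path) -> None:
    """Write a multiset, ascending, ten values per line."""
    values = D.to_sorted_list()
    lines = [
        " ".join(str(v) for v in values[i : i + 10])
        for i in range(0, len(values), 10)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_points(X, path: str | Path) -> None:
    """Write a point set, one coordinate per line, ascending."""
    Path(path).write_text("\n".join(str(x) for x in sorted(X)) + "\n")


def _write_solutions_stream(
    result: SolutionSet, out: TextIO, report_stats: bool
) -> None:
    for X in sorted(result.solutions):
        out.write(" ".join(str(x) for x in X) + "\n")
    if not result.solutions:
        out.write("# no solution\n")
    if report_stats:
        st = result.stats
        out.write(f"# algorithm: {st.algorithm}\n")
        out.write(f"# complete: {st.complete}\n")
        out.write(f"# total nodes expanded: {st.total_nodes}\n")
        out.write(f"# peak frontier: {st.peak_frontier}\n")
        out.write(f"# dedup hits: {st.dedup_hits}\n")
        for level in sorted(st.nodes_per_level):
            out.write(f"# level {level}: {st.nodes_per_level[level]} nodes\n")


def write_solutions(
    result: SolutionSet, path: str | Path, report_stats: bool = False
) -> None:
    """Write a solution set; stats appended as ``#`` comments on request."""
    with open(path, "w") as out:
        _write_solutions_stream(result, out, report_stats)


def parse_solutions_file(path: str | Path) -> list[tuple[int, ...]]:
    """Read back a solutions file (comments ignored)."""
    sols = []
    for line in Path(path).read_text().splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        sols.append(tuple(int(t) for t in stripped.split()))
    return sols
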