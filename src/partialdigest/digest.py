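"""In-silico partial digestion: from a DNA sequence to a PDP instance.

A partial digestion with a single restriction enzyme cuts a molecule at
every subset of its recognition sites, so ideally the observed fragment
lengths are *all* pairwise distances among the cut positions together with
the two molecule ends.  This module scans a sequence for a recognition
motif (e.g. TCGA for TaqI) and emits exactly that distance multiset, which
the solvers can then invert back to the site map.

Coordinates are 0-based motif start offsets on a linear molecule; a
constant cut offset within the recognition site only translates every
internal site and leaves the distance multiset of any fixed site map
unchanged, so it is exposed as an option but defaults to 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .multisets import DistanceMultiset, PDPError, delta_set


class MalformedFasta(PDPError):
    """The FASTA file has no records or an empty sequence."""


class SiteOutOfRange(PDPError):
    """A cut site does not lie strictly inside the molecule."""


class DuplicateSite(PDPError):
    """The same cut position was given twice."""


@dataclass(frozen=True)
class GenomeSequence:
    """A named DNA sequence (uppercased, whitespace-free)."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class DigestResult:
    """The PDP instance produced by digesting one molecule.

    sites  internal cut positions (strictly inside the molecule)
    X      {0} ∪ sites ∪ {L} — the full site map including both ends
    D      ΔX, the fragment-length multiset; |D| = n(n-1)/2 for n = |X|
    """

    sites: tuple[int, ...]
    X: tuple[int, ...]
    D: DistanceMultiset

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def N(self) -> int:
        return len(self.D)


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Parse all records of a FASTA file, in file order.

    Sequences are uppercased; raises MalformedFasta on an empty file or an
    empty sequence body.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace(" ", "")
        if not seq:
            raise MalformedFasta(f"record {rec.id!r} has an empty sequence")
        records.append(GenomeSequence(id=rec.id, seq=seq))
    if not records:
        raise MalformedFasta(f"no FASTA records found in {path}")
    return records


def find_motif_sites(seq: GenomeSequence | str, motif: str) -> tuple[int, ...]:
    """0-based start offsets of every exact occurrence of motif, ascending.

    Matching is case-insensitive and counts overlapping occurrences
    (AAAA contains AA at 0, 1 and 2).  No IUPAC degeneracy: the motif must
    be a literal string over the DNA alphabet.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    motif = motif.upper()
    if not set(motif) <= set("ACGT"):
        raise ValueError(f"motif must be a literal DNA string, got {motif!r}")
    text = seq.seq if isinstance(seq, GenomeSequence) else seq.upper()
    sites = []
    start = text.find(motif)
    while start != -1:
        sites.append(start)
        start = text.find(motif, start + 1)
    return tuple(sites)


def simulate_partial_digest(sites, L: int) -> DigestResult:
    """All pairwise fragment lengths for cut positions ``sites`` on a
    linear molecule of length L.

    Every site must lie strictly between the ends; the two ends themselves
    always participate, so an uncut molecule yields the single fragment
    {L}.  The result satisfies N = n(n-1)/2 with n = len(sites) + 2.
    """
    site_list = sorted(sites)
    for s in site_list:
        if not 0 < s < L:
            raise SiteOutOfRange(f"site {s} not strictly inside (0, {L})")
    if len(set(site_list)) != len(site_list):
        raise DuplicateSite(f"duplicate cut position in {site_list}")
    X = tuple([0, *site_list, L])
    return DigestResult(sites=tuple(site_list), X=X, D=delta_set(X))


def digest_sequence(
    seq: GenomeSequence,
    motif: str,
    cut_offset: int = 0,
) -> DigestResult:
    """Scan ``seq`` for ``motif`` and simulate the partial digestion.

    ``cut_offset`` shifts every cut position by a constant within the
    recognition site.  Motif occurrences whose shifted cut position falls
    on or outside the molecule ends are dropped (they do not create an
    internal cut).
    """
    starts = find_motif_sites(seq, motif)
    cuts = [s + cut_offset for s in starts if 0 < s + cut_offset < seq.length]
    return simulate_partial_digest(cuts, seq.length)
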