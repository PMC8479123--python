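"""In-silico restriction digestion and fragment-end catalogs.

4C-seq quantifies ligation partners of a viewpoint at the resolution of
primary restriction fragments. This module partitions a genome into
fragments with a primary 4-cutter (default DpnII, GATC), annotates each
fragment with its secondary-enzyme cut structure (default Csp6I, GTAC) —
which defines the sequenced fragment *ends* and flags "blind" fragments
lacking an internal secondary site — and builds a k-mer catalog of
fragment ends used to assign trimmed 4C reads.

Coordinates are 0-based half-open and origin-shifted throughout.
"""

from __future__ import annotations

import bisect
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

from hijackscan.genome import ToyGenome, as_genome, revcomp

logger = logging.getLogger(__name__)

Side = Literal["left", "right"]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme defined by recognition sequence and cut offset.

    ``cut_offset`` is measured in bp from the start of the recognition
    occurrence on the forward strand. Only palindromic recognition
    sequences are supported: for those the forward-strand scan finds
    every site.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.recognition:
            raise ValueError(f"{self.name}: empty recognition sequence")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError(
                f"{self.name}: cut_offset {self.cut_offset} outside "
                f"[0, {len(self.recognition)}]"
            )
        if revcomp(self.recognition) != self.recognition:
            raise ValueError(
                f"{self.name}: recognition {self.recognition!r} is not "
                "palindromic; only palindromic enzymes are supported"
            )

    def cut_positions(self, sequence: str) -> list[int]:
        """All cut positions (local, 0-based) on the forward strand.

        Overlapping occurrences are found (lookahead scan).
        """
        pat = re.compile(f"(?={re.escape(self.recognition)})")
        return [m.start() + self.cut_offset for m in pat.finditer(sequence)]


DPNII = RestrictionEnzyme("DpnII", "GATC", 0)
CSP6I = RestrictionEnzyme("Csp6I", "GTAC", 1)


@dataclass
class Fragment:
    """One primary restriction fragment.

    ``end_regions`` are the sub-intervals from each primary boundary to
    the nearest internal secondary cut — the parts of the fragment that
    a 4C library actually sequences. A *blind* fragment has no internal
    secondary cut; its end regions collapse to the whole fragment.
    """

    id: int
    contig: str
    start: int
    end: int
    blind: bool = False
    end_regions: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"fragment {self.id}: start {self.start} >= end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class FragmentMap:
    """Ordered, genome-tiling collection of primary restriction fragments."""

    fragments: list[Fragment]
    primary: RestrictionEnzyme
    secondary: RestrictionEnzyme | None = None
    genome_checksum: str = ""
    _index: dict[str, tuple[list[int], list[int]]] = field(
        default_factory=dict, repr=False
    )

    def __post_init__(self) -> None:
        self._reindex()

    def _reindex(self) -> None:
        self._index = {}
        for f in self.fragments:
            starts, ids = self._index.setdefault(f.contig, ([], []))
            starts.append(f.start)
            ids.append(f.id)

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)

    def __getitem__(self, fragment_id: int) -> Fragment:
        return self.fragments[fragment_id]

    def contigs(self) -> list[str]:
        return list(self._index)

    def by_contig(self, contig: str) -> list[Fragment]:
        starts, ids = self._index.get(contig, ([], []))
        return [self.fragments[i] for i in ids]

    def lookup(self, contig: str, position: int) -> Fragment | None:
        """Unique fragment covering (contig, position), or None."""
        if contig not in self._index:
            return None
        starts, ids = self._index[contig]
        i = bisect.bisect_right(starts, position) - 1
        if i < 0:
            return None
        frag = self.fragments[ids[i]]
        return frag if frag.start <= position < frag.end else None

    def boundaries(self, contig: str) -> tuple[list[int], list[int]]:
        """Sorted fragment starts and ends for one contig."""
        frags = self.by_contig(contig)
        return [f.start for f in frags], [f.end for f in frags]

    def to_bed(self, path: str | Path) -> None:
        """BED6: name = fragment id, score = 1 if blind else 0."""
        with open(path, "w") as fh:
            for f in self.fragments:
                fh.write(
                    f"{f.contig}\t{f.start}\t{f.end}\t{f.id}\t{int(f.blind)}\t+\n"
                )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# fragment map: primary=%s secondary=%s checksum=%s\n" % (
                self.primary.name,
                self.secondary.name if self.secondary else "none",
                self.genome_checksum,
            ))
            fh.write("fragment_id\tcontig\tstart\tend\tblind\tend_regions\n")
            for f in self.fragments:
                er = ";".join(f"{a}-{b}" for a, b in f.end_regions)
                fh.write(f"{f.id}\t{f.contig}\t{f.start}\t{f.end}\t{int(f.blind)}\t{er}\n")


def digest(genome: ToyGenome | str | Path, primary: RestrictionEnzyme = DPNII) -> FragmentMap:
    """Digest a genome with the primary enzyme into a FragmentMap.

    Fragments are the intervals between consecutive cut positions plus
    the contig ends; zero-length intervals (a cut at position 0, at the
    contig end, or two coincident cuts) are suppressed.
    """
    genome = as_genome(genome)
    if len(genome) == 0:
        return FragmentMap([], primary, genome_checksum=genome.checksum())
    fragments: list[Fragment] = []
    fid = 0
    for contig in genome:
        cuts = [c + contig.origin for c in primary.cut_positions(contig.sequence)]
        edges = [contig.start] + cuts + [contig.end]
        for a, b in zip(edges, edges[1:]):
            if a < b:  # suppress degenerate intervals
                fragments.append(Fragment(fid, contig.name, a, b))
                fid += 1
    return FragmentMap(fragments, primary, genome_checksum=genome.checksum())


def annotate_secondary(
    fragmap: FragmentMap,
    genome: ToyGenome | str | Path,
    secondary: RestrictionEnzyme = CSP6I,
) -> FragmentMap:
    """Annotate each fragment with secondary-enzyme end regions and blind flag.

    For a fragment with internal secondary cuts c1 < ... < cn the end
    regions are [start, c1) and [cn, end); a fragment without an internal
    cut is blind and its single end region is the whole fragment.
    Idempotent: re-annotating replaces the previous annotation.
    """
    genome = as_genome(genome)
    if fragmap.genome_checksum and fragmap.genome_checksum != genome.checksum():
        raise ValueError(
            "fragment map was built from a different genome (checksum mismatch)"
        )
    cuts_by_contig = {
        c.name: [p + c.origin for p in secondary.cut_positions(c.sequence)]
        for c in genome
    }
    annotated: list[Fragment] = []
    for f in fragmap.fragments:
        cuts = cuts_by_contig.get(f.contig, [])
        lo = bisect.bisect_right(cuts, f.start)
        hi = bisect.bisect_left(cuts, f.end)
        inside = cuts[lo:hi]  # strictly inside (start < cut < end)
        inside = [c for c in inside if f.start < c < f.end]
        if inside:
            annotated.append(
                replace(
                    f,
                    blind=False,
                    end_regions=((f.start, inside[0]), (inside[-1], f.end)),
                )
            )
        else:
            annotated.append(replace(f, blind=True, end_regions=((f.start, f.end),)))
    return FragmentMap(
        annotated, fragmap.primary, secondary, genome_checksum=fragmap.genome_checksum
    )


def end_catalog(
    fragmap: FragmentMap,
    genome: ToyGenome | str | Path,
    k: int,
    include_blind: bool = True,
) -> dict[str, list[tuple[int, Side]]]:
    """k-mer catalog of fragment ends, keyed by inward-reading sequence.

    For side ``left`` the k-mer is the forward-strand sequence starting
    at the fragment start; for side ``right`` it is the reverse
    complement of the last k bases, i.e. both read *into* the fragment
    from a primary boundary — exactly how a 4C read enters its ligated
    partner. Fragments shorter than k are skipped with a warning.

    The returned mapping is k-mer -> list of (fragment_id, side); a
    multi-entry list marks an ambiguous end sequence.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    genome = as_genome(genome)
    catalog: dict[str, list[tuple[int, Side]]] = {}
    skipped = 0
    for f in fragmap:
        if not include_blind and f.blind:
            continue
        if len(f) < k:
            skipped += 1
            continue
        contig = genome[f.contig]
        left = contig.slice(f.start, f.start + k)
        right = revcomp(contig.slice(f.end - k, f.end))
        catalog.setdefault(left, []).append((f.id, "left"))
        catalog.setdefault(right, []).append((f.id, "right"))
    if skipped:
        logger.warning("end_catalog: skipped %d fragments shorter than k=%d", skipped, k)
    return catalog
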