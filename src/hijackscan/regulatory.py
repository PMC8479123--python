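"""CTCF convergence, docking-site preservation, enhancer-module counts.

Chromatin loops form preferentially between CTCF motifs in convergent
orientation: a forward-oriented motif followed, in genomic order, by a
reverse-oriented one. When a translocation places a super-enhancer
upstream of a promoter that keeps its own forward-oriented CTCF site
(an enhancer-docking site), reverse-oriented motifs inside the hijacked
enhancer can anchor loops to it — provided the junction leaves the
docking site and promoter intact on one derivative segment. This module
tests exactly those configurations, and quantifies reads (e.g. H3K27ac
or ATAC) over named enhancer-module intervals as RPKM with descriptive
log2 fold changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd

from hijackscan.rearrange import DerivativeChromosome

logger = logging.getLogger(__name__)

Orientation = Literal["forward", "reverse"]


@dataclass(frozen=True)
class CtcfSite:
    """An oriented CTCF motif occurrence."""

    contig: str
    start: int
    end: int
    orientation: Orientation
    score: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"site {self.label!r}: start >= end")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class EnhancerModule:
    """A named constituent interval of a super-enhancer (modules A..I, S)."""

    name: str
    contig: str
    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PromoterAnchor:
    """A promoter plus its upstream forward-oriented CTCF docking site."""

    promoter_contig: str
    promoter_position: int
    docking_site: CtcfSite
    required_orientation: Orientation = "forward"


def load_sites(bed: str | Path | Iterable[str]) -> tuple[list[CtcfSite], int]:
    """Load oriented sites from 6-column BED (strand + = forward, - = reverse).

    Records with strand '.' are skipped with a warning and counted;
    malformed lines raise, naming the line number. Returns (sites,
    number skipped).
    """
    if isinstance(bed, (str, Path)):
        lines = open(bed).read().splitlines()
    else:
        lines = list(bed)
    sites: list[CtcfSite] = []
    skipped = 0
    for ln, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 6:
            raise ValueError(f"line {ln}: expected 6 BED columns, got {len(fields)}")
        try:
            contig, start, end, name, score, strand = fields[:6]
            start_i, end_i = int(start), int(end)
            score_f = float(score) if score != "." else 0.0
        except ValueError as exc:
            raise ValueError(f"line {ln}: malformed BED record ({exc})") from None
        if strand == "+":
            orientation: Orientation = "forward"
        elif strand == "-":
            orientation = "reverse"
        else:
            logger.warning("line %d: strandless site %r skipped", ln, name)
            skipped += 1
            continue
        sites.append(CtcfSite(contig, start_i, end_i, orientation, score_f, name))
    return sites, skipped


# ---------------------------------------------------------------------------
# Convergence


def site_positions(
    sites: list[CtcfSite], der: Optional[DerivativeChromosome] = None
) -> list[tuple[CtcfSite, int]]:
    """Pair each site with its analysis coordinate.

    With a derivative, positions are site midpoints lifted onto the
    derivative (sites not covered are dropped); without one, native
    midpoints are used and all sites must share a contig.
    """
    out = []
    if der is not None:
        for s in sites:
            pos = der.map_to(s.contig, s.midpoint)
            if pos is not None:
                out.append((s, pos))
    else:
        contigs = {s.contig for s in sites}
        if len(contigs) > 1:
            raise ValueError(
                f"sites span contigs {sorted(contigs)}; supply a derivative"
            )
        out = [(s, s.midpoint) for s in sites]
    return out


def convergent_pairs(
    sites: list[CtcfSite],
    der: Optional[DerivativeChromosome] = None,
    max_span: Optional[int] = None,
) -> list[tuple[CtcfSite, CtcfSite, int]]:
    """All loop-compatible (forward, reverse) site pairs.

    A pair is convergent when the forward site precedes the reverse site
    in (derivative or contig) coordinate order; ``max_span`` caps the
    separation. Sorted by span ascending (ties by position).
    """
    placed = site_positions(sites, der)
    pairs = []
    for si, pi in placed:
        if si.orientation != "forward":
            continue
        for sj, pj in placed:
            if sj.orientation != "reverse" or pj <= pi:
                continue
            span = pj - pi
            if max_span is not None and span > max_span:
                continue
            pairs.append((si, sj, span))
    pairs.sort(key=lambda t: (t[2], t[0].start, t[1].start))
    return pairs


# ---------------------------------------------------------------------------
# Docking-site preservation


@dataclass
class DockingVerdict:
    preserved: bool
    convergent_partner_possible: bool
    covered: bool = True
    details: str = ""
    pairs: list[tuple[CtcfSite, CtcfSite, int]] | None = None


def docking_preserved(
    anchor: PromoterAnchor,
    der: DerivativeChromosome,
    partner_sites: Optional[list[CtcfSite]] = None,
) -> DockingVerdict:
    """Check that a rearrangement leaves the docking configuration intact.

    ``preserved`` requires (i) the docking site interval and the promoter
    position to be covered by the *same* derivative segment and (ii) the
    site not truncated by a segment boundary. When the docking site has
    the required (forward) orientation on the derivative,
    ``convergent_partner_possible`` reports whether any reverse-oriented
    partner-segment site downstream of it can form a convergent pair.
    """
    site = anchor.docking_site
    seg_p = der.segment_of(anchor.promoter_contig, anchor.promoter_position)
    seg_s0 = der.segment_of(site.contig, site.start)
    seg_s1 = der.segment_of(site.contig, site.end - 1)
    if seg_p is None:
        return DockingVerdict(
            False, False, covered=False, details="promoter not covered by derivative"
        )
    if seg_s0 is None or seg_s1 is None or seg_s0 != seg_s1:
        return DockingVerdict(
            False,
            False,
            covered=seg_s0 is not None or seg_s1 is not None,
            details="docking site truncated or lost at a segment boundary",
        )
    if seg_s0 != seg_p:
        return DockingVerdict(
            False,
            False,
            details="junction separates docking site from promoter",
        )
    if site.orientation != anchor.required_orientation:
        return DockingVerdict(
            False, False, details="docking site lacks required orientation"
        )

    possible = False
    pairs: list[tuple[CtcfSite, CtcfSite, int]] = []
    if partner_sites:
        promoter_seg = der.segments[seg_p]
        foreign = [s for s in partner_sites if s.contig != promoter_seg.contig]
        pairs = [
            (a, b, sp)
            for a, b, sp in convergent_pairs([site] + foreign, der)
            if a == site
        ]
        possible = bool(pairs)
    return DockingVerdict(
        True,
        possible,
        details="docking site and promoter intact on one segment",
        pairs=pairs or None,
    )


# ---------------------------------------------------------------------------
# Module quantification


def module_quantify(
    reads_by_sample: dict[str, list[tuple[str, int, int]]],
    modules: list[EnhancerModule],
    library_sizes: Optional[dict[str, int]] = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Count reads over enhancer modules and derive RPKM per sample.

    A read (contig, start, end) counts toward a module iff it overlaps
    the module interval by >= 1 bp (once per module at most).
    RPKM = count * 1e9 / (library_size * module_length). With exactly
    two samples a log2 fold change log2((RPKM1+pc)/(RPKM2+pc)) column is
    appended.
    """
    names = [m.name for m in modules]
    if len(set(names)) != len(names):
        raise ValueError("module names must be unique")
    for i, a in enumerate(modules):
        for b in modules[i + 1 :]:
            if a.contig == b.contig and a.start < b.end and b.start < a.end:
                raise ValueError(f"modules {a.name!r} and {b.name!r} overlap")

    library_sizes = library_sizes or {
        s: len(rs) for s, rs in reads_by_sample.items()
    }
    for s, n in library_sizes.items():
        if n <= 0:
            raise ValueError(f"sample {s!r}: zero library size")

    rows = []
    for m in modules:
        row: dict = {"module": m.name, "contig": m.contig, "start": m.start,
                     "end": m.end, "length": len(m)}
        for sample, reads in reads_by_sample.items():
            count = sum(
                1 for c, s, e in reads if c == m.contig and s < m.end and e > m.start
            )
            row[f"count_{sample}"] = count
            row[f"rpkm_{sample}"] = count * 1e9 / (library_sizes[sample] * len(m))
        rows.append(row)
    table = pd.DataFrame(rows)
    samples = list(reads_by_sample)
    if len(samples) == 2:
        s1, s2 = samples
        table["log2_fold_change"] = np.log2(
            (table[f"rpkm_{s1}"] + pseudocount) / (table[f"rpkm_{s2}"] + pseudocount)
        )
    return table
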