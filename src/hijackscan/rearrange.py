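"""Translocation breakpoint calling and derivative-chromosome coordinates.

A reciprocal translocation such as t(3;8)(q26;q24) creates derivative
chromosomes on which an enhancer from one partner sits in cis with a
promoter from the other. This module provides:

* a minimal structural-variant caller in the BreakDancer tradition —
  discordant read-pair extraction, per-orientation single-linkage
  clustering, and split-read refinement to base-pair exactness;
* :class:`DerivativeChromosome`, an ordered list of oriented native
  segments with exact bidirectional coordinate maps, so annotations
  (CTCF sites, enhancer modules) can be lifted onto the rearranged
  chromosome and back.

Internally coordinates are 0-based half-open; human-facing breakpoint
reports are 1-based (pos_a = last retained base of partner A, pos_b =
first retained base of partner B).
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Optional

import pysam
from Bio import SeqIO

from hijackscan.genome import ToyGenome, as_genome, revcomp

logger = logging.getLogger(__name__)

SideKind = Literal["left-of", "right-of"]


@dataclass
class Breakpoint:
    """A two-partner junction with its read support.

    ``side_a``/``side_b`` say which flank of each partner joins the
    junction: ``right-of`` means the bases *left of* pos join (the
    partner's left flank is retained, junction at its right edge), and
    vice versa. ``resolution`` is ``"exact"`` only when split reads
    support the base-pair coordinate.
    """

    contig_a: str
    pos_a: int  # 0-based junction coordinate (see side semantics)
    contig_b: str
    pos_b: int
    side_a: SideKind = "right-of"
    side_b: SideKind = "left-of"
    support_pairs: int = 0
    support_split: int = 0
    resolution: str = "interval"
    interval_w: int = 0

    def report_coords(self) -> tuple[int, int]:
        """1-based coordinates in the style breakpoints are printed.

        For a ``right-of`` side the junction coordinate equals the count
        of retained bases, which is already the 1-based last retained
        base; for a ``left-of`` side the first retained base is pos
        (0-based), printed as pos+1.
        """
        a = self.pos_a if self.side_a == "right-of" else self.pos_a + 1
        b = self.pos_b if self.side_b == "right-of" else self.pos_b + 1
        return a, b


@dataclass(frozen=True)
class Segment:
    """One oriented native-genome piece of a derivative chromosome."""

    contig: str
    start: int
    end: int
    orientation: Literal["+", "-"] = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"degenerate segment {self.contig}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class DerivativeChromosome:
    """Ordered oriented segments forming a rearranged chromosome.

    Derivative coordinates run 0..total length; ``map_to``/``map_from``
    are mutually inverse bijections on covered positions.
    """

    name: str
    segments: list[Segment]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("derivative must have at least one segment")
        self._offsets = []
        off = 0
        for seg in self.segments:
            self._offsets.append(off)
            off += len(seg)
        self._length = off

    def __len__(self) -> int:
        return self._length

    @property
    def junctions(self) -> list[int]:
        """Derivative coordinates of each internal segment boundary."""
        return self._offsets[1:]

    def segment_of(self, contig: str, pos: int) -> Optional[int]:
        """Index of the first segment covering a native position, or None."""
        for i, seg in enumerate(self.segments):
            if seg.contig == contig and seg.start <= pos < seg.end:
                return i
        return None

    def map_to(self, contig: str, pos: int) -> Optional[int]:
        """Native (contig, pos) -> derivative coordinate; None if not covered."""
        i = self.segment_of(contig, pos)
        if i is None:
            return None
        seg, off = self.segments[i], self._offsets[i]
        if seg.orientation == "+":
            return off + (pos - seg.start)
        return off + (seg.end - 1 - pos)

    def map_from(self, der_pos: int) -> Optional[tuple[str, int]]:
        """Derivative coordinate -> native (contig, pos); None if out of range."""
        if not 0 <= der_pos < self._length:
            return None
        for seg, off in zip(self.segments, self._offsets):
            if off <= der_pos < off + len(seg):
                if seg.orientation == "+":
                    return seg.contig, seg.start + (der_pos - off)
                return seg.contig, seg.end - 1 - (der_pos - off)
        return None  # pragma: no cover

    def sequence(self, genome: ToyGenome) -> str:
        """Derivative sequence assembled from the native genome."""
        parts = []
        for seg in self.segments:
            s = genome[seg.contig].slice(seg.start, seg.end)
            parts.append(s if seg.orientation == "+" else revcomp(s))
        return "".join(parts)

    def to_genome(self, genome: ToyGenome, origin: int = 0) -> ToyGenome:
        """One-contig genome carrying the derivative sequence."""
        from hijackscan.genome import Contig

        return ToyGenome([Contig(self.name, self.sequence(genome), origin)])

    def to_table(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# derivative {self.name}\n")
            for seg in self.segments:
                fh.write(f"{seg.contig}\t{seg.start}\t{seg.end}\t{seg.orientation}\n")

    @classmethod
    def from_table(cls, name: str, path: str | Path) -> "DerivativeChromosome":
        segs = []
        for line in open(path):
            if line.startswith("#") or not line.strip():
                continue
            c, s, e, o = line.split()
            segs.append(Segment(c, int(s), int(e), o))  # type: ignore[arg-type]
        return cls(name, segs)


# ---------------------------------------------------------------------------
# Discordant-pair extraction


@dataclass(frozen=True)
class PairRecord:
    """Both mates of one sequenced fragment, as aligned."""

    name: str
    contig1: str
    start1: int
    end1: int
    reverse1: bool
    contig2: str
    start2: int
    end2: int
    reverse2: bool

    @property
    def orientation_class(self) -> str:
        return ("R" if self.reverse1 else "F") + ("R" if self.reverse2 else "F")


def find_discordant(
    sam: str | Path | Iterable[pysam.AlignedSegment],
    max_concordant_insert: int = 1000,
    min_mapq: int = 10,
) -> tuple[list[PairRecord], dict[str, int]]:
    """Extract discordant pairs from paired-end alignments.

    A pair is discordant when its mates map to different contigs, or to
    the same contig with insert span > ``max_concordant_insert`` or in a
    non-FR relative orientation. Records below ``min_mapq`` are dropped
    and counted. Returns (discordant pairs, tally dict).
    """
    if isinstance(sam, (str, Path)):
        with pysam.AlignmentFile(str(sam), "r") as fh:
            reads = [r for r in fh]
    else:
        reads = list(sam)

    stats = {"n_records": len(reads), "low_mapq": 0, "concordant": 0, "discordant": 0}
    by_name: dict[str, list[pysam.AlignedSegment]] = defaultdict(list)
    for r in reads:
        if r.is_unmapped or r.is_secondary or r.is_supplementary:
            continue
        if not r.is_paired:
            raise ValueError(f"unpaired record {r.query_name!r}: paired input required")
        if r.mapping_quality < min_mapq:
            stats["low_mapq"] += 1
            continue
        by_name[r.query_name].append(r)

    discordant: list[PairRecord] = []
    for name in sorted(by_name):
        mates = by_name[name]
        if len(mates) != 2:
            continue
        r1, r2 = sorted(mates, key=lambda r: not r.is_read1)
        pair = PairRecord(
            name,
            r1.reference_name, r1.reference_start, r1.reference_end, r1.is_reverse,
            r2.reference_name, r2.reference_start, r2.reference_end, r2.is_reverse,
        )
        if pair.contig1 != pair.contig2:
            disc = True
        else:
            span = max(pair.end1, pair.end2) - min(pair.start1, pair.start2)
            left_first = pair.start1 <= pair.start2
            fr = (
                (not pair.reverse1 and pair.reverse2)
                if left_first
                else (pair.reverse1 and not pair.reverse2)
            )
            disc = span > max_concordant_insert or not fr
        if disc:
            discordant.append(pair)
            stats["discordant"] += 1
        else:
            stats["concordant"] += 1
    return discordant, stats


# ---------------------------------------------------------------------------
# Clustering


def _innermost(edges_fwd: list[int], edges_rev: list[int], any_fwd: bool) -> int:
    """Innermost read edge: rightmost end for forward mates (junction to
    their right), leftmost start for reverse mates."""
    return max(edges_fwd) if any_fwd else min(edges_rev)


def cluster_candidates(
    pairs: list[PairRecord],
    cluster_window: int = 1000,
    min_support: int = 2,
) -> list[Breakpoint]:
    """Cluster discordant pairs into candidate breakpoints.

    Pairs are grouped by (ordered contig pair, orientation class); within
    a group, single-linkage clustering joins pairs whose positions on
    *both* partners are within ``cluster_window``. A cluster with
    support >= ``min_support`` yields one candidate whose coordinates are
    the innermost read edges. Output order is deterministic regardless of
    input order.
    """
    groups: dict[tuple, list[PairRecord]] = defaultdict(list)
    for p in pairs:
        if (p.contig1, p.start1) <= (p.contig2, p.start2):
            key_pair = p
        else:  # normalize partner order
            key_pair = PairRecord(
                p.name,
                p.contig2, p.start2, p.end2, p.reverse2,
                p.contig1, p.start1, p.end1, p.reverse1,
            )
        groups[(key_pair.contig1, key_pair.contig2, key_pair.orientation_class)].append(
            key_pair
        )

    candidates: list[Breakpoint] = []
    for (ca, cb, oclass), members in groups.items():
        members.sort(key=lambda p: (p.start1, p.start2, p.name))
        clusters: list[list[PairRecord]] = []
        for p in members:
            placed = False
            for cl in clusters:
                if any(
                    abs(p.start1 - q.start1) <= cluster_window
                    and abs(p.start2 - q.start2) <= cluster_window
                    for q in cl
                ):
                    cl.append(p)
                    placed = True
                    break
            if not placed:
                clusters.append([p])
        # single linkage: merge clusters that became linked transitively
        merged = True
        while merged:
            merged = False
            for i in range(len(clusters)):
                for j in range(i + 1, len(clusters)):
                    if any(
                        abs(p.start1 - q.start1) <= cluster_window
                        and abs(p.start2 - q.start2) <= cluster_window
                        for p in clusters[i]
                        for q in clusters[j]
                    ):
                        clusters[i].extend(clusters.pop(j))
                        merged = True
                        break
                if merged:
                    break

        for cl in clusters:
            if len(cl) < min_support:
                continue
            fwd_a = not cl[0].reverse1
            fwd_b = not cl[0].reverse2
            pos_a = (
                max(p.end1 for p in cl) if fwd_a else min(p.start1 for p in cl)
            )
            pos_b = (
                max(p.end2 for p in cl) if fwd_b else min(p.start2 for p in cl)
            )
            candidates.append(
                Breakpoint(
                    ca, pos_a, cb, pos_b,
                    side_a="right-of" if fwd_a else "left-of",
                    side_b="right-of" if fwd_b else "left-of",
                    support_pairs=len(cl),
                    resolution="interval",
                    interval_w=cluster_window,
                )
            )
    candidates.sort(key=lambda b: (b.contig_a, b.pos_a, -b.support_pairs))
    return candidates


# ---------------------------------------------------------------------------
# Split-read refinement


def refine_junction(
    candidate: Breakpoint,
    spanning_reads: str | Path | list,
    genome: ToyGenome | str | Path,
    window: int = 2000,
    min_match: int = 15,
) -> Breakpoint:
    """Refine a candidate to base-pair exactness using junction-spanning reads.

    For each read, every split point s (min_match <= s <= len-min_match)
    is tried: the prefix must occur in the partner-A flank window ending
    near the candidate, the suffix in the partner-B window. Among full
    two-sided matches the modal (pos_a, pos_b) across reads wins; ties
    break toward the smallest pos_a. Reads never achieving ``min_match``
    on both sides leave the candidate unrefined.
    """
    genome = as_genome(genome)
    if isinstance(spanning_reads, (str, Path)):
        reads = [str(r.seq) for r in SeqIO.parse(str(spanning_reads), "fastq")]
    else:
        reads = [str(getattr(r, "seq", r)) for r in spanning_reads]

    ctg_a, ctg_b = genome[candidate.contig_a], genome[candidate.contig_b]
    a_lo = max(ctg_a.start, candidate.pos_a - window)
    a_hi = min(ctg_a.end, candidate.pos_a + window)
    b_lo = max(ctg_b.start, candidate.pos_b - window)
    b_hi = min(ctg_b.end, candidate.pos_b + window)
    win_a = ctg_a.slice(a_lo, a_hi)
    win_b = ctg_b.slice(b_lo, b_hi)

    votes: Counter[tuple[int, int]] = Counter()
    for seq in reads:
        best: tuple[int, int, int] | None = None  # (score, pos_a, pos_b)
        for s in range(min_match, len(seq) - min_match + 1):
            pre, suf = seq[:s], seq[s:]
            i = win_a.find(pre)
            if i < 0:
                continue
            j = win_b.find(suf)
            if j < 0:
                continue
            # junction coords: A side joins at end of prefix, B at start of suffix
            pa = a_lo + i + s if candidate.side_a == "right-of" else a_lo + i
            pb = b_lo + j if candidate.side_b == "left-of" else b_lo + j + len(suf)
            cand = (len(seq), pa, pb)
            if best is None or cand[0] > best[0] or (cand[0] == best[0] and pa < best[1]):
                best = cand
        if best is not None:
            votes[(best[1], best[2])] += 1

    if not votes:
        return candidate
    top = max(votes.values())
    pos_a, pos_b = min(pos for pos, n in votes.items() if n == top)
    return replace(
        candidate,
        pos_a=pos_a,
        pos_b=pos_b,
        support_split=votes[(pos_a, pos_b)],
        resolution="exact",
        interval_w=0,
    )


# ---------------------------------------------------------------------------
# Derivative construction


def build_derivative(
    bp: Breakpoint,
    genome_sizes: dict[str, tuple[int, int]],
    name: str = "der",
    orientation_b: Literal["+", "-"] = "+",
    reciprocal: bool = False,
) -> DerivativeChromosome | tuple[DerivativeChromosome, DerivativeChromosome]:
    """Build the derivative chromosome implied by a breakpoint.

    ``genome_sizes`` maps contig -> (start, end) genomic extent. The
    retained flank of each partner follows its side: ``right-of`` keeps
    [start, pos), ``left-of`` keeps [pos, end). With ``reciprocal`` both
    products are returned.
    """
    a_lo, a_hi = genome_sizes[bp.contig_a]
    b_lo, b_hi = genome_sizes[bp.contig_b]
    seg_a = (
        Segment(bp.contig_a, a_lo, bp.pos_a)
        if bp.side_a == "right-of"
        else Segment(bp.contig_a, bp.pos_a, a_hi)
    )
    seg_b = (
        Segment(bp.contig_b, b_lo, bp.pos_b, orientation_b)
        if bp.side_b == "right-of"
        else Segment(bp.contig_b, bp.pos_b, b_hi, orientation_b)
    )
    der = DerivativeChromosome(name, [seg_a, seg_b])
    if not reciprocal:
        return der
    rec_a = (
        Segment(bp.contig_b, b_lo, bp.pos_b)
        if bp.side_b == "left-of"
        else Segment(bp.contig_b, bp.pos_b, b_hi)
    )
    rec_b = (
        Segment(bp.contig_a, bp.pos_a, a_hi)
        if bp.side_a == "right-of"
        else Segment(bp.contig_a, a_lo, bp.pos_a)
    )
    return der, DerivativeChromosome(name + "_reciprocal", [rec_a, rec_b])


def breakpoints_to_tsv(breakpoints: list[Breakpoint], path: str | Path) -> None:
    """Human-facing TSV report, 1-based coordinates."""
    with open(path, "w") as fh:
        fh.write(
            "contig_a\tpos_a\tside_a\tcontig_b\tpos_b\tside_b\t"
            "support_pairs\tsupport_split\tresolution\n"
        )
        for bp in breakpoints:
            a, b = bp.report_coords()
            fh.write(
                f"{bp.contig_a}\t{a}\t{bp.side_a}\t{bp.contig_b}\t{b}\t{bp.side_b}\t"
                f"{bp.support_pairs}\t{bp.support_split}\t{bp.resolution}\n"
            )
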