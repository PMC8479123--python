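"""4C-seq read processing: demultiplex, clip, assign to fragments, count.

The stages mirror a standard one-viewpoint 4C workflow: reads are
demultiplexed by their viewpoint-specific reading primer, the primer
bases before the primary restriction motif are clipped so the trimmed
read starts at the motif (the ligation junction), the trimmed read is
assigned to a restriction-fragment end, and per-fragment contact counts
are aggregated with the viewpoint's own neighborhood excluded
(self-ligation / undigested products). Reads whose alignment start does
not sit on a fragment boundary are removed — only fragment-end
sequences are genuine ligation products.

Every input read lands in exactly one tally (kept, excluded, unmapped,
ambiguous, unassigned); the bookkeeping identity is asserted in
:func:`count_contacts`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import pysam
from Bio import SeqIO

from hijackscan.fragments import FragmentMap, Side

logger = logging.getLogger(__name__)


@dataclass
class Viewpoint:
    """A 4C viewpoint: the locus whose ligation partners the library captures."""

    name: str
    contig: str
    position: int
    reading_primer: str
    exclusion_radius: int = 1

    def validate(self, primary_recognition: str) -> None:
        if not self.reading_primer.endswith(primary_recognition):
            raise ValueError(
                f"viewpoint {self.name!r}: reading primer must end with the "
                f"primary recognition sequence {primary_recognition}"
            )


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    fragment_id: int
    side: Side


@dataclass
class AssignmentResult:
    assignments: list[ReadAssignment]
    n_unmapped: int = 0
    n_ambiguous: int = 0
    n_filtered: int = 0  # alignment-based filter (off-boundary / unknown contig)


@dataclass
class ContactProfile:
    """Per-fragment contact counts for one viewpoint library."""

    viewpoint: Viewpoint
    counts: dict[int, int]
    n_total_reads: int = 0
    n_assigned: int = 0
    n_excluded: int = 0  # assigned but within the viewpoint exclusion zone
    n_filtered_out: int = 0  # unassigned/unmapped/ambiguous/off-boundary
    normalized: Optional[dict[int, float]] = None
    params: dict = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    def to_tsv(self, path: str | Path, fragmap: FragmentMap) -> None:
        with open(path, "w") as fh:
            fh.write(f"# viewpoint={self.viewpoint.name} "
                     f"contig={self.viewpoint.contig} position={self.viewpoint.position}\n")
            fh.write(f"# exclusion_radius={self.viewpoint.exclusion_radius} "
                     f"n_total={self.n_total_reads} n_assigned={self.n_assigned} "
                     f"n_excluded={self.n_excluded} n_filtered_out={self.n_filtered_out}\n")
            for key, val in sorted(self.params.items()):
                fh.write(f"# {key}={val}\n")
            fh.write("fragment_id\tcontig\tstart\tend\tcount" +
                     ("\trpm" if self.normalized else "") + "\n")
            for fid in sorted(self.counts):
                f = fragmap[fid]
                row = f"{fid}\t{f.contig}\t{f.start}\t{f.end}\t{self.counts[fid]}"
                if self.normalized:
                    row += f"\t{self.normalized[fid]:.6f}"
                fh.write(row + "\n")


# ---------------------------------------------------------------------------


def _read_fastq(reads: str | Path | Iterable) -> list[tuple[str, str]]:
    if isinstance(reads, (str, Path)):
        return [(r.id, str(r.seq)) for r in SeqIO.parse(str(reads), "fastq")]
    out = []
    for r in reads:
        if isinstance(r, tuple):
            out.append((r[0], r[1]))
        else:
            out.append((r.id, str(r.seq)))
    return out


def _mismatches(a: str, b: str, limit: int) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                break
    return n


def demultiplex_and_clip(
    reads: str | Path | Iterable,
    viewpoints: list[Viewpoint],
    primary_recognition: str = "GATC",
    max_mismatch: int = 0,
) -> tuple[dict[str, list[tuple[str, str]]], pd.DataFrame]:
    """Assign reads to viewpoints by primer prefix and clip the primer.

    Clipping removes the primer bases *before* the primary motif, so
    trimmed reads begin with the motif and can be matched against
    fragment-end sequences. A read matching several viewpoint primers
    within ``max_mismatch`` is ambiguous and dropped; a read matching
    none is unassigned and dropped. Returns per-viewpoint trimmed reads
    and a summary table.
    """
    primers = [vp.reading_primer for vp in viewpoints]
    if len(set(primers)) != len(primers):
        raise ValueError("two viewpoints share an identical reading primer")
    for vp in viewpoints:
        vp.validate(primary_recognition)
    for i, a in enumerate(viewpoints):
        for b in viewpoints[i + 1 :]:
            if len(a.reading_primer) == len(b.reading_primer) and _mismatches(
                a.reading_primer, b.reading_primer, max_mismatch
            ) <= max_mismatch:
                raise ValueError(
                    f"primers of {a.name!r} and {b.name!r} are not "
                    f"distinguishable at max_mismatch={max_mismatch}"
                )

    motif_len = len(primary_recognition)
    out: dict[str, list[tuple[str, str]]] = {vp.name: [] for vp in viewpoints}
    n_unassigned = n_ambiguous = 0
    records = _read_fastq(reads)
    for rid, seq in records:
        hits = [
            vp
            for vp in viewpoints
            if len(seq) >= len(vp.reading_primer)
            and _mismatches(seq[: len(vp.reading_primer)], vp.reading_primer, max_mismatch)
            <= max_mismatch
        ]
        if len(hits) == 1:
            vp = hits[0]
            clip_at = len(vp.reading_primer) - motif_len
            out[vp.name].append((rid, seq[clip_at:]))
        elif len(hits) == 0:
            n_unassigned += 1
        else:
            n_ambiguous += 1

    summary = pd.DataFrame(
        {
            "viewpoint": [vp.name for vp in viewpoints] + ["unassigned", "ambiguous"],
            "n_reads": [len(out[vp.name]) for vp in viewpoints]
            + [n_unassigned, n_ambiguous],
        }
    )
    return out, summary


def map_trimmed_reads(
    trimmed: list[tuple[str, str]],
    catalog: dict[str, list[tuple[int, Side]]],
    k: int,
) -> AssignmentResult:
    """Assign trimmed reads to fragment ends by exact k-mer lookup.

    The first k bases of each trimmed read are looked up in the end
    catalog built with the same k: a unique hit assigns the read; zero
    hits count as unmapped, several as ambiguous. Reads shorter than k
    are unmapped.
    """
    res = AssignmentResult([])
    for rid, seq in trimmed:
        if len(seq) < k:
            res.n_unmapped += 1
            continue
        hits = catalog.get(seq[:k], [])
        if len(hits) == 1:
            fid, side = hits[0]
            res.assignments.append(ReadAssignment(rid, fid, side))
        elif not hits:
            res.n_unmapped += 1
        else:
            res.n_ambiguous += 1
    return res


def assign_from_alignments(
    sam: str | Path | Iterable[pysam.AlignedSegment],
    fragmap: FragmentMap,
    boundary_tolerance: int = 2,
) -> AssignmentResult:
    """Assign aligned single-end reads to fragments via the boundary rule.

    A read is valid iff its strand-aware 5' alignment start lies within
    ``boundary_tolerance`` bp of a fragment primary boundary: forward
    reads at a fragment start (side left), reverse reads whose rightmost
    base sits at a fragment end-1 (side right). All other reads —
    mid-fragment starts, unmapped records, contigs absent from the map —
    are filtered out and counted.
    """
    if isinstance(sam, (str, Path)):
        with pysam.AlignmentFile(str(sam), "r") as fh:
            records = [r for r in fh]
    else:
        records = list(sam)

    res = AssignmentResult([])
    warned: set[str] = set()
    for r in records:
        if r.is_unmapped or r.is_secondary or r.is_supplementary:
            res.n_filtered += 1
            continue
        contig = r.reference_name
        if contig not in fragmap.contigs():
            if contig not in warned:
                logger.warning("alignment contig %r absent from fragment map", contig)
                warned.add(contig)
            res.n_filtered += 1
            continue
        if r.is_reverse:
            five_prime = r.reference_end - 1
            frag = fragmap.lookup(contig, five_prime)
            ok = frag is not None and abs(frag.end - 1 - five_prime) <= boundary_tolerance
            side: Side = "right"
        else:
            five_prime = r.reference_start
            frag = fragmap.lookup(contig, five_prime)
            ok = frag is not None and abs(five_prime - frag.start) <= boundary_tolerance
            side = "left"
        if ok:
            res.assignments.append(ReadAssignment(r.query_name, frag.id, side))
        else:
            res.n_filtered += 1
    return res


def count_contacts(
    result: AssignmentResult,
    viewpoint: Viewpoint,
    fragmap: FragmentMap,
    n_total_reads: Optional[int] = None,
    exclude_blind: bool = False,
) -> ContactProfile:
    """Aggregate assignments into a per-fragment contact profile.

    Fragments within ``viewpoint.exclusion_radius`` fragment indices of
    the viewpoint fragment (inclusive; radius 0 still excludes the
    viewpoint fragment itself) are removed from the counts and their
    reads tallied as excluded. The read-conservation identity
    ``n_total = kept + excluded + filtered_out`` is enforced.
    """
    vp_frag = fragmap.lookup(viewpoint.contig, viewpoint.position)
    if vp_frag is None:
        raise ValueError(
            f"viewpoint fragment not found at {viewpoint.contig}:{viewpoint.position}"
        )
    counts: dict[int, int] = {}
    n_excluded = 0
    n_blind_dropped = 0
    for a in result.assignments:
        frag = fragmap[a.fragment_id]
        if (
            frag.contig == viewpoint.contig
            and abs(a.fragment_id - vp_frag.id) <= viewpoint.exclusion_radius
        ):
            n_excluded += 1
            continue
        if exclude_blind and frag.blind:
            n_blind_dropped += 1
            continue
        counts[a.fragment_id] = counts.get(a.fragment_id, 0) + 1

    n_unassigned = result.n_unmapped + result.n_ambiguous + result.n_filtered
    total = (
        n_total_reads
        if n_total_reads is not None
        else len(result.assignments) + n_unassigned
    )
    profile = ContactProfile(
        viewpoint=viewpoint,
        counts=counts,
        n_total_reads=total,
        n_assigned=len(result.assignments),
        n_excluded=n_excluded,
        n_filtered_out=n_unassigned + n_blind_dropped,
        params={
            "viewpoint_fragment": vp_frag.id,
            "exclude_blind": exclude_blind,
        },
    )
    kept = sum(counts.values())
    if kept + n_excluded + profile.n_filtered_out != total:
        raise AssertionError("read conservation identity violated")
    return profile
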