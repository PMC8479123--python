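"""Synthetic toy genomes, 4C reads and capture pairs.

The study conditions this package targets — a reciprocal translocation
placing a super-enhancer in cis with a promoter, 4C libraries from a
fixed viewpoint, targeted capture sequencing across the junction — are
emulated here at desk scale so every downstream stage is testable
without controlled-access data.

Three generators:

* :func:`make_toy_genome` — contigs with planted primary/secondary
  restriction sites, oriented CTCF motifs and enhancer-module intervals;
  filler bases are rejection-screened so the planted occurrences are the
  *only* occurrences, making every site count exact.
* :func:`simulate_4c_reads` — viewpoint reads whose ligation partners
  follow a power-law contact decay (weight ∝ s^-α over fragment-midpoint
  separation in cis) times a loop-enrichment factor at designated anchor
  fragment pairs, the structure chromosome-conformation data show around
  CTCF-anchored loops.
* :func:`simulate_capture_pairs` — paired-end capture fragments over a
  derivative chromosome, a set fraction straddling the junction (mates
  landing on different native contigs = discordant evidence) plus
  single reads crossing the junction base (split evidence).

All randomness flows from explicit seeds; identical config => identical
output bytes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pysam

from hijackscan.genome import Contig, ToyGenome, revcomp
from hijackscan.fragments import FragmentMap
from hijackscan.rearrange import DerivativeChromosome, Segment

logger = logging.getLogger(__name__)

# Forward-orientation CTCF stand-in motif planted by make_toy_genome.
# Chosen free of GATC/GTAC on both strands so motifs never collide with
# restriction sites.
CTCF_MOTIF = "CCACCAGAGGGCA"

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class MotifSpec:
    position: int  # local coordinate within the contig
    orientation: str  # "forward" | "reverse"
    label: str = ""


@dataclass(frozen=True)
class ModuleSpec:
    name: str
    start: int  # local
    end: int


@dataclass
class ContigSpec:
    """Description of one toy contig.

    ``primary_sites``/``secondary_sites`` are local coordinates where the
    recognition sequences (GATC / GTAC) are planted; ``origin`` shifts
    all emitted coordinates so a small sequence can emulate a
    genome-scale locus.
    """

    name: str
    length: int
    origin: int = 0
    primary_sites: list[int] = field(default_factory=list)
    secondary_sites: list[int] = field(default_factory=list)
    motifs: list[MotifSpec] = field(default_factory=list)
    modules: list[ModuleSpec] = field(default_factory=list)


@dataclass
class GenomeSpec:
    contigs: list[ContigSpec] = field(default_factory=list)
    primary_recognition: str = "GATC"
    secondary_recognition: str = "GTAC"
    seed: int = 0


@dataclass
class ContactModel:
    """Power-law contact decay with loop enrichment.

    Sampling weight for partner fragment f at midpoint separation s from
    the viewpoint fragment (cis, on the supplied — typically derivative —
    contig) is ``background_rate * s**-decay_exponent * enrichment(f)``,
    normalized over eligible fragments. Fragments within
    ``self_exclusion_radius`` fragments of the viewpoint are ineligible,
    emulating the self-ligation/undigested signal a 4C analysis removes.
    """

    decay_exponent: float = 1.0
    background_rate: float = 1.0
    loop_anchors: list[tuple[int, int, float]] = field(default_factory=list)
    self_exclusion_radius: int = 2

    def __post_init__(self) -> None:
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be positive")
        if self.background_rate <= 0:
            raise ValueError("background_rate must be positive")
        for a, b, e in self.loop_anchors:
            if e < 1:
                raise ValueError(f"anchor ({a},{b}): enrichment {e} < 1")

    def enrichment_for(self, viewpoint_fragment: int, fragment: int) -> float:
        for a, b, e in self.loop_anchors:
            if {a, b} == {viewpoint_fragment, fragment}:
                return e
        return 1.0


@dataclass
class SimulationConfig:
    seed: int = 0
    n_reads: int = 1000
    read_length: int = 75
    insert_mean: int = 400
    insert_sd: int = 40
    junction_span_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not 0 <= self.junction_span_fraction <= 1:
            raise ValueError("junction_span_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# Toy genome construction


def _screened_filler(rng: np.random.Generator, n: int, forbidden: list[str]) -> str:
    """Random ACGT filler containing none of the forbidden motifs.

    Occurrences are destroyed by re-randomizing one base inside each hit
    until a clean scan; guaranteed to terminate for short motif lists.
    """
    arr = rng.choice(_BASES, size=n)
    for _ in range(200):
        seq = arr.tobytes().decode()
        hits: list[tuple[int, int]] = []
        for motif in forbidden:
            start = 0
            while (i := seq.find(motif, start)) >= 0:
                hits.append((i, len(motif)))
                start = i + 1
        if not hits:
            return seq
        for i, mlen in hits:
            arr[i + int(rng.integers(mlen))] = rng.choice(_BASES)
    raise RuntimeError("filler screening did not converge")  # pragma: no cover


def make_toy_genome(spec: GenomeSpec) -> tuple[ToyGenome, dict[str, list[str]]]:
    """Build a toy genome with exactly the planted features.

    Returns the genome plus BED-format annotation lines (0-based
    half-open, origin-shifted) under keys ``"ctcf"`` and ``"modules"``.
    Raises ValueError for infeasible specs (overlapping plants, plants
    out of range), naming the conflicting elements.
    """
    prim, sec = spec.primary_recognition, spec.secondary_recognition
    forbidden = [prim, sec, CTCF_MOTIF, revcomp(CTCF_MOTIF)]
    rng = np.random.default_rng(spec.seed)
    contigs: list[Contig] = []
    bed: dict[str, list[str]] = {"ctcf": [], "modules": []}

    for cs in spec.contigs:
        plants: list[tuple[int, str, str]] = []  # (local pos, seq, label)
        for p in cs.primary_sites:
            plants.append((p, prim, f"primary@{p}"))
        for p in cs.secondary_sites:
            plants.append((p, sec, f"secondary@{p}"))
        for m in cs.motifs:
            seq = CTCF_MOTIF if m.orientation == "forward" else revcomp(CTCF_MOTIF)
            plants.append((m.position, seq, f"motif:{m.label or m.orientation}@{m.position}"))
        plants.sort()
        prev_end, prev_label = 0, "contig start"
        for pos, seq, label in plants:
            if pos < prev_end:
                raise ValueError(
                    f"contig {cs.name!r}: {label} overlaps {prev_label}"
                )
            if pos + len(seq) > cs.length:
                raise ValueError(
                    f"contig {cs.name!r}: {label} extends past contig end"
                )
            prev_end, prev_label = pos + len(seq), label

        pieces: list[str] = []
        cursor = 0
        for pos, seq, _ in plants:
            pieces.append(_screened_filler(rng, pos - cursor, forbidden))
            pieces.append(seq)
            cursor = pos + len(seq)
        pieces.append(_screened_filler(rng, cs.length - cursor, forbidden))
        sequence = "".join(pieces)

        # Verify no accidental occurrences arose at filler/plant junctions.
        for motif in forbidden:
            expected = sum(1 for _, s, _ in plants if s == motif)
            found = _count_occurrences(sequence, motif)
            if found != expected:
                raise ValueError(
                    f"contig {cs.name!r}: accidental {motif} occurrence at a "
                    "plant boundary; adjust spacings"
                )
        contigs.append(Contig(cs.name, sequence, cs.origin))

        for m in cs.motifs:
            strand = "+" if m.orientation == "forward" else "-"
            s0 = cs.origin + m.position
            bed["ctcf"].append(
                f"{cs.name}\t{s0}\t{s0 + len(CTCF_MOTIF)}\t{m.label or 'ctcf'}\t0\t{strand}"
            )
        for mod in cs.modules:
            bed["modules"].append(
                f"{cs.name}\t{cs.origin + mod.start}\t{cs.origin + mod.end}\t{mod.name}\t0\t+"
            )
    return ToyGenome(contigs), bed


def make_translocation_scenario(
    seed: int = 5,
    contig_len: int = 200_000,
    origin_a: int = 168_800_000,
    origin_b: int = 130_400_000,
    break_a: int = 168_917_999,
    break_b: int = 130_487_191,
    names: tuple[str, str] = ("chr3", "chr8"),
    der_name: str = "der3",
) -> tuple[ToyGenome, DerivativeChromosome, tuple[int, int]]:
    """Two-contig toy genome plus the derivative of a reciprocal translocation.

    ``break_a``/``break_b`` are 1-based printed-style coordinates (last
    retained base of partner A, first retained base of partner B); the
    defaults encode a t(3;8)(q26;q24)-style junction on 200 kb loci with
    genome-scale origins. The filler is re-seeded until the junction
    carries no single-base microhomology, so split-read refinement has a
    unique base-pair answer — real junctions with microhomology are only
    resolvable to a range, which the toy scenario deliberately avoids.
    """
    pa, pb = break_a, break_b - 1  # 0-based: exclusive end / inclusive start
    genome = None
    for attempt in range(64):
        genome, _ = make_toy_genome(
            GenomeSpec(
                [
                    ContigSpec(names[0], contig_len, origin_a),
                    ContigSpec(names[1], contig_len, origin_b),
                ],
                seed=seed + 1000 * attempt,
            )
        )
        a, b = genome[names[0]], genome[names[1]]
        left_amb = b.slice(pb - 1, pb) == a.slice(pa - 1, pa)
        right_amb = a.slice(pa, pa + 1) == b.slice(pb, pb + 1)
        if not (left_amb or right_amb):
            break
    else:  # pragma: no cover
        raise RuntimeError("could not build a microhomology-free junction")
    der = DerivativeChromosome(
        der_name,
        [
            Segment(names[0], origin_a, pa),
            Segment(names[1], pb, origin_b + contig_len),
        ],
    )
    return genome, der, (break_a, break_b)


def _count_occurrences(seq: str, motif: str) -> int:
    n = start = 0
    while True:
        i = seq.find(motif, start)
        if i < 0:
            return n
        n += 1
        start = i + 1


# ---------------------------------------------------------------------------
# 4C read simulation


@dataclass
class FourCReadSet:
    """Simulated 4C reads with their ground truth."""

    records: list[tuple[str, str]]  # (name, sequence)
    source_fragments: list[int]  # partner fragment id per read
    weights: dict[int, float]  # sampling weight per eligible fragment

    def truth_counts(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for f in self.source_fragments:
            out[f] = out.get(f, 0) + 1
        return out

    def to_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.records:
                fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def simulate_4c_reads(
    genome: ToyGenome,
    fragments: FragmentMap,
    viewpoint,
    model: ContactModel,
    cfg: SimulationConfig,
) -> FourCReadSet:
    """Emit error-free 4C reads for one viewpoint.

    Each read is the viewpoint reading primer (ending in the primary
    recognition motif) followed by the partner fragment's left-end
    sequence continued past the shared motif, padded to ``read_length``.
    Partners are drawn per the ContactModel over cis fragments on the
    viewpoint's contig; fragments within the self-exclusion radius, and
    fragments too short to fill a read, are never sampled.
    """
    primer = viewpoint.reading_primer
    motif = fragments.primary.recognition
    tail_len = cfg.read_length - len(primer)
    if tail_len <= 0:
        raise ValueError(
            f"read_length {cfg.read_length} not longer than primer ({len(primer)} bp)"
        )
    vp_frag = fragments.lookup(viewpoint.contig, viewpoint.position)
    if vp_frag is None:
        raise ValueError(
            f"viewpoint position {viewpoint.contig}:{viewpoint.position} "
            "not covered by any fragment"
        )

    need = len(motif) + tail_len
    eligible: list[int] = []
    weights: list[float] = []
    vp_mid = vp_frag.midpoint
    contig_seq = genome[viewpoint.contig]
    for f in fragments.by_contig(viewpoint.contig):
        if abs(f.id - vp_frag.id) <= model.self_exclusion_radius:
            continue
        if len(f) < need:
            continue
        # only fragment ends at genuine cuts ligate; a contig-terminal
        # fragment whose left edge is the sequence start cannot yield a
        # motif-anchored junction read
        if contig_seq.slice(f.start, f.start + len(motif)) != motif:
            continue
        s = abs(f.midpoint - vp_mid)
        if s == 0:
            continue
        w = (
            model.background_rate
            * s ** (-model.decay_exponent)
            * model.enrichment_for(vp_frag.id, f.id)
        )
        eligible.append(f.id)
        weights.append(w)
    if cfg.n_reads > 0 and not eligible:
        raise ValueError("no eligible partner fragments for this viewpoint/model")

    rng = np.random.default_rng(cfg.seed)
    records: list[tuple[str, str]] = []
    sources: list[int] = []
    if cfg.n_reads > 0:
        p = np.asarray(weights) / np.sum(weights)
        chosen = rng.choice(len(eligible), size=cfg.n_reads, p=p)
        for i, ci in enumerate(chosen):
            f = fragments[eligible[ci]]
            contig = genome[f.contig]
            tail = contig.slice(f.start + len(motif), f.start + len(motif) + tail_len)
            records.append((f"fourc_{viewpoint.name}_{i}", primer + tail))
            sources.append(f.id)
    return FourCReadSet(records, sources, dict(zip(eligible, weights)))


# ---------------------------------------------------------------------------
# Capture pair simulation


@dataclass
class CapturePairSet:
    """Simulated capture library over a derivative, with ground truth."""

    header: dict
    alignments: list[pysam.AlignedSegment]
    spanning_reads: list[tuple[str, str]]  # junction-crossing (name, seq)
    straddling_names: list[str]  # qnames of junction-straddling pairs
    junction: dict  # native coordinates of the junction

    def to_sam(self, path: str | Path) -> None:
        with pysam.AlignmentFile(str(path), "w", header=self.header) as fh:
            for a in self.alignments:
                fh.write(a)

    def spanning_to_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.spanning_reads:
                fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def simulate_capture_pairs(
    genome: ToyGenome,
    derivative: DerivativeChromosome,
    cfg: SimulationConfig,
    n_pairs: Optional[int] = None,
) -> CapturePairSet:
    """Paired-end capture fragments over a derivative chromosome.

    A fraction ``junction_span_fraction`` of fragments straddle the
    first junction with both mates clear of the junction base, so the
    pair is discordant (mates on different native contigs for a
    translocation). Each straddling fragment also yields one
    junction-crossing single read centered on the junction (split
    evidence). Remaining fragments are concordant background placed
    entirely within single segments.
    """
    if not derivative.segments:
        raise ValueError("derivative with zero segments")
    n_pairs = cfg.n_reads if n_pairs is None else n_pairs
    rng = np.random.default_rng(cfg.seed)
    junction = derivative.junctions[0] if derivative.junctions else None
    L = cfg.read_length
    der_seq = derivative.sequence(genome)

    if junction is not None:
        if junction < cfg.insert_mean or len(derivative) - junction < cfg.insert_mean:
            raise ValueError("junction closer than insert_mean to a derivative end")

    contig_order = []
    for seg in derivative.segments:
        if seg.contig not in contig_order:
            contig_order.append(seg.contig)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": name, "LN": genome[name].end} for name in contig_order
        ],
    }
    tid = {name: i for i, name in enumerate(contig_order)}
    sam_header = pysam.AlignmentHeader.from_dict(header)

    n_span = int(round(cfg.junction_span_fraction * n_pairs)) if junction is not None else 0
    alignments: list[pysam.AlignedSegment] = []
    spanning: list[tuple[str, str]] = []
    straddling: list[str] = []

    def native_interval(d0: int, d1: int) -> tuple[str, int, int, str]:
        """Native (contig, start, end, strand) for a derivative interval
        wholly inside one segment."""
        c0 = derivative.map_from(d0)
        c1 = derivative.map_from(d1 - 1)
        assert c0 is not None and c1 is not None and c0[0] == c1[0]
        lo, hi = sorted((c0[1], c1[1]))
        strand = "+" if c0[1] <= c1[1] else "-"
        return c0[0], lo, hi + 1, strand

    def make_pair(qname: str, d0: int, insert: int) -> None:
        d1 = d0 + insert
        r1c, r1s, r1e, r1strand = native_interval(d0, d0 + L)
        r2c, r2s, r2e, r2strand = native_interval(d1 - L, d1)
        seq1 = der_seq[d0 : d0 + L]
        seq2 = der_seq[d1 - L : d1]  # reference-forward, as SAM stores it
        for idx, (c, s, e, seg_strand, seq) in enumerate(
            [(r1c, r1s, r1e, r1strand, seq1), (r2c, r2s, r2e, r2strand, seq2)]
        ):
            a = pysam.AlignedSegment(header=sam_header)
            a.query_name = qname
            # read1 sequenced forward on the derivative, read2 reverse;
            # native strand flips where the segment is inverted
            der_rev = idx == 1
            seg_rev = seg_strand == "-"
            a.is_reverse = der_rev != seg_rev
            a.is_paired = True
            a.is_read1 = idx == 0
            a.is_read2 = idx == 1
            a.reference_id = tid[c]
            a.reference_start = s
            a.mapping_quality = 60
            a.cigarstring = f"{L}M"
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array("I" * L)
            other = (r2c, r2s) if idx == 0 else (r1c, r1s)
            a.next_reference_id = tid[other[0]]
            a.next_reference_start = other[1]
            a.is_proper_pair = r1c == r2c
            alignments.append(a)

    i_span = 0
    for i in range(n_pairs):
        insert = int(
            np.clip(
                rng.normal(cfg.insert_mean, cfg.insert_sd),
                3 * L,
                cfg.insert_mean + 3 * cfg.insert_sd,
            )
        )
        qname = f"pair_{i}"
        if i < n_span:
            # place the junction strictly between the two mates
            insert = min(insert, junction, len(derivative) - junction)
            lo = junction - insert + L + 1
            hi = junction - L - 1
            d0 = int(rng.integers(lo, hi + 1))
            make_pair(qname, d0, insert)
            straddling.append(qname)
            # one junction-crossing read per straddling fragment
            off = int(rng.integers(10, L - 10))
            s0 = junction - off
            spanning.append((f"span_{i_span}", der_seq[s0 : s0 + L]))
            i_span += 1
        else:
            # concordant background within a single segment
            seg_i = int(rng.integers(len(derivative.segments)))
            seg = derivative.segments[seg_i]
            off0 = derivative.junctions[seg_i - 1] if seg_i > 0 else 0
            if len(seg) < insert + 2:
                insert = len(seg) - 2
            d0 = off0 + int(rng.integers(0, len(seg) - insert + 1))
            make_pair(qname, d0, insert)

    jct = {}
    if junction is not None:
        seg_a = derivative.segments[0]
        seg_b = derivative.segments[1]
        jct = {
            "contig_a": seg_a.contig,
            "pos_a": seg_a.end if seg_a.orientation == "+" else seg_a.start,
            "side_a": "right-of" if seg_a.orientation == "+" else "left-of",
            "contig_b": seg_b.contig,
            "pos_b": seg_b.start if seg_b.orientation == "+" else seg_b.end,
            "side_b": "left-of" if seg_b.orientation == "+" else "right-of",
        }
    return CapturePairSet(header, alignments, spanning, straddling, jct)
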