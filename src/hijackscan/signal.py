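"""Signal tracks: RPM normalization, running-mean smoothing, WIG/bedGraph.

4C contact profiles are normalized to reads per million (RPM) over the
kept reads, smoothed with a running mean (default window 21 fragments,
shrinking at contig edges), and exported as WIG (variableStep, 1-based
fragment midpoints) or bedGraph (0-based half-open fragment intervals).
Fixed-bin RPKM coverage tracks and a contact-domain extent summary — the
genomic span of the contiguous high-interaction zone around a viewpoint
target, the kind of multi-hundred-kb stretch seen between a hijacked
super-enhancer and its captured promoter — round out the module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Optional

import numpy as np

from hijackscan.fourc import ContactProfile
from hijackscan.fragments import FragmentMap

logger = logging.getLogger(__name__)


@dataclass
class SmoothingConfig:
    """Running-mean configuration; the window must be odd.

    ``edge_policy`` is always ``shrink``: near contig edges the mean is
    taken only over positions that exist, never over padding.
    """

    window: int = 21
    edge_policy: Literal["shrink"] = "shrink"

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and positive, got {self.window}")


@dataclass
class TrackInterval:
    contig: str
    start: int
    end: int
    value: float


@dataclass
class SignalTrack:
    """Ordered (interval, value) series, per-fragment or fixed-bin."""

    kind: Literal["per-fragment", "fixed-bin"]
    intervals: list[TrackInterval]
    bin_size: Optional[int] = None
    normalization: Literal["raw", "RPM", "RPKM"] = "raw"
    smoothing: str = "none"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        last: dict[str, int] = {}
        for iv in self.intervals:
            if not np.isfinite(iv.value) or iv.value < 0:
                raise ValueError(
                    f"invalid value {iv.value} at {iv.contig}:{iv.start}"
                )
            if iv.contig in last and iv.start < last[iv.contig]:
                raise ValueError(f"unordered positions on {iv.contig}")
            last[iv.contig] = iv.start

    def values(self, contig: str) -> np.ndarray:
        return np.array([iv.value for iv in self.intervals if iv.contig == contig])

    def contigs(self) -> list[str]:
        seen: list[str] = []
        for iv in self.intervals:
            if iv.contig not in seen:
                seen.append(iv.contig)
        return seen


def profile_track(
    profile: ContactProfile,
    fragmap: FragmentMap,
    use_normalized: bool = False,
) -> SignalTrack:
    """Per-fragment SignalTrack from a contact profile (zero-filled over
    all countable fragments of the profile's contigs)."""
    vals = profile.normalized if use_normalized else profile.counts
    if use_normalized and profile.normalized is None:
        raise ValueError("profile has no normalized values; run rpm_normalize first")
    ivs = [
        TrackInterval(f.contig, f.start, f.end, float(vals.get(f.id, 0.0)))
        for f in fragmap
    ]
    return SignalTrack(
        "per-fragment",
        ivs,
        normalization="RPM" if use_normalized else "raw",
        params={"viewpoint": profile.viewpoint.name},
    )


# ---------------------------------------------------------------------------


def rpm_normalize(profile: ContactProfile) -> ContactProfile:
    """Normalize counts to reads per million of kept reads.

    The denominator is the total of kept (post-filter, post-exclusion)
    counts, so normalized values always sum to 1e6 and profiles are
    comparable across viewpoints regardless of sequencing depth.
    """
    depth = profile.depth
    if depth == 0:
        raise ValueError(
            "zero-depth profile cannot be RPM-normalized; export raw counts instead"
        )
    normalized = {fid: c * 1e6 / depth for fid, c in profile.counts.items()}
    out = replace(profile, normalized=normalized)
    out.params = dict(profile.params, rpm_denominator=depth)
    return out


def running_mean(values: Iterable[float], cfg: SmoothingConfig | int = 21) -> np.ndarray:
    """Running mean with shrinking edges over one contig's ordered values.

    smoothed[i] = mean(values[max(0, i-h) : i+h+1]), h = (window-1)/2.
    Output length equals input length; a constant vector is unchanged.
    """
    if isinstance(cfg, int):
        cfg = SmoothingConfig(cfg)
    x = np.asarray(list(values), dtype=float)
    n = len(x)
    if n == 0:
        return x
    h = (cfg.window - 1) // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    i = np.arange(n)
    lo = np.maximum(i - h, 0)
    hi = np.minimum(i + h + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def smooth_track(track: SignalTrack, cfg: SmoothingConfig | int = 21) -> SignalTrack:
    """Smooth a track contig-by-contig; windows never span contigs."""
    if isinstance(cfg, int):
        cfg = SmoothingConfig(cfg)
    out: list[TrackInterval] = []
    for contig in track.contigs():
        ivs = [iv for iv in track.intervals if iv.contig == contig]
        sm = running_mean([iv.value for iv in ivs], cfg)
        out.extend(replace(iv, value=float(v)) for iv, v in zip(ivs, sm))
    return SignalTrack(
        track.kind,
        out,
        bin_size=track.bin_size,
        normalization=track.normalization,
        smoothing=f"running_mean({cfg.window})",
        params=dict(track.params),
    )


# ---------------------------------------------------------------------------
# Export


def write_wig(track: SignalTrack, path: str | Path, name: str = "hijackscan") -> None:
    """variableStep WIG; per-fragment values anchored at 1-based midpoints."""
    with open(path, "w") as fh:
        fh.write(
            f'track type=wiggle_0 name="{name}" '
            f"description=\"norm={track.normalization} smooth={track.smoothing}\"\n"
        )
        for contig in track.contigs():
            fh.write(f"variableStep chrom={contig}\n")
            for iv in track.intervals:
                if iv.contig != contig:
                    continue
                mid = (iv.start + iv.end) // 2 + 1  # 1-based midpoint
                fh.write(f"{mid}\t{iv.value:g}\n")


def write_bedgraph(track: SignalTrack, path: str | Path, name: str = "hijackscan") -> None:
    with open(path, "w") as fh:
        fh.write(
            f'track type=bedGraph name="{name}" '
            f"description=\"norm={track.normalization} smooth={track.smoothing}\"\n"
        )
        for iv in track.intervals:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.value:g}\n")


def read_bedgraph(path: str | Path, kind: str = "per-fragment") -> SignalTrack:
    """Round-trip reader for bedGraph written by :func:`write_bedgraph`."""
    ivs = []
    norm, smooth = "raw", "none"
    for line in open(path):
        if line.startswith("track"):
            if "norm=" in line:
                norm = line.split("norm=")[1].split()[0]
            if "smooth=" in line:
                smooth = line.split("smooth=")[1].split('"')[0].strip()
            continue
        if not line.strip():
            continue
        c, s, e, v = line.split()
        ivs.append(TrackInterval(c, int(s), int(e), float(v)))
    return SignalTrack(kind, ivs, normalization=norm, smoothing=smooth)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# Binned coverage


def binned_coverage(
    reads: list[tuple[str, int, int]],
    genome_sizes: dict[str, tuple[int, int]],
    bin_size: int = 20,
    smooth_length: int = 100,
    library_size: Optional[int] = None,
) -> SignalTrack:
    """RPKM-normalized fixed-bin coverage with running-mean smoothing.

    Reads are (contig, start, end) intervals; a read contributes to every
    bin it overlaps. RPKM = count * 1e9 / (library_size * bin_size). The
    smoothing window is smooth_length / bin_size bins, incremented to odd
    if even (logged).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if not reads:
        raise ValueError("empty read library")
    library_size = library_size if library_size is not None else len(reads)
    if smooth_length % bin_size:
        logger.info("smooth_length %d rounded down to a bin multiple", smooth_length)
    win = max(1, smooth_length // bin_size)
    if win % 2 == 0:
        win += 1
        logger.info("smoothing window incremented to odd: %d bins", win)

    ivs: list[TrackInterval] = []
    for contig, (lo, hi) in genome_sizes.items():
        n_bins = -(-(hi - lo) // bin_size)
        counts = np.zeros(n_bins)
        for c, s, e in reads:
            if c != contig:
                continue
            b0 = max(0, (s - lo) // bin_size)
            b1 = min(n_bins - 1, (e - 1 - lo) // bin_size)
            counts[b0 : b1 + 1] += 1
        rpkm = counts * 1e9 / (library_size * bin_size)
        sm = running_mean(rpkm, SmoothingConfig(win))
        for b in range(n_bins):
            ivs.append(
                TrackInterval(
                    contig,
                    lo + b * bin_size,
                    min(hi, lo + (b + 1) * bin_size),
                    float(sm[b]),
                )
            )
    return SignalTrack(
        "fixed-bin",
        ivs,
        bin_size=bin_size,
        normalization="RPKM",
        smoothing=f"running_mean({win})",
        params={"library_size": library_size, "smooth_length": smooth_length},
    )


# ---------------------------------------------------------------------------
# Interaction extent


def contact_domain_extent(
    track: SignalTrack,
    region: tuple[str, int, int],
    threshold_fraction: float = 0.5,
) -> tuple[int, list[TrackInterval]]:
    """Extent of the strongest contiguous high-signal run in a region.

    Within the region, the maximal run of consecutive intervals whose
    value >= threshold_fraction * regional maximum is found; the extent
    is end(last) - start(first) in bp. An all-zero region has extent 0.
    """
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must be in (0, 1]")
    contig, lo, hi = region
    ivs = [
        iv
        for iv in track.intervals
        if iv.contig == contig and iv.end > lo and iv.start < hi
    ]
    if not ivs:
        raise ValueError(f"region {contig}:{lo}-{hi} overlaps no track interval")
    peak = max(iv.value for iv in ivs)
    if peak == 0:
        return 0, []
    thr = threshold_fraction * peak
    best: list[TrackInterval] = []
    cur: list[TrackInterval] = []
    for iv in ivs:
        if iv.value >= thr:
            cur.append(iv)
            if len(cur) > len(best):
                best = list(cur)
        else:
            cur = []
    extent = best[-1].end - best[0].start if best else 0
    return extent, best
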