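"""Track operations: scaling factors, smoothing, two-file arithmetic and the
assay presets (replication timing, OK-seq RFD, END-seq).

Missing bins are NaN throughout; writers skip them.  A genuine 0 (e.g.
balanced replication forks) is therefore distinguishable from no data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coverage import AlignmentFilter, BinnedTrack, LibraryStats, binned_coverage

__all__ = [
    "ScalingSpec",
    "genome_size_factor",
    "libsize_factors",
    "scale_track",
    "smooth_track",
    "log2_ratio",
    "subtract",
    "rfd_track",
    "reptime_track",
    "endseq_tracks",
]


@dataclass(frozen=True)
class ScalingSpec:
    """How to derive per-sample scaling factors.

    ``genome`` scales each sample independently by genome length over
    aligned bases (i.e. divides by mean sequencing depth); ``libsize``
    scales a co-processed set to its smallest library; ``custom`` applies
    user-supplied positive factors; ``none`` leaves coverage raw.
    """

    method: str = "genome"  # genome | libsize | custom | none
    custom_factors: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.method not in ("genome", "libsize", "custom", "none"):
            raise ValueError(f"unknown scaling method: {self.method!r}")
        if self.method == "custom" and any(f <= 0 for f in self.custom_factors):
            raise ValueError("custom factors must be positive")

    def factors(self, stats: list[LibraryStats]) -> list[float]:
        if self.method == "none":
            return [1.0] * len(stats)
        if self.method == "genome":
            return [genome_size_factor(s) for s in stats]
        if self.method == "libsize":
            return libsize_factors(stats)
        if len(self.custom_factors) != len(stats):
            raise ValueError(
                f"{len(self.custom_factors)} custom factors for {len(stats)} samples"
            )
        return list(self.custom_factors)


def genome_size_factor(stats: LibraryStats) -> float:
    """Genome length / aligned bases — the reciprocal of mean depth.

    Multiplying a coverage track by it reduces values when more bases were
    sequenced than the genome holds and raises them otherwise, so samples
    become depth-comparable without co-processing.
    """
    if stats.aligned_bases <= 0:
        raise ValueError("no aligned bases; cannot derive a genome-size factor")
    if stats.genome_length <= 0:
        raise ValueError("genome length must be positive")
    return stats.genome_length / stats.aligned_bases


def libsize_factors(stats_list: list[LibraryStats]) -> list[float]:
    """Per-sample factors scaling each library to the smallest in the set."""
    if not stats_list:
        raise ValueError("need at least one sample")
    reads = [s.n_reads for s in stats_list]
    if any(r <= 0 for r in reads):
        raise ValueError("every library must have passing reads")
    smallest = min(reads)
    return [smallest / r for r in reads]


def scale_track(track: BinnedTrack, factor: float) -> BinnedTrack:
    if factor <= 0:
        raise ValueError("scaling factor must be positive")
    out = track.copy(kind="scaled")
    for chrom in out.data:
        out.data[chrom] = out.data[chrom] * factor
    return out


def smooth_track(track: BinnedTrack, n_adjacent: int) -> BinnedTrack:
    """Sliding-window mean over bins [i - n, i + n], per chromosome.

    The window truncates at chromosome ends (no zero padding), so edge bins
    average over fewer neighbours; n_adjacent = 0 is the identity and the
    window never crosses a chromosome boundary.
    """
    if n_adjacent < 0:
        raise ValueError("n_adjacent must be >= 0")
    out = track.copy()
    if n_adjacent == 0:
        return out
    for chrom, values in out.data.items():
        out.data[chrom] = _windowed_mean(values, n_adjacent)
    return out


def _windowed_mean(values: np.ndarray, n: int) -> np.ndarray:
    # cumulative-sum sliding window with truncated edges
    m = len(values)
    csum = np.concatenate(([0.0], np.cumsum(values)))
    idx = np.arange(m)
    lo = np.maximum(idx - n, 0)
    hi = np.minimum(idx + n + 1, m)
    return (csum[hi] - csum[lo]) / (hi - lo)


def _check_geometry(t1: BinnedTrack, t2: BinnedTrack) -> None:
    if not t1.same_geometry(t2):
        raise ValueError("tracks differ in bin size or chromosome set")


def log2_ratio(
    track1: BinnedTrack, track2: BinnedTrack, pseudocount: float = 0.0
) -> BinnedTrack:
    """Per-bin log2((v1 + p) / (v2 + p)); first track is the numerator.

    With the default pseudocount 0, bins where either side is 0 become
    missing (NaN) rather than fabricating an infinite or arbitrary ratio.
    """
    _check_geometry(track1, track2)
    out = track1.copy(kind="log2")
    for chrom in out.data:
        v1 = track1.data[chrom] + pseudocount
        v2 = track2.data[chrom] + pseudocount
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where((v1 > 0) & (v2 > 0), v1 / v2, np.nan)
            out.data[chrom] = np.log2(ratio)
    return out


def subtract(track1: BinnedTrack, track2: BinnedTrack) -> BinnedTrack:
    """Bin-wise track1 - track2; values may be negative."""
    _check_geometry(track1, track2)
    out = track1.copy(kind="difference")
    for chrom in out.data:
        out.data[chrom] = track1.data[chrom] - track2.data[chrom]
    return out


def rfd_track(
    bam_path: str,
    flt: AlignmentFilter = AlignmentFilter(),
    bin_size: int = 1000,
    orientation: str = "forward",
    threads: int = 1,
) -> BinnedTrack:
    """Replication fork directionality from OK-seq alignments.

    Per bin: (Crick - Watson) / (Crick + Watson), where Watson is the
    forward-strand and Crick the reverse-strand coverage under the same
    filters.  Values lie in [-1, 1]; right of a replication origin Okazaki
    fragments map to Crick, so an initiation zone shows a - to + transition.
    Bins with no coverage on either strand are missing.
    """
    watson = binned_coverage(
        bam_path, flt, bin_size, strand="forward", orientation=orientation,
        threads=threads,
    )
    crick = binned_coverage(
        bam_path, flt, bin_size, strand="reverse", orientation=orientation,
        threads=threads,
    )
    out = watson.copy(kind="rfd")
    for chrom in out.data:
        w = watson.data[chrom]
        c = crick.data[chrom]
        total = w + c
        with np.errstate(divide="ignore", invalid="ignore"):
            out.data[chrom] = np.where(total > 0, (c - w) / total, np.nan)
    return out


def reptime_track(
    bam_path1: str,
    bam_path2: str,
    flt: AlignmentFilter = AlignmentFilter(),
    bin_size: int = 100,
    smooth_bins: int = 500,
    pseudocount: float = 0.0,
    threads: int = 1,
) -> BinnedTrack:
    """Replication-timing log2 ratio of two cell-cycle fractions.

    Both files are binned (default 100 bp) and smoothed (default 500
    adjacent bins) before the log2 ratio, first file over second; pass the
    fraction you want in the numerator first.  Single-cell repli-seq and
    BrdU-IP data are conventionally run at 50 kb bins with 4-bin smoothing.
    """
    t1 = binned_coverage(bam_path1, flt, bin_size, threads=threads)
    t2 = binned_coverage(bam_path2, flt, bin_size, threads=threads)
    if not t1.same_geometry(t2):
        raise ValueError("BAM files disagree on reference chromosomes")
    t1 = smooth_track(t1, smooth_bins)
    t2 = smooth_track(t2, smooth_bins)
    return log2_ratio(t1, t2, pseudocount)


def endseq_tracks(
    bam_path: str,
    flt: AlignmentFilter = AlignmentFilter(),
    bin_size: int = 1,
    negate_reverse: bool = False,
    orientation: str = "forward",
    threads: int = 1,
) -> tuple[BinnedTrack, BinnedTrack]:
    """Strand-resolved coverage for double-strand-break mapping.

    Returns (forward, reverse) tracks; with ``negate_reverse`` every
    reverse-track value is multiplied by -1 so the two strands can be
    overlaid in one panel.
    """
    fwd = binned_coverage(
        bam_path, flt, bin_size, strand="forward", orientation=orientation,
        threads=threads,
    )
    rev = binned_coverage(
        bam_path, flt, bin_size, strand="reverse", orientation=orientation,
        threads=threads,
    )
    if negate_reverse:
        for chrom in rev.data:
            rev.data[chrom] = -rev.data[chrom]
    return fwd, rev
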