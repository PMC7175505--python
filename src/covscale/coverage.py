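"""Read filtering, library statistics and coverage extraction from BAM files.

Coverage is defined per base: the value at base ``b`` is the number of
filter-passing reads whose aligned reference segments cover ``b``.  Aligned
segments are the CIGAR ``M``/``=``/``X`` runs; skipped introns (``N``) are
treated as covered in the default (DNA) mode and as gaps in splice-aware
(RNA) mode.  Deletions (``D``) are never covered.  Binned tracks store the
mean per-base depth of each bin, which makes values comparable across bin
sizes and directly usable in ratio operations.

All coordinates are 0-based half-open; BAM's internal coordinates already
are, BED input is too, and bigWig output expects them.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pysam

__all__ = [
    "AlignmentFilter",
    "LibraryStats",
    "BinnedTrack",
    "IntervalTrack",
    "read_passes_filter",
    "read_strand",
    "aligned_segments",
    "compute_library_stats",
    "per_base_coverage",
    "binned_coverage",
]

_COVERED_OPS = frozenset({0, 7, 8})  # M, =, X
_REF_SKIP_OPS = frozenset({2, 3})  # D, N consume reference but carry no signal


@dataclass(frozen=True)
class AlignmentFilter:
    """Read-level inclusion rules defining the effective library.

    Defaults drop duplicate, secondary, supplementary, QC-fail and unmapped
    reads, and discard paired reads whose mate maps to a different
    chromosome — such discordant pairs are a known source of spurious peak
    signal.  ``min_mapq=0`` means no mapping-quality cut unless requested.

    ``fragment_mode`` switches paired-end counting from per-read to
    per-fragment.  ``strand_select`` restricts counting/coverage to reads on
    one strand, or to the strand of each feature (``match_feature``, peak
    counting only).
    """

    min_mapq: int = 0
    drop_duplicates: bool = True
    drop_secondary: bool = True
    drop_supplementary: bool = True
    drop_qcfail: bool = True
    drop_unmapped: bool = True
    require_same_chrom_mate: bool = True
    fragment_mode: bool = False
    strand_select: str = "both"  # both | forward | reverse | match_feature

    def __post_init__(self) -> None:
        if self.strand_select not in ("both", "forward", "reverse", "match_feature"):
            raise ValueError(f"unknown strand_select: {self.strand_select!r}")
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")

    def with_strand(self, strand_select: str) -> "AlignmentFilter":
        return replace(self, strand_select=strand_select)


@dataclass(frozen=True)
class LibraryStats:
    """Per-BAM totals over filter-passing reads (full pass, never the index).

    ``aligned_bases`` sums reference-consuming match operations (M/=/X) per
    passing read.  ``genome_length`` is the sum of contig lengths declared in
    the BAM header.
    """

    n_reads: int
    n_fragments: int
    aligned_bases: int
    genome_length: int

    def effective_size(self, fragment_mode: bool = False) -> int:
        return self.n_fragments if fragment_mode else self.n_reads


@dataclass
class BinnedTrack:
    """Fixed-bin signal: one dense array per chromosome, NaN = missing bin.

    Bin ``i`` of a chromosome of length ``L`` covers ``[i*bin_size,
    min((i+1)*bin_size, L))``; the array length is ``ceil(L / bin_size)``.
    ``kind`` tags the value semantics (raw-coverage, scaled, log2, rfd,
    difference).
    """

    bin_size: int
    chrom_lengths: dict[str, int]
    data: dict[str, np.ndarray]
    kind: str = "raw-coverage"

    def __post_init__(self) -> None:
        for chrom, length in self.chrom_lengths.items():
            expect = -(-length // self.bin_size)
            got = len(self.data[chrom])
            if got != expect:
                raise ValueError(
                    f"{chrom}: {got} bins for length {length} at bin_size "
                    f"{self.bin_size}, expected {expect}"
                )

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    def bin_bounds(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) arrays of every bin on ``chrom``."""
        length = self.chrom_lengths[chrom]
        n = len(self.data[chrom])
        starts = np.arange(n, dtype=np.int64) * self.bin_size
        ends = np.minimum(starts + self.bin_size, length)
        return starts, ends

    def bin_widths(self, chrom: str) -> np.ndarray:
        starts, ends = self.bin_bounds(chrom)
        return ends - starts

    def copy(self, kind: str | None = None) -> "BinnedTrack":
        return BinnedTrack(
            bin_size=self.bin_size,
            chrom_lengths=dict(self.chrom_lengths),
            data={c: v.copy() for c, v in self.data.items()},
            kind=self.kind if kind is None else kind,
        )

    def same_geometry(self, other: "BinnedTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and self.chrom_lengths == other.chrom_lengths
        )


@dataclass
class IntervalTrack:
    """Variable-width runs of (start, end, value), sorted and non-overlapping."""

    chrom_lengths: dict[str, int]
    runs: dict[str, list[tuple[int, int, float]]] = field(default_factory=dict)

    def validate(self) -> None:
        for chrom, rr in self.runs.items():
            length = self.chrom_lengths[chrom]
            prev_end = 0
            for start, end, _ in rr:
                if not (0 <= start < end <= length):
                    raise ValueError(f"{chrom}: run [{start},{end}) out of bounds")
                if start < prev_end:
                    raise ValueError(f"{chrom}: overlapping runs at {start}")
                prev_end = end

    def to_array(self, chrom: str) -> np.ndarray:
        """Expand runs to a dense per-base array (NaN where no run)."""
        out = np.full(self.chrom_lengths[chrom], np.nan)
        for start, end, value in self.runs.get(chrom, []):
            out[start:end] = value
        return out


# ---------------------------------------------------------------------------
# read-level predicates


def read_passes_filter(read: pysam.AlignedSegment, flt: AlignmentFilter) -> bool:
    """True iff ``read`` survives every enabled rule of ``flt``.

    Pure predicate on SAM flags, MAPQ and the mate reference; strand
    selection is handled by the coverage/counting layers, not here.
    """
    if flt.drop_unmapped and read.is_unmapped:
        return False
    if flt.drop_secondary and read.is_secondary:
        return False
    if flt.drop_supplementary and read.is_supplementary:
        return False
    if flt.drop_duplicates and read.is_duplicate:
        return False
    if flt.drop_qcfail and read.is_qcfail:
        return False
    if not read.is_unmapped and read.mapping_quality < flt.min_mapq:
        return False
    if (
        flt.require_same_chrom_mate
        and read.is_paired
        and not read.mate_is_unmapped
        and read.reference_id != read.next_reference_id
    ):
        return False
    return True


def read_strand(read: pysam.AlignedSegment, orientation: str = "forward") -> str:
    """Strand ('+'/'-') assigned to a read for strand-split modes.

    Single-end reads use their own flag strand.  For paired reads the
    fragment strand is the strand of mate 1, so mate 2's flag strand is
    flipped.  ``orientation="reverse"`` flips the result, accommodating
    dUTP-style protocols where mate 1 maps antisense to the transcript.
    """
    strand = "-" if read.is_reverse else "+"
    if read.is_paired and read.is_read2:
        strand = "-" if strand == "+" else "+"
    if orientation == "reverse":
        strand = "-" if strand == "+" else "+"
    return strand


def aligned_segments(
    read: pysam.AlignedSegment, splice_aware: bool = False
) -> Iterator[tuple[int, int]]:
    """Reference segments a read covers, merged, 0-based half-open.

    M/=/X runs carry coverage; D advances the reference without coverage;
    N advances the reference and is treated as covered unless
    ``splice_aware`` (so spliced RNA reads leave intron gaps).
    """
    covered = _COVERED_OPS if splice_aware else _COVERED_OPS | {3}
    pos = read.reference_start
    seg_start = None
    for op, length in read.cigartuples or ():
        if op in covered:
            if seg_start is None:
                seg_start = pos
            pos += length
        elif op in _REF_SKIP_OPS:
            if seg_start is not None:
                yield seg_start, pos
                seg_start = None
            pos += length
        # insertions / clips consume no reference
    if seg_start is not None:
        yield seg_start, pos


def _aligned_base_count(read: pysam.AlignedSegment) -> int:
    return sum(length for op, length in read.cigartuples or () if op in _COVERED_OPS)


# ---------------------------------------------------------------------------
# library statistics


def compute_library_stats(bam_path: str, flt: AlignmentFilter) -> LibraryStats:
    """Full pass over ``bam_path`` counting filter-passing reads.

    The BAM index only knows how many records aligned, duplicates and
    low-quality reads included; the effective library size needs the same
    filters as counting, hence the full pass.  ``n_fragments`` counts each
    passing read name once (a pair with one failing mate still contributes
    one fragment).
    """
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        if bam.nreferences == 0:
            raise ValueError(f"{bam_path}: BAM header declares no sequences")
        genome_length = sum(bam.lengths)
        n_reads = 0
        n_fragments = 0
        aligned_bases = 0
        paired_names: set[str] = set()
        for read in bam.fetch(until_eof=True):
            if not read_passes_filter(read, flt):
                continue
            n_reads += 1
            if read.is_unmapped:
                continue
            aligned_bases += _aligned_base_count(read)
            if read.is_paired:
                paired_names.add(read.query_name)
            else:
                n_fragments += 1
        n_fragments += len(paired_names)
    return LibraryStats(
        n_reads=n_reads,
        n_fragments=n_fragments,
        aligned_bases=aligned_bases,
        genome_length=genome_length,
    )


# ---------------------------------------------------------------------------
# coverage


def _strand_wanted(strand: str) -> str | None:
    if strand == "both":
        return None
    if strand in ("forward", "+"):
        return "+"
    if strand in ("reverse", "-"):
        return "-"
    raise ValueError(f"unknown strand selection: {strand!r}")


def per_base_coverage(
    bam_path: str,
    chrom: str,
    start: int = 0,
    end: int | None = None,
    flt: AlignmentFilter = AlignmentFilter(),
    splice_aware: bool = False,
    strand: str = "both",
    orientation: str = "forward",
) -> np.ndarray:
    """Dense per-base depth over ``[start, end)`` of ``chrom``.

    Implemented with a difference array: +1 at each covered segment start,
    -1 at its end, then a cumulative sum.
    """
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        if chrom not in bam.references:
            raise ValueError(f"{chrom}: not in BAM header of {bam_path}")
        chrom_len = bam.get_reference_length(chrom)
        if end is None:
            end = chrom_len
        if not (0 <= start < end <= chrom_len):
            raise ValueError(f"region {chrom}:{start}-{end} outside chromosome")
        return _region_coverage(bam, chrom, start, end, flt, splice_aware, strand, orientation)


def _region_coverage(
    bam: pysam.AlignmentFile,
    chrom: str,
    start: int,
    end: int,
    flt: AlignmentFilter,
    splice_aware: bool,
    strand: str,
    orientation: str,
) -> np.ndarray:
    wanted = _strand_wanted(strand)
    diff = np.zeros(end - start + 1, dtype=np.float64)
    for read in bam.fetch(chrom, start, end):
        if not read_passes_filter(read, flt):
            continue
        if wanted is not None and read_strand(read, orientation) != wanted:
            continue
        for seg_start, seg_end in aligned_segments(read, splice_aware):
            lo = max(seg_start, start)
            hi = min(seg_end, end)
            if lo < hi:
                diff[lo - start] += 1
                diff[hi - start] -= 1
    return np.cumsum(diff[:-1])


def _bin_means(base_cov: np.ndarray, bin_size: int, chrom_len: int) -> np.ndarray:
    n_bins = -(-chrom_len // bin_size)
    offsets = np.arange(n_bins, dtype=np.int64) * bin_size
    sums = np.add.reduceat(base_cov, offsets)
    widths = np.minimum(offsets + bin_size, chrom_len) - offsets
    return sums / widths


def binned_coverage(
    bam_path: str,
    flt: AlignmentFilter = AlignmentFilter(),
    bin_size: int = 5,
    splice_aware: bool = False,
    strand: str = "both",
    orientation: str = "forward",
    threads: int = 1,
) -> BinnedTrack:
    """Genome-wide binned coverage; bin value = mean per-base depth.

    Parallelism is per chromosome with one BAM handle per worker; results
    are assembled in header order, so output is identical for any thread
    count.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        chrom_lengths = dict(zip(bam.references, bam.lengths))

    def one_chrom(chrom: str) -> np.ndarray:
        length = chrom_lengths[chrom]
        with pysam.AlignmentFile(bam_path, "rb") as bam:
            base_cov = _region_coverage(
                bam, chrom, 0, length, flt, splice_aware, strand, orientation
            )
        return _bin_means(base_cov, bin_size, length)

    chroms = list(chrom_lengths)
    if threads <= 1 or len(chroms) <= 1:
        data = {c: one_chrom(c) for c in chroms}
    else:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            results = list(pool.map(one_chrom, chroms))
        data = dict(zip(chroms, results))
    return BinnedTrack(bin_size=bin_size, chrom_lengths=chrom_lengths, data=data)
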