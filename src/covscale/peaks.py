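"""Peak quantification: raw counts over BED intervals plus FPKM, TPM and
library-size-normalized scores for one or more BAM files.

Counting rules
--------------
A read counts toward a peak when its aligned reference span (outermost
aligned coordinates, introns included) overlaps the peak by at least one
base.  A read overlapping two peaks counts in both; merge peaks upstream if
that is not wanted.  In fragment mode a properly paired fragment counts
once, evaluated on the leftmost mate over the interval
``[leftmost start, leftmost start + |TLEN|)``; improper or half-mapped
pairs fall back to per-read counting.

The effective library size used by FPKM and library-size normalization is
the number of filter-passing reads (fragments in fragment mode) from a full
pass over the BAM — never the index totals, which include duplicates and
low-quality reads.
"""

from __future__ import annotations

import logging
import os
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .coverage import (
    AlignmentFilter,
    LibraryStats,
    compute_library_stats,
    read_passes_filter,
    read_strand,
)

__all__ = [
    "Peak",
    "PeakTable",
    "read_bed",
    "count_reads_in_peaks",
    "fpkm",
    "tpm",
    "libsize_normalize",
    "quantify",
    "write_quant_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int  # 0-based
    end: int  # exclusive
    name: str
    feature_strand: str = "."  # '+', '-' or '.'

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"peak {self.name}: end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PeakTable:
    """Quantification result: peaks plus per-sample score columns.

    ``table`` holds coordinate columns followed by ``<sample>.raw`` for
    every sample, then ``.fpkm``, ``.tpm`` and ``.libnorm`` blocks.
    """

    table: pd.DataFrame
    samples: list[str]
    stats: dict[str, LibraryStats]
    effective_sizes: dict[str, int]


def read_bed(path: str) -> list[Peak]:
    """Parse a BED3/BED6 file into peaks, in file order.

    A missing name becomes ``chrom:start-end``; a missing strand is ``.``.
    Malformed or zero-length lines abort with the offending line number.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) >= 4 and fields[3] not in ("", ".") else (
                f"{fields[0]}:{start}-{end}"
            )
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            try:
                peaks.append(Peak(fields[0], start, end, name, strand))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def count_reads_in_peaks(
    bam_path: str,
    peaks: list[Peak],
    flt: AlignmentFilter = AlignmentFilter(),
    orientation: str = "forward",
    threads: int = 1,
) -> np.ndarray:
    """Raw counts per peak, in peak order.

    One pass per chromosome over the BAM; peak lookup goes through an
    interval tree, so runtime is reads x log(peaks).  Peaks on chromosomes
    absent from the BAM header get count 0 with a warning.
    """
    counts = np.zeros(len(peaks), dtype=np.int64)
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        references = set(bam.references)

    by_chrom: dict[str, list[int]] = {}
    for i, peak in enumerate(peaks):
        if peak.chrom not in references:
            logger.warning(
                "peak %s on chromosome %s absent from %s header; count set to 0",
                peak.name, peak.chrom, bam_path,
            )
            continue
        by_chrom.setdefault(peak.chrom, []).append(i)

    def count_chrom(chrom: str) -> tuple[list[int], np.ndarray]:
        idx = by_chrom[chrom]
        tree = IntervalTree()
        for i in idx:
            tree.addi(peaks[i].start, peaks[i].end, i)
        local = np.zeros(len(peaks), dtype=np.int64)
        with pysam.AlignmentFile(bam_path, "rb") as bam:
            for read in bam.fetch(chrom):
                if not read_passes_filter(read, flt):
                    continue
                span = _counting_span(read, flt.fragment_mode)
                if span is None:
                    continue
                lo, hi = span
                if hi <= lo:
                    continue
                hits = tree.overlap(lo, hi)
                if not hits:
                    continue
                strand = read_strand(read, orientation)
                if flt.strand_select in ("forward", "reverse"):
                    wanted = "+" if flt.strand_select == "forward" else "-"
                    if strand != wanted:
                        continue
                for hit in hits:
                    peak = peaks[hit.data]
                    if flt.strand_select == "match_feature" and peak.feature_strand in (
                        "+",
                        "-",
                    ):
                        if strand != peak.feature_strand:
                            continue
                    local[hit.data] += 1
        return idx, local

    chroms = list(by_chrom)
    if threads <= 1 or len(chroms) <= 1:
        results = [count_chrom(c) for c in chroms]
    else:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            results = list(pool.map(count_chrom, chroms))
    for _, local in results:
        counts += local
    return counts


def _counting_span(
    read: pysam.AlignedSegment, fragment_mode: bool
) -> tuple[int, int] | None:
    """Reference interval a read contributes to counting, or None to skip.

    In fragment mode a proper pair is represented once by its leftmost mate
    (positive TLEN) spanning the whole fragment; the rightmost mate is
    skipped.  Anything else counts by its own aligned span.
    """
    if read.is_unmapped:
        return None
    if fragment_mode and read.is_paired and read.is_proper_pair:
        tlen = read.template_length
        if tlen > 0:
            return read.reference_start, read.reference_start + tlen
        if tlen < 0:
            return None
        # TLEN 0 on a proper pair: fall back to single-read span
    return read.reference_start, read.reference_end


# ---------------------------------------------------------------------------
# normalizations


def fpkm(
    raw_count: np.ndarray | float,
    peak_length_bp: np.ndarray | float,
    effective_library_size: int,
) -> np.ndarray | float:
    """Fragments per kilobase per million: count * 1e9 / (length * library)."""
    if effective_library_size <= 0:
        raise ValueError("effective library size must be positive")
    return np.asarray(raw_count, dtype=np.float64) * 1e9 / (
        np.asarray(peak_length_bp, dtype=np.float64) * effective_library_size
    )


def tpm(raw_counts: np.ndarray, peak_lengths_bp: np.ndarray) -> np.ndarray:
    """Transcripts per million over the peak set.

    Length-normalized rates are rescaled so the column sums to 1e6; an
    all-zero count vector maps to all zeros.
    """
    rates = np.asarray(raw_counts, dtype=np.float64) / np.asarray(
        peak_lengths_bp, dtype=np.float64
    )
    total = rates.sum()
    if total == 0:
        return np.zeros_like(rates)
    return rates * 1e6 / total


def libsize_normalize(
    raw: np.ndarray, effective_sizes: list[int] | np.ndarray
) -> np.ndarray:
    """Scale each sample's counts to the smallest library in the set.

    ``raw`` is (peaks x samples); sample ``s`` is multiplied by
    ``min(N) / N_s``, so the smallest library's counts pass unchanged.
    """
    sizes = np.asarray(effective_sizes, dtype=np.float64)
    if sizes.size == 0:
        raise ValueError("need at least one sample")
    if np.any(sizes <= 0):
        raise ValueError("effective library sizes must be positive")
    factors = sizes.min() / sizes
    return np.asarray(raw, dtype=np.float64) * factors


# ---------------------------------------------------------------------------
# orchestration


def _sample_names(bam_paths: list[str]) -> list[str]:
    names = []
    seen: dict[str, int] = {}
    for path in bam_paths:
        base = os.path.basename(path)
        if base.endswith(".bam"):
            base = base[:-4]
        seen[base] = seen.get(base, 0) + 1
        names.append(base if seen[base] == 1 else f"{base}.{seen[base]}")
    return names


def quantify(
    bam_paths: list[str],
    bed: str | list[Peak],
    flt: AlignmentFilter = AlignmentFilter(),
    orientation: str = "forward",
    threads: int = 1,
) -> PeakTable:
    """Count and normalize peaks across samples.

    Runs the full-pass library statistics, per-peak counting and all three
    normalizations for every BAM.
    """
    if not bam_paths:
        raise ValueError("need at least one BAM file")
    peaks = read_bed(bed) if isinstance(bed, str) else list(bed)
    samples = _sample_names(bam_paths)

    stats: dict[str, LibraryStats] = {}
    sizes: dict[str, int] = {}
    raw = np.zeros((len(peaks), len(bam_paths)), dtype=np.int64)
    for j, (path, sample) in enumerate(zip(bam_paths, samples)):
        st = compute_library_stats(path, flt)
        stats[sample] = st
        sizes[sample] = st.effective_size(flt.fragment_mode)
        raw[:, j] = count_reads_in_peaks(path, peaks, flt, orientation, threads)

    lengths = np.array([p.length for p in peaks], dtype=np.float64)
    size_vec = [sizes[s] for s in samples]
    table = pd.DataFrame(
        {
            "chrom": [p.chrom for p in peaks],
            "start": [p.start for p in peaks],
            "end": [p.end for p in peaks],
            "name": [p.name for p in peaks],
            "strand": [p.feature_strand for p in peaks],
        }
    )
    for j, s in enumerate(samples):
        table[f"{s}.raw"] = raw[:, j]
    for j, s in enumerate(samples):
        table[f"{s}.fpkm"] = (
            fpkm(raw[:, j], lengths, size_vec[j]) if len(peaks) else []
        )
    for j, s in enumerate(samples):
        table[f"{s}.tpm"] = tpm(raw[:, j], lengths) if len(peaks) else []
    if len(peaks):
        libnorm = libsize_normalize(raw, size_vec)
    else:
        libnorm = np.zeros((0, len(samples)))
    for j, s in enumerate(samples):
        table[f"{s}.libnorm"] = libnorm[:, j]
    return PeakTable(table=table, samples=samples, stats=stats, effective_sizes=sizes)


def write_quant_table(result: PeakTable, path: str) -> None:
    """Write the quantification table as TSV, floats with 6 significant digits."""
    result.table.to_csv(path, sep="\t", index=False, float_format="%.6g")
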