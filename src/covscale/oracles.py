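"""Brute-force verifiers, deliberately naive and independent of the
production paths.

These work directly on :class:`~covscale.fixtures.ReadSpec` lists — never
on BAM files — with plain Python loops and their own CIGAR walker, so a
bug in the pysam-based implementation cannot hide in its own oracle.
"""

from __future__ import annotations

import re

import numpy as np

from .coverage import AlignmentFilter
from .fixtures import ReadSpec
from .peaks import Peak

__all__ = [
    "oracle_counts",
    "oracle_per_base",
    "oracle_binned",
    "oracle_aligned_bases",
]

_CIG = re.compile(r"(\d+)([MIDNSHP=X])")


def _cigar_ops(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIG.findall(cigar)]


def _spec_passes(spec: ReadSpec, flt: AlignmentFilter) -> bool:
    if flt.drop_unmapped and spec.is_unmapped:
        return False
    if flt.drop_secondary and spec.is_secondary:
        return False
    if flt.drop_supplementary and spec.is_supplementary:
        return False
    if flt.drop_duplicates and spec.is_duplicate:
        return False
    if flt.drop_qcfail and spec.is_qcfail:
        return False
    if not spec.is_unmapped and spec.mapq < flt.min_mapq:
        return False
    if (
        flt.require_same_chrom_mate
        and spec.is_paired
        and spec.mate_chrom is not None
        and spec.mate_chrom != spec.chrom
    ):
        return False
    return True


def _spec_strand(spec: ReadSpec, orientation: str) -> str:
    strand = spec.strand
    if spec.is_paired and not spec.is_read1:
        strand = "+" if strand == "-" else "-"
    if orientation == "reverse":
        strand = "+" if strand == "-" else "-"
    return strand


def _spec_ref_end(spec: ReadSpec) -> int:
    end = spec.start
    for n, op in _cigar_ops(spec.cigar):
        if op in "MDN=X":
            end += n
    return end


def _spec_segments(spec: ReadSpec, splice_aware: bool) -> list[tuple[int, int]]:
    covered = "M=X" if splice_aware else "M=XN"
    segs: list[tuple[int, int]] = []
    pos = spec.start
    for n, op in _cigar_ops(spec.cigar):
        if op in covered:
            if segs and segs[-1][1] == pos:
                segs[-1] = (segs[-1][0], pos + n)
            else:
                segs.append((pos, pos + n))
            pos += n
        elif op in "DN":
            pos += n
    return segs


def oracle_aligned_bases(specs: list[ReadSpec], flt: AlignmentFilter) -> int:
    """Sum of M/=/X lengths over passing reads, by direct CIGAR walking."""
    total = 0
    for spec in specs:
        if not _spec_passes(spec, flt) or spec.is_unmapped:
            continue
        for n, op in _cigar_ops(spec.cigar):
            if op in "M=X":
                total += n
    return total


def oracle_counts(
    specs: list[ReadSpec],
    peaks: list[Peak],
    flt: AlignmentFilter = AlignmentFilter(),
    orientation: str = "forward",
) -> np.ndarray:
    """Exhaustive per-peak read/fragment counting, O(reads x peaks)."""
    counts = np.zeros(len(peaks), dtype=np.int64)
    peaks_by_chrom: dict[str, list[tuple[int, Peak]]] = {}
    for i, p in enumerate(peaks):
        peaks_by_chrom.setdefault(p.chrom, []).append((i, p))

    for spec in specs:
        if spec.is_unmapped or not _spec_passes(spec, flt):
            continue
        if flt.fragment_mode and spec.is_paired and spec.is_proper:
            if spec.tlen > 0:
                span = (spec.start, spec.start + spec.tlen)
            elif spec.tlen < 0:
                continue  # fragment already represented by the leftmost mate
            else:
                span = (spec.start, _spec_ref_end(spec))
        else:
            span = (spec.start, _spec_ref_end(spec))
        strand = _spec_strand(spec, orientation)
        if flt.strand_select == "forward" and strand != "+":
            continue
        if flt.strand_select == "reverse" and strand != "-":
            continue
        for i, p in peaks_by_chrom.get(spec.chrom, ()):
            if span[0] < p.end and p.start < span[1]:
                if flt.strand_select == "match_feature" and p.feature_strand in "+-":
                    if strand != p.feature_strand:
                        continue
                counts[i] += 1
    return counts


def oracle_per_base(
    specs: list[ReadSpec],
    chrom: str,
    length: int,
    flt: AlignmentFilter = AlignmentFilter(),
    splice_aware: bool = False,
    strand: str = "both",
    orientation: str = "forward",
) -> np.ndarray:
    """Interval-stabbing per-base depth by incrementing one base at a time."""
    cov = np.zeros(length, dtype=np.float64)
    for spec in specs:
        if spec.chrom != chrom or spec.is_unmapped:
            continue
        if not _spec_passes(spec, flt):
            continue
        if strand in ("forward", "reverse"):
            wanted = "+" if strand == "forward" else "-"
            if _spec_strand(spec, orientation) != wanted:
                continue
        for s, e in _spec_segments(spec, splice_aware):
            for b in range(max(s, 0), min(e, length)):
                cov[b] += 1
    return cov


def oracle_binned(base_cov: np.ndarray, bin_size: int) -> np.ndarray:
    """Mean per-base depth of each bin, by slicing one bin at a time."""
    n = len(base_cov)
    out = []
    for lo in range(0, n, bin_size):
        chunk = base_cov[lo : min(lo + bin_size, n)]
        out.append(chunk.sum() / len(chunk))
    return np.array(out)
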