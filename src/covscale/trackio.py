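"""bigWig and bedGraph writers for binned and adaptive tracks.

Chromosome order always follows the BAM header, never re-sorted, so output
is deterministic across runs.  Consecutive equal-valued fixed bins are
merged into single intervals; missing (NaN) bins are omitted.  bigWig
stores 32-bit floats, so round-trips are exact only to ~1e-7 relative.
"""

from __future__ import annotations

import math

import numpy as np
import pyBigWig
import pysam

from .coverage import BinnedTrack, IntervalTrack

__all__ = [
    "header_from_bam",
    "track_intervals",
    "write_bigwig",
    "write_bedgraph",
    "read_bigwig_intervals",
]


def header_from_bam(bam_path: str) -> list[tuple[str, int]]:
    """Ordered (chromosome, length) pairs from a BAM header."""
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        return list(zip(bam.references, bam.lengths))


def track_intervals(
    track: BinnedTrack | IntervalTrack,
) -> dict[str, list[tuple[int, int, float]]]:
    """Per-chromosome (start, end, value) intervals ready for writing.

    Fixed bins expand to intervals with adjacent equal values merged and
    NaN bins dropped; adaptive tracks pass through with the same merge.
    """
    out: dict[str, list[tuple[int, int, float]]] = {}
    if isinstance(track, BinnedTrack):
        for chrom in track.chroms:
            values = track.data[chrom]
            starts, ends = track.bin_bounds(chrom)
            merged: list[tuple[int, int, float]] = []
            for s, e, v in zip(starts, ends, values):
                if math.isnan(v):
                    continue
                if merged and merged[-1][2] == v and merged[-1][1] == s:
                    merged[-1] = (merged[-1][0], int(e), float(v))
                else:
                    merged.append((int(s), int(e), float(v)))
            out[chrom] = merged
    else:
        for chrom, runs in track.runs.items():
            merged = []
            for s, e, v in runs:
                if math.isnan(v):
                    continue
                if merged and merged[-1][2] == v and merged[-1][1] == s:
                    merged[-1] = (merged[-1][0], int(e), float(v))
                else:
                    merged.append((int(s), int(e), float(v)))
            out[chrom] = merged
    return out


def _check_bounds(
    intervals: dict[str, list[tuple[int, int, float]]],
    header: list[tuple[str, int]],
) -> None:
    lengths = dict(header)
    for chrom, runs in intervals.items():
        if runs and chrom not in lengths:
            raise ValueError(f"track chromosome {chrom} absent from header")
        for s, e, _ in runs:
            if not (0 <= s < e <= lengths[chrom]):
                raise ValueError(
                    f"interval {chrom}:{s}-{e} outside declared length "
                    f"{lengths[chrom]} (upstream bug)"
                )


def write_bigwig(
    track: BinnedTrack | IntervalTrack,
    header: list[tuple[str, int]],
    path: str,
) -> None:
    """Write a track as bigWig (UCSC), 0-based half-open intervals."""
    intervals = track_intervals(track)
    _check_bounds(intervals, header)
    bw = pyBigWig.open(path, "w")
    try:
        bw.addHeader(header)
        for chrom, _ in header:
            runs = intervals.get(chrom)
            if not runs:
                continue
            bw.addEntries(
                [chrom] * len(runs),
                [s for s, _, _ in runs],
                ends=[e for _, e, _ in runs],
                values=[v for _, _, v in runs],
            )
    finally:
        bw.close()


def write_bedgraph(
    track: BinnedTrack | IntervalTrack,
    header: list[tuple[str, int]],
    path: str,
) -> None:
    """Text fallback: 4-column bedGraph, values with 6 significant digits."""
    intervals = track_intervals(track)
    _check_bounds(intervals, header)
    with open(path, "w") as fh:
        for chrom, _ in header:
            for s, e, v in intervals.get(chrom, []):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def read_bigwig_intervals(path: str) -> dict[str, list[tuple[int, int, float]]]:
    """Read back a bigWig's intervals (for round-trip checks and plotting)."""
    out: dict[str, list[tuple[int, int, float]]] = {}
    bw = pyBigWig.open(path)
    try:
        for chrom in bw.chroms():
            ivals = bw.intervals(chrom)
            out[chrom] = [
                (int(s), int(e), float(v)) for s, e, v in (ivals or [])
            ]
    finally:
        bw.close()
    return out


def expand_intervals(
    intervals: list[tuple[int, int, float]], length: int
) -> np.ndarray:
    """Dense per-base array from intervals; NaN where nothing is emitted."""
    out = np.full(length, np.nan)
    for s, e, v in intervals:
        out[s:e] = v
    return out
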