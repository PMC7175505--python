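"""Synthetic-data generation: toy genomes, hand-specified reads and
simulated assays (ATAC/ChIP, OK-seq, END-seq, replication timing, RNA-seq)
with truth tables recording every planted feature.

Everything is seed-deterministic, so tests and self-checks need no external
downloads.  Scale is kept small (<= ~10^5 reads per sample) so whole-suite
runs stay in minutes on one CPU.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pysam

from .peaks import Peak

__all__ = [
    "ReadSpec",
    "ToyGenome",
    "SimulatedAssay",
    "make_pair",
    "make_bam",
    "simulate_assay",
]

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_QUERY_OPS = set("MIS=X")
_FLAG = {
    "paired": 0x1, "proper": 0x2, "unmapped": 0x4, "mate_unmapped": 0x8,
    "reverse": 0x10, "mate_reverse": 0x20, "read1": 0x40, "read2": 0x80,
    "secondary": 0x100, "qcfail": 0x200, "dup": 0x400, "supplementary": 0x800,
}


@dataclass(frozen=True)
class ReadSpec:
    """Declarative description of one BAM record."""

    name: str
    chrom: str
    start: int  # 0-based leftmost aligned position
    cigar: str
    strand: str = "+"
    mapq: int = 60
    is_duplicate: bool = False
    is_secondary: bool = False
    is_supplementary: bool = False
    is_qcfail: bool = False
    is_unmapped: bool = False
    is_paired: bool = False
    is_proper: bool = False
    is_read1: bool = True
    mate_chrom: str | None = None
    mate_start: int | None = None
    mate_strand: str | None = None
    tlen: int = 0

    def query_length(self) -> int:
        ops = _CIGAR_RE.findall(self.cigar)
        if "".join(f"{n}{o}" for n, o in ops) != self.cigar:
            raise ValueError(f"invalid CIGAR: {self.cigar!r}")
        return sum(int(n) for n, o in ops if o in _QUERY_OPS)


@dataclass(frozen=True)
class ToyGenome:
    """A handful of small named chromosomes."""

    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        if any(length <= 0 for length in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")


@dataclass
class SimulatedAssay:
    """Generated BAM path(s), the specs behind them and the planted truth."""

    genome: ToyGenome
    bam_paths: dict[str, str]
    read_specs: dict[str, list[ReadSpec]]
    truth: dict


def make_pair(
    name: str,
    chrom: str,
    frag_start: int,
    frag_end: int,
    read_len: int,
    mapq: int = 60,
    duplicate: bool = False,
    fragment_strand: str = "+",
) -> tuple[ReadSpec, ReadSpec]:
    """A proper FR pair covering ``[frag_start, frag_end)``.

    ``fragment_strand`` places mate 1 on that strand (mate 2 opposite), the
    convention strand-split modes recover.
    """
    read_len = min(read_len, frag_end - frag_start)
    tlen = frag_end - frag_start
    left_start = frag_start
    right_start = frag_end - read_len
    left_is_read1 = fragment_strand == "+"
    common = dict(
        name=name, mapq=mapq, is_duplicate=duplicate, is_paired=True,
        is_proper=True, mate_chrom=chrom,
    )
    left = ReadSpec(
        chrom=chrom, start=left_start, cigar=f"{read_len}M", strand="+",
        is_read1=left_is_read1, mate_start=right_start, mate_strand="-",
        tlen=tlen, **common,
    )
    right = ReadSpec(
        chrom=chrom, start=right_start, cigar=f"{read_len}M", strand="-",
        is_read1=not left_is_read1, mate_start=left_start, mate_strand="+",
        tlen=-tlen, **common,
    )
    return left, right


def _spec_flag(spec: ReadSpec) -> int:
    flag = 0
    if spec.is_paired:
        flag |= _FLAG["paired"]
        flag |= _FLAG["read1"] if spec.is_read1 else _FLAG["read2"]
        if spec.is_proper:
            flag |= _FLAG["proper"]
        if spec.mate_strand == "-":
            flag |= _FLAG["mate_reverse"]
    if spec.strand == "-":
        flag |= _FLAG["reverse"]
    if spec.is_unmapped:
        flag |= _FLAG["unmapped"]
    if spec.is_duplicate:
        flag |= _FLAG["dup"]
    if spec.is_secondary:
        flag |= _FLAG["secondary"]
    if spec.is_supplementary:
        flag |= _FLAG["supplementary"]
    if spec.is_qcfail:
        flag |= _FLAG["qcfail"]
    return flag


def make_bam(genome: ToyGenome, read_specs: list[ReadSpec], path: str) -> str:
    """Write ``read_specs`` as a coordinate-sorted, indexed BAM.

    Deterministic for a fixed spec list: record content depends only on the
    specs and the header only on the genome.
    """
    refs = list(genome.chrom_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": genome.chrom_lengths[c]} for c in refs],
    }
    tid = {c: i for i, c in enumerate(refs)}
    tmp = path + ".unsorted.bam"
    with pysam.AlignmentFile(tmp, "wb", header=header) as out:
        for spec in read_specs:
            a = pysam.AlignedSegment()
            a.query_name = spec.name
            a.flag = _spec_flag(spec)
            a.reference_id = tid[spec.chrom]
            a.reference_start = spec.start
            a.mapping_quality = spec.mapq
            qlen = spec.query_length()
            a.query_sequence = "A" * qlen
            a.cigarstring = spec.cigar
            if spec.is_paired:
                a.next_reference_id = tid[spec.mate_chrom]
                a.next_reference_start = (
                    spec.mate_start if spec.mate_start is not None else spec.start
                )
                a.template_length = spec.tlen
            else:
                a.next_reference_id = -1
                a.next_reference_start = -1
            out.write(a)
    # --no-PG keeps the header free of the temp-file path, so identical
    # spec lists yield byte-identical BAMs
    pysam.sort("--no-PG", "-o", path, tmp)
    os.remove(tmp)
    pysam.index(path)
    return path


# ---------------------------------------------------------------------------
# assay simulators


def simulate_assay(kind: str, outdir: str, seed: int, **params) -> SimulatedAssay:
    """Generate BAM(s) plus truth tables emulating an assay class.

    kinds: ``atac``/``chip`` (peaks over background, paired-end,
    duplicates and discordant pairs), ``okseq`` (strand bias flipping at
    planted origins), ``endseq`` (stranded break ends), ``reptime``
    (G1 + S pair with deeper early blocks), ``rna`` (spliced reads over
    multi-exon toy genes).
    """
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(seed)
    builders = {
        "atac": _sim_atac,
        "chip": _sim_atac,
        "okseq": _sim_okseq,
        "endseq": _sim_endseq,
        "reptime": _sim_reptime,
        "rna": _sim_rna,
    }
    if kind not in builders:
        raise ValueError(f"unknown assay kind: {kind!r}")
    return builders[kind](outdir, rng, **params)


def _sim_atac(
    outdir: str,
    rng: np.random.Generator,
    chrom_lengths: dict[str, int] | None = None,
    n_pairs: int = 25_000,
    n_peaks: int = 200,
    peak_len_range: tuple[int, int] = (200, 2000),
    frac_in_peaks: float = 0.6,
    dup_frac: float = 0.05,
    discordant_frac: float = 0.01,
    read_len: int = 50,
    frag_mean: float = 250.0,
    frag_sd: float = 30.0,
) -> SimulatedAssay:
    """ATAC/ChIP-like: paired-end reads enriched in planted peaks."""
    if chrom_lengths is None:
        chrom_lengths = {"chr1": 50_000, "chr2": 50_000, "chr3": 50_000}
    genome = ToyGenome(chrom_lengths)
    chroms = list(chrom_lengths)

    peaks: list[Peak] = []
    for i in range(n_peaks):
        chrom = chroms[int(rng.integers(len(chroms)))]
        width = int(rng.integers(peak_len_range[0], peak_len_range[1] + 1))
        start = int(rng.integers(0, chrom_lengths[chrom] - width))
        peaks.append(Peak(chrom, start, start + width, f"peak_{i}", "."))

    specs: list[ReadSpec] = []
    for i in range(n_pairs):
        frag_len = int(np.clip(rng.normal(frag_mean, frag_sd), read_len + 10, 1000))
        if rng.random() < frac_in_peaks and peaks:
            peak = peaks[int(rng.integers(len(peaks)))]
            chrom = peak.chrom
            center = int(rng.integers(peak.start, peak.end))
        else:
            chrom = chroms[int(rng.integers(len(chroms)))]
            center = int(rng.integers(0, chrom_lengths[chrom]))
        length = chrom_lengths[chrom]
        start = int(np.clip(center - frag_len // 2, 0, length - frag_len))
        dup = bool(rng.random() < dup_frac)
        if rng.random() < discordant_frac and len(chroms) > 1:
            # read pair mapping to two chromosomes: dropped by default filters
            other = chroms[(chroms.index(chrom) + 1) % len(chroms)]
            mate_start = int(rng.integers(0, chrom_lengths[other] - read_len))
            specs.append(ReadSpec(
                name=f"frag_{i}", chrom=chrom, start=start,
                cigar=f"{read_len}M", strand="+", is_duplicate=dup,
                is_paired=True, is_proper=False, is_read1=True,
                mate_chrom=other, mate_start=mate_start, mate_strand="-",
                tlen=0,
            ))
            specs.append(ReadSpec(
                name=f"frag_{i}", chrom=other, start=mate_start,
                cigar=f"{read_len}M", strand="-", is_duplicate=dup,
                is_paired=True, is_proper=False, is_read1=False,
                mate_chrom=chrom, mate_start=start, mate_strand="+",
                tlen=0,
            ))
        else:
            specs.extend(make_pair(
                f"frag_{i}", chrom, start, start + frag_len, read_len,
                duplicate=dup,
            ))

    path = os.path.join(outdir, "sample.bam")
    make_bam(genome, specs, path)
    truth = {
        "peaks": peaks,
        "peak_table": pd.DataFrame(
            [(p.chrom, p.start, p.end, p.name) for p in peaks],
            columns=["chrom", "start", "end", "name"],
        ),
    }
    return SimulatedAssay(genome, {"sample": path}, {"sample": specs}, truth)


def _sim_okseq(
    outdir: str,
    rng: np.random.Generator,
    chrom_lengths: dict[str, int] | None = None,
    origins: tuple[int, ...] = (50_000, 150_000),
    reads_per_origin: int = 20_000,
    domain_halfwidth: int = 30_000,
    strand_bias: float = 0.9,
    read_len: int = 100,
) -> SimulatedAssay:
    """OK-seq: Okazaki reads Watson-biased left of each origin, Crick right.

    True RFD = (Crick - Watson)/(Crick + Watson) therefore crosses zero
    from - to + at every planted origin.
    """
    if chrom_lengths is None:
        chrom_lengths = {"chr1": 200_000}
    genome = ToyGenome(chrom_lengths)
    chrom = next(iter(chrom_lengths))
    length = chrom_lengths[chrom]

    specs: list[ReadSpec] = []
    i = 0
    for origin in origins:
        offsets = rng.integers(-domain_halfwidth, domain_halfwidth, reads_per_origin)
        for off in offsets:
            pos = int(np.clip(origin + off, 0, length - read_len))
            rightward = off >= 0
            crick = rng.random() < (strand_bias if rightward else 1 - strand_bias)
            specs.append(ReadSpec(
                name=f"ok_{i}", chrom=chrom, start=pos, cigar=f"{read_len}M",
                strand="-" if crick else "+",
            ))
            i += 1

    path = os.path.join(outdir, "okseq.bam")
    make_bam(genome, specs, path)
    truth = {"origins": list(origins), "chrom": chrom}
    return SimulatedAssay(genome, {"okseq": path}, {"okseq": specs}, truth)


def _sim_endseq(
    outdir: str,
    rng: np.random.Generator,
    chrom_lengths: dict[str, int] | None = None,
    breaks: tuple[int, ...] = (10_000, 30_000),
    reads_per_break: int = 500,
    read_len: int = 50,
    strands: str = "both",  # both | forward
) -> SimulatedAssay:
    """END-seq: reads pile up at break ends, forward left / reverse right."""
    if chrom_lengths is None:
        chrom_lengths = {"chr1": 50_000}
    genome = ToyGenome(chrom_lengths)
    chrom = next(iter(chrom_lengths))
    length = chrom_lengths[chrom]

    specs: list[ReadSpec] = []
    i = 0
    for brk in breaks:
        for _ in range(reads_per_break):
            jitter = int(rng.integers(0, 20))
            fwd = strands == "forward" or rng.random() < 0.5
            if fwd:
                start = max(brk - read_len - jitter, 0)
                strand = "+"
            else:
                start = min(brk + jitter, length - read_len)
                strand = "-"
            specs.append(ReadSpec(
                name=f"end_{i}", chrom=chrom, start=start,
                cigar=f"{read_len}M", strand=strand,
            ))
            i += 1

    path = os.path.join(outdir, "endseq.bam")
    make_bam(genome, specs, path)
    truth = {"breaks": list(breaks), "chrom": chrom}
    return SimulatedAssay(genome, {"endseq": path}, {"endseq": specs}, truth)


def _sim_reptime(
    outdir: str,
    rng: np.random.Generator,
    chrom_lengths: dict[str, int] | None = None,
    early_blocks: tuple[tuple[int, int], ...] = ((100_000, 400_000),),
    base_depth: float = 4.0,
    early_ratio: float = 2.0,
    read_len: int = 100,
) -> SimulatedAssay:
    """Replication timing: G1 uniform; S deeper by ``early_ratio`` in blocks.

    The planted log2(S/G1) is log2(early_ratio) inside early blocks and 0
    elsewhere.
    """
    if chrom_lengths is None:
        chrom_lengths = {"chr1": 500_000}
    genome = ToyGenome(chrom_lengths)
    chrom = next(iter(chrom_lengths))
    length = chrom_lengths[chrom]

    def uniform_reads(prefix: str, n: int, lo: int, hi: int) -> list[ReadSpec]:
        starts = rng.integers(lo, max(hi - read_len, lo + 1), n)
        return [
            ReadSpec(
                name=f"{prefix}_{k}", chrom=chrom, start=int(s),
                cigar=f"{read_len}M",
                strand="+" if rng.random() < 0.5 else "-",
            )
            for k, s in enumerate(starts)
        ]

    n_base = int(base_depth * length / read_len)
    g1 = uniform_reads("g1", n_base, 0, length)
    s_phase = uniform_reads("s", n_base, 0, length)
    for b, (lo, hi) in enumerate(early_blocks):
        n_extra = int(base_depth * (early_ratio - 1.0) * (hi - lo) / read_len)
        s_phase.extend(uniform_reads(f"s_early{b}", n_extra, lo, hi))

    g1_path = os.path.join(outdir, "g1.bam")
    s_path = os.path.join(outdir, "s.bam")
    make_bam(genome, g1, g1_path)
    make_bam(genome, s_phase, s_path)
    truth = {
        "early_blocks": list(early_blocks),
        "log2_early": float(np.log2(early_ratio)),
        "chrom": chrom,
    }
    return SimulatedAssay(
        genome, {"g1": g1_path, "s": s_path}, {"g1": g1, "s": s_phase}, truth
    )


def _sim_rna(
    outdir: str,
    rng: np.random.Generator,
    chrom_lengths: dict[str, int] | None = None,
    genes: list[dict] | None = None,
    reads_per_gene: int = 300,
    read_len: int = 80,
) -> SimulatedAssay:
    """RNA-seq: spliced reads from multi-exon toy genes (N over introns)."""
    if chrom_lengths is None:
        chrom_lengths = {"chr1": 10_000}
    if genes is None:
        genes = [
            {"exons": [(1000, 1600), (2600, 3200), (4200, 4800)], "strand": "+"},
            {"exons": [(6000, 6500), (7500, 8000)], "strand": "-"},
        ]
    genome = ToyGenome(chrom_lengths)
    chrom = next(iter(chrom_lengths))

    specs: list[ReadSpec] = []
    i = 0
    for gene in genes:
        exons = gene["exons"]
        tx_len = sum(e - s for s, e in exons)
        for _ in range(reads_per_gene):
            tx_start = int(rng.integers(0, tx_len - read_len + 1))
            start, cigar = _project_to_genome(exons, tx_start, read_len)
            specs.append(ReadSpec(
                name=f"rna_{i}", chrom=chrom, start=start, cigar=cigar,
                strand=gene["strand"],
            ))
            i += 1

    path = os.path.join(outdir, "rna.bam")
    make_bam(genome, specs, path)
    truth = {"genes": genes, "chrom": chrom}
    return SimulatedAssay(genome, {"rna": path}, {"rna": specs}, truth)


def _project_to_genome(
    exons: list[tuple[int, int]], tx_start: int, read_len: int
) -> tuple[int, str]:
    """Map a transcript-coordinate read onto the genome as a spliced CIGAR."""
    remaining = read_len
    pos = tx_start
    parts: list[str] = []
    genome_start = None
    offset = 0
    for k, (ex_start, ex_end) in enumerate(exons):
        ex_len = ex_end - ex_start
        if pos >= offset + ex_len:
            offset += ex_len
            continue
        within = pos - offset
        take = min(remaining, ex_len - within)
        if genome_start is None:
            genome_start = ex_start + within
        else:
            intron = ex_start - exons[k - 1][1]
            parts.append(f"{intron}N")
        parts.append(f"{take}M")
        remaining -= take
        pos += take
        offset += ex_len
        if remaining == 0:
            break
    if remaining != 0 or genome_start is None:
        raise ValueError("read extends beyond the transcript")
    return genome_start, "".join(parts)
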