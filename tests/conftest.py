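import numpy as np
import pysam
import pytest
from hypothesis import settings

from covscale.fixtures import ReadSpec, ToyGenome, make_bam, make_pair, simulate_assay

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_genome():
    return ToyGenome({"chr1": 10_000, "chr2": 8_000})


@pytest.fixture(scope="session")
def bam_header(toy_genome):
    return pysam.AlignmentHeader.from_references(
        list(toy_genome.chrom_lengths),
        list(toy_genome.chrom_lengths.values()),
    )


def random_read_specs(rng, genome, n_reads=200):
    """A messy mix of read shapes and flags for oracle-equivalence checks."""
    cigar_shapes = [
        lambda L: f"{L}M",
        lambda L: f"{L // 2}M{rng.integers(5, 50)}D{L - L // 2}M",
        lambda L: f"{L // 2}M{rng.integers(50, 500)}N{L - L // 2}M",
        lambda L: f"5S{L}M",
        lambda L: f"{L}M3I10M",
    ]
    chroms = list(genome.chrom_lengths)
    specs = []
    for i in range(n_reads):
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(20, 80))
        cigar = cigar_shapes[int(rng.integers(len(cigar_shapes)))](length)
        ref_len = ReadSpec(name="x", chrom=chrom, start=0, cigar=cigar).query_length()
        start = int(rng.integers(0, genome.chrom_lengths[chrom] - ref_len - 600))
        specs.append(ReadSpec(
            name=f"r{i}",
            chrom=chrom,
            start=start,
            cigar=cigar,
            strand="+" if rng.random() < 0.5 else "-",
            mapq=int(rng.integers(0, 61)),
            is_duplicate=bool(rng.random() < 0.1),
            is_qcfail=bool(rng.random() < 0.05),
        ))
    return specs


@pytest.fixture(scope="session")
def random_bam(tmp_path_factory, toy_genome):
    """(bam_path, specs) with single-end reads of varied CIGARs and flags."""
    rng = np.random.default_rng(1234)
    specs = random_read_specs(rng, toy_genome, n_reads=200)
    path = str(tmp_path_factory.mktemp("randbam") / "random.bam")
    make_bam(toy_genome, specs, path)
    return path, specs


@pytest.fixture(scope="session")
def paired_bam(tmp_path_factory, toy_genome):
    """(bam_path, specs): proper pairs, some duplicates, some discordant."""
    rng = np.random.default_rng(99)
    specs = []
    for i in range(150):
        chrom = "chr1" if rng.random() < 0.7 else "chr2"
        length = toy_genome.chrom_lengths[chrom]
        frag = int(rng.integers(120, 400))
        start = int(rng.integers(0, length - frag))
        if rng.random() < 0.1:
            other = "chr2" if chrom == "chr1" else "chr1"
            mstart = int(rng.integers(0, toy_genome.chrom_lengths[other] - 50))
            specs.append(ReadSpec(
                name=f"p{i}", chrom=chrom, start=start, cigar="50M", strand="+",
                is_paired=True, is_proper=False, is_read1=True,
                mate_chrom=other, mate_start=mstart, mate_strand="-", tlen=0,
            ))
            specs.append(ReadSpec(
                name=f"p{i}", chrom=other, start=mstart, cigar="50M", strand="-",
                is_paired=True, is_proper=False, is_read1=False,
                mate_chrom=chrom, mate_start=start, mate_strand="+", tlen=0,
            ))
        else:
            specs.extend(make_pair(
                f"p{i}", chrom, start, start + frag, 50,
                duplicate=bool(rng.random() < 0.08),
                fragment_strand="+" if rng.random() < 0.5 else "-",
            ))
    path = str(tmp_path_factory.mktemp("pairbam") / "paired.bam")
    make_bam(toy_genome, specs, path)
    return path, specs


@pytest.fixture(scope="session")
def atac_sim(tmp_path_factory):
    outdir = str(tmp_path_factory.mktemp("atac"))
    return simulate_assay("atac", outdir, seed=11, n_pairs=3000, n_peaks=50)


def make_segment(header, **kw):
    """In-memory AlignedSegment for predicate tests (no file needed)."""
    a = pysam.AlignedSegment(header)
    a.query_name = kw.get("name", "q")
    a.reference_id = kw.get("reference_id", 0)
    a.reference_start = kw.get("start", 100)
    a.mapping_quality = kw.get("mapq", 60)
    length = kw.get("length", 50)
    a.query_sequence = "A" * length
    a.cigarstring = kw.get("cigar", f"{length}M")
    flag = 0
    for bit, key in (
        (0x1, "paired"), (0x2, "proper"), (0x4, "unmapped"), (0x10, "reverse"),
        (0x40, "read1"), (0x80, "read2"), (0x100, "secondary"),
        (0x200, "qcfail"), (0x400, "duplicate"), (0x800, "supplementary"),
    ):
        if kw.get(key):
            flag |= bit
    a.flag = flag
    if kw.get("unmapped"):
        a.cigarstring = None
    a.next_reference_id = kw.get("mate_reference_id", -1)
    a.next_reference_start = kw.get("mate_start", -1)
    a.template_length = kw.get("tlen", 0)
    return a
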