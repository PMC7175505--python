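# Methods

## Coverage model

Coverage is defined per reference base: the value at base `b` is the number
of filter-passing reads whose aligned segments cover `b`. Aligned segments
are the reference-consuming CIGAR match operations (`M`, `=`, `X`).
Deletions (`D`) consume reference but carry no signal. Skipped regions
(`N`) are treated as covered in the default DNA mode — a non-splice-aware
counter sees the read as one span — and as gaps in splice-aware mode, which
is what makes RNA tracks drop to zero over introns. Insertions and clips
consume no reference.

A binned track stores, for every bin of `bin_size` bases, the **mean**
per-base depth within the bin (the last bin uses its true width). The mean
rather than the sum keeps values comparable across bin sizes and gives log2
and RFD ratios their natural depth-ratio semantics; anyone comparing
numbers against a tool that stores bin sums should multiply by the bin
width. All coordinates are 0-based half-open (BED/bigWig convention);
`ceil(chrom_length / bin_size)` bins tile each chromosome exactly.

Missing values are NaN in memory and omitted from written files. This
keeps a genuine zero (e.g. balanced replication forks, RFD = 0)
distinguishable from absence of data.

## Alignment filters and the effective library

Default filters drop duplicate, secondary, supplementary, QC-fail and
unmapped reads, and discard paired reads whose mate maps to a different
chromosome. The mate rule exists because discordant pairs can pile into a
single locus and fabricate a peak; disabling it (`require_same_chrom_mate=
False`) restores those reads for users who want them. MAPQ filtering is
off by default (`min_mapq=0`).

The effective library size used for FPKM and library-size normalization is
the number of filter-passing reads — fragments when counting in fragment
mode, for internal consistency — obtained by a full pass over the BAM. The
BAM index's mapped-read totals are deliberately not used: they include
duplicates and low-quality reads and would bias every normalized score.
`aligned_bases` (for genome-size scaling) sums M/=/X lengths over passing
reads, matching the visual tracks, which show no deletion or intron signal.

## Peak counting

A read counts toward a peak on ≥1 bp overlap between its outermost aligned
reference span and the peak. The outermost span (introns included) is used
rather than the spliced segments because DNA assays dominate interval
quantification; RNA users should know that a junction-spanning read counts
toward a peak inside its intron. A read overlapping two peaks counts in
both — merge peaks upstream if double counting is unwanted.

Fragment mode represents each properly paired fragment once, on its
leftmost mate (positive TLEN), over `[start, start + |TLEN|)`; the interior
of the fragment therefore counts even where neither mate aligns. Improper
or half-mapped pairs fall back to per-read counting, which keeps the mode
robust without inventing fragment extents.

Strand handling: a single-end read's strand is its flag strand; a paired
fragment's strand is mate 1's strand, and `orientation="reverse"` flips the
convention for dUTP-style stranded protocols. `strand_select=
"match_feature"` counts only reads matching each peak's BED strand
(unstranded `.` peaks accept both).

## Normalizations and scaling factors

- FPKM: `count · 10⁹ / (length_bp · N)`.
- TPM: per-peak rates `count/length`, rescaled to sum to 10⁶ per sample;
  an all-zero sample stays all-zero.
- Library-size: `factor_s = min_t(N_t)/N_s`; the smallest library passes
  through unchanged.
- Genome-size track scaling: `genome_length / aligned_bases`, both from
  the same filtered pass and the BAM header. It divides coverage by mean
  depth, so each sample can be scaled alone.
- Custom factors (e.g. reciprocal size factors from a
  differential-expression fit) multiply bin or run values directly.

When both scaling and smoothing are requested, scaling is applied first;
as a scalar it commutes with the windowed mean, so the order is a
convention, not a modelling choice.

## Smoothing

`smooth_track(t, n)` replaces bin `i` with the mean of bins `[i−n, i+n]`
intersected with the chromosome. Windows truncate at chromosome ends
rather than padding with zeros, avoiding systematic edge deflation, and
never cross chromosomes. `n=0` is the identity.

## Two-file operations and presets

`log2_ratio` takes the **first** file as numerator; with the default
pseudocount 0, bins where either side is zero are missing rather than
±inf. A positive `--pseudocount` emits them. For replication timing the
convention means argument order decides the sign: pass the fraction you
want positive first. The preset bins at 100 bp and smooths over ±500 bins
(±50 kb) before the ratio; the 50 kb/4-bin parameterization serves
single-cell repli-seq and BrdU-IP, whose sparser coverage needs coarser
bins.

`rfd` computes Watson (forward-flag) and Crick (reverse-flag) binned
coverage under one filter set and emits `(C−W)/(C+W)` per bin, undefined
bins omitted. Values are bounded in [−1, 1] by construction; swapping
strand roles flips the sign.

`endseq` emits forward and reverse tracks; `endseqr` negates the reverse
track so both strands overlay in one browser panel. Default bin size is
1 bp (break ends are base-precise), 1 kb for RFD, 5 bp for generic runs —
all overridable.

## Adaptive RNA binning

The chromosome is tiled with bins (default 15 bases). A bin is emitted at
single-base resolution when any adjacent-base pair inside it differs by
**strictly more than** `jump_threshold` reads (default 4, i.e. a jump of
≥5 triggers); other bins are emitted as one run at the bin mean. The pair
straddling a bin boundary belongs to the downstream bin, so every pair is
checked exactly once. Equal-valued adjacent runs are merged for file size;
zero runs are emitted explicitly so intron gaps are visible and the run
list tiles the chromosome completely. With `bin_size=1` the output equals
per-base coverage for any threshold.

## Synthetic data and what passing tests show

`covscale.fixtures` generates all test inputs; nothing is downloaded.
The generators plant known truth and record it:

- **atac/chip**: 200 peaks of 200–2,000 bp on three 50 kb chromosomes,
  ~50,000 paired-end 50 bp reads (60% peak-derived, fragment length
  ~N(250, 30)), ~5% duplicate-flagged, ~1% discordant-mate pairs.
- **okseq**: single-end reads in ±30 kb domains around planted origins,
  90% Watson left of the origin and 90% Crick right, so true RFD crosses
  zero −→+ at each origin.
- **reptime**: a G1 sample at uniform depth and an S sample 2× deeper
  inside planted early blocks (500 kb chromosome for the 100 bp preset,
  5 Mb for the 50 kb preset, depths 4 and 2 — sized so that
  Poisson sampling noise after smoothing stays well inside the ±0.1 band
  the tests assert).
- **endseq**: reads piling onto planted break coordinates, strand by side.
- **rna**: spliced reads drawn uniformly along 2- and 3-exon toy genes,
  ~13× exon depth, so junction jumps far exceed the threshold.

The brute-force oracles (exhaustive overlap counting, per-base
interval stabbing, an independent regex CIGAR walker) operate on the read
*specifications*, never on the BAM, and share no code with the production
path — agreement therefore checks both the computation and the BAM
round-trip. The generators emulate mapped-read geometry only: no sequence
content, base qualities, GC or mappability bias, chimeric alignments or
soft-clip pathologies. Passing tests demonstrate correctness of counting,
normalization and track arithmetic on well-formed alignments, not
robustness to aligner quirks absent from the fixtures.

## Numerical choices

- Bin means and smoothing use float64 cumulative sums; written bigWig is
  32-bit float, so round-trip checks tolerate ~1e-6 relative error.
- TPM's column-sum invariant is asserted to 1e-6 relative.
- Thread parallelism is per chromosome with results assembled in header
  order, making outputs bit-identical for any worker count.
- Chromosome order always follows the BAM header; nothing is re-sorted.
- Degenerate inputs: zero-length peaks, zero library sizes, mismatched
  track geometry and out-of-bounds intervals are fatal errors; peaks on
  chromosomes missing from a BAM header count 0 with a warning, since
  mixed reference subsets are common in practice.

## Known limitations

- No CRAM input, no base-quality weighting, no apportioning of multi-peak
  reads.
- Fragment mode trusts TLEN; aligners that leave TLEN 0 on proper pairs
  degrade gracefully to per-read counting.
- Whole-chromosome per-base arrays are held in memory during binning
  (8 bytes/base, ~25 MB for a 3 Gb genome's largest chromosome at one
  float per base) — fine for typical genomes, generous for megabase-scale
  contig counts.
- The adaptive-binning trigger compares total depth between adjacent
  bases; a jump composed of balanced gains and losses (e.g. one read
  ending exactly where another starts) cancels and does not trigger.
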