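# Methods

This note documents the models behind `skimseq`, the defaults that
matter, what the simulators do and do not emulate, and the design
choices made where more than one reasonable option existed.

## Coverage arithmetic

Fold coverage is computed from read-pair totals:

    coverage = read_count × read_length × 2 / (genome_size × n_samples)

`read_count` is the raw pair count of the multiplexed file (the ×2
supplies the second mate). The complementary conversion from binned
data is `effective_depth = mean_pairs_per_bin × 2 × read_length /
bin_size`; the two agree by construction when all reads are binned.
The raw-file total (not the post-trim or post-filter total) is used for
population coverage summaries, because that is the quantity a
sequencing provider reports; per-sample normalization (below) instead
uses counted units after filtering, since normalization should reflect
usable signal. Both choices are exposed as parameters.

## Binned counting and normalization

Bins are fixed-width (default 1 Mb), 0-based half-open, anchored at
contig coordinate 0, with the last bin per contig truncated. The
counting unit defaults to **pairs**, counted once at the leftmost
mapped mate position; per-record counting (`unit="reads"`) is available
and the unit is recorded in the output metadata. Alignments are first
reduced to uniquely mapped concordant pairs, defined by the aligner
tags `NH:i:1` and `YT:Z:CP` plus the proper-pair FLAG; records with
neither tag (other aligners) are dropped with a warning rather than
guessed from MAPQ, because the criterion is tag-defined.

Normalization is either `fixed_factor` (reads per 10 million by
default: `raw / total × 10⁷`) or `mean_bin` (`raw / mean raw per bin` of
that sample). A sample with zero counted units is flagged `failed` and
its normalized track set to 0.

## Copy ratios and the baseline problem

A copy ratio is a normalized bin density divided by the expected
disomic level. Two baselines are implemented:

- **population_median** (default for panels): per-bin median across
  samples, after which each sample is rescaled so its genome-wide
  median ratio is 1. This is robust while fewer than half the samples
  share an event on a chromosome. When a chromosome's population-median
  level deviates more than 20% from the genome-wide level — as happens
  when most of a panel segregates from a monosomic parent — that
  chromosome automatically falls back to the per-sample baseline.
- **self_genome_median**: the sample's own median bin density over the
  recipient genome, valid when most of the sample's genome is disomic.
  This is the default for single-sample introgression analysis.

On hybrid catalogs, donor-genome contigs always use the per-sample
baseline: their population median is ~0 whenever fewer than half the
samples carry donor material, which would otherwise mask the signal.
Bins with a zero baseline are masked (NaN) and excluded downstream.

Caveat: the genome-wide median rescale assumes aberrant bins are a
minority of the genome. On toy catalogs where a single aneuploid
chromosome is a third of all bins the rescale is visibly biased; real
catalogs (21 wheat chromosomes) and the test catalogs keep the focal
chromosome a small fraction.

## Dosage classification

Arm-level ratios (split at the centromere; whole-chromosome when no
centromere is supplied) are converted to integer copies as
`round(2 × ratio)` clamped to [0, 4]. Calls where 2×ratio falls within
±0.15 of a rounding boundary (half-integer) are flagged low-confidence;
the band is configurable. Classes derive from the arm-copy pair:
(2,2) disomic, (1,1) monosomic, (0,0) nullisomic, (≥3,≥3) trisomic,
(0,≥1) telosomic (the covered arm), {1,2} monosomic-plus-telosomic;
anything else is reported as `partial`.

Sample QC precedes classification: blank wells pass when they receive
less than 0.01% of the mean non-blank reads; non-blank samples below 5%
of that mean are flagged `failed`. The 5% cutoff is this package's
choice — failure in the source workflows was judged from plots — and
both flags exclude a sample from population baselines.

Donor-chromosome additions are called per sample: a donor contig is
`present` when ≥80% of its bins exceed a presence threshold (ratio 0.25,
i.e. half of a single-copy level), `partial` between 20% and 80% (the
covered run is then delimited by segmentation), `absent` below.

## Breakpoint segmentation

Copy-ratio tracks are segmented by recursive binary segmentation of a
piecewise-constant mean model: each segment is split at the bin
boundary maximizing the least-squares gain
`n_l n_r / n × (mean_l − mean_r)²` (identically the minimizer of the
within-segment sum of squares, and therefore interchangeable with an
exhaustive single-split search), and the split is accepted when the
mean-shift z-score exceeds `z_threshold` (default 4) with both sides
holding at least `min_seg_bins` (default 3) bins.

The noise scale for the z-score is re-estimated per segment from
successive differences, taking the larger of the median-based estimator
(`median|Δ| / 0.9539`, robust to the few large differences true shifts
contribute) and the mean-based one (`mean|Δ| / 1.1284`, steadier on
short segments). Re-estimating locally matters on zero-inflated donor
tracks: a constant stretch has zero scale, so a genuine shift out of it
is always significant, while a noisy stretch gates spurious splits.
Masked bins are dropped before segmentation; segment coordinates come
from the surviving bins' boundaries. A BED of known-artifact bins
(e.g. a mispositioned reference scaffold) can be masked the same way.

Segment dosage states reuse the copy bands: 0 copies `absent`, 1
`hemizygous`, 2 `normal`, >2 `gain`.

## Translocation pairing and zygosity

Recipient-genome segments at reduced dosage are paired with
donor-genome gain segments of *matching* dosage class: a fully absent
recipient segment with a ~2-copy donor gain is a homozygous
translocation; a hemizygous loss with a ~1-copy gain is heterozygous.
Matching is greedy by segment length. Unpaired losses are reported as
deletions and unpaired gains as additions — pairing by dosage class is
this package's stated rule for separating a heterozygous translocation
from an independent deletion-plus-addition. Segments shorter than
`min_mb` (default 3 Mb, far below the ~30 Mb cytology detection floor)
are ignored. Carrier counts per designation feed a Pearson
goodness-of-fit χ² against 1:1 (df = 1).

## Demultiplexing

Matching is per-index Hamming distance ≤ `max_mismatch` on both i7 and
i5, with exact matching (0) as the conservative default; a pair tying
two samples at the winning combined distance is rejected as ambiguous.
The i5 orientation (machine-dependent) is detected once per run from
the first 10,000 index reads by exact-match rate, as-is winning ties.
Barcodes may also arrive embedded in the FASTQ comment as `<i7>+<i5>`.
Adapter/quality trimming is out of scope (dedicated trimmers do it
better). Assigned + undetermined always equals the input pair count.

## Sparse genotyping and haplotype blocks

Parental SNP discovery is a counting/purity caller, not a
genotype-likelihood caller: at ~8x parental coverage, requiring
per-parent depth in [6, 100], own-allele depth ≥ 3, and major-allele
fraction ≥ 0.9 (the homozygosity proxy; our parameter) on joint
coordinates is a transparent stand-in for a likelihood model, which is
deliberately out of scope. Progeny calls count reads per parental
allele: A-only → A, B-only → B, both → het, neither → missing; third
alleles are tallied and ignored. DH lines are effectively homozygous,
so `het` is retained only as a contamination/error QC signal.

Haplotype blocks use non-overlapping 5 Mb windows: a window is assigned
a parent when it holds ≥3 informative calls and the majority parent
reaches 80%. Unresolved windows flanked by the same parent are absorbed
when consistent; an unresolved window between discordant parents is
split at the marker index minimizing discordance with its flanks, which
places the crossover boundary midway between the last left-parent and
first right-parent markers. An HMM was deliberately not used: the
window rule is transparent and its failure mode (unresolved, never
confidently wrong) is the right one for breeding QC. Window size,
marker minimum and majority are configurable.

## Simulators

All generators are pure functions of their configuration and seed.

- **Bin counts**: independent Poisson per bin with mean
  `λ = coverage × bin_width / (2 × read_length) × copy/2` — the
  expected pair count of a bin at the given fold coverage, linear in
  copy number. Partial-bin overlaps of a copy interval scale λ by the
  overlapped fraction. A negative-binomial overdispersion hook exists
  but is off by default: the Poisson model has no GC, mappability or
  library-size structure, so passing tests demonstrate correctness of
  the estimators under sampling noise, not robustness to real-data
  artifacts.
- **Tagged SAM**: pairs placed uniformly within copy-weighted bins,
  proper-pair FLAGs, `NH:i:1`/`YT:Z:CP` on the unique fraction and
  `NH:i:2` on a configurable multimapper fraction; filtering then
  binning the output reproduces the emitted truth counts exactly.
- **Aneuploid panel**: per-sample dosage classes on a focal chromosome
  (telosomics split at the centromere), blanks at zero reads, failed
  wells at 2% of the normal total.
- **BC1 population**: carriers (probability 0.5) receive one
  translocated chromosome — recipient interval at copy 1, donor
  interval at copy 1.
- **DH population**: Poisson crossovers per chromosome (mean 2) at
  uniform positions, alternating parental phase; each marker is
  observed with probability `1 − exp(−coverage)` (reads over a site are
  Poisson with mean equal to the fold coverage) and reports the true
  phase allele, error-free. Sequencing error and heterozygosity are not
  modeled.
- **Index reads**: barcodes copied with per-base substitution errors,
  i5 written in either orientation, blanks at zero reads.

## Default study conditions used in tests

The end-to-end checks run at the coverages of the motivating designs:
translocation lines and the BC1 population (n = 335) at 0.025x on a
hybrid catalog of 650–700 Mb chromosomes; the 864-sample dosage panel
at 0.01x (674 monosomic, 130 euploid, 35 + 1 telosomic, 10 nullisomic,
5 failed, 9 blank) on a three-chromosome catalog; DH genotyping with 48
lines, markers every 2 kb (the genome-wide SNP density between two
related wheat cultivars is of this order), at 0.05x and 0.01x. Catalogs
are scaled to a few hundred Mb per chromosome so every suite runs in
minutes on one CPU; the statistics per chromosome (bins per arm,
markers per window, pairs per bin) match the full-genome setting.

## Numerical details and edge cases

- Coordinates are 1-based inclusive facing SAM/pileups and 0-based
  half-open facing bins and BED, converted at module boundaries.
- Bin-ratio division guards: zero baselines mask bins; zero self-median
  (empty libraries) yields NaN ratios, and such samples are flagged
  before baselines are formed.
- Segmentation split ties take the leftmost maximizer; an all-masked
  track returns no segments.
- Exact-count down-sampling draws `round(fraction × N)` pairs without
  replacement with mates kept together, so repeated runs at one seed
  are byte-identical and nested fractions are exactly sized.
- Copy numbers are clamped to [0, 4]; higher amplifications read as 4.

## Known limitations

- No GC or mappability correction; bin boundaries are fixed by
  coordinate, not data-driven.
- Breakpoints resolve to the bin (1 Mb by default); no split-read
  refinement.
- The dosage classifier assumes a mostly disomic genome per sample;
  polyploid dosage series beyond 4 copies are out of scope.
- The genotyper handles biallelic SNPs only — no indels, no
  multi-allelic sites, no imputation.
- Barcode sets are validated for uniqueness but not designed (no
  minimum-distance construction, no index-hopping model).
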