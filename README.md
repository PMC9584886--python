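# skimseq

A toolkit for **whole-genome skim sequencing** (skim-seq): genotyping,
chromosome-dosage estimation and alien-introgression mapping from very
low-coverage sequencing (0.01x–1x per sample), aimed at plant
geneticists and breeders who multiplex hundreds of samples per lane —
doubled-haploid (DH) populations, aneuploid genetic stocks, and
interspecific introgression lines in crops like wheat.

At that coverage there is no per-site depth to call variants in the
usual way. Instead, skim-seq leans on reference genomes and read
*counting*:

- **Dosage from binned depth.** Reads are counted in fixed 1 Mb bins and
  normalized per sample,

  `norm_count = raw_count_in_bin / total_reads_per_sample × NF` (NF = 10⁷ by default),

  and converted to **copy ratios** against a disomic baseline: ~1 for two
  chromosome copies, ~0.5 for one, ~0 for none. Whole-chromosome and
  arm-level classes (euploid, monosomic, nullisomic, trisomic,
  telosomic) follow by rounding 2×ratio to integer copies.
- **Introgressions on an in-silico hybrid reference.** Concatenating the
  recipient and donor assemblies (headers renamed `<label>_<id>`) lets
  reads partition between genomes by best match; a translocation appears
  as a recipient segment at reduced dosage paired with a donor segment
  at matching dosage. Breakpoints are delimited by binary segmentation
  of the copy-ratio track, and carrier:non-carrier counts are tested
  against 1:1 with a Pearson χ² (df = 1).
- **Sparse genotyping.** Homozygous SNP differences between two parents
  (per-parent depth in [6, 100], own-allele depth ≥ 3, major-allele
  purity ≥ 0.9) are genotyped in progeny from raw allele counts — a
  single read is evidence at 0.01x — and parental haplotype blocks are
  assembled by majority vote in 5 Mb windows.
- **Fold coverage** is estimated as
  `coverage = read_count × read_length × 2 / (genome_size × n_samples)`.

Everything upstream is covered too: combinatorial dual-index
demultiplexing (i5 per plate, i7 per sample, automatic i5-orientation
detection, blank-well QC at 0.01% of the mean), selection of uniquely
mapped concordant pairs via the `NH:i:1`/`YT:Z:CP` SAM tags, and exact-
count down-sampling. A `simulate` module generates every input type with
machine-readable truth, so the whole pipeline is testable without real
data.

## Worked example: delimiting a wheat–barley translocation

Simulate a homozygous 7AS.7HL-7AL line — the wheat 7A interval
362–473 Mb replaced by barley 7H 337–456 Mb — at 0.025x coverage, then
recover the event from the binned counts:

```python
from skimseq import *
from skimseq.refhybrid import CatalogEntry

MB = 1_000_000
catalog = GenomeCatalog([
    CatalogEntry("wheat_7A", 700 * MB, "wheat", "7A"),
    CatalogEntry("barley_7H", 650 * MB, "barley", "7H"),
])
karyotype = SimKaryotype([
    KaryotypeRegion("barley_7H", 0),                        # no donor background
    KaryotypeRegion("wheat_7A", 0, 362 * MB, 473 * MB),     # wheat segment lost
    KaryotypeRegion("barley_7H", 2, 337 * MB, 456 * MB),    # barley segment gained
])
config = SimConfig(catalog=catalog, coverage=0.025, seed=7)
matrix = normalize(simulate_bin_counts(karyotype, config))
profile = compute_copy_ratio(matrix, baseline="self_genome_median",
                             catalog=catalog, reference_label="wheat")
sample = matrix.samples[0]
recipient = segment_sample(profile, sample, ["wheat_7A"])
donor = segment_sample(profile, sample, ["barley_7H"])
for call in pair_translocation(recipient, donor, catalog):
    print(call.designation, call.zygosity,
          f"loss={call.recipient_loss_mb:.0f}Mb gain={call.donor_gain_mb:.0f}Mb")
print(segregation_test(169, 166))
```

prints

```
7A:362-473Mb::7H:337-456Mb homozygous loss=111Mb gain=119Mb
{'chi_square': 0.026865671641791045, 'df': 1.0, 'p_value': 0.8698039553986283}
```

The segmentation finds the breakpoints on the exact bin boundaries — a
111 Mb wheat loss paired with a 119 Mb barley gain, called homozygous
because the wheat segment is fully absent while the barley segment sits
at two copies. The χ² line tests a 169:166 carrier ratio against 1:1
(p ≈ 0.87, i.e. ordinary Mendelian segregation of a single heterozygous
translocation).

## Command line

```sh
skimseq hybrid-ref --recipient wheat.fa --donor barley.fa --labels wheat,barley --out hybrid.fa
skimseq demux --r1 R1.fq --r2 R2.fq --i1 I1.fq --i2 I2.fq --sheet sheet.tsv --out demux/
skimseq filter --in aligned.sam --out filtered.sam
skimseq bin --in filtered.sam --catalog hybrid.fa.catalog.tsv --out bins.tsv
skimseq karyotype --bins bins.tsv --catalog cat.tsv --centromeres cen.bed --out karyo/
skimseq introgress --bins bins.tsv --catalog cat.tsv --reference-label wheat --out calls/
skimseq genotype discover --parent-a a.pileup.tsv --parent-b b.pileup.tsv --out snps.tsv
skimseq simulate bins --config sim.yaml --seed 7 --out fixtures/
skimseq pipeline aneuploidy --config run.yaml
```

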