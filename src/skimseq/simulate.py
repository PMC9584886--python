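"""Synthetic skim-seq data generators with machine-readable truth.

Every analysis stage has a matching generator: per-bin read counts
under an arbitrary copy-number karyotype, tagged SAM mimicking a
spliced-alignment-disabled paired-end aligner, aneuploid panels,
backcross (BC1) populations segregating a translocation, doubled-
haploid (DH) populations with crossovers and sparse marker
observations, and dual-index reads for demultiplexing.

The count model is per-bin independent Poisson with mean

    lambda = coverage * bin_width / (2 * read_length) * (copy / 2)

i.e. the expected number of read *pairs* a bin receives at the given
fold coverage, scaled linearly by copy number (a negative-binomial
overdispersion hook is available but off by default).  Coverage
semantics follow the same fold-coverage arithmetic the analysis uses,
so estimating coverage from simulated totals recovers the configured
fold.  All generators are pure functions of (config, seed).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .bincount import (
    DEFAULT_BIN_SIZE,
    DEFAULT_READ_LENGTH,
    BinCountMatrix,
    BinGrid,
)
from .demux import SampleSheet, reverse_complement
from .refhybrid import CentromereMap, GenomeCatalog

logger = logging.getLogger("skimseq")

PARENT_A = "A"
PARENT_B = "B"


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class KaryotypeRegion:
    contig_id: str
    copy_number: int
    start_bp: int | None = None  # None, None = whole contig
    end_bp: int | None = None

    def __post_init__(self) -> None:
        if self.copy_number < 0:
            raise SimulationError("copy_number must be >= 0")
        if (self.start_bp is None) != (self.end_bp is None):
            raise SimulationError("give both start_bp and end_bp or neither")
        if self.start_bp is not None and self.start_bp >= self.end_bp:
            raise SimulationError("empty karyotype interval")


@dataclass
class SimKaryotype:
    """Ground-truth copy-number spec: default 2 everywhere unless overridden.

    One whole-contig region per contig may set that contig's base copy
    number; interval regions (which must not overlap each other) are
    layered on top of the base.
    """

    regions: list[KaryotypeRegion] = field(default_factory=list)

    def __post_init__(self) -> None:
        per_contig: dict[str, list[KaryotypeRegion]] = {}
        for r in self.regions:
            per_contig.setdefault(r.contig_id, []).append(r)
        for contig, regs in per_contig.items():
            whole = [r for r in regs if r.start_bp is None]
            if len(whole) > 1:
                raise SimulationError(f"multiple whole-contig regions for {contig!r}")
            ivs = sorted(
                [(r.start_bp, r.end_bp) for r in regs if r.start_bp is not None]
            )
            for (s1, e1), (s2, e2) in zip(ivs[:-1], ivs[1:]):
                if s2 < e1:
                    raise SimulationError(f"overlapping interval overrides on {contig!r}")

    def base_copy(self, contig: str) -> int:
        for r in self.regions:
            if r.contig_id == contig and r.start_bp is None:
                return r.copy_number
        return 2

    def copy_per_bin(self, contig: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Length-weighted mean copy number for each bin of a contig."""
        copies = np.full(len(starts), float(self.base_copy(contig)))
        widths = (ends - starts).astype(float)
        for r in self.regions:
            if r.contig_id != contig or r.start_bp is None:
                continue
            ov = np.clip(
                np.minimum(ends, r.end_bp) - np.maximum(starts, r.start_bp), 0, None
            ).astype(float)
            copies += ov / widths * (r.copy_number - self.base_copy(contig))
        return copies


@dataclass
class SimConfig:
    catalog: GenomeCatalog
    coverage: float
    seed: int
    read_length_bp: int = DEFAULT_READ_LENGTH
    bin_size_bp: int = DEFAULT_BIN_SIZE
    n_samples: int = 1
    composition: dict[str, int] | None = None
    crossover_mean_per_chrom: float = 2.0
    carrier_prob: float = 0.5
    multimapper_fraction: float = 0.0
    index_error_rate: float = 0.0
    dispersion: float = 0.0  # negative-binomial overdispersion; 0 = Poisson

    def __post_init__(self) -> None:
        if self.coverage < 0:
            raise SimulationError("coverage must be >= 0")
        if self.seed is None:
            raise SimulationError("seed is mandatory")
        if self.composition is not None and sum(self.composition.values()) != self.n_samples:
            raise SimulationError("composition counts must sum to n_samples")
        if not 0 <= self.multimapper_fraction < 1:
            raise SimulationError("multimapper_fraction must be in [0, 1)")


def _bin_arrays(config: SimConfig) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    grid = BinGrid.from_catalog(config.catalog, config.bin_size_bp)
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    for contig in config.catalog.contigs():
        for s, e in grid.bins(contig):
            chroms.append(contig)
            starts.append(s)
            ends.append(e)
    return chroms, np.array(starts), np.array(ends), np.array(
        [e - s for s, e in zip(starts, ends)], dtype=float
    )


def _lambda_per_bin(config: SimConfig, widths: np.ndarray, copies: np.ndarray) -> np.ndarray:
    return config.coverage * widths / (2 * config.read_length_bp) * (copies / 2.0)


def _draw_counts(rng: np.random.Generator, lam: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(lam)
    # gamma-poisson mixture: mean lam, variance lam * (1 + dispersion * lam)
    shape = 1.0 / dispersion
    mixed = rng.gamma(shape, np.where(lam > 0, lam * dispersion, 1.0))
    return np.where(lam > 0, rng.poisson(mixed), 0)


def _copies_matrix(
    config: SimConfig, karyotypes: list[SimKaryotype]
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    chroms, starts, ends, widths = _bin_arrays(config)
    copies = np.empty((len(karyotypes), len(starts)))
    chrom_arr = np.array(chroms)
    for i, kt in enumerate(karyotypes):
        row = np.empty(len(starts))
        for contig in config.catalog.contigs():
            m = chrom_arr == contig
            row[m] = kt.copy_per_bin(contig, starts[m], ends[m])
        copies[i] = row
    return chroms, starts, ends, copies


def _assemble_matrix(
    config: SimConfig,
    sample_ids: list[str],
    chroms: list[str],
    starts: np.ndarray,
    ends: np.ndarray,
    raw: np.ndarray,
) -> BinCountMatrix:
    n_bins = len(chroms)
    df = pd.DataFrame(
        {
            "sample": np.repeat(sample_ids, n_bins),
            "chrom": np.tile(chroms, len(sample_ids)),
            "start": np.tile(starts, len(sample_ids)),
            "end": np.tile(ends, len(sample_ids)),
            "raw": raw.reshape(-1),
        }
    )
    totals = {s: float(raw[i].sum()) for i, s in enumerate(sample_ids)}
    return BinCountMatrix(df, totals, unit="pairs", meta={"simulated": True})


def simulate_bin_counts(
    karyotype: SimKaryotype,
    config: SimConfig,
    sample_ids: list[str] | None = None,
) -> BinCountMatrix:
    """Per-bin pair counts under one karyotype for config.n_samples samples."""
    rng = np.random.default_rng(config.seed)
    if sample_ids is None:
        sample_ids = [f"s{i + 1:04d}" for i in range(config.n_samples)]
    chroms, starts, ends, copies = _copies_matrix(config, [karyotype])
    widths = (ends - starts).astype(float)
    lam = _lambda_per_bin(config, widths, copies[0])
    raw = np.stack(
        [_draw_counts(rng, lam, config.dispersion) for _ in sample_ids]
    )
    return _assemble_matrix(config, sample_ids, chroms, starts, ends, raw)


# ---------------------------------------------------------------------------
# tagged SAM emulation

_FLAG_R1 = 0x1 | 0x2 | 0x20 | 0x40  # paired, proper, mate reverse, first
_FLAG_R2 = 0x1 | 0x2 | 0x10 | 0x80


def simulate_sam(
    karyotype: SimKaryotype,
    config: SimConfig,
    out_sam: str | Path,
    fragment_bp: int = 300,
    sample_id: str = "sim",
) -> tuple[Path, BinCountMatrix]:
    """Emit concordant read pairs as SAM plus the truth bin counts.

    The unique fraction carries ``NH:i:1`` and ``YT:Z:CP``; a
    ``multimapper_fraction`` of extra pairs carries ``NH:i:2`` and must
    be removed by the alignment filter.  Filtering then binning the
    output reproduces the truth counts exactly.
    """
    rng = np.random.default_rng(config.seed)
    chroms, starts, ends, copies = _copies_matrix(config, [karyotype])
    widths = (ends - starts).astype(float)
    m = config.multimapper_fraction
    lam = _lambda_per_bin(config, widths, copies[0])
    unique = _draw_counts(rng, lam * (1 - m), config.dispersion)
    multi = _draw_counts(rng, lam * m, config.dispersion) if m > 0 else np.zeros_like(unique)

    truth = _assemble_matrix(
        config, [sample_id], chroms, starts, ends, unique[np.newaxis, :]
    )
    out_sam = Path(out_sam)
    lengths = config.catalog.lengths
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": lengths[c]} for c in config.catalog.contigs()],
    }
    rl = config.read_length_bp
    n_pair = 0
    with pysam.AlignmentFile(str(out_sam), "w", header=header) as out:
        tid = {c: i for i, c in enumerate(config.catalog.contigs())}
        for b in range(len(chroms)):
            contig = chroms[b]
            clen = lengths[contig]
            for n_reads, nh in ((int(unique[b]), 1), (int(multi[b]), 2)):
                if n_reads == 0:
                    continue
                hi = min(ends[b], clen - fragment_bp)
                lo = starts[b]
                hi = max(hi, lo + 1)
                positions = rng.integers(lo, hi, size=n_reads)
                for pos in positions:
                    n_pair += 1
                    qname = f"r{n_pair:08d}"
                    mate_pos = int(pos) + fragment_bp - rl
                    for flag, p, mp in (
                        (_FLAG_R1, int(pos), mate_pos),
                        (_FLAG_R2, mate_pos, int(pos)),
                    ):
                        rec = pysam.AlignedSegment()
                        rec.query_name = qname
                        rec.flag = flag
                        rec.reference_id = tid[contig]
                        rec.reference_start = p
                        rec.mapping_quality = 60 if nh == 1 else 1
                        rec.cigarstring = f"{rl}M"
                        rec.next_reference_id = tid[contig]
                        rec.next_reference_start = mp
                        rec.template_length = (
                            fragment_bp if flag == _FLAG_R1 else -fragment_bp
                        )
                        rec.query_sequence = "A" * rl
                        rec.query_qualities = pysam.qualitystring_to_array("I" * rl)
                        rec.set_tag("NH", nh)
                        rec.set_tag("YT", "CP")
                        out.write(rec)
    return out_sam, truth


# ---------------------------------------------------------------------------
# aneuploid panel

PANEL_CLASSES = (
    "disomic",
    "monosomic",
    "nullisomic",
    "trisomic",
    "telosomic_short_arm",
    "telosomic_long_arm",
    "mono_plus_telo",
    "failed",
    "blank",
)


def _panel_karyotype(
    cls: str, focal_contig: str, centromere_bp: int | None, contig_len: int
) -> SimKaryotype:
    def telo(short_copy: int, long_copy: int) -> SimKaryotype:
        if centromere_bp is None:
            raise SimulationError(
                f"telosomic class {cls!r} needs a centromere for {focal_contig!r}"
            )
        return SimKaryotype(
            [
                KaryotypeRegion(focal_contig, short_copy, 0, centromere_bp),
                KaryotypeRegion(focal_contig, long_copy, centromere_bp, contig_len),
            ]
        )

    if cls in ("disomic", "failed", "blank"):
        return SimKaryotype([])
    if cls == "monosomic":
        return SimKaryotype([KaryotypeRegion(focal_contig, 1)])
    if cls == "nullisomic":
        return SimKaryotype([KaryotypeRegion(focal_contig, 0)])
    if cls == "trisomic":
        return SimKaryotype([KaryotypeRegion(focal_contig, 3)])
    if cls == "telosomic_short_arm":
        return telo(1, 0)
    if cls == "telosomic_long_arm":
        return telo(0, 1)
    if cls == "mono_plus_telo":
        return telo(1, 2)
    raise SimulationError(f"unknown panel class {cls!r}")


def simulate_monosomic_panel(
    config: SimConfig,
    focal_contig: str,
    centromeres: CentromereMap | None = None,
    failed_level: float = 0.02,
) -> tuple[BinCountMatrix, pd.DataFrame]:
    """Panel segregating dosage of one chromosome (euploid/monosomic/
    nullisomic/telosomic/...), with blank and failed wells.

    ``config.composition`` maps class name -> sample count.  Blank
    samples emit zero reads; failed samples emit ``failed_level`` of
    the normal total.  Returns (counts, truth) where truth has columns
    sample, cls.
    """
    if not config.composition:
        raise SimulationError("composition required for panel simulation")
    rng = np.random.default_rng(config.seed)
    cen = centromeres.get(focal_contig) if centromeres is not None else None
    contig_len = config.catalog.lengths[focal_contig]

    classes: list[str] = []
    for cls, count in config.composition.items():
        if cls not in PANEL_CLASSES:
            raise SimulationError(f"unknown panel class {cls!r}")
        classes.extend([cls] * count)
    order = rng.permutation(len(classes))
    classes = [classes[i] for i in order]
    sample_ids = [f"s{i + 1:04d}" for i in range(len(classes))]

    chroms, starts, ends, widths = _bin_arrays(config)
    chrom_arr = np.array(chroms)
    lam_by_class: dict[str, np.ndarray] = {}
    for cls in set(classes):
        kt = _panel_karyotype(cls, focal_contig, cen, contig_len)
        copies = np.empty(len(starts))
        for contig in config.catalog.contigs():
            msk = chrom_arr == contig
            copies[msk] = kt.copy_per_bin(contig, starts[msk], ends[msk])
        lam = _lambda_per_bin(config, widths, copies)
        if cls == "blank":
            lam = np.zeros_like(lam)
        elif cls == "failed":
            lam = lam * failed_level
        lam_by_class[cls] = lam

    raw = np.stack(
        [_draw_counts(rng, lam_by_class[cls], config.dispersion) for cls in classes]
    )
    matrix = _assemble_matrix(config, sample_ids, chroms, starts, ends, raw)
    truth = pd.DataFrame({"sample": sample_ids, "cls": classes})
    return matrix, truth


# ---------------------------------------------------------------------------
# BC1 translocation population

def simulate_bc1_population(
    config: SimConfig,
    recipient_contig: str,
    recipient_interval: tuple[int, int],
    donor_contig: str,
    donor_interval: tuple[int, int],
) -> tuple[BinCountMatrix, pd.DataFrame]:
    """Backcross progeny segregating one heterozygous translocation.

    Carriers (probability ``config.carrier_prob``) carry one
    translocated chromosome: recipient interval at copy 1 with the
    matching donor interval at copy 1; non-carriers are euploid with no
    donor material.  Returns (counts, truth) with truth columns sample,
    carrier.
    """
    rng = np.random.default_rng(config.seed)
    carriers = rng.random(config.n_samples) < config.carrier_prob
    sample_ids = [f"s{i + 1:04d}" for i in range(config.n_samples)]

    kt_carrier = SimKaryotype(
        [
            KaryotypeRegion(donor_contig, 0),
            KaryotypeRegion(recipient_contig, 1, *recipient_interval),
            KaryotypeRegion(donor_contig, 1, *donor_interval),
        ]
    )
    kt_noncarrier = SimKaryotype([KaryotypeRegion(donor_contig, 0)])
    chroms, starts, ends, copies = _copies_matrix(config, [kt_carrier, kt_noncarrier])
    widths = (ends - starts).astype(float)
    lam_car = _lambda_per_bin(config, widths, copies[0])
    lam_non = _lambda_per_bin(config, widths, copies[1])
    raw = np.stack(
        [
            _draw_counts(rng, lam_car if c else lam_non, config.dispersion)
            for c in carriers
        ]
    )
    matrix = _assemble_matrix(config, sample_ids, chroms, starts, ends, raw)
    truth = pd.DataFrame({"sample": sample_ids, "carrier": carriers})
    return matrix, truth


# ---------------------------------------------------------------------------
# DH population

def uniform_marker_map(catalog: GenomeCatalog, spacing_bp: int) -> pd.DataFrame:
    """Evenly spaced parental marker positions (1-based) over a catalog."""
    rows = []
    for e in catalog:
        for pos in range(spacing_bp, e.length_bp + 1, spacing_bp):
            rows.append((e.contig_id, pos))
    return pd.DataFrame(rows, columns=["chrom", "pos"])


def simulate_dh_population(
    marker_map: pd.DataFrame,
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """DH lines: per-chromosome crossovers, sparse marker observations.

    Each chromosome receives Poisson(``crossover_mean_per_chrom``)
    crossovers at uniform positions; the parental phase alternates from
    a random starting parent.  A marker is observed when at least one
    read covers it — reads per site are Poisson(coverage), so
    P(observed) = 1 - exp(-coverage) — and an observed marker reports
    the true phase allele (error-free).

    Returns (calls, truth_segments).  ``calls`` holds only the observed
    (non-missing) markers with columns sample, chrom, pos, call and
    attrs ``n_markers_total``; truth segments have columns sample,
    chrom, start, end, parent (0-based half-open).
    """
    rng = np.random.default_rng(config.seed)
    p_obs = 1.0 - np.exp(-config.coverage)
    lengths = config.catalog.lengths
    sample_ids = [f"dh{i + 1:04d}" for i in range(config.n_samples)]
    calls_rows = []
    truth_rows = []
    for sample in sample_ids:
        for contig, clen in lengths.items():
            pos = marker_map.loc[marker_map["chrom"] == contig, "pos"].to_numpy()
            n_x = rng.poisson(config.crossover_mean_per_chrom)
            breaks = np.sort(rng.integers(1, clen, size=n_x))
            start_parent = PARENT_A if rng.random() < 0.5 else PARENT_B
            bounds = [0, *breaks.tolist(), clen]
            parents = [
                (PARENT_A if (i % 2 == 0) == (start_parent == PARENT_A) else PARENT_B)
                for i in range(len(bounds) - 1)
            ]
            for (s, e), par in zip(zip(bounds[:-1], bounds[1:]), parents):
                if e > s:
                    truth_rows.append((sample, contig, s, e, par))
            if len(pos) == 0:
                continue
            seg_idx = np.searchsorted(breaks, pos, side="left")
            allele = np.array(parents)[seg_idx]
            observed = rng.random(len(pos)) < p_obs
            for p, a in zip(pos[observed], allele[observed]):
                calls_rows.append((sample, contig, int(p), a))
    calls = pd.DataFrame(calls_rows, columns=["sample", "chrom", "pos", "call"])
    calls.attrs["n_markers_total"] = int(len(marker_map)) * config.n_samples
    calls.attrs["p_obs"] = float(p_obs)
    truth = pd.DataFrame(
        truth_rows, columns=["sample", "chrom", "start", "end", "parent"]
    )
    return calls, truth


def score_haplotype_blocks(
    blocks: pd.DataFrame, truth: pd.DataFrame, catalog: GenomeCatalog
) -> dict[str, float]:
    """Length fractions of the genome assigned to the true parent,
    the wrong parent, or left unresolved/uncovered, against simulation
    truth segments."""
    total = 0.0
    correct = 0.0
    wrong = 0.0
    resolved = blocks[blocks["parent"].isin((PARENT_A, PARENT_B))]
    samples = truth["sample"].unique()
    lengths = catalog.lengths
    for sample in samples:
        for contig, clen in lengths.items():
            total += clen
            t = truth[(truth["sample"] == sample) & (truth["chrom"] == contig)]
            b = resolved[
                (resolved["sample"] == sample) & (resolved["chrom"] == contig)
            ]
            for _, blk in b.iterrows():
                for _, seg in t.iterrows():
                    ov = min(blk["end"], seg["end"]) - max(blk["start"], seg["start"])
                    if ov <= 0:
                        continue
                    if blk["parent"] == seg["parent"]:
                        correct += ov
                    else:
                        wrong += ov
    return {
        "fraction_correct": correct / total if total else 0.0,
        "fraction_wrong": wrong / total if total else 0.0,
        "fraction_unresolved": 1.0 - (correct + wrong) / total if total else 1.0,
    }


# ---------------------------------------------------------------------------
# index reads for demultiplexing

_BASE_ARR = np.array(list("ACGT"))


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    chars = np.array(list(seq))
    hit = rng.random(len(chars)) < error_rate
    for i in np.flatnonzero(hit):
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def simulate_index_reads(
    sheet: SampleSheet,
    out_dir: str | Path,
    seed: int,
    reads_per_sample: int = 100,
    error_rate: float = 0.0,
    i5_orientation: str = "as-is",
    read_length_bp: int = 50,
    blank_reads: int = 0,
) -> tuple[dict[str, Path], dict[str, int]]:
    """Write R1/R2/I1/I2 FASTQ for a sheet plus per-sample truth counts.

    Index reads copy each sample's barcodes with per-base substitution
    at ``error_rate``; i5 is written in the requested orientation.
    Blank wells receive ``blank_reads`` pairs (0 by default).
    """
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {k: out_dir / f"{k}.fastq" for k in ("R1", "R2", "I1", "I2")}
    truth: dict[str, int] = {}
    blankset = set(sheet.blank_ids)
    handles = {k: open(p, "w") for k, p in paths.items()}
    try:
        n_read = 0
        for _, row in sheet.rows.iterrows():
            n = blank_reads if row["sample_id"] in blankset else reads_per_sample
            truth[row["sample_id"]] = n
            i5 = (
                row["i5"]
                if i5_orientation == "as-is"
                else reverse_complement(row["i5"])
            )
            for _ in range(n):
                n_read += 1
                name = f"read{n_read:08d}"
                for key, seq in (
                    ("R1", "".join(_BASE_ARR[rng.integers(0, 4, read_length_bp)])),
                    ("R2", "".join(_BASE_ARR[rng.integers(0, 4, read_length_bp)])),
                    ("I1", _mutate(row["i7"], error_rate, rng)),
                    ("I2", _mutate(i5, error_rate, rng)),
                ):
                    handles[key].write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
    finally:
        for h in handles.values():
            h.close()
    return paths, truth


def write_truth(df: pd.DataFrame, path: str | Path) -> Path:
    df.to_csv(path, sep="\t", index=False)
    return Path(path)
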