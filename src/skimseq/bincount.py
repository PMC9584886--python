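"""Binned read counting, normalization and coverage arithmetic.

The central analysis object is the *bin-count matrix*: for each sample
and each fixed-width genomic bin (default 1 Mb, 0-based half-open, last
bin per contig truncated) the raw number of counted units and a
normalized value.  Two normalizations are supported:

``fixed_factor``   norm = raw / total_units_per_sample * factor
                   (default factor 10,000,000, i.e. reads per 10 M)
``mean_bin``       norm = raw / mean raw over that sample's bins

Genome coverage (fold) is estimated from read totals as

    coverage = read_count * read_length * 2 / (genome_size * n_samples)

and an effective depth can be recovered from a mean per-bin pair count
as ``mean_pairs_per_bin * 2 * read_length / bin_size``.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .refhybrid import GenomeCatalog

logger = logging.getLogger("skimseq")

DEFAULT_BIN_SIZE = 1_000_000
DEFAULT_NORM_FACTOR = 10_000_000
DEFAULT_READ_LENGTH = 150
UNPLACED = "unplaced"


class BinCountError(ValueError):
    pass


@dataclass
class BinGrid:
    """Fixed-width bins over a catalog; contiguous, sorted, last bin truncated."""

    bin_size_bp: int
    contig_lengths: dict[str, int]

    def __post_init__(self) -> None:
        if self.bin_size_bp <= 0:
            raise BinCountError(f"bin size must be positive, got {self.bin_size_bp}")

    @classmethod
    def from_catalog(
        cls, catalog: GenomeCatalog, bin_size_bp: int = DEFAULT_BIN_SIZE
    ) -> "BinGrid":
        return cls(bin_size_bp, dict(catalog.lengths))

    def n_bins(self, contig: str) -> int:
        return -(-self.contig_lengths[contig] // self.bin_size_bp)

    def bins(self, contig: str) -> list[tuple[int, int]]:
        length = self.contig_lengths[contig]
        starts = range(0, length, self.bin_size_bp)
        return [(s, min(s + self.bin_size_bp, length)) for s in starts]

    def bin_index(self, contig: str, pos0: int) -> int:
        if not 0 <= pos0 < self.contig_lengths[contig]:
            raise BinCountError(f"position {pos0} outside contig {contig!r}")
        return pos0 // self.bin_size_bp

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (c, s, e)
            for c in self.contig_lengths
            for s, e in self.bins(c)
        ]
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])


@dataclass
class BinCountMatrix:
    """Long-format sample x bin counts plus per-sample totals.

    ``df`` columns: sample, chrom, start, end, raw, norm (norm is NaN
    until :func:`normalize` runs).  ``totals`` are the counted units per
    sample after filtering — the Eq.-style "total reads per sample" used
    by fixed-factor normalization; they include units that fell outside
    the grid so the binned fraction is visible.
    """

    df: pd.DataFrame
    totals: dict[str, float]
    unit: str = "pairs"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"sample", "chrom", "start", "end", "raw"}
        if missing := required - set(self.df.columns):
            raise BinCountError(f"matrix missing columns {sorted(missing)}")
        if "norm" not in self.df.columns:
            self.df["norm"] = np.nan
        if (self.df["raw"] < 0).any():
            raise BinCountError("negative raw counts")

    @property
    def samples(self) -> list[str]:
        return list(self.df["sample"].unique())

    def pivot(self, value: str = "norm") -> pd.DataFrame:
        """bins x samples wide matrix indexed by (chrom, start, end)."""
        return self.df.pivot_table(
            index=["chrom", "start", "end"],
            columns="sample",
            values=value,
            sort=False,
        )

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# unit\t{self.unit}\n")
            for s, t in self.totals.items():
                fh.write(f"# total\t{s}\t{t:g}\n")
            self.df.to_csv(fh, sep="\t", index=False)
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BinCountMatrix":
        totals: dict[str, float] = {}
        unit = "pairs"
        skip = 0
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                skip += 1
                fields = line[1:].strip().split("\t")
                if fields[0] == "unit":
                    unit = fields[1]
                elif fields[0] == "total":
                    totals[fields[1]] = float(fields[2])
        df = pd.read_csv(path, sep="\t", skiprows=skip)
        df["sample"] = df["sample"].astype(str)
        if not totals:
            totals = df.groupby("sample", sort=False)["raw"].sum().to_dict()
        return cls(df, totals, unit)


@dataclass
class NormalizationSpec:
    mode: str = "fixed_factor"  # or "mean_bin"
    factor: float = DEFAULT_NORM_FACTOR

    def __post_init__(self) -> None:
        if self.mode not in ("fixed_factor", "mean_bin"):
            raise BinCountError(f"unknown normalization mode {self.mode!r}")
        if self.factor <= 0:
            raise BinCountError("normalization factor must be > 0")


@dataclass
class CoverageModel:
    read_count: float
    read_length_bp: float = DEFAULT_READ_LENGTH
    genome_size_bp: float = 15e9
    n_samples: int = 1

    def __post_init__(self) -> None:
        if self.read_count < 0:
            raise BinCountError("read_count must be >= 0")
        for name in ("read_length_bp", "genome_size_bp", "n_samples"):
            if getattr(self, name) <= 0:
                raise BinCountError(f"{name} must be > 0")


def estimate_coverage(model: CoverageModel) -> float:
    """Fold coverage from paired-end read totals.

    read_count is the number of read *pairs* as counted in the raw file
    listing (each pair contributes read_length * 2 bases).
    """
    return (
        model.read_count
        * model.read_length_bp
        * 2
        / (model.genome_size_bp * model.n_samples)
    )


def effective_depth_from_bin_mean(
    mean_pairs_per_bin: float,
    read_length_bp: float = DEFAULT_READ_LENGTH,
    bin_size_bp: float = DEFAULT_BIN_SIZE,
) -> float:
    """Effective fold coverage implied by a mean per-bin pair count."""
    if read_length_bp <= 0 or bin_size_bp <= 0:
        raise BinCountError("read length and bin size must be > 0")
    return mean_pairs_per_bin * 2 * read_length_bp / bin_size_bp


def count_in_bins(
    aln_path: str | Path,
    grid: BinGrid,
    unit: str = "pairs",
    sample_id: str | None = None,
) -> BinCountMatrix:
    """Count filtered alignments per bin for one sample.

    unit="pairs" (default): each pair counts once, in the bin holding the
    leftmost mapped mate position.  unit="reads": every record counts in
    its own bin.  Units on contigs absent from the grid go to an
    ``unplaced`` bucket (kept in totals, reported in meta).
    """
    if unit not in ("pairs", "reads"):
        raise BinCountError(f"unknown counting unit {unit!r}")
    aln_path = Path(aln_path)
    if sample_id is None:
        sample_id = aln_path.name.split(".")[0]
    counts: dict[str, np.ndarray] = {
        c: np.zeros(grid.n_bins(c), dtype=np.int64) for c in grid.contig_lengths
    }
    unplaced = 0
    total = 0
    with pysam.AlignmentFile(str(aln_path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            if unit == "pairs":
                if rec.is_paired and not rec.mate_is_unmapped:
                    mpos = rec.next_reference_start
                    # count the pair once, at its leftmost mate
                    if rec.reference_start > mpos:
                        continue
                    if rec.reference_start == mpos and rec.is_read2:
                        continue
            total += 1
            contig = rec.reference_name
            if contig not in counts:
                unplaced += 1
                continue
            counts[contig][rec.reference_start // grid.bin_size_bp] += 1
    rows = []
    for contig in grid.contig_lengths:
        for (s, e), n in zip(grid.bins(contig), counts[contig]):
            rows.append((sample_id, contig, s, e, int(n)))
    df = pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "raw"])
    if unplaced:
        logger.warning("%s: %d units on contigs absent from the grid", sample_id, unplaced)
    return BinCountMatrix(
        df, {sample_id: float(total)}, unit, meta={"unplaced": {sample_id: unplaced}}
    )


def concat_matrices(matrices: list[BinCountMatrix]) -> BinCountMatrix:
    """Stack per-sample matrices into one all-samples matrix."""
    if not matrices:
        raise BinCountError("no matrices to concatenate")
    df = pd.concat([m.df for m in matrices], ignore_index=True)
    totals: dict[str, float] = {}
    unplaced: dict[str, int] = {}
    for m in matrices:
        totals.update(m.totals)
        unplaced.update(m.meta.get("unplaced", {}))
    return BinCountMatrix(df, totals, matrices[0].unit, meta={"unplaced": unplaced})


def normalize(
    matrix: BinCountMatrix, spec: NormalizationSpec | None = None
) -> BinCountMatrix:
    """Fill the norm column; zero-total samples get norm 0 and a 'failed' flag."""
    spec = spec or NormalizationSpec()
    df = matrix.df.copy()
    failed: list[str] = []
    norm = np.empty(len(df), dtype=float)
    for sample, idx in df.groupby("sample", sort=False).groups.items():
        raw = df.loc[idx, "raw"].to_numpy(dtype=float)
        if spec.mode == "fixed_factor":
            total = matrix.totals.get(sample, raw.sum())
            if total <= 0:
                failed.append(sample)
                norm[df.index.get_indexer(idx)] = 0.0
                continue
            norm[df.index.get_indexer(idx)] = raw / total * spec.factor
        else:
            mean = raw.mean()
            if mean <= 0:
                failed.append(sample)
                norm[df.index.get_indexer(idx)] = 0.0
                continue
            norm[df.index.get_indexer(idx)] = raw / mean
    df["norm"] = norm
    meta = dict(matrix.meta)
    meta["normalization"] = {"mode": spec.mode, "factor": spec.factor}
    if failed:
        meta["failed_samples"] = failed
        logger.warning("samples with zero total flagged failed: %s", failed)
    return BinCountMatrix(df, dict(matrix.totals), matrix.unit, meta)


DEFAULT_UNKNOWN_PATTERNS = ("Un", "unplaced")


def drop_unknown_contigs(
    matrix: BinCountMatrix,
    patterns: tuple[str, ...] = DEFAULT_UNKNOWN_PATTERNS,
) -> BinCountMatrix:
    """Remove bins on unknown/unplaced contigs (case-insensitive substring match)."""
    regex = re.compile("|".join(re.escape(p) for p in patterns), re.IGNORECASE)
    mask = matrix.df["chrom"].astype(str).str.contains(regex)
    n_removed = int(mask.sum())
    df = matrix.df.loc[~mask].reset_index(drop=True)
    if df.empty:
        raise BinCountError("unknown-contig filter removed every bin")
    meta = dict(matrix.meta)
    meta["unknown_bins_removed"] = n_removed
    return BinCountMatrix(df, dict(matrix.totals), matrix.unit, meta)


def per_chromosome_density(matrix: BinCountMatrix) -> pd.DataFrame:
    """Mean raw and norm count per bin, per contig: per sample and population-wide.

    Population-wide rows use sample id "__population__"; the frame's
    ``attrs`` record the min/max contigs by population mean raw density.
    """
    if matrix.df.empty:
        raise BinCountError("empty matrix")
    per_sample = (
        matrix.df.groupby(["sample", "chrom"], sort=False)[["raw", "norm"]]
        .mean()
        .reset_index()
        .rename(columns={"raw": "mean_raw", "norm": "mean_norm"})
    )
    pop = (
        matrix.df.groupby("chrom", sort=False)[["raw", "norm"]]
        .mean()
        .reset_index()
        .rename(columns={"raw": "mean_raw", "norm": "mean_norm"})
    )
    pop.insert(0, "sample", "__population__")
    out = pd.concat([per_sample, pop], ignore_index=True)
    out.attrs["min_contig"] = pop.loc[pop["mean_raw"].idxmin(), "chrom"]
    out.attrs["max_contig"] = pop.loc[pop["mean_raw"].idxmax(), "chrom"]
    return out
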