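"""Alignment filtering and read down-sampling.

Skim-seq counts only read pairs that the aligner placed uniquely and
concordantly.  For a spliced-alignment-disabled paired-end aligner this
is tag-defined: hit count ``NH:i:1`` and pair class ``YT:Z:CP``, plus
the proper-pair FLAG as a safety check.  Records from aligners that set
neither tag are dropped with a warning rather than guessed from MAPQ.

Down-sampling draws an exact-count subset of pairs without replacement
(mates stay together) so that target fractions like 0.05x/0.01x are
exactly sized and reproducible for a fixed seed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from .bincount import CoverageModel, estimate_coverage

logger = logging.getLogger("skimseq")


class FilterError(ValueError):
    pass


@dataclass
class FilterStats:
    input_records: int
    kept_records: int
    missing_tag_records: int = 0

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"input_records\t{self.input_records}\n")
            fh.write(f"kept_records\t{self.kept_records}\n")
            fh.write(f"missing_tag_records\t{self.missing_tag_records}\n")
        return path


def _is_unique_concordant(rec: pysam.AlignedSegment) -> tuple[bool, bool]:
    """(keep, missing_both_tags) for one record."""
    if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
        return False, False
    has_nh = rec.has_tag("NH")
    has_yt = rec.has_tag("YT")
    if not has_nh and not has_yt:
        return False, True
    if not (has_nh and rec.get_tag("NH") == 1):
        return False, False
    if not (has_yt and rec.get_tag("YT") == "CP"):
        return False, False
    if not rec.is_proper_pair:
        return False, False
    return True, False


def filter_unique_concordant(
    in_path: str | Path, out_path: str | Path
) -> FilterStats:
    """Keep mapped, primary, non-supplementary records with NH:i:1 and YT:Z:CP.

    Output order follows input order.  Records carrying neither tag are
    dropped and counted separately (warned, not fatal).
    """
    in_path, out_path = str(in_path), str(out_path)
    write_mode = "wb" if out_path.endswith(".bam") else "w"
    n_in = n_kept = n_missing = 0
    with pysam.AlignmentFile(in_path, check_sq=False) as src:
        with pysam.AlignmentFile(out_path, write_mode, template=src) as dst:
            for rec in src:
                n_in += 1
                keep, missing = _is_unique_concordant(rec)
                n_missing += missing
                if keep:
                    n_kept += 1
                    dst.write(rec)
    if n_missing:
        logger.warning(
            "%d of %d records carried neither NH nor YT tag and were dropped",
            n_missing,
            n_in,
        )
    return FilterStats(n_in, n_kept, n_missing)


def _resolve_fraction(
    n_pairs: int,
    fraction: float | None,
    target_coverage: float | None,
    read_length_bp: float | None,
    genome_size_bp: float | None,
) -> float:
    if (fraction is None) == (target_coverage is None):
        raise FilterError("give exactly one of fraction / target_coverage")
    if fraction is not None:
        if not 0 < fraction <= 1:
            raise FilterError(f"fraction must be in (0, 1], got {fraction}")
        return fraction
    if read_length_bp is None or genome_size_bp is None:
        raise FilterError("target_coverage requires read_length_bp and genome_size_bp")
    current = estimate_coverage(
        CoverageModel(
            read_count=n_pairs,
            read_length_bp=read_length_bp,
            genome_size_bp=genome_size_bp,
            n_samples=1,
        )
    )
    if target_coverage > current:
        raise FilterError(
            f"target coverage {target_coverage} exceeds current coverage {current:.4g}"
        )
    return target_coverage / current


def _sample_indices(n: int, fraction: float, seed: int) -> np.ndarray:
    k = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(n, size=k, replace=False))


def downsample_fastq(
    r1: str | Path,
    r2: str | Path,
    out_r1: str | Path,
    out_r2: str | Path,
    seed: int,
    fraction: float | None = None,
    target_coverage: float | None = None,
    read_length_bp: float | None = None,
    genome_size_bp: float | None = None,
) -> int:
    """Subsample exactly round(fraction*N) read pairs; returns pairs written."""
    with pysam.FastxFile(str(r1)) as fh:
        n_pairs = sum(1 for _ in fh)
    fraction = _resolve_fraction(
        n_pairs, fraction, target_coverage, read_length_bp, genome_size_bp
    )
    keep = _sample_indices(n_pairs, fraction, seed)
    keep_set = set(keep.tolist())
    for src, dst in ((r1, out_r1), (r2, out_r2)):
        with pysam.FastxFile(str(src)) as fh, open(dst, "w") as out:
            for i, rec in enumerate(fh):
                if i in keep_set:
                    out.write(str(rec) + "\n")
    return len(keep_set)


def downsample_alignments(
    in_path: str | Path,
    out_path: str | Path,
    seed: int,
    fraction: float | None = None,
    target_coverage: float | None = None,
    read_length_bp: float | None = None,
    genome_size_bp: float | None = None,
) -> int:
    """Subsample whole read pairs (grouped by query name) from SAM/BAM."""
    in_path, out_path = str(in_path), str(out_path)
    names: list[str] = []
    seen: set[str] = set()
    with pysam.AlignmentFile(in_path, check_sq=False) as src:
        for rec in src:
            if rec.query_name not in seen:
                seen.add(rec.query_name)
                names.append(rec.query_name)
    fraction = _resolve_fraction(
        len(names), fraction, target_coverage, read_length_bp, genome_size_bp
    )
    keep_idx = _sample_indices(len(names), fraction, seed)
    keep_names = {names[i] for i in keep_idx}
    write_mode = "wb" if out_path.endswith(".bam") else "w"
    n = 0
    with pysam.AlignmentFile(in_path, check_sq=False) as src:
        with pysam.AlignmentFile(out_path, write_mode, template=src) as dst:
            for rec in src:
                if rec.query_name in keep_names:
                    dst.write(rec)
        n = len(keep_names)
    return n
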