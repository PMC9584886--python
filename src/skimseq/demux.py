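"""Combinatorial dual-index demultiplexing of multiplexed skim-seq libraries.

Libraries multiplex hundreds of samples per lane with a unique i5 index
per plate and a unique i7 index per sample.  Reads arrive either with
separate index FASTQs (I1 = i7, I2 = i5) or with ``<i7>+<i5>`` embedded
in the FASTQ comment field; both layouts are supported.  Depending on
the sequencing machine the i5 read may come back reverse-complemented,
so orientation is auto-detected once per run from an initial sample of
index reads.

Blank wells — one random empty well per plate — act as negative
controls: a blank passes QC when it receives less than 0.01% of the
mean reads of the real samples.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import pysam

logger = logging.getLogger("skimseq")

SHEET_COLUMNS = ("sample_id", "plate_id", "well", "i7", "i5", "is_blank")
UNDETERMINED = "undetermined"
DEFAULT_BLANK_THRESHOLD = 1e-4  # fraction of mean non-blank reads

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


class DemuxError(ValueError):
    pass


@dataclass
class SampleSheet:
    """Sample sheet mapping (i7, i5) barcode pairs to samples."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.rows
        missing = set(SHEET_COLUMNS) - set(df.columns)
        if missing:
            raise DemuxError(f"sample sheet missing columns: {sorted(missing)}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise DemuxError(f"duplicate sample_id {dup!r}")
        pairs = list(zip(df["i7"], df["i5"]))
        if len(set(pairs)) != len(pairs):
            raise DemuxError("duplicate (i7, i5) barcode pair in sheet")
        for col in ("i7", "i5"):
            seqs = df[col].astype(str)
            if seqs.str.len().nunique() != 1:
                raise DemuxError(f"all {col} sequences must share one length")
            if not seqs.str.fullmatch("[ACGT]+").all():
                raise DemuxError(f"{col} sequences must be over alphabet ACGT")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        df["is_blank"] = (
            df["is_blank"].str.strip().str.lower().isin(("1", "true", "yes", "y"))
        )
        return cls(df)

    def to_tsv(self, path: str | Path) -> Path:
        self.rows.to_csv(path, sep="\t", index=False)
        return Path(path)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.rows["sample_id"])

    @property
    def blank_ids(self) -> list[str]:
        return list(self.rows.loc[self.rows["is_blank"], "sample_id"])

    @property
    def i7_len(self) -> int:
        return len(self.rows["i7"].iloc[0])

    @property
    def i5_len(self) -> int:
        return len(self.rows["i5"].iloc[0])

    def barcodes(self, i5_orientation: str = "as-is") -> dict[tuple[str, str], str]:
        """(i7, i5) -> sample_id, with i5 optionally reverse-complemented."""
        out = {}
        for _, r in self.rows.iterrows():
            i5 = r["i5"] if i5_orientation == "as-is" else reverse_complement(r["i5"])
            out[(r["i7"], i5)] = r["sample_id"]
        return out


@dataclass
class DemuxReport:
    assigned: dict[str, int]
    undetermined: int
    total: int
    i5_orientation: str
    blank_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if sum(self.assigned.values()) + self.undetermined != self.total:
            raise DemuxError("read conservation violated: assigned + undetermined != total")

    def blank_fractions(self) -> dict[str, float]:
        """Per-blank assigned reads as a fraction of the mean non-blank sample."""
        nonblank = [n for s, n in self.assigned.items() if s not in self.blank_ids]
        if not nonblank:
            return {}
        mean = sum(nonblank) / len(nonblank)
        if mean == 0:
            return {b: 0.0 for b in self.blank_ids}
        return {b: self.assigned.get(b, 0) / mean for b in self.blank_ids}

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# total_pairs\t{self.total}\n")
            fh.write(f"# i5_orientation\t{self.i5_orientation}\n")
            fh.write("sample_id\tn_pairs\tis_blank\n")
            for s, n in self.assigned.items():
                fh.write(f"{s}\t{n}\t{int(s in self.blank_ids)}\n")
            fh.write(f"{UNDETERMINED}\t{self.undetermined}\t0\n")
        return path


def _hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        return max(len(a), len(b))
    return sum(x != y for x, y in zip(a, b))


def detect_i5_orientation(
    i5_reads: Iterable[str], sheet: SampleSheet, n_sample: int = 10_000
) -> str:
    """Pick the i5 orientation with the higher exact-match rate.

    Ties (including zero matches both ways) fall back to ``as-is``.
    """
    asis = set(sheet.rows["i5"])
    rc = {reverse_complement(s) for s in asis}
    k = sheet.i5_len
    n_asis = n_rc = n_seen = 0
    for seq in i5_reads:
        seq = seq[:k]
        n_seen += 1
        if seq in asis:
            n_asis += 1
        if seq in rc:
            n_rc += 1
        if n_seen >= n_sample:
            break
    if n_asis == 0 and n_rc == 0:
        logger.warning("no i5 reads matched the sheet in either orientation; assuming as-is")
    return "reverse-complement" if n_rc > n_asis else "as-is"


def _fastq_records(path: str | Path) -> Iterator[tuple[str, str, str, str | None]]:
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            yield rec.name, rec.sequence, rec.quality or "", rec.comment


def _parse_header_barcodes(comment: str | None) -> tuple[str, str]:
    """Extract ``<i7>+<i5>`` from an Illumina-style comment field."""
    if not comment:
        raise DemuxError("read lacks comment field with embedded barcodes")
    token = comment.split()[-1].split(":")[-1]
    if "+" not in token:
        raise DemuxError(f"cannot parse barcodes from comment {comment!r}")
    i7, i5 = token.split("+", 1)
    return i7, i5


def _match_sample(
    i7: str,
    i5: str,
    sheet_rows: list[tuple[str, str, str]],
    exact: dict[tuple[str, str], str],
    max_mismatch: int,
) -> str | None:
    """Resolve one barcode pair to a sample id, or None for undetermined.

    Per-index Hamming distance must be <= max_mismatch for both indexes;
    ties at the winning combined distance are rejected as ambiguous.
    """
    hit = exact.get((i7, i5))
    if hit is not None:
        return hit
    if max_mismatch == 0:
        return None
    best: str | None = None
    best_d = None
    ambiguous = False
    for sid, s7, s5 in sheet_rows:
        d7 = _hamming(i7, s7)
        if d7 > max_mismatch:
            continue
        d5 = _hamming(i5, s5)
        if d5 > max_mismatch:
            continue
        d = d7 + d5
        if best_d is None or d < best_d:
            best, best_d, ambiguous = sid, d, False
        elif d == best_d:
            ambiguous = True
    return None if ambiguous else best


def demultiplex(
    r1: str | Path,
    r2: str | Path,
    i1: str | Path | None,
    i2: str | Path | None,
    sheet: SampleSheet,
    out_dir: str | Path,
    max_mismatch: int = 0,
    i5_orientation: str = "auto",
) -> DemuxReport:
    """Split a multiplexed run into per-sample paired FASTQ files.

    With ``i1``/``i2`` given, the four streams must be record-synchronized;
    without them, barcodes are parsed from the R1 comment field.  Every
    pair lands in exactly one sample's files or in ``undetermined``.
    """
    if max_mismatch < 0:
        raise DemuxError("max_mismatch must be >= 0")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header_mode = i1 is None or i2 is None

    if i5_orientation == "auto":
        if header_mode:
            src = (
                _parse_header_barcodes(c)[1] for _, _, _, c in _fastq_records(r1)
            )
        else:
            src = (seq for _, seq, _, _ in _fastq_records(i2))
        i5_orientation = detect_i5_orientation(src, sheet)
    exact = sheet.barcodes(i5_orientation)
    sheet_rows = [(exact[k], k[0], k[1]) for k in exact]
    k7, k5 = sheet.i7_len, sheet.i5_len

    counts: dict[str, int] = {s: 0 for s in sheet.sample_ids}
    undetermined = 0
    total = 0
    handles: dict[str, tuple] = {}

    def _get_handles(name: str):
        if name not in handles:
            handles[name] = (
                open(out_dir / f"{name}_R1.fastq", "w"),
                open(out_dir / f"{name}_R2.fastq", "w"),
            )
        return handles[name]

    streams = [_fastq_records(r1), _fastq_records(r2)]
    if not header_mode:
        streams += [_fastq_records(i1), _fastq_records(i2)]
    try:
        for recs in zip(*streams):
            names = {r[0] for r in recs}
            if len(names) != 1:
                raise DemuxError(f"desynchronized FASTQ streams at ids {sorted(names)}")
            total += 1
            if header_mode:
                bi7, bi5 = _parse_header_barcodes(recs[0][3])
            else:
                bi7, bi5 = recs[2][1], recs[3][1]
            sample = _match_sample(bi7[:k7], bi5[:k5], sheet_rows, exact, max_mismatch)
            if sample is None:
                undetermined += 1
                sample = UNDETERMINED
            else:
                counts[sample] += 1
            h1, h2 = _get_handles(sample)
            for h, (name, seq, qual, comment) in zip((h1, h2), recs[:2]):
                suffix = f" {comment}" if comment else ""
                h.write(f"@{name}{suffix}\n{seq}\n+\n{qual}\n")
        # all streams must end together
        for st in streams:
            if next(st, None) is not None:
                raise DemuxError("desynchronized FASTQ streams: unequal record counts")
    finally:
        for h1, h2 in handles.values():
            h1.close()
            h2.close()

    return DemuxReport(
        assigned=counts,
        undetermined=undetermined,
        total=total,
        i5_orientation=i5_orientation,
        blank_ids=sheet.blank_ids,
    )


def check_blanks(
    report: DemuxReport, threshold_fraction: float = DEFAULT_BLANK_THRESHOLD
) -> dict[str, bool]:
    """Blank-well QC: pass iff reads < threshold_fraction of the non-blank mean."""
    return {
        blank: frac < threshold_fraction
        for blank, frac in report.blank_fractions().items()
    }
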