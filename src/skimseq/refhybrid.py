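"""Reference catalogs and in-silico interspecific hybrid construction.

Skim-seq analyses are anchored to a *genome catalog*: the ordered set of
contigs (chromosomes or pseudomolecules), their lengths, and the source
genome each one came from.  For alien-introgression mapping the catalog
describes a concatenated "hybrid" reference built from a recipient and a
donor assembly, with every sequence renamed ``<label>_<original_id>`` so
ids stay unique even when both assemblies use names like ``chr7``.

Coordinate conventions: positions facing SAM records are 1-based
inclusive; bins and BED-facing intervals are 0-based half-open.
Conversions happen at module boundaries, never inside.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

logger = logging.getLogger("skimseq")

CATALOG_COLUMNS = ("contig_id", "source_genome", "original_id", "length_bp")


class CatalogError(ValueError):
    """Raised for malformed or inconsistent catalogs and references."""


@dataclass(frozen=True)
class CatalogEntry:
    contig_id: str
    length_bp: int
    source_genome: str
    original_id: str

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise CatalogError(
                f"contig {self.contig_id!r}: length must be positive, got {self.length_bp}"
            )


@dataclass
class GenomeCatalog:
    """Ordered collection of contigs forming the coordinate frame.

    Invariants enforced at construction: unique contig ids, positive
    lengths.  ``source_labels`` preserves first-seen order of genomes.
    """

    entries: list[CatalogEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.contig_id in seen:
                raise CatalogError(f"duplicate contig id {e.contig_id!r} in catalog")
            seen.add(e.contig_id)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[CatalogEntry]:
        return iter(self.entries)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GenomeCatalog) and self.entries == other.entries

    @property
    def lengths(self) -> dict[str, int]:
        return {e.contig_id: e.length_bp for e in self.entries}

    @property
    def source_labels(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e.source_genome not in out:
                out.append(e.source_genome)
        return out

    def contigs(self, source_genome: str | None = None) -> list[str]:
        return [
            e.contig_id
            for e in self.entries
            if source_genome is None or e.source_genome == source_genome
        ]

    def entry(self, contig_id: str) -> CatalogEntry:
        for e in self.entries:
            if e.contig_id == contig_id:
                return e
        raise KeyError(contig_id)

    def total_length(self) -> int:
        return sum(e.length_bp for e in self.entries)

    # ---- I/O -------------------------------------------------------------

    @classmethod
    def from_fasta(cls, path: str | Path, source_genome: str = "genome") -> "GenomeCatalog":
        entries = []
        for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
            if len(rec.seq) == 0:
                raise CatalogError(f"{path}: record {i} ({rec.id!r}) has empty sequence")
            entries.append(CatalogEntry(rec.id, len(rec.seq), source_genome, rec.id))
        if not entries:
            raise CatalogError(f"{path}: FASTA contains no sequences")
        return cls(entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomeCatalog":
        entries = []
        with open(path) as fh:
            header: list[str] | None = None
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if header is None:
                    if set(CATALOG_COLUMNS) - set(fields):
                        raise CatalogError(
                            f"{path}: header must contain columns {CATALOG_COLUMNS}"
                        )
                    header = fields
                    continue
                row = dict(zip(header, fields))
                try:
                    entries.append(
                        CatalogEntry(
                            row["contig_id"],
                            int(row["length_bp"]),
                            row["source_genome"],
                            row["original_id"],
                        )
                    )
                except (KeyError, ValueError, CatalogError) as exc:
                    raise CatalogError(f"{path}: bad record at line {lineno}: {exc}") from exc
        if not entries:
            raise CatalogError(f"{path}: catalog is empty")
        return cls(entries)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("\t".join(CATALOG_COLUMNS) + "\n")
            for e in self.entries:
                fh.write(f"{e.contig_id}\t{e.source_genome}\t{e.original_id}\t{e.length_bp}\n")
        return path


def load_catalog(path: str | Path, source_genome: str = "genome") -> GenomeCatalog:
    """Load a catalog from a TSV sidecar or by scanning a FASTA.

    The format is sniffed from the first non-blank line: a tab-separated
    header containing ``contig_id`` means TSV, a ``>`` means FASTA.
    """
    path = Path(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line
                break
    if first.startswith(">"):
        return GenomeCatalog.from_fasta(path, source_genome)
    if "contig_id" in first.split("\t"):
        return GenomeCatalog.from_tsv(path)
    raise CatalogError(f"{path}: neither FASTA nor catalog TSV")


def write_catalog(catalog: GenomeCatalog, path: str | Path) -> Path:
    return catalog.to_tsv(path)


def build_hybrid_reference(
    fasta_recipient: str | Path,
    fasta_donor: str | Path,
    label_recipient: str,
    label_donor: str,
    out_fasta: str | Path,
    out_catalog: str | Path | None = None,
) -> tuple[Path, GenomeCatalog]:
    """Concatenate recipient and donor assemblies into a hybrid reference.

    Every header is rewritten ``<label>_<original_id>`` so the combined
    reference has unique ids; recipient contigs come first.  A mapping
    table (catalog TSV) is always emitted next to the FASTA so external
    aligner output can be interpreted.
    """
    if label_recipient == label_donor:
        raise CatalogError("recipient and donor labels must differ")
    out_fasta = Path(out_fasta)
    if out_catalog is None:
        out_catalog = out_fasta.with_suffix(out_fasta.suffix + ".catalog.tsv")
    entries: list[CatalogEntry] = []
    seen: set[str] = set()
    with open(out_fasta, "w") as out:
        for label, src in ((label_recipient, fasta_recipient), (label_donor, fasta_donor)):
            n_in = 0
            for rec in SeqIO.parse(str(src), "fasta"):
                n_in += 1
                if len(rec.seq) == 0:
                    raise CatalogError(f"{src}: empty sequence {rec.id!r}")
                new_id = f"{label}_{rec.id}"
                if new_id in seen:
                    raise CatalogError(f"duplicate rewritten id {new_id!r}")
                seen.add(new_id)
                entries.append(CatalogEntry(new_id, len(rec.seq), label, rec.id))
                out.write(f">{new_id}\n")
                seq = str(rec.seq)
                for i in range(0, len(seq), 60):
                    out.write(seq[i : i + 60] + "\n")
            if n_in == 0:
                raise CatalogError(f"{src}: FASTA contains no sequences")
    catalog = GenomeCatalog(entries)
    catalog.to_tsv(out_catalog)
    return out_fasta, catalog


@dataclass
class CentromereMap:
    """contig_id -> centromere position (bp, 1-based on the contig)."""

    positions: dict[str, int] = field(default_factory=dict)

    def __getitem__(self, contig_id: str) -> int:
        return self.positions[contig_id]

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self.positions

    def get(self, contig_id: str, default: int | None = None) -> int | None:
        return self.positions.get(contig_id, default)

    def items(self) -> Iterable[tuple[str, int]]:
        return self.positions.items()

    def validate_against(self, catalog: GenomeCatalog) -> None:
        lengths = catalog.lengths
        for contig, pos in self.positions.items():
            if contig not in lengths:
                raise CatalogError(f"centromere for unknown contig {contig!r}")
            if not 0 < pos < lengths[contig]:
                raise CatalogError(
                    f"centromere {pos} outside contig {contig!r} (length {lengths[contig]})"
                )

    @classmethod
    def from_file(
        cls, path: str | Path, catalog: GenomeCatalog | None = None
    ) -> "CentromereMap":
        """Read centromeres from 3-column BED (contig, pos-1, pos) or 2-column TSV."""
        positions: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                fields = line.split("\t")
                if len(fields) >= 3 and fields[1].isdigit() and fields[2].isdigit():
                    positions[fields[0]] = int(fields[2])
                elif len(fields) >= 2:
                    positions[fields[0]] = int(fields[1])
                else:
                    raise CatalogError(f"{path}: malformed centromere line {line!r}")
        cmap = cls(positions)
        if catalog is not None:
            cmap.validate_against(catalog)
        return cmap

    def to_bed(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for contig, pos in self.positions.items():
                fh.write(f"{contig}\t{pos - 1}\t{pos}\n")
        return path
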