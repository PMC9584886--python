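"""Shared fixtures: toy catalogs, sample sheets and FASTA writers.

All fixtures are generated programmatically; nothing is read from disk
except what the tests themselves write into tmp_path.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd
import pytest

from skimseq.demux import SampleSheet
from skimseq.refhybrid import CatalogEntry, CentromereMap, GenomeCatalog

MB = 1_000_000


def write_fasta(path: Path, records: dict[str, str]) -> Path:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    return path


@pytest.fixture
def wheat_catalog() -> GenomeCatalog:
    """Small three-chromosome recipient genome, Mb scale."""
    return GenomeCatalog(
        [
            CatalogEntry("1A", 250 * MB, "wheat", "1A"),
            CatalogEntry("3B", 300 * MB, "wheat", "3B"),
            CatalogEntry("5D", 250 * MB, "wheat", "5D"),
        ]
    )


@pytest.fixture
def wheat_centromeres() -> CentromereMap:
    return CentromereMap({"1A": 120 * MB, "3B": 150 * MB, "5D": 100 * MB})


@pytest.fixture
def hybrid_catalog() -> GenomeCatalog:
    """Recipient + donor group-7 chromosomes on one coordinate frame."""
    return GenomeCatalog(
        [
            CatalogEntry("wheat_7A", 700 * MB, "wheat", "7A"),
            CatalogEntry("wheat_7D", 700 * MB, "wheat", "7D"),
            CatalogEntry("barley_7H", 650 * MB, "barley", "7H"),
        ]
    )


@pytest.fixture
def sample_sheet() -> SampleSheet:
    """Two plates x three samples plus one blank well per plate."""
    rows = []
    i7s = ["ACGTACGT", "TTGGCCAA", "GATCGATC", "CCCCTTTT"]
    # note: neither i5 is the reverse complement of the other, so
    # orientation detection on this sheet is unambiguous
    i5s = {"P1": "AAGGAAGG", "P2": "CACACACA"}
    for plate, i5 in i5s.items():
        for j, i7 in enumerate(i7s):
            blank = j == 3
            rows.append(
                {
                    "sample_id": f"{plate}_{'blank' if blank else f's{j + 1}'}",
                    "plate_id": plate,
                    "well": f"A{j + 1}",
                    "i7": i7,
                    "i5": i5,
                    "is_blank": blank,
                }
            )
    return SampleSheet(pd.DataFrame(rows))
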