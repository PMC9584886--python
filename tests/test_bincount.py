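"""Bin counting, normalization and coverage arithmetic."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pysam
import pytest

from skimseq.bincount import (
    BinCountError,
    BinCountMatrix,
    BinGrid,
    CoverageModel,
    NormalizationSpec,
    count_in_bins,
    drop_unknown_contigs,
    effective_depth_from_bin_mean,
    estimate_coverage,
    normalize,
    per_chromosome_density,
)
from skimseq.refhybrid import CatalogEntry, GenomeCatalog
from skimseq.simulate import KaryotypeRegion, SimConfig, SimKaryotype, simulate_bin_counts

MB = 1_000_000


def test_grid_contiguous_with_truncated_last_bin():
    grid = BinGrid(MB, {"c1": int(2.5 * MB)})
    assert grid.bins("c1") == [(0, MB), (MB, 2 * MB), (2 * MB, int(2.5 * MB))]
    assert grid.bin_index("c1", 1_500_000) == 1


def _write_pair_sam(path, catalog, positions):
    """positions: list of (contig, leftmost_pos0). Emits one proper pair each."""
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": e.contig_id, "LN": e.length_bp} for e in catalog],
    }
    tid = {e.contig_id: i for i, e in enumerate(catalog)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, (contig, pos) in enumerate(positions):
            for flag, p, mp in ((0x63, pos, pos + 200), (0x93, pos + 200, pos)):
                r = pysam.AlignedSegment()
                r.query_name = f"p{i}"
                r.flag = flag
                r.reference_id = tid[contig]
                r.reference_start = p
                r.mapping_quality = 60
                r.cigarstring = "100M"
                r.next_reference_id = tid[contig]
                r.next_reference_start = mp
                r.query_sequence = "A" * 100
                r.set_tag("NH", 1)
                r.set_tag("YT", "CP")
                out.write(r)
    return path


def test_count_pairs_at_leftmost_mate(tmp_path, wheat_catalog):
    positions = [
        ("1A", 1_500_000),  # bin [1, 2) Mb
        ("1A", 1_999_999),  # same bin
        ("1A", 0),
        ("3B", 10_000_000),
        ("3B", 10_500_000),
    ]
    sam = _write_pair_sam(tmp_path / "s.sam", wheat_catalog, positions)
    grid = BinGrid.from_catalog(wheat_catalog)
    matrix = count_in_bins(sam, grid, sample_id="s1")
    df = matrix.df.set_index(["chrom", "start"])
    assert df.loc[("1A", 1 * MB), "raw"] == 2
    assert df.loc[("1A", 0), "raw"] == 1
    assert df.loc[("3B", 10 * MB), "raw"] == 2
    # conservation: every pair counted exactly once
    assert matrix.df["raw"].sum() == len(positions)
    assert matrix.totals["s1"] == len(positions)
    # unit=reads counts both mates
    reads = count_in_bins(sam, grid, unit="reads", sample_id="s1")
    assert reads.df["raw"].sum() == 2 * len(positions)


def _toy_matrix():
    df = pd.DataFrame(
        {
            "sample": ["s1"] * 3,
            "chrom": ["c1"] * 3,
            "start": [0, MB, 2 * MB],
            "end": [MB, 2 * MB, 3 * MB],
            "raw": [70, 50, 30],
        }
    )
    return BinCountMatrix(df, {"s1": 1_000_000.0})


def test_normalize_fixed_factor_arithmetic():
    matrix = normalize(_toy_matrix(), NormalizationSpec(factor=10_000_000))
    # raw 70 over 1e6 total at factor 1e7 -> 700 normalized reads per bin
    assert matrix.df["norm"].tolist() == pytest.approx([700.0, 500.0, 300.0])


def test_normalize_with_factor_equal_to_total_is_identity():
    m = _toy_matrix()
    out = normalize(m, NormalizationSpec(factor=m.totals["s1"]))
    assert np.allclose(out.df["norm"], out.df["raw"])


def test_normalize_mean_bin_mode():
    df = pd.DataFrame(
        {
            "sample": ["s1", "s1"],
            "chrom": ["c1", "c1"],
            "start": [0, MB],
            "end": [MB, 2 * MB],
            "raw": [50, 0],
        }
    )
    m = BinCountMatrix(df, {"s1": 50.0})
    out = normalize(m, NormalizationSpec(mode="mean_bin"))
    # sample mean per bin is 25 -> 50/25 = 2.0
    assert out.df["norm"].tolist() == [2.0, 0.0]


def test_normalize_flags_zero_total_sample():
    df = _toy_matrix().df.copy()
    m = BinCountMatrix(df, {"s1": 0.0})
    out = normalize(m)
    assert out.meta["failed_samples"] == ["s1"]
    assert (out.df["norm"] == 0).all()


def test_norm_sum_equals_factor_when_all_reads_binned():
    m = _toy_matrix()
    m.totals["s1"] = float(m.df["raw"].sum())
    out = normalize(m, NormalizationSpec(factor=5_000.0))
    assert out.df["norm"].sum() == pytest.approx(5_000.0)


@pytest.mark.parametrize(
    "reads, genome, n, printed",
    [
        (485_575_828, 15e9, 384, "0.025"),
        (359_405_323, 12e9, 288, "0.031"),
    ],
)
def test_estimate_coverage_reproduces_printed_means(reads, genome, n, printed):
    cov = estimate_coverage(
        CoverageModel(read_count=reads, read_length_bp=150,
                      genome_size_bp=genome, n_samples=n)
    )
    assert f"{cov:.3f}" == printed


def test_estimate_coverage_zero_reads_is_zero():
    assert estimate_coverage(CoverageModel(read_count=0)) == 0.0


@pytest.mark.parametrize(
    "mean, expected",
    [(30.6, 0.00918), (0.0, 0.0), (83.3, 0.02499)],
)
def test_effective_depth_from_bin_mean(mean, expected):
    assert effective_depth_from_bin_mean(mean, 150, 1e6) == pytest.approx(
        expected, abs=1e-5
    )


def test_drop_unknown_contigs():
    df = pd.DataFrame(
        {
            "sample": ["s1"] * 3,
            "chrom": ["1A", "chrUn", "scaffold_unplaced_1"],
            "start": [0, 0, 0],
            "end": [MB] * 3,
            "raw": [5, 5, 5],
        }
    )
    m = BinCountMatrix(df, {"s1": 15.0})
    out = drop_unknown_contigs(m)
    assert out.df["chrom"].tolist() == ["1A"]
    assert out.meta["unknown_bins_removed"] == 2
    # no matches -> identity
    clean = BinCountMatrix(df[df["chrom"] == "1A"].copy(), {"s1": 5.0})
    assert drop_unknown_contigs(clean).df["chrom"].tolist() == ["1A"]
    with pytest.raises(BinCountError):
        drop_unknown_contigs(m, patterns=("",))  # matches everything


def test_per_chromosome_density_uniform_and_zero_copy(wheat_catalog):
    kt = SimKaryotype([KaryotypeRegion("5D", 0)])
    cfg = SimConfig(catalog=wheat_catalog, coverage=0.1, seed=3, n_samples=4)
    m = simulate_bin_counts(kt, cfg)
    from skimseq.bincount import normalize as _norm

    dens = per_chromosome_density(_norm(m))
    pop = dens[dens["sample"] == "__population__"].set_index("chrom")
    assert pop.loc["5D", "mean_raw"] == 0
    # disomic contigs uniform within sampling error (lambda=166.7, n>=1000 bins)
    assert abs(pop.loc["1A", "mean_raw"] / pop.loc["3B", "mean_raw"] - 1) < 0.05
    assert dens.attrs["min_contig"] == "5D"


def test_matrix_tsv_round_trip(tmp_path, wheat_catalog):
    kt = SimKaryotype([])
    cfg = SimConfig(catalog=wheat_catalog, coverage=0.01, seed=9, n_samples=2)
    m = normalize(simulate_bin_counts(kt, cfg))
    path = m.to_tsv(tmp_path / "bins.tsv")
    again = BinCountMatrix.from_tsv(path)
    pd.testing.assert_frame_equal(m.df, again.df)
    assert again.totals == m.totals
    assert again.unit == m.unit
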