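"""Dual-index demultiplexing: assignment, orientation, blank QC."""
from __future__ import annotations

from pathlib import Path

import pandas as pd
import pytest

from skimseq.demux import (
    DemuxReport,
    SampleSheet,
    check_blanks,
    demultiplex,
    detect_i5_orientation,
    reverse_complement,
)
from skimseq.simulate import simulate_index_reads


def _write_fastq(path: Path, records: list[tuple[str, str]]) -> Path:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
    return path


@pytest.fixture
def tiny_run(tmp_path, sample_sheet):
    """Four pairs: two for P1_s1, one for P2_s2, one with an unknown i7."""
    rows = sample_sheet.rows
    bc = {r.sample_id: (r.i7, r.i5) for r in rows.itertuples()}
    reads = [
        ("r1", *bc["P1_s1"]),
        ("r2", *bc["P1_s1"]),
        ("r3", *bc["P2_s2"]),
        ("r4", "NNNNNNNN", bc["P1_s1"][1]),  # unknown i7
    ]
    paths = {}
    paths["r1"] = _write_fastq(tmp_path / "R1.fq", [(n, "ACGTACGTAC") for n, *_ in reads])
    paths["r2"] = _write_fastq(tmp_path / "R2.fq", [(n, "TGCATGCATG") for n, *_ in reads])
    paths["i1"] = _write_fastq(tmp_path / "I1.fq", [(n, i7) for n, i7, _ in reads])
    paths["i2"] = _write_fastq(tmp_path / "I2.fq", [(n, i5) for n, _, i5 in reads])
    return paths


def test_demultiplex_assigns_and_conserves(tmp_path, sample_sheet, tiny_run):
    report = demultiplex(
        tiny_run["r1"], tiny_run["r2"], tiny_run["i1"], tiny_run["i2"],
        sample_sheet, tmp_path / "out", max_mismatch=0,
    )
    assert report.assigned["P1_s1"] == 2
    assert report.assigned["P2_s2"] == 1
    assert report.undetermined == 1
    assert sum(report.assigned.values()) + report.undetermined == report.total == 4
    # the assigned pairs landed in the right files
    out = (tmp_path / "out" / "P1_s1_R1.fastq").read_text()
    assert out.count("@") == 2


def test_demultiplex_deterministic_output(tmp_path, sample_sheet, tiny_run):
    for d in ("a", "b"):
        demultiplex(
            tiny_run["r1"], tiny_run["r2"], tiny_run["i1"], tiny_run["i2"],
            sample_sheet, tmp_path / d,
        )
    for f in sorted((tmp_path / "a").iterdir()):
        assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()


def test_reverse_complemented_i5_auto_detected(tmp_path, sample_sheet, tiny_run):
    # rewrite I2 reverse-complemented; assignments must be unchanged
    rc = [
        (name, reverse_complement(seq))
        for name, seq, _, _ in _read_fastq(tiny_run["i2"])
    ]
    i2rc = _write_fastq(tmp_path / "I2rc.fq", rc)
    rep_rc = demultiplex(
        tiny_run["r1"], tiny_run["r2"], tiny_run["i1"], i2rc,
        sample_sheet, tmp_path / "rc",
    )
    rep = demultiplex(
        tiny_run["r1"], tiny_run["r2"], tiny_run["i1"], tiny_run["i2"],
        sample_sheet, tmp_path / "fw",
    )
    assert rep_rc.i5_orientation == "reverse-complement"
    assert rep_rc.assigned == rep.assigned


def _read_fastq(path):
    import pysam

    with pysam.FastxFile(str(path)) as fh:
        return [(r.name, r.sequence, r.quality, r.comment) for r in fh]


def test_orientation_majority_vote(sample_sheet):
    i5 = sample_sheet.rows["i5"].iloc[0]
    reads = [i5] * 60 + [reverse_complement(i5)] * 40
    assert detect_i5_orientation(reads, sample_sheet) == "as-is"
    reads = [i5] * 40 + [reverse_complement(i5)] * 60
    assert detect_i5_orientation(reads, sample_sheet) == "reverse-complement"
    # all-exact both directions of a palindrome-free set: ties -> as-is
    assert detect_i5_orientation([], sample_sheet) == "as-is"


@pytest.mark.parametrize(
    "blank_reads, expect_pass",
    [(0, True), (3, False), (0, True)],
)
def test_blank_well_threshold(blank_reads, expect_pass):
    assigned = {f"s{i}": 10_000 for i in range(4)}
    assigned["blank"] = blank_reads
    report = DemuxReport(
        assigned=assigned,
        undetermined=0,
        total=sum(assigned.values()),
        i5_orientation="as-is",
        blank_ids=["blank"],
    )
    assert check_blanks(report)["blank"] is expect_pass


def test_blank_boundary_arithmetic():
    # 0.009% of mean passes, 0.03% fails, at the 0.01% threshold
    report = DemuxReport(
        assigned={"s1": 100_000, "s2": 100_000, "b1": 9, "b2": 30},
        undetermined=0,
        total=200_039,
        i5_orientation="as-is",
        blank_ids=["b1", "b2"],
    )
    flags = check_blanks(report)
    assert flags == {"b1": True, "b2": False}


def test_simulator_round_trip_exact(tmp_path, sample_sheet):
    paths, truth = simulate_index_reads(
        sample_sheet, tmp_path / "sim", seed=7, reads_per_sample=25
    )
    report = demultiplex(
        paths["R1"], paths["R2"], paths["I1"], paths["I2"],
        sample_sheet, tmp_path / "dm",
    )
    assert report.assigned == truth
    assert report.undetermined == 0


def test_round_trip_with_reverse_complement_orientation(tmp_path, sample_sheet):
    paths, truth = simulate_index_reads(
        sample_sheet, tmp_path / "sim", seed=7, reads_per_sample=25,
        i5_orientation="reverse-complement",
    )
    report = demultiplex(
        paths["R1"], paths["R2"], paths["I1"], paths["I2"],
        sample_sheet, tmp_path / "dm",
    )
    assert report.i5_orientation == "reverse-complement"
    assert report.assigned == truth


def test_mismatch_tolerance_recovers_more_reads(tmp_path, sample_sheet):
    paths, truth = simulate_index_reads(
        sample_sheet, tmp_path / "sim", seed=11, reads_per_sample=200,
        error_rate=0.02,
    )
    args = (paths["R1"], paths["R2"], paths["I1"], paths["I2"], sample_sheet)
    strict = demultiplex(*args, tmp_path / "mm0", max_mismatch=0)
    lenient = demultiplex(*args, tmp_path / "mm1", max_mismatch=1)
    assert sum(lenient.assigned.values()) > sum(strict.assigned.values())
    assert lenient.undetermined < strict.undetermined


def test_desynchronized_streams_fatal(tmp_path, sample_sheet, tiny_run):
    bad = _write_fastq(
        tmp_path / "bad_i1.fq",
        [(n + "_x", s) for n, s, *_ in _read_fastq(tiny_run["i1"])],
    )
    with pytest.raises(Exception, match="desynchronized"):
        demultiplex(
            tiny_run["r1"], tiny_run["r2"], bad, tiny_run["i2"],
            sample_sheet, tmp_path / "out",
        )


def test_sheet_invariants_enforced(sample_sheet):
    df = sample_sheet.rows.copy()
    df.loc[1, "sample_id"] = df.loc[0, "sample_id"]
    with pytest.raises(Exception, match="duplicate sample_id"):
        SampleSheet(df)
    df = sample_sheet.rows.copy()
    df.loc[1, ["i7", "i5"]] = df.loc[0, ["i7", "i5"]].values
    with pytest.raises(Exception, match="barcode pair"):
        SampleSheet(df)
    df = sample_sheet.rows.copy()
    df.loc[0, "i7"] = "ACGTXCGT"
    with pytest.raises(Exception, match="alphabet"):
        SampleSheet(df)
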