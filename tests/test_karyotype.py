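"""Copy-ratio computation and dosage classification."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from skimseq.bincount import BinCountMatrix, normalize
from skimseq.karyotype import (
    DosageProfile,
    call_karyotypes,
    classify_dosage,
    compute_copy_ratio,
    copies_from_ratio,
    detect_alien_additions,
    detect_failed_and_blank,
)
from skimseq.simulate import (
    KaryotypeRegion,
    SimConfig,
    SimKaryotype,
    simulate_bin_counts,
)

MB = 1_000_000


def _profile_from_arms(arm_ratios: dict[str, tuple[float, float]]) -> DosageProfile:
    """Build a profile with given (short, long) arm ratios for one sample."""
    rows = []
    arm_rows = []
    for chrom, (short, long) in arm_ratios.items():
        rows.append(("s1", chrom, (short + long) / 2))
        arm_rows.append(("s1", chrom, "short", short))
        arm_rows.append(("s1", chrom, "long", long))
    return DosageProfile(
        bin_ratios=pd.DataFrame(columns=["sample", "chrom", "start", "end", "ratio"]),
        contig_means=pd.DataFrame(rows, columns=["sample", "chrom", "mean_ratio"]),
        arm_means=pd.DataFrame(
            arm_rows, columns=["sample", "chrom", "arm", "mean_ratio"]
        ),
    )


from skimseq.refhybrid import CentromereMap


@pytest.mark.parametrize(
    "arms, expected_cls, expected_copies",
    [
        ((1.0, 1.0), "disomic", (2, 2)),
        ((0.5, 0.5), "monosomic", (1, 1)),
        ((0.0, 0.0), "nullisomic", (0, 0)),
        ((1.5, 1.5), "trisomic", (3, 3)),
        ((0.02, 0.51), "telosomic_long_arm", (0, 1)),
        ((0.51, 0.02), "telosomic_short_arm", (1, 0)),
        ((0.49, 1.02), "mono_plus_telo", (1, 2)),
    ],
)
def test_arm_dosage_classes(arms, expected_cls, expected_copies):
    profile = _profile_from_arms({"5D": arms})
    cen = CentromereMap({"5D": 100 * MB})
    calls = classify_dosage(profile, cen)
    row = calls.iloc[0]
    assert row["cls"] == expected_cls
    assert (row["copies_short"], row["copies_long"]) == expected_copies


def test_confidence_band_flags_ambiguous_ratios():
    # 2 * 0.74 = 1.48 sits within 0.15 of the 1.5 rounding boundary
    assert copies_from_ratio(0.74) == (1, True)
    assert copies_from_ratio(1.0) == (2, False)
    assert copies_from_ratio(0.51) == (1, False)


def test_whole_chromosome_call_without_centromere():
    profile = _profile_from_arms({"1A": (0.5, 0.5)})
    calls = classify_dosage(profile, centromeres=None)
    assert calls.iloc[0]["cls"] == "monosomic"


def test_identical_samples_have_unit_ratios(wheat_catalog):
    kt = SimKaryotype([])
    cfg = SimConfig(catalog=wheat_catalog, coverage=0, seed=1, n_samples=4)
    m = simulate_bin_counts(kt, cfg)
    m.df["raw"] = 10  # identical deterministic counts
    m.totals = {s: float(m.df[m.df["sample"] == s]["raw"].sum()) for s in m.samples}
    profile = compute_copy_ratio(normalize(m))
    assert np.allclose(profile.bin_ratios["ratio"], 1.0)


def test_monosomic_chromosome_recovered_from_simulation():
    # 1 of 12 samples monosomic for 5D at skim coverage; like the real
    # genome, the focal chromosome is a small fraction of the catalog
    from skimseq.refhybrid import CatalogEntry, GenomeCatalog

    catalog = GenomeCatalog(
        [
            CatalogEntry("1A", 300 * MB, "wheat", "1A"),
            CatalogEntry("2B", 300 * MB, "wheat", "2B"),
            CatalogEntry("3D", 200 * MB, "wheat", "3D"),
            CatalogEntry("5D", 100 * MB, "wheat", "5D"),
        ]
    )
    cfg = SimConfig(catalog=catalog, coverage=0.01, seed=17, n_samples=11)
    m_eu = simulate_bin_counts(SimKaryotype([]), cfg)
    cfg_mono = SimConfig(catalog=catalog, coverage=0.01, seed=18, n_samples=1)
    m_mono = simulate_bin_counts(
        SimKaryotype([KaryotypeRegion("5D", 1)]), cfg_mono, sample_ids=["mono"]
    )
    from skimseq.bincount import concat_matrices

    m = normalize(concat_matrices([m_eu, m_mono]))
    profile = compute_copy_ratio(m, baseline="population_median")
    means = profile.contig_means.set_index(["sample", "chrom"])["mean_ratio"]
    assert 0.4 <= means[("mono", "5D")] <= 0.6
    for chrom in ("1A", "2B", "3D"):
        assert 0.9 <= means[("mono", chrom)] <= 1.1


def test_copy_call_monotone_in_simulated_copy_number(wheat_catalog):
    called = []
    for copy in range(5):
        cfg = SimConfig(catalog=wheat_catalog, coverage=0.05, seed=40 + copy)
        m = normalize(
            simulate_bin_counts(SimKaryotype([KaryotypeRegion("5D", copy)]), cfg)
        )
        profile = compute_copy_ratio(m, baseline="self_genome_median")
        calls = classify_dosage(profile)
        row = calls[calls["chrom"] == "5D"].iloc[0]
        called.append(row["copies_short"])
    assert called == sorted(called)
    assert called[0] == 0 and called[2] == 2


def test_failed_and_blank_flags():
    totals = {"s1": 10_000, "s2": 9_500, "s3": 200, "b1": 0.4, "b2": 10}
    status = detect_failed_and_blank(totals, blank_ids=["b1", "b2"])
    lookup = status.set_index("sample")["status"]
    assert lookup["s1"] == "ok"
    assert lookup["s3"] == "failed"  # 2% of the non-blank mean
    assert lookup["b1"] == "blank_pass"  # 0.004% of mean < 0.01%
    assert lookup["b2"] == "blank_fail"
    # comparable samples -> no flags
    ok = detect_failed_and_blank({"a": 100.0, "b": 110.0, "c": 95.0})
    assert (ok["status"] == "ok").all()


def test_blanks_never_enter_population_baseline(wheat_catalog, wheat_centromeres):
    cfg = SimConfig(catalog=wheat_catalog, coverage=0.02, seed=50, n_samples=6)
    m = simulate_bin_counts(SimKaryotype([]), cfg)
    blank = m.df["sample"] == "s0006"
    m.df.loc[blank, "raw"] = 0
    m.totals["s0006"] = 0.0
    m = normalize(m)
    calls, profile, status = call_karyotypes(
        m, wheat_centromeres, wheat_catalog, "wheat", blank_ids=["s0006"]
    )
    assert (calls.loc[calls["sample"] == "s0006", "cls"] == "blank").all()
    # remaining samples classify disomic everywhere
    rest = calls[calls["sample"] != "s0006"]
    assert (rest["cls"] == "disomic").all()


def test_alien_addition_states(hybrid_catalog):
    # sample with whole donor 7H, sample with half of it, sample with none
    cfg = SimConfig(catalog=hybrid_catalog, coverage=0.05, seed=60, n_samples=1)
    karyotypes = {
        "whole": SimKaryotype(
            [KaryotypeRegion("barley_7H", 0), KaryotypeRegion("barley_7H", 1, 0, 650 * MB)]
        ),
        "half": SimKaryotype(
            [KaryotypeRegion("barley_7H", 0), KaryotypeRegion("barley_7H", 1, 0, 325 * MB)]
        ),
        "none": SimKaryotype([KaryotypeRegion("barley_7H", 0)]),
    }
    from skimseq.bincount import concat_matrices

    mats = [
        simulate_bin_counts(kt, cfg, sample_ids=[name])
        for name, kt in karyotypes.items()
    ]
    m = normalize(concat_matrices(mats))
    profile = compute_copy_ratio(
        m, baseline="self_genome_median", catalog=hybrid_catalog,
        reference_label="wheat",
    )
    calls, counts = detect_alien_additions(profile, hybrid_catalog, "barley")
    states = calls.set_index("sample")["status"]
    assert states["whole"] == "present"
    assert states["half"] == "partial"
    assert states["none"] == "absent"
    # the partial call delimits the covered half
    row = calls.set_index("sample").loc["half"]
    assert row["seg_start"] == 0 and abs(row["seg_end"] - 325 * MB) <= MB
    assert counts.set_index("sample")["n_additions"].to_dict() == {
        "whole": 1, "half": 1, "none": 0
    }
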