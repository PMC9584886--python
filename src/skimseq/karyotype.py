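"""Chromosome dosage estimation and karyotype classification.

Normalized bin counts are converted to *copy ratios* — observed bin
density over the expected disomic baseline, so ~1 means two copies,
~0.5 one copy, ~0 none.  Two baselines are available:

``population_median``
    per-bin median across samples, then each sample rescaled so its
    genome-wide median ratio is 1.  Robust as long as fewer than half
    the samples share an event on a given chromosome; chromosomes where
    the population median itself is aberrant (e.g. a panel segregating
    from a monosomic parent, where most progeny carry one copy) are
    detected (>20% deviation from the genome-wide level) and fall back
    to the per-sample baseline.
``self_genome_median``
    the sample's own median bin density, assuming most of its genome is
    disomic.  On hybrid catalogs, donor-genome contigs always use this
    baseline: their population median is ~0 whenever fewer than half
    the samples carry donor material.

Whole-chromosome and arm-level dosage classes (euploid/disomic,
monosomic, nullisomic, trisomic, telosomic, monosomic-plus-telosomic)
are called by rounding twice the arm copy ratio to an integer copy
number, with a configurable low-confidence band around the rounding
boundaries.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .bincount import BinCountMatrix
from .demux import DEFAULT_BLANK_THRESHOLD
from .refhybrid import CentromereMap, GenomeCatalog

logger = logging.getLogger("skimseq")

DEFAULT_CONFIDENCE_BAND = 0.15  # around half-integers of 2*ratio
DEFAULT_ABERRANT_DEVIATION = 0.2
DEFAULT_FAILURE_FRACTION = 0.05
DEFAULT_PRESENCE_THRESHOLD = 0.25

CLASS_DISOMIC = "disomic"
CLASS_MONOSOMIC = "monosomic"
CLASS_NULLISOMIC = "nullisomic"
CLASS_TRISOMIC = "trisomic"
CLASS_TELO_SHORT = "telosomic_short_arm"
CLASS_TELO_LONG = "telosomic_long_arm"
CLASS_MONO_PLUS_TELO = "mono_plus_telo"
CLASS_PARTIAL = "partial"
CLASS_FAILED = "failed"
CLASS_BLANK = "blank"


class KaryotypeError(ValueError):
    pass


@dataclass
class DosageProfile:
    """Copy-ratio tracks plus per-contig and per-arm summaries."""

    bin_ratios: pd.DataFrame  # sample, chrom, start, end, ratio
    contig_means: pd.DataFrame  # sample, chrom, mean_ratio
    arm_means: pd.DataFrame | None  # sample, chrom, arm, mean_ratio
    aberrant_contigs: list[str] = field(default_factory=list)
    self_medians: dict[str, float] = field(default_factory=dict)

    def track(self, sample: str, contig: str) -> pd.DataFrame:
        br = self.bin_ratios
        out = br[(br["sample"] == sample) & (br["chrom"] == contig)]
        return out.sort_values("start").reset_index(drop=True)


def compute_copy_ratio(
    matrix: BinCountMatrix,
    baseline: str = "population_median",
    catalog: GenomeCatalog | None = None,
    centromeres: CentromereMap | None = None,
    reference_label: str | None = None,
    exclude_samples: Iterable[str] = (),
    aberrant_deviation: float = DEFAULT_ABERRANT_DEVIATION,
) -> DosageProfile:
    """Turn normalized bin counts into copy ratios.

    ``exclude_samples`` (blanks, failed libraries) never enter the
    population baseline but still receive ratio tracks.  With a hybrid
    ``catalog`` and ``reference_label``, the per-sample baseline is
    estimated from recipient-genome bins only and donor contigs are
    always expressed relative to it.
    """
    if baseline not in ("population_median", "self_genome_median"):
        raise KaryotypeError(f"unknown baseline {baseline!r}")
    wide = matrix.pivot("norm")
    if wide.isna().all().all():
        raise KaryotypeError("matrix has no normalized counts; run normalize() first")
    exclude = set(exclude_samples)
    base_samples = [s for s in wide.columns if s not in exclude]
    if baseline == "population_median" and len(base_samples) < 3:
        logger.warning(
            "population baseline needs >=3 samples, falling back to self baseline"
        )
        baseline = "self_genome_median"

    chrom_idx = wide.index.get_level_values("chrom")
    if catalog is not None and reference_label is not None:
        ref_contigs = set(catalog.contigs(reference_label))
        donor_contigs = [c for c in catalog.contigs() if c not in ref_contigs]
    else:
        ref_contigs = set(chrom_idx.unique())
        donor_contigs = []
    ref_mask = chrom_idx.isin(ref_contigs)

    self_med = wide.loc[ref_mask].median(axis=0)
    self_med = self_med.where(self_med > 0)

    aberrant: list[str] = list(donor_contigs)
    if baseline == "self_genome_median":
        ratio = wide.div(self_med, axis=1)
    else:
        base = wide.loc[:, base_samples].median(axis=1)
        global_level = base[ref_mask & (base > 0)].median()
        if not np.isfinite(global_level) or global_level <= 0:
            raise KaryotypeError("population baseline level is zero; data unusable")
        for contig in sorted(set(chrom_idx[ref_mask])):
            level = base[chrom_idx == contig].median()
            if abs(level / global_level - 1) > aberrant_deviation:
                aberrant.append(contig)
        ab_mask = chrom_idx.isin(aberrant)
        ratio = wide.div(base.where(base > 0), axis=0)
        # rescale each sample so its median ratio over trusted bins is 1
        scale = ratio.loc[ref_mask & ~ab_mask].median(axis=0)
        ratio = ratio.div(scale.where(scale > 0), axis=1)
        if ab_mask.any():
            ratio.loc[ab_mask] = wide.loc[ab_mask].div(self_med, axis=1)

    long = (
        ratio.stack(future_stack=True)
        .rename("ratio")
        .reset_index()
        .rename(columns={"level_3": "sample"})
    )
    long = long[["sample", "chrom", "start", "end", "ratio"]]
    long["ratio"] = long["ratio"].replace([np.inf, -np.inf], np.nan)

    contig_means = (
        long.groupby(["sample", "chrom"], sort=False)["ratio"]
        .mean()
        .reset_index()
        .rename(columns={"ratio": "mean_ratio"})
    )
    arm_means = None
    if centromeres is not None:
        with_cen = long[long["chrom"].isin(centromeres.positions)].copy()
        if not with_cen.empty:
            cen = with_cen["chrom"].map(centromeres.positions)
            mid = (with_cen["start"] + with_cen["end"]) / 2
            with_cen["arm"] = np.where(mid < cen, "short", "long")
            arm_means = (
                with_cen.groupby(["sample", "chrom", "arm"], sort=False)["ratio"]
                .mean()
                .reset_index()
                .rename(columns={"ratio": "mean_ratio"})
            )
    return DosageProfile(
        bin_ratios=long,
        contig_means=contig_means,
        arm_means=arm_means,
        aberrant_contigs=sorted(set(aberrant)),
        self_medians=self_med.to_dict(),
    )


def copies_from_ratio(ratio: float, band: float = DEFAULT_CONFIDENCE_BAND) -> tuple[int, bool]:
    """(integer copies, low_confidence) from one copy ratio.

    Copies are the nearest integer of 2*ratio clamped to [0, 4]; values
    within +/-band of a rounding boundary (half-integer) are low
    confidence.
    """
    if not np.isfinite(ratio):
        return 0, True
    doubled = 2.0 * ratio
    copies = int(np.clip(np.rint(doubled), 0, 4))
    low = abs((doubled % 1.0) - 0.5) <= band
    return copies, low


def _class_from_arm_copies(copies_short: int, copies_long: int) -> str:
    if copies_short == copies_long:
        return {
            0: CLASS_NULLISOMIC,
            1: CLASS_MONOSOMIC,
            2: CLASS_DISOMIC,
        }.get(copies_short, CLASS_TRISOMIC)
    if copies_short == 0 and copies_long >= 1:
        return CLASS_TELO_LONG
    if copies_long == 0 and copies_short >= 1:
        return CLASS_TELO_SHORT
    if {copies_short, copies_long} == {1, 2}:
        return CLASS_MONO_PLUS_TELO
    return CLASS_PARTIAL


def classify_dosage(
    profile: DosageProfile,
    centromeres: CentromereMap | None = None,
    band: float = DEFAULT_CONFIDENCE_BAND,
) -> pd.DataFrame:
    """Per sample x contig karyotype calls.

    Columns: sample, chrom, cls, copies_short, copies_long, mean_ratio,
    confidence.  Contigs without a centromere get a whole-chromosome
    call (both arms set to the whole-contig copy number).
    """
    arm = profile.arm_means
    rows = []
    for (sample, chrom), grp in profile.contig_means.groupby(
        ["sample", "chrom"], sort=False
    ):
        mean_ratio = float(grp["mean_ratio"].iloc[0])
        cen_known = (
            centromeres is not None
            and chrom in centromeres
            and arm is not None
        )
        if cen_known:
            sub = arm[(arm["sample"] == sample) & (arm["chrom"] == chrom)]
            ratios = dict(zip(sub["arm"], sub["mean_ratio"]))
            cs, low_s = copies_from_ratio(ratios.get("short", np.nan), band)
            cl, low_l = copies_from_ratio(ratios.get("long", np.nan), band)
            cls = _class_from_arm_copies(cs, cl)
            low = low_s or low_l
        else:
            c, low = copies_from_ratio(mean_ratio, band)
            cs = cl = c
            cls = _class_from_arm_copies(c, c)
        rows.append(
            (sample, chrom, cls, cs, cl, mean_ratio, "low" if low else "ok")
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample",
            "chrom",
            "cls",
            "copies_short",
            "copies_long",
            "mean_ratio",
            "confidence",
        ],
    )


def detect_failed_and_blank(
    totals: Mapping[str, float],
    blank_ids: Iterable[str] = (),
    failure_fraction: float = DEFAULT_FAILURE_FRACTION,
    blank_threshold: float = DEFAULT_BLANK_THRESHOLD,
) -> pd.DataFrame:
    """Flag blank wells and failed libraries from per-sample read totals.

    Blanks pass when below ``blank_threshold`` of the non-blank mean;
    other samples below ``failure_fraction`` of that mean are failed and
    must be excluded from population baselines.
    """
    blanks = set(blank_ids)
    nonblank = [t for s, t in totals.items() if s not in blanks]
    if not nonblank:
        raise KaryotypeError("no non-blank samples")
    mean = float(np.mean(nonblank))
    rows = []
    for sample, total in totals.items():
        if sample in blanks:
            ok = mean > 0 and total / mean < blank_threshold
            status = "blank_pass" if ok else "blank_fail"
        elif mean > 0 and total / mean < failure_fraction:
            status = "failed"
        else:
            status = "ok"
        rows.append((sample, total, status))
    return pd.DataFrame(rows, columns=["sample", "total", "status"])


def call_karyotypes(
    matrix: BinCountMatrix,
    centromeres: CentromereMap | None = None,
    catalog: GenomeCatalog | None = None,
    reference_label: str | None = None,
    blank_ids: Iterable[str] = (),
    baseline: str = "population_median",
    band: float = DEFAULT_CONFIDENCE_BAND,
    failure_fraction: float = DEFAULT_FAILURE_FRACTION,
) -> tuple[pd.DataFrame, DosageProfile, pd.DataFrame]:
    """End-to-end dosage calling: QC flags -> copy ratios -> classes.

    Returns (calls, profile, status).  Blank and failed samples are kept
    in the call table with classes "blank"/"failed" on every contig.
    """
    status = detect_failed_and_blank(
        matrix.totals, blank_ids, failure_fraction=failure_fraction
    )
    excluded = status.loc[status["status"] != "ok", "sample"].tolist()
    profile = compute_copy_ratio(
        matrix,
        baseline=baseline,
        catalog=catalog,
        centromeres=centromeres,
        reference_label=reference_label,
        exclude_samples=excluded,
    )
    calls = classify_dosage(profile, centromeres, band)
    flag_cls = {
        s: CLASS_BLANK if st.startswith("blank") else CLASS_FAILED
        for s, st in zip(status["sample"], status["status"])
        if st != "ok"
    }
    mask = calls["sample"].isin(flag_cls)
    calls.loc[mask, "cls"] = calls.loc[mask, "sample"].map(flag_cls)
    calls.loc[mask, ["copies_short", "copies_long"]] = 0
    calls.loc[mask, "confidence"] = "na"
    return calls, profile, status


def detect_alien_additions(
    profile: DosageProfile,
    catalog: GenomeCatalog,
    donor_label: str,
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
    present_fraction: float = 0.8,
    absent_fraction: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call donor chromosomes present / partial / absent per sample.

    A donor contig is *present* when >= ``present_fraction`` of its bins
    exceed ``presence_threshold`` (ratio vs expected single copy),
    *partial* in between (with the contiguous covered segment delimited
    by segmentation), *absent* otherwise.  Returns (per-contig calls,
    per-sample addition-count summary).
    """
    if len(catalog.source_labels) < 2:
        raise KaryotypeError("alien additions need a hybrid catalog with >=2 genomes")
    from .introgression import segment_bins  # local import avoids a cycle

    donor_contigs = catalog.contigs(donor_label)
    rows = []
    for sample in profile.bin_ratios["sample"].unique():
        for contig in donor_contigs:
            track = profile.track(sample, contig)
            ratios = track["ratio"].to_numpy()
            valid = np.isfinite(ratios)
            if not valid.any():
                continue
            frac = float((ratios[valid] > presence_threshold).mean())
            if frac >= present_fraction:
                status, seg = "present", (track["start"].min(), track["end"].max())
            elif frac > absent_fraction:
                status = "partial"
                _, segments = segment_bins(
                    ratios,
                    bin_starts=track["start"].to_numpy(),
                    bin_ends=track["end"].to_numpy(),
                    sample_id=sample,
                    contig_id=contig,
                )
                covered = [s for s in segments if s.mean_ratio > presence_threshold]
                seg = (
                    (min(s.start_bp for s in covered), max(s.end_bp for s in covered))
                    if covered
                    else (np.nan, np.nan)
                )
            else:
                status, seg = "absent", (np.nan, np.nan)
            rows.append((sample, contig, status, frac, seg[0], seg[1]))
    calls = pd.DataFrame(
        rows, columns=["sample", "chrom", "status", "frac_bins", "seg_start", "seg_end"]
    )
    counts = (
        calls.assign(n=(calls["status"] != "absent").astype(int))
        .groupby("sample", sort=False)["n"]
        .sum()
        .reset_index(name="n_additions")
    )
    counts.attrs["min"] = int(counts["n_additions"].min()) if len(counts) else 0
    counts.attrs["median"] = float(counts["n_additions"].median()) if len(counts) else 0.0
    counts.attrs["max"] = int(counts["n_additions"].max()) if len(counts) else 0
    return calls, counts


def plot_karyogram(
    matrix: BinCountMatrix,
    sample: str,
    out_path: str | Path,
    catalog: GenomeCatalog | None = None,
    centromeres: CentromereMap | None = None,
    value: str = "norm",
) -> Path:
    """Write a karyogram: per-bin values along concatenated chromosomes,
    centromeres marked as dashed vertical lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = matrix.df[matrix.df["sample"] == sample]
    if df.empty:
        raise KaryotypeError(f"sample {sample!r} not in matrix")
    contigs = (
        catalog.contigs() if catalog is not None else list(df["chrom"].unique())
    )
    fig, ax = plt.subplots(figsize=(max(8, len(contigs) * 1.2), 3))
    offset = 0
    ticks, labels = [], []
    for contig in contigs:
        sub = df[df["chrom"] == contig].sort_values("start")
        if sub.empty:
            continue
        x = (sub["start"] + sub["end"]) / 2 + offset
        ax.scatter(x, sub[value], s=3, rasterized=True)
        if centromeres is not None and contig in centromeres:
            ax.axvline(offset + centromeres[contig], ls="--", lw=0.8, color="0.4")
        end = int(sub["end"].max())
        ticks.append(offset + end / 2)
        labels.append(contig)
        offset += end
        ax.axvline(offset, lw=0.5, color="0.8")
    ax.set_xticks(ticks, labels, rotation=90, fontsize=7)
    ax.set_ylabel(value)
    ax.set_title(sample)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return Path(out_path)
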