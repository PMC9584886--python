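"""Parental SNP discovery and sparse progeny genotyping.

For a biparental doubled-haploid (DH) population the marker set is the
homozygous differences between the two parents, discovered from
high-coverage pileups under depth filters: per-parent filtered depth in
[6, 100], each parent's own allele supported by >= 3 reads, major
allele fraction >= 0.9 as a homozygosity proxy, and differing major
alleles.  This is a counting/purity caller — deliberately transparent
rather than likelihood-based.

Progeny sequenced at 0.01x-1x are genotyped at those sites from raw
allele counts: one read is enough evidence at skim coverage.  DH lines
are effectively homozygous, so heterozygous calls (both alleles seen)
are retained only as a QC signal.  Parental haplotype blocks are then
assembled from the sparse calls with a majority-vote sliding window.

Pileup tables are TSV (chrom, pos, ref, A, C, G, T) or VCF with AD.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("skimseq")

BASES = ("A", "C", "G", "T")
CALL_A = "A"
CALL_B = "B"
CALL_HET = "het"
CALL_MISSING = "missing"

DEFAULT_MIN_DP = 6
DEFAULT_MAX_DP = 100
DEFAULT_MIN_ALLELE_DEPTH = 3
DEFAULT_MIN_PURITY = 0.9
DEFAULT_WINDOW_BP = 5_000_000
DEFAULT_MIN_MARKERS = 3
DEFAULT_MAJORITY = 0.8


class GenotypingError(ValueError):
    pass


def read_pileup_tsv(path: str | Path) -> pd.DataFrame:
    """Read a pileup table: chrom, pos (1-based), ref, A, C, G, T depths."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"chrom", "pos", "ref", *BASES} - set(df.columns)
    if missing:
        raise GenotypingError(f"{path}: pileup missing columns {sorted(missing)}")
    df["DP"] = df[list(BASES)].sum(axis=1)
    return df


def read_pileup_vcf(path: str | Path) -> pd.DataFrame:
    """Read per-site allele depths from a VCF annotated with AD."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        sample = list(vcf.header.samples)[0] if list(vcf.header.samples) else None
        for rec in vcf:
            alleles = [rec.ref, *(rec.alts or ())]
            if sample is not None:
                ad = rec.samples[sample].get("AD")
            else:
                ad = rec.info.get("AD")
            if ad is None:
                continue
            depths = dict.fromkeys(BASES, 0)
            for allele, d in zip(alleles, ad):
                if allele in depths and d is not None:
                    depths[allele] += int(d)
            rows.append((rec.chrom, rec.pos, rec.ref, *(depths[b] for b in BASES)))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", *BASES])
    df["DP"] = df[list(BASES)].sum(axis=1)
    return df


def read_pileup(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix in (".vcf", ".bcf") or str(path).endswith(".vcf.gz"):
        return read_pileup_vcf(path)
    return read_pileup_tsv(path)


def _major_allele(df: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    depths = df[list(BASES)].to_numpy(dtype=float)
    idx = depths.argmax(axis=1)
    major = pd.Series(np.array(BASES)[idx], index=df.index)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = depths.max(axis=1) / depths.sum(axis=1)
    return major, pd.Series(frac, index=df.index)


def discover_parental_snps(
    pileup_a: pd.DataFrame,
    pileup_b: pd.DataFrame,
    min_dp: int = DEFAULT_MIN_DP,
    max_dp: int = DEFAULT_MAX_DP,
    min_allele_depth: int = DEFAULT_MIN_ALLELE_DEPTH,
    min_purity: float = DEFAULT_MIN_PURITY,
) -> pd.DataFrame:
    """Homozygous SNP differences between two parents.

    A site is kept iff each parent's filtered depth is within
    [min_dp, max_dp], each parent is near-homozygous (major allele
    fraction >= min_purity), the major alleles differ, and each
    parent's own allele has depth >= min_allele_depth.

    Returns columns: chrom, pos, allele_a, allele_b, dp_a, dp_b,
    ad_a, ad_b.  Site counts excluded per criterion go to ``attrs``.
    """
    merged = pileup_a.merge(
        pileup_b, on=["chrom", "pos"], suffixes=("_a", "_b"), how="inner"
    )
    n_joint = len(merged)
    a_cols = [f"{b}_a" for b in BASES]
    b_cols = [f"{b}_b" for b in BASES]
    da = merged[a_cols].to_numpy(dtype=float)
    db = merged[b_cols].to_numpy(dtype=float)
    dp_a, dp_b = da.sum(axis=1), db.sum(axis=1)
    ok_dp = (
        (dp_a >= min_dp) & (dp_a <= max_dp) & (dp_b >= min_dp) & (dp_b <= max_dp)
    )
    ia, ib = da.argmax(axis=1), db.argmax(axis=1)
    major_a = np.array(BASES)[ia]
    major_b = np.array(BASES)[ib]
    with np.errstate(invalid="ignore", divide="ignore"):
        pur_a = np.where(dp_a > 0, da.max(axis=1) / dp_a, 0.0)
        pur_b = np.where(dp_b > 0, db.max(axis=1) / dp_b, 0.0)
    ok_pur = (pur_a >= min_purity) & (pur_b >= min_purity)
    ok_diff = major_a != major_b
    ad_a = da.max(axis=1)
    ad_b = db.max(axis=1)
    ok_ad = (ad_a >= min_allele_depth) & (ad_b >= min_allele_depth)
    keep = ok_dp & ok_pur & ok_diff & ok_ad
    out = pd.DataFrame(
        {
            "chrom": merged["chrom"][keep].to_numpy(),
            "pos": merged["pos"][keep].to_numpy(),
            "allele_a": major_a[keep],
            "allele_b": major_b[keep],
            "dp_a": dp_a[keep].astype(int),
            "dp_b": dp_b[keep].astype(int),
            "ad_a": ad_a[keep].astype(int),
            "ad_b": ad_b[keep].astype(int),
        }
    )
    out.attrs["excluded"] = {
        "joint_sites": int(n_joint),
        "depth": int((~ok_dp).sum()),
        "purity": int((ok_dp & ~ok_pur).sum()),
        "same_major": int((ok_dp & ok_pur & ~ok_diff).sum()),
        "allele_depth": int((ok_dp & ok_pur & ok_diff & ~ok_ad).sum()),
    }
    return out.sort_values(["chrom", "pos"]).reset_index(drop=True)


def genotype_at_sites(
    sample_pileup: pd.DataFrame,
    variants: pd.DataFrame,
    sample_id: str = "sample",
) -> pd.DataFrame:
    """Genotype one low-coverage sample at the parental SNP sites.

    Per site the reads supporting each parental allele are counted:
    call A when only parent-A reads are seen, B when only parent-B,
    het when both, missing when neither.  Reads supporting a third
    allele are ignored (tallied in attrs).
    """
    if variants.empty:
        raise GenotypingError("variant list is empty")
    merged = variants.merge(
        sample_pileup[["chrom", "pos", *BASES]], on=["chrom", "pos"], how="left"
    )
    depths = merged[list(BASES)].fillna(0).to_numpy(dtype=float)
    base_idx = {b: i for i, b in enumerate(BASES)}
    ia = merged["allele_a"].map(base_idx).to_numpy()
    ib = merged["allele_b"].map(base_idx).to_numpy()
    n = np.arange(len(merged))
    n_a = depths[n, ia].astype(int)
    n_b = depths[n, ib].astype(int)
    third = depths.sum(axis=1).astype(int) - n_a - n_b
    call = np.where(
        (n_a > 0) & (n_b > 0),
        CALL_HET,
        np.where(n_a > 0, CALL_A, np.where(n_b > 0, CALL_B, CALL_MISSING)),
    )
    out = pd.DataFrame(
        {
            "sample": sample_id,
            "chrom": merged["chrom"],
            "pos": merged["pos"],
            "call": call,
            "n_reads_a": n_a,
            "n_reads_b": n_b,
        }
    )
    out.attrs["third_allele_reads"] = int(third.sum())
    return out


def missingness_profile(
    calls: pd.DataFrame, n_sites_per_sample: int | None = None
) -> pd.DataFrame:
    """Per-sample missing fraction and genotyped-marker count.

    ``calls`` holds one row per variant site per sample (as emitted by
    :func:`genotype_at_sites`); for sparse tables carrying only the
    observed markers, pass the total marker count per sample as
    ``n_sites_per_sample``.  attrs carry the number of unique sites
    genotyped in at least one sample.
    """
    if calls.empty:
        raise GenotypingError("no calls")
    grp = calls.groupby("sample", sort=False)["call"]
    n_sites = grp.size() if n_sites_per_sample is None else None
    n_genotyped = grp.apply(lambda c: int((c != CALL_MISSING).sum()))
    out = pd.DataFrame(
        {
            "sample": n_genotyped.index,
            "n_sites": (
                n_sites.to_numpy()
                if n_sites is not None
                else np.full(len(n_genotyped), n_sites_per_sample)
            ),
            "n_genotyped": n_genotyped.to_numpy(),
        }
    )
    out["fraction_missing"] = 1 - out["n_genotyped"] / out["n_sites"]
    genotyped = calls[calls["call"] != CALL_MISSING]
    out.attrs["population_unique_sites"] = int(
        genotyped[["chrom", "pos"]].drop_duplicates().shape[0]
    )
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class HaplotypeBlock:
    sample_id: str
    contig_id: str
    start_bp: int
    end_bp: int
    parent: str  # A | B | unresolved
    n_markers: int
    fraction_concordant: float


def call_haplotype_blocks(
    calls: pd.DataFrame,
    window_bp: int = DEFAULT_WINDOW_BP,
    min_markers: int = DEFAULT_MIN_MARKERS,
    majority: float = DEFAULT_MAJORITY,
    sample_id: str | None = None,
) -> list[HaplotypeBlock]:
    """Assemble parental haplotype blocks from one sample's sparse calls.

    Non-overlapping windows are labelled A/B when they hold at least
    ``min_markers`` informative (A or B) calls and the majority parent
    reaches ``majority``; otherwise unresolved.  Adjacent same-label
    windows merge; boundaries between discordant resolved blocks sit
    midway between the flanking informative markers.
    """
    if sample_id is None:
        sample_id = str(calls["sample"].iloc[0]) if "sample" in calls else "sample"
    blocks: list[HaplotypeBlock] = []
    informative = calls[calls["call"].isin((CALL_A, CALL_B))]
    for contig, sub in informative.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        if sub.empty:
            continue
        pos = sub["pos"].to_numpy()
        is_a = (sub["call"] == CALL_A).to_numpy()
        runs = _window_runs(pos, is_a, window_bp, min_markers, majority)
        runs = _refine_runs(runs, is_a, majority)
        for i, (lab, i0, i1) in enumerate(runs):
            n = i1 - i0
            na = int(is_a[i0:i1].sum())
            if lab == CALL_A:
                frac = na / n
            elif lab == CALL_B:
                frac = (n - na) / n
            else:
                frac = max(na, n - na) / n
            start = int(pos[i0]) if i == 0 else int((pos[i0 - 1] + pos[i0]) // 2)
            end = (
                int(pos[i1 - 1])
                if i == len(runs) - 1
                else int((pos[i1 - 1] + pos[i1]) // 2)
            )
            blocks.append(
                HaplotypeBlock(
                    sample_id=sample_id,
                    contig_id=str(contig),
                    start_bp=start,
                    end_bp=end,
                    parent=lab,
                    n_markers=n,
                    fraction_concordant=float(frac),
                )
            )
    return blocks


def _window_runs(
    pos: np.ndarray, is_a: np.ndarray, window_bp: int, min_markers: int, majority: float
) -> list[list]:
    """Label non-overlapping windows and merge runs of equal label.

    Returns runs as [label, i0, i1) over marker indices.
    """
    win = pos // window_bp
    runs: list[list] = []
    i = 0
    n_markers = len(pos)
    while i < n_markers:
        j = i
        while j < n_markers and win[j] == win[i]:
            j += 1
        n = j - i
        na = int(is_a[i:j].sum())
        frac = max(na, n - na) / n
        if n >= min_markers and frac >= majority:
            lab = CALL_A if na >= n - na else CALL_B
        else:
            lab = "unresolved"
        if runs and runs[-1][0] == lab:
            runs[-1][2] = j
        else:
            runs.append([lab, i, j])
        i = j
    return runs


def _refine_runs(runs: list[list], is_a: np.ndarray, majority: float) -> list[list]:
    """Resolve unresolved runs against their flanking resolved runs.

    A run flanked by the same parent on both sides (or at a chromosome
    end) is absorbed when its markers agree at the majority level; a
    run between discordant parents is split at the marker index that
    minimizes discordance with the flanks, which places the crossover
    boundary between the last left-parent and first right-parent
    markers.
    """

    def frac_parent(i0: int, i1: int, parent: str) -> float:
        n = i1 - i0
        na = int(is_a[i0:i1].sum())
        return (na if parent == CALL_A else n - na) / n if n else 1.0

    out: list[list] = []
    for idx, run in enumerate(runs):
        lab, i0, i1 = run
        left = out[-1][0] if out and out[-1][0] != "unresolved" else None
        nxt = runs[idx + 1] if idx + 1 < len(runs) else None
        right = nxt[0] if nxt and nxt[0] != "unresolved" else None
        if lab == "unresolved":
            if left and right and left == right:
                if frac_parent(i0, i1, left) >= majority:
                    lab = left
            elif left and right:  # discordant flanks: split at the transition
                mism = _transition_costs(is_a[i0:i1], left)
                s = i0 + int(np.argmin(mism))
                if s > i0:
                    out.append([left, i0, s])
                if s < i1:
                    out.append([right, s, i1])
                if out and len(out) >= 2 and out[-2][0] == out[-1][0]:
                    out[-2][2] = out[-1][2]
                    out.pop()
                continue
            elif left and frac_parent(i0, i1, left) >= majority:
                lab = left
            elif right and frac_parent(i0, i1, right) >= majority:
                lab = right
        if out and out[-1][0] == lab:
            out[-1][2] = i1
        else:
            out.append([lab, i0, i1])
    return out


def _transition_costs(is_a_run: np.ndarray, left_parent: str) -> np.ndarray:
    """cost[s] = markers before s matching the right parent plus markers
    from s on matching the left parent, for a left->right parent switch."""
    left_is_a = left_parent == CALL_A
    matches_left = is_a_run == left_is_a
    n = len(is_a_run)
    costs = np.empty(n + 1, dtype=int)
    # prefix of right-parent markers + suffix of left-parent markers
    right_before = np.concatenate([[0], np.cumsum(~matches_left)])
    left_after = np.concatenate([np.cumsum(matches_left[::-1])[::-1], [0]])
    costs[:] = right_before + left_after
    return costs


def blocks_to_frame(blocks: list[HaplotypeBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (b.sample_id, b.contig_id, b.start_bp, b.end_bp, b.parent,
             b.n_markers, b.fraction_concordant)
            for b in blocks
        ],
        columns=["sample", "chrom", "start", "end", "parent", "n_markers",
                 "fraction_concordant"],
    )


def write_genotype_matrix(
    calls: pd.DataFrame, path: str | Path
) -> Path:
    """Sites x samples matrix coded A/B/H/N."""
    code = {CALL_A: "A", CALL_B: "B", CALL_HET: "H", CALL_MISSING: "N"}
    wide = calls.assign(code=calls["call"].map(code)).pivot_table(
        index=["chrom", "pos"], columns="sample", values="code", aggfunc="first",
        sort=False,
    )
    wide.to_csv(path, sep="\t")
    return Path(path)


def plot_genotypes(
    calls: pd.DataFrame,
    out_path: str | Path,
    contigs: list[str] | None = None,
) -> Path:
    """Per-chromosome scatter of parental calls along the genome."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    informative = calls[calls["call"].isin((CALL_A, CALL_B))]
    if contigs is None:
        contigs = list(informative["chrom"].unique())
    fig, axes = plt.subplots(
        len(contigs), 1, figsize=(8, 1.2 * max(len(contigs), 1)), squeeze=False
    )
    colors = {CALL_A: "tab:blue", CALL_B: "tab:orange"}
    for ax, contig in zip(axes[:, 0], contigs):
        sub = informative[informative["chrom"] == contig]
        for call, color in colors.items():
            pts = sub[sub["call"] == call]
            ax.scatter(pts["pos"] / 1e6, [call] * len(pts), s=2, color=color)
        ax.set_ylabel(contig, rotation=0, ha="right", fontsize=8)
    axes[-1, 0].set_xlabel("position (Mb)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return Path(out_path)
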