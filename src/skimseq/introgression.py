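"""Copy-ratio segmentation, translocation delimitation and segregation tests.

Alien translocations show up on a hybrid reference as a recipient
chromosome segment at reduced dosage paired with a donor segment at
matching dosage: a homozygous translocation replaces both recipient
copies (recipient segment ~0 copies, donor segment ~2), a heterozygous
one replaces one (both segments at ~half depth).

Breakpoints are delimited by recursive binary segmentation of the
per-bin copy-ratio track: each segment is split at the bin boundary
minimizing the within-segment sum of squares (equivalently maximizing
the least-squares gain of a mean shift), and the split is accepted when
the two-sided mean-difference z-score clears a threshold and both sides
hold at least ``min_seg_bins`` bins.  Segment dosage states follow the
same copy bands used for whole-chromosome calling.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .karyotype import copies_from_ratio
from .refhybrid import GenomeCatalog

logger = logging.getLogger("skimseq")

DEFAULT_MIN_SEG_BINS = 3
DEFAULT_Z_THRESHOLD = 4.0
DEFAULT_MIN_MB = 3.0

STATE_ABSENT = "absent"
STATE_HEMIZYGOUS = "hemizygous"
STATE_NORMAL = "normal"
STATE_GAIN = "gain"

_STATE_BY_COPIES = {0: STATE_ABSENT, 1: STATE_HEMIZYGOUS, 2: STATE_NORMAL}


def state_from_ratio(mean_ratio: float) -> tuple[str, int]:
    """(dosage state, integer copies) for a segment mean copy ratio."""
    copies, _ = copies_from_ratio(mean_ratio)
    return _STATE_BY_COPIES.get(copies, STATE_GAIN), copies


@dataclass(frozen=True)
class SegmentCall:
    sample_id: str
    contig_id: str
    start_bp: int
    end_bp: int
    n_bins: int
    mean_ratio: float
    state: str
    copies: int

    @property
    def length_mb(self) -> float:
        return (self.end_bp - self.start_bp) / 1e6


@dataclass(frozen=True)
class TranslocationCall:
    designation: str
    sample_id: str
    recipient_contig: str | None
    recipient_start_bp: int | None
    recipient_end_bp: int | None
    donor_contig: str | None
    donor_start_bp: int | None
    donor_end_bp: int | None
    zygosity: str  # homozygous | heterozygous | absent
    recipient_loss_mb: float
    donor_gain_mb: float
    kind: str = "translocation"  # translocation | deletion | addition


def _noise_sd(x: np.ndarray) -> float:
    """Per-bin noise SD from successive differences.

    Two estimators are combined by taking the larger: the median-based
    one (median |diff| = sqrt(2)*0.6745*sd for Gaussian noise) is robust
    to the few large differences contributed by true mean shifts but has
    high small-sample variance; the mean-based one (mean |diff| =
    (2/sqrt(pi))*sd) is steadier and only mildly inflated by an
    occasional true shift.  Taking the max keeps the split gate
    conservative on short segments without losing robustness on
    zero-inflated tracks.
    """
    d = np.abs(np.diff(x))
    if len(d) == 0:
        return 0.0
    return float(max(np.median(d) / 0.9539, np.mean(d) / 1.1284))


def _best_split(x: np.ndarray, min_seg_bins: int, sigma: float) -> tuple[int | None, float]:
    """Best single changepoint of a mean-shift model.

    Returns (k, z): split index (right segment starts at k) chosen by
    maximum least-squares gain among candidates leaving >= min_seg_bins
    on each side, and the z-score of the mean difference at that split
    under the track-level noise SD.  (None, 0) when no candidate exists.
    """
    n = len(x)
    if n < 2 * min_seg_bins:
        return None, 0.0
    cs = np.cumsum(x)
    ks = np.arange(min_seg_bins, n - min_seg_bins + 1)
    nl = ks.astype(float)
    nr = n - nl
    ml = cs[ks - 1] / nl
    mr = (cs[-1] - cs[ks - 1]) / nr
    gain = nl * nr / n * (ml - mr) ** 2
    i = int(np.argmax(gain))  # leftmost maximum
    k = int(ks[i])
    diff = abs(ml[i] - mr[i])
    if sigma == 0.0:
        z = np.inf if diff > 0 else 0.0
    else:
        z = diff / (sigma * np.sqrt(1 / nl[i] + 1 / nr[i]))
    return k, float(z)


def _recurse(x: np.ndarray, lo: int, hi: int, min_seg_bins: int, z_threshold: float,
             out: list[int]) -> None:
    seg = x[lo:hi]
    # the noise scale is re-estimated per segment: a constant stretch has
    # zero scale (any real shift is then infinitely significant), while a
    # noisy stretch gates spurious splits at z_threshold
    k, z = _best_split(seg, min_seg_bins, _noise_sd(seg))
    if k is None or z < z_threshold:
        return
    cp = lo + k
    out.append(cp)
    _recurse(x, lo, cp, min_seg_bins, z_threshold, out)
    _recurse(x, cp, hi, min_seg_bins, z_threshold, out)


def segment_bins(
    ratio_track: Sequence[float] | np.ndarray,
    bin_starts: Sequence[int] | np.ndarray | None = None,
    bin_ends: Sequence[int] | np.ndarray | None = None,
    min_seg_bins: int = DEFAULT_MIN_SEG_BINS,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    sample_id: str = "",
    contig_id: str = "",
) -> tuple[list[int], list[SegmentCall]]:
    """Segment one contig's ordered copy-ratio track.

    Masked bins (NaN ratio) are excluded before segmentation.
    Changepoints are indices into the *unmasked* track; the SegmentCall
    coordinates come from the surviving bins' start/end positions (bin
    index scale when none are given).
    """
    if min_seg_bins < 1:
        raise ValueError("min_seg_bins must be >= 1")
    x = np.asarray(ratio_track, dtype=float)
    n = len(x)
    if bin_starts is None:
        bin_starts = np.arange(n)
        bin_ends = np.arange(1, n + 1)
    starts = np.asarray(bin_starts)
    ends = np.asarray(bin_ends)
    keep = np.isfinite(x)
    x, starts, ends = x[keep], starts[keep], ends[keep]
    if len(x) == 0:
        return [], []
    cps: list[int] = []
    _recurse(x, 0, len(x), min_seg_bins, z_threshold, cps)
    cps.sort()
    segments = []
    bounds = [0, *cps, len(x)]
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        mean = float(x[lo:hi].mean())
        state, copies = state_from_ratio(mean)
        segments.append(
            SegmentCall(
                sample_id=sample_id,
                contig_id=contig_id,
                start_bp=int(starts[lo]),
                end_bp=int(ends[hi - 1]),
                n_bins=hi - lo,
                mean_ratio=mean,
                state=state,
                copies=copies,
            )
        )
    return cps, segments


def segment_sample(
    profile,
    sample: str,
    contigs: Iterable[str],
    min_seg_bins: int = DEFAULT_MIN_SEG_BINS,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> list[SegmentCall]:
    """Segment every listed contig of one sample's dosage profile."""
    segments: list[SegmentCall] = []
    for contig in contigs:
        track = profile.track(sample, contig)
        if track.empty:
            continue
        _, segs = segment_bins(
            track["ratio"].to_numpy(),
            bin_starts=track["start"].to_numpy(),
            bin_ends=track["end"].to_numpy(),
            min_seg_bins=min_seg_bins,
            z_threshold=z_threshold,
            sample_id=sample,
            contig_id=contig,
        )
        segments.extend(segs)
    return segments


def _designation(
    catalog: GenomeCatalog | None, rec: SegmentCall | None, don: SegmentCall | None
) -> str:
    def orig(contig: str) -> str:
        if catalog is not None:
            try:
                return catalog.entry(contig).original_id
            except KeyError:
                pass
        return contig

    parts = []
    if rec is not None:
        parts.append(
            f"{orig(rec.contig_id)}:{rec.start_bp / 1e6:g}-{rec.end_bp / 1e6:g}Mb"
        )
    if don is not None:
        parts.append(
            f"{orig(don.contig_id)}:{don.start_bp / 1e6:g}-{don.end_bp / 1e6:g}Mb"
        )
    return "::".join(parts)


def pair_translocation(
    recipient_segments: Iterable[SegmentCall],
    donor_segments: Iterable[SegmentCall],
    catalog: GenomeCatalog | None = None,
    min_mb: float = DEFAULT_MIN_MB,
) -> list[TranslocationCall]:
    """Pair recipient dosage losses with donor gains of matching class.

    Recipient segments at 0 copies pair with ~2-copy donor gains
    (homozygous translocation); 1-copy losses pair with ~1-copy donor
    gains (heterozygous).  Unpaired losses and gains are reported as
    deletions and additions.  Segments shorter than ``min_mb`` are
    ignored.
    """
    losses = [
        s
        for s in recipient_segments
        if s.state in (STATE_ABSENT, STATE_HEMIZYGOUS) and s.length_mb >= min_mb
    ]
    gains = [
        s
        for s in donor_segments
        if s.copies >= 1 and s.length_mb >= min_mb
    ]
    losses.sort(key=lambda s: -s.length_mb)
    gains.sort(key=lambda s: -s.length_mb)
    used: set[int] = set()
    calls: list[TranslocationCall] = []
    for loss in losses:
        want_donor_copies = 2 if loss.state == STATE_ABSENT else 1
        match = None
        for j, gain in enumerate(gains):
            if j in used:
                continue
            if gain.copies == want_donor_copies:
                match = j
                break
        if match is None:
            calls.append(
                TranslocationCall(
                    designation=_designation(catalog, loss, None),
                    sample_id=loss.sample_id,
                    recipient_contig=loss.contig_id,
                    recipient_start_bp=loss.start_bp,
                    recipient_end_bp=loss.end_bp,
                    donor_contig=None,
                    donor_start_bp=None,
                    donor_end_bp=None,
                    zygosity="homozygous" if loss.state == STATE_ABSENT else "heterozygous",
                    recipient_loss_mb=loss.length_mb,
                    donor_gain_mb=0.0,
                    kind="deletion",
                )
            )
            continue
        used.add(match)
        gain = gains[match]
        calls.append(
            TranslocationCall(
                designation=_designation(catalog, loss, gain),
                sample_id=loss.sample_id,
                recipient_contig=loss.contig_id,
                recipient_start_bp=loss.start_bp,
                recipient_end_bp=loss.end_bp,
                donor_contig=gain.contig_id,
                donor_start_bp=gain.start_bp,
                donor_end_bp=gain.end_bp,
                zygosity="homozygous" if loss.state == STATE_ABSENT else "heterozygous",
                recipient_loss_mb=loss.length_mb,
                donor_gain_mb=gain.length_mb,
            )
        )
    for j, gain in enumerate(gains):
        if j not in used:
            calls.append(
                TranslocationCall(
                    designation=_designation(catalog, None, gain),
                    sample_id=gain.sample_id,
                    recipient_contig=None,
                    recipient_start_bp=None,
                    recipient_end_bp=None,
                    donor_contig=gain.contig_id,
                    donor_start_bp=gain.start_bp,
                    donor_end_bp=gain.end_bp,
                    zygosity="homozygous" if gain.copies >= 2 else "heterozygous",
                    recipient_loss_mb=0.0,
                    donor_gain_mb=gain.length_mb,
                    kind="addition",
                )
            )
    return calls


def segregation_test(n_carrier: int, n_noncarrier: int) -> dict[str, float]:
    """Pearson goodness-of-fit chi-square against a 1:1 carrier ratio."""
    n = n_carrier + n_noncarrier
    if n <= 0:
        raise ValueError("need at least one observation")
    chi2 = (n_carrier - n_noncarrier) ** 2 / n
    return {
        "chi_square": float(chi2),
        "df": 1.0,
        "p_value": float(stats.chi2.sf(chi2, df=1)),
    }


def summarize_population(
    sample_designations: Iterable[tuple[str, str | None]],
) -> pd.DataFrame:
    """Carrier counts per translocation designation plus 1:1 segregation test.

    ``sample_designations`` is (sample_id, designation-or-None) — None
    for non-carriers.  Non-carriers count toward every designation seen
    in the population.
    """
    pairs = list(sample_designations)
    designations = sorted({d for _, d in pairs if d})
    rows = []
    n_noncarrier = sum(1 for _, d in pairs if not d)
    for desig in designations:
        n_car = sum(1 for _, d in pairs if d == desig)
        test = segregation_test(n_car, n_noncarrier)
        rows.append(
            (desig, n_car, n_noncarrier, n_car + n_noncarrier,
             test["chi_square"], test["p_value"])
        )
    return pd.DataFrame(
        rows,
        columns=["designation", "n_carrier", "n_noncarrier", "n", "chi_square", "p_value"],
    )


def segments_to_frame(segments: Iterable[SegmentCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.sample_id, s.contig_id, s.start_bp, s.end_bp, s.n_bins,
             s.mean_ratio, s.state, s.copies)
            for s in segments
        ],
        columns=["sample", "chrom", "start", "end", "n_bins", "mean_ratio", "state", "copies"],
    )


def translocations_to_frame(calls: Iterable[TranslocationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.sample_id, c.designation, c.kind, c.recipient_contig,
             c.recipient_start_bp, c.recipient_end_bp, c.donor_contig,
             c.donor_start_bp, c.donor_end_bp, c.zygosity,
             c.recipient_loss_mb, c.donor_gain_mb)
            for c in calls
        ],
        columns=[
            "sample", "designation", "kind", "recipient_chrom",
            "recipient_start", "recipient_end", "donor_chrom",
            "donor_start", "donor_end", "zygosity",
            "recipient_loss_mb", "donor_gain_mb",
        ],
    )
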