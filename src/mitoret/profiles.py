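"""RPM-normalized average read-density profiles and the subsampled-
control contamination null.

The contamination control asks whether an apparent mitotic binding
profile could be explained by a small fraction of interphase cells
surviving the sort: the observed mitotic profile is compared with a
profile built from 5% of the control reads in peak regions, kept on the
control sample's reads-per-million scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .intervals import IntervalSet, ReadSet, build_trees


@dataclass
class AverageProfile:
    """Mean fragment coverage in fixed-width bins around anchor
    midpoints, in reads per million mapped reads (RPM) per bin."""

    bin_size: int
    flank: int
    values: np.ndarray  # RPM per bin
    n_sites: int
    total_mapped: int

    @property
    def n_bins(self) -> int:
        return len(self.values)

    def bin_centers(self) -> np.ndarray:
        """Offsets of bin centers relative to the anchor midpoint."""
        starts = np.arange(self.n_bins) * self.bin_size - self.flank
        return starts + self.bin_size / 2

    def central_mean(self, half_width: int = 200) -> float:
        """Mean RPM over bins whose center lies within +/- half_width of
        the anchor."""
        centers = self.bin_centers()
        sel = np.abs(centers) <= half_width
        return float(self.values[sel].mean())

    def baseline_mean(self) -> float:
        """Mean RPM over the outer half of the window (bins with
        |center| >= flank / 2) — the profile's own background level."""
        centers = self.bin_centers()
        sel = np.abs(centers) >= self.flank / 2
        return float(self.values[sel].mean())

    def central_enrichment(self, half_width: int = 200) -> float:
        """Central mean minus the profile's own baseline: RPM enrichment
        attributable to the anchored sites."""
        return self.central_mean(half_width) - self.baseline_mean()


def average_profile(
    reads: ReadSet,
    anchors: IntervalSet,
    flank: int,
    bin_size: int = 50,
    fragment_size: int = 36,
) -> AverageProfile:
    """Fragment coverage binned across [mid - flank, mid + flank) around
    each anchor midpoint, averaged over anchors, scaled by
    10^6 / total_mapped.

    Windows running off a chromosome end are clipped (the anchor still
    counts; out-of-range bins receive no coverage).
    """
    if len(anchors) == 0:
        raise ValueError("anchors must be non-empty")
    if flank % bin_size != 0:
        raise ValueError("flank must be a multiple of bin_size")
    n_bins = 2 * flank // bin_size
    acc = np.zeros(n_bins, dtype=float)

    # per-chromosome fragment start positions, sorted (fixed length)
    starts_by_chrom: dict[str, list[int]] = {}
    for chrom, pos, strand in reads.reads:
        fs = pos - fragment_size + 1 if strand == "-" else pos
        starts_by_chrom.setdefault(chrom, []).append(fs)
    s_sorted = {c: np.sort(np.array(v)) for c, v in starts_by_chrom.items()}

    for anchor in anchors:
        s_arr = s_sorted.get(anchor.chrom)
        if s_arr is None:
            continue
        mid = anchor.midpoint
        w_start, w_end = mid - flank, mid + flank
        # fragment [fs, fs+L) overlaps window iff fs in (w_start-L, w_end)
        lo = int(np.searchsorted(s_arr, w_start - fragment_size, "right"))
        hi = int(np.searchsorted(s_arr, w_end, "left"))
        for fs in s_arr[lo:hi]:
            a = max(int(fs), w_start) - w_start
            b = min(int(fs) + fragment_size, w_end) - w_start
            if b <= a:
                continue
            for bi in range(a // bin_size, (b - 1) // bin_size + 1):
                acc[bi] += min(b, (bi + 1) * bin_size) - max(a, bi * bin_size)
    values = acc / (bin_size * len(anchors)) * 1e6 / max(reads.total_mapped, 1)
    return AverageProfile(
        bin_size=bin_size,
        flank=flank,
        values=values,
        n_sites=len(anchors),
        total_mapped=reads.total_mapped,
    )


def subsample_reads_in_regions(
    reads: ReadSet, regions: IntervalSet, fraction: float, seed: int = 0
) -> ReadSet:
    """Keep each in-region read independently with probability
    ``fraction``; drop reads outside the regions.

    The output keeps the ORIGINAL total_mapped, so a profile of the
    subsample stays on the source sample's RPM scale — this models a
    given fraction of interphase cells contaminating a library of the
    original sequencing depth.  Renormalizing by the subsampled count
    would cancel the effect under test.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    trees = build_trees(regions)
    kept = []
    for chrom, pos, strand in reads.reads:
        tree = trees.get(chrom)
        if tree is None or not tree.overlaps_point(pos):
            continue
        if fraction == 1.0 or rng.random() < fraction:
            kept.append((chrom, pos, strand))
    return ReadSet(reads=kept, total_mapped=reads.total_mapped)


@dataclass
class ContaminationCheck:
    """Observed mitotic profile vs the subsampled-control null."""

    mitotic_profile: AverageProfile
    null_profile: AverageProfile
    per_bin_ratio: np.ndarray
    per_bin_difference: np.ndarray
    central_ratio: float  # headline: mitotic / null over central bins


def contamination_check(
    control: ReadSet,
    mitotic: ReadSet,
    peak_regions: IntervalSet,
    fraction: float = 0.05,
    flank: int = 1000,
    bin_size: int = 50,
    fragment_size: int = 36,
    central_half_width: int = 200,
    seed: int = 0,
) -> ContaminationCheck:
    """Compare the mitotic average profile at peak anchors with the
    profile of a ``fraction`` subsample of control reads in the peak
    regions (the interphase-contamination null).

    The headline statistic is the ratio of central-bin enrichment (mean
    over bins within +/- central_half_width of the anchor, minus each
    profile's own baseline level from the outer half of the window),
    mitotic / null.  Each profile is measured above its own baseline
    because the mitotic library is sequenced to full depth and so
    carries a uniform background pedestal that the in-peak-only
    subsample lacks.  A ratio near 1 means the mitotic profile is
    indistinguishable from pure contamination; a ratio well above 1
    indicates genuine retained binding.
    """
    null_reads = subsample_reads_in_regions(control, peak_regions, fraction, seed=seed)
    mito_prof = average_profile(mitotic, peak_regions, flank, bin_size, fragment_size)
    null_prof = average_profile(null_reads, peak_regions, flank, bin_size, fragment_size)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            null_prof.values > 0, mito_prof.values / null_prof.values, np.nan
        )
    diff = mito_prof.values - null_prof.values
    denom = null_prof.central_enrichment(central_half_width)
    central = (
        mito_prof.central_enrichment(central_half_width) / denom
        if denom > 0
        else float("inf")
    )
    return ContaminationCheck(
        mitotic_profile=mito_prof,
        null_profile=null_prof,
        per_bin_ratio=ratio,
        per_bin_difference=diff,
        central_ratio=float(central),
    )


def write_profile_tsv(profile: AverageProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#bin_center_offset\trpm\n")
        for c, v in zip(profile.bin_centers(), profile.values):
            fh.write(f"{c:.1f}\t{v:.6g}\n")
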