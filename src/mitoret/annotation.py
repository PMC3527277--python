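"""Gene/TSS assignment, border and insulator overlap summaries, and
chromosome-level peak distribution analysis."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .intervals import IntervalSet, count_overlapping
from .io import TssRecord


@dataclass
class OverlapSummary:
    """Counts and fractions for a query set against a subject set, in
    both directions (n/m numerator-denominator form)."""

    n_query: int
    n_query_overlapping: int
    n_subject: int
    n_subject_overlapped: int

    @property
    def query_fraction(self) -> float:
        return self.n_query_overlapping / self.n_query if self.n_query else float("nan")

    @property
    def subject_fraction(self) -> float:
        return (
            self.n_subject_overlapped / self.n_subject
            if self.n_subject
            else float("nan")
        )

    def as_row(self) -> str:
        return (
            f"{self.n_query_overlapping}/{self.n_query} "
            f"({100 * self.query_fraction:.0f}%)"
        )


def summarize_overlap(
    query: IntervalSet, subject: IntervalSet, min_bp: int = 1
) -> OverlapSummary:
    return OverlapSummary(
        n_query=len(query),
        n_query_overlapping=count_overlapping(query, subject, min_bp=min_bp),
        n_subject=len(subject),
        n_subject_overlapped=count_overlapping(subject, query, min_bp=min_bp),
    )


def genes_near_peaks(
    peaks: IntervalSet, tss: list[TssRecord], max_dist: int = 2000
) -> dict[str, float]:
    """Genes whose TSS lies within max_dist bp of a peak (strand
    ignored), with the nearest-peak distance per gene.

    A gene is included iff some peak has at least 1 bp within
    [tss - max_dist, tss + max_dist]; the distance is 0 when a peak
    covers the TSS.
    """
    if not tss:
        raise ValueError("empty TSS table")
    by_chrom_starts: dict[str, np.ndarray] = {}
    by_chrom_ends: dict[str, np.ndarray] = {}
    tmp: dict[str, list[tuple[int, int]]] = {}
    for iv in peaks:
        tmp.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for chrom, ivs in tmp.items():
        ivs.sort()
        by_chrom_starts[chrom] = np.array([a for a, _ in ivs])
        by_chrom_ends[chrom] = np.array([b for _, b in ivs])
    out: dict[str, float] = {}
    for rec in tss:
        starts = by_chrom_starts.get(rec.chrom)
        if starts is None:
            continue
        ends = by_chrom_ends[rec.chrom]
        # distance from TSS point to each interval [start, end)
        dist = np.maximum(
            0, np.maximum(starts - rec.position, rec.position - (ends - 1))
        )
        d = int(dist.min())
        if d <= max_dist:
            prev = out.get(rec.gene_id)
            if prev is None or d < prev:
                out[rec.gene_id] = d
    return out


@dataclass
class BorderOverlapResult:
    control: OverlapSummary  # control peaks vs borders
    mitotic: OverlapSummary  # mitotic peaks vs borders
    borders_bound_control: float  # fraction of borders with a control peak
    borders_bound_mitotic: float
    preferential_retention_ratio: float  # mitotic peak border-fraction / control's


def border_overlap_summary(
    control_peaks: IntervalSet,
    mitotic_peaks: IntervalSet,
    borders: IntervalSet,
    min_bp: int = 1,
) -> BorderOverlapResult:
    """Per-condition border overlap: what fraction of peaks fall at
    chromatin-domain borders, what fraction of borders carry a peak, and
    how much more border-enriched the mitotic peak set is than the
    control set."""
    if len(borders) == 0:
        raise ValueError("empty border set")
    ctrl = summarize_overlap(control_peaks, borders, min_bp=min_bp)
    mit = summarize_overlap(mitotic_peaks, borders, min_bp=min_bp)
    ratio = (
        mit.query_fraction / ctrl.query_fraction
        if ctrl.query_fraction and not np.isnan(ctrl.query_fraction)
        else float("nan")
    )
    return BorderOverlapResult(
        control=ctrl,
        mitotic=mit,
        borders_bound_control=ctrl.subject_fraction,
        borders_bound_mitotic=mit.subject_fraction,
        preferential_retention_ratio=ratio,
    )


def chromosome_distribution(
    peaks_control: IntervalSet, peaks_mitotic: IntervalSet
) -> dict[str, tuple[float, float, float]]:
    """Per-chromosome percentage of each condition's sites and their
    difference (control% - mitotic%); each condition sums to 100."""
    if len(peaks_control) == 0 or len(peaks_mitotic) == 0:
        raise ValueError("peak sets must be non-empty")
    chroms = sorted(
        set(peaks_control.chromosomes()) | set(peaks_mitotic.chromosomes())
    )
    out = {}
    for chrom in chroms:
        pc = 100.0 * sum(1 for iv in peaks_control if iv.chrom == chrom) / len(peaks_control)
        pm = 100.0 * sum(1 for iv in peaks_mitotic if iv.chrom == chrom) / len(peaks_mitotic)
        out[chrom] = (pc, pm, pc - pm)
    return out


def windowed_site_difference(
    peaks_control: IntervalSet,
    peaks_mitotic: IntervalSet,
    genome: dict[str, int],
    window: int = 5_000_000,
) -> list[tuple[str, int, int, float]]:
    """Difference in per-window percentage of sites between conditions
    over a fixed genome tiling.

    Each peak is assigned to the window containing its midpoint (a peak
    straddling a boundary counts once).  Per condition, window
    percentages sum to 100; the output Delta = control% - mitotic% per
    window, so the deltas sum to 0.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(peaks_control) == 0 or len(peaks_mitotic) == 0:
        raise ValueError("peak sets must be non-empty")
    windows: list[tuple[str, int, int]] = []
    index: dict[tuple[str, int], int] = {}
    for chrom, length in genome.items():
        for ws in range(0, length, window):
            index[(chrom, ws // window)] = len(windows)
            windows.append((chrom, ws, min(ws + window, length)))

    def percents(peaks: IntervalSet) -> np.ndarray:
        counts = np.zeros(len(windows))
        for iv in peaks:
            key = (iv.chrom, iv.midpoint // window)
            if key not in index:
                raise ValueError(f"peak outside genome tiling: {iv.chrom}:{iv.start}")
            counts[index[key]] += 1
        return 100.0 * counts / counts.sum()

    delta = percents(peaks_control) - percents(peaks_mitotic)
    return [(c, s, e, float(d)) for (c, s, e), d in zip(windows, delta)]


def write_gene_list(
    genes: dict[str, float], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("#gene_id\tdistance_bp\n")
        for gid in sorted(genes):
            fh.write(f"{gid}\t{genes[gid]:.0f}\n")


def write_border_summary(result: BorderOverlapResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "condition\tpeaks_at_borders\tn_peaks\tpeak_fraction\t"
            "borders_bound\tn_borders\tborder_fraction\n"
        )
        for label, s in (("control", result.control), ("mitotic", result.mitotic)):
            fh.write(
                f"{label}\t{s.n_query_overlapping}\t{s.n_query}\t"
                f"{s.query_fraction:.4f}\t{s.n_subject_overlapped}\t"
                f"{s.n_subject}\t{s.subject_fraction:.4f}\n"
            )
        fh.write(
            f"#preferential_retention_ratio\t{result.preferential_retention_ratio:.4f}\n"
        )
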