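"""Poisson local-background peak calling for single-end ChIP-seq tags.

A deliberately minimal MACS-1.x-style caller: reads are extended to a
fixed fragment size (no shift-model estimation), piled up at bp
resolution, and windows whose tag count exceeds the Poisson upper tail
of a local background rate are merged into peaks.  An empirical FDR is
obtained by the sample-swap convention (calling peaks with treatment
and control exchanged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import poisson

from .intervals import GenomicInterval, IntervalSet, ReadSet

logger = logging.getLogger(__name__)


@dataclass
class CoverageTrack:
    """Per-chromosome integer fragment pileup at bp resolution."""

    coverage: dict[str, np.ndarray]
    fragment_size: int
    source_reads: int
    total_mapped: int

    def total_coverage_bp(self) -> int:
        """Sum of coverage x bp; equals stored reads x fragment size up
        to clipping at chromosome edges."""
        return int(sum(int(c.sum()) for c in self.coverage.values()))


@dataclass
class Peak:
    """A called peak with the four ranking metrics used downstream:
    Poisson p-value, reads in peak, pileup height, fold over background."""

    interval: GenomicInterval
    summit: int
    height: int
    n_reads: int
    fold: float
    p_value: float
    fdr: float | None = None

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


def extend_and_pileup(
    reads: ReadSet, fragment_size: int, genome: dict[str, int]
) -> CoverageTrack:
    """Extend each read to fragment_size in its strand direction and
    pile up coverage.

    A + read at p covers [p, p + fragment_size); a - read at p covers
    (p - fragment_size, p].  Fragments are clipped at chromosome edges.
    """
    if fragment_size < 1:
        raise ValueError(f"fragment_size must be >= 1, got {fragment_size}")
    cov = {c: np.zeros(l, dtype=np.int64) for c, l in genome.items()}
    for chrom, pos, strand in reads.reads:
        if chrom not in cov:
            raise ValueError(f"read on unknown chromosome {chrom!r}")
        n = len(cov[chrom])
        if strand == "-":
            start, end = pos - fragment_size + 1, pos + 1
        else:
            start, end = pos, pos + fragment_size
        start, end = max(0, start), min(n, end)
        if start < end:
            cov[chrom][start:end] += 1
    return CoverageTrack(
        coverage=cov,
        fragment_size=fragment_size,
        source_reads=len(reads.reads),
        total_mapped=reads.total_mapped,
    )


def poisson_sf(k: int | np.ndarray, lam: float | np.ndarray) -> np.ndarray:
    """Upper-tail Poisson probability P(X >= k) at rate lam."""
    return poisson.sf(np.asarray(k) - 1, lam)


def _fragment_bounds(
    reads: ReadSet, fragment_size: int
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Sorted (starts, ends) of extended fragments per chromosome."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, pos, strand in reads.reads:
        if strand == "-":
            s, e = pos - fragment_size + 1, pos + 1
        else:
            s, e = pos, pos + fragment_size
        per_chrom.setdefault(chrom, []).append((s, e))
    out = {}
    for chrom, frags in per_chrom.items():
        starts = np.sort(np.array([f[0] for f in frags], dtype=np.int64))
        ends = np.sort(np.array([f[1] for f in frags], dtype=np.int64))
        out[chrom] = (starts, ends)
    return out


def _count_in_window(
    starts: np.ndarray, ends: np.ndarray, ws: np.ndarray, we: np.ndarray
) -> np.ndarray:
    """Number of fragments intersecting [ws, we): start < we and end > ws."""
    return np.searchsorted(starts, we, side="left") - np.searchsorted(
        ends, ws, side="right"
    )


def call_peaks(
    track: CoverageTrack,
    reads: ReadSet,
    effective_genome_size: float,
    bandwidth: int = 200,
    p_cutoff: float = 1e-5,
    control_track: CoverageTrack | None = None,
    local_windows: tuple[int, ...] = (1000, 10000),
) -> list[Peak]:
    """Scan fixed-width windows, keep those beating the Poisson tail at
    the local background rate, and merge nearby survivors into peaks.

    The genome-wide background rate is
    ``total_reads x fragment_size / effective_genome_size`` per bp.
    When a control track is supplied the local rate is the max of the
    genome-wide rate and the control rate measured in the surrounding
    1-kb and 10-kb windows (MACS convention); otherwise genome-wide
    only.  Candidate windows closer than ``bandwidth`` are merged; each
    merged region yields one Peak with summit, height, reads-in-peak,
    fold over background, and a Poisson p-value for its read count.
    """
    if effective_genome_size <= 0:
        raise ValueError("effective_genome_size must be positive")
    if not 0 < p_cutoff < 1:
        raise ValueError(f"p_cutoff must be in (0,1), got {p_cutoff}")
    if effective_genome_size < bandwidth:
        raise ValueError("genome smaller than bandwidth")

    n_reads_total = track.source_reads
    if n_reads_total == 0:
        return []
    L = track.fragment_size
    rate_bg = n_reads_total / effective_genome_size  # reads per bp

    frag_bounds = _fragment_bounds(reads, L)
    if control_track is not None:
        # control lambda is scaled to the treatment depth
        ctrl_scale = n_reads_total / max(control_track.source_reads, 1)
    peaks: list[Peak] = []

    win = bandwidth
    step = max(1, bandwidth // 2)
    for chrom, cov in track.coverage.items():
        if chrom not in frag_bounds:
            continue
        starts, ends = frag_bounds[chrom]
        n = len(cov)
        ws = np.arange(0, max(1, n - win + 1), step, dtype=np.int64)
        we = np.minimum(ws + win, n)
        counts = _count_in_window(starts, ends, ws, we)
        # expected fragments intersecting a w-bp window: rate x (w + L - 1)
        lam_win = rate_bg * (we - ws + L - 1)
        sig = poisson.sf(counts - 1, lam_win) < p_cutoff
        if not sig.any():
            continue
        # merge significant windows within `bandwidth` of each other
        idx = np.flatnonzero(sig)
        regions: list[tuple[int, int]] = []
        rs, re = int(ws[idx[0]]), int(we[idx[0]])
        for i in idx[1:]:
            if int(ws[i]) <= re + bandwidth:
                re = max(re, int(we[i]))
            else:
                regions.append((rs, re))
                rs, re = int(ws[i]), int(we[i])
        regions.append((rs, re))

        for rs, re in regions:
            seg = cov[rs:re]
            if seg.max() == 0:
                continue
            nz = np.flatnonzero(seg)
            ps, pe = rs + int(nz[0]), rs + int(nz[-1]) + 1
            seg = cov[ps:pe]
            # coverage centroid: stabler than raw argmax on the flat,
            # noisy plateau a uniform-occupancy site produces
            summit = ps + int(round(float(np.average(np.arange(len(seg)), weights=seg))))
            height = int(seg.max())
            k = int(
                _count_in_window(
                    starts, ends, np.array([ps]), np.array([pe])
                )[0]
            )
            lam_local_rate = rate_bg
            if control_track is not None:
                ccov = control_track.coverage.get(chrom)
                if ccov is not None:
                    for w_local in local_windows:
                        a = max(0, summit - w_local // 2)
                        b = min(len(ccov), summit + w_local // 2)
                        if b > a:
                            # control pileup bp -> reads, rescaled to depth
                            local_reads = ccov[a:b].sum() / control_track.fragment_size
                            lam_local_rate = max(
                                lam_local_rate,
                                ctrl_scale * local_reads / (b - a),
                            )
            lam_peak = lam_local_rate * (pe - ps + L - 1)
            pval = float(poisson.sf(k - 1, lam_peak))
            fold = height / (lam_local_rate * L)
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, ps, pe, name=f"peak_{chrom}_{ps}"),
                    summit=summit,
                    height=height,
                    n_reads=k,
                    fold=fold,
                    p_value=max(pval, 1e-300),
                )
            )
    # deterministic order: p-value, then more reads, then coordinate
    peaks.sort(key=lambda p: (p.p_value, -p.n_reads, p.chrom, p.start))
    return peaks


def empirical_fdr(
    treatment_peaks: list[Peak],
    swap_peaks: list[Peak] | None,
    threshold: float = 0.05,
    p_cutoff_fallback: float = 1e-5,
) -> list[Peak]:
    """Attach sample-swap empirical FDRs and filter at ``threshold``.

    For a treatment peak with p-value p,
    ``fdr = #(swap peaks with p-value <= p) / #(treatment peaks with
    p-value <= p)``, clipped to [0, 1] and made monotone non-decreasing
    in p-value rank (running maximum).  With no control track the swap
    list is unavailable: fdr stays undefined and filtering falls back to
    the p-value cutoff (logged loudly).
    """
    if not treatment_peaks:
        return []
    if swap_peaks is None:
        logger.warning(
            "no control track: empirical FDR unavailable, "
            "filtering at p-value cutoff %g instead",
            p_cutoff_fallback,
        )
        return [p for p in treatment_peaks if p.p_value < p_cutoff_fallback]

    order = sorted(
        range(len(treatment_peaks)),
        key=lambda i: (
            treatment_peaks[i].p_value,
            -treatment_peaks[i].n_reads,
            treatment_peaks[i].chrom,
            treatment_peaks[i].start,
        ),
    )
    swap_p = np.sort(np.array([p.p_value for p in swap_peaks]))
    running = 0.0
    kept: list[Peak] = []
    for rank, i in enumerate(order, start=1):
        p = treatment_peaks[i]
        n_swap = int(np.searchsorted(swap_p, p.p_value, side="right"))
        fdr = min(1.0, n_swap / rank)
        running = max(running, fdr)
        p.fdr = running
        if running <= threshold:
            kept.append(p)
    kept.sort(key=lambda p: (p.chrom, p.start))
    return kept


def peaks_to_interval_set(
    peaks: list[Peak], genome: dict[str, int] | None = None
) -> IntervalSet:
    return IntervalSet([p.interval for p in peaks], genome=genome)


def write_peaks_tsv(peaks: list[Peak], path: str | Path) -> None:
    """Write peaks as BED6+ TSV: chrom, start, end, name, score
    (-log10 p), strand, fold, n_reads, height, fdr."""
    with open(path, "w") as fh:
        fh.write(
            "#chrom\tstart\tend\tname\tneg_log10_pvalue\tstrand\t"
            "fold\tn_reads\theight\tfdr\n"
        )
        for p in sorted(peaks, key=lambda q: (q.chrom, q.start)):
            nlp = -np.log10(p.p_value)
            fdr = f"{p.fdr:.6g}" if p.fdr is not None else "NA"
            name = p.interval.name or "."
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{nlp:.4f}\t.\t"
                f"{p.fold:.4f}\t{p.n_reads}\t{p.height}\t{fdr}\n"
            )


def read_peaks_tsv(path: str | Path) -> list[Peak]:
    peaks = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        iv = GenomicInterval(f[0], int(f[1]), int(f[2]), name=f[3])
        pval = 10 ** (-float(f[4]))
        fdr = None if f[9] == "NA" else float(f[9])
        peaks.append(
            Peak(
                interval=iv,
                summit=iv.midpoint,
                height=int(f[8]),
                n_reads=int(f[7]),
                fold=float(f[6]),
                p_value=pval,
                fdr=fdr,
            )
        )
    return peaks
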