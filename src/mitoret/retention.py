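"""Two-condition peak-set comparison: persistent vs condition-specific
sites, rank-dependence of retention, and reads-in-peaks correlation.

The central question is which control-condition binding sites keep a
peak in the mitotic condition ("persistent"), which lose it
("control-only"), and whether any sites appear only in mitosis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .intervals import GenomicInterval, IntervalSet, ReadSet, overlap_pairs
from .peaks import Peak

RANK_METRICS = ("p_value", "n_reads", "height", "fold")


@dataclass
class RetentionResult:
    """Partition of two peak sets by cross-condition overlap."""

    persistent: IntervalSet
    control_only: IntervalSet
    mitotic_only: IntervalSet
    pairing: list[tuple[int, int]]  # (control index, mitotic index)

    @property
    def n_control(self) -> int:
        return len(self.persistent) + len(self.control_only)

    def summary(self) -> dict:
        n_ctrl = self.n_control
        return {
            "n_control": n_ctrl,
            "n_persistent": len(self.persistent),
            "n_control_only": len(self.control_only),
            "n_mitotic_only": len(self.mitotic_only),
            "fraction_persistent": (
                len(self.persistent) / n_ctrl if n_ctrl else float("nan")
            ),
        }


def _check_disjoint(peaks: list[Peak], label: str) -> None:
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    for chrom, ps in by_chrom.items():
        ps.sort(key=lambda p: p.start)
        for a, b in zip(ps, ps[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"{label} peaks overlap on {chrom}: "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )


def classify_sites(
    control: list[Peak], mitotic: list[Peak], min_bp: int = 1
) -> RetentionResult:
    """Classify control peaks as persistent (>= min_bp overlap with a
    mitotic peak) or control-only, and mitotic peaks with no control
    partner as mitotic-only.

    A mitotic peak overlapping several control peaks is assigned to the
    one with the largest intersection, ties to the better-ranked
    (smaller p-value) control peak.  Mitotic-only peaks are reported,
    never auto-discarded.
    """
    _check_disjoint(control, "control")
    _check_disjoint(mitotic, "mitotic")
    cset = IntervalSet([p.interval for p in control])
    mset = IntervalSet([p.interval for p in mitotic])
    # indices into the sorted IntervalSets map back to the sorted peak lists
    ctrl_sorted = sorted(control, key=lambda p: (p.chrom, p.start, p.end))
    mit_sorted = sorted(mitotic, key=lambda p: (p.chrom, p.start, p.end))

    pairs, _ = overlap_pairs(cset, mset, min_bp=min_bp)
    # per mitotic peak, choose the control partner with the largest
    # intersection; ties go to the smaller p-value, then coordinate
    best: dict[int, int] = {}
    per_mit: dict[int, list[tuple[int, int]]] = {}
    for ci, mi in pairs:
        per_mit.setdefault(mi, []).append(
            (ctrl_sorted[ci].interval.intersection_length(mit_sorted[mi].interval), ci)
        )
    for mi, cands in per_mit.items():
        cands.sort(
            key=lambda t: (-t[0], ctrl_sorted[t[1]].p_value, t[1])
        )
        best[mi] = cands[0][1]

    persistent_ci = {ci for ci, _ in pairs}
    pairing = sorted((ci, mi) for mi, ci in best.items())
    persistent = IntervalSet([ctrl_sorted[i].interval for i in sorted(persistent_ci)])
    control_only = IntervalSet(
        [p.interval for i, p in enumerate(ctrl_sorted) if i not in persistent_ci]
    )
    mitotic_only = IntervalSet(
        [p.interval for i, p in enumerate(mit_sorted) if i not in per_mit]
    )
    return RetentionResult(persistent, control_only, mitotic_only, pairing)


def decile_retention(
    control: list[Peak],
    mitotic: list[Peak],
    metric: str = "p_value",
    min_bp: int = 1,
) -> list[float]:
    """Percentage of partnered mitotic peaks per decile of control peaks
    ranked best-first by ``metric``.

    Ranking is ascending for p_value, descending for n_reads / height /
    fold.  Control peaks are split into 10 equal-size bins, with any
    remainder spread one-per-bin over the leading bins.  Entry i is
    100 x (#mitotic peaks whose assigned control partner lies in decile
    i) / (#mitotic peaks with a partner); entries sum to 100 when every
    mitotic peak has a partner.
    """
    if metric not in RANK_METRICS:
        raise ValueError(f"metric must be one of {RANK_METRICS}")
    if len(control) < 10:
        raise ValueError("need at least 10 control peaks for deciles")
    result = classify_sites(control, mitotic, min_bp=min_bp)
    if not result.pairing:
        raise ValueError("no mitotic peak has a control partner")

    ctrl_sorted = sorted(control, key=lambda p: (p.chrom, p.start, p.end))
    sign = 1.0 if metric == "p_value" else -1.0
    order = sorted(
        range(len(ctrl_sorted)),
        key=lambda i: (
            sign * getattr(ctrl_sorted[i], metric),
            ctrl_sorted[i].chrom,
            ctrl_sorted[i].start,
        ),
    )
    rank_of = {ci: r for r, ci in enumerate(order)}

    n = len(ctrl_sorted)
    base, rem = divmod(n, 10)
    sizes = [base + (1 if d < rem else 0) for d in range(10)]
    decile_of = np.repeat(np.arange(10), sizes)

    counts = np.zeros(10)
    for ci, _mi in result.pairing:
        counts[decile_of[rank_of[ci]]] += 1
    return list(100.0 * counts / len(result.pairing))


def count_reads_in_intervals(reads: ReadSet, regions: IntervalSet,
                             fragment_size: int) -> np.ndarray:
    """Per-region count of reads whose extended fragment overlaps the
    region (same fragment model as the peak caller)."""
    by_chrom_frags: dict[str, list[int]] = {}
    frag_starts: dict[str, np.ndarray] = {}
    frag_ends: dict[str, np.ndarray] = {}
    tmp: dict[str, list[tuple[int, int]]] = {}
    for chrom, pos, strand in reads.reads:
        if strand == "-":
            s, e = pos - fragment_size + 1, pos + 1
        else:
            s, e = pos, pos + fragment_size
        tmp.setdefault(chrom, []).append((s, e))
    for chrom, frags in tmp.items():
        frag_starts[chrom] = np.sort(np.array([f[0] for f in frags]))
        frag_ends[chrom] = np.sort(np.array([f[1] for f in frags]))
    counts = np.zeros(len(regions), dtype=np.int64)
    for i, iv in enumerate(regions):
        if iv.chrom not in frag_starts:
            continue
        s = frag_starts[iv.chrom]
        e = frag_ends[iv.chrom]
        counts[i] = np.searchsorted(s, iv.end, side="left") - np.searchsorted(
            e, iv.start, side="right"
        )
    return counts


def reads_in_peaks_correlation(
    peak_union: IntervalSet,
    reads_a: ReadSet,
    reads_b: ReadSet,
    fragment_size: int = 36,
) -> float:
    """Pearson correlation of per-peak read counts between two samples,
    over the union of peaks called in either sample."""
    if len(peak_union) < 2:
        raise ValueError("need at least two peaks for a correlation")
    a = count_reads_in_intervals(reads_a, peak_union, fragment_size).astype(float)
    b = count_reads_in_intervals(reads_b, peak_union, fragment_size).astype(float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in a per-peak count vector")
    return float(np.corrcoef(a, b)[0, 1])


def write_retention_summary(result: RetentionResult, path: str | Path) -> None:
    s = result.summary()
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for k, v in s.items():
            fh.write(f"{k}\t{v:.6g}\n" if isinstance(v, float) else f"{k}\t{v}\n")


def write_decile_table(
    deciles: dict[str, list[float]], path: str | Path
) -> None:
    """TSV with one column per ranking metric, rows = deciles 1..10."""
    metrics = list(deciles)
    with open(path, "w") as fh:
        fh.write("decile\t" + "\t".join(metrics) + "\n")
        for d in range(10):
            row = "\t".join(f"{deciles[m][d]:.4f}" for m in metrics)
            fh.write(f"{d + 1}\t{row}\n")
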