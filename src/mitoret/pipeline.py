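"""Pipeline orchestration: compose the stages into the three analyses
(ChIP-seq retention, fractionation, imaging) with a single config and
seed, writing all declared outputs plus a machine-readable manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .annotation import (
    border_overlap_summary,
    chromosome_distribution,
    genes_near_peaks,
    windowed_site_difference,
    write_border_summary,
    write_gene_list,
)
from .intervals import IntervalSet, ReadSet
from .io import read_bed, read_genome, read_reads_bed, read_tss_table, write_bed
from .peaks import (
    call_peaks,
    empirical_fdr,
    extend_and_pileup,
    peaks_to_interval_set,
    write_peaks_tsv,
)
from .profiles import average_profile, contamination_check, write_profile_tsv
from .retention import (
    RANK_METRICS,
    classify_sites,
    decile_retention,
    reads_in_peaks_correlation,
    write_decile_table,
    write_retention_summary,
)
from .fractionation import read_fractionation_tsv, summarize_protein, write_summary_tsv
from .imaging import (
    batch_summarize,
    colocalization_ratio,
    read_image_pair,
    write_cell_results_tsv,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run.

    Parameter defaults follow the study design this pipeline reproduces:
    36-bp fragments, 200-bp scanning bandwidth, Poisson p < 1e-5,
    5% sample-swap FDR, 50-bp profile bins, 2-kb TSS windows, 5-Mb
    distribution windows, and a 5% contamination subsample.
    ``effective_genome_size`` of None means the mappable genome is taken
    as the total length of the supplied genome map (for the fly genome a
    user would set 120e6).
    """

    # inputs
    genome_path: str | None = None
    control_reads_path: str | None = None
    mitotic_reads_path: str | None = None
    input_reads_path: str | None = None  # sequencing input (MACS control)
    borders_path: str | None = None
    tss_path: str | None = None
    # parameters
    fragment_size: int = 36
    effective_genome_size: float | None = None
    bandwidth: int = 200
    p_cutoff: float = 1e-5
    fdr: float = 0.05
    bin_size: int = 50
    flank: int = 1000
    tss_dist: int = 2000
    window: int = 5_000_000
    subsample: float = 0.05
    drop_chromosomes: tuple[str, ...] = ("chrU", "chrUextra")
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.p_cutoff < 1:
            raise ValueError("p_cutoff must be in (0,1)")
        if not 0 < self.fdr <= 1:
            raise ValueError("fdr must be in (0,1]")
        if not 0 <= self.subsample <= 1:
            raise ValueError("subsample must be in [0,1]")
        if self.fragment_size < 1 or self.bandwidth < 1:
            raise ValueError("fragment_size and bandwidth must be >= 1")


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _require(path: str | None, key: str) -> Path:
    if path is None:
        raise ValueError(f"missing required input: config key {key!r}")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config key {key!r}: no such file {path}")
    return p


def _write_manifest(
    outdir: Path, cfg: PipelineConfig, inputs: dict[str, str], outputs: list[str]
) -> None:
    manifest = {
        "package": "mitoret",
        "version": __version__,
        "parameters": {
            k: v for k, v in asdict(cfg).items() if not k.endswith("_path")
        },
        "input_digests": inputs,
        "outputs": sorted(outputs),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def run_retention(
    cfg: PipelineConfig,
    outdir: str | Path,
    control: ReadSet | None = None,
    mitotic: ReadSet | None = None,
    genome: dict[str, int] | None = None,
    borders: IntervalSet | None = None,
    tss=None,
) -> dict:
    """Run the full two-condition retention analysis.

    Inputs may be passed in memory or loaded from the configured paths.
    Writes peak tables, retention sets, decile tables, average profiles,
    the contamination check, overlap summaries and gene lists under
    ``outdir``, plus a manifest; returns a dict of headline numbers.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    input_digests: dict[str, str] = {}

    if genome is None:
        p = _require(cfg.genome_path, "genome_path")
        genome = read_genome(p)
        input_digests["genome"] = _sha256(p)
    if control is None:
        p = _require(cfg.control_reads_path, "control_reads_path")
        control = read_reads_bed(p)
        input_digests["control_reads"] = _sha256(p)
    if mitotic is None:
        p = _require(cfg.mitotic_reads_path, "mitotic_reads_path")
        mitotic = read_reads_bed(p)
        input_digests["mitotic_reads"] = _sha256(p)
    input_reads = None
    if cfg.input_reads_path is not None:
        input_reads = read_reads_bed(_require(cfg.input_reads_path, "input_reads_path"))
        input_digests["input_reads"] = _sha256(cfg.input_reads_path)
    if borders is None and cfg.borders_path is not None:
        borders = read_bed(_require(cfg.borders_path, "borders_path"))
        input_digests["borders"] = _sha256(cfg.borders_path)
    if tss is None and cfg.tss_path is not None:
        tss = read_tss_table(_require(cfg.tss_path, "tss_path"))
        input_digests["tss"] = _sha256(cfg.tss_path)

    egs = cfg.effective_genome_size or float(sum(genome.values()))
    outputs: list[str] = []
    results: dict = {}

    # 1. peak calling per condition
    input_track = (
        extend_and_pileup(input_reads, cfg.fragment_size, genome)
        if input_reads is not None
        else None
    )
    peak_sets = {}
    for label, reads in (("control", control), ("mitotic", mitotic)):
        track = extend_and_pileup(reads, cfg.fragment_size, genome)
        peaks = call_peaks(
            track,
            reads,
            egs,
            bandwidth=cfg.bandwidth,
            p_cutoff=cfg.p_cutoff,
            control_track=input_track,
        )
        if input_track is not None and input_reads is not None:
            swap = call_peaks(
                input_track,
                input_reads,
                egs,
                bandwidth=cfg.bandwidth,
                p_cutoff=cfg.p_cutoff,
                control_track=track,
            )
            peaks = empirical_fdr(peaks, swap, threshold=cfg.fdr)
        else:
            peaks = empirical_fdr(peaks, None, p_cutoff_fallback=cfg.p_cutoff)
        kept = peaks_to_interval_set(peaks, genome=genome).filter_chromosomes(
            cfg.drop_chromosomes
        )
        kept_names = {(iv.chrom, iv.start, iv.end) for iv in kept}
        peaks = [p for p in peaks if (p.chrom, p.start, p.end) in kept_names]
        peak_sets[label] = peaks
        fn = outdir / f"peaks_{label}.tsv"
        write_peaks_tsv(peaks, fn)
        outputs.append(fn.name)
        results[f"n_peaks_{label}"] = len(peaks)

    # 2. retention classification
    retention = classify_sites(peak_sets["control"], peak_sets["mitotic"])
    for name, iset in (
        ("persistent", retention.persistent),
        ("control_only", retention.control_only),
        ("mitotic_only", retention.mitotic_only),
    ):
        fn = outdir / f"sites_{name}.bed"
        write_bed(iset, fn)
        outputs.append(fn.name)
    write_retention_summary(retention, outdir / "retention_summary.tsv")
    outputs.append("retention_summary.tsv")
    results["retention"] = retention.summary()

    # 3. decile tables over the four ranking metrics
    if len(peak_sets["control"]) >= 10 and retention.pairing:
        deciles = {
            m: decile_retention(peak_sets["control"], peak_sets["mitotic"], metric=m)
            for m in RANK_METRICS
        }
        write_decile_table(deciles, outdir / "decile_retention.tsv")
        outputs.append("decile_retention.tsv")
        results["deciles"] = deciles

    # 4. reads-in-peaks correlation over the union of called peaks
    union = IntervalSet(
        [p.interval for p in peak_sets["control"] + peak_sets["mitotic"]]
    ).merged()
    if len(union) >= 2:
        r = reads_in_peaks_correlation(union, control, mitotic, cfg.fragment_size)
        results["reads_in_peaks_pearson_r"] = r

    # 5. average profiles and contamination null at control peak anchors
    anchors = peaks_to_interval_set(peak_sets["control"])
    if len(anchors) > 0:
        for label, reads in (("control", control), ("mitotic", mitotic)):
            prof = average_profile(
                reads, anchors, cfg.flank, cfg.bin_size, cfg.fragment_size
            )
            fn = outdir / f"profile_{label}.tsv"
            write_profile_tsv(prof, fn)
            outputs.append(fn.name)
        check = contamination_check(
            control,
            mitotic,
            anchors,
            fraction=cfg.subsample,
            flank=cfg.flank,
            bin_size=cfg.bin_size,
            fragment_size=cfg.fragment_size,
            seed=cfg.seed,
        )
        write_profile_tsv(check.null_profile, outdir / "profile_contamination_null.tsv")
        outputs.append("profile_contamination_null.tsv")
        results["contamination_central_ratio"] = check.central_ratio

    # 6. annotation overlaps
    if borders is not None and len(peak_sets["mitotic"]) > 0:
        b = border_overlap_summary(
            peaks_to_interval_set(peak_sets["control"]),
            peaks_to_interval_set(peak_sets["mitotic"]),
            borders,
        )
        write_border_summary(b, outdir / "border_overlap.tsv")
        outputs.append("border_overlap.tsv")
        results["border_overlap"] = {
            "control_peak_fraction": b.control.query_fraction,
            "mitotic_peak_fraction": b.mitotic.query_fraction,
            "borders_bound_control": b.borders_bound_control,
            "borders_bound_mitotic": b.borders_bound_mitotic,
            "preferential_retention_ratio": b.preferential_retention_ratio,
        }
    if tss is not None:
        for label in ("control", "mitotic"):
            genes = genes_near_peaks(
                peaks_to_interval_set(peak_sets[label]), tss, cfg.tss_dist
            )
            fn = outdir / f"genes_{label}.tsv"
            write_gene_list(genes, fn)
            outputs.append(fn.name)
            results[f"n_genes_{label}"] = len(genes)

    # 7. chromosome-scale distributions
    if peak_sets["control"] and peak_sets["mitotic"]:
        dist = chromosome_distribution(
            peaks_to_interval_set(peak_sets["control"]),
            peaks_to_interval_set(peak_sets["mitotic"]),
        )
        with open(outdir / "chromosome_distribution.tsv", "w") as fh:
            fh.write("chrom\tcontrol_pct\tmitotic_pct\tdifference\n")
            for chrom, (pc, pm, d) in dist.items():
                fh.write(f"{chrom}\t{pc:.4f}\t{pm:.4f}\t{d:.4f}\n")
        outputs.append("chromosome_distribution.tsv")
        wd = windowed_site_difference(
            peaks_to_interval_set(peak_sets["control"]),
            peaks_to_interval_set(peak_sets["mitotic"]),
            genome,
            window=cfg.window,
        )
        with open(outdir / "windowed_difference.tsv", "w") as fh:
            fh.write("chrom\tstart\tend\tdelta_pct\n")
            for chrom, s, e, d in wd:
                fh.write(f"{chrom}\t{s}\t{e}\t{d:.6f}\n")
        outputs.append("windowed_difference.tsv")

    _write_manifest(outdir, cfg, input_digests, outputs + ["results.json"])
    (outdir / "results.json").write_text(
        json.dumps(results, indent=2, sort_keys=True, default=float) + "\n"
    )
    return results


def run_fractionation(table_path: str | Path, outdir: str | Path) -> dict:
    """Fractionation analysis: per-protein P3 summary with the
    mitotic-index correction and percent-of-control column."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = read_fractionation_tsv(table_path)
    if not records:
        raise ValueError(f"no usable rows in {table_path}")
    by_protein: dict[str, list] = {}
    for r in records:
        by_protein.setdefault(r.protein, []).append(r)
    summaries = [summarize_protein(v) for v in by_protein.values()]
    write_summary_tsv(summaries, outdir / "fractionation_summary.tsv")
    return {
        s.protein: {
            "corrected_mitotic_p3": s.corrected_p3_mean,
            "percent_of_control": s.percent_of_control,
        }
        for s in summaries
    }


def run_imaging(
    pairs: list[tuple[str, str, str, str]], outdir: str | Path
) -> dict:
    """Imaging analysis on (cell_id, group, dna_path, protein_path)
    image pairs: per-cell colocalization ratios and group summaries."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    ratios, groups = [], []
    for cell_id, group, dna_path, protein_path in pairs:
        res = colocalization_ratio(read_image_pair(dna_path, protein_path))
        rows.append((cell_id, group, res))
        ratios.append(res.ratio)
        groups.append(group)
    write_cell_results_tsv(rows, outdir / "cell_colocalization.tsv")
    summary = batch_summarize(ratios, groups)
    with open(outdir / "group_summary.tsv", "w") as fh:
        fh.write("group\tmean_ratio\tsd\tn\n")
        for g, s in summary.items():
            fh.write(f"{g}\t{s.mean:.4f}\t{s.sd:.4f}\t{s.n}\n")
    return {g: {"mean": s.mean, "sd": s.sd, "n": s.n} for g, s in summary.items()}
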