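"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators mirror the three experimental arms of a mitotic-
retention study:

* ``simulate_experiment`` — two-condition ChIP-seq read sets (control
  and mitotic) over a toy genome, with ~10% of binding sites retained in
  mitosis at reduced occupancy, uniform background, optional interphase
  contamination of the mitotic sample, and a truth table of site status.
* ``simulate_fractionation`` — subcellular-fractionation percentage
  tables in which the G2/M sample is a (1-m)/m mixture of control-like
  and truly mitotic cells.
* ``simulate_cell_image`` — two-channel (DNA, protein) cell images with
  known nucleus / cytoplasm / background region means.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicInterval, IntervalSet, ReadSet

DEFAULT_GENOME = {
    "chr2L": 1_000_000,
    "chr2R": 1_000_000,
    "chr3L": 1_000_000,
    "chr4": 1_000_000,
}


@dataclass
class SiteTruth:
    """Ground truth for one simulated binding site."""

    site: GenomicInterval
    occupancy_control: float
    retained: bool
    occupancy_scale_mitotic: float
    at_border: bool = False


@dataclass
class SimulationConfig:
    """Study conditions for the two-condition ChIP-seq simulation.

    ``depth`` is the expected total number of signal (in-site) reads in
    the control condition; per-site means are depth-proportional to a
    log-normal occupancy draw.  Retained sites keep
    ``occupancy_scale_mitotic`` of their control occupancy in the
    mitotic sample; non-retained sites contribute no mitotic signal.
    ``contamination`` adds the stated fraction of a control-like signal
    draw to the mitotic sample (interphase cells passing the sort).
    With ``matched_depth`` the mitotic library is topped up with extra
    uniform background reads so both conditions are sequenced to the
    same expected library size, as matched sequencing runs would be.
    """

    genome: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GENOME))
    n_sites: int = 5000
    retained_fraction: float = 0.1
    background_rate: float = 0.001  # reads per bp, per condition
    depth: int = 250_000  # expected signal reads, control condition
    contamination: float = 0.0  # fraction of control cells in mitotic sample
    fragment_size: int = 36
    occupancy_scale_mitotic: float = 0.3
    occupancy_sigma: float = 0.8  # log-normal spread of site occupancy
    retained_bias: float = 2.5  # retention weight ~ occupancy ** bias
    site_width: int = 200
    min_gap: int = 300  # bp between adjacent sites
    site_free_chroms: tuple[str, ...] = ("chr4",)
    border_sites_fraction: float = 0.1
    border_retention_enrichment: float = 1.0
    border_pad: int = 300
    matched_depth: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.retained_fraction <= 1:
            raise ValueError("retained_fraction must be in [0,1]")
        if not 0 <= self.contamination <= 0.05:
            raise ValueError("contamination must be in [0, 0.05]")
        if self.depth <= 0 or self.n_sites <= 0:
            raise ValueError("depth and n_sites must be positive")
        if not 0 < self.occupancy_scale_mitotic <= 1:
            raise ValueError("occupancy_scale_mitotic must be in (0,1]")


class GenerationError(RuntimeError):
    """Sites could not be placed under the configured geometry."""


def _place_sites(
    cfg: SimulationConfig, rng: np.random.Generator
) -> list[GenomicInterval]:
    """Place non-overlapping sites, at least min_gap apart, allocated to
    site-bearing chromosomes proportionally to length."""
    chroms = [c for c in cfg.genome if c not in cfg.site_free_chroms]
    if not chroms:
        raise GenerationError("no site-bearing chromosomes")
    lengths = np.array([cfg.genome[c] for c in chroms], dtype=float)
    counts = rng.multinomial(cfg.n_sites, lengths / lengths.sum())
    pitch = cfg.site_width + cfg.min_gap
    sites: list[GenomicInterval] = []
    for chrom, n_c in zip(chroms, counts):
        if n_c == 0:
            continue
        L = cfg.genome[chrom]
        slack = L - n_c * pitch
        if slack < 0:
            raise GenerationError(
                f"cannot place {n_c} sites of pitch {pitch} on {chrom} "
                f"({L} bp); enlarge the genome or reduce n_sites"
            )
        offsets = np.sort(rng.integers(0, slack + 1, size=n_c))
        starts = offsets + np.arange(n_c) * pitch
        for i, s in enumerate(starts):
            sites.append(
                GenomicInterval(chrom, int(s), int(s) + cfg.site_width,
                                name=f"site_{chrom}_{i}")
            )
    return sites


def _site_reads(
    sites: list[GenomicInterval],
    counts: np.ndarray,
    fragment_size: int,
    rng: np.random.Generator,
) -> list[tuple[str, int, str]]:
    """Draw 5' read positions so each extended fragment lies within its
    site."""
    reads: list[tuple[str, int, str]] = []
    for site, k in zip(sites, counts):
        if k == 0:
            continue
        span = max(1, site.width - fragment_size)
        strands = rng.random(k) < 0.5
        offsets = rng.integers(0, span, size=k)
        for fwd, off in zip(strands, offsets):
            if fwd:
                reads.append((site.chrom, site.start + int(off), "+"))
            else:
                reads.append(
                    (site.chrom, site.start + int(off) + fragment_size - 1, "-")
                )
    return reads


def _background_reads(
    genome: dict[str, int], n: int, rng: np.random.Generator
) -> list[tuple[str, int, str]]:
    chroms = list(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    counts = rng.multinomial(n, lengths / lengths.sum())
    reads: list[tuple[str, int, str]] = []
    for chrom, k in zip(chroms, counts):
        positions = rng.integers(0, genome[chrom], size=k)
        strands = rng.random(k) < 0.5
        for pos, fwd in zip(positions, strands):
            reads.append((chrom, int(pos), "+" if fwd else "-"))
    return reads


def simulate_experiment(
    cfg: SimulationConfig,
) -> tuple[ReadSet, ReadSet, list[SiteTruth]]:
    """Generate (control, mitotic) read sets and the site truth table.

    Control: per-site Poisson counts with mean depth x occ_i / sum(occ),
    plus uniform background.  Mitotic: retained-site signal scaled by
    ``occupancy_scale_mitotic``, plus background, plus
    ``contamination`` x a control-like signal draw, plus (with
    ``matched_depth``) background top-up to the control library size.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    sites = _place_sites(cfg, rng)
    n = len(sites)

    # log-normal occupancies, mean-normalized to depth / n_sites reads
    occ = rng.lognormal(mean=0.0, sigma=cfg.occupancy_sigma, size=n)
    occ = occ / occ.sum()  # occupancy shares

    # borders and retention: weight ~ occ**bias, optionally enriched at
    # border-proximal sites
    at_border = rng.random(n) < cfg.border_sites_fraction
    n_ret = int(round(cfg.retained_fraction * n))
    weights = occ ** cfg.retained_bias
    weights = weights * np.where(at_border, cfg.border_retention_enrichment, 1.0)
    retained = np.zeros(n, dtype=bool)
    if n_ret > 0:
        chosen = rng.choice(n, size=n_ret, replace=False, p=weights / weights.sum())
        retained[chosen] = True

    truth = [
        SiteTruth(
            site=sites[i],
            occupancy_control=float(cfg.depth * occ[i]),
            retained=bool(retained[i]),
            occupancy_scale_mitotic=cfg.occupancy_scale_mitotic,
            at_border=bool(at_border[i]),
        )
        for i in range(n)
    ]

    genome_bp = sum(cfg.genome.values())
    bg_expected = cfg.background_rate * genome_bp

    # control condition
    ctrl_counts = rng.poisson(cfg.depth * occ)
    ctrl_reads = _site_reads(sites, ctrl_counts, cfg.fragment_size, rng)
    ctrl_reads += _background_reads(cfg.genome, rng.poisson(bg_expected), rng)

    # mitotic condition
    mit_means = np.where(retained, cfg.occupancy_scale_mitotic, 0.0) * cfg.depth * occ
    mit_counts = rng.poisson(mit_means)
    mit_reads = _site_reads(sites, mit_counts, cfg.fragment_size, rng)
    if cfg.contamination > 0:
        cont_counts = rng.poisson(cfg.contamination * cfg.depth * occ)
        mit_reads += _site_reads(sites, cont_counts, cfg.fragment_size, rng)
    mit_reads += _background_reads(cfg.genome, rng.poisson(bg_expected), rng)
    if cfg.matched_depth:
        deficit = (cfg.depth + bg_expected) - (
            float(mit_means.sum()) + cfg.contamination * cfg.depth + bg_expected
        )
        if deficit > 0:
            mit_reads += _background_reads(cfg.genome, rng.poisson(deficit), rng)

    control = ReadSet(reads=ctrl_reads, total_mapped=len(ctrl_reads))
    mitotic = ReadSet(reads=mit_reads, total_mapped=len(mit_reads))
    return control, mitotic, truth


def truth_sites(truth: list[SiteTruth], genome: dict[str, int] | None = None) -> IntervalSet:
    return IntervalSet([t.site for t in truth], genome=genome)


def truth_retained(truth: list[SiteTruth], genome: dict[str, int] | None = None) -> IntervalSet:
    return IntervalSet([t.site for t in truth if t.retained], genome=genome)


def truth_borders(
    truth: list[SiteTruth], pad: int = 300, genome: dict[str, int] | None = None
) -> IntervalSet:
    """Border intervals: padded windows around the border-proximal sites."""
    return IntervalSet(
        [
            GenomicInterval(t.site.chrom, max(0, t.site.start - pad), t.site.end + pad)
            for t in truth
            if t.at_border
        ],
        genome=genome,
    )


def write_truth_tsv(truth: list[SiteTruth], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#chrom\tstart\tend\tname\toccupancy_control\tretained\t"
            "occupancy_scale_mitotic\tat_border\n"
        )
        for t in truth:
            fh.write(
                f"{t.site.chrom}\t{t.site.start}\t{t.site.end}\t{t.site.name}\t"
                f"{t.occupancy_control:.4f}\t{int(t.retained)}\t"
                f"{t.occupancy_scale_mitotic:g}\t{int(t.at_border)}\n"
            )


# ---------------------------------------------------------------------------
# fractionation fixture


FRACTIONS = ("S2", "P2", "S3", "P3")


def _check_percent_vector(v: dict[str, float], label: str) -> None:
    total = sum(v[f] for f in FRACTIONS)
    if abs(total - 100.0) > 0.01:
        raise ValueError(f"{label} percentages sum to {total}, expected 100")


def simulate_fractionation(
    true_control: dict[str, float],
    true_mitotic: dict[str, float],
    mitotic_fraction: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> dict:
    """Observed fractionation percentages for a control culture and a
    G2/M culture that is a mixture of (1-m) control-like and m mitotic
    cells, plus Gaussian measurement noise.  Truth is retained for
    recovery tests.
    """
    _check_percent_vector(true_control, "control")
    _check_percent_vector(true_mitotic, "mitotic")
    if not 0 < mitotic_fraction <= 1:
        raise ValueError("mitotic_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    m = mitotic_fraction
    observed_control = {
        f: true_control[f] + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
        for f in FRACTIONS
    }
    observed_g2m = {
        f: (1 - m) * true_control[f]
        + m * true_mitotic[f]
        + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
        for f in FRACTIONS
    }
    return {
        "control": observed_control,
        "g2m": observed_g2m,
        "mitotic_fraction": m,
        "truth": {"control": dict(true_control), "mitotic": dict(true_mitotic)},
    }


# ---------------------------------------------------------------------------
# cell-image fixture


def simulate_cell_image(
    nucleus_mean: float = 300.0,
    cyto_mean: float = 100.0,
    background_mean: float = 5.0,
    dna_nucleus_mean: float = 200.0,
    dna_background_mean: float = 2.0,
    shape: tuple[int, int] = (128, 128),
    cell_radius: int = 40,
    nucleus_radius: int = 18,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> dict:
    """One synthetic cell: DNA channel bright in the nucleus only; the
    protein channel takes the configured means in nucleus, cytoplasm and
    background.  Returns both channels and the truth masks.
    """
    if nucleus_radius >= cell_radius:
        raise ValueError("nucleus must lie strictly inside the cell")
    if min(nucleus_mean, cyto_mean, background_mean) < 0:
        raise ValueError("region means must be >= 0")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy, cx = shape[0] / 2, shape[1] / 2
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    cell = r2 <= cell_radius**2
    nucleus = r2 <= nucleus_radius**2

    protein = np.full(shape, background_mean, dtype=float)
    protein[cell] = cyto_mean
    protein[nucleus] = nucleus_mean
    dna = np.full(shape, dna_background_mean, dtype=float)
    dna[nucleus] = dna_nucleus_mean
    if noise_sd > 0:
        protein = np.clip(protein + rng.normal(0, noise_sd, shape), 0, None)
        dna = np.clip(dna + rng.normal(0, noise_sd, shape), 0, None)
    return {
        "dna": dna,
        "protein": protein,
        "nucleus_mask": nucleus,
        "cell_mask": cell,
        "cyto_mask": cell & ~nucleus,
    }
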