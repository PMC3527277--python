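"""Subcellular fractionation quantification and the mitotic-index
correction.

Cultures arrested in G2/M are only partly mitotic (typically ~2/3);
observed chromatin-pellet percentages are therefore a mixture of truly
mitotic and residual interphase-like cells.  Given the mitotic index m,
the mitotic-cell chromatin percentage is recovered as

    P3_mitotic = (P3_observed - (1 - m) * P3_control) / m

and retention is reported as the corrected mitotic P3 relative to the
control P3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

FRACTIONS = ("S2", "P2", "S3", "P3")


@dataclass
class FractionationRecord:
    """Per-protein fraction percentages for one condition/replicate."""

    protein: str
    condition: str  # "control" or "G2M"
    percent: dict[str, float]
    mitotic_fraction: float | None = None  # G2/M only
    replicate: str | int = 1

    def __post_init__(self) -> None:
        if self.condition not in ("control", "G2M"):
            raise ValueError("condition must be 'control' or 'G2M'")
        if (self.condition == "G2M") != (self.mitotic_fraction is not None):
            raise ValueError("mitotic_fraction must be present iff condition is G2M")
        total = sum(self.percent.get(f, 0.0) for f in FRACTIONS)
        if abs(total - 100.0) > 0.5:
            raise ValueError(f"fraction percentages sum to {total:.2f}, expected 100")


def normalize_fractions(intensities: dict[str, float]) -> dict[str, float]:
    """Convert raw band intensities to percentages summing to 100."""
    vals = {f: float(intensities[f]) for f in FRACTIONS if f in intensities}
    if any(v < 0 for v in vals.values()):
        raise ValueError("band intensities must be >= 0")
    total = sum(vals.values())
    if total <= 0:
        raise ValueError("all band intensities are zero")
    return {f: 100.0 * v / total for f, v in vals.items()}


@dataclass
class CorrectedP3:
    value: float  # corrected, possibly clipped for export
    raw: float  # before clipping
    clipped: bool
    negative_warning: bool  # noise exceeded the mixture model


def correct_mitotic_p3(
    p3_gm: float, p3_control: float, mitotic_fraction: float
) -> CorrectedP3:
    """Invert the interphase/mitotic mixture for the chromatin pellet:
    corrected = (P3_G2M - (1 - m) * P3_control) / m.

    A negative pre-clip result (measurement noise exceeding the mixture
    model) is flagged, and clipping to [0, 100] applies only to the
    exported value; the raw value is preserved.
    """
    if not 0 < mitotic_fraction <= 1:
        raise ValueError("mitotic_fraction must be in (0, 1]")
    for name, v in (("p3_gm", p3_gm), ("p3_control", p3_control)):
        if not 0 <= v <= 100:
            raise ValueError(f"{name} must be a percentage in [0, 100]")
    raw = (p3_gm - (1 - mitotic_fraction) * p3_control) / mitotic_fraction
    clipped_value = min(100.0, max(0.0, raw))
    return CorrectedP3(
        value=clipped_value,
        raw=raw,
        clipped=clipped_value != raw,
        negative_warning=raw < 0,
    )


def correct_mitotic_fraction(
    observed_gm: float, observed_control: float, mitotic_fraction: float
) -> CorrectedP3:
    """The same mixture inversion applied to an arbitrary fraction
    (extension of the P3-only formula under the same model)."""
    return correct_mitotic_p3(observed_gm, observed_control, mitotic_fraction)


def retention_ratio(corrected_gm_p3: float, control_p3: float) -> float:
    """Corrected mitotic chromatin percentage as a percent of control."""
    if control_p3 <= 0:
        raise ValueError("control_p3 must be positive")
    return 100.0 * corrected_gm_p3 / control_p3


@dataclass
class ProteinSummary:
    protein: str
    control_p3_mean: float
    control_p3_sd: float
    g2m_p3_mean: float
    g2m_p3_sd: float
    corrected_p3_mean: float
    percent_of_control: float
    n_replicates: int
    warnings: list[str] = field(default_factory=list)


def _mean_sd(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else float("nan")
    return float(arr.mean()), sd


def summarize_protein(records: list[FractionationRecord]) -> ProteinSummary:
    """Aggregate replicates of one protein: mean +/- SD (n-1) of P3 per
    condition, mitotic-index-corrected P3, and percent of control."""
    proteins = {r.protein for r in records}
    if len(proteins) != 1:
        raise ValueError(f"records span multiple proteins: {proteins}")
    ctrl = [r for r in records if r.condition == "control"]
    g2m = [r for r in records if r.condition == "G2M"]
    if not ctrl or not g2m:
        raise ValueError("need both control and G2M records")
    c_mean, c_sd = _mean_sd([r.percent["P3"] for r in ctrl])
    g_mean, g_sd = _mean_sd([r.percent["P3"] for r in g2m])
    warnings: list[str] = []
    corrected = []
    for r in g2m:
        assert r.mitotic_fraction is not None
        res = correct_mitotic_p3(r.percent["P3"], c_mean, r.mitotic_fraction)
        if res.negative_warning:
            warnings.append(
                f"replicate {r.replicate}: corrected P3 negative ({res.raw:.2f})"
            )
        corrected.append(res.raw)
    corr_mean = float(np.mean(corrected))
    return ProteinSummary(
        protein=next(iter(proteins)),
        control_p3_mean=c_mean,
        control_p3_sd=c_sd,
        g2m_p3_mean=g_mean,
        g2m_p3_sd=g_sd,
        corrected_p3_mean=corr_mean,
        percent_of_control=retention_ratio(max(corr_mean, 0.0), c_mean),
        n_replicates=len(g2m),
        warnings=warnings,
    )


def read_fractionation_tsv(path: str | Path) -> list[FractionationRecord]:
    """Read a fractionation table: protein, condition, replicate, S2,
    P2, S3, P3, mitotic_fraction (empty for control).  A header line
    ``#units=intensity`` declares raw band intensities (normalized on
    load); default is percentages."""
    lines = Path(path).read_text().splitlines()
    as_intensity = any(l.strip() == "#units=intensity" for l in lines)
    records = []
    errors = []
    for lineno, line in enumerate(lines, 1):
        if not line.strip() or line.startswith("#") or line.startswith("protein\t"):
            continue
        f = line.split("\t")
        try:
            if len(f) < 7:
                raise ValueError("expected >=7 fields")
            vals = dict(zip(FRACTIONS, (float(x) for x in f[3:7])))
            if as_intensity:
                vals = normalize_fractions(vals)
            m = float(f[7]) if len(f) > 7 and f[7].strip() else None
            records.append(
                FractionationRecord(
                    protein=f[0],
                    condition=f[1],
                    percent=vals,
                    mitotic_fraction=m,
                    replicate=f[2],
                )
            )
        except ValueError as exc:
            errors.append(f"{path}:{lineno}: {exc}")
    if errors and not records:
        raise ValueError("; ".join(errors))
    for e in errors:
        logger.warning("skipped row: %s", e)
    return records


def write_summary_tsv(summaries: list[ProteinSummary], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "protein\tcontrol_P3\tcontrol_P3_sd\tG2M_P3\tG2M_P3_sd\t"
            "corrected_mitotic_P3\tpercent_of_control\tn\twarnings\n"
        )
        for s in summaries:
            fh.write(
                f"{s.protein}\t{s.control_p3_mean:.2f}\t{s.control_p3_sd:.2f}\t"
                f"{s.g2m_p3_mean:.2f}\t{s.g2m_p3_sd:.2f}\t"
                f"{s.corrected_p3_mean:.2f}\t{s.percent_of_control:.1f}\t"
                f"{s.n_replicates}\t{';'.join(s.warnings)}\n"
            )
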