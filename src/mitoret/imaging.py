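"""Single-cell protein/DNA colocalization from two-channel images.

The DNA channel is thresholded with the Li minimum cross-entropy method
to give a DNA (chromosome) mask; the protein channel is thresholded the
same way to give a cell mask; the cytoplasmic mask is the cell mask
minus the DNA mask.  The colocalization readout is the ratio of mean
protein intensity on DNA versus in the cytoplasm.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_li
from skimage.measure import label

import imageio.v3 as iio


@dataclass
class CellImagePair:
    """Two registered grayscale channels (DNA, protein) for one cell."""

    dna: np.ndarray
    protein: np.ndarray

    def __post_init__(self) -> None:
        self.dna = np.asarray(self.dna, dtype=float)
        self.protein = np.asarray(self.protein, dtype=float)
        if self.dna.shape != self.protein.shape:
            raise ValueError("channels must have identical shapes")
        if self.dna.min() < 0 or self.protein.min() < 0:
            raise ValueError("intensities must be >= 0")


@dataclass
class MaskSet:
    dna_mask: np.ndarray
    cell_mask: np.ndarray
    cyto_mask: np.ndarray  # cell AND NOT dna, by construction


def li_threshold(image: np.ndarray) -> float:
    """Li-Lee minimum cross-entropy threshold; foreground is strictly
    above the returned value."""
    image = np.asarray(image, dtype=float)
    if np.ptp(image) == 0:
        raise ValueError("constant image has no threshold")
    return float(threshold_li(image))


def _main_object_mask(image: np.ndarray, threshold: float) -> np.ndarray:
    """Foreground mask: the thresholded connected component containing
    the global intensity maximum, holes filled.

    Automatable stand-in for manually outlining the object at the
    signal/background border.
    """
    fg = image > threshold
    if not fg.any():
        raise ValueError("empty foreground at threshold")
    labels = label(fg, connectivity=2)
    peak_idx = np.unravel_index(np.argmax(image), image.shape)
    lab = labels[peak_idx]
    if lab == 0:  # max fell outside foreground (cannot happen for finite images)
        lab = np.argmax(np.bincount(labels[fg])) or 1
    mask = labels == lab
    return ndimage.binary_fill_holes(mask)


def make_masks(pair: CellImagePair) -> MaskSet:
    """DNA mask from the DNA channel, cell mask from the protein
    channel, cytoplasm = cell minus DNA.

    The DNA mask is not constrained to lie inside the cell mask; the
    subtraction is literal.
    """
    dna_mask = _main_object_mask(pair.dna, li_threshold(pair.dna))
    cell_mask = _main_object_mask(pair.protein, li_threshold(pair.protein))
    return MaskSet(
        dna_mask=dna_mask,
        cell_mask=cell_mask,
        cyto_mask=cell_mask & ~dna_mask,
    )


@dataclass
class ColocalizationResult:
    pcg_dna: float
    pcg_cyto: float
    ratio: float


def colocalization_ratio(pair: CellImagePair) -> ColocalizationResult:
    """Mean protein intensity on the DNA mask (PcG_DNA), in the
    cytoplasmic mask (PcG_cyto), and their ratio."""
    masks = make_masks(pair)
    if not masks.dna_mask.any():
        raise ValueError("empty DNA mask")
    pcg_dna = float(pair.protein[masks.dna_mask].mean())
    if not masks.cyto_mask.any():
        return ColocalizationResult(pcg_dna, float("nan"), float("nan"))
    pcg_cyto = float(pair.protein[masks.cyto_mask].mean())
    return ColocalizationResult(pcg_dna, pcg_cyto, pcg_dna / pcg_cyto)


@dataclass
class GroupSummary:
    group: str
    mean: float
    sd: float  # nan for a single cell
    n: int


def batch_summarize(
    ratios: list[float], groups: list[str]
) -> dict[str, GroupSummary]:
    """Per-group mean, SD (n-1 denominator) and n of per-cell ratios.
    No hypothesis testing is performed."""
    if len(ratios) != len(groups):
        raise ValueError("ratios and groups must align")
    out: dict[str, GroupSummary] = {}
    for g in sorted(set(groups)):
        vals = np.array([r for r, gg in zip(ratios, groups) if gg == g], dtype=float)
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
        out[g] = GroupSummary(group=g, mean=float(vals.mean()), sd=sd, n=len(vals))
    return out


def read_image_pair(dna_path: str | Path, protein_path: str | Path) -> CellImagePair:
    """Read 8/16-bit grayscale TIFF/PNG channels into a CellImagePair."""
    return CellImagePair(dna=iio.imread(dna_path), protein=iio.imread(protein_path))


def write_cell_results_tsv(
    rows: list[tuple[str, str, ColocalizationResult]], path: str | Path
) -> None:
    """Rows of (cell id, group, result)."""
    with open(path, "w") as fh:
        fh.write("cell_id\tgroup\tpcg_dna\tpcg_cyto\tratio\n")
        for cell_id, group, res in rows:
            fh.write(
                f"{cell_id}\t{group}\t{res.pcg_dna:.4f}\t"
                f"{res.pcg_cyto:.4f}\t{res.ratio:.4f}\n"
            )
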