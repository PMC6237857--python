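"""Dual-stain histology quantification: fibrosis area and CD8 cell spatial classes.

A trichrome-stained nodule image is segmented for collagenous fibrotic
clusters (dark blue: blue channel minus the mean of red and green, followed
by morphological cleanup and size filtering).  CD8+ T cells are detected as
red-dominant disks, and each cell is classified by its Euclidean distance
from the nearest fibrotic pixel: trapped when within the 5 µm cutoff (or
inside a deposit), infiltrated beyond it.  Fibrosis is reported as percent
positive area relative to the tissue area, with the slide background/cavity
excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import morphology

from .io_formats import FormatError

#: counts-per-fibrosis-area rates are reported per mm^2 (1e6 um^2)
_UM2_PER_MM2 = 1.0e6


@dataclass(frozen=True)
class AnnotatedImage:
    """8-bit RGB pixels with a physical scale in microns per pixel."""

    pixels: np.ndarray  # H x W x 3, uint8
    microns_per_pixel: float

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3:
            raise FormatError(f"expected an RGB image, got shape {p.shape}")
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")


@dataclass(frozen=True)
class FibrosisMask:
    mask: np.ndarray  # boolean H x W
    component_count: int
    positive_pixels: int


@dataclass(frozen=True)
class CellRecord:
    centroid: tuple[float, float]  # (row, col) in pixels
    distance_um: float  # 0 inside fibrosis
    category: str  # "trapped" | "infiltrated"


@dataclass(frozen=True)
class NoduleQuantification:
    fibrosis_area_um2: float
    tissue_area_um2: float
    fibrosis_percent: float
    n_trapped: int
    n_infiltrated: int
    trapped_per_fibrosis_mm2: float
    infiltrated_per_fibrosis_mm2: float
    trapped_fraction_of_cells: float
    cells: tuple[CellRecord, ...] = field(default=())

    def to_dict(self) -> dict:
        return {
            "fibrosis_area_um2": self.fibrosis_area_um2,
            "tissue_area_um2": self.tissue_area_um2,
            "fibrosis_percent": self.fibrosis_percent,
            "n_trapped": self.n_trapped,
            "n_infiltrated": self.n_infiltrated,
            "trapped_per_fibrosis_mm2": self.trapped_per_fibrosis_mm2,
            "infiltrated_per_fibrosis_mm2": self.infiltrated_per_fibrosis_mm2,
            "trapped_fraction_of_cells": self.trapped_fraction_of_cells,
        }


def _channels(img: AnnotatedImage) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    p = np.asarray(img.pixels, dtype=float)
    return p[:, :, 0], p[:, :, 1], p[:, :, 2]


def trichrome_mask(
    img: AnnotatedImage,
    score_threshold: int = 50,
    morph_radius_px: int = 2,
    min_area_px: int = 100,
) -> FibrosisMask:
    """Segment blue-dominant fibrotic clusters.

    Pixel score S = B - (R + G)/2; candidates at S > threshold are cleaned
    by morphological closing then opening with a disk of ``morph_radius_px``
    (0 disables) and 8-connected components below ``min_area_px`` are removed.
    """
    if score_threshold <= 0 or min_area_px <= 0:
        raise ValueError("thresholds must be positive")
    r, g, b = _channels(img)
    cand = (b - (r + g) / 2.0) > score_threshold
    if morph_radius_px > 0:
        disk = morphology.disk(morph_radius_px)
        cand = morphology.closing(cand, disk)
        cand = morphology.opening(cand, disk)
    labeled, n = ndimage.label(cand, structure=np.ones((3, 3), dtype=int))
    if n:
        sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, range(1, n + 1))
        keep = np.flatnonzero(sizes >= min_area_px) + 1
        mask = np.isin(labeled, keep)
    else:
        mask = cand
    n_final = int(ndimage.label(mask, structure=np.ones((3, 3), dtype=int))[1])
    return FibrosisMask(mask=mask, component_count=n_final,
                        positive_pixels=int(mask.sum()))


def tissue_mask(img: AnnotatedImage, background_min_intensity: int = 240) -> np.ndarray:
    """Tissue = complement of near-white background/cavity, closed with radius 2."""
    r, g, b = _channels(img)
    background = (
        (r >= background_min_intensity)
        & (g >= background_min_intensity)
        & (b >= background_min_intensity)
    )
    tissue = ~background
    if tissue.any():
        tissue = morphology.closing(tissue, morphology.disk(2))
    return tissue


def positive_area_fraction(mask: np.ndarray, tissue: np.ndarray) -> float:
    """Percent positive area within tissue: 100 * |positive & tissue| / |tissue|."""
    mask = np.asarray(mask, dtype=bool)
    tissue = np.asarray(tissue, dtype=bool)
    if mask.shape != tissue.shape:
        raise ValueError("masks must share a shape")
    denom = int(tissue.sum())
    if denom == 0:
        raise ValueError("empty tissue mask")
    return 100.0 * int((mask & tissue).sum()) / denom


def detect_cd8_cells(
    img: AnnotatedImage,
    score_threshold: int = 50,
    min_area_px: int = 5,
    max_area_px: int = 500,
) -> list[tuple[float, float]]:
    """Detect red-dominant cell components and return their centroids.

    Pixel score C = R - B; 8-connected components within the
    [min_area_px, max_area_px] size window yield one (row, col) centroid
    each.  The score function suits DAB-brown/red renderings; for real
    micrographs swap in a stain-specific score via the threshold parameters.
    """
    if score_threshold <= 0:
        raise ValueError("score_threshold must be positive")
    if not 0 < min_area_px < max_area_px:
        raise ValueError("need 0 < min_area_px < max_area_px")
    r, _, b = _channels(img)
    cand = (r - b) > score_threshold
    labeled, n = ndimage.label(cand, structure=np.ones((3, 3), dtype=int))
    if not n:
        return []
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, range(1, n + 1))
    keep = np.flatnonzero((sizes >= min_area_px) & (sizes <= max_area_px)) + 1
    if keep.size == 0:
        return []
    centroids = ndimage.center_of_mass(cand, labeled, keep)
    return [(float(r_), float(c_)) for r_, c_ in centroids]


def classify_cells(
    centroids,
    mask: FibrosisMask,
    microns_per_pixel: float,
    cutoff_um: float = 5.0,
) -> list[CellRecord]:
    """Classify each cell centroid as trapped (<= cutoff) or infiltrated.

    Distances come from the Euclidean distance transform of the fibrosis
    mask complement, evaluated at the (rounded) centroid pixel, scaled by
    ``microns_per_pixel``; centroids inside fibrosis get distance 0.  With an
    empty mask every cell is infiltrated (infinite distance convention).
    """
    if microns_per_pixel <= 0:
        raise ValueError("microns_per_pixel must be positive")
    m = np.asarray(mask.mask, dtype=bool)
    h, w = m.shape
    if m.any():
        dist_px = ndimage.distance_transform_edt(~m)
    else:
        dist_px = np.full(m.shape, np.inf)
    out = []
    for row, col in centroids:
        i, j = int(round(row)), int(round(col))
        if not (0 <= i < h and 0 <= j < w):
            raise ValueError(f"centroid ({row}, {col}) outside the image")
        d_um = float(dist_px[i, j]) * microns_per_pixel
        out.append(
            CellRecord(
                centroid=(float(row), float(col)),
                distance_um=d_um,
                category="trapped" if d_um <= cutoff_um else "infiltrated",
            )
        )
    return out


def quantify_nodule(
    img: AnnotatedImage,
    score_threshold: int = 50,
    morph_radius_px: int = 2,
    min_area_px: int = 100,
    cell_score_threshold: int = 50,
    cell_min_area_px: int = 5,
    cell_max_area_px: int = 500,
    cutoff_um: float = 5.0,
    background_min_intensity: int = 240,
) -> NoduleQuantification:
    """Full per-nodule quantification: fibrosis fraction and cell categories.

    Composes tissue and trichrome segmentation, percent positive area, CD8
    detection and the distance-based trapped/infiltrated split; reports raw
    counts, per-fibrosis-area rates (per mm^2) and category fractions.
    """
    tissue = tissue_mask(img, background_min_intensity)
    fib = trichrome_mask(img, score_threshold, morph_radius_px, min_area_px)
    fibrosis_pct = positive_area_fraction(fib.mask, tissue)
    centroids = detect_cd8_cells(
        img, cell_score_threshold, cell_min_area_px, cell_max_area_px
    )
    cells = classify_cells(centroids, fib, img.microns_per_pixel, cutoff_um)
    um2 = img.microns_per_pixel ** 2
    fib_area_um2 = fib.positive_pixels * um2
    n_trapped = sum(c.category == "trapped" for c in cells)
    n_infiltrated = len(cells) - n_trapped
    fib_mm2 = fib_area_um2 / _UM2_PER_MM2
    return NoduleQuantification(
        fibrosis_area_um2=fib_area_um2,
        tissue_area_um2=float(tissue.sum()) * um2,
        fibrosis_percent=fibrosis_pct,
        n_trapped=n_trapped,
        n_infiltrated=n_infiltrated,
        trapped_per_fibrosis_mm2=n_trapped / fib_mm2 if fib_mm2 > 0 else float("nan"),
        infiltrated_per_fibrosis_mm2=(
            n_infiltrated / fib_mm2 if fib_mm2 > 0 else float("nan")
        ),
        trapped_fraction_of_cells=n_trapped / len(cells) if cells else float("nan"),
        cells=tuple(cells),
    )


def sirius_red_mask(
    img: AnnotatedImage,
    score_threshold: int = 50,
    morph_radius_px: int = 2,
    min_area_px: int = 100,
) -> FibrosisMask:
    """Sirius-Red preset: red-dominant collagen, score R - (G + B)/2."""
    if score_threshold <= 0 or min_area_px <= 0:
        raise ValueError("thresholds must be positive")
    r, g, b = _channels(img)
    cand = (r - (g + b) / 2.0) > score_threshold
    if morph_radius_px > 0:
        disk = morphology.disk(morph_radius_px)
        cand = morphology.closing(cand, disk)
        cand = morphology.opening(cand, disk)
    labeled, n = ndimage.label(cand, structure=np.ones((3, 3), dtype=int))
    if n:
        sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, range(1, n + 1))
        keep = np.flatnonzero(sizes >= min_area_px) + 1
        mask = np.isin(labeled, keep)
    else:
        mask = cand
    n_final = int(ndimage.label(mask, structure=np.ones((3, 3), dtype=int))[1])
    return FibrosisMask(mask=mask, component_count=n_final,
                        positive_pixels=int(mask.sum()))
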