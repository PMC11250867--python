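"""Necrosome-like punctum detection and per-cell summaries.

Necrosomes appear in chromogenic stains as small bright puncta, often near
the resolution limit of brightfield slide scanners. Detection is a
difference-of-Gaussian band-pass on the inverted-gray DAB channel: spots
of diameter roughly 2-6 px respond maximally between the small and large
Gaussian scales, while diffuse cytoplasmic signal and single-pixel
quantization noise are suppressed. Local maxima of the DoG response above
a small technical floor become candidate puncta; each is assigned to the
cell whose label covers its maximum, and its amplitude is the mean
inverted-gray intensity over a disk footprint of radius two small-sigmas.

False positives are controlled by the amplitude rule: a punctum is kept
only if its amplitude exceeds twice the mean signal of its parent cell
(cell mean computed over the entire cell, punctum pixels included, by
default). Summaries report the percent of cells containing at least one
accepted punctum, puncta counts per cell, and puncta per 100 cells within
user-supplied region labels (e.g. individual crypts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max

__all__ = [
    "Punctum",
    "CellPunctaSummary",
    "cells_from_nuclei",
    "detect_puncta",
    "filter_puncta",
    "summarize",
    "puncta_per_100_cells",
    "puncta_to_frame",
]


@dataclass
class Punctum:
    x: int
    y: int
    scale_sigma_px: float
    mean_amplitude: float
    parent_cell: int
    accepted: bool | None = None


@dataclass
class CellPunctaSummary:
    n_cells: int
    n_cells_with_puncta: int
    percent_with_puncta: float
    puncta_per_cell: dict[int, int]  # cell label -> accepted punctum count


def cells_from_nuclei(
    hema_gray: np.ndarray,
    pixel_size_um: float,
    expand_um: float = 5.0,
) -> np.ndarray:
    """Fallback cell segmentation: nuclei-seeded watershed-style expansion.

    Segments nuclei on the inverted-gray hematoxylin channel and grows
    each label outward by ``expand_um`` (nearest-seed partition where
    territories meet). A stand-in for a dedicated cell segmenter when only
    a counterstain is available; any externally produced label image can
    be passed to the detector instead.
    """
    from skimage.segmentation import expand_labels

    from .regions import segment_nuclei

    _, labels = segment_nuclei(hema_gray, pixel_size_um)
    return expand_labels(labels, distance=expand_um / pixel_size_um)


def _footprint_mean(img: np.ndarray, y: int, x: int, radius: float) -> float:
    r = int(np.ceil(radius))
    h, w = img.shape
    ys, xs = np.mgrid[max(y - r, 0) : min(y + r + 1, h), max(x - r, 0) : min(x + r + 1, w)]
    inside = (ys - y) ** 2 + (xs - x) ** 2 <= radius**2
    return float(img[ys[inside], xs[inside]].mean())


def detect_puncta(
    dab_gray: np.ndarray,
    cell_labels: np.ndarray,
    sigma_small_px: float = 1.2,
    sigma_large_px: float | None = None,
    dog_floor: float = 2.0,
) -> list[Punctum]:
    """Difference-of-Gaussian spot detection within labeled cells.

    ``DoG = G(sigma_small) * I - G(sigma_large) * I`` (default
    ``sigma_large = 2 * sigma_small``); candidate puncta are local maxima
    of the DoG response above ``dog_floor`` gray units, with non-maximum
    suppression at the small scale. Maxima on background (label 0) are
    discarded. Amplitude is measured on the original image over a disk of
    radius ``2 * sigma_small`` centred on the maximum.
    """
    if sigma_large_px is None:
        sigma_large_px = 2.0 * sigma_small_px
    if not sigma_small_px < sigma_large_px:
        raise ValueError("sigma_small must be smaller than sigma_large")
    cell_labels = np.asarray(cell_labels)
    if not (cell_labels > 0).any():
        raise ValueError("cell label image contains no cells")
    img = np.asarray(dab_gray, float)
    dog = ndi.gaussian_filter(img, sigma_small_px) - ndi.gaussian_filter(img, sigma_large_px)
    coords = peak_local_max(
        dog,
        min_distance=max(int(round(2 * sigma_small_px)), 1),
        threshold_abs=dog_floor,
        exclude_border=False,
    )
    out: list[Punctum] = []
    for y, x in coords:
        parent = int(cell_labels[y, x])
        if parent == 0:
            continue
        amp = _footprint_mean(img, int(y), int(x), 2.0 * sigma_small_px)
        out.append(Punctum(x=int(x), y=int(y), scale_sigma_px=sigma_small_px,
                           mean_amplitude=amp, parent_cell=parent))
    return out


def filter_puncta(
    puncta: list[Punctum],
    dab_gray: np.ndarray,
    cell_labels: np.ndarray,
    multiple: float = 2.0,
    exclude_punctum_pixels: bool = False,
) -> list[Punctum]:
    """Keep puncta strictly brighter than ``multiple`` times their cell mean.

    The cell mean is taken over the parent cell's entire labeled region;
    with ``exclude_punctum_pixels`` the disk footprints of all candidate
    puncta in that cell are excluded from the mean first. A punctum at
    exactly the threshold is rejected (strict inequality). All puncta get
    their ``accepted`` flag set; the returned list holds the accepted ones.
    """
    img = np.asarray(dab_gray, float)
    cell_labels = np.asarray(cell_labels)
    exclude = np.zeros(img.shape, bool)
    if exclude_punctum_pixels:
        yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
        for p in puncta:
            r = 2.0 * p.scale_sigma_px
            exclude |= (yy - p.y) ** 2 + (xx - p.x) ** 2 <= r**2
    means: dict[int, float] = {}
    accepted = []
    for p in puncta:
        if p.parent_cell not in means:
            region = (cell_labels == p.parent_cell) & ~exclude
            means[p.parent_cell] = float(img[region].mean()) if region.any() else np.inf
        p.accepted = p.mean_amplitude > multiple * means[p.parent_cell]
        if p.accepted:
            accepted.append(p)
    return accepted


def summarize(accepted: list[Punctum], cell_labels: np.ndarray) -> CellPunctaSummary:
    """Per-cell accepted-punctum counts over all labeled cells."""
    cell_labels = np.asarray(cell_labels)
    labels = np.unique(cell_labels)
    labels = labels[labels > 0]
    if labels.size == 0:
        raise ValueError("cell label image contains no cells")
    counts = {int(lab): 0 for lab in labels}
    for p in accepted:
        counts[p.parent_cell] += 1
    n_with = sum(1 for c in counts.values() if c > 0)
    return CellPunctaSummary(
        n_cells=len(counts),
        n_cells_with_puncta=n_with,
        percent_with_puncta=100.0 * n_with / len(counts),
        puncta_per_cell=counts,
    )


def puncta_per_100_cells(
    accepted: list[Punctum],
    cell_labels: np.ndarray,
    region_of_cell: dict[int, str],
) -> pd.DataFrame:
    """Accepted puncta per 100 cells within each region (e.g. per crypt).

    ``region_of_cell`` maps cell label -> region id; regions with zero
    cells are impossible by construction, and cells missing from the map
    raise. Returns columns region, n_cells, n_puncta, per_100_cells.
    """
    cell_labels = np.asarray(cell_labels)
    labels = [int(v) for v in np.unique(cell_labels) if v > 0]
    missing = [lab for lab in labels if lab not in region_of_cell]
    if missing:
        raise ValueError(f"cells without a region assignment: {missing}")
    rows: dict[str, dict] = {}
    for lab in labels:
        r = rows.setdefault(region_of_cell[lab], dict(n_cells=0, n_puncta=0))
        r["n_cells"] += 1
    for p in accepted:
        rows[region_of_cell[p.parent_cell]]["n_puncta"] += 1
    table = pd.DataFrame(
        [dict(region=k, **v, per_100_cells=100.0 * v["n_puncta"] / v["n_cells"])
         for k, v in sorted(rows.items())]
    )
    return table


def puncta_to_frame(puncta: list[Punctum]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in puncta],
                        columns=["x", "y", "scale_sigma_px", "mean_amplitude",
                                 "parent_cell", "accepted"])
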