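"""Knockout-controlled staining specificity (S/N index).

The specificity of an immunostain is gauged by comparing matched wild-type
and knockout sections stained in the same run: DAB pixel intensities are
histogrammed inside a dilated nuclear (tissue) mask, the wild-type
histogram is divided by the knockout histogram bin-by-bin to give a
signal-to-noise curve, and a weighted integral of that curve yields a
single scalar index used to rank staining protocols.

Histograms are normalized to frequencies before ratioing, so the index is
insensitive to differences in section area between the two micrographs. A
shared pseudocount keeps the ratio finite in empty knockout bins and makes
the identical-input case exactly 1. The integral weights each bin in
proportion to its intensity, w_i = i / sum_j j: high-intensity bins — where
specific chromogen lives — dominate, and the empty-stain bin contributes
nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stains import (
    Mask,
    auto_threshold,
    dilate_mask,
    hdab_vectors,
    to_inverted_gray,
    unmix,
)

__all__ = [
    "IntensityHistogram",
    "SNResult",
    "masked_histogram",
    "sn_curve",
    "sn_index_from_images",
    "sn_batch",
    "BIN_WEIGHTS",
]

N_BINS = 256
#: intensity-proportional bin weights, summing to 1
BIN_WEIGHTS = np.arange(N_BINS, dtype=float) / np.arange(N_BINS, dtype=float).sum()


@dataclass
class IntensityHistogram:
    """256-bin histogram of 8-bit inverted-gray DAB intensities."""

    counts: np.ndarray
    source: str = "WT"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_BINS,):
            raise ValueError(f"expected {N_BINS} bins, got shape {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("negative bin counts")
        if self.counts.sum() == 0:
            raise ValueError("empty histogram")

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.counts.sum()


@dataclass
class SNResult:
    """Per-bin WT/KO frequency ratio and its scalar specificity index."""

    ratio: np.ndarray
    index: float
    pseudocount: float
    weights: np.ndarray = field(default_factory=lambda: BIN_WEIGHTS.copy())


def masked_histogram(dab_gray: np.ndarray, mask: Mask | np.ndarray, source: str = "WT") -> IntensityHistogram:
    """Histogram of masked pixel intensities."""
    data = mask.data if isinstance(mask, Mask) else np.asarray(mask, bool)
    gray = np.asarray(dab_gray)
    if gray.shape != data.shape:
        raise ValueError("mask and image shapes differ")
    if not data.any():
        raise ValueError("empty mask")
    counts = np.bincount(gray[data].ravel(), minlength=N_BINS)[:N_BINS]
    return IntensityHistogram(counts, source=source)


def sn_curve(
    wt: IntensityHistogram,
    ko: IntensityHistogram,
    pseudocount: float | None = None,
) -> SNResult:
    """Ratio the WT histogram to the KO histogram and integrate.

    ``ratio_i = (f_wt,i + eps) / (f_ko,i + eps)`` on frequencies, with a
    shared pseudocount ``eps`` (default: one count at the smaller sample
    size, 1 / min(n_wt, n_ko)). Index = sum_i w_i * ratio_i with the
    intensity-proportional weights; identical histograms give exactly 1.
    """
    if pseudocount is None:
        pseudocount = 1.0 / min(wt.n_pixels, ko.n_pixels)
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    ratio = (wt.frequencies + pseudocount) / (ko.frequencies + pseudocount)
    index = float(np.sum(BIN_WEIGHTS * ratio))
    return SNResult(ratio=ratio, index=index, pseudocount=pseudocount)


def sn_index_from_images(
    wt_rgb: np.ndarray,
    ko_rgb: np.ndarray,
    dilation_radius_px: int = 5,
    pseudocount: float | None = None,
) -> SNResult:
    """Full specificity pipeline on a matched WT/KO RGB pair.

    Both images are H-DAB unmixed; the wild-type hematoxylin channel is
    auto-thresholded and dilated to define the tissue area of interest,
    and the DAB inverted-gray histograms inside that mask are ratioed.
    """
    vectors = hdab_vectors()
    hists = {}
    for tag, rgb in (("WT", wt_rgb), ("KO", ko_rgb)):
        hema, dab, _ = unmix(rgb, vectors)
        mask = dilate_mask(auto_threshold(to_inverted_gray(hema)), dilation_radius_px)
        hists[tag] = masked_histogram(to_inverted_gray(dab), mask, source=tag)
    return sn_curve(hists["WT"], hists["KO"], pseudocount=pseudocount)


def sn_batch(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    pair_ids: list[str] | None = None,
    dilation_radius_px: int = 5,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Specificity indices for a batch of matched WT/KO pairs.

    All pairs are processed with one shared parameter set (stain matrix,
    threshold rule, dilation radius), as required for indices to be
    comparable. Returns one row per pair with the raw index and the
    batch-relative index (normalized to the batch maximum, for heatmap
    style comparison). Per-pair failures are recorded, not raised.
    """
    if pair_ids is None:
        pair_ids = [f"pair{i}" for i in range(len(pairs))]
    rows = []
    for pid, (wt, ko) in zip(pair_ids, pairs):
        try:
            res = sn_index_from_images(wt, ko, dilation_radius_px, pseudocount)
            rows.append(dict(pair_id=pid, index=res.index, status="ok", error=""))
        except Exception as exc:  # isolate per-pair failures
            rows.append(dict(pair_id=pid, index=np.nan, status="failed", error=str(exc)))
    df = pd.DataFrame(rows)
    ok = df["status"] == "ok"
    top = df.loc[ok, "index"].max()
    df["relative_index"] = np.where(ok & (top > 0), df["index"] / top, np.nan)
    return df
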