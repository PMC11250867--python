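"""Expression gradients along anatomical axes (tissue zonation).

Zonation is quantified by drawing a wide polyline along an anatomical axis
(crypt base to villus tip, pericentral to periportal, white to red pulp)
and averaging the inverted-gray DAB signal over the line width at each
arc-length position — the classic wide-line "plot profile". Axes differ in
physical length, so profiles are normalized to [0, 1] arc length before
averaging across axes, and a LOWESS curve summarizes the pooled or
averaged profile.

Following the published measurement order for this assay, the RGB image is
brightness-rescaled (display range 0-235) before deconvolution; pass
``rescale=False`` to skip it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .stains import hdab_vectors, rescale_brightness, to_inverted_gray, unmix

__all__ = [
    "PolylineAxis",
    "LineProfile",
    "dab_gray_for_zonation",
    "profile",
    "average_profiles",
    "lowess_fit",
    "compare_profiles",
]

#: default line width, approximately two epithelial cell widths
DEFAULT_WIDTH_UM = 27.4


@dataclass(frozen=True)
class PolylineAxis:
    """An ordered polyline axis with a physical sampling width."""

    vertices: tuple[tuple[float, float], ...]  # (x, y) px
    pixel_size_um: float
    width_um: float = DEFAULT_WIDTH_UM

    def __post_init__(self) -> None:
        if len(self.vertices) < 2:
            raise ValueError("axis needs at least 2 vertices")
        if self.width_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("width and pixel size must be positive")
        if self.length_px <= 0:
            raise ValueError("axis has zero length")

    @property
    def width_px(self) -> float:
        return self.width_um / self.pixel_size_um

    @property
    def length_px(self) -> float:
        v = np.asarray(self.vertices, float)
        return float(np.hypot(*(np.diff(v, axis=0).T)).sum())


@dataclass
class LineProfile:
    """Signal along an axis: normalized positions in [0, 1] and mean values."""

    positions: np.ndarray
    values: np.ndarray
    n_samples: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        self.values = np.asarray(self.values, float)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values must match in length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not self.n_samples:
            self.n_samples = self.positions.size


def dab_gray_for_zonation(rgb: np.ndarray, rescale: bool = True) -> np.ndarray:
    """Inverted-gray DAB channel, optionally after the 0-235 display rescale."""
    img = rescale_brightness(rgb) if rescale else np.asarray(rgb)
    _, dab, _ = unmix(img, hdab_vectors())
    return to_inverted_gray(dab)


def _axis_samples(axis: PolylineAxis, step_px: float = 1.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample points along the polyline plus unit normals at each sample."""
    v = np.asarray(axis.vertices, float)
    seg = np.diff(v, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    keep = seg_len > 0
    seg, seg_len = seg[keep], seg_len[keep]
    starts = v[:-1][keep]
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    s = np.arange(0.0, total + step_px / 2, step_px)
    s = np.clip(s, 0.0, total)
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg_len) - 1)
    frac = (s - cum[idx]) / seg_len[idx]
    pts = starts[idx] + seg[idx] * frac[:, None]
    tang = seg[idx] / seg_len[idx][:, None]
    normals = np.column_stack([-tang[:, 1], tang[:, 0]])
    return s / total, pts, normals


def profile(channel_gray: np.ndarray, axis: PolylineAxis) -> LineProfile:
    """Wide-line intensity profile along a polyline axis.

    At every arc-length step (1 px) the value is the mean over equally
    spaced samples (0.5-px spacing) spanning the full width perpendicular
    to the local axis direction; off-grid samples use bilinear
    interpolation. Raises if any sample falls outside the image.
    """
    img = np.asarray(channel_gray, float)
    if axis.width_px < 1.0:
        raise ValueError("line width is below one pixel")
    positions, pts, normals = _axis_samples(axis)
    half = axis.width_px / 2.0
    offsets = np.arange(-half, half + 1e-9, 0.5)
    # sample grid: (n_samples, n_offsets, 2)
    xy = pts[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    xs, ys = xy[..., 0], xy[..., 1]
    h, w = img.shape
    if xs.min() < 0 or ys.min() < 0 or xs.max() > w - 1 or ys.max() > h - 1:
        raise ValueError("axis (including its width) exits the image")
    vals = ndi.map_coordinates(img, [ys.ravel(), xs.ravel()], order=1, mode="nearest")
    vals = vals.reshape(xs.shape).mean(axis=1)
    # guard against duplicate end positions from the final clipped sample
    positions, unique_idx = np.unique(positions, return_index=True)
    return LineProfile(positions, vals[unique_idx])


def average_profiles(profiles: list[LineProfile], grid_n: int = 100) -> LineProfile:
    """Pointwise mean of profiles resampled to a common [0, 1] grid."""
    if not profiles:
        raise ValueError("no profiles to average")
    grid = np.linspace(0.0, 1.0, grid_n)
    stack = np.vstack([np.interp(grid, p.positions, p.values) for p in profiles])
    return LineProfile(grid, stack.mean(axis=0), n_samples=len(profiles))


def lowess_fit(positions: np.ndarray, values: np.ndarray, span: float = 0.3) -> LineProfile:
    """LOWESS (locally weighted linear regression, tricube weights, 2
    robustness iterations) evaluated at the data positions."""
    positions = np.asarray(positions, float)
    values = np.asarray(values, float)
    if positions.size < 10:
        raise ValueError("need at least 10 points for a LOWESS fit")
    if not (0 < span <= 1):
        raise ValueError("span must lie in (0, 1]")
    if span * positions.size < 3:
        raise ValueError("span covers fewer than 3 points per window")
    fitted = _sm_lowess(values, positions, frac=span, it=2, return_sorted=True)
    pos, unique_idx = np.unique(fitted[:, 0], return_index=True)
    return LineProfile(pos, fitted[unique_idx, 1])


def compare_profiles(group_a: list[LineProfile], group_b: list[LineProfile], grid_n: int = 100):
    """Per-position unpaired two-tailed t-tests between two groups of profiles.

    Profiles are resampled to a common grid; at each position Welch-free
    (pooled-variance) two-sample t statistics and p values are computed.
    Positions where both groups are constant get NaN and a flag. Returns a
    DataFrame with columns position, mean_a, mean_b, t, p, flagged.
    """
    import pandas as pd

    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 profiles per group")
    grid = np.linspace(0.0, 1.0, grid_n)
    a = np.vstack([np.interp(grid, p.positions, p.values) for p in group_a])
    b = np.vstack([np.interp(grid, p.positions, p.values) for p in group_b])
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=True)
    zero_var = (a.std(axis=0) == 0) & (b.std(axis=0) == 0)
    same = zero_var & (a.mean(axis=0) == b.mean(axis=0))
    t = np.where(same, 0.0, t)
    p = np.where(same, 1.0, p)
    flagged = zero_var & ~same  # perfectly separated constants: p undefined
    t = np.where(flagged, np.nan, t)
    p = np.where(flagged, np.nan, p)
    return pd.DataFrame(
        dict(position=grid, mean_a=a.mean(axis=0), mean_b=b.mean(axis=0), t=t, p=p, flagged=flagged)
    )
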