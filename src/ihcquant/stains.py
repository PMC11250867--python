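"""Color deconvolution of H-DAB brightfield images.

Brightfield stains obey Beer-Lambert absorption: the optical density
``OD_c = -log10(I_c / I0)`` of each RGB channel is (to a good approximation)
a linear combination of per-stain concentrations. Unmixing therefore reduces
to inverting a 3x3 matrix whose columns are the unit-norm absorption
spectra ("stain vectors") of hematoxylin, DAB and a residual component.

This module provides the fixed H-DAB vector preset, the unmixing itself,
the OD-to-inverted-grayscale conversion used by all downstream intensity
measurements, and the global auto-threshold / mask-dilation helpers that
the quantification modules share.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import disk

__all__ = [
    "HDAB_HEMATOXYLIN",
    "HDAB_DAB",
    "StainVectors",
    "StainChannel",
    "Mask",
    "hdab_vectors",
    "rgb_to_od",
    "od_to_rgb",
    "unmix",
    "to_inverted_gray",
    "inverted_gray_to_od",
    "auto_threshold",
    "dilate_mask",
    "rescale_brightness",
]

# Standard H-DAB absorption spectra (Ruifrok & Johnston preset, as shipped
# by the common color-deconvolution tools).
HDAB_HEMATOXYLIN = np.array([0.650, 0.704, 0.286])
HDAB_DAB = np.array([0.269, 0.568, 0.778])

#: OD ceiling: a stain density of 3.0 transmits 255 * 10^-3 < 1 intensity
#: unit, i.e. the pixel is black at 8-bit depth. Values above carry no
#: information in an 8-bit image.
OD_MAX = 3.0


@dataclass(frozen=True)
class StainVectors:
    """A 3x3 stain matrix; columns are unit-norm OD vectors (one per stain).

    ``matrix[:, 0]`` is hematoxylin, ``matrix[:, 1]`` DAB, ``matrix[:, 2]``
    the residual (complement) vector.
    """

    matrix: np.ndarray
    names: tuple[str, str, str] = ("hematoxylin", "DAB", "residual")

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"stain matrix must be 3x3, got {m.shape}")
        norms = np.linalg.norm(m, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError(f"stain columns must be unit norm, got norms {norms}")
        if np.linalg.cond(m) >= 1e6:
            raise ValueError("stain matrix is ill-conditioned (cond >= 1e6)")
        object.__setattr__(self, "matrix", m)

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)


def hdab_vectors() -> StainVectors:
    """The standard hematoxylin/DAB preset with an orthogonal residual."""
    h = HDAB_HEMATOXYLIN / np.linalg.norm(HDAB_HEMATOXYLIN)
    d = HDAB_DAB / np.linalg.norm(HDAB_DAB)
    r = np.cross(h, d)
    r /= np.linalg.norm(r)
    return StainVectors(np.column_stack([h, d, r]))


@dataclass
class StainChannel:
    """Per-stain concentration (optical density) map after unmixing."""

    name: str
    od_map: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.od_map = np.asarray(self.od_map, dtype=float)
        if np.any(self.od_map < 0):
            raise ValueError("od_map must be nonnegative")


@dataclass
class Mask:
    """Boolean region mask with a provenance tag."""

    data: np.ndarray
    provenance: str = "user-supplied"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)

    @property
    def n_pixels(self) -> int:
        return int(self.data.sum())


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB image, got shape {image.shape}")
    return image


def rgb_to_od(image: np.ndarray) -> np.ndarray:
    """Per-channel optical density: OD = -log10(max(I, 1) / 255)."""
    image = _check_rgb(image).astype(float)
    return -np.log10(np.maximum(image, 1.0) / 255.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_od` with 8-bit quantization."""
    transmit = 255.0 * np.power(10.0, -np.asarray(od, dtype=float))
    return np.clip(np.rint(transmit), 0, 255).astype(np.uint8)


def unmix(
    image: np.ndarray,
    vectors: StainVectors | None = None,
    pixel_size_um: float = 1.0,
) -> tuple[StainChannel, StainChannel, StainChannel]:
    """Unmix an 8-bit RGB image into per-stain concentration maps.

    Negative concentrations (numerical leakage outside the stain simplex)
    are clamped to zero, matching the behaviour of the standard
    color-deconvolution tools.
    """
    if vectors is None:
        vectors = hdab_vectors()
    od = rgb_to_od(image)
    conc = od @ vectors.inverse.T  # per pixel: M^-1 @ OD
    conc = np.clip(conc, 0.0, None)
    return tuple(
        StainChannel(name, conc[..., i], pixel_size_um)
        for i, name in enumerate(vectors.names)
    )


def to_inverted_gray(channel: StainChannel | np.ndarray) -> np.ndarray:
    """Map a stain OD map to an 8-bit "signal" image (more stain = brighter).

    The OD map is first converted back to transmittance gray
    (``255 * 10^-OD``, the appearance of that stain alone on a white
    background) and then inverted, so the output is monotone increasing in
    stain amount: OD 0 -> 0, OD >= 3 -> 255.
    """
    od = channel.od_map if isinstance(channel, StainChannel) else np.asarray(channel, float)
    od = np.clip(od, 0.0, OD_MAX)
    gray = np.rint(255.0 * np.power(10.0, -od))
    return (255 - gray).astype(np.uint8)


def inverted_gray_to_od(gray: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_inverted_gray` (up to 8-bit quantization)."""
    transmit = np.maximum(255.0 - np.asarray(gray, dtype=float), 1.0)
    return -np.log10(transmit / 255.0)


def auto_threshold(gray: np.ndarray, provenance: str = "auto-threshold") -> Mask:
    """Global Otsu threshold of an 8-bit image; foreground = stained (bright).

    Raises on a constant image, where no threshold exists.
    """
    gray = np.asarray(gray)
    if gray.min() == gray.max():
        raise ValueError("cannot threshold a constant image")
    t = threshold_otsu(gray)
    return Mask(gray > t, provenance=provenance)


def dilate_mask(mask: Mask | np.ndarray, radius_px: int) -> Mask:
    """Morphological dilation with a Euclidean disk structuring element."""
    if radius_px < 0:
        raise ValueError("dilation radius must be >= 0")
    data = mask.data if isinstance(mask, Mask) else np.asarray(mask, bool)
    if radius_px == 0:
        return Mask(data.copy(), provenance="dilated-nuclear")
    out = ndi.binary_dilation(data, structure=disk(radius_px))
    return Mask(out, provenance="dilated-nuclear")


def rescale_brightness(image: np.ndarray, lo: int = 0, hi: int = 235) -> np.ndarray:
    """Linear clamp-rescale of each RGB channel from [lo, hi] to [0, 255].

    Mirrors a display brightness/contrast adjustment: values at or above
    ``hi`` saturate to 255. Used by the zonation workflow, which applies
    this adjustment before deconvolution; all other quantification paths
    operate on raw intensities.
    """
    image = np.asarray(image, dtype=float)
    out = (np.clip(image, lo, hi) - lo) * (255.0 / (hi - lo))
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)
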