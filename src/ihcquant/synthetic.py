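"""Synthetic brightfield IHC scenes with exact ground truth.

Real knockout-controlled slide scans are not redistributable, so every
quantification stage in this package is exercised against parametric
scenes rendered here. A scene is described by a :class:`SceneSpec` —
nuclei (hematoxylin-stained ellipses), cytoplasmic DAB (constant, linear
gradient along an axis, or per-cell), subresolution Gaussian puncta, and
vessel rings with an endothelial DAB band — and rendered to an 8-bit RGB
image through the same Beer-Lambert H-DAB mixing model that the
:mod:`ihcquant.stains` module inverts. The renderer returns a
:class:`GroundTruth` holding every planted quantity (label images, per-cell
ODs, puncta tables, the gradient function), so downstream measurements can
be checked against exact expected values rather than against themselves.

Setting ``knockout=True`` zeroes every target-specific DAB contribution
(cytoplasm, puncta, endothelium) while retaining counterstain and
background, emulating a knockout tissue section stained in the same run.

The module also generates the two matrix-level inputs used by
:mod:`ihcquant.expression`: cells-by-genes expression tables with planted
per-ontology detection rates, and gene-by-cluster log-fold-change matrices
with planted zone structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .stains import hdab_vectors, to_inverted_gray

__all__ = [
    "NucleusSpec",
    "PunctumSpec",
    "VesselSpec",
    "ConstantField",
    "LinearGradientField",
    "PerCellField",
    "SceneSpec",
    "GroundTruth",
    "render_scene",
    "make_wt_ko_pair",
    "make_snr_scene",
    "make_gradient_scene",
    "make_nuclei_population_scene",
    "make_puncta_scene",
    "make_vessel_scene",
    "make_area_fraction_scene",
    "make_expression_table",
    "make_logfc_matrix",
]


# ---------------------------------------------------------------------------
# Scene description
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NucleusSpec:
    """An elliptical nucleus plus its surrounding cytoplasm disk.

    ``radius_um`` is the semi-major axis; ``eccentricity`` is the
    minor/major axis ratio (1.0 = circle). The cytoplasm disk (radius
    ``cell_radius_um``, centred on the nucleus) defines the cell body used
    for per-cell DAB and as the parent region of puncta.
    """

    center: tuple[float, float]  # (x, y) in px
    radius_um: float
    eccentricity: float = 1.0
    angle_deg: float = 0.0
    hematoxylin_od: float = 0.6
    dab_od: float = 0.0  # cytoplasmic DAB when the scene uses PerCellField
    nuclear_dab_od: float = 0.0  # DAB inside the object itself (e.g. apoptotic body)
    cell_radius_um: float | None = None
    cls: str = "other"  # planted class: hepatocyte | kupffer | other


@dataclass(frozen=True)
class PunctumSpec:
    """An isotropic Gaussian DAB spot inside a parent cell."""

    center: tuple[float, float]
    sigma_um: float
    peak_dab_od: float
    parent_cell_id: int  # 1-based label of the parent nucleus/cell
    decoy: bool = False  # planted below the acceptance amplitude rule


@dataclass(frozen=True)
class VesselSpec:
    """An annular vessel wall with an endothelial band interior to it.

    The ring (``inner_radius_um``..``outer_radius_um``) carries the
    structural wall stain on the hematoxylin channel; the endothelial band
    (``band_um`` wide, luminal to the inner wall boundary) carries
    target-specific DAB.
    """

    center: tuple[float, float]
    inner_radius_um: float
    outer_radius_um: float
    ring_stain_od: float = 0.8
    endothelial_dab_od: float = 0.0
    band_um: float = 2.0


@dataclass(frozen=True)
class ConstantField:
    od: float

    def __call__(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return np.full_like(np.asarray(x, float), self.od)


@dataclass(frozen=True)
class LinearGradientField:
    """DAB density interpolated linearly along the axis p0 -> p1.

    The scalar position t is the projection onto the axis, clamped to
    [0, 1]; planted density is ``start_od + (end_od - start_od) * t``.
    """

    start_od: float
    end_od: float
    p0: tuple[float, float]
    p1: tuple[float, float]

    def t(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        dx, dy = self.p1[0] - self.p0[0], self.p1[1] - self.p0[1]
        denom = dx * dx + dy * dy
        t = ((np.asarray(x, float) - self.p0[0]) * dx + (np.asarray(y, float) - self.p0[1]) * dy) / denom
        return np.clip(t, 0.0, 1.0)

    def g(self, t: np.ndarray) -> np.ndarray:
        """Planted density as a function of normalized axis position."""
        return self.start_od + (self.end_od - self.start_od) * np.asarray(t, float)

    def __call__(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return self.g(self.t(x, y))


@dataclass(frozen=True)
class PerCellField:
    """Marker: each cell's cytoplasm uses its own ``NucleusSpec.dab_od``."""


@dataclass(frozen=True)
class SceneSpec:
    width_px: int = 256
    height_px: int = 256
    pixel_size_um: float = 0.27
    seed: int = 0
    nuclei: tuple[NucleusSpec, ...] = ()
    cytoplasm: ConstantField | LinearGradientField | PerCellField | None = None
    puncta: tuple[PunctumSpec, ...] = ()
    vessels: tuple[VesselSpec, ...] = ()
    background_hema_od: float = 0.0
    background_dab_od: float = 0.0
    knockout: bool = False
    noise_sigma: float = 0.0  # additive Gaussian noise on 8-bit intensities

    def validate(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0 or self.pixel_size_um <= 0:
            raise ValueError("image dimensions and pixel size must be positive")
        for v in (self.background_hema_od, self.background_dab_od):
            if v < 0:
                raise ValueError("background OD must be nonnegative")
        for i, nuc in enumerate(self.nuclei):
            r_px = nuc.radius_um / self.pixel_size_um
            x, y = nuc.center
            if not (0 <= x - r_px and x + r_px < self.width_px and 0 <= y - r_px and y + r_px < self.height_px):
                raise ValueError(f"nucleus {i + 1} extends outside the image")
            if nuc.hematoxylin_od < 0 or nuc.dab_od < 0 or nuc.nuclear_dab_od < 0 or nuc.radius_um <= 0:
                raise ValueError(f"nucleus {i + 1} has a negative OD or radius")
            if not (0 < nuc.eccentricity <= 1):
                raise ValueError(f"nucleus {i + 1}: eccentricity must be in (0, 1]")
        n = len(self.nuclei)
        for p in self.puncta:
            if not (1 <= p.parent_cell_id <= n):
                raise ValueError(f"punctum parent id {p.parent_cell_id} has no matching nucleus")
            if p.peak_dab_od < 0 or p.sigma_um <= 0:
                raise ValueError("puncta must have nonnegative peak OD and positive sigma")
            x, y = p.center
            if not (0 <= x < self.width_px and 0 <= y < self.height_px):
                raise ValueError("punctum center outside the image")
        for v in self.vessels:
            if not (0 < v.inner_radius_um < v.outer_radius_um):
                raise ValueError("vessel radii must satisfy 0 < inner < outer")
            if v.ring_stain_od < 0 or v.endothelial_dab_od < 0:
                raise ValueError("vessel ODs must be nonnegative")
            r_px = v.outer_radius_um / self.pixel_size_um
            x, y = v.center
            if not (0 <= x - r_px and x + r_px < self.width_px and 0 <= y - r_px and y + r_px < self.height_px):
                raise ValueError("vessel extends outside the image")


@dataclass
class GroundTruth:
    """Every quantity planted into a rendered scene.

    ``label_image`` labels nuclei, ``cell_labels`` labels full cell bodies
    (nucleus + cytoplasm disk); label i corresponds to ``spec.nuclei[i-1]``
    and 0 is background. ``hema_od`` / ``dab_od`` are the exact planted OD
    fields before quantization (wild-type rendering).
    """

    spec: SceneSpec
    label_image: np.ndarray
    cell_labels: np.ndarray
    classes: list[str]
    cell_dab_od: np.ndarray  # planted cytoplasmic OD per cell (label order)
    puncta: pd.DataFrame  # columns: x, y, sigma_px, peak_od, parent, decoy
    vessel_ring_labels: np.ndarray
    vessel_band_labels: np.ndarray
    hema_od: np.ndarray
    dab_od: np.ndarray
    gradient: LinearGradientField | None = None

    def nucleus_table(self) -> pd.DataFrame:
        rows = []
        for i, nuc in enumerate(self.spec.nuclei, start=1):
            rows.append(
                dict(label=i, x=nuc.center[0], y=nuc.center[1], cls=self.classes[i - 1],
                     dab_od=self.cell_dab_od[i - 1])
            )
        return pd.DataFrame(rows)

    def percent_area_above(self, lo: int, hi: int = 255, region: np.ndarray | None = None) -> float:
        """Percent of region pixels whose planted DAB signal falls in [lo, hi].

        Computed from the planted OD field, independently of rendering,
        unmixing or thresholding code paths.
        """
        gray = to_inverted_gray(self.dab_od)
        sel = np.ones_like(gray, bool) if region is None else np.asarray(region, bool)
        if not sel.any():
            raise ValueError("empty region")
        hit = (gray >= lo) & (gray <= hi) & sel
        return 100.0 * hit.sum() / sel.sum()


# ---------------------------------------------------------------------------
# Rasterization helpers
# ---------------------------------------------------------------------------


def _grid(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    y, x = np.mgrid[0 : spec.height_px, 0 : spec.width_px]
    return x.astype(float), y.astype(float)


def _ellipse_mask(x, y, nuc: NucleusSpec, pixel_size_um: float) -> np.ndarray:
    a = nuc.radius_um / pixel_size_um
    b = a * nuc.eccentricity
    th = math.radians(nuc.angle_deg)
    dx, dy = x - nuc.center[0], y - nuc.center[1]
    u = dx * math.cos(th) + dy * math.sin(th)
    v = -dx * math.sin(th) + dy * math.cos(th)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _disk_mask(x, y, center, radius_px: float) -> np.ndarray:
    return (x - center[0]) ** 2 + (y - center[1]) ** 2 <= radius_px**2


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def planted_od_fields(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Rasterize the planted hematoxylin and DAB OD fields (wild-type)."""
    spec.validate()
    x, y = _grid(spec)
    hema = np.full(x.shape, spec.background_hema_od)
    dab = np.full(x.shape, spec.background_dab_od)

    labels = np.zeros(x.shape, dtype=np.int32)
    cells = np.zeros(x.shape, dtype=np.int32)
    classes: list[str] = []
    cell_od = np.zeros(len(spec.nuclei))

    # cytoplasm field over the whole tissue, if a global field is set
    if isinstance(spec.cytoplasm, (ConstantField, LinearGradientField)):
        dab = dab + spec.cytoplasm(x, y)

    for i, nuc in enumerate(spec.nuclei, start=1):
        nmask = _ellipse_mask(x, y, nuc, spec.pixel_size_um)
        hema[nmask] += nuc.hematoxylin_od
        if nuc.nuclear_dab_od:
            dab[nmask] += nuc.nuclear_dab_od
        labels[nmask] = i
        cr = (nuc.cell_radius_um or 2.0 * nuc.radius_um) / spec.pixel_size_um
        cmask = _disk_mask(x, y, nuc.center, cr)
        cells[cmask & (cells == 0)] = i
        cells[nmask] = i
        classes.append(nuc.cls)
        if isinstance(spec.cytoplasm, PerCellField):
            dab[cmask & ~nmask] += nuc.dab_od
            cell_od[i - 1] = nuc.dab_od
        elif isinstance(spec.cytoplasm, ConstantField):
            cell_od[i - 1] = spec.cytoplasm.od
        elif isinstance(spec.cytoplasm, LinearGradientField):
            cell_od[i - 1] = float(spec.cytoplasm(np.array(nuc.center[0]), np.array(nuc.center[1])))

    prows = []
    for p in spec.puncta:
        s_px = p.sigma_um / spec.pixel_size_um
        r2 = (x - p.center[0]) ** 2 + (y - p.center[1]) ** 2
        dab += p.peak_dab_od * np.exp(-r2 / (2.0 * s_px**2))
        prows.append(dict(x=p.center[0], y=p.center[1], sigma_px=s_px,
                          peak_od=p.peak_dab_od, parent=p.parent_cell_id, decoy=p.decoy))

    ring_labels = np.zeros(x.shape, dtype=np.int32)
    band_labels = np.zeros(x.shape, dtype=np.int32)
    for j, v in enumerate(spec.vessels, start=1):
        ri = v.inner_radius_um / spec.pixel_size_um
        ro = v.outer_radius_um / spec.pixel_size_um
        rb = max(ri - v.band_um / spec.pixel_size_um, 0.0)
        r2 = (x - v.center[0]) ** 2 + (y - v.center[1]) ** 2
        ring = (r2 > ri**2) & (r2 <= ro**2)
        band = (r2 > rb**2) & (r2 <= ri**2)
        hema[ring] += v.ring_stain_od
        dab[band] += v.endothelial_dab_od
        ring_labels[ring] = j
        band_labels[band] = j

    puncta_df = pd.DataFrame(prows, columns=["x", "y", "sigma_px", "peak_od", "parent", "decoy"])
    gt = GroundTruth(
        spec=spec, label_image=labels, cell_labels=cells, classes=classes,
        cell_dab_od=cell_od, puncta=puncta_df,
        vessel_ring_labels=ring_labels, vessel_band_labels=band_labels,
        hema_od=hema, dab_od=dab,
        gradient=spec.cytoplasm if isinstance(spec.cytoplasm, LinearGradientField) else None,
    )
    return hema, dab, gt


def _specific_dab(spec: SceneSpec) -> SceneSpec:
    """The spec with all target-specific DAB terms removed (knockout)."""
    nuclei = tuple(replace(n, dab_od=0.0, nuclear_dab_od=0.0) for n in spec.nuclei)
    vessels = tuple(replace(v, endothelial_dab_od=0.0) for v in spec.vessels)
    cyto = spec.cytoplasm
    if isinstance(cyto, ConstantField):
        cyto = ConstantField(0.0)
    elif isinstance(cyto, LinearGradientField):
        cyto = replace(cyto, start_od=0.0, end_od=0.0)
    return replace(spec, nuclei=nuclei, vessels=vessels, cytoplasm=cyto, puncta=(), knockout=False)


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a scene to an 8-bit RGB image plus its ground truth.

    Each pixel obeys Beer-Lambert mixing through the fixed H-DAB stain
    matrix: ``I_c = round(255 * 10^(-sum_s M[c, s] * A_s))``, quantized
    once to 8 bits. Ground truth always describes the wild-type planting,
    also when ``knockout=True`` is rendered.
    """
    hema, dab, gt = planted_od_fields(spec)
    if spec.knockout:
        hema_r, dab_r, _ = planted_od_fields(_specific_dab(spec))
    else:
        hema_r, dab_r = hema, dab
    M = hdab_vectors().matrix
    od_rgb = hema_r[..., None] * M[:, 0] + dab_r[..., None] * M[:, 1]
    img = 255.0 * np.power(10.0, -od_rgb)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img, gt


def make_wt_ko_pair(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Render matched wild-type and knockout images of the same scene."""
    if spec.knockout:
        raise ValueError("pass the wild-type spec; the knockout is derived from it")
    wt, gt = render_scene(spec)
    ko, _ = render_scene(replace(spec, knockout=True))
    return wt, ko, gt


# ---------------------------------------------------------------------------
# Study-condition scene builders
# ---------------------------------------------------------------------------


def make_snr_scene(
    dab_amplitude: float,
    seed: int = 0,
    n_nuclei: int = 40,
    size_px: int = 256,
    pixel_size_um: float = 0.27,
) -> SceneSpec:
    """A field of counterstained nuclei with uniform specific cytoplasmic DAB.

    Used with :func:`make_wt_ko_pair` to emulate matched wild-type/knockout
    sections of the same tissue stained in one run.
    """
    rng = np.random.default_rng(seed)
    margin = 14
    nuclei = []
    for _ in range(n_nuclei):
        cx = rng.uniform(margin, size_px - margin)
        cy = rng.uniform(margin, size_px - margin)
        nuclei.append(
            NucleusSpec(center=(cx, cy), radius_um=rng.uniform(2.2, 3.2),
                        eccentricity=rng.uniform(0.8, 1.0),
                        angle_deg=rng.uniform(0, 180),
                        hematoxylin_od=rng.uniform(0.5, 0.9))
        )
    return SceneSpec(
        width_px=size_px, height_px=size_px, pixel_size_um=pixel_size_um, seed=seed,
        nuclei=tuple(nuclei), cytoplasm=ConstantField(dab_amplitude),
        background_hema_od=0.02, background_dab_od=0.02,
    )


def make_gradient_scene(
    start_od: float = 0.1,
    end_od: float = 1.0,
    seed: int = 0,
    size_px: int = 256,
    pixel_size_um: float = 0.27,
) -> tuple[SceneSpec, LinearGradientField]:
    """A tissue with DAB graded linearly along the horizontal axis."""
    grad = LinearGradientField(start_od, end_od, p0=(0.0, size_px / 2), p1=(size_px - 1.0, size_px / 2))
    spec = SceneSpec(width_px=size_px, height_px=size_px, pixel_size_um=pixel_size_um,
                     seed=seed, cytoplasm=grad, background_hema_od=0.02)
    return spec, grad


def make_nuclei_population_scene(
    n_hepatocyte: int = 15,
    n_kupffer: int = 15,
    seed: int = 0,
    size_px: int = 384,
    pixel_size_um: float = 0.5,
) -> SceneSpec:
    """Well-separated hepatocyte-like and Kupffer-like nuclei on one slide.

    Hepatocyte-like nuclei are large and near-circular (semi-major about
    4-5 um, axis ratio >= 0.9); Kupffer-like nuclei are small and elongated
    (semi-major about 3 um, axis ratio about 0.33), mirroring the
    morphometric criteria used to tell the two apart.
    """
    rng = np.random.default_rng(seed)
    n = n_hepatocyte + n_kupffer
    # place centers on a jittered grid so nuclei never touch
    cols = int(np.ceil(np.sqrt(n)))
    pitch = (size_px - 40) / cols
    centers = []
    for i in range(n):
        gx, gy = i % cols, i // cols
        centers.append((30 + gx * pitch + rng.uniform(-3, 3), 30 + gy * pitch + rng.uniform(-3, 3)))
    order = rng.permutation(n)
    # distinct, well-spaced per-cell cytoplasmic ODs so rank order survives
    # 8-bit quantization of the rendered image
    cell_ods = rng.permutation(np.linspace(0.2, 0.8, n))
    nuclei = []
    for k in range(n):
        cx, cy = centers[order[k]]
        if k < n_hepatocyte:
            nuclei.append(NucleusSpec((cx, cy), radius_um=rng.uniform(4.0, 5.0),
                                      eccentricity=rng.uniform(0.9, 1.0),
                                      angle_deg=rng.uniform(0, 180),
                                      hematoxylin_od=0.8, cls="hepatocyte",
                                      dab_od=float(cell_ods[k])))
        else:
            nuclei.append(NucleusSpec((cx, cy), radius_um=rng.uniform(2.8, 3.2),
                                      eccentricity=rng.uniform(0.30, 0.36),
                                      angle_deg=rng.uniform(0, 180),
                                      hematoxylin_od=0.8, cls="kupffer",
                                      dab_od=float(cell_ods[k])))
    return SceneSpec(width_px=size_px, height_px=size_px, pixel_size_um=pixel_size_um,
                     seed=seed, nuclei=tuple(nuclei), cytoplasm=PerCellField(),
                     background_hema_od=0.02)


def _footprint_mean_gray(base_od: float, peak_od: float, sigma_px: float, radius_px: float) -> float:
    """Mean inverted-gray over a disk footprint centred on a Gaussian punctum."""
    r = int(np.ceil(radius_px)) + 1
    y, x = np.mgrid[-r : r + 1, -r : r + 1]
    r2 = x**2 + y**2
    inside = r2 <= radius_px**2
    od = base_od + peak_od * np.exp(-r2[inside] / (2.0 * sigma_px**2))
    gray = 255.0 - np.rint(255.0 * np.power(10.0, -od))
    return float(gray.mean())


def calibrated_peak_od(
    base_od: float, sigma_px: float, target_mean_gray: float, radius_factor: float = 2.0
) -> float:
    """Peak OD whose footprint-mean inverted-gray equals a target value.

    The footprint is the disk of radius ``radius_factor * sigma`` used by
    the detector to measure punctum amplitude; the mapping from peak OD to
    measured mean gray is monotone, so bisection suffices.
    """
    lo, hi = 0.0, 3.0
    if _footprint_mean_gray(base_od, hi, sigma_px, radius_factor * sigma_px) < target_mean_gray:
        raise ValueError("target amplitude not reachable within the OD dynamic range")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _footprint_mean_gray(base_od, mid, sigma_px, radius_factor * sigma_px) < target_mean_gray:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def make_puncta_scene(
    puncta_per_cell: tuple[int, ...] = (0, 0, 1, 2, 5),
    decoys_per_cell: tuple[int, ...] | None = None,
    planted_multiple: float = 3.0,
    decoy_multiple: float = 1.5,
    seed: int = 0,
    cytoplasm_od: float = 0.15,
    sigma_um: float = 0.405,
    pixel_size_um: float = 0.27,
) -> SceneSpec:
    """Cells carrying planted necrosome-like puncta and optional dim decoys.

    Punctum peak ODs are calibrated so each planted punctum's measured mean
    amplitude (over the detector's 2-sigma disk footprint) is
    ``planted_multiple`` times the parent cell's mean DAB signal, and each
    decoy ``decoy_multiple`` times — straddling the 2x-mean acceptance
    rule from either side. Puncta are spaced at least 4 large-DoG-sigmas
    apart so detections never merge.
    """
    rng = np.random.default_rng(seed)
    n_cells = len(puncta_per_cell)
    if decoys_per_cell is None:
        decoys_per_cell = tuple(0 for _ in puncta_per_cell)
    cell_r_um = 5.4  # 20 px at the default pixel size
    cell_r_px = cell_r_um / pixel_size_um
    pitch = int(np.ceil(2 * cell_r_px + 8))
    cols = int(np.ceil(np.sqrt(n_cells)))
    rowsn = int(np.ceil(n_cells / cols))
    w = cols * pitch + 20
    h = rowsn * pitch + 20

    sigma_px = sigma_um / pixel_size_um
    min_sep = 4 * (2 * 1.2)  # 4 x sigma_large of the default DoG detector

    nuclei = []
    puncta = []
    # estimate the cell-mean gray from the planting: nucleus area carries no
    # cytoplasmic DAB (background only), cytoplasm carries cytoplasm_od
    nuc_r_um = 1.9
    for i in range(n_cells):
        gx, gy = i % cols, i // cols
        cx = 10 + gx * pitch + cell_r_px
        cy = 10 + gy * pitch + cell_r_px
        nuclei.append(NucleusSpec((cx, cy), radius_um=nuc_r_um, hematoxylin_od=0.7,
                                  dab_od=cytoplasm_od, cell_radius_um=cell_r_um))
        base_gray = 255.0 - np.rint(255.0 * 10.0**-cytoplasm_od)
        nuc_gray = 255.0 - np.rint(255.0 * 10.0**-0.0)
        frac_nuc = (nuc_r_um / cell_r_um) ** 2
        cell_mean = frac_nuc * nuc_gray + (1 - frac_nuc) * base_gray
        # place puncta in the cytoplasm annulus, pairwise separated
        placed: list[tuple[float, float]] = []
        n_want = puncta_per_cell[i] + decoys_per_cell[i]
        attempts = 0
        while len(placed) < n_want and attempts < 4000:
            attempts += 1
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(nuc_r_um / pixel_size_um + 3 * sigma_px, cell_r_px - 3 * sigma_px)
            px, py = cx + rad * np.cos(ang), cy + rad * np.sin(ang)
            if all((px - qx) ** 2 + (py - qy) ** 2 >= min_sep**2 for qx, qy in placed):
                placed.append((px, py))
        if len(placed) < n_want:
            raise RuntimeError("could not place puncta with the required spacing")
        for k, (px, py) in enumerate(placed):
            decoy = k >= puncta_per_cell[i]
            mult = decoy_multiple if decoy else planted_multiple
            peak = calibrated_peak_od(cytoplasm_od, sigma_px, mult * cell_mean)
            puncta.append(PunctumSpec((px, py), sigma_um=sigma_um, peak_dab_od=peak,
                                      parent_cell_id=i + 1, decoy=decoy))

    return SceneSpec(width_px=w, height_px=h, pixel_size_um=pixel_size_um, seed=seed,
                     nuclei=tuple(nuclei), cytoplasm=PerCellField(),
                     puncta=tuple(puncta), background_hema_od=0.01)


def make_vessel_scene(
    endothelial_ods: tuple[float, ...] = (0.6, 0.1),
    seed: int = 0,
    pixel_size_um: float = 0.5,
) -> tuple[SceneSpec, list[tuple[int, int, int, int]]]:
    """Vessel cross-sections with stated endothelial DAB; returns seed boxes.

    Each returned box (x0, y0, x1, y1) encloses one vessel, emulating the
    manually chosen regions of a semi-automated vessel workflow.
    """
    n = len(endothelial_ods)
    pitch = 120
    w = n * pitch + 20
    h = pitch + 20
    vessels = []
    boxes = []
    for i, od in enumerate(endothelial_ods):
        cx = 10 + i * pitch + pitch / 2
        cy = h / 2
        vessels.append(VesselSpec((cx, cy), inner_radius_um=12.0, outer_radius_um=18.0,
                                  ring_stain_od=0.9, endothelial_dab_od=od, band_um=2.5))
        half = pitch // 2 - 2
        boxes.append((int(cx - half), int(cy - half), int(cx + half), int(cy + half)))
    spec = SceneSpec(width_px=w, height_px=h, pixel_size_um=pixel_size_um, seed=seed,
                     vessels=tuple(vessels), background_hema_od=0.02, background_dab_od=0.02)
    return spec, boxes


def make_area_fraction_scene(
    target_percent: float = 7.5,
    seed: int = 0,
    size_px: int = 200,
    spot_od: float = 1.0,
    pixel_size_um: float = 0.5,
) -> tuple[SceneSpec, np.ndarray, float]:
    """A region with bright DAB disks covering a known analytic area fraction.

    Returns the scene, the region mask (the full image) and the analytic
    percent of the region covered by the planted disks (continuous
    geometry, before rasterization).
    """
    rng = np.random.default_rng(seed)
    region_area = float(size_px * size_px)
    n_spots = 6
    spot_area = region_area * target_percent / 100.0 / n_spots
    r_px = math.sqrt(spot_area / math.pi)
    # place spots without overlap so areas add exactly
    centers: list[tuple[float, float]] = []
    while len(centers) < n_spots:
        cx = rng.uniform(r_px + 2, size_px - r_px - 2)
        cy = rng.uniform(r_px + 2, size_px - r_px - 2)
        if all((cx - qx) ** 2 + (cy - qy) ** 2 >= (2 * r_px + 2) ** 2 for qx, qy in centers):
            centers.append((cx, cy))
    r_um = r_px * pixel_size_um
    # DAB+ disks rendered as counterstain-free objects carrying the
    # chromogen directly (apoptotic-body-like signal in a uniform region)
    nuclei = tuple(
        NucleusSpec((cx, cy), radius_um=r_um, hematoxylin_od=0.0, nuclear_dab_od=spot_od)
        for cx, cy in centers
    )
    spec = SceneSpec(width_px=size_px, height_px=size_px, pixel_size_um=pixel_size_um,
                     seed=seed, nuclei=nuclei, background_dab_od=0.02)
    region = np.ones((size_px, size_px), dtype=bool)
    analytic_percent = 100.0 * n_spots * math.pi * r_px**2 / region_area
    return spec, region, analytic_percent


# ---------------------------------------------------------------------------
# Synthetic expression matrices
# ---------------------------------------------------------------------------


def make_expression_table(
    rates: pd.DataFrame,
    n_cells_per_group: int = 500,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cells-by-genes table with planted per-ontology detection rates.

    ``rates`` has one row per (ontology, tissue) group — index of tuples or
    a MultiIndex — and one column per gene, holding the probability that a
    cell of that group expresses the gene (value > 0). Expressing cells get
    a positive log-normal magnitude. Returns (expression table, cell
    metadata with ``ontology`` and ``tissue`` columns).
    """
    rng = np.random.default_rng(seed)
    genes = list(rates.columns)
    blocks = []
    meta = []
    for key, row in rates.iterrows():
        ontology, tissue = key if isinstance(key, tuple) else (key, "all")
        expressed = rng.random((n_cells_per_group, len(genes))) < row.to_numpy()[None, :]
        magnitude = rng.lognormal(mean=0.0, sigma=0.5, size=expressed.shape)
        blocks.append(np.where(expressed, magnitude, 0.0))
        meta.extend({"ontology": ontology, "tissue": tissue} for _ in range(n_cells_per_group))
    table = pd.DataFrame(np.vstack(blocks), columns=genes)
    return table, pd.DataFrame(meta)


def make_logfc_matrix(
    n_clusters: int = 6,
    zone_gene_sets: dict[str, list[str]] | None = None,
    planted_zone_clusters: dict[str, list[int]] | None = None,
    seed: int = 0,
    noise_sd: float = 0.3,
    planted_lfc: float = 2.0,
) -> pd.DataFrame:
    """Gene-by-cluster log-fold-change matrix with planted zone structure.

    Genes in a zone's marker set receive a large positive log-fold change
    in that zone's planted clusters, small noise elsewhere — the shape of a
    one-vs-rest differential-expression summary.
    """
    rng = np.random.default_rng(seed)
    if zone_gene_sets is None:
        zone_gene_sets = {
            "white_pulp": ["Cd19", "Ms4a1", "Cd3e"],
            "red_pulp": ["Hba-a1", "Alas2", "Slc4a1"],
            "marginal_zone": ["Marco", "Cd209b", "Sn"],
        }
        planted_zone_clusters = {"white_pulp": [0, 1], "red_pulp": [2, 3], "marginal_zone": [4]}
    if planted_zone_clusters is None:
        raise ValueError("planted_zone_clusters required when zone_gene_sets is given")
    pathway = ["Casp8", "Ripk1", "Ripk3", "Mlkl"]
    genes = sorted({g for gs in zone_gene_sets.values() for g in gs} | set(pathway))
    mat = rng.normal(0.0, noise_sd, size=(len(genes), n_clusters))
    df = pd.DataFrame(mat, index=genes, columns=[str(c) for c in range(n_clusters)])
    for zone, gs in zone_gene_sets.items():
        for c in planted_zone_clusters[zone]:
            df.loc[gs, str(c)] += planted_lfc + rng.normal(0, noise_sd, size=len(gs))
    return df
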