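"""Reading and writing images, scene specifications and axis files."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .synthetic import (
    ConstantField,
    LinearGradientField,
    NucleusSpec,
    PerCellField,
    PunctumSpec,
    SceneSpec,
    VesselSpec,
)
from .zonation import PolylineAxis

__all__ = [
    "read_rgb",
    "write_rgb",
    "write_label_image",
    "read_label_image",
    "scene_to_dict",
    "scene_from_dict",
    "load_scene",
    "save_scene",
    "load_axes_csv",
]


def read_rgb(path: str | Path) -> np.ndarray:
    img = tifffile.imread(str(path)) if str(path).lower().endswith((".tif", ".tiff")) else None
    if img is None:
        import imageio.v3 as iio

        img = iio.imread(str(path))
    img = np.asarray(img)
    if img.ndim == 3 and img.shape[2] == 4:  # drop alpha
        img = img[..., :3]
    if img.ndim != 3 or img.shape[2] != 3 or img.dtype != np.uint8:
        raise ValueError(f"{path}: expected an 8-bit RGB image, got {img.shape} {img.dtype}")
    return img


def write_rgb(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(image, np.uint8), photometric="rgb")


def write_label_image(path: str | Path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels")
    tifffile.imwrite(str(path), labels.astype(np.uint16))


def read_label_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int32)


# ---------------------------------------------------------------------------
# Scene spec (de)serialization
# ---------------------------------------------------------------------------

_FIELD_TAGS = {"constant": ConstantField, "gradient": LinearGradientField, "per_cell": PerCellField}


def _cytoplasm_to_dict(f):
    if f is None:
        return None
    if isinstance(f, ConstantField):
        return {"kind": "constant", "od": float(f.od)}
    if isinstance(f, LinearGradientField):
        return {"kind": "gradient", "start_od": float(f.start_od), "end_od": float(f.end_od),
                "p0": [float(v) for v in f.p0], "p1": [float(v) for v in f.p1]}
    if isinstance(f, PerCellField):
        return {"kind": "per_cell"}
    raise TypeError(f"unknown cytoplasm field {type(f)}")


def _cytoplasm_from_dict(d):
    if d is None:
        return None
    kind = d["kind"]
    if kind == "constant":
        return ConstantField(float(d["od"]))
    if kind == "gradient":
        return LinearGradientField(float(d["start_od"]), float(d["end_od"]),
                                   tuple(d["p0"]), tuple(d["p1"]))
    if kind == "per_cell":
        return PerCellField()
    raise ValueError(f"unknown cytoplasm kind {kind!r}")


def _xy(point) -> list[float]:
    return [float(point[0]), float(point[1])]


def scene_to_dict(spec: SceneSpec) -> dict:
    return {
        "width_px": int(spec.width_px),
        "height_px": int(spec.height_px),
        "pixel_size_um": float(spec.pixel_size_um),
        "seed": int(spec.seed),
        "knockout": bool(spec.knockout),
        "noise_sigma": float(spec.noise_sigma),
        "background_hema_od": float(spec.background_hema_od),
        "background_dab_od": float(spec.background_dab_od),
        "cytoplasm": _cytoplasm_to_dict(spec.cytoplasm),
        "nuclei": [
            {"center": _xy(n.center), "radius_um": float(n.radius_um),
             "eccentricity": float(n.eccentricity), "angle_deg": float(n.angle_deg),
             "hematoxylin_od": float(n.hematoxylin_od), "dab_od": float(n.dab_od),
             "nuclear_dab_od": float(n.nuclear_dab_od),
             "cell_radius_um": None if n.cell_radius_um is None else float(n.cell_radius_um),
             "cls": n.cls}
            for n in spec.nuclei
        ],
        "puncta": [
            {"center": _xy(p.center), "sigma_um": float(p.sigma_um),
             "peak_dab_od": float(p.peak_dab_od),
             "parent_cell_id": int(p.parent_cell_id), "decoy": bool(p.decoy)}
            for p in spec.puncta
        ],
        "vessels": [
            {"center": _xy(v.center), "inner_radius_um": float(v.inner_radius_um),
             "outer_radius_um": float(v.outer_radius_um), "ring_stain_od": float(v.ring_stain_od),
             "endothelial_dab_od": float(v.endothelial_dab_od), "band_um": float(v.band_um)}
            for v in spec.vessels
        ],
    }


def scene_from_dict(d: dict) -> SceneSpec:
    return SceneSpec(
        width_px=int(d["width_px"]),
        height_px=int(d["height_px"]),
        pixel_size_um=float(d["pixel_size_um"]),
        seed=int(d.get("seed", 0)),
        knockout=bool(d.get("knockout", False)),
        noise_sigma=float(d.get("noise_sigma", 0.0)),
        background_hema_od=float(d.get("background_hema_od", 0.0)),
        background_dab_od=float(d.get("background_dab_od", 0.0)),
        cytoplasm=_cytoplasm_from_dict(d.get("cytoplasm")),
        nuclei=tuple(
            NucleusSpec(center=tuple(n["center"]), radius_um=float(n["radius_um"]),
                        eccentricity=float(n.get("eccentricity", 1.0)),
                        angle_deg=float(n.get("angle_deg", 0.0)),
                        hematoxylin_od=float(n.get("hematoxylin_od", 0.6)),
                        dab_od=float(n.get("dab_od", 0.0)),
                        nuclear_dab_od=float(n.get("nuclear_dab_od", 0.0)),
                        cell_radius_um=n.get("cell_radius_um"),
                        cls=n.get("cls", "other"))
            for n in d.get("nuclei", [])
        ),
        puncta=tuple(
            PunctumSpec(center=tuple(p["center"]), sigma_um=float(p["sigma_um"]),
                        peak_dab_od=float(p["peak_dab_od"]),
                        parent_cell_id=int(p["parent_cell_id"]),
                        decoy=bool(p.get("decoy", False)))
            for p in d.get("puncta", [])
        ),
        vessels=tuple(
            VesselSpec(center=tuple(v["center"]), inner_radius_um=float(v["inner_radius_um"]),
                       outer_radius_um=float(v["outer_radius_um"]),
                       ring_stain_od=float(v.get("ring_stain_od", 0.8)),
                       endothelial_dab_od=float(v.get("endothelial_dab_od", 0.0)),
                       band_um=float(v.get("band_um", 2.0)))
            for v in d.get("vessels", [])
        ),
    )


def save_scene(path: str | Path, spec: SceneSpec) -> None:
    Path(path).write_text(yaml.safe_dump(scene_to_dict(spec), sort_keys=False))


def load_scene(path: str | Path) -> SceneSpec:
    return scene_from_dict(yaml.safe_load(Path(path).read_text()))


def load_axes_csv(path: str | Path, pixel_size_um: float, width_um: float) -> list[PolylineAxis]:
    """Axes from a CSV with columns axis_id, x, y (vertices in order)."""
    df = pd.read_csv(path)
    axes = []
    for _, grp in df.groupby("axis_id", sort=True):
        verts = tuple(zip(grp["x"].astype(float), grp["y"].astype(float)))
        axes.append(PolylineAxis(verts, pixel_size_um=pixel_size_um, width_um=width_um))
    return axes
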