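"""Tabular and image I/O for the pipeline's external interfaces.

Formats:

* recovery curves — long CSV with columns ``cell_id, objective_label,
  omega_um, time_s, intensity, prebleach_level``;
* per-cell fit tables and per-group summaries — plain CSV via pandas;
* polygon outlines — CSV vertex tables (``x_um, y_um, cell_id``);
* binary cell masks — single-channel PNG/TIFF (nonzero = cell), with the
  pixel size supplied by the caller.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .models import BeamProfile, FrapCurve
from .shape import CellShape, DEFAULT_PIXEL_SIZE_UM

__all__ = [
    "curves_to_frame",
    "frame_to_curves",
    "write_curves_csv",
    "read_curves_csv",
    "write_mask",
    "read_mask",
    "polygons_to_frame",
    "frame_to_polygons",
]

CURVE_COLUMNS = ["cell_id", "objective_label", "omega_um", "time_s", "intensity", "prebleach_level"]


def curves_to_frame(curves: Iterable[FrapCurve]) -> pd.DataFrame:
    """Flatten recovery curves into the long-format curve table."""
    parts = []
    for c in curves:
        parts.append(
            pd.DataFrame(
                {
                    "cell_id": c.cell_id,
                    "objective_label": c.beam.objective_label,
                    "omega_um": c.beam.omega,
                    "time_s": c.times,
                    "intensity": c.intensities,
                    "prebleach_level": c.prebleach_level,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)[CURVE_COLUMNS]


def frame_to_curves(df: pd.DataFrame) -> list[FrapCurve]:
    """Reassemble FrapCurve objects from a long-format curve table."""
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"curve table is missing columns: {missing}")
    curves = []
    for (cell_id, obj, omega, pre), g in df.groupby(
        ["cell_id", "objective_label", "omega_um", "prebleach_level"], sort=False
    ):
        g = g.sort_values("time_s")
        beam = BeamProfile(objective_label=str(obj), omega=float(omega))
        curves.append(
            FrapCurve(
                times=g["time_s"].to_numpy(),
                intensities=g["intensity"].to_numpy(),
                prebleach_level=float(pre),
                beam=beam,
                cell_id=str(cell_id),
            )
        )
    return curves


def write_curves_csv(curves: Iterable[FrapCurve], path: str | Path) -> None:
    curves_to_frame(curves).to_csv(path, index=False)


def read_curves_csv(path: str | Path) -> list[FrapCurve]:
    return frame_to_curves(pd.read_csv(path))


def write_mask(shape: CellShape, path: str | Path, ground_truth_sidecar: bool = True) -> None:
    """Save a cell mask as an 8-bit single-channel image (255 = cell).

    Polygons are rasterized first.  When the shape carries a ground-truth
    lobe count, a small JSON sidecar (``<path>.json``) records it together
    with the pixel size.
    """
    from .shape import rasterize_polygon

    mask = shape.mask if shape.mask is not None else rasterize_polygon(
        shape.boundary, shape.pixel_size_um
    )
    img = Image.fromarray((mask.astype(np.uint8)) * 255, mode="L")
    img.save(path)
    if ground_truth_sidecar:
        meta = {
            "pixel_size_um": shape.pixel_size_um,
            "cell_id": shape.cell_id,
            "genotype_label": shape.genotype_label,
            "true_lobe_count": shape.true_lobe_count,
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def read_mask(path: str | Path, pixel_size_um: float | None = None) -> CellShape:
    """Load a cell mask image (nonzero = cell), with optional JSON sidecar."""
    arr = np.asarray(Image.open(path).convert("L")) > 0
    meta = {}
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um", DEFAULT_PIXEL_SIZE_UM)
    shape = CellShape(
        mask=arr,
        pixel_size_um=float(px),
        cell_id=str(meta.get("cell_id", "")),
        genotype_label=str(meta.get("genotype_label", "")),
        true_lobe_count=meta.get("true_lobe_count"),
    )
    return shape


def polygons_to_frame(shapes: Sequence[CellShape]) -> pd.DataFrame:
    """Vertex table (x_um, y_um, cell_id) for polygon-backed shapes."""
    parts = []
    for s in shapes:
        if s.boundary is None:
            raise ValueError(f"shape {s.cell_id!r} has no polygon boundary")
        parts.append(
            pd.DataFrame(
                {"x_um": s.boundary[:, 0], "y_um": s.boundary[:, 1], "cell_id": s.cell_id}
            )
        )
    return pd.concat(parts, ignore_index=True)


def frame_to_polygons(df: pd.DataFrame, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> list[CellShape]:
    shapes = []
    for cell_id, g in df.groupby("cell_id", sort=False):
        shapes.append(
            CellShape(
                boundary=g[["x_um", "y_um"]].to_numpy(),
                pixel_size_um=pixel_size_um,
                cell_id=str(cell_id),
            )
        )
    return shapes
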