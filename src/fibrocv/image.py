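"""Registered binary tissue-label masks and their on-disk representation.

A :class:`LabeledTissueImage` holds the three segmented channels used
throughout the pipeline — extracellular space (ES), fibroblasts (F) and
myofibroblasts (MF) — as boolean rasters of equal shape, together with the
physical pixel size and the myocyte orientation convention (images are
analysed with the myocyte long axis parallel to the X axis, i.e. image
columns).  The three masks partition the non-myocyte space: ES excludes
pixels claimed by F or MF, and F and MF are mutually disjoint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["LabeledTissueImage", "save_image", "load_image"]


@dataclass
class LabeledTissueImage:
    """Binary ES / fibroblast / myofibroblast masks with pixel metadata.

    Parameters
    ----------
    es_mask, fibroblast_mask, myofibroblast_mask
        Boolean arrays of identical shape ``(rows, cols)``; rows run along
        the image Y axis, columns along X (the myocyte long axis for
        ``myocyte_axis == "x-aligned"``).
    pixel_size_nm
        Physical edge length of one pixel in nanometres (acquisition
        default 378 nm).
    myocyte_axis
        ``"x-aligned"`` when the myocyte long axis runs along image
        columns, ``"cross-section"`` for axial cross-section images.
    provenance
        Free-form origin note (generator spec repr or file path).
    """

    es_mask: np.ndarray
    fibroblast_mask: np.ndarray
    myofibroblast_mask: np.ndarray
    pixel_size_nm: float = 378.0
    myocyte_axis: str = "x-aligned"
    provenance: str = "unknown"
    group: str | None = None

    def __post_init__(self) -> None:
        self.es_mask = np.asarray(self.es_mask, dtype=bool)
        self.fibroblast_mask = np.asarray(self.fibroblast_mask, dtype=bool)
        self.myofibroblast_mask = np.asarray(self.myofibroblast_mask, dtype=bool)
        if not (
            self.es_mask.shape
            == self.fibroblast_mask.shape
            == self.myofibroblast_mask.shape
        ):
            raise ValueError("all three masks must have the same shape")
        if self.es_mask.ndim != 2:
            raise ValueError("masks must be 2D rasters")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if np.any(self.fibroblast_mask & self.myofibroblast_mask):
            raise ValueError("fibroblast and myofibroblast masks must be disjoint")
        if self.myocyte_axis not in ("x-aligned", "cross-section"):
            raise ValueError(f"unknown myocyte_axis {self.myocyte_axis!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.es_mask.shape

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / 1000.0

    @property
    def extent_um(self) -> tuple[float, float]:
        """Physical size ``(height, width)`` of the raster in micrometres."""
        ny, nx = self.shape
        return (ny * self.pixel_size_um, nx * self.pixel_size_um)

    def nonmyocyte_mask(self) -> np.ndarray:
        """Combined non-myocyte mask (ES or F or MF)."""
        return self.es_mask | self.fibroblast_mask | self.myofibroblast_mask


_CHANNELS = ("es", "fibroblast", "myofibroblast")


def save_image(image: LabeledTissueImage, out_dir: str | Path, stem: str = "tissue") -> Path:
    """Write the three masks as 8-bit single-channel TIFFs plus a JSON sidecar.

    Returns the path of the sidecar file.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in _CHANNELS:
        mask = getattr(image, f"{name}_mask")
        tifffile.imwrite(
            out_dir / f"{stem}_{name}.tif", (mask.astype(np.uint8) * 255)
        )
    sidecar = {
        "pixel_size_nm": image.pixel_size_nm,
        "myocyte_axis": image.myocyte_axis,
        "provenance": image.provenance,
        "group": image.group,
        "channels": {name: f"{stem}_{name}.tif" for name in _CHANNELS},
    }
    sidecar_path = out_dir / f"{stem}.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return sidecar_path


def load_image(sidecar_path: str | Path) -> LabeledTissueImage:
    """Read a mask set written by :func:`save_image`."""
    sidecar_path = Path(sidecar_path)
    meta = json.loads(sidecar_path.read_text())
    masks = {}
    for name in _CHANNELS:
        arr = tifffile.imread(sidecar_path.parent / meta["channels"][name])
        masks[f"{name}_mask"] = arr > 0
    return LabeledTissueImage(
        pixel_size_nm=meta["pixel_size_nm"],
        myocyte_axis=meta["myocyte_axis"],
        provenance=str(sidecar_path),
        group=meta.get("group"),
        **masks,
    )
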