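"""Fibrosis composition, heterogeneity, and patch morphometry.

The non-myocyte volume fraction of a region is the sum of its
extracellular-space, fibroblast and myofibroblast area fractions,

    V_nm = V_e + V_f + V_mf,

and fibrosis of a heart-failure sample is the excess of its V_nm over the
donor-group mean.  Intra-subject heterogeneity is quantified by tiling the
region of interest into 50 um x 50 um sub-images and taking the sample
standard deviation of the per-tile V_nm (sigma_intra, reported in percent).
Patch morphometry runs connected-component analysis on the combined
non-myocyte mask, keeping components larger than 150 um^2 and describing
each by the ellipse with matching second central moments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

from .image import LabeledTissueImage

__all__ = [
    "CompositionFractions",
    "HeterogeneityProfile",
    "PatchFeatures",
    "compute_fractions",
    "compute_fibrosis",
    "heterogeneity_profile",
    "patch_geometry",
    "subject_table",
    "tile_edges",
]


@dataclass(frozen=True)
class CompositionFractions:
    """Area fractions of the labeled classes within one region of interest."""

    v_e: float
    v_f: float
    v_mf: float
    v_nm: float
    roi_area_um2: float


@dataclass
class HeterogeneityProfile:
    """Per-tile V_nm values and their dispersion for one subject.

    ``sigma_intra`` is the sample SD (n-1 denominator) of the tile V_nm
    values expressed in percent; ``histogram`` holds probability per bin.
    """

    tile_vnm: np.ndarray  # 2D array (tile rows, tile cols), fractions
    tile_edge_um: float
    mean_vnm: float
    sigma_intra: float
    histogram: np.ndarray
    bin_edges: np.ndarray

    @property
    def n_tiles(self) -> int:
        return self.tile_vnm.size


@dataclass(frozen=True)
class PatchFeatures:
    """Morphometry of fibrotic patches above the area threshold.

    ``mean_axis_ratio`` is the major/minor axis ratio (>= 1), the ratio
    definition of eccentricity used in this field; the standard ellipse
    eccentricity in [0, 1) is also reported as ``mean_eccentricity``.
    Feature fields are NaN when no component survives the threshold.
    """

    n_patches: int
    largest_area_um2: float
    mean_area_um2: float
    mean_major_axis_um: float
    mean_minor_axis_um: float
    mean_axis_ratio: float
    mean_eccentricity: float


def _resolve_roi(shape: tuple[int, int], roi) -> tuple[slice, slice]:
    if roi is None:
        return slice(0, shape[0]), slice(0, shape[1])
    r0, r1, c0, c1 = roi
    if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
        raise ValueError(f"roi {roi} outside image bounds {shape} or empty")
    return slice(r0, r1), slice(c0, c1)


def compute_fractions(image: LabeledTissueImage, roi=None) -> CompositionFractions:
    """Pixel-count area fractions of ES, F, MF and their sum V_nm.

    Parameters
    ----------
    image
        Labeled tissue image.
    roi
        Optional ``(row0, row1, col0, col1)`` rectangle in pixels; the full
        image when omitted.
    """
    rs, cs = _resolve_roi(image.shape, roi)
    es = image.es_mask[rs, cs]
    f = image.fibroblast_mask[rs, cs]
    mf = image.myofibroblast_mask[rs, cs]
    if es.size == 0:
        raise ValueError("empty roi")
    if np.any(f & mf):
        raise ValueError("fibroblast and myofibroblast masks overlap in roi")
    n = es.size
    v_e = float(np.count_nonzero(es)) / n
    v_f = float(np.count_nonzero(f)) / n
    v_mf = float(np.count_nonzero(mf)) / n
    return CompositionFractions(
        v_e=v_e,
        v_f=v_f,
        v_mf=v_mf,
        v_nm=v_e + v_f + v_mf,
        roi_area_um2=n * image.pixel_size_um**2,
    )


def compute_fibrosis(vnm_sample: float, donor_mean_vnm: float) -> float:
    """Fibrosis as the increase of V_nm over the donor-group mean.

    May be negative for samples below the donor mean; returned as-is.
    """
    if not (0.0 <= vnm_sample <= 1.0 and 0.0 <= donor_mean_vnm <= 1.0):
        raise ValueError("V_nm values must lie in [0, 1]")
    return vnm_sample - donor_mean_vnm


def tile_edges(n_pixels: int, pixel_size_um: float, tile_edge_um: float) -> np.ndarray:
    """Pixel boundaries of non-overlapping tiles defined in physical units.

    Tiles are anchored at index 0; edges are rasterized to the nearest
    pixel and the incomplete remainder at the far edge is dropped.
    """
    n_tiles = int(np.floor(n_pixels * pixel_size_um / tile_edge_um))
    edges = np.rint(np.arange(n_tiles + 1) * tile_edge_um / pixel_size_um)
    return edges.astype(np.intp)


def heterogeneity_profile(
    image: LabeledTissueImage,
    roi=None,
    tile_edge_um: float = 50.0,
    n_bins: int = 20,
) -> HeterogeneityProfile:
    """Tile V_nm over the roi and summarize its intra-subject dispersion.

    The roi is divided into non-overlapping ``tile_edge_um`` square tiles,
    row-major, anchored at the roi origin; incomplete edge tiles are
    discarded.  Raises if the roi is smaller than one tile.
    """
    rs, cs = _resolve_roi(image.shape, roi)
    nm = image.nonmyocyte_mask()[rs, cs]
    px = image.pixel_size_um
    rows = tile_edges(nm.shape[0], px, tile_edge_um)
    cols = tile_edges(nm.shape[1], px, tile_edge_um)
    if len(rows) < 2 or len(cols) < 2:
        raise ValueError("roi smaller than one tile")
    # integral image -> per-tile sums without python loops over pixels
    ii = np.zeros((nm.shape[0] + 1, nm.shape[1] + 1), dtype=np.int64)
    np.cumsum(np.cumsum(nm, axis=0), axis=1, out=ii[1:, 1:])
    s = ii[np.ix_(rows, cols)]
    counts = s[1:, 1:] - s[:-1, 1:] - s[1:, :-1] + s[:-1, :-1]
    areas = np.outer(np.diff(rows), np.diff(cols))
    tile_vnm = counts / areas
    flat = tile_vnm.ravel()
    sigma = float(np.std(flat, ddof=1)) * 100.0 if flat.size > 1 else 0.0
    hist, bin_edges = np.histogram(flat, bins=n_bins, range=(0.0, 1.0))
    return HeterogeneityProfile(
        tile_vnm=tile_vnm,
        tile_edge_um=tile_edge_um,
        mean_vnm=float(flat.mean()),
        sigma_intra=sigma,
        histogram=hist / flat.size,
        bin_edges=bin_edges,
    )


def patch_geometry(
    mask: np.ndarray,
    pixel_size_nm: float,
    min_area_um2: float = 150.0,
) -> PatchFeatures:
    """Connected-component morphometry of a binary non-myocyte raster.

    Components are 8-connected; those at or below ``min_area_um2`` are
    excluded before any statistic.  Axis lengths come from the ellipse with
    the same second central moments as each component.
    """
    mask = np.asarray(mask, dtype=bool)
    px_um = pixel_size_nm / 1000.0
    labels = measure.label(mask, connectivity=2)
    props = measure.regionprops(labels)
    area_px_thresh = min_area_um2 / px_um**2
    props = [p for p in props if p.area > area_px_thresh]
    if not props:
        return PatchFeatures(0, *([float("nan")] * 6))
    areas = np.array([p.area for p in props]) * px_um**2
    major = np.array([p.axis_major_length for p in props]) * px_um
    minor = np.array([p.axis_minor_length for p in props]) * px_um
    ecc = np.array([p.eccentricity for p in props])
    with np.errstate(divide="ignore"):
        ratio = np.where(minor > 0, major / np.maximum(minor, 1e-300), np.inf)
    return PatchFeatures(
        n_patches=len(props),
        largest_area_um2=float(areas.max()),
        mean_area_um2=float(areas.mean()),
        mean_major_axis_um=float(major.mean()),
        mean_minor_axis_um=float(minor.mean()),
        mean_axis_ratio=float(ratio.mean()),
        mean_eccentricity=float(ecc.mean()),
    )


def subject_table(
    images,
    groups=None,
    tile_edge_um: float = 50.0,
    min_area_um2: float = 150.0,
) -> pd.DataFrame:
    """Per-subject feature rows (composition, heterogeneity, patch geometry).

    ``images`` is an iterable of :class:`LabeledTissueImage`; ``groups``
    optionally overrides the per-image group labels.  Returns one row per
    subject with the columns used downstream by the etiology classifier.
    """
    rows = []
    for i, image in enumerate(images):
        frac = compute_fractions(image)
        prof = heterogeneity_profile(image, tile_edge_um=tile_edge_um)
        patches = patch_geometry(
            image.nonmyocyte_mask(), image.pixel_size_nm, min_area_um2
        )
        rows.append(
            {
                "subject": i,
                "group": groups[i] if groups is not None else image.group,
                "v_e": frac.v_e,
                "v_f": frac.v_f,
                "v_mf": frac.v_mf,
                "v_nm": frac.v_nm,
                "sigma_intra": prof.sigma_intra,
                "n_patches": patches.n_patches,
                "largest_patch_area_um2": patches.largest_area_um2,
                "mean_patch_area_um2": patches.mean_area_um2,
                "mean_major_axis_um": patches.mean_major_axis_um,
                "mean_minor_axis_um": patches.mean_minor_axis_um,
                "mean_axis_ratio": patches.mean_axis_ratio,
            }
        )
    return pd.DataFrame(rows)
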