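"""Image-derived regular meshes for 2D bidomain simulation.

Each 50-um square element carries the volume fractions of extracellular
space (V_e), fibroblasts (V_f), myofibroblasts (V_mf) and myocytes
(V_myo = 1 - V_e - V_f - V_mf), averaged from the underlying binary masks.
Conductivities scale linearly with the respective volume fraction,

    sigma_myo = V_myo * sigma_myo_100,     sigma_e = V_e * sigma_e_100,

as diagonal 2x2 tensors in the (X = myocyte long axis, Y = transverse)
frame with longitudinal:transverse anisotropy 10 (myocyte domain) and 2
(extracellular domain).  Fibroblast/myofibroblast fractions conduct in
neither domain.  The myocyte number density beta_myo = V_myo / V_single
converts single-cell membrane currents to tissue current densities.

Two printed 100%-fraction conductivity sets exist for the myocyte domain
(0.5 S/m longitudinal in the tensor definition, 0.1 S/m in the conduction
evaluation); both are available as presets and the choice materially
shifts conduction velocity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .image import LabeledTissueImage
from .quantify import tile_edges

__all__ = [
    "ConductivityParams",
    "BidomainMesh",
    "downsample_fractions",
    "build_mesh",
    "homogeneous_mesh",
    "mesh_from_image",
    "extend_homogeneous",
    "to_vtk",
]

#: elements below this myocyte fraction carry no membrane model
PASSIVE_VMYO = 1e-6


@dataclass(frozen=True)
class ConductivityParams:
    """Electrical and membrane constants of the tissue model.

    ``sigma_myo_long_100`` / ``sigma_e_long_100`` are the longitudinal
    conductivities at 100% volume fraction (S/m); transverse values follow
    from the anisotropy ratios.  ``membrane_R`` (Ohm m^2) and ``beta_sv``
    (1/m, myocyte surface-to-volume ratio) parameterize the passive space
    constants.  ``cm_per_myocyte`` (F) defaults to the membrane area of one
    myocyte (beta_sv * V_single) times 0.01 F/m^2, about 82 pF.
    """

    sigma_myo_long_100: float = 0.1
    sigma_e_long_100: float = 1.0
    anis_myo: float = 10.0
    anis_e: float = 2.0
    membrane_R: float = 0.2
    beta_sv: float = 2.0e5
    v_myo_single_um3: float = 41073.0
    cm_per_myocyte: float | None = None

    def __post_init__(self):
        if min(
            self.sigma_myo_long_100,
            self.sigma_e_long_100,
            self.membrane_R,
            self.beta_sv,
            self.v_myo_single_um3,
        ) <= 0:
            raise ValueError("all conductivity parameters must be positive")
        if self.anis_myo < 1 or self.anis_e < 1:
            raise ValueError("anisotropy ratios must be >= 1")

    @property
    def cm_F(self) -> float:
        """Membrane capacitance per myocyte in farad."""
        if self.cm_per_myocyte is not None:
            return self.cm_per_myocyte
        area_m2 = self.beta_sv * self.v_myo_single_um3 * 1e-18
        return area_m2 * 0.01  # 0.01 F/m^2 specific capacitance

    @property
    def v_myo_single_m3(self) -> float:
        return self.v_myo_single_um3 * 1e-18

    @classmethod
    def preset(cls, name: str) -> "ConductivityParams":
        """Named conductivity sets.

        ``"evaluation"`` — the 0.1 S/m longitudinal myocyte set enumerated
        with the space-constant calculation (default).
        ``"tensor"`` — the 0.5 S/m set stated with the tensor definition;
        its transverse ratios reproduce the ~2:1 conduction anisotropy.
        """
        if name == "evaluation":
            return cls(sigma_myo_long_100=0.1)
        if name == "tensor":
            return cls(sigma_myo_long_100=0.5)
        raise ValueError(f"unknown preset {name!r}")


@dataclass
class BidomainMesh:
    """Regular 2D element grid with per-element fractions and tensors.

    Arrays are shaped ``(ny, nx)`` with x (columns) along the myocyte long
    axis.  ``sigma_myo_x/y`` and ``sigma_e_x/y`` are the diagonal tensor
    entries in S/m; ``beta_myo`` is the myocyte number density in 1/m^3.
    """

    nx: int
    ny: int
    element_edge_um: float
    v_e: np.ndarray
    v_f: np.ndarray
    v_mf: np.ndarray
    v_myo: np.ndarray
    sigma_myo_x: np.ndarray
    sigma_myo_y: np.ndarray
    sigma_e_x: np.ndarray
    sigma_e_y: np.ndarray
    beta_myo: np.ndarray
    params: ConductivityParams
    orientation: str = "x-aligned"
    embedded_cols: tuple[int, int] | None = None  # column span of an
    # original mesh inside an extended domain, for matched CV sampling

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def n_elements(self) -> int:
        return self.ny * self.nx

    @property
    def element_edge_m(self) -> float:
        return self.element_edge_um * 1e-6

    @property
    def passive(self) -> np.ndarray:
        return self.v_myo < PASSIVE_VMYO


def downsample_fractions(
    image: LabeledTissueImage, element_edge_um: float = 50.0
) -> dict:
    """Per-element mean of each binary mask over its physical footprint.

    The element grid is anchored at the image origin with edge remainders
    dropped; footprints are rasterized by nearest-pixel edges.  Raises if
    the image is smaller than one element.
    """
    px = image.pixel_size_um
    rows = tile_edges(image.shape[0], px, element_edge_um)
    cols = tile_edges(image.shape[1], px, element_edge_um)
    if len(rows) < 2 or len(cols) < 2:
        raise ValueError("image smaller than one mesh element")
    out = {}
    for name in ("es", "fibroblast", "myofibroblast"):
        mask = getattr(image, f"{name}_mask")
        ii = np.zeros((mask.shape[0] + 1, mask.shape[1] + 1), dtype=np.int64)
        np.cumsum(np.cumsum(mask, axis=0), axis=1, out=ii[1:, 1:])
        s = ii[np.ix_(rows, cols)]
        counts = s[1:, 1:] - s[:-1, 1:] - s[1:, :-1] + s[:-1, :-1]
        areas = np.outer(np.diff(rows), np.diff(cols))
        out[name] = counts / areas
    return {"v_e": out["es"], "v_f": out["fibroblast"], "v_mf": out["myofibroblast"]}


def build_mesh(
    fractions: dict,
    params: ConductivityParams | None = None,
    element_edge_um: float = 50.0,
    orientation: str = "x-aligned",
) -> BidomainMesh:
    """Assemble a :class:`BidomainMesh` from per-element fraction grids."""
    params = params or ConductivityParams()
    v_e = np.asarray(fractions["v_e"], dtype=float)
    v_f = np.asarray(fractions["v_f"], dtype=float)
    v_mf = np.asarray(fractions["v_mf"], dtype=float)
    if not (v_e.shape == v_f.shape == v_mf.shape) or v_e.ndim != 2:
        raise ValueError("fraction grids must share one 2D shape")
    v_myo = 1.0 - v_e - v_f - v_mf
    bad = np.argwhere(v_myo < -1e-9)
    if len(bad):
        iy, ix = bad[0]
        raise ValueError(
            f"element (row {iy}, col {ix}) has V_e+V_f+V_mf > 1 "
            f"(V_myo = {v_myo[iy, ix]:.3g})"
        )
    v_myo = np.clip(v_myo, 0.0, 1.0)
    ny, nx = v_e.shape
    return BidomainMesh(
        nx=nx,
        ny=ny,
        element_edge_um=element_edge_um,
        v_e=v_e,
        v_f=v_f,
        v_mf=v_mf,
        v_myo=v_myo,
        sigma_myo_x=v_myo * params.sigma_myo_long_100,
        sigma_myo_y=v_myo * params.sigma_myo_long_100 / params.anis_myo,
        sigma_e_x=v_e * params.sigma_e_long_100,
        sigma_e_y=v_e * params.sigma_e_long_100 / params.anis_e,
        beta_myo=v_myo / params.v_myo_single_m3,
        params=params,
        orientation=orientation,
    )


def homogeneous_mesh(
    nx: int,
    ny: int,
    v_e: float,
    v_f: float = 0.0,
    v_mf: float = 0.0,
    params: ConductivityParams | None = None,
    element_edge_um: float = 50.0,
) -> BidomainMesh:
    """Uniform mesh at the given fractions (e.g. donor-mean surrogate)."""
    ones = np.ones((ny, nx))
    return build_mesh(
        {"v_e": v_e * ones, "v_f": v_f * ones, "v_mf": v_mf * ones},
        params,
        element_edge_um,
    )


def mesh_from_image(
    image: LabeledTissueImage,
    params: ConductivityParams | None = None,
    element_edge_um: float = 50.0,
) -> BidomainMesh:
    """Downsample an image and build its bidomain mesh in one step."""
    return build_mesh(
        downsample_fractions(image, element_edge_um),
        params,
        element_edge_um,
        orientation=image.myocyte_axis,
    )


def extend_homogeneous(mesh: BidomainMesh, total_length_x_mm: float = 5.0) -> BidomainMesh:
    """Embed ``mesh`` centrally in a homogeneous domain of the given length.

    Flanking elements (left and right along X) carry the mean volume
    fractions of the original mesh; the original's column span is recorded
    in ``embedded_cols`` so conduction can be sampled at matched locations.
    """
    nx_total = int(round(total_length_x_mm * 1000.0 / mesh.element_edge_um))
    pad = nx_total - mesh.nx
    if pad <= 0:
        raise ValueError("requested total length does not exceed the mesh")
    left = pad // 2
    right = pad - left
    means = {
        "v_e": float(mesh.v_e.mean()),
        "v_f": float(mesh.v_f.mean()),
        "v_mf": float(mesh.v_mf.mean()),
    }
    fractions = {}
    for key in ("v_e", "v_f", "v_mf"):
        orig = getattr(mesh, key)
        fractions[key] = np.concatenate(
            [
                np.full((mesh.ny, left), means[key]),
                orig,
                np.full((mesh.ny, right), means[key]),
            ],
            axis=1,
        )
    out = build_mesh(fractions, mesh.params, mesh.element_edge_um, mesh.orientation)
    out.embedded_cols = (left, left + mesh.nx)
    return out


def to_vtk(mesh: BidomainMesh, path) -> Path:
    """Write the element grids as a legacy-VTK ASCII rectilinear file."""
    path = Path(path)
    h = mesh.element_edge_um
    fields = {
        "V_e": mesh.v_e,
        "V_f": mesh.v_f,
        "V_mf": mesh.v_mf,
        "V_myo": mesh.v_myo,
        "sigma_myo_x": mesh.sigma_myo_x,
        "sigma_e_x": mesh.sigma_e_x,
    }
    with path.open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\nbidomain mesh\nASCII\n")
        fh.write("DATASET RECTILINEAR_GRID\n")
        fh.write(f"DIMENSIONS {mesh.nx + 1} {mesh.ny + 1} 1\n")
        for axis, n in (("X", mesh.nx), ("Y", mesh.ny)):
            fh.write(f"{axis}_COORDINATES {n + 1} float\n")
            fh.write(" ".join(f"{i * h:.1f}" for i in range(n + 1)) + "\n")
        fh.write("Z_COORDINATES 1 float\n0.0\n")
        fh.write(f"CELL_DATA {mesh.n_elements}\n")
        for name, arr in fields.items():
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join(f"{v:.6g}" for v in arr.ravel()) + "\n")
    return path
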