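"""Activation maps, conduction-velocity vectors, and derived diagnostics.

Local activation time is the time of maximal upstroke velocity dVm/dt
restricted to samples with Vm between -60 and 0 mV; elements never meeting
the criterion are non-conductive (conduction block).  At four L-shaped
triplets of adjacent grid points (corner plus one neighbour along +x and
one along +y, spacing l = 50 um) the conduction-velocity vector follows
from the activation-time differences tx and ty:

    |CV| = l / sqrt(tx^2 + ty^2)

with the tilt angle measured from the direction normal to the line
stimulus through the direction-specific arctangent branches (+x: atan;
-x: 180 deg - atan; +y: 90 deg - atan; -y: 90 deg + atan).  Passive space
constants lambda = sqrt((R / beta) * sigma_myo sigma_e / (sigma_myo +
sigma_e)) quantify how far boundary effects reach.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .bidomain import FieldRecording
from .mesh import ConductivityParams

__all__ = [
    "ActivationMap",
    "CVMeasurement",
    "SpaceConstants",
    "BoundaryError",
    "activation_map",
    "default_triplets",
    "cv_vectors",
    "pool_and_summarize",
    "boundary_error",
    "space_constants",
]

#: minimum upstroke (V/s) for a window sample to count as an activation
MIN_UPSTROKE_VPS = 5.0


@dataclass
class ActivationMap:
    """Per-element activation times, upstroke velocities, and block mask."""

    times_ms: np.ndarray  # relative to stimulus onset; NaN if non-conductive
    upstroke_vps: np.ndarray
    conductive: np.ndarray  # bool
    block_labels: np.ndarray  # labeled connected non-conductive regions
    n_block_regions: int
    direction: str
    element_edge_um: float

    @property
    def has_block(self) -> bool:
        return self.n_block_regions > 0


@dataclass(frozen=True)
class CVMeasurement:
    """One conduction-velocity vector at an L-shaped sampling triplet."""

    location: tuple[int, int]  # (row, col) of the corner point
    direction: str  # +x, -x, +y, -y
    tx_s: float
    ty_s: float
    magnitude_m_s: float
    angle_deg: float
    blocked: bool

    @property
    def valid(self) -> bool:
        return not self.blocked and np.isfinite(self.magnitude_m_s)


@dataclass(frozen=True)
class SpaceConstants:
    lambda_l_mm: float
    lambda_t_mm: float


@dataclass(frozen=True)
class BoundaryError:
    mean_error_magnitude_m_s: float
    mean_error_angle_deg: float
    rmse_pct_magnitude: float
    rmse_pct_angle: float
    n: int


def activation_map(
    recording: FieldRecording,
    vm_window: tuple[float, float] = (-60.0, 0.0),
    min_upstroke_vps: float = MIN_UPSTROKE_VPS,
) -> ActivationMap:
    """Derive activation times and the conduction-block mask.

    Activation time is taken at the recorded sample with the largest
    forward-difference dVm/dt among samples whose Vm lies inside
    ``vm_window``; it is reported relative to stimulus onset.  Clamped
    stimulus-edge elements jump across the window between samples, so they
    are assigned activation at stimulus onset.  Elements that never enter
    the window with a sufficient upstroke are non-conductive; their
    8-connected regions are labeled as conduction blocks.
    """
    vm = recording.vm.astype(float)  # (T, ny, nx)
    t = recording.times_ms
    if vm.shape[0] < 3:
        raise ValueError("recording too short to resolve activation")
    dt_rec = float(np.median(np.diff(t)))
    if dt_rec > 0.05:
        warnings.warn(
            f"recording stride {dt_rec:.3g} ms may under-resolve 200-300 V/s "
            "upstrokes; activation times are quantized accordingly",
            stacklevel=2,
        )
    dvdt = np.diff(vm, axis=0) / np.diff(t)[:, None, None]  # mV/ms = V/s
    in_window = (vm[:-1] > vm_window[0]) & (vm[:-1] < vm_window[1])
    dv_masked = np.where(in_window, dvdt, -np.inf)
    best = np.argmax(dv_masked, axis=0)
    ny, nx = vm.shape[1:]
    iy, ix = np.indices((ny, nx))
    best_slope = dv_masked[best, iy, ix]
    conductive = np.isfinite(best_slope) & (best_slope > min_upstroke_vps)
    times = np.where(conductive, t[best] - recording.stim_onset_ms, np.nan)

    upstroke = np.max(np.where(np.isfinite(dvdt), dvdt, -np.inf), axis=0)
    upstroke = np.where(np.isfinite(upstroke), upstroke, np.nan)

    # clamped edge elements are activated by definition at stimulus onset
    clamped = recording.clamped
    conductive = conductive | clamped
    times = np.where(clamped, 0.0, times)

    passive_nan = np.isnan(vm[0])
    nonconductive = ~conductive
    labels, n_regions = ndimage.label(
        nonconductive, structure=np.ones((3, 3), dtype=int)
    )
    return ActivationMap(
        times_ms=times,
        upstroke_vps=upstroke,
        conductive=conductive,
        block_labels=labels,
        n_block_regions=int(n_regions),
        direction=recording.direction,
        element_edge_um=recording.mesh.element_edge_um,
    )


def default_triplets(ny: int, nx: int) -> list[tuple[int, int]]:
    """Corner points of four L-triplets spread uniformly over the grid.

    The corners form a centered 2x2 lattice chosen so that the set of
    sampled element gaps maps onto itself under mirroring of the domain:
    opposite-direction runs on a symmetric mesh then sample identical
    locations.
    """
    ys = (ny // 4, ny - 2 - ny // 4)
    xs = (nx // 4, nx - 2 - nx // 4)
    return [(iy, ix) for iy in ys for ix in xs]


def _angle(tx: float, ty: float, direction: str) -> float:
    base = np.degrees(np.arctan2(ty, tx))
    if direction == "+x":
        ang = base
    elif direction == "-x":
        ang = 180.0 - base
    elif direction == "+y":
        ang = 90.0 - base
    elif direction == "-y":
        ang = 90.0 + base
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return float((ang + 180.0) % 360.0 - 180.0)


def cv_vectors(
    amap: ActivationMap,
    direction: str | None = None,
    locations=None,
    spacing_um: float | None = None,
) -> list[CVMeasurement]:
    """CV vectors at the sampling triplets of an activation map.

    ``tx``/``ty`` are the activation-time differences from the corner to
    its +x and +y neighbours.  A triplet touching a non-conductive point
    yields a block-marked measurement, never a number; a degenerate
    tx = ty = 0 triplet is likewise undefined.
    """
    direction = direction or amap.direction
    ny, nx = amap.times_ms.shape
    locations = list(locations) if locations is not None else default_triplets(ny, nx)
    l_m = (spacing_um or amap.element_edge_um) * 1e-6
    out = []
    for (iy, ix) in locations:
        if not (0 <= iy < ny - 1 and 0 <= ix < nx - 1):
            raise ValueError(f"triplet corner {(iy, ix)} outside grid {(ny, nx)}")
        t0 = amap.times_ms[iy, ix]
        t_x = amap.times_ms[iy, ix + 1]
        t_y = amap.times_ms[iy + 1, ix]
        if np.isnan(t0) or np.isnan(t_x) or np.isnan(t_y):
            out.append(
                CVMeasurement((iy, ix), direction, np.nan, np.nan, np.nan, np.nan, True)
            )
            continue
        tx = (t_x - t0) * 1e-3  # ms -> s
        ty = (t_y - t0) * 1e-3
        denom = np.hypot(tx, ty)
        if denom == 0.0:
            out.append(
                CVMeasurement((iy, ix), direction, tx, ty, np.nan, np.nan, False)
            )
            continue
        out.append(
            CVMeasurement(
                (iy, ix), direction, tx, ty, l_m / denom, _angle(tx, ty, direction),
                False,
            )
        )
    return out


def pool_and_summarize(measurements_by_subject: dict) -> pd.DataFrame:
    """Per-subject medians of |CV| and |angle| split by conduction axis.

    ``measurements_by_subject`` maps a subject key to an iterable of
    :class:`CVMeasurement` pooled over directions.  Longitudinal rows pool
    the +x/-x vectors, transverse rows +y/-y; subjects whose measurements
    are all blocked are reported with NaN medians and excluded downstream.
    """
    rows = []
    for subject, ms in measurements_by_subject.items():
        ms = list(ms)
        row = {"subject": subject}
        for axis, dirs in (("l", ("+x", "-x")), ("t", ("+y", "-y"))):
            sel = [m for m in ms if m.direction in dirs]
            val = [m for m in sel if m.valid]
            row[f"n_{axis}"] = len(sel)
            row[f"n_blocked_{axis}"] = sum(m.blocked for m in sel)
            if val:
                row[f"median_cv{axis}_m_s"] = float(
                    np.median([m.magnitude_m_s for m in val])
                )
                row[f"median_abs_angle_{axis}_deg"] = float(
                    np.median([abs(m.angle_deg) for m in val])
                )
                row[f"sd_cv{axis}_m_s"] = float(
                    np.std([m.magnitude_m_s for m in val], ddof=1)
                ) if len(val) > 1 else 0.0
            else:
                row[f"median_cv{axis}_m_s"] = np.nan
                row[f"median_abs_angle_{axis}_deg"] = np.nan
                row[f"sd_cv{axis}_m_s"] = np.nan
        if np.isfinite(row["median_cvl_m_s"]) and np.isfinite(row["median_cvt_m_s"]):
            row["anisotropy"] = row["median_cvl_m_s"] / row["median_cvt_m_s"]
        else:
            row["anisotropy"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def boundary_error(original, extended) -> BoundaryError:
    """Mean signed error and per-point RMSE%% between matched CV samples.

    Magnitude errors are normalized per point by the original magnitudes;
    angle RMSE is normalized by the 90-degree tilt scale because original
    tilt angles on near-planar waves are close to zero.
    """
    orig = [m for m in original]
    ext = [m for m in extended]
    if len(orig) != len(ext) or any(
        a.location != b.location for a, b in zip(orig, ext)
    ):
        raise ValueError("boundary comparison requires matched sampling locations")
    pairs = [(a, b) for a, b in zip(orig, ext) if a.valid and b.valid]
    if not pairs:
        raise ValueError("no valid matched measurements")
    d_mag = np.array([b.magnitude_m_s - a.magnitude_m_s for a, b in pairs])
    d_ang = np.array([b.angle_deg - a.angle_deg for a, b in pairs])
    ref_mag = np.array([a.magnitude_m_s for a, b in pairs])
    return BoundaryError(
        mean_error_magnitude_m_s=float(d_mag.mean()),
        mean_error_angle_deg=float(d_ang.mean()),
        rmse_pct_magnitude=float(np.sqrt(np.mean((d_mag / ref_mag) ** 2)) * 100.0),
        rmse_pct_angle=float(np.sqrt(np.mean((d_ang / 90.0) ** 2)) * 100.0),
        n=len(pairs),
    )


def space_constants(
    params: ConductivityParams, v_myo: float = 1.0, v_e: float = 1.0
) -> SpaceConstants:
    """Passive space constants (mm) along and across the myocyte axis.

    Evaluated at the given volume-fraction context (100% by default):
    lambda = sqrt((R / beta) * sigma_myo sigma_e / (sigma_myo + sigma_e))
    with the membrane resistance R and surface-to-volume ratio beta.
    """
    out = []
    for s_m, s_e in (
        (v_myo * params.sigma_myo_long_100, v_e * params.sigma_e_long_100),
        (
            v_myo * params.sigma_myo_long_100 / params.anis_myo,
            v_e * params.sigma_e_long_100 / params.anis_e,
        ),
    ):
        if s_m + s_e <= 0:
            raise ZeroDivisionError("zero conductivity sum in space constant")
        lam_m = np.sqrt(params.membrane_R / params.beta_sv * s_m * s_e / (s_m + s_e))
        out.append(lam_m * 1e3)
    return SpaceConstants(lambda_l_mm=float(out[0]), lambda_t_mm=float(out[1]))
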