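"""Coupled elliptic/parabolic bidomain solver on image-derived meshes.

The bidomain equations couple the myocyte-domain potential phi_myo and the
extracellular potential phi_e through the membrane current of the myocytes
in each element.  With Vm = phi_myo - phi_e they are solved as an elliptic
equation for phi_e,

    div((sigma_myo + sigma_e) grad phi_e) = -div(sigma_myo grad Vm),

and a parabolic update for Vm,

    beta_myo (Cm dVm/dt + I_ion) = div(sigma_myo grad (Vm + phi_e)),

discretized by a five-point finite-volume stencil with harmonic-mean face
conductivities (so fully fibrotic elements insulate the myocyte domain),
no-flux exterior boundaries, and operator splitting with forward-Euler
time stepping (exponential Rush-Larsen gate updates by default).  The
stimulus is a Dirichlet clamp of Vm along one domain edge, released after
the stimulus window; intracellular and extracellular source densities are
zero.  The elliptic operator is gauge-fixed at one reference element and,
being time-invariant, is factorized once and reused at every step.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit
from scipy import sparse

from . import _kernels, ionic
from .mesh import BidomainMesh

__all__ = [
    "SimulationConfig",
    "FieldRecording",
    "Operators",
    "assemble_operators",
    "simulate",
    "run_protocol",
    "EDGE_DIRECTIONS",
]

#: conduction direction label excited by a clamp on each edge
EDGE_DIRECTIONS = {"left": "+x", "right": "-x", "top": "+y", "bottom": "-y"}

RESTING_VM = ionic._INITIAL["vm"]


@dataclass(frozen=True)
class SimulationConfig:
    """Protocol and numerical settings for one bidomain run.

    Times follow the experimental protocol: the tissue rests for
    ``equilibration_ms``, one edge is clamped at ``stimulus_value_mv`` for
    ``stimulus_duration_ms``, and the run ends at ``total_time_ms`` (the
    stimulus window counts toward the total).  ``dt`` is in seconds;
    ``record_stride`` defaults to a 1-us sampling of Vm.
    """

    dt: float = 1e-8
    total_time_ms: float = 15.0
    equilibration_ms: float = 2.0
    stimulus_duration_ms: float = 2.0
    stimulus_value_mv: float = 1.0
    stimulus_edge: str = "left"
    linear_solver_rel_tol: float = 1e-12
    linear_solver_abs_tol: float = 1e-12
    record_stride: int | None = None
    gate_update: str = "rush_larsen"
    cell_type: str = "epi"

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.equilibration_ms + self.stimulus_duration_ms > self.total_time_ms:
            raise ValueError("equilibration + stimulus must fit in total_time")
        if self.stimulus_edge not in EDGE_DIRECTIONS:
            raise ValueError(f"unknown stimulus_edge {self.stimulus_edge!r}")
        if min(self.linear_solver_rel_tol, self.linear_solver_abs_tol) <= 0:
            raise ValueError("solver tolerances must be positive")

    @property
    def stride(self) -> int:
        """Recording stride in steps (default: one sample per microsecond)."""
        if self.record_stride is not None:
            return self.record_stride
        return max(1, int(round(1e-6 / self.dt)))


@dataclass
class FieldRecording:
    """Time-resolved Vm with protocol metadata for one simulation."""

    times_ms: np.ndarray  # absolute times of the snapshots
    vm: np.ndarray  # (T, ny, nx) float32, NaN on passive elements
    vm_final: np.ndarray  # (ny, nx) float64 end-state membrane voltage
    phi_e_final: np.ndarray  # (ny, nx) extracellular potential at the end
    stimulus_edge: str
    stim_onset_ms: float
    clamped: np.ndarray  # (ny, nx) bool, elements clamped by the stimulus
    config: SimulationConfig
    mesh: BidomainMesh

    @property
    def direction(self) -> str:
        return EDGE_DIRECTIONS[self.stimulus_edge]


@dataclass
class Operators:
    """Discrete operators of one mesh: myocyte-domain divgrad (CSR), the
    gauge-fixed elliptic matrix, its dense inverse, and the active set."""

    l_myo: sparse.csr_matrix
    a_elliptic: sparse.csr_matrix
    a_inverse: np.ndarray
    active: np.ndarray  # flattened bool
    gauge_index: int
    inv_beta_cm: np.ndarray  # 1/(beta_myo*Cm), zero on passive elements


def _harmonic(a, b):
    s = a + b
    out = np.zeros_like(a)
    nz = s > 0
    out[nz] = 2.0 * a[nz] * b[nz] / s[nz]
    return out


def _divgrad(sx: np.ndarray, sy: np.ndarray, h: float) -> sparse.csr_matrix:
    """Five-point div(sigma grad .) with harmonic-mean faces, no-flux edges.

    ``sx``/``sy`` are per-element tensor entries (S/m) for fluxes along x
    and y; ``h`` is the element edge in metres.  Row i sums to zero, so a
    constant field is in the kernel (pure Neumann).
    """
    ny, nx = sx.shape
    n = ny * nx
    idx = np.arange(n).reshape(ny, nx)
    rows, cols, vals = [], [], []

    fx = _harmonic(sx[:, :-1], sx[:, 1:]) / h**2  # faces between (iy,ix),(iy,ix+1)
    fy = _harmonic(sy[:-1, :], sy[1:, :]) / h**2
    for f, a_idx, b_idx in (
        (fx, idx[:, :-1], idx[:, 1:]),
        (fy, idx[:-1, :], idx[1:, :]),
    ):
        fr = f.ravel()
        ar = a_idx.ravel()
        br = b_idx.ravel()
        rows += [ar, ar, br, br]
        cols += [br, ar, ar, br]
        vals += [fr, -fr, fr, -fr]
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    return sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def assemble_operators(mesh: BidomainMesh) -> Operators:
    """Build and factorize the discrete operators for ``mesh``."""
    active = ~mesh.passive.ravel()
    if not np.any(active):
        raise ValueError("mesh has no active (myocyte-bearing) elements")
    h = mesh.element_edge_m
    l_myo = _divgrad(mesh.sigma_myo_x, mesh.sigma_myo_y, h)
    a_ell = _divgrad(
        mesh.sigma_myo_x + mesh.sigma_e_x, mesh.sigma_myo_y + mesh.sigma_e_y, h
    ).tolil()
    # gauge fix the potential at the first conducting element, and pin any
    # fully non-conducting elements (no myocyte and no ES) at zero
    row_scale = np.abs(a_ell).sum(axis=1).A1
    conducting = row_scale > 0
    gauge = int(np.argmax(conducting))
    pin = ~conducting
    pin[gauge] = True
    scale = row_scale.max()
    for i in np.flatnonzero(pin):
        a_ell.rows[i] = [i]
        a_ell.data[i] = [scale]
    a_csr = a_ell.tocsr()
    a_inv = np.linalg.inv(a_csr.toarray())

    beta_cm = mesh.beta_myo.ravel() * mesh.params.cm_F
    inv_beta_cm = np.zeros_like(beta_cm)
    inv_beta_cm[active] = 1.0 / beta_cm[active]
    return Operators(
        l_myo=l_myo,
        a_elliptic=a_csr,
        a_inverse=a_inv,
        active=active,
        gauge_index=gauge,
        inv_beta_cm=inv_beta_cm,
    )


def _edge_indices(ny: int, nx: int, edge: str) -> np.ndarray:
    idx = np.arange(ny * nx).reshape(ny, nx)
    return {
        "left": idx[:, 0],
        "right": idx[:, -1],
        "top": idx[0, :],
        "bottom": idx[-1, :],
    }[edge].copy()


@njit(cache=True)
def _csr_matvec(data, indices, indptr, x, out):
    for i in range(out.shape[0]):
        acc = 0.0
        for k in range(indptr[i], indptr[i + 1]):
            acc += data[k] * x[indices[k]]
        out[i] = acc


@njit(cache=True)
def _run_loop(
    vm, y, phie, cell_type_arr, active_idx, clamp_idx, pin_idx,
    lm_data, lm_indices, lm_indptr, a_inv, inv_beta_cm,
    dt_s, n_steps, stim_start_step, stim_end_step, stim_value,
    rush_larsen, stride, rec_vm, rec_times, iion,
):
    dt_ms = dt_s * 1e3
    n = vm.shape[0]
    lap_v = np.empty(n)
    lap_p = np.empty(n)
    rhs = np.empty(n)
    vm_act = np.empty(active_idx.shape[0])
    y_act = np.empty((active_idx.shape[0], y.shape[1]))
    rec = 0
    for step in range(n_steps):
        # membrane states and ionic current on active elements
        for a in range(active_idx.shape[0]):
            vm_act[a] = vm[active_idx[a]]
            for q in range(y.shape[1]):
                y_act[a, q] = y[active_idx[a], q]
        _kernels.step_states(vm_act, y_act, dt_ms, cell_type_arr, rush_larsen, iion)
        for a in range(active_idx.shape[0]):
            for q in range(y.shape[1]):
                y[active_idx[a], q] = y_act[a, q]

        # elliptic solve for phi_e
        _csr_matvec(lm_data, lm_indices, lm_indptr, vm, lap_v)
        for i in range(n):
            rhs[i] = -lap_v[i]
        for k in range(pin_idx.shape[0]):
            rhs[pin_idx[k]] = 0.0
        phie[:] = np.dot(a_inv, rhs)

        # parabolic update of Vm
        _csr_matvec(lm_data, lm_indices, lm_indptr, phie, lap_p)
        for a in range(active_idx.shape[0]):
            i = active_idx[a]
            vm[i] += dt_s * (
                (lap_v[i] + lap_p[i]) * inv_beta_cm[i] - 1000.0 * iion[a]
            )
        if stim_start_step <= step < stim_end_step:
            for k in range(clamp_idx.shape[0]):
                vm[clamp_idx[k]] = stim_value

        if (step + 1) % stride == 0:
            for i in range(n):
                rec_vm[rec, i] = vm[i]
            rec_times[rec] = (step + 1) * dt_ms
            rec += 1
    return rec


def simulate(
    mesh: BidomainMesh,
    config: SimulationConfig | None = None,
    operators: Operators | None = None,
) -> FieldRecording:
    """Run the stimulus protocol on ``mesh`` and record Vm over time."""
    config = config or SimulationConfig()
    ops = operators or assemble_operators(mesh)
    n = mesh.n_elements
    ny, nx = mesh.shape

    vm = np.full(n, RESTING_VM)
    phie = np.zeros(n)
    state0 = ionic.initial_state(config.cell_type)
    y = np.tile(state0.y, (n, 1))
    active_idx = np.flatnonzero(ops.active)
    cell_type_arr = np.full(
        active_idx.shape[0], ionic.CELL_TYPES.index(config.cell_type), dtype=np.int64
    )
    clamp_idx = _edge_indices(ny, nx, config.stimulus_edge)

    dt_ms = config.dt * 1e3
    n_steps = int(round(config.total_time_ms / dt_ms))
    stim_start = int(round(config.equilibration_ms / dt_ms))
    stim_end = int(
        round((config.equilibration_ms + config.stimulus_duration_ms) / dt_ms)
    )
    stride = config.stride
    n_rec = n_steps // stride
    rec_vm = np.empty((n_rec, n), dtype=np.float32)
    rec_times = np.empty(n_rec)
    iion = np.zeros(active_idx.shape[0])

    # elements pinned in the elliptic system (gauge + non-conducting rows)
    diag_rows = np.flatnonzero(
        np.diff(ops.a_elliptic.indptr) == 1
    )
    try:
        n_rec_done = _run_loop(
            vm, y, phie, cell_type_arr, active_idx, clamp_idx, diag_rows,
            ops.l_myo.data, ops.l_myo.indices, ops.l_myo.indptr,
            ops.a_inverse, ops.inv_beta_cm,
            config.dt, n_steps, stim_start, stim_end, config.stimulus_value_mv,
            config.gate_update == "rush_larsen", stride, rec_vm, rec_times, iion,
        )
    except (ZeroDivisionError, ValueError) as err:
        raise FloatingPointError(
            f"membrane state collapsed during integration (dt={config.dt:g} s): {err}"
        ) from err
    if not (np.all(np.isfinite(vm[active_idx])) and np.all(np.isfinite(phie))):
        raise FloatingPointError(
            f"non-finite fields after step {n_steps} (dt={config.dt:g} s)"
        )
    # re-solve the elliptic system at the final membrane state so the
    # stored (vm, phi_e) pair satisfies the conservation identity
    rhs = -(ops.l_myo @ vm)
    rhs[diag_rows] = 0.0
    phie = ops.a_inverse @ rhs
    rec_vm = rec_vm[:n_rec_done].reshape(n_rec_done, ny, nx)
    rec_vm[:, mesh.passive] = np.nan
    clamped = np.zeros((ny, nx), dtype=bool)
    clamped.ravel()[clamp_idx] = True
    return FieldRecording(
        times_ms=rec_times[:n_rec_done],
        vm=rec_vm,
        vm_final=vm.reshape(ny, nx),
        phi_e_final=phie.reshape(ny, nx),
        stimulus_edge=config.stimulus_edge,
        stim_onset_ms=config.equilibration_ms,
        clamped=clamped,
        config=config,
        mesh=mesh,
    )


def run_protocol(
    mesh: BidomainMesh,
    config: SimulationConfig | None = None,
    edges=None,
) -> dict:
    """Simulate the line stimulus on each domain edge.

    For meshes built from long-axis images all four edges are run (left and
    right excite longitudinal conduction, top and bottom transverse); for
    axial cross-section images only the transverse pair is run.  Returns
    ``{edge: FieldRecording}``; the assembled operators are shared.
    """
    config = config or SimulationConfig()
    if edges is None:
        if mesh.orientation == "cross-section":
            edges = ("top", "bottom")
        else:
            edges = ("left", "right", "top", "bottom")
    ops = assemble_operators(mesh)
    out = {}
    for edge in edges:
        out[edge] = simulate(mesh, replace(config, stimulus_edge=edge), operators=ops)
    return out


def elliptic_residual(recording: FieldRecording) -> float:
    """Relative residual of the final elliptic solve (current conservation).

    The elliptic equation expresses that the total membrane current equals
    the negative divergence of the extracellular current; its discrete
    residual relative to the forcing is the conservation error.
    """
    mesh = recording.mesh
    ops = assemble_operators(mesh)
    vm = recording.vm_final.astype(float).ravel()
    rhs = -(ops.l_myo @ vm)
    rhs[np.flatnonzero(np.diff(ops.a_elliptic.indptr) == 1)] = 0.0
    phie = recording.phi_e_final.ravel()
    r = ops.a_elliptic @ phie - rhs
    denom = max(float(np.linalg.norm(rhs)), 1e-30)
    return float(np.linalg.norm(r)) / denom
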