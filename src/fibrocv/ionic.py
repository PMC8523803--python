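"""Human ventricular myocyte membrane model (ten Tusscher–Panfilov 2006).

Provides the total ionic current I_ion and the evolution of gating
variables and intracellular ion concentrations for each active mesh
element.  Twelve membrane currents are included: I_Na, I_CaL, I_to, I_Kr,
I_Ks, I_K1, I_NaCa, I_NaK, I_pCa, I_pK, I_bCa and I_bNa, plus the
three-compartment calcium subsystem (cytosol, subspace, SR) with
calsequestrin/calmodulin buffering and a four-state-reduced ryanodine
release gate.  Currents are expressed per unit membrane capacitance
(pA/pF); the tissue solver converts to amperes per myocyte via the
membrane capacitance when coupling into the bidomain equations.

This module is the readable NumPy formulation used for reference
integrations and single-state queries; :mod:`fibrocv._kernels` holds the
numba-compiled vectorized stepper used by the tissue solver.  The two are
cross-checked in the test suite.

The epicardial parameter set is the default cell type; endocardial and
mid-myocardial variants differ in I_to density/kinetics and I_Ks density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CellState",
    "MembraneCurrents",
    "CELL_TYPES",
    "STATE_NAMES",
    "initial_state",
    "compute_currents",
    "state_derivatives",
    "advance_state",
    "simulate_single_cell",
]

CELL_TYPES = ("epi", "endo", "M")

# gate variables first, then Ca subsystem and concentrations
STATE_NAMES = (
    "m", "h", "j", "xr1", "xr2", "xs", "r", "s", "d", "f", "f2", "fcass",
    "rbar", "cai", "casr", "cass", "nai", "ki",
)
N_GATES = 12  # indices 0..11 are Hodgkin-Huxley-type gates

# physical constants
R_GAS = 8314.472  # mJ/(mol K)
TEMP = 310.0  # K
FARADAY = 96485.3415  # C/mol
RTONF = R_GAS * TEMP / FARADAY  # mV

# extracellular concentrations (mM)
KO = 5.4
CAO = 2.0
NAO = 140.0

# maximal conductances / fluxes (per-pF convention of the published model)
G_NA = 14.838
G_K1 = 5.405
G_KR = 0.153
G_CAL = 3.98e-5
G_PCA = 0.1238
K_PCA = 0.0005
G_PK = 0.0146
G_BNA = 0.00029
G_BCA = 0.000592
P_NAK = 2.724
KM_K = 1.0
KM_NA = 40.0
K_NACA = 1000.0
K_SAT = 0.1
ALPHA_NACA = 2.5
GAMMA_NACA = 0.35
KM_NAI = 87.5
KM_CA = 1.38
PK_NA = 0.03

# calcium subsystem
BUF_C, K_BUF_C = 0.2, 0.001
BUF_SR, K_BUF_SR = 10.0, 0.3
BUF_SS, K_BUF_SS = 0.4, 0.00025
V_MAX_UP, K_UP = 0.006375, 0.00025
V_REL, V_LEAK, V_XFER = 0.102, 0.00036, 0.0038
K1_PRIME, K2_PRIME, K3, K4 = 0.15, 0.045, 0.060, 0.005
EC_SR, MAX_SR, MIN_SR = 1.5, 2.5, 1.0

# cell geometry (volumes in the units of the published source)
V_C = 0.016404
V_SR = 0.001094
V_SS = 0.00005468
CAPACITANCE = 0.185

_CELL_PARAMS = {
    # (G_to, G_Ks, epicardial-form s gate)
    "epi": (0.294, 0.392, True),
    "endo": (0.073, 0.392, False),
    "M": (0.294, 0.098, True),
}

#: published 1-Hz steady state (epicardial); used for all cell types as the
#: starting point, from which each variant settles within a few beats.
_INITIAL = {
    "vm": -85.23,
    "m": 0.00172, "h": 0.7444, "j": 0.7045,
    "xr1": 0.00621, "xr2": 0.4712, "xs": 0.0095,
    "r": 2.42e-8, "s": 0.999998,
    "d": 3.373e-5, "f": 0.7888, "f2": 0.9755, "fcass": 0.9953,
    "rbar": 0.9073,
    "cai": 0.000126, "casr": 3.64, "cass": 0.00036,
    "nai": 8.604, "ki": 136.89,
}


@dataclass
class CellState:
    """Membrane voltage plus the 18 gating/concentration states."""

    vm: float
    y: np.ndarray
    cell_type: str = "epi"

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (len(STATE_NAMES),):
            raise ValueError(f"state vector must have {len(STATE_NAMES)} entries")
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell_type {self.cell_type!r}")

    def __getattr__(self, name):
        if name in STATE_NAMES:
            return float(self.y[STATE_NAMES.index(name)])
        raise AttributeError(name)


@dataclass(frozen=True)
class MembraneCurrents:
    """The twelve membrane currents (pA/pF) and their sum."""

    i_na: float
    i_cal: float
    i_to: float
    i_kr: float
    i_ks: float
    i_k1: float
    i_naca: float
    i_nak: float
    i_pca: float
    i_pk: float
    i_bca: float
    i_bna: float

    @property
    def total(self) -> float:
        return (
            self.i_na + self.i_cal + self.i_to + self.i_kr + self.i_ks
            + self.i_k1 + self.i_naca + self.i_nak + self.i_pca + self.i_pk
            + self.i_bca + self.i_bna
        )


def initial_state(cell_type: str = "epi") -> CellState:
    """Published resting (1-Hz paced steady) state for the given cell type."""
    if cell_type not in CELL_TYPES:
        raise ValueError(f"unknown cell_type {cell_type!r}")
    y = np.array([_INITIAL[name] for name in STATE_NAMES])
    return CellState(vm=_INITIAL["vm"], y=y, cell_type=cell_type)


# ---------------------------------------------------------------------------
# rate functions (voltage in mV, time constants in ms)

def _gate_tables(v, cass, cell_type):
    """Steady states and time constants of all 12 gates at voltage ``v``."""
    _, _, epi_s = _cell_params(cell_type)
    exp = np.exp

    m_inf = 1.0 / (1.0 + exp((-56.86 - v) / 9.03)) ** 2
    a_m = 1.0 / (1.0 + exp((-60.0 - v) / 5.0))
    b_m = 0.1 / (1.0 + exp((v + 35.0) / 5.0)) + 0.1 / (1.0 + exp((v - 50.0) / 200.0))
    tau_m = a_m * b_m

    h_inf = 1.0 / (1.0 + exp((v + 71.55) / 7.43)) ** 2
    if v < -40.0:
        a_h = 0.057 * exp(-(v + 80.0) / 6.8)
        b_h = 2.7 * exp(0.079 * v) + 3.1e5 * exp(0.3485 * v)
    else:
        a_h = 0.0
        b_h = 0.77 / (0.13 * (1.0 + exp(-(v + 10.66) / 11.1)))
    tau_h = 1.0 / (a_h + b_h)

    j_inf = h_inf
    if v < -40.0:
        a_j = (
            (-2.5428e4 * exp(0.2444 * v) - 6.948e-6 * exp(-0.04391 * v))
            * (v + 37.78)
            / (1.0 + exp(0.311 * (v + 79.23)))
        )
        b_j = 0.02424 * exp(-0.01052 * v) / (1.0 + exp(-0.1378 * (v + 40.14)))
    else:
        a_j = 0.0
        b_j = 0.6 * exp(0.057 * v) / (1.0 + exp(-0.1 * (v + 32.0)))
    tau_j = 1.0 / (a_j + b_j)

    xr1_inf = 1.0 / (1.0 + exp((-26.0 - v) / 7.0))
    a_xr1 = 450.0 / (1.0 + exp((-45.0 - v) / 10.0))
    b_xr1 = 6.0 / (1.0 + exp((v + 30.0) / 11.5))
    tau_xr1 = a_xr1 * b_xr1

    xr2_inf = 1.0 / (1.0 + exp((v + 88.0) / 24.0))
    a_xr2 = 3.0 / (1.0 + exp((-60.0 - v) / 20.0))
    b_xr2 = 1.12 / (1.0 + exp((v - 60.0) / 20.0))
    tau_xr2 = a_xr2 * b_xr2

    xs_inf = 1.0 / (1.0 + exp((-5.0 - v) / 14.0))
    a_xs = 1400.0 / np.sqrt(1.0 + exp((5.0 - v) / 6.0))
    b_xs = 1.0 / (1.0 + exp((v - 35.0) / 15.0))
    tau_xs = a_xs * b_xs + 80.0

    r_inf = 1.0 / (1.0 + exp((20.0 - v) / 6.0))
    tau_r = 9.5 * exp(-((v + 40.0) ** 2) / 1800.0) + 0.8

    if epi_s:
        s_inf = 1.0 / (1.0 + exp((v + 20.0) / 5.0))
        tau_s = (
            85.0 * exp(-((v + 45.0) ** 2) / 320.0)
            + 5.0 / (1.0 + exp((v - 20.0) / 5.0))
            + 3.0
        )
    else:
        s_inf = 1.0 / (1.0 + exp((v + 28.0) / 5.0))
        tau_s = 1000.0 * exp(-((v + 67.0) ** 2) / 1000.0) + 8.0

    d_inf = 1.0 / (1.0 + exp((-8.0 - v) / 7.5))
    a_d = 1.4 / (1.0 + exp((-35.0 - v) / 13.0)) + 0.25
    b_d = 1.4 / (1.0 + exp((v + 5.0) / 5.0))
    g_d = 1.0 / (1.0 + exp((50.0 - v) / 20.0))
    tau_d = a_d * b_d + g_d

    f_inf = 1.0 / (1.0 + exp((v + 20.0) / 7.0))
    tau_f = (
        1102.5 * exp(-((v + 27.0) ** 2) / 225.0)
        + 200.0 / (1.0 + exp((13.0 - v) / 10.0))
        + 180.0 / (1.0 + exp((v + 30.0) / 10.0))
        + 20.0
    )

    f2_inf = 0.67 / (1.0 + exp((v + 35.0) / 7.0)) + 0.33
    tau_f2 = (
        562.0 * exp(-((v + 27.0) ** 2) / 240.0)
        + 31.0 / (1.0 + exp((25.0 - v) / 10.0))
        + 80.0 / (1.0 + exp((v + 30.0) / 10.0))
    )

    fcass_inf = 0.6 / (1.0 + (cass / 0.05) ** 2) + 0.4
    tau_fcass = 80.0 / (1.0 + (cass / 0.05) ** 2) + 2.0

    inf = np.array([
        m_inf, h_inf, j_inf, xr1_inf, xr2_inf, xs_inf, r_inf, s_inf,
        d_inf, f_inf, f2_inf, fcass_inf,
    ])
    tau = np.array([
        tau_m, tau_h, tau_j, tau_xr1, tau_xr2, tau_xs, tau_r, tau_s,
        tau_d, tau_f, tau_f2, tau_fcass,
    ])
    return inf, tau


def _cell_params(cell_type):
    try:
        return _CELL_PARAMS[cell_type]
    except KeyError:
        raise ValueError(f"unknown cell_type {cell_type!r}") from None


def _currents(v, y, cell_type):
    g_to, g_ks, _ = _cell_params(cell_type)
    exp = np.exp
    m, h, j, xr1, xr2, xs, r, s, d, f, f2, fcass = y[:N_GATES]
    cai, casr, cass, nai, ki = y[13], y[14], y[15], y[16], y[17]

    e_na = RTONF * np.log(NAO / nai)
    e_k = RTONF * np.log(KO / ki)
    e_ks = RTONF * np.log((KO + PK_NA * NAO) / (ki + PK_NA * nai))
    e_ca = 0.5 * RTONF * np.log(CAO / cai)

    i_na = G_NA * m**3 * h * j * (v - e_na)

    vshift = v - 15.0
    if abs(vshift) < 1e-6:
        vshift = 1e-6  # removable singularity of the GHK-type flux
    expv = exp(2.0 * vshift * FARADAY / (R_GAS * TEMP))
    i_cal = (
        G_CAL * d * f * f2 * fcass * 4.0 * vshift
        * (FARADAY**2 / (R_GAS * TEMP))
        * (0.25 * cass * expv - CAO) / (expv - 1.0)
    )

    i_to = g_to * r * s * (v - e_k)
    i_kr = G_KR * np.sqrt(KO / 5.4) * xr1 * xr2 * (v - e_k)
    i_ks = g_ks * xs**2 * (v - e_ks)

    a_k1 = 0.1 / (1.0 + exp(0.06 * (v - e_k - 200.0)))
    b_k1 = (
        3.0 * exp(0.0002 * (v - e_k + 100.0)) + exp(0.1 * (v - e_k - 10.0))
    ) / (1.0 + exp(-0.5 * (v - e_k)))
    i_k1 = G_K1 * np.sqrt(KO / 5.4) * a_k1 / (a_k1 + b_k1) * (v - e_k)

    vf_rt = v * FARADAY / (R_GAS * TEMP)
    i_naca = (
        K_NACA
        * (exp(GAMMA_NACA * vf_rt) * nai**3 * CAO
           - exp((GAMMA_NACA - 1.0) * vf_rt) * NAO**3 * cai * ALPHA_NACA)
        / (
            (KM_NAI**3 + NAO**3)
            * (KM_CA + CAO)
            * (1.0 + K_SAT * exp((GAMMA_NACA - 1.0) * vf_rt))
        )
    )
    i_nak = (
        P_NAK * KO * nai
        / ((KO + KM_K) * (nai + KM_NA))
        / (1.0 + 0.1245 * exp(-0.1 * vf_rt) + 0.0353 * exp(-vf_rt))
    )
    i_pca = G_PCA * cai / (K_PCA + cai)
    i_pk = G_PK * (v - e_k) / (1.0 + exp((25.0 - v) / 5.98))
    i_bna = G_BNA * (v - e_na)
    i_bca = G_BCA * (v - e_ca)

    return MembraneCurrents(
        i_na=i_na, i_cal=i_cal, i_to=i_to, i_kr=i_kr, i_ks=i_ks, i_k1=i_k1,
        i_naca=i_naca, i_nak=i_nak, i_pca=i_pca, i_pk=i_pk,
        i_bca=i_bca, i_bna=i_bna,
    )


def compute_currents(state: CellState) -> MembraneCurrents:
    """Membrane currents (pA/pF) at the given state."""
    if not (np.isfinite(state.vm) and np.all(np.isfinite(state.y))):
        raise ValueError("non-finite state")
    return _currents(state.vm, state.y, state.cell_type)


def state_derivatives(vm: float, y: np.ndarray, cell_type: str = "epi", i_stim: float = 0.0):
    """Time derivatives (per ms) of Vm and the 18 states.

    ``dvm/dt = -(I_ion + I_stim)``; used by reference ODE integrations.
    """
    y = np.asarray(y, dtype=float)
    cur = _currents(vm, y, cell_type)
    inf, tau = _gate_tables(vm, y[15], cell_type)
    dy = np.empty_like(y)
    dy[:N_GATES] = (inf - y[:N_GATES]) / tau

    cai, casr, cass, nai = y[13], y[14], y[15], y[16]
    rbar = y[12]

    kcasr = MAX_SR - (MAX_SR - MIN_SR) / (1.0 + (EC_SR / casr) ** 2)
    k1 = K1_PRIME / kcasr
    k2 = K2_PRIME * kcasr
    o_gate = k1 * cass**2 * rbar / (K3 + k1 * cass**2)
    dy[12] = -k2 * cass * rbar + K4 * (1.0 - rbar)

    i_leak = V_LEAK * (casr - cai)
    i_up = V_MAX_UP / (1.0 + (K_UP / cai) ** 2)
    i_rel = V_REL * o_gate * (casr - cass)
    i_xfer = V_XFER * (cass - cai)

    buf_c = 1.0 / (1.0 + BUF_C * K_BUF_C / (cai + K_BUF_C) ** 2)
    buf_sr = 1.0 / (1.0 + BUF_SR * K_BUF_SR / (casr + K_BUF_SR) ** 2)
    buf_ss = 1.0 / (1.0 + BUF_SS * K_BUF_SS / (cass + K_BUF_SS) ** 2)

    dy[13] = buf_c * (
        (i_leak - i_up) * V_SR / V_C
        + i_xfer
        - (cur.i_bca + cur.i_pca - 2.0 * cur.i_naca)
        * CAPACITANCE
        / (2.0 * V_C * FARADAY)
    )
    dy[14] = buf_sr * (i_up - i_rel - i_leak)
    dy[15] = buf_ss * (
        -cur.i_cal * CAPACITANCE / (2.0 * V_SS * FARADAY)
        + i_rel * V_SR / V_SS
        - i_xfer * V_C / V_SS
    )
    dy[16] = -(cur.i_na + cur.i_bna + 3.0 * cur.i_nak + 3.0 * cur.i_naca) * (
        CAPACITANCE / (V_C * FARADAY)
    )
    dy[17] = -(
        cur.i_k1 + cur.i_to + cur.i_kr + cur.i_ks - 2.0 * cur.i_nak
        + cur.i_pk + i_stim
    ) * (CAPACITANCE / (V_C * FARADAY))

    dvm = -(cur.total + i_stim)
    return dvm, dy


def advance_state(state: CellState, dt: float, method: str = "rush_larsen") -> CellState:
    """Advance gates and concentrations one step of ``dt`` seconds.

    Gates use the exponential (Rush-Larsen) update by default or forward
    Euler with ``method="euler"``; concentrations always use forward
    Euler.  The membrane voltage is left untouched — in tissue it evolves
    through the parabolic bidomain update, and single-cell runs use
    :func:`simulate_single_cell`.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    dt_ms = dt * 1e3
    _, dy = state_derivatives(state.vm, state.y, state.cell_type)
    y = state.y + dt_ms * dy
    if method == "rush_larsen":
        inf, tau = _gate_tables(state.vm, state.y[15], state.cell_type)
        y[:N_GATES] = inf + (state.y[:N_GATES] - inf) * np.exp(-dt_ms / tau)
    elif method != "euler":
        raise ValueError(f"unknown method {method!r}")
    if not np.all(np.isfinite(y)):
        raise ValueError(f"state became non-finite at dt={dt:g} s")
    return CellState(vm=state.vm, y=y, cell_type=state.cell_type)


def simulate_single_cell(
    duration_ms: float = 500.0,
    dt_ms: float = 0.002,
    stim_start_ms: float = 10.0,
    stim_duration_ms: float = 1.0,
    stim_amplitude: float = -52.0,
    cell_type: str = "epi",
    record_every: int = 10,
):
    """Integrate one stimulated cell; returns times, Vm trace and the state.

    The stimulus is a current injection in pA/pF (negative = depolarizing
    by the sign convention dVm/dt = -I).  Uses the numba stepper shared
    with the tissue solver.
    """
    from . import _kernels

    state = initial_state(cell_type)
    vm = np.array([state.vm])
    y = state.y[None, :].copy()
    ct = np.array([CELL_TYPES.index(cell_type)])
    n_steps = int(round(duration_ms / dt_ms))
    times, trace = [], []
    iion = np.zeros(1)
    for k in range(n_steps):
        t = k * dt_ms
        stim = stim_amplitude if stim_start_ms <= t < stim_start_ms + stim_duration_ms else 0.0
        _kernels.step_states(vm, y, dt_ms, ct, True, iion)
        vm[0] += dt_ms * (-(iion[0] + stim))
        if k % record_every == 0:
            times.append(t)
            trace.append(vm[0])
    return {
        "times_ms": np.array(times),
        "vm_mv": np.array(trace),
        "state": CellState(vm=float(vm[0]), y=y[0], cell_type=cell_type),
    }
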