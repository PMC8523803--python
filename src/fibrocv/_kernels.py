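"""Numba-compiled membrane stepper shared by the tissue and cell solvers.

``step_states`` advances the 18 gating/concentration states of every
active element by one time step (exponential Rush-Larsen update for the
12 voltage gates, forward Euler for concentrations and the release gate)
and writes the total ionic current I_ion (pA/pF) evaluated at the step's
initial state.  The formulation mirrors :mod:`fibrocv.ionic`; the two are
cross-checked in the test suite.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# cell-type parameter rows: (G_to, G_Ks, epicardial-form s gate)
CELLTYPE_PARAMS = np.array(
    [
        [0.294, 0.392, 1.0],  # epi
        [0.073, 0.392, 0.0],  # endo
        [0.294, 0.098, 1.0],  # M
    ]
)

RTONF = 8314.472 * 310.0 / 96485.3415
F_RT = 96485.3415 / (8314.472 * 310.0)
FFRT = 96485.3415 * 96485.3415 / (8314.472 * 310.0)


@njit(cache=True, fastmath=True)
def step_states(vm, y, dt_ms, cell_type, rush_larsen, iion_out):  # noqa: C901
    """Advance states in place; fill ``iion_out`` with I_ion (pA/pF)."""
    n = vm.shape[0]
    for i in range(n):
        v = vm[i]
        p = CELLTYPE_PARAMS[cell_type[i]]
        g_to = p[0]
        g_ks = p[1]
        epi_s = p[2] > 0.5

        m = y[i, 0]; h = y[i, 1]; j = y[i, 2]
        xr1 = y[i, 3]; xr2 = y[i, 4]; xs = y[i, 5]
        r = y[i, 6]; s = y[i, 7]
        d = y[i, 8]; f = y[i, 9]; f2 = y[i, 10]; fcass = y[i, 11]
        rbar = y[i, 12]
        cai = y[i, 13]; casr = y[i, 14]; cass = y[i, 15]
        nai = y[i, 16]; ki = y[i, 17]

        e_na = RTONF * math.log(140.0 / nai)
        e_k = RTONF * math.log(5.4 / ki)
        e_ks = RTONF * math.log((5.4 + 0.03 * 140.0) / (ki + 0.03 * nai))
        e_ca = 0.5 * RTONF * math.log(2.0 / cai)

        i_na = 14.838 * m * m * m * h * j * (v - e_na)

        vshift = v - 15.0
        if abs(vshift) < 1e-6:
            vshift = 1e-6
        expv = math.exp(2.0 * vshift * F_RT)
        i_cal = (
            3.98e-5 * d * f * f2 * fcass * 4.0 * vshift * FFRT
            * (0.25 * cass * expv - 2.0) / (expv - 1.0)
        )

        i_to = g_to * r * s * (v - e_k)
        i_kr = 0.153 * xr1 * xr2 * (v - e_k)  # sqrt(Ko/5.4) = 1
        i_ks = g_ks * xs * xs * (v - e_ks)

        a_k1 = 0.1 / (1.0 + math.exp(0.06 * (v - e_k - 200.0)))
        b_k1 = (
            3.0 * math.exp(0.0002 * (v - e_k + 100.0))
            + math.exp(0.1 * (v - e_k - 10.0))
        ) / (1.0 + math.exp(-0.5 * (v - e_k)))
        i_k1 = 5.405 * a_k1 / (a_k1 + b_k1) * (v - e_k)

        vf_rt = v * F_RT
        i_naca = (
            1000.0
            * (math.exp(0.35 * vf_rt) * nai**3 * 2.0
               - math.exp(-0.65 * vf_rt) * 140.0**3 * cai * 2.5)
            / ((87.5**3 + 140.0**3) * (1.38 + 2.0)
               * (1.0 + 0.1 * math.exp(-0.65 * vf_rt)))
        )
        i_nak = (
            2.724 * 5.4 * nai / ((5.4 + 1.0) * (nai + 40.0))
            / (1.0 + 0.1245 * math.exp(-0.1 * vf_rt) + 0.0353 * math.exp(-vf_rt))
        )
        i_pca = 0.1238 * cai / (0.0005 + cai)
        i_pk = 0.0146 * (v - e_k) / (1.0 + math.exp((25.0 - v) / 5.98))
        i_bna = 0.00029 * (v - e_na)
        i_bca = 0.000592 * (v - e_ca)

        iion_out[i] = (
            i_na + i_cal + i_to + i_kr + i_ks + i_k1 + i_naca + i_nak
            + i_pca + i_pk + i_bca + i_bna
        )

        # --- calcium subsystem and concentrations (forward Euler) ---
        kcasr = 2.5 - 1.5 / (1.0 + (1.5 / casr) ** 2)
        k1 = 0.15 / kcasr
        k2 = 0.045 * kcasr
        o_gate = k1 * cass * cass * rbar / (0.060 + k1 * cass * cass)
        d_rbar = -k2 * cass * rbar + 0.005 * (1.0 - rbar)

        i_leak = 0.00036 * (casr - cai)
        i_up = 0.006375 / (1.0 + (0.00025 / cai) ** 2)
        i_rel = 0.102 * o_gate * (casr - cass)
        i_xfer = 0.0038 * (cass - cai)

        buf_c = 1.0 / (1.0 + 0.2 * 0.001 / ((cai + 0.001) * (cai + 0.001)))
        buf_sr = 1.0 / (1.0 + 10.0 * 0.3 / ((casr + 0.3) * (casr + 0.3)))
        buf_ss = 1.0 / (1.0 + 0.4 * 0.00025 / ((cass + 0.00025) * (cass + 0.00025)))

        cap_2vcf = 0.185 / (2.0 * 0.016404 * 96485.3415)
        cap_vcf = 0.185 / (0.016404 * 96485.3415)
        cap_2vssf = 0.185 / (2.0 * 0.00005468 * 96485.3415)
        vsr_vc = 0.001094 / 0.016404
        vsr_vss = 0.001094 / 0.00005468
        vc_vss = 0.016404 / 0.00005468

        d_cai = buf_c * (
            (i_leak - i_up) * vsr_vc + i_xfer
            - (i_bca + i_pca - 2.0 * i_naca) * cap_2vcf
        )
        d_casr = buf_sr * (i_up - i_rel - i_leak)
        d_cass = buf_ss * (
            -i_cal * cap_2vssf + i_rel * vsr_vss - i_xfer * vc_vss
        )
        d_nai = -(i_na + i_bna + 3.0 * i_nak + 3.0 * i_naca) * cap_vcf
        d_ki = -(i_k1 + i_to + i_kr + i_ks - 2.0 * i_nak + i_pk) * cap_vcf

        y[i, 12] = rbar + dt_ms * d_rbar
        y[i, 13] = cai + dt_ms * d_cai
        y[i, 14] = casr + dt_ms * d_casr
        y[i, 15] = cass + dt_ms * d_cass
        y[i, 16] = nai + dt_ms * d_nai
        y[i, 17] = ki + dt_ms * d_ki

        # --- voltage gates ---
        m_inf = 1.0 / (1.0 + math.exp((-56.86 - v) / 9.03)) ** 2
        a_m = 1.0 / (1.0 + math.exp((-60.0 - v) / 5.0))
        b_m = 0.1 / (1.0 + math.exp((v + 35.0) / 5.0)) + 0.1 / (
            1.0 + math.exp((v - 50.0) / 200.0)
        )
        tau_m = a_m * b_m

        h_inf = 1.0 / (1.0 + math.exp((v + 71.55) / 7.43)) ** 2
        if v < -40.0:
            a_h = 0.057 * math.exp(-(v + 80.0) / 6.8)
            b_h = 2.7 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.3485 * v)
        else:
            a_h = 0.0
            b_h = 0.77 / (0.13 * (1.0 + math.exp(-(v + 10.66) / 11.1)))
        tau_h = 1.0 / (a_h + b_h)

        j_inf = h_inf
        if v < -40.0:
            a_j = (
                (-2.5428e4 * math.exp(0.2444 * v) - 6.948e-6 * math.exp(-0.04391 * v))
                * (v + 37.78)
                / (1.0 + math.exp(0.311 * (v + 79.23)))
            )
            b_j = 0.02424 * math.exp(-0.01052 * v) / (
                1.0 + math.exp(-0.1378 * (v + 40.14))
            )
        else:
            a_j = 0.0
            b_j = 0.6 * math.exp(0.057 * v) / (1.0 + math.exp(-0.1 * (v + 32.0)))
        tau_j = 1.0 / (a_j + b_j)

        xr1_inf = 1.0 / (1.0 + math.exp((-26.0 - v) / 7.0))
        tau_xr1 = (450.0 / (1.0 + math.exp((-45.0 - v) / 10.0))) * (
            6.0 / (1.0 + math.exp((v + 30.0) / 11.5))
        )
        xr2_inf = 1.0 / (1.0 + math.exp((v + 88.0) / 24.0))
        tau_xr2 = (3.0 / (1.0 + math.exp((-60.0 - v) / 20.0))) * (
            1.12 / (1.0 + math.exp((v - 60.0) / 20.0))
        )
        xs_inf = 1.0 / (1.0 + math.exp((-5.0 - v) / 14.0))
        tau_xs = (1400.0 / math.sqrt(1.0 + math.exp((5.0 - v) / 6.0))) * (
            1.0 / (1.0 + math.exp((v - 35.0) / 15.0))
        ) + 80.0

        r_inf = 1.0 / (1.0 + math.exp((20.0 - v) / 6.0))
        tau_r = 9.5 * math.exp(-((v + 40.0) ** 2) / 1800.0) + 0.8
        if epi_s:
            s_inf = 1.0 / (1.0 + math.exp((v + 20.0) / 5.0))
            tau_s = (
                85.0 * math.exp(-((v + 45.0) ** 2) / 320.0)
                + 5.0 / (1.0 + math.exp((v - 20.0) / 5.0))
                + 3.0
            )
        else:
            s_inf = 1.0 / (1.0 + math.exp((v + 28.0) / 5.0))
            tau_s = 1000.0 * math.exp(-((v + 67.0) ** 2) / 1000.0) + 8.0

        d_inf = 1.0 / (1.0 + math.exp((-8.0 - v) / 7.5))
        tau_d = (1.4 / (1.0 + math.exp((-35.0 - v) / 13.0)) + 0.25) * (
            1.4 / (1.0 + math.exp((v + 5.0) / 5.0))
        ) + 1.0 / (1.0 + math.exp((50.0 - v) / 20.0))

        f_inf = 1.0 / (1.0 + math.exp((v + 20.0) / 7.0))
        tau_f = (
            1102.5 * math.exp(-((v + 27.0) ** 2) / 225.0)
            + 200.0 / (1.0 + math.exp((13.0 - v) / 10.0))
            + 180.0 / (1.0 + math.exp((v + 30.0) / 10.0))
            + 20.0
        )
        f2_inf = 0.67 / (1.0 + math.exp((v + 35.0) / 7.0)) + 0.33
        tau_f2 = (
            562.0 * math.exp(-((v + 27.0) ** 2) / 240.0)
            + 31.0 / (1.0 + math.exp((25.0 - v) / 10.0))
            + 80.0 / (1.0 + math.exp((v + 30.0) / 10.0))
        )
        fcass_inf = 0.6 / (1.0 + (cass / 0.05) ** 2) + 0.4
        tau_fcass = 80.0 / (1.0 + (cass / 0.05) ** 2) + 2.0

        if rush_larsen:
            y[i, 0] = m_inf + (m - m_inf) * math.exp(-dt_ms / tau_m)
            y[i, 1] = h_inf + (h - h_inf) * math.exp(-dt_ms / tau_h)
            y[i, 2] = j_inf + (j - j_inf) * math.exp(-dt_ms / tau_j)
            y[i, 3] = xr1_inf + (xr1 - xr1_inf) * math.exp(-dt_ms / tau_xr1)
            y[i, 4] = xr2_inf + (xr2 - xr2_inf) * math.exp(-dt_ms / tau_xr2)
            y[i, 5] = xs_inf + (xs - xs_inf) * math.exp(-dt_ms / tau_xs)
            y[i, 6] = r_inf + (r - r_inf) * math.exp(-dt_ms / tau_r)
            y[i, 7] = s_inf + (s - s_inf) * math.exp(-dt_ms / tau_s)
            y[i, 8] = d_inf + (d - d_inf) * math.exp(-dt_ms / tau_d)
            y[i, 9] = f_inf + (f - f_inf) * math.exp(-dt_ms / tau_f)
            y[i, 10] = f2_inf + (f2 - f2_inf) * math.exp(-dt_ms / tau_f2)
            y[i, 11] = fcass_inf + (fcass - fcass_inf) * math.exp(-dt_ms / tau_fcass)
        else:
            y[i, 0] = m + dt_ms * (m_inf - m) / tau_m
            y[i, 1] = h + dt_ms * (h_inf - h) / tau_h
            y[i, 2] = j + dt_ms * (j_inf - j) / tau_j
            y[i, 3] = xr1 + dt_ms * (xr1_inf - xr1) / tau_xr1
            y[i, 4] = xr2 + dt_ms * (xr2_inf - xr2) / tau_xr2
            y[i, 5] = xs + dt_ms * (xs_inf - xs) / tau_xs
            y[i, 6] = r + dt_ms * (r_inf - r) / tau_r
            y[i, 7] = s + dt_ms * (s_inf - s) / tau_s
            y[i, 8] = d + dt_ms * (d_inf - d) / tau_d
            y[i, 9] = f + dt_ms * (f_inf - f) / tau_f
            y[i, 10] = f2 + dt_ms * (f2_inf - f2) / tau_f2
            y[i, 11] = fcass + dt_ms * (fcass_inf - fcass) / tau_fcass
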