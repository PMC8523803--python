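"""Activation detection, CV vector arithmetic, pooling, space constants."""

import numpy as np
import pandas as pd
import pytest

from fibrocv import bidomain, cv
from fibrocv.cv import ActivationMap, CVMeasurement
from fibrocv.mesh import ConductivityParams


def make_recording(traces, times_ms, stim_onset=0.0):
    """Wrap per-element Vm traces (T, ny, nx) in a minimal FieldRecording."""
    traces = np.asarray(traces, dtype=np.float32)
    ny, nx = traces.shape[1:]
    return bidomain.FieldRecording(
        times_ms=np.asarray(times_ms, dtype=float),
        vm=traces,
        vm_final=traces[-1].astype(float),
        phi_e_final=np.zeros((ny, nx)),
        stimulus_edge="left",
        stim_onset_ms=stim_onset,
        clamped=np.zeros((ny, nx), dtype=bool),
        config=None,
        mesh=type("M", (), {"element_edge_um": 50.0, "passive": np.zeros((ny, nx), bool)})(),
    )


def make_amap(times_ms, direction="+x", edge_um=50.0):
    times_ms = np.asarray(times_ms, dtype=float)
    conductive = np.isfinite(times_ms)
    return ActivationMap(
        times_ms=times_ms,
        upstroke_vps=np.full_like(times_ms, 200.0),
        conductive=conductive,
        block_labels=np.zeros_like(times_ms, dtype=int),
        n_block_regions=int((~conductive).any()),
        direction=direction,
        element_edge_um=edge_um,
    )


class TestActivationMap:
    def test_single_upstroke_found_at_max_slope_sample(self):
        """Brute-force scan of a synthetic trace crossing -60..0 mV."""
        t = np.arange(0, 10, 0.05)
        v = -85.0 + 120.0 / (1.0 + np.exp(-(t - 5.0) / 0.25))
        rec = make_recording(np.tile(v[:, None, None], (1, 2, 2)), t)
        amap = cv.activation_map(rec)
        dv = np.diff(v) / np.diff(t)
        window = (v[:-1] > -60.0) & (v[:-1] < 0.0)
        expected = t[np.flatnonzero(window)[np.argmax(dv[window])]]
        assert amap.conductive.all()
        assert amap.times_ms[0, 0] == pytest.approx(expected, abs=1e-9)

    def test_flat_resting_trace_is_non_conductive(self):
        t = np.arange(0, 10, 0.05)
        v = np.full_like(t, -85.0)
        rec = make_recording(np.tile(v[:, None, None], (1, 3, 3)), t)
        amap = cv.activation_map(rec)
        assert not amap.conductive.any()
        assert amap.n_block_regions == 1

    def test_coarse_stride_warns(self):
        t = np.arange(0, 10, 0.5)
        v = -85.0 + 120.0 / (1.0 + np.exp(-(t - 5.0) / 0.25))
        rec = make_recording(np.tile(v[:, None, None], (1, 2, 2)), t)
        with pytest.warns(UserWarning, match="under-resolve"):
            cv.activation_map(rec)


class TestCvVectors:
    def test_pure_longitudinal_triplet(self):
        """tx = 125 us, ty = 0 along +x: 0.4 m/s at 0 degrees."""
        t = np.zeros((3, 3))
        t[:, 1] = 0.125  # ms
        t[:, 2] = 0.250
        ms = cv.cv_vectors(make_amap(t), locations=[(0, 0)])
        assert ms[0].magnitude_m_s == pytest.approx(0.4)
        assert ms[0].angle_deg == pytest.approx(0.0)

    def test_diagonal_triplet(self):
        """tx = ty = 100 us along +x: 50 um / 141 us at 45 degrees."""
        t = np.array([[0.0, 0.1], [0.1, 0.2]])
        ms = cv.cv_vectors(make_amap(t), locations=[(0, 0)])
        assert ms[0].magnitude_m_s == pytest.approx(50e-6 / np.hypot(1e-4, 1e-4))
        assert ms[0].magnitude_m_s == pytest.approx(0.354, abs=5e-4)
        assert ms[0].angle_deg == pytest.approx(45.0)

    def test_negative_x_branch_reflects_angle(self):
        t = np.array([[0.0, 0.1], [0.1, 0.2]])
        ms = cv.cv_vectors(make_amap(t, direction="-x"), locations=[(0, 0)])
        assert ms[0].angle_deg == pytest.approx(135.0)

    @pytest.mark.parametrize(
        "direction, tx, ty, expected",
        [
            ("+x", 1.0, 0.0, 0.0),
            ("-x", -1.0, 0.0, 0.0),
            ("+y", 0.0, 1.0, 0.0),
            ("-y", 0.0, -1.0, 0.0),
            ("+y", 1.0, 1.0, 45.0),
            ("-y", 1.0, -1.0, 45.0),
        ],
    )
    def test_planar_waves_have_zero_tilt_in_every_branch(
        self, direction, tx, ty, expected
    ):
        t = np.zeros((2, 2))
        t[0, 1] = tx * 0.1
        t[1, 0] = ty * 0.1
        t[1, 1] = (tx + ty) * 0.1
        ms = cv.cv_vectors(make_amap(t, direction=direction), locations=[(0, 0)])
        assert ms[0].angle_deg == pytest.approx(expected)

    def test_triplet_touching_block_is_marked_blocked(self):
        t = np.zeros((2, 2))
        t[0, 1] = np.nan
        ms = cv.cv_vectors(make_amap(t), locations=[(0, 0)])
        assert ms[0].blocked and not ms[0].valid

    def test_degenerate_simultaneous_triplet_is_undefined(self):
        ms = cv.cv_vectors(make_amap(np.zeros((2, 2))), locations=[(0, 0)])
        assert not ms[0].blocked
        assert np.isnan(ms[0].magnitude_m_s)

    def test_out_of_grid_location_raises(self):
        with pytest.raises(ValueError):
            cv.cv_vectors(make_amap(np.zeros((3, 3))), locations=[(2, 2)])

    def test_default_triplets_are_mirror_invariant(self):
        pts = cv.default_triplets(20, 20)
        assert len(pts) == 4
        gaps = sorted(ix for _, ix in pts)
        mirrored = sorted(20 - 2 - ix for _, ix in pts)
        assert gaps == mirrored


class TestPoolAndSummarize:
    def test_identical_vectors_have_zero_spread(self):
        ms = [
            CVMeasurement((0, 0), d, 1e-4, 0.0, 0.4, 0.0, False)
            for d in ("+x", "-x", "+x", "-x")
        ]
        df = cv.pool_and_summarize({"s1": ms})
        row = df.iloc[0]
        assert row["median_cvl_m_s"] == pytest.approx(0.4)
        assert row["sd_cvl_m_s"] == pytest.approx(0.0)

    def test_median_of_three(self):
        ms = [
            CVMeasurement((0, 0), "+x", 1e-4, 0.0, v, 0.0, False)
            for v in (0.3, 0.4, 0.5)
        ]
        df = cv.pool_and_summarize({"s": ms})
        assert df.iloc[0]["median_cvl_m_s"] == pytest.approx(0.4)

    def test_all_blocked_subject_reports_nan(self):
        ms = [CVMeasurement((0, 0), "+x", np.nan, np.nan, np.nan, np.nan, True)]
        df = cv.pool_and_summarize({"s": ms})
        assert np.isnan(df.iloc[0]["median_cvl_m_s"])
        assert df.iloc[0]["n_blocked_l"] == 1

    def test_anisotropy_is_ratio_of_axis_medians(self):
        ms = [
            CVMeasurement((0, 0), "+x", 1e-4, 0.0, 0.4, 0.0, False),
            CVMeasurement((0, 0), "+y", 0.0, 1e-4, 0.2, 0.0, False),
        ]
        df = cv.pool_and_summarize({"s": ms})
        assert df.iloc[0]["anisotropy"] == pytest.approx(2.0)


class TestBoundaryError:
    def _vec(self, mag, ang=0.0, loc=(0, 0)):
        return CVMeasurement(loc, "+x", 1e-4, 0.0, mag, ang, False)

    def test_identical_inputs_give_zero_error(self):
        a = [self._vec(0.4, loc=(0, i)) for i in range(4)]
        out = cv.boundary_error(a, a)
        assert out.mean_error_magnitude_m_s == 0.0
        assert out.rmse_pct_magnitude == 0.0

    def test_constant_offset_formula(self):
        """+0.01 m/s on four 0.4 m/s magnitudes: mean 0.01, RMSE 2.5%."""
        a = [self._vec(0.4, loc=(0, i)) for i in range(4)]
        b = [self._vec(0.41, loc=(0, i)) for i in range(4)]
        out = cv.boundary_error(a, b)
        assert out.mean_error_magnitude_m_s == pytest.approx(0.01)
        assert out.rmse_pct_magnitude == pytest.approx(2.5)

    def test_mismatched_locations_raise(self):
        a = [self._vec(0.4, loc=(0, 0))]
        b = [self._vec(0.4, loc=(1, 1))]
        with pytest.raises(ValueError):
            cv.boundary_error(a, b)


class TestSpaceConstants:
    def test_printed_parameter_set(self):
        """R = 0.2 Ohm m^2, beta = 2e5 /m, sigma_myol = 0.1, sigma_el = 1:
        lambda_l = 0.30 mm; the transverse pair evaluates to 0.099 mm
        (printed as 0.09 after truncation)."""
        sc = cv.space_constants(ConductivityParams.preset("evaluation"))
        assert round(sc.lambda_l_mm, 2) == 0.30
        assert sc.lambda_t_mm == pytest.approx(0.0990, abs=5e-4)

    def test_vanishing_myocyte_conductivity_limit(self):
        p = ConductivityParams(sigma_myo_long_100=1e-12)
        sc = cv.space_constants(p)
        assert sc.lambda_l_mm < 1e-3

    def test_equal_conductivities_closed_form(self):
        p = ConductivityParams(
            sigma_myo_long_100=0.4, sigma_e_long_100=0.4, anis_myo=1.0, anis_e=1.0
        )
        sc = cv.space_constants(p)
        expected = np.sqrt(p.membrane_R * 0.4 / (2.0 * p.beta_sv)) * 1e3
        assert sc.lambda_l_mm == pytest.approx(expected)
        assert sc.lambda_t_mm == pytest.approx(expected)
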