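"""Composition fractions, fibrosis measure, tiling, and patch morphometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fibrocv import quantify
from fibrocv.image import LabeledTissueImage


def make_image(es, f=None, mf=None, pixel_size_nm=1000.0):
    es = np.asarray(es, dtype=bool)
    zero = np.zeros_like(es)
    return LabeledTissueImage(
        es, zero if f is None else f, zero if mf is None else mf,
        pixel_size_nm=pixel_size_nm,
    )


class TestFractions:
    def test_full_es_mask_gives_unit_fractions(self):
        img = make_image(np.ones((40, 40)))
        fr = quantify.compute_fractions(img)
        assert fr.v_e == 1.0 and fr.v_nm == 1.0 and fr.v_f == 0.0

    def test_half_filled_mask_gives_half(self):
        es = np.zeros((40, 40), dtype=bool)
        es[:, :20] = True
        fr = quantify.compute_fractions(make_image(es))
        assert fr.v_e == 0.5

    def test_matches_brute_force_pixel_counts(self):
        rng = np.random.default_rng(3)
        es = rng.random((37, 53)) < 0.3
        f = (~es) & (rng.random((37, 53)) < 0.05)
        mf = (~es) & (~f) & (rng.random((37, 53)) < 0.05)
        fr = quantify.compute_fractions(make_image(es, f, mf))
        n = es.size
        assert fr.v_e == sum(es.ravel()) / n
        assert fr.v_f == sum(f.ravel()) / n
        assert fr.v_mf == sum(mf.ravel()) / n

    def test_roi_restriction_and_errors(self):
        es = np.zeros((30, 30), dtype=bool)
        es[:10] = True
        img = make_image(es)
        fr = quantify.compute_fractions(img, roi=(0, 10, 0, 30))
        assert fr.v_e == 1.0
        with pytest.raises(ValueError):
            quantify.compute_fractions(img, roi=(5, 5, 0, 30))
        with pytest.raises(ValueError):
            quantify.compute_fractions(img, roi=(0, 40, 0, 30))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2**32 - 1))
    def test_composition_identity_holds(self, seed):
        """V_nm equals V_e + V_f + V_mf for any disjoint mask triplet."""
        rng = np.random.default_rng(seed)
        es = rng.random((16, 16)) < rng.random()
        f = (~es) & (rng.random((16, 16)) < 0.2)
        mf = (~es) & (~f) & (rng.random((16, 16)) < 0.2)
        fr = quantify.compute_fractions(make_image(es, f, mf))
        assert fr.v_nm == pytest.approx(fr.v_e + fr.v_f + fr.v_mf, abs=1e-12)


class TestFibrosisMeasure:
    @pytest.mark.parametrize(
        "sample, donor_mean, expected",
        [
            (0.3968, 0.2209, 0.1759),  # the cohort-mean worked example
            (0.5, 0.5, 0.0),
            (0.10, 0.2209, -0.1209),
        ],
    )
    def test_excess_over_donor_mean(self, sample, donor_mean, expected):
        assert quantify.compute_fibrosis(sample, donor_mean) == pytest.approx(
            expected, abs=1e-12
        )

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            quantify.compute_fibrosis(1.2, 0.2)


class TestHeterogeneity:
    def test_one_mm_roi_with_50um_tiles_gives_400_tiles(self):
        # acquisition geometry: 378 nm pixels covering 1 mm
        n = int(round(1_000_000 / 378))
        img = make_image(np.zeros((n, n), dtype=bool), pixel_size_nm=378.0)
        prof = quantify.heterogeneity_profile(img)
        assert prof.n_tiles == 400

    def test_uniform_mask_has_zero_sigma(self):
        img = make_image(np.ones((200, 200)), pixel_size_nm=2000.0)
        prof = quantify.heterogeneity_profile(img)
        assert prof.sigma_intra == 0.0
        assert prof.mean_vnm == 1.0

    def test_checkerboard_matches_direct_sample_sd(self):
        # 50-um checkerboard at 2.5-um pixels: 400 tiles, half full half empty
        tile_px = 20
        block = np.indices((20, 20)).sum(axis=0) % 2 == 0
        es = np.kron(block, np.ones((tile_px, tile_px), dtype=bool))
        img = make_image(es, pixel_size_nm=2500.0)
        prof = quantify.heterogeneity_profile(img)
        direct = np.std([0.0] * 200 + [1.0] * 200, ddof=1) * 100
        assert prof.sigma_intra == pytest.approx(direct, abs=1e-9)
        assert prof.sigma_intra == pytest.approx(50.06, abs=0.01)

    def test_sigma_invariant_under_mirroring(self):
        rng = np.random.default_rng(8)
        es = rng.random((250, 250)) < 0.3
        img = make_image(es, pixel_size_nm=2000.0)
        mirrored = make_image(es[::-1, ::-1], pixel_size_nm=2000.0)
        a = quantify.heterogeneity_profile(img)
        b = quantify.heterogeneity_profile(mirrored)
        assert a.sigma_intra == pytest.approx(b.sigma_intra, abs=1e-12)
        assert a.histogram == pytest.approx(b.histogram)

    def test_histogram_is_probability_per_bin(self):
        rng = np.random.default_rng(9)
        img = make_image(rng.random((250, 250)) < 0.4, pixel_size_nm=2000.0)
        prof = quantify.heterogeneity_profile(img)
        assert prof.histogram.sum() == pytest.approx(1.0)
        assert prof.mean_vnm == pytest.approx(prof.tile_vnm.mean())

    def test_roi_smaller_than_tile_raises(self):
        img = make_image(np.ones((10, 10)), pixel_size_nm=1000.0)
        with pytest.raises(ValueError):
            quantify.heterogeneity_profile(img, tile_edge_um=50.0)


class TestPatchGeometry:
    def test_solid_rectangle_matches_moment_ellipse(self):
        """A 100x20 um bar: axes from the closed-form second moments.

        A solid W x H rectangle has variance (W^2-1)/12 along its axis
        (discrete pixels), and the moment-matched ellipse axis is
        4*sqrt(variance) ~ 2W/sqrt(3).
        """
        mask = np.zeros((60, 140), dtype=bool)
        mask[20:40, 20:120] = True  # 20 x 100 px at 1 um/px
        pf = quantify.patch_geometry(mask, pixel_size_nm=1000.0)
        assert pf.n_patches == 1
        assert pf.largest_area_um2 == pytest.approx(2000.0)
        assert pf.mean_major_axis_um == pytest.approx(np.sqrt(16 * (100**2 - 1) / 12), rel=1e-6)
        assert pf.mean_minor_axis_um == pytest.approx(np.sqrt(16 * (20**2 - 1) / 12), rel=1e-6)
        assert pf.mean_major_axis_um == pytest.approx(115.5, abs=0.2)
        assert pf.mean_minor_axis_um == pytest.approx(23.1, abs=0.2)
        assert pf.mean_axis_ratio == pytest.approx(5.0, rel=0.01)

    def test_blob_below_area_threshold_is_dropped(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[10:20, 10:20] = True  # 100 um^2 < 150 um^2
        pf = quantify.patch_geometry(mask, pixel_size_nm=1000.0)
        assert pf.n_patches == 0
        assert np.isnan(pf.largest_area_um2)

    def test_disc_has_unit_axis_ratio(self):
        yy, xx = np.indices((80, 80))
        mask = (yy - 40) ** 2 + (xx - 40) ** 2 < 30**2
        pf = quantify.patch_geometry(mask, pixel_size_nm=1000.0)
        assert pf.mean_axis_ratio == pytest.approx(1.0, rel=0.02)
        assert pf.mean_eccentricity < 0.2

    def test_features_invariant_under_translation(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[10:30, 10:60] = True
        rolled = np.roll(np.roll(mask, 30, axis=0), 25, axis=1)
        a = quantify.patch_geometry(mask, 1000.0)
        b = quantify.patch_geometry(rolled, 1000.0)
        assert a.largest_area_um2 == b.largest_area_um2
        assert a.mean_major_axis_um == pytest.approx(b.mean_major_axis_um)

    def test_diagonal_strand_kept_by_8_connectivity(self):
        mask = np.eye(30, dtype=bool)  # 1-px diagonal: one 8-connected strand
        pf = quantify.patch_geometry(mask, pixel_size_nm=3000.0, min_area_um2=150.0)
        assert pf.n_patches == 1
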