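"""Synthetic phantom generator: analytic truths, rasterisation, cohorts."""

import math

import numpy as np
import pytest

from ssdekit.geometry import BACKGROUND
from ssdekit.phantom import (
    CohortRanges,
    Disc,
    Ellipse,
    PhantomSpec,
    analytic_corrected_dims,
    analytic_dw,
    generate_cohort,
    generate_phantom,
)


def water_disc_spec(radius=10.0):
    return PhantomSpec(body_semi_axes=(radius, radius), lungs=(), bone=None,
                       raster_shape=(256, 256))


class TestAnalyticDw:
    def test_all_water_body_is_geometric_effective_diameter(self):
        spec = PhantomSpec(body_semi_axes=(15.0, 10.0), lungs=(), bone=None,
                           raster_shape=(384, 384))
        assert analytic_dw(spec) == pytest.approx(2 * math.sqrt(150), abs=1e-9)

    def test_two_lungs_hand_value(self):
        # body (15,10), lungs each (6,4) at -700 HU: mean HU = -224, d_w = 21.576
        spec = PhantomSpec(
            body_semi_axes=(15.0, 10.0),
            lungs=(Ellipse((-7.5, 0.0), (6.0, 4.0)), Ellipse((7.5, 0.0), (6.0, 4.0))),
            bone=None,
            raster_shape=(384, 384),
        )
        mean_hu = (-700 * 2 * math.pi * 24) / (math.pi * 150)
        assert mean_hu == pytest.approx(-224)
        assert analytic_dw(spec) == pytest.approx(2 * math.sqrt(0.776 * 150), abs=1e-6)
        assert analytic_dw(spec) == pytest.approx(21.576, abs=2e-3)


class TestAnalyticCorrectedDims:
    def test_all_tissue_body(self):
        spec = PhantomSpec(body_semi_axes=(15.0, 10.0), lungs=(), bone=None,
                           raster_shape=(384, 384))
        m = analytic_corrected_dims(spec)
        assert m.ap_corr == pytest.approx(20.0)
        assert m.lat_corr == pytest.approx(30.0)

    def test_lat_chord_through_both_lungs(self):
        # total lung chord 20 cm in a 30 cm body: lat = 10 + 0.3*20 = 16
        spec = PhantomSpec(
            body_semi_axes=(15.0, 10.0),
            lungs=(Ellipse((-7.0, 0.0), (5.0, 3.0)), Ellipse((7.0, 0.0), (5.0, 3.0))),
            bone=None,
            raster_shape=(384, 384),
        )
        m = analytic_corrected_dims(spec)
        assert m.lat_corr == pytest.approx(16.0, abs=1e-9)
        assert m.ap_corr == pytest.approx(20.0, abs=1e-9)  # lungs miss the AP chord

    def test_ap_chord_through_bone(self):
        # bone disc diameter 3 cm in a 20 cm AP body: ap = 17 + 1.2*3 = 20.6
        spec = PhantomSpec(
            body_semi_axes=(15.0, 10.0),
            lungs=(),
            bone=Disc((0.0, 5.0), 1.5),
            raster_shape=(384, 384),
        )
        m = analytic_corrected_dims(spec)
        assert m.ap_corr == pytest.approx(20.6, abs=1e-9)
        assert m.lat_corr == pytest.approx(30.0, abs=1e-9)

    def test_tangent_region_rejected(self):
        spec = PhantomSpec(
            body_semi_axes=(15.0, 10.0),
            lungs=(Ellipse((5.0, 0.0), (5.0, 3.0)),),  # tangent to the AP chord x=0
            bone=None,
            raster_shape=(384, 384),
        )
        with pytest.raises(ValueError, match="tangent"):
            analytic_corrected_dims(spec)


class TestGeneratePhantom:
    def test_water_disc_truths(self):
        hu, truth = generate_phantom(water_disc_spec(10.0))
        assert truth.d_w == pytest.approx(20.0)
        assert truth.d_eff_corr == pytest.approx(20.0)

    def test_truth_invariant_deff_is_geometric_mean(self, default_phantom):
        _, _, truth = default_phantom
        assert truth.d_eff_corr == pytest.approx(
            math.sqrt(truth.ap_corr * truth.lat_corr), abs=1e-9)

    def test_same_seed_reproduces_raster(self):
        spec = PhantomSpec(noise_sigma=15.0, seed=3)
        hu1, _ = generate_phantom(spec)
        hu2, _ = generate_phantom(spec)
        assert np.array_equal(hu1, hu2)

    def test_hu_assignments(self, default_phantom):
        spec, hu, truth = default_phantom
        labels = truth.class_map.labels
        assert set(np.unique(hu[labels == 0])) == {-1000.0}
        assert set(np.unique(hu[labels == 1])) == {-700.0}
        assert set(np.unique(hu[labels == 2])) == {0.0}
        assert set(np.unique(hu[labels == 3])) == {300.0}

    def test_out_of_body_region_rejected(self):
        with pytest.raises(ValueError, match="outside the body"):
            PhantomSpec(body_semi_axes=(10.0, 8.0),
                        lungs=(Ellipse((8.0, 0.0), (4.0, 4.0)),), bone=None,
                        raster_shape=(384, 384))

    def test_bone_lung_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            PhantomSpec(
                body_semi_axes=(15.0, 10.0),
                lungs=(Ellipse((-3.0, 0.0), (2.5, 2.5)), Ellipse((7.0, 0.0), (2.0, 2.0))),
                bone=Disc((0.0, 1.0), 1.5),
                raster_shape=(384, 384),
            )

    def test_raster_area_converges_to_analytic(self, default_phantom):
        spec, _, truth = default_phantom
        body_px = int((truth.class_map.labels != BACKGROUND).sum())
        analytic = truth.body_area / (spec.pixel_spacing[0] * spec.pixel_spacing[1] / 100)
        assert abs(body_px - analytic) / analytic < 0.02


class TestGenerateCohort:
    def test_reproducible_and_distinct(self):
        c1 = generate_cohort(8, seed=11, raster_shape=(96, 96), pixel_spacing=(5.0, 5.0))
        c2 = generate_cohort(8, seed=11, raster_shape=(96, 96), pixel_spacing=(5.0, 5.0))
        for (h1, t1, _), (h2, t2, _) in zip(c1, c2):
            assert np.array_equal(h1, h2)
            assert t1.d_eff_corr == t2.d_eff_corr
        sizes = {round(t.d_eff_corr, 6) for _, t, _ in c1}
        assert len(sizes) == 8

    def test_collapsed_ranges_give_identical_geometry(self):
        ranges = CohortRanges(
            d_eff_corr=(20.0, 20.0), aspect=(0.66, 0.66),
            lung_halfwidth_frac=(0.3, 0.3), lung_halfheight_frac=(0.6, 0.6),
            lung_offset_frac=(0.5, 0.5), bone_radius_frac=(0.1, 0.1),
            ctdi_vol=(8.5, 8.5),
        )
        cohort = generate_cohort(4, ranges, seed=2, raster_shape=(96, 96),
                                 pixel_spacing=(5.0, 5.0))
        axes = {s.body_semi_axes for _, _, s in cohort}
        assert len(axes) == 1
        assert all(t.d_eff_corr == pytest.approx(20.0, abs=1e-9) for _, t, _ in cohort)

    def test_sizes_span_requested_range(self):
        cohort = generate_cohort(25, seed=5, raster_shape=(96, 96), pixel_spacing=(5.0, 5.0))
        d = [t.d_eff_corr for _, t, _ in cohort]
        assert min(d) >= 15.9 - 1e-9 and max(d) <= 26.7 + 1e-9

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            generate_cohort(0)
        with pytest.raises(ValueError):
            CohortRanges(d_eff_corr=(10.0, 5.0))
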