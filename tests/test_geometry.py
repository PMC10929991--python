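"""Body mask, axes, chord scanning and ROI statistics."""

import math

import numpy as np
import pytest

from conftest import ellipse_mask
from ssdekit.dosimetry import water_equivalent_diameter
from ssdekit.geometry import (
    BACKGROUND,
    BONE,
    LUNG,
    TISSUE,
    LineSegment,
    TissueClassMap,
    body_axes,
    extract_body_mask,
    measure_corrected_dimensions,
    roi_stats,
    scan_tissue_runs,
)


def _cmap(labels, spacing=(1.0, 1.0)):
    return TissueClassMap(labels=np.asarray(labels, dtype=np.uint8), pixel_spacing=spacing)


class TestExtractBodyMask:
    def test_plain_ellipse_unchanged(self):
        mask = ellipse_mask((200, 300), (100, 150), (120, 80))  # (a_col, b_row)
        labels = np.where(mask, TISSUE, BACKGROUND)
        assert np.array_equal(extract_body_mask(_cmap(labels)), mask)

    def test_internal_classes_absorbed_and_filled(self):
        mask = ellipse_mask((200, 300), (100, 150), (120, 80))
        labels = np.where(mask, TISSUE, BACKGROUND)
        lung = ellipse_mask((200, 300), (100, 110), (30, 40))
        labels[lung] = LUNG
        hole = ellipse_mask((200, 300), (100, 190), (10, 10))
        labels[hole] = BACKGROUND  # internal air pocket
        assert np.array_equal(extract_body_mask(_cmap(labels)), mask)

    def test_disconnected_couch_blob_removed(self):
        mask = ellipse_mask((220, 300), (100, 150), (120, 80))
        labels = np.where(mask, TISSUE, BACKGROUND)
        labels[210:215, 50:250] = TISSUE  # couch fragment, smaller than body
        assert np.array_equal(extract_body_mask(_cmap(labels)), mask)

    def test_empty_segmentation_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_body_mask(_cmap(np.zeros((16, 16))))


class TestBodyAxes:
    def test_axis_aligned_ellipse_chords(self):
        # semi-axes 150 px (cols) x 100 px (rows)
        mask = ellipse_mask((240, 340), (120, 170), (150, 100))
        geom = body_axes(mask, (1.0, 1.0))
        assert geom.centroid == pytest.approx((120, 170), abs=0.5)
        assert geom.lat_line.length_mm((1.0, 1.0)) == pytest.approx(300, abs=1.5)
        assert geom.ap_line.length_mm((1.0, 1.0)) == pytest.approx(200, abs=1.5)
        # LAT horizontal, AP vertical for a supine-thorax-shaped mask
        assert geom.lat_line.start[0] == pytest.approx(geom.lat_line.end[0], abs=1e-6)
        assert geom.ap_line.start[1] == pytest.approx(geom.ap_line.end[1], abs=1e-6)

    def test_circle_tie_breaks_to_image_axes(self):
        mask = ellipse_mask((220, 220), (110, 110), (90, 90))
        geom = body_axes(mask, (1.0, 1.0))
        assert geom.lat_line.length_mm((1.0, 1.0)) == pytest.approx(180, abs=1.5)
        assert geom.ap_line.length_mm((1.0, 1.0)) == pytest.approx(180, abs=1.5)
        assert geom.lat_line.start[0] == pytest.approx(geom.lat_line.end[0], abs=1e-6)

    def test_rotated_ellipse_chords_match_analytic_axes(self):
        mask = ellipse_mask((300, 300), (150, 150), (110, 70), angle_deg=30.0)
        geom = body_axes(mask, (1.0, 1.0))
        assert geom.lat_line.length_mm((1.0, 1.0)) == pytest.approx(220, abs=2.0)
        assert geom.ap_line.length_mm((1.0, 1.0)) == pytest.approx(140, abs=2.0)
        # chord direction ~30 degrees off horizontal
        dr = geom.lat_line.end[0] - geom.lat_line.start[0]
        dc = geom.lat_line.end[1] - geom.lat_line.start[1]
        assert abs(math.degrees(math.atan2(abs(dr), abs(dc)))) == pytest.approx(30, abs=2)

    def test_anisotropic_spacing_measured_in_mm(self):
        # circle in mm-space = ellipse in pixels when spacing is anisotropic
        mask = ellipse_mask((240, 140), (120, 70), (50, 100))  # 100 rows x 50 cols semi
        geom = body_axes(mask, (0.5, 1.0))  # physically 50 mm x 50 mm semi
        assert geom.lat_line.length_mm((0.5, 1.0)) == pytest.approx(100, abs=1.5)
        assert geom.ap_line.length_mm((0.5, 1.0)) == pytest.approx(100, abs=1.5)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            body_axes(np.zeros((8, 8), dtype=bool), (1.0, 1.0))


class TestScanTissueRuns:
    def test_uniform_tissue_chord(self):
        labels = np.zeros((40, 240), dtype=np.uint8)
        labels[10:30, 20:220] = TISSUE  # 200 px = 20 cm wide bar
        cmap = _cmap(labels)
        runs = scan_tissue_runs(cmap, LineSegment((20, 20), (20, 219)))
        assert [r.tissue_class for r in runs] == ["tissue"]
        assert runs[0].length == pytest.approx(20.0, abs=0.15)

    def test_five_segment_chord_counts(self):
        # tissue 2 | lung 8 | bone 3 | lung 8 | tissue 2 (cm), 1 mm pixels
        labels = np.zeros((40, 260), dtype=np.uint8)
        labels[10:30, 10:240] = TISSUE
        labels[10:30, 30:110] = LUNG
        labels[10:30, 110:140] = BONE
        labels[10:30, 140:220] = LUNG
        cmap = _cmap(labels)
        runs = scan_tissue_runs(cmap, LineSegment((20, 10), (20, 239)))
        assert [r.tissue_class for r in runs] == ["tissue", "lung", "bone", "lung", "tissue"]
        for run, expect in zip(runs, [2, 8, 3, 8, 2]):
            assert run.length == pytest.approx(expect, abs=0.15)

    def test_pixel_spacing_honoured(self):
        labels = np.zeros((8, 16), dtype=np.uint8)
        labels[3:6, 3:13] = TISSUE  # 10 px at 0.7 mm/px = 0.7 cm
        cmap = _cmap(labels, spacing=(0.7, 0.7))
        runs = scan_tissue_runs(cmap, LineSegment((4, 3), (4, 12)))
        assert sum(r.length for r in runs) == pytest.approx(0.7, abs=0.08)

    def test_internal_air_scored_as_lung(self):
        labels = np.zeros((40, 140), dtype=np.uint8)
        labels[10:30, 10:130] = TISSUE
        labels[15:25, 50:90] = BACKGROUND  # trachea-like air pocket
        cmap = _cmap(labels)
        body = extract_body_mask(cmap)
        runs = scan_tissue_runs(cmap, LineSegment((20, 10), (20, 129)), body_mask=body)
        assert [r.tissue_class for r in runs] == ["tissue", "lung", "tissue"]
        assert runs[1].length == pytest.approx(4.0, abs=0.15)

    def test_degenerate_line_gives_no_runs(self):
        labels = np.zeros((10, 10), dtype=np.uint8)
        labels[2:8, 2:8] = TISSUE
        assert scan_tissue_runs(_cmap(labels), LineSegment((5, 5), (5, 5))) == []


class TestMeasureCorrectedDimensions:
    def test_all_tissue_ellipse(self):
        # 2a = 30 cm lateral, 2b = 20 cm AP at 1 mm pixels
        mask = ellipse_mask((240, 340), (120, 170), (150, 100))
        cmap = _cmap(np.where(mask, TISSUE, BACKGROUND))
        m = measure_corrected_dimensions(cmap)
        assert m.lat_corr == pytest.approx(30.0, abs=0.2)
        assert m.ap_corr == pytest.approx(20.0, abs=0.2)

    def test_central_lung_band_discounts_lateral(self):
        mask = ellipse_mask((240, 340), (120, 170), (150, 100))
        labels = np.where(mask, TISSUE, BACKGROUND)
        labels[:, 120:220][mask[:, 120:220]] = LUNG  # 10 cm lung band on the LAT chord
        m = measure_corrected_dimensions(_cmap(labels))
        assert m.lat_corr == pytest.approx(20 + 0.3 * 10, abs=0.25)

    def test_ninety_degree_rotation_preserves_anatomy_labels(self):
        mask = ellipse_mask((240, 340), (120, 170), (150, 100))
        labels = np.where(mask, TISSUE, BACKGROUND)
        labels[:, 120:220][mask[:, 120:220]] = LUNG
        m0 = measure_corrected_dimensions(_cmap(labels))
        m90 = measure_corrected_dimensions(_cmap(np.rot90(labels)))
        # axes are anatomical (LAT = major), so the values survive rotation
        assert m90.lat_corr == pytest.approx(m0.lat_corr, abs=0.15)
        assert m90.ap_corr == pytest.approx(m0.ap_corr, abs=0.15)

    def test_density_bounds_vs_geometric_chords(self):
        mask = ellipse_mask((240, 340), (120, 170), (150, 100))
        labels = np.where(mask, TISSUE, BACKGROUND)
        labels[:, 120:220][mask[:, 120:220]] = LUNG
        m = measure_corrected_dimensions(_cmap(labels))
        assert m.lat_corr <= 30.0 + 0.2  # lung discount can only shorten
        assert sum(r.length for r in m.lat_runs) == pytest.approx(30.0, abs=0.2)


class TestRoiStats:
    def test_uniform_water_disc(self):
        hu = np.zeros((60, 60))
        mask = np.zeros((60, 60), dtype=bool)
        mask.flat[:1000] = True  # exactly 1000 pixels at 1 mm^2
        s = roi_stats(hu, mask, (1.0, 1.0))
        assert s.mean_ct == 0.0
        assert s.area == pytest.approx(10.0)

    def test_mean_is_arithmetic(self):
        hu = np.full((10, 10), -1000.0)
        hu[:5] = 0.0
        mask = np.ones((10, 10), dtype=bool)
        assert roi_stats(hu, mask, (1.0, 1.0)).mean_ct == pytest.approx(-500.0)

    def test_water_phantom_dw_matches_geometric_diameter(self):
        mask = ellipse_mask((320, 400), (160, 200), (160, 110))  # a=16, b=11 cm
        hu = np.where(mask, 0.0, -1000.0)
        s = roi_stats(hu, mask, (1.0, 1.0))
        d_w = water_equivalent_diameter(s.mean_ct, s.area)
        assert d_w == pytest.approx(2 * math.sqrt(16 * 11), rel=0.01)

    def test_errors(self):
        with pytest.raises(ValueError):
            roi_stats(np.zeros((4, 4)), np.zeros((4, 4), dtype=bool), (1.0, 1.0))
        with pytest.raises(ValueError):
            roi_stats(np.zeros((4, 4)), np.zeros((5, 4), dtype=bool), (1.0, 1.0))
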