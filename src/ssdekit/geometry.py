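"""Geometry extraction from a tissue class map.

Turns a per-pixel tissue labelling of an axial slice into the quantities the
dose equations need: the body mask (ROI for the water-equivalent diameter),
the AP and LAT body axes, and the per-tissue segment runs along each axis
that feed the electron-density-corrected dimension sum.

Raster convention: row 0 is anterior, indices are 0-based ``(row, col)``,
and pixel spacing may be anisotropic — it is honoured per direction, with
all physical lengths computed in millimetres and reported in centimetres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .dosimetry import AxisMeasurement, ElectronDensityTable, SegmentRun, corrected_dimension

__all__ = [
    "BACKGROUND",
    "LUNG",
    "TISSUE",
    "BONE",
    "CLASS_NAMES",
    "TissueClassMap",
    "LineSegment",
    "BodyGeometry",
    "ROIStats",
    "extract_body_mask",
    "body_axes",
    "scan_tissue_runs",
    "measure_corrected_dimensions",
    "roi_stats",
]

BACKGROUND, LUNG, TISSUE, BONE = 0, 1, 2, 3
CLASS_NAMES = {BACKGROUND: "background", LUNG: "lung", TISSUE: "tissue", BONE: "bone"}

# Fraction of a pixel used as the sampling step along measurement chords.
_CHORD_STEP_PX = 0.5
# Major/minor axis ratios closer to 1 than this resolve to image axes.
_AXIS_TIE_TOL = 0.01


@dataclass(frozen=True)
class TissueClassMap:
    """Per-pixel labelling over {background, lung, tissue, bone}."""

    labels: np.ndarray  # 2-D int array, values in {0, 1, 2, 3}
    pixel_spacing: tuple[float, float]  # (row mm, col mm)

    def __post_init__(self) -> None:
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D raster")
        if not set(np.unique(self.labels)) <= {BACKGROUND, LUNG, TISSUE, BONE}:
            raise ValueError("labels must be within {0, 1, 2, 3}")
        if min(self.pixel_spacing) <= 0:
            raise ValueError("pixel spacing must be > 0")


@dataclass(frozen=True)
class LineSegment:
    """A straight pixel-space segment from ``start`` to ``end`` (row, col)."""

    start: tuple[float, float]
    end: tuple[float, float]

    def length_mm(self, pixel_spacing: tuple[float, float]) -> float:
        dr = (self.end[0] - self.start[0]) * pixel_spacing[0]
        dc = (self.end[1] - self.start[1]) * pixel_spacing[1]
        return float(np.hypot(dr, dc))


@dataclass(frozen=True)
class BodyGeometry:
    """Body mask with its centroid and the AP/LAT measurement chords."""

    body_mask: np.ndarray
    centroid: tuple[float, float]  # (row, col), pixels
    ap_line: LineSegment
    lat_line: LineSegment


@dataclass(frozen=True)
class ROIStats:
    """Mean CT number (HU) and area (cm^2) of a region of interest."""

    mean_ct: float
    area: float


def extract_body_mask(class_map: TissueClassMap) -> np.ndarray:
    """Binary body mask: non-background pixels, hole-filled, largest component.

    Hole filling absorbs internal air (trachea, bowel gas) into the body so
    it contributes to the D_w ROI, as in TG220 outer-body contouring;
    keeping only the largest connected component drops couch or clothing
    fragments.
    """
    fg = class_map.labels != BACKGROUND
    if not fg.any():
        raise ValueError("empty segmentation: no non-background pixels")
    filled = ndimage.binary_fill_holes(fg)
    labelled, n = ndimage.label(filled)
    if n > 1:
        sizes = ndimage.sum_labels(filled, labelled, index=np.arange(1, n + 1))
        filled = labelled == (1 + int(np.argmax(sizes)))
    return filled


def _chord_through(
    mask: np.ndarray,
    centroid_mm: np.ndarray,
    direction_mm: np.ndarray,
    spacing: np.ndarray,
) -> LineSegment:
    """Longest in-mask chord through the centroid along a physical direction."""
    step_mm = _CHORD_STEP_PX * float(spacing.min()) * 0.5
    unit = direction_mm / np.linalg.norm(direction_mm)

    def march(sign: float) -> np.ndarray:
        pos = centroid_mm.copy()
        last_inside = centroid_mm.copy()
        while True:
            pos = pos + sign * step_mm * unit
            idx = np.round(pos / spacing).astype(int)
            if not (0 <= idx[0] < mask.shape[0] and 0 <= idx[1] < mask.shape[1]):
                break
            if not mask[idx[0], idx[1]]:
                break
            last_inside = pos.copy()
        return last_inside

    p0 = march(-1.0) / spacing
    p1 = march(+1.0) / spacing
    return LineSegment(start=(float(p0[0]), float(p0[1])), end=(float(p1[0]), float(p1[1])))


def body_axes(body_mask: np.ndarray, pixel_spacing: tuple[float, float]) -> BodyGeometry:
    """Locate the AP and LAT measurement chords of a body mask.

    The centroid is the mask's centre of mass.  The LAT line is the chord
    through the centroid along the mask's principal (major) axis and the AP
    line the chord along the orthogonal minor axis, both computed in
    physical (mm) coordinates so anisotropic pixels are handled correctly.
    Near-isotropic masks (axis ratio within 1%) fall back to the image
    column (LAT) and row (AP) axes — the supine-thorax orientation.
    """
    if not body_mask.any():
        raise ValueError("empty body mask")
    spacing = np.asarray(pixel_spacing, dtype=float)
    rows, cols = np.nonzero(body_mask)
    pts_mm = np.stack([rows * spacing[0], cols * spacing[1]], axis=1)
    centroid_mm = pts_mm.mean(axis=0)

    cov = np.cov((pts_mm - centroid_mm).T)
    eigvals, eigvecs = np.linalg.eigh(cov)  # ascending
    ratio = np.sqrt(eigvals[1] / max(eigvals[0], 1e-12))
    if ratio <= 1.0 + _AXIS_TIE_TOL:
        major = np.array([0.0, 1.0])  # image columns = lateral
        minor = np.array([1.0, 0.0])  # image rows = anterior-posterior
    else:
        major = eigvecs[:, 1]
        minor = eigvecs[:, 0]

    lat_line = _chord_through(body_mask, centroid_mm, major, spacing)
    ap_line = _chord_through(body_mask, centroid_mm, minor, spacing)
    centroid_px = centroid_mm / spacing
    return BodyGeometry(
        body_mask=body_mask,
        centroid=(float(centroid_px[0]), float(centroid_px[1])),
        ap_line=ap_line,
        lat_line=lat_line,
    )


def scan_tissue_runs(
    class_map: TissueClassMap,
    line: LineSegment,
    body_mask: np.ndarray | None = None,
) -> list[SegmentRun]:
    """Sample tissue classes along a chord and merge them into segment runs.

    The chord is sampled at sub-pixel steps (0.5 px of the finer spacing
    direction) with nearest-neighbour label lookup.  Background samples that
    fall inside the body — internal air such as the trachea — are scored as
    lung, the closest available attenuation class; samples outside the body
    are ignored.  Run lengths are returned in centimetres and their sum
    equals the within-body chord length to within one pixel.
    """
    if body_mask is None:
        body_mask = extract_body_mask(class_map)
    spacing = np.asarray(class_map.pixel_spacing, dtype=float)
    p0 = np.asarray(line.start) * spacing
    p1 = np.asarray(line.end) * spacing
    total_mm = float(np.linalg.norm(p1 - p0))
    if total_mm == 0:
        return []
    step_mm = _CHORD_STEP_PX * float(spacing.min())
    n = max(int(np.ceil(total_mm / step_mm)), 1)
    step_mm = total_mm / n
    ts = (np.arange(n) + 0.5) / n
    pts_mm = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
    idx = np.round(pts_mm / spacing).astype(int)
    idx[:, 0] = np.clip(idx[:, 0], 0, class_map.labels.shape[0] - 1)
    idx[:, 1] = np.clip(idx[:, 1], 0, class_map.labels.shape[1] - 1)

    inside = body_mask[idx[:, 0], idx[:, 1]]
    labels = class_map.labels[idx[:, 0], idx[:, 1]]
    labels = np.where(labels == BACKGROUND, LUNG, labels)  # internal air -> lung

    runs: list[SegmentRun] = []
    current: int | None = None
    count = 0
    for lab, ins in zip(labels, inside):
        if not ins:
            lab = -1  # break runs at out-of-body samples
        if lab == current:
            count += 1
        else:
            if current is not None and current >= 0 and count:
                runs.append(SegmentRun(CLASS_NAMES[current], count * step_mm / 10.0))
            current, count = int(lab), 1
    if current is not None and current >= 0 and count:
        runs.append(SegmentRun(CLASS_NAMES[current], count * step_mm / 10.0))
    return runs


def measure_corrected_dimensions(
    class_map: TissueClassMap,
    densities: ElectronDensityTable | None = None,
) -> AxisMeasurement:
    """Corrected AP and LAT dimensions of a slice from its class map.

    Composes body-mask extraction, axis location, chord scanning and the
    electron-density-weighted dimension sum.
    """
    densities = densities or ElectronDensityTable()
    mask = extract_body_mask(class_map)
    geom = body_axes(mask, class_map.pixel_spacing)
    ap_runs = tuple(scan_tissue_runs(class_map, geom.ap_line, mask))
    lat_runs = tuple(scan_tissue_runs(class_map, geom.lat_line, mask))
    return AxisMeasurement(
        ap_corr=corrected_dimension(ap_runs, densities),
        lat_corr=corrected_dimension(lat_runs, densities),
        ap_runs=ap_runs,
        lat_runs=lat_runs,
    )


def roi_stats(
    hu_image: np.ndarray,
    body_mask: np.ndarray,
    pixel_spacing: tuple[float, float],
) -> ROIStats:
    """Mean HU and area (cm^2) of the masked ROI — the inputs to D_w."""
    if hu_image.shape != body_mask.shape:
        raise ValueError("image and mask shapes differ")
    n = int(body_mask.sum())
    if n == 0:
        raise ValueError("empty ROI mask")
    pixel_area_cm2 = (pixel_spacing[0] / 10.0) * (pixel_spacing[1] / 10.0)
    return ROIStats(
        mean_ct=float(hu_image[body_mask].mean()),
        area=n * pixel_area_cm2,
    )
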