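"""Synthetic thoracic-slice phantoms with analytic dose ground truth.

Each phantom is an axial cross-section built from exact geometric primitives
in physical (cm) coordinates: an elliptical soft-tissue body on an air
background, two lung ellipses mirrored about the anterior-posterior axis,
and a posterior vertebral bone disc centred on the AP chord — so both
measurement chords cross non-tissue classes, as in a real thorax.  Default
HU assignments (air −1000, lung −700, tissue 0, bone +300) sit at least
100 HU inside the reference segmenter's thresholds.

Because the geometry is exact, the water-equivalent diameter and the
electron-density-corrected effective diameter have closed forms
(:func:`analytic_dw`, :func:`analytic_corrected_dims`) computed from ellipse
and disc areas and chord intersections — never from the raster — so the
rasterised pipeline's error is measurable against them.

Coordinate convention: x runs laterally (columns), y runs
anterior→posterior (rows); the body is centred on the raster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .dosimetry import (
    AxisMeasurement,
    ElectronDensityTable,
    SegmentRun,
    corrected_dimension,
    corrected_effective_diameter,
    water_equivalent_diameter,
)
from .geometry import BACKGROUND, BONE, LUNG, TISSUE, TissueClassMap

__all__ = [
    "Ellipse",
    "Disc",
    "PhantomSpec",
    "PhantomTruth",
    "CohortRanges",
    "generate_phantom",
    "analytic_dw",
    "analytic_corrected_dims",
    "generate_cohort",
]


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse: centre (x, y) and semi-axes (sx, sy), in cm."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]

    @property
    def area(self) -> float:
        return math.pi * self.semi_axes[0] * self.semi_axes[1]

    def contains(self, x, y):
        cx, cy = self.center
        sx, sy = self.semi_axes
        return ((x - cx) / sx) ** 2 + ((y - cy) / sy) ** 2 <= 1.0

    def boundary(self, n: int = 128) -> np.ndarray:
        t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
        return np.stack([
            self.center[0] + self.semi_axes[0] * np.cos(t),
            self.center[1] + self.semi_axes[1] * np.sin(t),
        ], axis=1)


@dataclass(frozen=True)
class Disc:
    """Circle: centre (x, y) and radius, in cm."""

    center: tuple[float, float]
    radius: float

    @property
    def area(self) -> float:
        return math.pi * self.radius**2

    def contains(self, x, y):
        return (x - self.center[0]) ** 2 + (y - self.center[1]) ** 2 <= self.radius**2

    def boundary(self, n: int = 128) -> np.ndarray:
        t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
        return np.stack([
            self.center[0] + self.radius * np.cos(t),
            self.center[1] + self.radius * np.sin(t),
        ], axis=1)


_DEFAULT_HU = {"air": -1000.0, "lung": -700.0, "tissue": 0.0, "bone": 300.0}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric and imaging parameters of one synthetic slice."""

    body_semi_axes: tuple[float, float] = (15.0, 10.0)  # (a_lat, b_ap) cm
    lungs: tuple[Ellipse, ...] = (
        Ellipse(center=(-7.5, 0.0), semi_axes=(4.5, 6.5)),
        Ellipse(center=(7.5, 0.0), semi_axes=(4.5, 6.5)),
    )
    bone: Disc | None = Disc(center=(0.0, 6.5), radius=1.3)
    hu: dict = field(default_factory=lambda: dict(_DEFAULT_HU))
    pixel_spacing: tuple[float, float] = (1.0, 1.0)  # (row mm, col mm)
    raster_shape: tuple[int, int] = (384, 384)  # (rows, cols)
    ctdi_vol: float | None = 8.5  # mGy
    noise_sigma: float = 0.0  # HU
    seed: int = 0

    def __post_init__(self) -> None:
        a, b = self.body_semi_axes
        if a <= 0 or b <= 0:
            raise ValueError("body semi-axes must be > 0")
        body = Ellipse(center=(0.0, 0.0), semi_axes=(a, b))
        for region in (*self.lungs, *((self.bone,) if self.bone else ())):
            pts = region.boundary()
            if not np.all(body.contains(pts[:, 0], pts[:, 1])):
                raise ValueError("phantom region extends outside the body ellipse")
        if self.bone is not None:
            for lung in self.lungs:
                pts = self.bone.boundary()
                if np.any(lung.contains(pts[:, 0], pts[:, 1])):
                    raise ValueError("bone disc overlaps a lung")
                pts = lung.boundary()
                if np.any(self.bone.contains(pts[:, 0], pts[:, 1])):
                    raise ValueError("lung overlaps the bone disc")
        fov_x = self.raster_shape[1] * self.pixel_spacing[1] / 10.0
        fov_y = self.raster_shape[0] * self.pixel_spacing[0] / 10.0
        if 2 * a >= fov_x or 2 * b >= fov_y:
            raise ValueError("body does not fit inside the raster field of view")

    @property
    def body(self) -> Ellipse:
        return Ellipse(center=(0.0, 0.0), semi_axes=self.body_semi_axes)


@dataclass(frozen=True)
class PhantomTruth:
    """Analytic ground truth for one phantom (exact geometry, not raster)."""

    class_map: TissueClassMap
    d_w: float  # cm
    ap_corr: float  # cm
    lat_corr: float  # cm
    d_eff_corr: float  # cm
    mean_hu: float
    body_area: float  # cm^2


def _grid_cm(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = spec.raster_shape
    dy, dx = spec.pixel_spacing
    y = (np.arange(rows) - (rows - 1) / 2.0) * dy / 10.0
    x = (np.arange(cols) - (cols - 1) / 2.0) * dx / 10.0
    return np.meshgrid(x, y)  # (X, Y) each (rows, cols)


def _class_raster(spec: PhantomSpec) -> np.ndarray:
    X, Y = _grid_cm(spec)
    labels = np.full(spec.raster_shape, BACKGROUND, dtype=np.uint8)
    labels[spec.body.contains(X, Y)] = TISSUE
    for lung in spec.lungs:
        labels[lung.contains(X, Y)] = LUNG
    if spec.bone is not None:
        labels[spec.bone.contains(X, Y)] = BONE
    return labels


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    """Rasterise a phantom to an HU image and compute its analytic truth.

    Regions are painted back to front (body, lungs, bone); Gaussian HU
    noise of ``spec.noise_sigma`` is added when positive, seeded by
    ``spec.seed``.  The returned truth comes from the exact geometry.
    """
    labels = _class_raster(spec)
    hu_of = {BACKGROUND: spec.hu["air"], LUNG: spec.hu["lung"],
             TISSUE: spec.hu["tissue"], BONE: spec.hu["bone"]}
    hu = np.empty(spec.raster_shape, dtype=float)
    for cid, val in hu_of.items():
        hu[labels == cid] = val
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_sigma, size=hu.shape)

    dims = analytic_corrected_dims(spec)
    mean_hu, body_area = _analytic_roi(spec)
    truth = PhantomTruth(
        class_map=TissueClassMap(labels=labels, pixel_spacing=spec.pixel_spacing),
        d_w=analytic_dw(spec),
        ap_corr=dims.ap_corr,
        lat_corr=dims.lat_corr,
        d_eff_corr=corrected_effective_diameter(dims.ap_corr, dims.lat_corr),
        mean_hu=mean_hu,
        body_area=body_area,
    )
    return hu, truth


def _analytic_roi(spec: PhantomSpec) -> tuple[float, float]:
    """Area-weighted mean HU over the body and the exact body area (cm^2)."""
    a_body = spec.body.area
    a_lung = sum(l.area for l in spec.lungs)
    a_bone = spec.bone.area if spec.bone is not None else 0.0
    a_tissue = a_body - a_lung - a_bone
    mean_hu = (
        spec.hu["tissue"] * a_tissue + spec.hu["lung"] * a_lung + spec.hu["bone"] * a_bone
    ) / a_body
    return mean_hu, a_body


def analytic_dw(spec: PhantomSpec) -> float:
    """Closed-form water-equivalent diameter from exact region areas."""
    mean_hu, a_body = _analytic_roi(spec)
    return water_equivalent_diameter(mean_hu, a_body)


def _chord_intervals(spec: PhantomSpec, axis: str) -> list[tuple[float, float, str]]:
    """Non-tissue intervals cut by the central AP (x=0) or LAT (y=0) chord."""
    regions: list[tuple[str, Ellipse | Disc]] = [("lung", l) for l in spec.lungs]
    if spec.bone is not None:
        regions.append(("bone", spec.bone))
    out = []
    for name, reg in regions:
        if isinstance(reg, Ellipse):
            cx, cy = reg.center
            sx, sy = reg.semi_axes
        else:
            cx, cy = reg.center
            sx = sy = reg.radius
        # distance of the chord from the region centre, along the cut axis
        if axis == "ap":  # chord x = 0, varying y
            d, half, c_along = abs(cx), sx, cy
            semi_along = sy
        else:  # chord y = 0, varying x
            d, half, c_along = abs(cy), sy, cx
            semi_along = sx
        if abs(d - half) < 1e-9:
            raise ValueError(f"chord is tangent to a {name} region")
        if d >= half:
            continue
        h = semi_along * math.sqrt(1.0 - (d / half) ** 2)
        out.append((c_along - h, c_along + h, name))
    return sorted(out)


def analytic_corrected_dims(
    spec: PhantomSpec,
    densities: ElectronDensityTable | None = None,
) -> AxisMeasurement:
    """Exact corrected AP and LAT dimensions from chord-region intersections."""
    densities = densities or ElectronDensityTable()
    a, b = spec.body_semi_axes
    axes = {"ap": b, "lat": a}
    runs: dict[str, tuple[SegmentRun, ...]] = {}
    for axis, semi in axes.items():
        intervals = _chord_intervals(spec, axis)
        segs: list[SegmentRun] = []
        pos = -semi
        for lo, hi, name in intervals:
            if lo < pos - 1e-9:
                raise ValueError("overlapping regions on the measurement chord")
            if lo > pos:
                segs.append(SegmentRun("tissue", lo - pos))
            segs.append(SegmentRun(name, hi - lo))
            pos = hi
        if pos < semi:
            segs.append(SegmentRun("tissue", semi - pos))
        runs[axis] = tuple(segs)
    return AxisMeasurement(
        ap_corr=corrected_dimension(runs["ap"], densities),
        lat_corr=corrected_dimension(runs["lat"], densities),
        ap_runs=runs["ap"],
        lat_runs=runs["lat"],
    )


@dataclass(frozen=True)
class CohortRanges:
    """Sampling ranges for a phantom cohort.

    Shapes are sampled scale-free (aspect ratio, relative lung and bone
    sizes) and each phantom is then scaled so its analytic corrected
    effective diameter lands uniformly inside ``d_eff_corr`` — by default
    the adult thoracic span of 15.9–26.7 cm.
    """

    d_eff_corr: tuple[float, float] = (15.9, 26.7)  # cm
    aspect: tuple[float, float] = (0.60, 0.72)  # b_ap / a_lat
    lung_halfwidth_frac: tuple[float, float] = (0.26, 0.32)  # of a_lat
    lung_halfheight_frac: tuple[float, float] = (0.55, 0.68)  # of b_ap
    lung_offset_frac: tuple[float, float] = (0.48, 0.54)  # lung centre x, of a_lat
    bone_radius_frac: tuple[float, float] = (0.09, 0.13)  # of b_ap
    bone_offset_frac: float = 0.62  # bone centre y, of b_ap
    ctdi_vol: tuple[float, float] = (4.2, 10.5)  # mGy

    def __post_init__(self) -> None:
        for name in ("d_eff_corr", "aspect", "lung_halfwidth_frac",
                     "lung_halfheight_frac", "lung_offset_frac",
                     "bone_radius_frac", "ctdi_vol"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"invalid range for {name}")


def _sample_spec(rng: np.random.Generator, ranges: CohortRanges,
                 raster_shape, pixel_spacing, noise_sigma) -> PhantomSpec:
    u = lambda r: rng.uniform(*r)
    a = 1.0  # unit lateral semi-axis; rescaled below
    b = u(ranges.aspect) * a
    sx = u(ranges.lung_halfwidth_frac) * a
    sy = u(ranges.lung_halfheight_frac) * b
    x0 = u(ranges.lung_offset_frac) * a
    r = u(ranges.bone_radius_frac) * b
    spec = PhantomSpec(
        body_semi_axes=(a, b),
        lungs=(Ellipse((-x0, 0.0), (sx, sy)), Ellipse((x0, 0.0), (sx, sy))),
        bone=Disc((0.0, ranges.bone_offset_frac * b), r),
        pixel_spacing=pixel_spacing,
        raster_shape=(8192, 8192),  # placeholder: unit phantom trivially fits
        ctdi_vol=u(ranges.ctdi_vol),
        noise_sigma=noise_sigma,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    target = u(ranges.d_eff_corr)
    dims = analytic_corrected_dims(spec)
    s = target / corrected_effective_diameter(dims.ap_corr, dims.lat_corr)
    return replace(
        spec,
        body_semi_axes=(a * s, b * s),
        lungs=tuple(
            Ellipse((l.center[0] * s, l.center[1] * s),
                    (l.semi_axes[0] * s, l.semi_axes[1] * s))
            for l in spec.lungs
        ),
        bone=Disc((0.0, spec.bone.center[1] * s), spec.bone.radius * s),
        raster_shape=raster_shape,
    )


def generate_cohort(
    n: int,
    ranges: CohortRanges | None = None,
    seed: int = 0,
    raster_shape: tuple[int, int] = (480, 480),
    pixel_spacing: tuple[float, float] = (1.0, 1.0),
    noise_sigma: float = 0.0,
) -> list[tuple[np.ndarray, PhantomTruth, PhantomSpec]]:
    """Sample ``n`` reproducible phantoms spanning the requested size range."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = ranges or CohortRanges()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        spec = _sample_spec(rng, ranges, raster_shape, pixel_spacing, noise_sigma)
        hu, truth = generate_phantom(spec)
        out.append((hu, truth, spec))
    return out
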