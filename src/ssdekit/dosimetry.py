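"""Closed-form SSDE dose mathematics.

The size-specific dose estimate (SSDE) scales the scanner-reported CTDIvol by
a size-dependent conversion factor *f*.  Patient size on an axial slice is
expressed either as the water-equivalent diameter D_w (AAPM TG220) or as the
corrected effective diameter D_eff_corr, the geometric mean of the
anterior-posterior and lateral body dimensions after each tissue segment
along those axes has been re-weighted by its electron density relative to
water (lung 0.3, soft tissue 1.0, bone 1.2).

All diameters are in centimetres, doses in mGy.  The conversion-factor
coefficients assume the 32-cm PMMA body phantom at 120 kVp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "F_COEFF_A",
    "F_COEFF_B",
    "ElectronDensityTable",
    "SegmentRun",
    "AxisMeasurement",
    "DoseResult",
    "water_equivalent_diameter",
    "corrected_dimension",
    "corrected_effective_diameter",
    "conversion_factor",
    "ssde",
]

# f = A * exp(-B * D) for the 32-cm body phantom at 120 kVp.
F_COEFF_A = 3.704369
F_COEFF_B = 0.03671937

#: Diameters below this give f > 1 (ln A / B).
F_UNITY_DIAMETER_CM = math.log(F_COEFF_A) / F_COEFF_B

_TISSUE_CLASSES = ("lung", "tissue", "bone")


@dataclass(frozen=True)
class ElectronDensityTable:
    """Per-class electron density relative to water (dimensionless)."""

    lung: float = 0.3
    tissue: float = 1.0
    bone: float = 1.2

    def __post_init__(self) -> None:
        for name in _TISSUE_CLASSES:
            if getattr(self, name) <= 0:
                raise ValueError(f"relative electron density for {name!r} must be > 0")

    def density(self, tissue_class: str) -> float:
        if tissue_class not in _TISSUE_CLASSES:
            raise ValueError(
                f"unknown tissue class {tissue_class!r}; expected one of {_TISSUE_CLASSES}"
            )
        return getattr(self, tissue_class)


@dataclass(frozen=True)
class SegmentRun:
    """A contiguous stretch of one tissue class along a measurement axis."""

    tissue_class: str
    length: float  # cm

    def __post_init__(self) -> None:
        if self.tissue_class not in _TISSUE_CLASSES:
            raise ValueError(
                f"unknown tissue class {self.tissue_class!r}; expected one of {_TISSUE_CLASSES}"
            )
        if self.length < 0:
            raise ValueError("segment length must be >= 0")


@dataclass(frozen=True)
class AxisMeasurement:
    """Corrected AP and LAT body dimensions with their per-class runs."""

    ap_corr: float  # cm
    lat_corr: float  # cm
    ap_runs: tuple[SegmentRun, ...] = field(default_factory=tuple)
    lat_runs: tuple[SegmentRun, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class DoseResult:
    """Per-slice dose summary: diameters, conversion factors and SSDEs.

    ``ssde_dw``/``ssde_deff`` are None when the slice carried no CTDIvol.
    """

    d_w: float  # cm
    d_eff_corr: float  # cm
    f_dw: float
    f_deff: float
    ctdi_vol: float | None  # mGy
    ssde_dw: float | None  # mGy
    ssde_deff: float | None  # mGy

    def __post_init__(self) -> None:
        for name in ("d_w", "d_eff_corr", "f_dw", "f_deff"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.ctdi_vol is not None:
            for f, s in ((self.f_dw, self.ssde_dw), (self.f_deff, self.ssde_deff)):
                if s is None or abs(s - f * self.ctdi_vol) > 1e-9:
                    raise ValueError("ssde must equal f x ctdi_vol")


def water_equivalent_diameter(mean_ct: float, area: float) -> float:
    """Water-equivalent diameter (cm) of an ROI from its mean CT number and area.

    D_w = 2 * sqrt((mean_ct/1000 + 1) * area / pi).  A water ROI (0 HU)
    reduces to the geometric diameter; an air ROI (-1000 HU) gives 0.

    Parameters
    ----------
    mean_ct : mean CT number over the ROI, in HU (>= -1000).
    area : ROI area in cm^2 (>= 0).
    """
    if area < 0:
        raise ValueError("area must be >= 0")
    if mean_ct < -1000:
        raise ValueError("mean CT number below -1000 HU has no water equivalent")
    return 2.0 * math.sqrt((mean_ct / 1000.0 + 1.0) * area / math.pi)


def corrected_dimension(
    runs: list[SegmentRun] | tuple[SegmentRun, ...],
    densities: ElectronDensityTable | None = None,
) -> float:
    """Water-equivalent body dimension (cm): sum of rho_e-weighted run lengths."""
    densities = densities or ElectronDensityTable()
    return sum(densities.density(r.tissue_class) * r.length for r in runs)


def corrected_effective_diameter(ap_corr: float, lat_corr: float) -> float:
    """Geometric mean sqrt(AP_corr x LAT_corr) of the corrected dimensions (cm)."""
    if ap_corr < 0 or lat_corr < 0:
        raise ValueError("corrected dimensions must be >= 0")
    return math.sqrt(ap_corr * lat_corr)


def conversion_factor(diameter: float) -> float:
    """Size-dependent conversion factor f at the given body diameter (cm).

    f = 3.704369 * exp(-0.03671937 * D); strictly decreasing in D, and > 1
    for all diameters below ~35.7 cm.  Applies identically whether D is the
    corrected effective diameter or the water-equivalent diameter.
    """
    if diameter < 0:
        raise ValueError("diameter must be >= 0")
    return F_COEFF_A * math.exp(-F_COEFF_B * diameter)


def ssde(f: float, ctdi_vol: float) -> float:
    """Size-specific dose estimate SSDE = f x CTDIvol (mGy)."""
    if f <= 0:
        raise ValueError("conversion factor must be > 0")
    if ctdi_vol < 0:
        raise ValueError("CTDIvol must be >= 0")
    return f * ctdi_vol


def dose_result(
    d_w: float,
    d_eff_corr: float,
    ctdi_vol: float | None,
) -> DoseResult:
    """Assemble a DoseResult from the two diameters and (optional) CTDIvol."""
    f_dw = conversion_factor(d_w)
    f_deff = conversion_factor(d_eff_corr)
    if ctdi_vol is None:
        return DoseResult(d_w, d_eff_corr, f_dw, f_deff, None, None, None)
    return DoseResult(
        d_w,
        d_eff_corr,
        f_dw,
        f_deff,
        ctdi_vol,
        ssde(f_dw, ctdi_vol),
        ssde(f_deff, ctdi_vol),
    )
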