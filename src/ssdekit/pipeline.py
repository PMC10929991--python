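"""Per-slice SSDE pipeline: segment -> geometry -> dose.

The flow for one slice is: tissue class map -> body mask -> ROI statistics
-> water-equivalent diameter, and in parallel body axes -> per-tissue
segment runs -> corrected AP/LAT dimensions -> corrected effective
diameter; both diameters then map through the size-dependent conversion
factor to SSDE = f x CTDIvol.
"""

from __future__ import annotations

from .dosimetry import DoseResult, ElectronDensityTable, corrected_effective_diameter, dose_result
from .geometry import (
    TissueClassMap,
    extract_body_mask,
    measure_corrected_dimensions,
    roi_stats,
)
from .imaging_io import CTSlice
from .segmentation import ThresholdConfig, threshold_segment

__all__ = ["compute_dose", "compute_dose_from_classmap"]


def compute_dose_from_classmap(
    ct: CTSlice,
    class_map: TissueClassMap,
    densities: ElectronDensityTable | None = None,
    ctdi_vol: float | None = None,
) -> DoseResult:
    """Dose result for a slice given an already-computed class map.

    ``ctdi_vol`` overrides the slice's own value when given (scanners often
    omit the DICOM tag); if neither is present the SSDE fields are None.
    """
    densities = densities or ElectronDensityTable()
    mask = extract_body_mask(class_map)
    stats = roi_stats(ct.hu_pixels, mask, ct.pixel_spacing)
    from .dosimetry import water_equivalent_diameter

    d_w = water_equivalent_diameter(stats.mean_ct, stats.area)
    dims = measure_corrected_dimensions(class_map, densities)
    d_eff = corrected_effective_diameter(dims.ap_corr, dims.lat_corr)
    ctdi = ctdi_vol if ctdi_vol is not None else ct.ctdi_vol
    return dose_result(d_w, d_eff, ctdi)


def compute_dose(
    ct: CTSlice,
    segmenter: str = "threshold",
    model=None,
    densities: ElectronDensityTable | None = None,
    thresholds: ThresholdConfig | None = None,
    ctdi_vol: float | None = None,
) -> DoseResult:
    """End-to-end dose computation for one slice.

    ``segmenter`` selects the tissue classifier: ``"threshold"`` (the
    deterministic HU-threshold reference, the default) or ``"unet"``
    (requires a trained ``model``).
    """
    if segmenter == "threshold":
        cmap = threshold_segment(ct.hu_pixels, ct.pixel_spacing, thresholds)
    elif segmenter == "unet":
        if model is None:
            raise ValueError("segmenter='unet' requires a trained model")
        from .segmentation import predict_classmap

        cmap = predict_classmap(model, ct.hu_pixels, ct.pixel_spacing)
    else:
        raise ValueError(f"unknown segmenter {segmenter!r}")
    return compute_dose_from_classmap(ct, cmap, densities, ctdi_vol)
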