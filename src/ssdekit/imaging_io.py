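"""Reading CT slices (DICOM or portable fixtures) and writing dose reports.

A fixture is a raster of Hounsfield units (``.npy``, or whitespace-delimited
text) next to a JSON sidecar of the same stem carrying at least
``pixel_spacing_mm``; optional keys are ``ctdi_vol_mgy``, ``id`` and any
provenance metadata (e.g. a phantom's analytic truth).  Fixture and DICOM
paths produce the identical :class:`CTSlice` contract, so everything
downstream is source-agnostic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dosimetry import DoseResult

logger = logging.getLogger(__name__)

__all__ = ["CTSlice", "load_dicom_slice", "load_fixture", "write_fixture",
           "write_report", "read_report"]

#: DICOM tag for CTDIvol (0018,9345); many scanners omit it.
_CTDIVOL_TAG = (0x0018, 0x9345)

REPORT_COLUMNS = ["id", "d_w_cm", "d_eff_corr_cm", "f_dw", "f_deff",
                  "ctdi_vol_mgy", "ssde_dw_mgy", "ssde_deff_mgy"]


@dataclass(frozen=True)
class CTSlice:
    """One axial slice: HU raster, pixel spacing (mm), optional CTDIvol (mGy)."""

    hu_pixels: np.ndarray
    pixel_spacing: tuple[float, float]  # (row mm, col mm)
    ctdi_vol: float | None = None
    slice_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.pixel_spacing) <= 0:
            raise ValueError("pixel spacing must be > 0")
        if self.hu_pixels.min() < -1024:
            logger.warning("slice %s: HU below -1024 floor", self.slice_id or "<unnamed>")


def load_dicom_slice(path) -> CTSlice:
    """Read a single-frame CT DICOM file into a CTSlice.

    HU = stored value x RescaleSlope + RescaleIntercept.  CTDIvol is taken
    from tag (0018,9345) when present, else left absent with a warning.
    """
    import pydicom

    ds = pydicom.dcmread(path)
    if getattr(ds, "Modality", None) != "CT":
        raise ValueError(f"{path}: not a CT DICOM (Modality={getattr(ds, 'Modality', None)!r})")
    if "PixelSpacing" not in ds:
        raise ValueError(f"{path}: missing PixelSpacing")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    hu = ds.pixel_array.astype(float) * slope + intercept
    elem = ds.get(_CTDIVOL_TAG)
    ctdi = float(elem.value) if elem is not None and elem.value is not None else None
    if ctdi is None:
        logger.warning("%s: no CTDIvol tag (0018,9345); SSDE will need an override", path)
    return CTSlice(
        hu_pixels=hu,
        pixel_spacing=(float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1])),
        ctdi_vol=ctdi,
        slice_id=str(getattr(ds, "SOPInstanceUID", Path(path).stem)),
        metadata={"source": str(path), "format": "dicom"},
    )


def _sidecar_path(raster_path: Path) -> Path:
    return raster_path.with_suffix(".json")


def load_fixture(path) -> CTSlice:
    """Read a raster + JSON-sidecar fixture into a CTSlice."""
    raster_path = Path(path)
    sidecar = _sidecar_path(raster_path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    missing = [k for k in ("pixel_spacing_mm",) if k not in meta]
    if missing:
        raise ValueError(f"{sidecar}: missing required keys: {', '.join(missing)}")
    if raster_path.suffix == ".npy":
        hu = np.load(raster_path)
    else:
        hu = np.loadtxt(raster_path)
    ctdi = meta.get("ctdi_vol_mgy")
    if ctdi is None:
        logger.warning("%s: no ctdi_vol_mgy in sidecar; SSDE will need an override", path)
    return CTSlice(
        hu_pixels=np.asarray(hu, dtype=float),
        pixel_spacing=tuple(float(v) for v in meta["pixel_spacing_mm"]),
        ctdi_vol=None if ctdi is None else float(ctdi),
        slice_id=str(meta.get("id", raster_path.stem)),
        metadata={**meta, "source": str(raster_path), "format": "fixture"},
    )


def write_fixture(path, hu_image: np.ndarray, pixel_spacing, ctdi_vol=None,
                  slice_id: str | None = None, extra: dict | None = None) -> Path:
    """Write a raster (+ sidecar) fixture; returns the raster path."""
    raster_path = Path(path)
    if raster_path.suffix == ".npy":
        np.save(raster_path, np.asarray(hu_image, dtype=np.float32))
    else:
        np.savetxt(raster_path, np.asarray(hu_image), fmt="%.1f")
    meta = {
        "pixel_spacing_mm": [float(pixel_spacing[0]), float(pixel_spacing[1])],
        "id": slice_id or raster_path.stem,
    }
    if ctdi_vol is not None:
        meta["ctdi_vol_mgy"] = float(ctdi_vol)
    if extra:
        meta.update(extra)
    _sidecar_path(raster_path).write_text(json.dumps(meta, indent=1))
    return raster_path


def _results_frame(results: list[tuple[str, DoseResult]]) -> pd.DataFrame:
    rows = []
    for slice_id, r in results:
        rows.append({
            "id": slice_id,
            "d_w_cm": r.d_w,
            "d_eff_corr_cm": r.d_eff_corr,
            "f_dw": r.f_dw,
            "f_deff": r.f_deff,
            "ctdi_vol_mgy": r.ctdi_vol,
            "ssde_dw_mgy": r.ssde_dw,
            "ssde_deff_mgy": r.ssde_deff,
        })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_report(results: list[tuple[str, DoseResult]], path, format: str = "csv") -> Path:
    """Write per-slice dose results.

    CSV rounds numeric cells to one decimal (the reporting convention for
    dose tables); JSON keeps full precision.
    """
    path = Path(path)
    df = _results_frame(results)
    if format == "csv":
        out = df.copy()
        for col in REPORT_COLUMNS[1:]:
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.1f}")
        out.to_csv(path, index=False)
    elif format == "json":
        path.write_text(df.to_json(orient="records", indent=1))
    else:
        raise ValueError(f"unknown report format {format!r}")
    return path


def read_report(path) -> pd.DataFrame:
    """Read back a dose report written by :func:`write_report`."""
    path = Path(path)
    if path.suffix == ".json":
        return pd.DataFrame(json.loads(path.read_text()), columns=REPORT_COLUMNS)
    return pd.read_csv(path)
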