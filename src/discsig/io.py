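"""Readers and writers for slices, masks, frames and metric rows.

Supported slice formats:

* **DICOM** (``.dcm``/``.ima``) — spacing from ``PixelSpacing``, rescale
  slope/intercept applied when present;
* **NIfTI** (``.nii``/``.nii.gz``) — spacing from the header zooms, 2D or
  singleton-third-dimension volumes;
* **PNG/TIFF + JSON sidecar** — 16-bit integer raster with a
  ``<stem>.json`` sidecar holding ``pixel_spacing_mm``, an
  ``intensity_scale`` (stored counts = intensity * scale) and free meta.

Masks are written as 8-bit PNG (0/255) with a JSON provenance sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .core import DiscFrame, DiscMetrics, NucleusMask, SagittalSlice, ValidationError

__all__ = [
    "read_slice",
    "write_slice_png",
    "write_slice_nifti",
    "write_mask_png",
    "read_mask_png",
    "write_frame_json",
    "read_frame_json",
    "write_metrics_json",
]

DICOM_SUFFIXES = {".dcm", ".ima", ".dicom"}
RASTER_SUFFIXES = {".png", ".tif", ".tiff"}


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def read_slice(path: str | Path) -> SagittalSlice:
    """Read a sagittal slice from DICOM, NIfTI or raster+sidecar."""
    path = Path(path)
    name = path.name.lower()
    if path.suffix.lower() in DICOM_SUFFIXES:
        return _read_dicom(path)
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        return _read_nifti(path)
    if path.suffix.lower() in RASTER_SUFFIXES:
        return _read_raster(path)
    raise ValidationError(f"unrecognised image format: {path.name}")


def _read_dicom(path: Path) -> SagittalSlice:
    import pydicom

    ds = pydicom.dcmread(path)
    data = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    data = data * slope + intercept
    spacing = getattr(ds, "PixelSpacing", None)
    if spacing is None:
        raise ValidationError(f"{path.name}: DICOM file lacks PixelSpacing")
    meta = {"format": "dicom"}
    for tag in ("RepetitionTime", "EchoTime", "PatientID", "SeriesDescription"):
        if hasattr(ds, tag):
            meta[tag] = str(getattr(ds, tag))
    return SagittalSlice(intensity=np.clip(data, 0, None),
                         pixel_spacing_mm=(float(spacing[0]), float(spacing[1])),
                         meta=meta)


def _read_nifti(path: Path) -> SagittalSlice:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim == 3:
        if data.shape[2] != 1:
            raise ValidationError(
                f"{path.name}: expected a single 2D slice, got shape {data.shape}")
        data = data[:, :, 0]
    zooms = img.header.get_zooms()[:2]
    return SagittalSlice(intensity=np.clip(data, 0, None),
                         pixel_spacing_mm=(float(zooms[0]), float(zooms[1])),
                         meta={"format": "nifti"})


def _read_raster(path: Path) -> SagittalSlice:
    side = _sidecar(path)
    if not side.exists():
        raise ValidationError(f"{path.name}: missing JSON sidecar {side.name}")
    meta = json.loads(side.read_text())
    spacing = meta.pop("pixel_spacing_mm")
    scale = float(meta.pop("intensity_scale", 1.0))
    data = iio.imread(path).astype(np.float64) / scale
    return SagittalSlice(intensity=data,
                         pixel_spacing_mm=(float(spacing[0]), float(spacing[1])),
                         meta={"format": "raster", **meta})


def write_slice_png(slc: SagittalSlice, path: str | Path) -> Path:
    """Write a slice as 16-bit PNG with a JSON sidecar (spacing + meta).

    Intensities are stored as ``round(I * intensity_scale)`` with a scale
    chosen to use the 16-bit range; the sidecar records the scale so the
    round trip loses at most half a count.
    """
    path = Path(path)
    vmax = float(slc.intensity.max())
    scale = 1.0 if vmax == 0 else min(100.0, 65535.0 / vmax)
    counts = np.round(slc.intensity * scale).astype(np.uint16)
    iio.imwrite(path, counts)
    sidecar = {"pixel_spacing_mm": list(slc.pixel_spacing_mm),
               "intensity_scale": scale, **slc.meta}
    _sidecar(path).write_text(json.dumps(sidecar, indent=1, default=str))
    return path


def write_slice_nifti(slc: SagittalSlice, path: str | Path) -> Path:
    """Write a slice as NIfTI with spacing in the header zooms."""
    path = Path(path)
    sr, sc = slc.pixel_spacing_mm
    affine = np.diag([sr, sc, 1.0, 1.0])
    img = nib.Nifti1Image(slc.intensity[:, :, None], affine)
    img.header.set_zooms((sr, sc, 1.0))
    nib.save(img, str(path))
    return path


def write_mask_png(mask: NucleusMask, path: str | Path) -> Path:
    path = Path(path)
    iio.imwrite(path, (mask.mask.astype(np.uint8) * 255))
    _sidecar(path).write_text(json.dumps(mask.provenance, indent=1, default=str))
    return path


def read_mask_png(path: str | Path) -> NucleusMask:
    path = Path(path)
    data = iio.imread(path)
    prov = {}
    if _sidecar(path).exists():
        prov = json.loads(_sidecar(path).read_text())
    return NucleusMask(mask=data > 0, provenance=prov)


def write_frame_json(frame: DiscFrame, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(frame.to_dict(), indent=1))
    return path


def read_frame_json(path: str | Path) -> DiscFrame:
    return DiscFrame.from_dict(json.loads(Path(path).read_text()))


def write_metrics_json(metrics: DiscMetrics, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(metrics.as_dict(with_provenance=True),
                               indent=1, default=str))
    return path
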