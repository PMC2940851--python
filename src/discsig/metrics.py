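"""The four nucleus signal-distribution parameters: DX, H, SM, PSM.

Working in the disc-aligned raster (columns = longitudinal direction):

* the **weighted centre** is X = sum(Xi*Si) / sum(Si) over masked pixels,
  with Xi the pixel-centre coordinate in mm and Si its intensity;
* **DX** (mm) is the distance on the longitudinal axis between the
  weighted centre and the geometric centre (the unweighted mean of masked
  pixel centres) — reported as an absolute value, the signed value is
  retained;
* the **intensity profile** sums the masked intensities of each
  longitudinal column down the perpendicular axis; **SM** is the maximum
  sum and **PSM** (mm) its longitudinal position, ties broken to the
  smallest (posterior-most) position;
* **H** (mm) is the nucleus height: the maximum perpendicular extent of
  the mask over columns (or the extent at the central column with
  ``h_mode="center"``).

:func:`compute_all` chains segmentation -> frame estimation -> resampling
-> metrics and records full provenance.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np

from . import geometry, segmentation
from .core import (
    DiscAlignedImage,
    DiscFrame,
    DiscMetrics,
    IntensityProfile,
    SagittalSlice,
    ValidationError,
    ZeroMassError,
    settings_hash,
)

__all__ = [
    "PipelineSettings",
    "weighted_center",
    "geometric_center",
    "compute_DX",
    "compute_profile",
    "compute_SM_PSM",
    "compute_H",
    "compute_all",
]


def _masked_coords(aligned: DiscAlignedImage):
    rr, cc = np.nonzero(aligned.mask)
    if rr.size == 0:
        raise ValidationError("aligned mask is empty")
    t = aligned.axis_positions_mm[cc]
    w = aligned.perp_positions_mm[rr]
    return rr, cc, t, w


def weighted_center(aligned: DiscAlignedImage) -> np.ndarray:
    """Intensity-weighted centre (longitudinal, perpendicular) in mm."""
    rr, cc, t, w = _masked_coords(aligned)
    si = aligned.intensity[rr, cc]
    total = float(si.sum())
    if total <= 0:
        raise ZeroMassError("total masked intensity is zero")
    return np.array([float((t * si).sum() / total),
                     float((w * si).sum() / total)])


def geometric_center(aligned: DiscAlignedImage) -> np.ndarray:
    """Unweighted mean of masked pixel centres (longitudinal, perpendicular)."""
    _, _, t, w = _masked_coords(aligned)
    return np.array([float(t.mean()), float(w.mean())])


def compute_DX(aligned: DiscAlignedImage) -> tuple[float, float]:
    """(signed_DX_mm, DX_mm): weighted minus geometric centre, longitudinal.

    Perpendicular components are discarded; DX is the absolute value of
    the signed longitudinal offset.
    """
    signed = float(weighted_center(aligned)[0] - geometric_center(aligned)[0])
    return signed, abs(signed)


def compute_profile(aligned: DiscAlignedImage) -> IntensityProfile:
    """Masked intensity sums per longitudinal column.

    Covers exactly the columns intersecting the mask; the total of the
    sums equals the total masked intensity exactly.
    """
    rr, cc, _, _ = _masked_coords(aligned)
    cols = np.unique(cc)
    masked = np.where(aligned.mask, aligned.intensity, 0.0)
    sums = masked.sum(axis=0)[cols]
    return IntensityProfile(positions_mm=aligned.axis_positions_mm[cols],
                            sums=sums)


def compute_SM_PSM(profile: IntensityProfile) -> tuple[float, float]:
    """Maximum profile sum and its position; ties to the smallest position."""
    idx = int(np.argmax(profile.sums))     # argmax returns the first maximum
    return float(profile.sums[idx]), float(profile.positions_mm[idx])


def compute_H(aligned: DiscAlignedImage, mode: str = "max") -> float:
    """Nucleus height (mm): perpendicular mask extent.

    ``mode="max"`` (default): the maximum column-wise masked-row span.
    ``mode="center"``: the span of the column nearest the geometric centre.
    """
    rr, cc, _, _ = _masked_coords(aligned)
    s = aligned.pixel_spacing_mm
    cols = np.unique(cc)
    if mode == "max":
        spans = [rr[cc == j].max() - rr[cc == j].min() + 1 for j in cols]
        return float(max(spans) * s)
    if mode == "center":
        gc_t = geometric_center(aligned)[0]
        j = cols[int(np.argmin(np.abs(aligned.axis_positions_mm[cols] - gc_t)))]
        return float((rr[cc == j].max() - rr[cc == j].min() + 1) * s)
    raise ValidationError(f"unknown h_mode {mode!r}; use 'max' or 'center'")


@dataclass
class PipelineSettings:
    """Settings for the end-to-end pipeline.

    ``axis_points_mm`` switches the frame to a manual endplate-line frame
    ((x1, y1), (x2, y2)); otherwise the frame is estimated from the mask.
    """

    threshold_fraction: float = 0.5
    h_mode: str = "max"
    axis_points_mm: tuple | None = None

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def metrics_from_aligned(aligned: DiscAlignedImage, h_mode: str = "max",
                         provenance: dict | None = None) -> DiscMetrics:
    """Compute all four parameters on an already aligned image."""
    signed_dx, dx = compute_DX(aligned)
    profile = compute_profile(aligned)
    sm, psm = compute_SM_PSM(profile)
    tie = int((profile.sums == profile.sums.max()).sum()) > 1
    h = compute_H(aligned, mode=h_mode)
    prov = dict(provenance or {})
    prov["sm_tie"] = tie
    return DiscMetrics(DX_mm=dx, H_mm=h, SM=sm, PSM_mm=psm,
                       signed_DX_mm=signed_dx, provenance=prov)


def compute_all(slc: SagittalSlice, seed: tuple[int, int],
                settings: PipelineSettings | None = None,
                frame: DiscFrame | None = None) -> DiscMetrics:
    """Segmentation -> frame -> resampling -> metrics, with provenance.

    Deterministic given inputs and settings.  An explicit ``frame``
    overrides both the estimated and the manual-axis frame (used e.g. to
    measure several phantoms in one common disc frame).  Stage failures
    are re-raised with the stage name attached.
    """
    settings = settings or PipelineSettings()
    captured: list[str] = []

    def _stage(name, fn, *args, **kwargs):
        try:
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                out = fn(*args, **kwargs)
            for wrn in wlist:
                captured.append(f"{name}: {wrn.category.__name__}")
                warnings.warn_explicit(wrn.message, wrn.category,
                                       wrn.filename, wrn.lineno)
            return out
        except Exception as exc:
            exc.add_note(f"pipeline stage: {name}")
            raise

    mask = _stage("segmentation", segmentation.segment_nucleus,
                  slc, seed, settings.threshold_fraction)
    if frame is None:
        if settings.axis_points_mm is not None:
            p1, p2 = settings.axis_points_mm
            frame = geometry.frame_from_points(p1, p2)
        else:
            frame = _stage("frame", geometry.estimate_disc_frame, mask, slc)
    aligned = _stage("resample", geometry.to_disc_frame, slc, mask, frame)

    prov = {
        "settings": settings.as_dict(),
        "settings_hash": settings_hash(settings.as_dict()),
        "seed": tuple(int(v) for v in seed),
        "segmentation": mask.provenance,
        "frame": frame.to_dict(),
        "warnings": captured,
    }
    return _stage("metrics", metrics_from_aligned, aligned,
                  settings.h_mode, prov)
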