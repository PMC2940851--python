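"""Core data containers, coordinate conventions, errors and warnings.

Coordinate convention
---------------------
All physical coordinates are 2-vectors ``(x, y)`` in millimetres, with *x*
increasing along image columns and *y* along image rows.  Pixel ``(r, c)``
(0-based) has its centre at ``((c + 0.5) * col_spacing, (r + 0.5) *
row_spacing)``.  This pixel-centre convention is used everywhere:
rasterisation, segmentation, frame estimation and resampling.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
from scipy import ndimage

__all__ = [
    "DiscSigError",
    "ValidationError",
    "GeometryError",
    "CongruenceError",
    "ZeroMassError",
    "InsufficientDataError",
    "SeedBoundsError",
    "DegenerateSeedError",
    "BorderLeakWarning",
    "AmbiguousAxisWarning",
    "DegenerateStatisticsWarning",
    "EmptyCellWarning",
    "SagittalSlice",
    "NucleusMask",
    "DiscFrame",
    "DiscAlignedImage",
    "IntensityProfile",
    "DiscMetrics",
    "pixel_centers",
    "settings_hash",
]

EIGHT_CONN = np.ones((3, 3), dtype=bool)


# ---------------------------------------------------------------------------
# errors / warnings
# ---------------------------------------------------------------------------

class DiscSigError(Exception):
    """Base class for all package errors."""


class ValidationError(DiscSigError, ValueError):
    """An input object violates a declared invariant."""


class GeometryError(DiscSigError, ValueError):
    """A geometric precondition fails (e.g. nucleus not contained in disc)."""


class CongruenceError(DiscSigError, ValueError):
    """Two objects that must share a raster grid do not."""


class ZeroMassError(DiscSigError, ZeroDivisionError):
    """Total masked intensity is zero; the weighted centre is undefined."""


class InsufficientDataError(DiscSigError, ValueError):
    """Fewer observations than the statistic requires."""


class SeedBoundsError(DiscSigError, IndexError):
    """Seed point lies outside the image raster."""


class DegenerateSeedError(DiscSigError, ValueError):
    """Seed pixel cannot anchor a region (zero or sub-threshold intensity)."""


class BorderLeakWarning(UserWarning):
    """Grown region touched the image border — containment likely failed."""


class AmbiguousAxisWarning(UserWarning):
    """Mask is nearly isotropic; the principal axis is ill-defined."""


class DegenerateStatisticsWarning(UserWarning):
    """A statistic is undefined (e.g. zero residual variance in an ANOVA)."""


class EmptyCellWarning(UserWarning):
    """A factorial cell has no observations; the interaction was dropped."""


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def pixel_centers(shape: tuple[int, int],
                  spacing: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Physical (x, y) mm coordinates of every pixel centre.

    Returns ``(X, Y)`` arrays of the given shape; ``X`` varies along
    columns, ``Y`` along rows.
    """
    rows, cols = shape
    sr, sc = spacing
    y = (np.arange(rows) + 0.5) * sr
    x = (np.arange(cols) + 0.5) * sc
    return np.meshgrid(x, y)[0], np.meshgrid(x, y)[1]


def settings_hash(settings: Mapping[str, Any]) -> str:
    """Stable short hash of a settings mapping, for provenance rows."""
    blob = json.dumps(settings, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _as_float_image(a: np.ndarray, name: str) -> np.ndarray:
    a = np.ascontiguousarray(np.asarray(a, dtype=np.float64))
    if a.ndim != 2:
        raise ValidationError(f"{name} must be a 2D raster, got ndim={a.ndim}")
    return a


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SagittalSlice:
    """A single 2D sagittal T2-weighted slice with physical pixel spacing.

    Parameters
    ----------
    intensity : (R, C) array of finite, non-negative intensities.
    pixel_spacing_mm : (row_spacing, col_spacing), both > 0.
    meta : free-form acquisition tags (TR, TE, disc level, patient id ...).
    """

    intensity: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = _as_float_image(self.intensity, "intensity")
        if self.intensity.shape[0] < 8 or self.intensity.shape[1] < 8:
            raise ValidationError(
                f"intensity raster must be at least 8x8, got {self.intensity.shape}")
        if not np.all(np.isfinite(self.intensity)):
            raise ValidationError("intensity contains non-finite values")
        if np.any(self.intensity < 0):
            raise ValidationError("intensity contains negative values")
        sr, sc = (float(s) for s in self.pixel_spacing_mm)
        if sr <= 0 or sc <= 0:
            raise ValidationError(
                f"pixel_spacing_mm must be strictly positive, got {(sr, sc)}")
        self.pixel_spacing_mm = (sr, sc)

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape  # type: ignore[return-value]

    def pixel_center_mm(self, row: float, col: float) -> np.ndarray:
        sr, sc = self.pixel_spacing_mm
        return np.array([(col + 0.5) * sc, (row + 0.5) * sr])


@dataclass
class NucleusMask:
    """Binary mask of the segmented high-intensity nucleus zone.

    Invariants: non-empty, exactly one 8-connected component and, when a
    seed is recorded in the provenance, the mask contains the seed pixel.
    """

    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ValidationError(f"mask must be 2D, got ndim={m.ndim}")
        self.mask = np.ascontiguousarray(m.astype(bool))
        n = int(self.mask.sum())
        if n == 0:
            raise ValidationError("mask is empty")
        _, ncomp = ndimage.label(self.mask, structure=EIGHT_CONN)
        if ncomp != 1:
            raise ValidationError(
                f"mask must have exactly one 8-connected component, got {ncomp}")
        seed = self.provenance.get("seed")
        if seed is not None and not self.mask[tuple(int(v) for v in seed)]:
            raise ValidationError("mask does not contain its seed pixel")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class DiscFrame:
    """Disc coordinate frame: origin + orthonormal longitudinal/perpendicular axes.

    ``origin_mm`` lies on the longitudinal line through the mask centroid at
    the posterior-most masked projection (auto frames) or at a user-given
    point (manual endplate-line frames).  ``angle_deg`` is the angle of the
    longitudinal axis against the image x-axis, in ``(-90, 90]``.
    """

    origin_mm: np.ndarray
    longitudinal_axis: np.ndarray
    perpendicular_axis: np.ndarray
    angle_deg: float
    manual: bool = False

    def __post_init__(self) -> None:
        self.origin_mm = np.asarray(self.origin_mm, dtype=float).reshape(2)
        u = np.asarray(self.longitudinal_axis, dtype=float).reshape(2)
        v = np.asarray(self.perpendicular_axis, dtype=float).reshape(2)
        if not (np.isclose(u @ u, 1.0, atol=1e-9)
                and np.isclose(v @ v, 1.0, atol=1e-9)
                and np.isclose(u @ v, 0.0, atol=1e-9)):
            raise ValidationError("frame axes must be orthonormal")
        self.longitudinal_axis = u
        self.perpendicular_axis = v
        self.angle_deg = float(self.angle_deg)
        if not (-90.0 < self.angle_deg <= 90.0):
            raise ValidationError(
                f"angle_deg must lie in (-90, 90], got {self.angle_deg}")

    def to_dict(self) -> dict:
        return {
            "origin_mm": self.origin_mm.tolist(),
            "longitudinal_axis": self.longitudinal_axis.tolist(),
            "perpendicular_axis": self.perpendicular_axis.tolist(),
            "angle_deg": self.angle_deg,
            "manual": self.manual,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "DiscFrame":
        return cls(
            origin_mm=np.asarray(d["origin_mm"], dtype=float),
            longitudinal_axis=np.asarray(d["longitudinal_axis"], dtype=float),
            perpendicular_axis=np.asarray(d["perpendicular_axis"], dtype=float),
            angle_deg=float(d["angle_deg"]),
            manual=bool(d.get("manual", False)),
        )


@dataclass
class DiscAlignedImage:
    """Slice + mask resampled into the disc frame at isotropic spacing.

    Columns index the longitudinal direction; ``axis_positions_mm[j]`` is
    the longitudinal position (relative to the frame origin) of column *j*,
    ``perp_positions_mm[i]`` the perpendicular position of row *i*.
    """

    intensity: np.ndarray
    mask: np.ndarray
    pixel_spacing_mm: float
    axis_positions_mm: np.ndarray
    perp_positions_mm: np.ndarray

    def __post_init__(self) -> None:
        self.intensity = _as_float_image(self.intensity, "intensity")
        self.mask = np.ascontiguousarray(np.asarray(self.mask).astype(bool))
        if self.mask.shape != self.intensity.shape:
            raise CongruenceError("aligned mask and intensity shapes differ")
        self.pixel_spacing_mm = float(self.pixel_spacing_mm)
        if self.pixel_spacing_mm <= 0:
            raise ValidationError("pixel_spacing_mm must be > 0")
        self.axis_positions_mm = np.asarray(self.axis_positions_mm, dtype=float)
        self.perp_positions_mm = np.asarray(self.perp_positions_mm, dtype=float)
        if self.axis_positions_mm.shape != (self.intensity.shape[1],):
            raise CongruenceError("axis_positions_mm must have one entry per column")
        if self.perp_positions_mm.shape != (self.intensity.shape[0],):
            raise CongruenceError("perp_positions_mm must have one entry per row")
        if self.axis_positions_mm.size > 1 and \
                np.any(np.diff(self.axis_positions_mm) <= 0):
            raise ValidationError("axis_positions_mm must be strictly increasing")


@dataclass
class IntensityProfile:
    """Per-position sums of masked intensity along the longitudinal axis."""

    positions_mm: np.ndarray
    sums: np.ndarray

    def __post_init__(self) -> None:
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        self.sums = np.asarray(self.sums, dtype=float)
        if self.positions_mm.ndim != 1 or self.positions_mm.size == 0:
            raise ValidationError("profile positions must be a non-empty 1D array")
        if self.sums.shape != self.positions_mm.shape:
            raise CongruenceError("profile sums/positions length mismatch")
        if self.positions_mm.size > 1 and np.any(np.diff(self.positions_mm) <= 0):
            raise ValidationError("profile positions must be strictly increasing")
        if np.any(self.sums < 0):
            raise ValidationError("profile sums must be non-negative")


@dataclass
class DiscMetrics:
    """The four distribution parameters of one disc.

    DX_mm : |longitudinal offset| of the intensity-weighted centre from the
        geometric centre of the nucleus zone.
    H_mm : nucleus height (extent perpendicular to the longitudinal axis).
    SM : maximum per-column masked intensity sum (scanner-arbitrary units).
    PSM_mm : longitudinal position of SM relative to the frame origin.
    """

    DX_mm: float
    H_mm: float
    SM: float
    PSM_mm: float
    signed_DX_mm: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.DX_mm = float(self.DX_mm)
        self.H_mm = float(self.H_mm)
        self.SM = float(self.SM)
        self.PSM_mm = float(self.PSM_mm)
        self.signed_DX_mm = float(self.signed_DX_mm)
        if not np.isclose(self.DX_mm, abs(self.signed_DX_mm)):
            raise ValidationError("DX_mm must equal |signed_DX_mm|")

    def as_dict(self, with_provenance: bool = False) -> dict:
        d = {
            "DX_mm": self.DX_mm,
            "H_mm": self.H_mm,
            "SM": self.SM,
            "PSM_mm": self.PSM_mm,
            "signed_DX_mm": self.signed_DX_mm,
        }
        if with_provenance:
            d["provenance"] = self.provenance
        return d
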