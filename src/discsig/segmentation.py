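"""Semi-automatic segmentation of the high-intensity nucleus zone.

The nucleus is detected by seeded region growing: starting from a single
user click inside the bright nucleus, all 8-connected pixels whose
intensity reaches a fraction of a robust seed reference intensity (median
of the 3x3 neighbourhood around the seed) are collected, the seed's
connected component is kept, lightly closed (1-pixel disk) and
hole-filled.  Every setting is recorded in the mask provenance so a run
can be reproduced exactly.

A manual-outline fallback (:func:`mask_from_polygon`) rasterises a
user-supplied polygon by pixel-centre inclusion, mirroring a hand-drawn
nucleus outline.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.measure import points_in_poly
from skimage.morphology import closing, disk

from .core import (
    EIGHT_CONN,
    BorderLeakWarning,
    CongruenceError,
    DegenerateSeedError,
    NucleusMask,
    SagittalSlice,
    SeedBoundsError,
    ValidationError,
)

__all__ = ["segment_nucleus", "mask_summary", "mask_from_polygon"]


def _seed_reference(intensity: np.ndarray, seed: tuple[int, int]) -> float:
    """Median of the 3x3 neighbourhood of the seed (clipped at the border)."""
    r, c = seed
    rows, cols = intensity.shape
    win = intensity[max(r - 1, 0):min(r + 2, rows), max(c - 1, 0):min(c + 2, cols)]
    return float(np.median(win))


def segment_nucleus(slc: SagittalSlice, seed: tuple[int, int],
                    threshold_fraction: float = 0.5) -> NucleusMask:
    """Grow the high-intensity nucleus region from a seed point.

    Parameters
    ----------
    slc : the sagittal slice.
    seed : (row, col) pixel inside the nucleus.
    threshold_fraction : fraction of the seed reference intensity (median
        of the seed's 3x3 neighbourhood) a pixel must reach to join the
        region; in ``(0, 1]``.

    Raises
    ------
    SeedBoundsError : seed outside the raster.
    DegenerateSeedError : zero intensity at the seed, or seed below its
        own threshold.

    Warns
    -----
    BorderLeakWarning : the grown region touches the image border, which
        signals a failed containment; the flag is also recorded in the
        provenance so batch callers can react.
    """
    if not (0.0 < threshold_fraction <= 1.0):
        raise ValidationError(
            f"threshold_fraction must be in (0, 1], got {threshold_fraction}")
    r, c = (int(v) for v in seed)
    rows, cols = slc.shape
    if not (0 <= r < rows and 0 <= c < cols):
        raise SeedBoundsError(f"seed {seed} outside raster of shape {slc.shape}")
    if slc.intensity[r, c] <= 0:
        raise DegenerateSeedError(f"zero intensity at seed {seed}")

    reference = _seed_reference(slc.intensity, (r, c))
    threshold = threshold_fraction * reference
    candidate = slc.intensity >= threshold
    if not candidate[r, c]:
        raise DegenerateSeedError(
            f"seed intensity {slc.intensity[r, c]:g} below its own "
            f"threshold {threshold:g}")

    labels, _ = ndimage.label(candidate, structure=EIGHT_CONN)
    region = labels == labels[r, c]
    # closing (1-px disk) and hole filling; both are increasing operators,
    # so raising the threshold can never enlarge the final mask
    region = closing(region, disk(1))
    region = ndimage.binary_fill_holes(region)
    labels, _ = ndimage.label(region, structure=EIGHT_CONN)
    region = labels == labels[r, c]

    border_leak = bool(region[0, :].any() or region[-1, :].any()
                       or region[:, 0].any() or region[:, -1].any())
    if border_leak:
        warnings.warn("grown region touches the image border; the nucleus "
                      "containment likely failed", BorderLeakWarning,
                      stacklevel=2)

    provenance = {
        "method": "seeded_region_growing",
        "seed": (r, c),
        "threshold_fraction": float(threshold_fraction),
        "reference_intensity": reference,
        "threshold": float(threshold),
        "morphology": "closing(disk1)+fill_holes",
        "connectivity": 8,
        "border_leak": border_leak,
    }
    return NucleusMask(mask=region, provenance=provenance)


def mask_summary(mask: NucleusMask, slc: SagittalSlice) -> dict:
    """Area (mm^2), 8-connected component count and bounding box (mm).

    The bounding box spans the outer edges of the extreme mask pixels,
    reported as ``(xmin, ymin, xmax, ymax)``.
    """
    if mask.mask.shape != slc.shape:
        raise CongruenceError(
            f"mask shape {mask.mask.shape} does not match slice {slc.shape}")
    sr, sc = slc.pixel_spacing_mm
    n = mask.n_pixels
    _, ncomp = ndimage.label(mask.mask, structure=EIGHT_CONN)
    rr, cc = np.nonzero(mask.mask)
    return {
        "area_mm2": n * sr * sc,
        "n_pixels": n,
        "n_components": int(ncomp),
        "bbox_mm": (float(cc.min() * sc), float(rr.min() * sr),
                    float((cc.max() + 1) * sc), float((rr.max() + 1) * sr)),
    }


def mask_from_polygon(slc: SagittalSlice,
                      vertices_mm: np.ndarray) -> NucleusMask:
    """Rasterise a manually outlined nucleus polygon.

    ``vertices_mm`` is an (N, 2) array of (x, y) mm vertices.  A pixel
    belongs to the mask iff its centre lies inside the polygon — the same
    pixel-centre rule the phantom generator uses.
    """
    vertices_mm = np.asarray(vertices_mm, dtype=float)
    if vertices_mm.ndim != 2 or vertices_mm.shape[0] < 3 or vertices_mm.shape[1] != 2:
        raise ValidationError("polygon needs at least 3 (x, y) vertices")
    rows, cols = slc.shape
    sr, sc = slc.pixel_spacing_mm
    x = (np.arange(cols) + 0.5) * sc
    y = (np.arange(rows) + 0.5) * sr
    X, Y = np.meshgrid(x, y)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    inside = points_in_poly(pts, vertices_mm).reshape(rows, cols)
    provenance = {"method": "manual_polygon",
                  "vertices_mm": vertices_mm.tolist()}
    return NucleusMask(mask=inside, provenance=provenance)
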