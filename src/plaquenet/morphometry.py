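"""Caliper measurements of a plaque mask: long and short diameters.

The long diameter is the maximum Feret diameter — the largest
pixel-center-to-pixel-center Euclidean distance between boundary pixels of
the (largest) foreground component.  The short diameter is the extent of
the component measured perpendicular to the long-diameter axis.  Distances
use pixel centers with no end-cap correction; degenerate components (a
single pixel, or zero perpendicular extent) measure one pixel spacing.

An alternative convention based on the minimum-area enclosing rectangle of
the boundary points is available via ``method="min_rect"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

__all__ = ["DiameterPair", "EmptyMaskError", "largest_component", "measure_diameters"]


class EmptyMaskError(ValueError):
    """Raised when a mask contains no foreground: no plaque found."""


@dataclass
class DiameterPair:
    long_mm: float
    short_mm: float

    def __post_init__(self) -> None:
        if not self.long_mm >= self.short_mm > 0:
            raise ValueError("require long_mm >= short_mm > 0")


_EIGHT = np.ones((3, 3), dtype=int)


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected foreground component.

    An empty mask passes through unchanged.
    """
    mask = np.asarray(mask) != 0
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n <= 1:
        return mask.astype(np.uint8)
    sizes = np.bincount(labels.ravel())[1:]
    keep = int(np.argmax(sizes)) + 1
    return (labels == keep).astype(np.uint8)


def _boundary_points(mask: np.ndarray) -> np.ndarray:
    """(row, col) centers of foreground pixels on the component boundary."""
    eroded = ndimage.binary_erosion(mask, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool), border_value=0)
    boundary = mask & ~eroded
    return np.argwhere(boundary).astype(float)


def _max_feret(points: np.ndarray) -> tuple[float, np.ndarray]:
    """Maximum pairwise distance and the direction(s) achieving it.

    Pixel centers have integer coordinates, so squared distances are exact
    integers and ties are exact; all tied diametral axes are returned,
    which keeps downstream measurements invariant under flips and 90-degree
    rotations regardless of argmax order.
    """
    if len(points) >= 4:
        try:
            hull = ConvexHull(points)
            points = points[hull.vertices]
        except QhullError:
            pass  # collinear points: brute force on the full set
    # brute force over the (small) hull vertex set
    d = points[:, None, :] - points[None, :, :]
    dist2 = (d ** 2).sum(axis=-1)
    best2 = dist2.max()
    best = float(np.sqrt(best2))
    if best == 0.0:
        return 0.0, np.array([[1.0, 0.0]])
    ii, jj = np.nonzero(dist2 == best2)
    axes = (points[ii] - points[jj]) / best
    return best, axes


def _min_area_rectangle(points: np.ndarray) -> tuple[float, float]:
    """(long, short) side lengths of the minimum-area enclosing rectangle."""
    try:
        hull = ConvexHull(points)
        pts = points[hull.vertices]
    except QhullError:
        pts = points
    best = None
    n = len(pts)
    for a in range(n):
        e = pts[(a + 1) % n] - pts[a]
        norm = np.hypot(*e)
        if norm == 0:
            continue
        u = e / norm
        v = np.array([-u[1], u[0]])
        pu = pts @ u
        pv = pts @ v
        du = pu.max() - pu.min()
        dv = pv.max() - pv.min()
        if best is None or du * dv < best[0]:
            best = (du * dv, max(du, dv), min(du, dv))
    if best is None:  # single point
        return 0.0, 0.0
    return best[1], best[2]


def measure_diameters(mask: np.ndarray, spacing_mm_per_px: float,
                      method: str = "feret",
                      keep_all_components: bool = False) -> DiameterPair:
    """Measure the plaque's long and short diameters in millimetres.

    Parameters
    ----------
    mask : binary array, nonzero = plaque.
    spacing_mm_per_px : isotropic pixel spacing in mm.
    method : ``"feret"`` (max Feret + perpendicular extent, default) or
        ``"min_rect"`` (minimum-area enclosing rectangle sides).
    keep_all_components : if False (default), only the largest 8-connected
        component is measured — robust to fragmented predictions.
    """
    if spacing_mm_per_px <= 0:
        raise ValueError("spacing must be positive")
    mask = np.asarray(mask) != 0
    if not mask.any():
        raise EmptyMaskError("no plaque found in mask")
    if not keep_all_components:
        mask = largest_component(mask).astype(bool)
    pts = _boundary_points(mask)

    if method == "min_rect":
        long_px, short_px = _min_area_rectangle(pts)
    elif method == "feret":
        long_px, axes = _max_feret(pts)
        all_pts = np.argwhere(mask).astype(float)
        # perpendicular extent, maximized over all tied long axes
        short_px = 0.0
        for axis in axes:
            proj = all_pts @ np.array([-axis[1], axis[0]])
            short_px = max(short_px, float(proj.max() - proj.min()))
    else:
        raise ValueError(f"unknown method {method!r}")

    # degenerate extents measure one pixel (a pixel has unit width);
    # the perpendicular extent is mathematically <= the Feret maximum,
    # so clamp float round-off that would invert the pair
    long_px = max(long_px, 1.0)
    short_px = min(max(short_px, 1.0), long_px)
    s = spacing_mm_per_px
    return DiameterPair(long_mm=long_px * s, short_mm=short_px * s)
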