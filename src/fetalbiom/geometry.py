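"""Orientation estimation and perpendicular caliper-width profiling.

Every linear measurement in this package follows the same recipe: estimate a
mask's principal ("main") direction, project foreground pixels onto that axis
and its perpendicular, and read off the perpendicular extent at each axial
position.  The measurement itself is then a maximum of the resulting distance
profile, optionally restricted to a superior fraction of the extent.

Conventions
-----------
* Physical coordinates are ``(row_mm, col_mm)`` with the row axis pointing
  superior → inferior (row index grows toward the feet).
* The principal direction is estimated by PCA of foreground pixel-center
  coordinates in mm; its row component is kept nonnegative, so smaller axial
  positions are more superior.
* Widths use an outer-edge convention: the span between the extreme pixel
  centers plus one in-plane pixel extent, mimicking clinical calipers placed
  on the outer edges of a structure.  A pure center-to-center span would
  under-read by one pixel.  The pixel extent along a unit direction ``v`` is
  ``sqrt((v_r s_r)^2 + (v_c s_c)^2)``, which equals the perpendicular spacing
  for axis-aligned masks and stays one pixel for rotated axes.
* Widths are spans of extremes, not longest contiguous runs: internal holes
  (e.g. annotation gaps) do not split a diameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateMaskError
from .mask_io import BinaryMask

__all__ = [
    "PrincipalAxis",
    "DistanceProfile",
    "WidthMeasurement",
    "principal_axis",
    "distance_profile",
    "max_width",
]

_ISO_RTOL = 1e-9  # relative eigenvalue gap below which a mask counts as isotropic


@dataclass(frozen=True)
class PrincipalAxis:
    """Dominant spread direction of a mask in physical (mm) coordinates."""

    direction: np.ndarray  # unit vector (row, col)
    centroid: np.ndarray  # (row_mm, col_mm)
    anisotropy_ratio: float  # first / second principal extent, >= 1

    @property
    def perpendicular(self) -> np.ndarray:
        d = self.direction
        return np.array([-d[1], d[0]])


@dataclass(frozen=True)
class DistanceProfile:
    """Perpendicular widths sampled along a mask's principal direction.

    ``positions_mm`` are signed offsets along the axis from the centroid
    (strictly increasing, more negative = more superior); ``widths_mm`` are
    the matching perpendicular outer-edge extents; ``endpoints_mm`` has shape
    ``(n, 2, 2)`` storing, per position, the two (row_mm, col_mm) points that
    realize the width.
    """

    positions_mm: np.ndarray
    widths_mm: np.ndarray
    endpoints_mm: np.ndarray
    step_mm: float | None = None

    def __len__(self) -> int:
        return len(self.positions_mm)


@dataclass(frozen=True)
class WidthMeasurement:
    """A single caliper measurement: value, axial position and endpoints."""

    value_mm: float
    position_mm: float
    endpoints_mm: np.ndarray  # (2, 2): two (row_mm, col_mm) points
    slice_index: int | None = None

    def with_slice(self, slice_index: int) -> "WidthMeasurement":
        return WidthMeasurement(
            self.value_mm, self.position_mm, self.endpoints_mm, int(slice_index)
        )


def _pixel_coords_mm(mask: BinaryMask) -> np.ndarray:
    idx = np.argwhere(mask.pixels)
    return idx * np.asarray(mask.spacing_mm)


def principal_axis(mask: BinaryMask) -> PrincipalAxis:
    """Estimate the main direction of a mask by PCA of pixel coordinates.

    The sign convention keeps the row (superior→inferior) component
    nonnegative.  For isotropic masks (equal principal extents, e.g. a filled
    disc) a deterministic fallback along the row axis is returned with
    ``anisotropy_ratio`` 1.  Fewer than two foreground pixels is degenerate.
    """
    pts = _pixel_coords_mm(mask)
    if len(pts) < 2:
        raise DegenerateMaskError(
            f"principal axis needs >= 2 foreground pixels, got {len(pts)}"
        )
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered / (len(pts) - 1)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    lo, hi = float(evals[0]), float(evals[1])
    if hi <= 0 or (hi - lo) <= _ISO_RTOL * hi:
        return PrincipalAxis(
            direction=np.array([1.0, 0.0]), centroid=centroid, anisotropy_ratio=1.0
        )
    direction = evecs[:, 1].copy()
    if direction[0] < 0 or (direction[0] == 0 and direction[1] < 0):
        direction = -direction
    ratio = float(np.sqrt(hi / lo)) if lo > 0 else float("inf")
    return PrincipalAxis(direction=direction, centroid=centroid, anisotropy_ratio=ratio)


def _pixel_extent_along(direction: np.ndarray, spacing_mm) -> float:
    sr, sc = spacing_mm
    return float(np.hypot(direction[0] * sr, direction[1] * sc))


def distance_profile(
    mask: BinaryMask, axis: PrincipalAxis, step_mm: float | None = None
) -> DistanceProfile:
    """Profile of perpendicular outer-edge widths along the principal axis.

    Pixel centers are projected onto (axis, perpendicular); axial positions
    are binned on a grid of pitch ``step_mm`` (default: min in-plane spacing)
    with half-open bins ``[pos - step/2, pos + step/2)``.  Each occupied bin
    contributes the span (max − min) of perpendicular coordinates plus one
    in-plane pixel extent; empty bins are omitted.
    """
    pts = _pixel_coords_mm(mask)
    if len(pts) == 0:
        raise DegenerateMaskError("cannot profile an empty mask")
    if step_mm is None:
        step_mm = float(min(mask.spacing_mm))
    if step_mm <= 0:
        raise ValueError("step_mm must be positive")
    u = np.asarray(axis.direction, dtype=float)
    v = axis.perpendicular
    centered = pts - axis.centroid
    t = centered @ u
    w = centered @ v
    extent = _pixel_extent_along(v, mask.spacing_mm)

    tmin, tmax = float(t.min()), float(t.max())
    nbins = max(1, int(np.ceil((tmax - tmin) / step_mm - 1e-12)))
    idx = np.floor((t - tmin) / step_mm).astype(np.int64)
    np.clip(idx, 0, nbins - 1, out=idx)

    wmin = np.full(nbins, np.inf)
    wmax = np.full(nbins, -np.inf)
    np.minimum.at(wmin, idx, w)
    np.maximum.at(wmax, idx, w)
    occupied = np.flatnonzero(np.isfinite(wmin))

    positions = tmin + (occupied + 0.5) * step_mm
    lo = wmin[occupied] - extent / 2.0
    hi = wmax[occupied] + extent / 2.0
    widths = hi - lo

    centers = axis.centroid + positions[:, None] * u
    endpoints = np.stack(
        [centers + lo[:, None] * v, centers + hi[:, None] * v], axis=1
    )
    return DistanceProfile(
        positions_mm=positions,
        widths_mm=widths,
        endpoints_mm=endpoints,
        step_mm=float(step_mm),
    )


def max_width(
    profile: DistanceProfile, range_fraction: tuple[float, float] = (0.0, 1.0)
) -> WidthMeasurement:
    """Maximum width of a profile, restricted to a fraction of its extent.

    ``range_fraction`` = (low, high) restricts positions to the stated
    fraction of the profile's axial extent measured from the superior end
    (the smallest position); a bin represents the half-open interval
    ``[pos − step/2, pos + step/2)``, so bins overlapping the restriction
    window are included.  Ties are broken toward the most superior position.
    """
    lo_f, hi_f = float(range_fraction[0]), float(range_fraction[1])
    if not (0.0 <= lo_f < hi_f <= 1.0):
        raise ValueError(f"range_fraction must satisfy 0 <= low < high <= 1, got {range_fraction}")
    if len(profile) == 0:
        raise DegenerateMaskError("empty profile")
    pos = profile.positions_mm
    pmin, pmax = float(pos[0]), float(pos[-1])
    length = pmax - pmin
    eps = 1e-9 * max(1.0, length)
    if profile.step_mm is not None:
        eps = max(eps, profile.step_mm / 2.0)
    keep = (pos >= pmin + lo_f * length - eps) & (pos <= pmin + hi_f * length + eps)
    if not np.any(keep):
        raise DegenerateMaskError(
            f"range restriction {range_fraction} leaves no profile positions"
        )
    sel = np.flatnonzero(keep)
    best = sel[int(np.argmax(profile.widths_mm[sel]))]  # argmax → first (most superior) tie
    return WidthMeasurement(
        value_mm=float(profile.widths_mm[best]),
        position_mm=float(profile.positions_mm[best]),
        endpoints_mm=profile.endpoints_mm[best].copy(),
    )
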