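"""Seeded synthetic segmentation phantoms with analytically exact diameters.

The phantom emulates the annotated anatomy of a coronal fetal-brain
segmentation — a large cerebrum body, a smaller inferior cerebellum, and two
elongated lateral ventricles interior to the cerebrum but carrying their own
labels — as rotated ellipsoids voxelized by their implicit inequality at
voxel centers.  Ellipsoids keep every true diameter closed-form:

* ``cbpd = 2 ×`` cerebrum transverse half-axis,
* ``tcd  = 2 ×`` cerebellum transverse half-axis,
* ``lad/rad =`` the per-side ventricular short diameter,
* the atrial slice is the slice of maximal combined ventricular chord area.

Each structure's in-plane superior–inferior half-axis exceeds its transverse
half-axis so that the PCA principal direction is the anatomical SI axis and
the perpendicular caliper reads the transverse diameter.  Cortical folding
and MR intensities are deliberately absent: the measurement operators consume
only mask geometry, and realism there is a non-goal.

Boundary noise is a smooth, seeded radial perturbation (low-order harmonics
of the surface direction, normalized to the requested amplitude) so masks
stay simply connected while the analytic truth — by construction — is
unaffected by both voxelization and noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import PhantomSpecError
from .mask_io import LabelSchema, SegmentationVolume

__all__ = ["PhantomSpec", "PhantomTruth", "growth_defaults", "generate_phantom"]

GA_MIN, GA_MAX = 21.0, 38.0
NOISE_PAD_MM = 2.0  # fixed surface allowance; also the max supported noise amplitude


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric specification of one phantom.

    Half-axis triples are ordered (superior–inferior, transverse,
    anterior–posterior), i.e. (row, column, slice) grid axes before rotation.
    ``ventricle_long_mm`` / ``ventricle_short_mm`` are full in-plane diameters
    as ``(left, right)`` pairs; the short diameter is the atrial-width truth.
    ``spacing_mm`` is (slice pitch, row, column).  ``in_plane_rotation_deg``
    rotates the whole assembly rigidly within coronal slices.
    """

    ga_weeks: float = 30.0
    cerebrum_half_axes_mm: tuple[float, float, float] = (46.0, 37.0, 39.0)
    cerebellum_half_axes_mm: tuple[float, float, float] = (26.0, 20.0, 13.0)
    ventricle_long_mm: tuple[float, float] = (22.0, 22.0)
    ventricle_short_mm: tuple[float, float] = (6.44, 5.88)
    in_plane_rotation_deg: float = 0.0
    spacing_mm: tuple[float, float, float] = (3.0, 0.7, 0.7)
    boundary_noise_mm: float = 0.0
    seed: int = 0
    # placement parameters (rarely changed)
    ventricle_tilt_deg: float = 25.0
    ventricle_slice_half_mm: float = 8.0
    ventricle_lateral_frac: float = 0.38
    cerebellum_gap_mm: float = 4.0

    def __post_init__(self) -> None:
        sizes = (
            *self.cerebrum_half_axes_mm,
            *self.cerebellum_half_axes_mm,
            *self.ventricle_long_mm,
            *self.ventricle_short_mm,
            self.ventricle_slice_half_mm,
        )
        if any(s <= 0 for s in sizes):
            raise PhantomSpecError("all phantom sizes must be positive")
        if any(s <= 0 for s in self.spacing_mm):
            raise PhantomSpecError("spacing components must be positive")
        if not 0.0 <= self.boundary_noise_mm <= NOISE_PAD_MM:
            raise PhantomSpecError(
                f"boundary_noise_mm must be within [0, {NOISE_PAD_MM}] mm"
            )
        for side in (0, 1):
            if self.ventricle_short_mm[side] >= self.ventricle_long_mm[side]:
                raise PhantomSpecError(
                    "ventricle short diameter must be smaller than its long diameter"
                )


@dataclass(frozen=True)
class PhantomTruth:
    """Closed-form diameters and atrial slice implied by a PhantomSpec."""

    cbpd_mm: float
    tcd_mm: float
    lad_mm: float
    rad_mm: float
    atrial_slice: int

    def as_dict(self) -> dict[str, float]:
        return {
            "cbpd": self.cbpd_mm,
            "tcd": self.tcd_mm,
            "lad": self.lad_mm,
            "rad": self.rad_mm,
        }


def growth_defaults(ga_weeks: float, *, seed: int = 0) -> PhantomSpec:
    """Default phantom sizes for a gestational age in weeks (21–38).

    Cerebrum and cerebellum diameters grow along smooth quadratic curves
    (strictly increasing over the supported range, echoing normal second/
    third-trimester growth), while the ventricular short diameters stay
    GA-independent at 6.44 mm (left) and 5.88 mm (right) — atrial width is
    clinically stable across the second and third trimesters.
    """
    ga = float(ga_weeks)
    if not GA_MIN <= ga <= GA_MAX:
        raise ValueError(f"ga_weeks must be within [{GA_MIN}, {GA_MAX}], got {ga}")
    # decelerating quadratic growth: CBPD slows from ~3.8 to ~1.7 mm/week
    # between 24 and 37 weeks, reaching ~76 mm at 30 weeks
    cbpd = -0.08 * ga**2 + 7.6 * ga - 80.0
    tcd = -0.01 * ga**2 + 2.4 * ga - 24.0
    cer_tr = cbpd / 2.0
    cb_tr = tcd / 2.0
    return PhantomSpec(
        ga_weeks=ga,
        cerebrum_half_axes_mm=(1.25 * cer_tr, cer_tr, 1.05 * cer_tr),
        cerebellum_half_axes_mm=(1.3 * cb_tr, cb_tr, max(12.5, 0.55 * cb_tr)),
        ventricle_long_mm=(22.0, 22.0),
        ventricle_short_mm=(6.44, 5.88),
        seed=int(seed),
    )


class _Ellipsoid:
    """A rotated ellipsoid with an optional smooth radial perturbation."""

    def __init__(self, center, half_axes, inplane_angle_rad, noise_amp, rng):
        self.center = np.asarray(center, dtype=float)  # (z, row, col) mm
        self.half = np.asarray(half_axes, dtype=float)  # (si, tr, ap)
        self.angle = float(inplane_angle_rad)
        self.noise_amp = float(noise_amp)
        if self.noise_amp > 0:
            coeffs = rng.normal(size=7)
            # normalize so the max |perturbation| over the sphere equals the amplitude
            dirs = _fibonacci_sphere(2048)
            m = np.abs(_harmonics(dirs) @ coeffs).max()
            self._coeffs = coeffs * (self.noise_amp / m)
        else:
            self._coeffs = None

    def support_mm(self):
        """Half-extents of the bounding box along (z, row, col).

        Padded by the fixed maximum noise allowance (not the actual
        amplitude) so that grids are identical across noise settings and
        phantoms differing only in noise stay voxel-aligned.
        """
        a, b, c = self.half  # si, tr, ap
        cos, sin = np.cos(self.angle), np.sin(self.angle)
        row = np.hypot(a * cos, b * sin)
        col = np.hypot(a * sin, b * cos)
        return np.array([c + NOISE_PAD_MM, row + NOISE_PAD_MM, col + NOISE_PAD_MM])

    def contains(self, z, rows, cols):
        """Evaluate the implicit inequality at voxel centers (broadcastable)."""
        dz = z - self.center[0]
        dy = rows - self.center[1]
        dx = cols - self.center[2]
        cos, sin = np.cos(self.angle), np.sin(self.angle)
        p_a = dy * cos + dx * sin  # along SI-ish axis
        p_b = -dy * sin + dx * cos  # along transverse axis
        a, b, c = self.half
        s = np.sqrt((p_a / a) ** 2 + (p_b / b) ** 2 + (dz / c) ** 2)
        if self._coeffs is None:
            return s <= 1.0
        r = np.sqrt(p_a**2 + p_b**2 + dz**2)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.stack(
                [np.where(r > 0, q / r, 0.0) for q in (p_a, p_b, dz * np.ones_like(p_a))],
                axis=-1,
            )
            delta = _harmonics_xyz(d[..., 0], d[..., 1], d[..., 2]) @ self._coeffs
            # inside iff radius <= surface radius + delta:  r (1 - 1/s) <= delta
            inside = np.where(s > 0, r * (1.0 - 1.0 / np.maximum(s, 1e-12)) <= delta, True)
        return inside


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _harmonics_xyz(x, y, z):
    """Low-order smooth angular basis evaluated on unit directions."""
    return np.stack(
        [
            x * y,
            y * z,
            z * x,
            x**2 - y**2,
            3 * z**2 - 1,
            x * (x**2 - 3 * y**2),
            y * (3 * x**2 - y**2),
        ],
        axis=-1,
    )


def _harmonics(dirs: np.ndarray) -> np.ndarray:
    return _harmonics_xyz(dirs[:, 0], dirs[:, 1], dirs[:, 2])


def _voxelize(struct: _Ellipsoid, grid_shape, spacing) -> np.ndarray:
    """Rasterize one structure over its bounding sub-box of the grid."""
    sz, sr, sc = spacing
    support = struct.support_mm()
    lo = struct.center - support - np.array([sz, sr, sc])
    hi = struct.center + support + np.array([sz, sr, sc])
    k0 = max(0, int(np.floor(lo[0] / sz)))
    k1 = min(grid_shape[0], int(np.ceil(hi[0] / sz)) + 1)
    r0 = max(0, int(np.floor(lo[1] / sr)))
    r1 = min(grid_shape[1], int(np.ceil(hi[1] / sr)) + 1)
    c0 = max(0, int(np.floor(lo[2] / sc)))
    c1 = min(grid_shape[2], int(np.ceil(hi[2] / sc)) + 1)
    mask = np.zeros(grid_shape, dtype=bool)
    if k0 >= k1 or r0 >= r1 or c0 >= c1:
        return mask
    z = (np.arange(k0, k1) * sz)[:, None, None]
    rows = (np.arange(r0, r1) * sr)[None, :, None]
    cols = (np.arange(c0, c1) * sc)[None, None, :]
    mask[k0:k1, r0:r1, c0:c1] = struct.contains(z, rows, cols)
    return mask


def generate_phantom(
    spec: PhantomSpec, schema: LabelSchema | None = None
) -> tuple[SegmentationVolume, PhantomTruth]:
    """Voxelize a phantom and return it with its analytic truth.

    The same spec and seed always produce a bit-identical volume.  Ventricle
    labels override the cerebrum where both inequalities hold (the annotation
    convention excludes the ventricular system from the cerebrum label); a
    cerebellum that intersects the cerebrum after rotation/noise is a spec
    error, as is a ventricle not contained in the cerebrum envelope.
    """
    schema = schema or LabelSchema()
    theta = np.deg2rad(spec.in_plane_rotation_deg)
    tilt = np.deg2rad(spec.ventricle_tilt_deg)
    rng = np.random.default_rng(spec.seed)

    cer_half = np.asarray(spec.cerebrum_half_axes_mm)
    cb_half = np.asarray(spec.cerebellum_half_axes_mm)
    # in-plane rotation matrix acting on (row, col) offsets
    cos, sin = np.cos(theta), np.sin(theta)

    def rot(row, col):
        return np.array([row * cos - col * sin, row * sin + col * cos])

    # assembly in cerebrum-centered coordinates (z, row, col)
    cb_offset_inplane = rot(cer_half[0] + cb_half[0] + spec.cerebellum_gap_mm, 0.0)
    lat = spec.ventricle_lateral_frac * cer_half[1]
    offsets = {
        "cerebrum": np.array([0.0, 0.0, 0.0]),
        "cerebellum": np.array([0.0, *cb_offset_inplane]),
        "left_ventricle": np.array([0.0, *rot(0.0, +lat)]),
        "right_ventricle": np.array([0.0, *rot(0.0, -lat)]),
    }
    half_axes = {
        "cerebrum": cer_half,
        "cerebellum": cb_half,
        "left_ventricle": np.array(
            [spec.ventricle_long_mm[0] / 2, spec.ventricle_short_mm[0] / 2,
             spec.ventricle_slice_half_mm]
        ),
        "right_ventricle": np.array(
            [spec.ventricle_long_mm[1] / 2, spec.ventricle_short_mm[1] / 2,
             spec.ventricle_slice_half_mm]
        ),
    }
    angles = {
        "cerebrum": theta,
        "cerebellum": theta,
        "left_ventricle": theta + tilt,
        "right_ventricle": theta - tilt,
    }

    # noise fields are drawn in a fixed structure order for determinism
    structs: dict[str, _Ellipsoid] = {}
    supports = {}
    for name in ("cerebrum", "cerebellum", "left_ventricle", "right_ventricle"):
        e = _Ellipsoid(offsets[name], half_axes[name], angles[name],
                       spec.boundary_noise_mm, rng)
        structs[name] = e
        supports[name] = e.support_mm()

    sz, sr, sc = spec.spacing_mm
    margin = 2.0 * max(sr, sc) + 2.0
    lo = np.min([offsets[n] - supports[n] for n in structs], axis=0) - margin
    hi = np.max([offsets[n] + supports[n] for n in structs], axis=0) + margin
    shift = -lo  # move assembly so the grid origin is at physical 0
    for name in structs:
        structs[name].center = offsets[name] + shift
    extent = hi - lo
    grid_shape = (
        int(np.ceil(extent[0] / sz)) + 1,
        int(np.ceil(extent[1] / sr)) + 1,
        int(np.ceil(extent[2] / sc)) + 1,
    )

    masks = {n: _voxelize(structs[n], grid_shape, spec.spacing_mm) for n in structs}

    if (masks["cerebellum"] & masks["cerebrum"]).any():
        raise PhantomSpecError("cerebellum intersects cerebrum after rotation/noise")
    for side in ("left_ventricle", "right_ventricle"):
        if (masks[side] & ~masks["cerebrum"]).any():
            raise PhantomSpecError(f"{side} is not interior to the cerebrum envelope")

    labels = np.zeros(grid_shape, dtype=np.int16)
    labels[masks["cerebrum"]] = schema.cerebrum
    labels[masks["cerebellum"]] = schema.cerebellum
    labels[masks["left_ventricle"]] = schema.left_ventricle  # ventricles override cerebrum
    labels[masks["right_ventricle"]] = schema.right_ventricle

    volume = SegmentationVolume(labels=labels, spacing_mm=spec.spacing_mm, schema=schema)
    truth = PhantomTruth(
        cbpd_mm=2.0 * float(cer_half[1]),
        tcd_mm=2.0 * float(cb_half[1]),
        lad_mm=float(spec.ventricle_short_mm[0]),
        rad_mm=float(spec.ventricle_short_mm[1]),
        atrial_slice=_analytic_atrial_slice(spec, structs, grid_shape[0]),
    )
    return volume, truth


def _analytic_atrial_slice(spec: PhantomSpec, structs, n_slices: int) -> int:
    """Slice index maximizing the combined analytic ventricular chord area."""
    sz = spec.spacing_mm[0]
    z = np.arange(n_slices) * sz
    area = np.zeros(n_slices)
    for side, key in ((0, "left_ventricle"), (1, "right_ventricle")):
        c = spec.ventricle_slice_half_mm
        dz = z - structs[key].center[0]
        f2 = np.maximum(0.0, 1.0 - (dz / c) ** 2)
        area += np.pi * (spec.ventricle_long_mm[side] / 2) * (
            spec.ventricle_short_mm[side] / 2
        ) * f2
    return int(np.argmax(area))  # ties → smallest index
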