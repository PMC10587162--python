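"""The measurement stage: CBPD, TCD, LAD and RAD from a segmentation volume.

Clinical definitions implemented here (all on coronal slices):

* CBPD — maximum transverse diameter of the brain parenchyma above the
  Sylvian fissure, searched over all slices containing cerebrum.  The fissure
  itself is not detected; its level is approximated as a configurable
  superior fraction of the cerebrum's axial extent (default: the top half).
* TCD — maximum transverse diameter over all slices containing cerebellum,
  with no axial restriction.
* LAD / RAD — inner width of the lateral-ventricle atrium, measured on a
  single atrial-level slice perpendicular to each ventricle's own long axis.
  The atrial slice is located by default as the slice maximizing combined
  left+right ventricular area (the atria are the widest ventricular level);
  normalized template cross-correlation is available behind a flag.

Each operation returns a :class:`~fetalbiom.geometry.WidthMeasurement`
carrying the value, slice index and caliper endpoint coordinates so that
measurements can be rendered as overlays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateMaskError, MissingStructureError
from .geometry import WidthMeasurement, distance_profile, max_width, principal_axis
from .mask_io import BinaryMask, SegmentationVolume, extract_slice

__all__ = ["BiometryConfig", "BiometrySet", "measure_cbpd", "measure_tcd",
           "locate_atrial_slice", "measure_ad", "measure_all"]

ATRIAL_LOCATORS = ("max_ventricle_area", "template_correlation")


@dataclass
class BiometryConfig:
    """Tunable parameters of the measurement stage.

    cbpd_superior_fraction
        Fraction of the cerebrum's axial extent, measured from the superior
        end, within which CBPD is searched (proxy for "above the Sylvian
        fissure"); default 0.5.
    atrial_locator
        Strategy for finding the atrial slice; ``max_ventricle_area``
        (default) or ``template_correlation`` (requires ``template``).
    step_mm
        Axial sampling pitch of distance profiles; default (None) uses the
        minimum in-plane spacing.
    """

    cbpd_superior_fraction: float = 0.5
    atrial_locator: str = "max_ventricle_area"
    template: BinaryMask | None = None
    step_mm: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.cbpd_superior_fraction <= 1.0:
            raise ValueError("cbpd_superior_fraction must be in (0, 1]")
        if self.atrial_locator not in ATRIAL_LOCATORS:
            raise ValueError(
                f"atrial_locator must be one of {ATRIAL_LOCATORS}, got {self.atrial_locator!r}"
            )


@dataclass(frozen=True)
class BiometrySet:
    """The four coronal biometric measurements of one volume."""

    cbpd: WidthMeasurement
    tcd: WidthMeasurement
    lad: WidthMeasurement
    rad: WidthMeasurement

    def as_dict(self) -> dict[str, WidthMeasurement]:
        return {"cbpd": self.cbpd, "tcd": self.tcd, "lad": self.lad, "rad": self.rad}

    def values_mm(self) -> dict[str, float]:
        return {name: m.value_mm for name, m in self.as_dict().items()}


def _slices_with_label(volume: SegmentationVolume, label: int) -> np.ndarray:
    return np.flatnonzero((volume.labels == label).any(axis=(1, 2)))


def _max_width_over_slices(
    volume: SegmentationVolume,
    label: int,
    structure: str,
    range_fraction: tuple[float, float],
    step_mm: float | None,
) -> WidthMeasurement:
    slices = _slices_with_label(volume, label)
    if len(slices) == 0:
        raise MissingStructureError(structure)
    best: WidthMeasurement | None = None
    for k in slices:
        mask = extract_slice(volume, int(k), label)
        try:
            axis = principal_axis(mask)
            profile = distance_profile(mask, axis, step_mm)
            m = max_width(profile, range_fraction)
        except DegenerateMaskError:
            continue  # single-pixel slices cannot be profiled reliably
        if best is None or m.value_mm > best.value_mm:
            best = m.with_slice(int(k))
    if best is None:
        raise MissingStructureError(structure, "no measurable slice")
    return best


def measure_cbpd(volume: SegmentationVolume, config: BiometryConfig | None = None) -> WidthMeasurement:
    """Cerebral biparietal diameter: max transverse width in the superior
    fraction of the cerebrum, over all slices containing cerebrum."""
    config = config or BiometryConfig()
    return _max_width_over_slices(
        volume,
        volume.schema.cerebrum,
        "cerebrum",
        (0.0, config.cbpd_superior_fraction),
        config.step_mm,
    )


def measure_tcd(volume: SegmentationVolume, config: BiometryConfig | None = None) -> WidthMeasurement:
    """Transverse cerebellar diameter: max width over all cerebellar slices."""
    config = config or BiometryConfig()
    return _max_width_over_slices(
        volume, volume.schema.cerebellum, "cerebellum", (0.0, 1.0), config.step_mm
    )


def _template_score(mask_pixels: np.ndarray, template: BinaryMask) -> float:
    """Normalized cross-correlation of two binary masks after centroid alignment."""
    a = mask_pixels
    b = template.pixels
    if not a.any() or not b.any():
        return 0.0
    ca = np.argwhere(a).mean(axis=0)
    cb = np.argwhere(b).mean(axis=0)
    shift = np.rint(ca - cb).astype(int)
    score = 0
    for (r, c) in np.argwhere(b):
        rr, cc = r + shift[0], c + shift[1]
        if 0 <= rr < a.shape[0] and 0 <= cc < a.shape[1] and a[rr, cc]:
            score += 1
    return score / float(np.sqrt(a.sum() * b.sum()))


def locate_atrial_slice(volume: SegmentationVolume, config: BiometryConfig | None = None) -> int:
    """Find the coronal slice at the level of the atria.

    Default strategy: the slice maximizing summed left+right ventricular
    area in mm² (ties → smallest index).  The ``template_correlation``
    strategy instead maximizes normalized cross-correlation between the
    combined-ventricle mask and a supplied template after centroid alignment.
    """
    config = config or BiometryConfig()
    lv, rv = volume.schema.left_ventricle, volume.schema.right_ventricle
    combined = (volume.labels == lv) | (volume.labels == rv)
    counts = combined.sum(axis=(1, 2))
    if counts.sum() == 0:
        raise MissingStructureError(["left_ventricle", "right_ventricle"])
    if config.atrial_locator == "max_ventricle_area":
        return int(np.argmax(counts))  # argmax → smallest index on ties
    if config.template is None:
        raise ValueError("template_correlation locator requires config.template")
    scores = np.array(
        [
            _template_score(combined[k], config.template) if counts[k] else -np.inf
            for k in range(volume.n_slices)
        ]
    )
    return int(np.argmax(scores))


def measure_ad(
    volume: SegmentationVolume, side: str, config: BiometryConfig | None = None
) -> WidthMeasurement:
    """Atrial diameter of one lateral ventricle on the atrial slice.

    The ventricle's own long axis is estimated on the atrial slice and the
    maximum width perpendicular to it is returned.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    config = config or BiometryConfig()
    structure = f"{side}_ventricle"
    label = volume.label_for(structure)
    k = locate_atrial_slice(volume, config)
    mask = extract_slice(volume, k, label)
    if mask.count < 2:
        raise MissingStructureError(structure, f"absent on atrial slice {k}")
    axis = principal_axis(mask)
    profile = distance_profile(mask, axis, config.step_mm)
    return max_width(profile, (0.0, 1.0)).with_slice(k)


def measure_all(volume: SegmentationVolume, config: BiometryConfig | None = None) -> BiometrySet:
    """Compute all four measurements, reporting all missing structures at once."""
    config = config or BiometryConfig()
    counts = volume.voxel_counts()
    missing = [name for name, n in counts.items() if n == 0]
    if missing:
        raise MissingStructureError(missing)
    return BiometrySet(
        cbpd=measure_cbpd(volume, config),
        tcd=measure_tcd(volume, config),
        lad=measure_ad(volume, "left", config),
        rad=measure_ad(volume, "right", config),
    )
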