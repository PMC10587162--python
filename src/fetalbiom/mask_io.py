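"""Reading, validating and writing multi-label fetal-brain segmentation volumes.

A segmentation volume holds integer labels for four structures — cerebrum,
cerebellum and the two lateral ventricles — on a coronal slice stack.  All
in-memory grids use 0-based ``(slice, row, column)`` index order where the
slice axis is the coronal (anterior–posterior) direction, rows run
superior → inferior and columns run across the head.  On load, NIfTI volumes
are permuted/flipped from their header orientation into this convention so
that downstream geometry can treat "up" uniformly.

Only the in-plane (row, column) spacing enters width computations; the slice
pitch (thickness + gap, typically 3–5 mm for fetal SSFSE acquisitions) is kept
as a single number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .errors import FetalBiomError, SchemaViolationError

__all__ = [
    "LabelSchema",
    "SegmentationVolume",
    "BinaryMask",
    "read_volume",
    "write_volume",
    "extract_slice",
]


@dataclass(frozen=True)
class LabelSchema:
    """Integer label codes for the four annotated structures.

    Defaults follow the package convention cerebrum=1, cerebellum=2,
    left ventricle=3, right ventricle=4; all four must be distinct and
    positive (0 is background).
    """

    cerebrum: int = 1
    cerebellum: int = 2
    left_ventricle: int = 3
    right_ventricle: int = 4

    def __post_init__(self) -> None:
        labels = self.as_dict()
        if any(int(v) <= 0 for v in labels.values()):
            raise ValueError("all labels must be positive integers (0 is background)")
        if len(set(labels.values())) != 4:
            raise ValueError(f"labels must be distinct, got {labels}")

    def as_dict(self) -> dict[str, int]:
        return {
            "cerebrum": int(self.cerebrum),
            "cerebellum": int(self.cerebellum),
            "left_ventricle": int(self.left_ventricle),
            "right_ventricle": int(self.right_ventricle),
        }

    @property
    def labels(self) -> tuple[int, int, int, int]:
        return (self.cerebrum, self.cerebellum, self.left_ventricle, self.right_ventricle)

    @classmethod
    def from_yaml(cls, path) -> "LabelSchema":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        if isinstance(cfg, dict) and "labels" in cfg:
            cfg = cfg["labels"]
        return cls(**{k: int(v) for k, v in cfg.items()})


@dataclass
class SegmentationVolume:
    """A 3D integer label grid with physical voxel spacing in mm.

    ``labels`` is indexed ``(slice, row, column)`` with coronal slices along
    axis 0.  ``spacing_mm`` is ``(slice_pitch, row, column)``.
    """

    labels: np.ndarray
    spacing_mm: tuple[float, float, float]
    schema: LabelSchema = field(default_factory=LabelSchema)
    slice_axis_is_coronal: bool = True

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be three positive reals")
        self.validate()

    def validate(self) -> None:
        present = np.unique(self.labels)
        allowed = {0, *self.schema.labels}
        bad = [int(v) for v in present if int(v) not in allowed]
        if bad:
            raise SchemaViolationError(bad)

    @property
    def n_slices(self) -> int:
        return self.labels.shape[0]

    @property
    def in_plane_spacing_mm(self) -> tuple[float, float]:
        return self.spacing_mm[1:]

    def label_for(self, structure: str) -> int:
        return self.schema.as_dict()[structure]

    def voxel_counts(self) -> dict[str, int]:
        return {
            name: int(np.count_nonzero(self.labels == lab))
            for name, lab in self.schema.as_dict().items()
        }


@dataclass(frozen=True)
class BinaryMask:
    """A 2D boolean pixel grid with (row, column) spacing in mm."""

    pixels: np.ndarray
    spacing_mm: tuple[float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", np.asarray(self.pixels, dtype=bool))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2D")
        if len(self.spacing_mm) != 2 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be two positive reals")

    @property
    def count(self) -> int:
        return int(np.count_nonzero(self.pixels))


# NIfTI axis bookkeeping: canonical (RAS) data axes are (R, A, S).  The package
# convention is (slice=A/P, row=S→I, col=L/R), i.e. transpose to (A, S, R) and
# flip the S axis so row 0 is superior.
_CANONICAL_TO_INTERNAL = (1, 2, 0)
_INTERNAL_TO_CANONICAL = (2, 0, 1)


def read_volume(path, schema: LabelSchema | None = None) -> SegmentationVolume:
    """Read a NIfTI label image and orient it coronal-slice-first.

    The image is reoriented to its closest canonical (RAS) orientation, then
    permuted so that the anterior–posterior axis (coronal slicing direction)
    is first and rows run superior → inferior.  Voxel values are validated
    against ``schema``; any value outside ``{0} ∪ schema`` raises
    :class:`SchemaViolationError`.
    """
    schema = schema or LabelSchema()
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise FetalBiomError(f"cannot read NIfTI file {path}: {exc}") from exc
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FetalBiomError(f"{path}: expected a 3D label image, got {data.ndim}D")
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise FetalBiomError(f"{path}: voxel values are not integer labels")
        data = rounded.astype(np.int32)
    zooms = img.header.get_zooms()[:3]  # (R, A, S)
    labels = np.transpose(data, _CANONICAL_TO_INTERNAL)[:, ::-1, :]
    spacing = (float(zooms[1]), float(zooms[2]), float(zooms[0]))
    return SegmentationVolume(
        labels=np.ascontiguousarray(labels.astype(np.int16)),
        spacing_mm=spacing,
        schema=schema,
    )


def write_volume(volume: SegmentationVolume, path) -> None:
    """Write a volume as NIfTI, losslessly invertible by :func:`read_volume`."""
    path = Path(path)
    data = np.transpose(volume.labels[:, ::-1, :], _INTERNAL_TO_CANONICAL)
    sp_slice, sp_row, sp_col = volume.spacing_mm
    affine = np.diag([sp_col, sp_slice, sp_row, 1.0])
    img = nib.Nifti1Image(np.ascontiguousarray(data).astype(np.int16), affine)
    img.header.set_zooms((sp_col, sp_slice, sp_row))
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise FetalBiomError(f"cannot write NIfTI file {path}: {exc}") from exc


def extract_slice(volume: SegmentationVolume, slice_index: int, label: int) -> BinaryMask:
    """Extract one coronal slice of one label as a binary mask.

    A slice with no voxels of the label yields an all-false mask (not an
    error); an out-of-range index or a label absent from the schema raises.
    """
    if not 0 <= slice_index < volume.n_slices:
        raise IndexError(
            f"slice index {slice_index} out of range [0, {volume.n_slices})"
        )
    if int(label) not in volume.schema.labels:
        raise SchemaViolationError([label])
    return BinaryMask(
        pixels=volume.labels[slice_index] == int(label),
        spacing_mm=volume.in_plane_spacing_mm,
    )
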