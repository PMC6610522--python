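"""NIfTI-backed volume container and round-trip I/O.

A :class:`Volume` is a plain ``(rows, cols, slices)`` array plus a 4x4 affine.
Masks and label maps use integer dtypes so they survive a round trip
bit-exactly; intensity volumes are stored as float32/float64.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import AlignmentError, ContractViolation

__all__ = ["Volume", "read_volume", "write_volume", "check_aligned"]


@dataclass
class Volume:
    """3-D image with spatial metadata.

    Attributes
    ----------
    data : ndarray, shape (rows, cols, slices)
    affine : ndarray, shape (4, 4)
        Voxel-to-world transform; the voxel size in mm is recovered from it.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ContractViolation(f"expected a 3-D array, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ContractViolation("affine must be 4x4")

    @classmethod
    def from_voxel_size(cls, data: np.ndarray, voxel_size=(1.0, 1.0, 1.0)) -> "Volume":
        aff = np.diag(list(voxel_size) + [1.0])
        return cls(np.asarray(data), aff)

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm, one per axis."""
        return np.asarray(nib.affines.voxel_sizes(self.affine), dtype=float)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.voxel_size))

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.affine.copy())


def read_volume(path) -> Volume:
    """Load a NIfTI file, keeping its native dtype (masks stay integer)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    return Volume(data, img.affine)


def write_volume(vol: Volume, path) -> Path:
    """Write ``vol`` as NIfTI; ``.nii`` and ``.nii.gz`` both work."""
    path = Path(path)
    img = nib.Nifti1Image(vol.data, vol.affine)
    nib.save(img, str(path))
    return path


def check_aligned(**volumes: Volume) -> None:
    """Raise :class:`AlignmentError` naming every volume whose shape or affine
    deviates from the first one given."""
    items = list(volumes.items())
    ref_name, ref = items[0]
    bad = [
        name
        for name, v in items[1:]
        if v.shape != ref.shape or not np.allclose(v.affine, ref.affine, atol=1e-6)
    ]
    if bad:
        raise AlignmentError(
            f"volumes {bad} are not aligned with '{ref_name}' "
            f"(shape {ref.shape}, affine diag {np.diag(ref.affine)[:3]})"
        )
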