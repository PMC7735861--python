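"""Binary volume masks in a common template space.

A :class:`VolumeMask` wraps a 3-D boolean voxel grid together with its voxel
geometry (mm) and the identity of the longitudinal (inferior-superior) axis.
Lesion volumes-of-interest and the bilateral corticospinal-tract atlas are
both represented this way; all masks entering a comparison must share the
same grid shape and voxel size, i.e. live in the same template space.

NIfTI-1 I/O goes through nibabel.  Masks are stored with 0/1 integer data on
disk and converted to boolean in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import nibabel as nib
import numpy as np

__all__ = ["VolumeMask", "lesion_volume", "lesion_side"]

Side = Literal["left", "right", "bilateral"]

#: Grid axis conventions used throughout the package (RAS-like ordering):
#: axis 0 is lateral (left-right), axis 2 is longitudinal (inferior-superior).
LATERAL_AXIS = 0
LONGITUDINAL_AXIS = 2


@dataclass(frozen=True)
class VolumeMask:
    """A 3-D binary mask with voxel geometry.

    Parameters
    ----------
    data
        Boolean voxel grid.  Any 0/1-valued array is accepted and cast.
    voxel_size
        Voxel edge lengths in mm, strictly positive.
    longitudinal_axis
        Grid axis running inferior to superior (increasing index = superior).
    affine
        Optional 4x4 voxel-to-mm affine.  Defaults to a diagonal affine built
        from ``voxel_size``; carried through NIfTI round trips.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    longitudinal_axis: int = LONGITUDINAL_AXIS
    affine: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3-D, got {arr.ndim}-D")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.isin(uniq, (0, 1)).all():
                raise ValueError("mask must be binary (0/1) valued")
            arr = arr.astype(bool)
        object.__setattr__(self, "data", arr)
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be 3 positive lengths, got {self.voxel_size}")
        object.__setattr__(self, "voxel_size", vs)
        if not 0 <= self.longitudinal_axis <= 2:
            raise ValueError("longitudinal_axis must be 0, 1 or 2")

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    def count(self) -> int:
        """Number of set voxels."""
        return int(self.data.sum())

    def is_empty(self) -> bool:
        return not self.data.any()

    def same_grid(self, other: "VolumeMask") -> None:
        """Raise if the two masks do not share grid shape and voxel size."""
        for axis, (a, b) in enumerate(zip(self.shape, other.shape)):
            if a != b:
                raise ValueError(
                    f"grid mismatch along axis {axis}: {a} != {b} voxels"
                )
        if not np.allclose(self.voxel_size, other.voxel_size):
            raise ValueError(
                f"voxel size mismatch: {self.voxel_size} != {other.voxel_size}"
            )
        if self.longitudinal_axis != other.longitudinal_axis:
            raise ValueError("longitudinal axis mismatch")

    # -- I/O -------------------------------------------------------------
    @classmethod
    def from_nifti(cls, path: str | Path, longitudinal_axis: int = LONGITUDINAL_AXIS) -> "VolumeMask":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        zooms = img.header.get_zooms()[:3]
        return cls(
            data=data > 0.5,
            voxel_size=tuple(float(z) for z in zooms),
            longitudinal_axis=longitudinal_axis,
            affine=np.asarray(img.affine),
        )

    def to_nifti(self, path: str | Path) -> None:
        affine = self.affine
        if affine is None:
            affine = np.diag(list(self.voxel_size) + [1.0])
        img = nib.Nifti1Image(self.data.astype(np.uint8), affine)
        img.header.set_zooms(self.voxel_size)
        nib.save(img, str(path))


def lesion_volume(lesion: VolumeMask) -> float:
    """Lesion volume in mm^3: voxel count times voxel volume."""
    return lesion.count() * lesion.voxel_volume_mm3


def lesion_side(
    lesion: VolumeMask,
    midline_index: int,
    lateral_axis: int = LATERAL_AXIS,
) -> Side:
    """Classify a lesion as left, right or bilateral relative to a midline.

    The midline is the sagittal voxel plane ``index == midline_index`` on the
    lateral axis.  The convention is half-open: voxel indices strictly below
    ``midline_index`` are *left*, indices at or above it (including the
    midline plane itself) are *right*.  Bilateral lesions must be flagged so
    the caller can exclude the patient.

    Raises
    ------
    ValueError
        If the lesion is empty or the midline falls outside the grid.
    """
    if lesion.is_empty():
        raise ValueError("cannot determine the side of an empty lesion")
    n = lesion.shape[lateral_axis]
    if not 0 < midline_index < n:
        raise ValueError(f"midline_index {midline_index} not strictly inside grid of {n} voxels")
    lateral_idx = np.nonzero(lesion.data)[lateral_axis]
    has_left = bool((lateral_idx < midline_index).any())
    has_right = bool((lateral_idx >= midline_index).any())
    if has_left and has_right:
        return "bilateral"
    return "left" if has_left else "right"
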