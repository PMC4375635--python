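"""3-D scalar volumes with voxel-spacing metadata.

:class:`VolumeGrid` is the in-memory container passed between all pipeline
stages.  By convention axis 2 (the third NIfTI axis) is the through-plane
(coronal-slice) axis; the first two axes are in-plane.  Volumes are written
as NIfTI-1 with an RAS+ diagonal affine carrying the voxel spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

from .errors import GridMismatchError

#: axis index of the coronal-slice (through-plane) direction
SLICE_AXIS = 2


@dataclass
class VolumeGrid:
    """A 3-D scalar image plus voxel spacing in mm.

    Parameters
    ----------
    data:
        3-D array; integer dtypes denote label volumes, floats intensities.
    spacing:
        Voxel edge lengths in mm, ordered like the array axes.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (0.94, 0.94, 5.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise GridMismatchError(f"expected a 3-D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GridMismatchError(f"invalid voxel spacing {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_slices(self) -> int:
        return self.data.shape[SLICE_AXIS]

    @property
    def pixel_area(self) -> float:
        """In-plane pixel area in mm^2."""
        return self.spacing[0] * self.spacing[1]

    def slice(self, index: int) -> np.ndarray:
        """Return the 2-D in-plane array of coronal slice ``index``."""
        return self.data[:, :, index]

    def same_grid(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.spacing, other.spacing, atol=atol
        )

    def require_same_grid(self, other: "VolumeGrid", what: str = "volume") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"{what}: shape/spacing mismatch "
                f"({self.shape}@{self.spacing} vs {other.shape}@{other.spacing})"
            )

    def with_data(self, data: np.ndarray) -> "VolumeGrid":
        return VolumeGrid(data=data, spacing=self.spacing)

    # ------------------------------------------------------------------ I/O
    def affine(self) -> np.ndarray:
        return np.diag(list(self.spacing) + [1.0])

    def to_nifti(self) -> nib.Nifti1Image:
        data = self.data
        if np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float32)  # stored as 32-bit float
        else:
            data = data.astype(np.int16)
        img = nib.Nifti1Image(data, self.affine())
        img.header.set_zooms(self.spacing)
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "VolumeGrid":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        return cls(data=np.asanyarray(img.dataobj), spacing=tuple(float(z) for z in zooms))
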