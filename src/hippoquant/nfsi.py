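"""Normalised FLAIR signal intensity (nFSI).

FLAIR is not quantitative: raw intensities carry an arbitrary scanner gain.
nFSI removes the gain by dividing each voxel by the mean FLAIR intensity of
white-matter reference regions (pons and anterior frontal lobes) and
re-expressing the result in normalised units (n.u.), where the reference
mean maps to ``scale_factor`` (default 1500 n.u.).  The transform is a
simple linear ratio scaling — deliberately minimal: no histogram matching,
z-scoring or bias-field correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ReferenceRegionError
from .grid import VolumeGrid

__all__ = ["NFSIVolume", "reference_mean", "normalise_flair", "DEFAULT_SCALE_FACTOR"]

#: normalised units assigned to the white-matter reference mean
DEFAULT_SCALE_FACTOR = 1500.0


@dataclass
class NFSIVolume:
    """A FLAIR volume in normalised units.

    The mean of ``values`` over the reference-region union equals
    ``scale_factor`` (to floating-point precision).
    """

    values: VolumeGrid
    reference_mean: float
    scale_factor: float

    @property
    def data(self) -> np.ndarray:
        return self.values.data


def _mask_array(flair: VolumeGrid, mask: VolumeGrid | np.ndarray, name: str) -> np.ndarray:
    if isinstance(mask, VolumeGrid):
        flair.require_same_grid(mask, name)
        return mask.data.astype(bool)
    arr = np.asarray(mask).astype(bool)
    if arr.shape != flair.shape:
        raise ReferenceRegionError(f"{name} mask shape {arr.shape} != {flair.shape}")
    return arr


def reference_mean(
    flair: VolumeGrid,
    pons_mask: VolumeGrid | np.ndarray,
    frontal_mask: VolumeGrid | np.ndarray,
    pooling: str = "union",
) -> float:
    """Mean raw FLAIR intensity over the white-matter reference regions.

    ``pooling='union'`` (default) averages over the voxel union of both
    masks with every voxel weighted equally; ``pooling='regional'`` averages
    the two regional means instead.
    """
    pons = _mask_array(flair, pons_mask, "pons")
    frontal = _mask_array(flair, frontal_mask, "frontal")
    union = pons | frontal
    if not union.any():
        raise ReferenceRegionError("empty white-matter reference region union")
    data = np.asarray(flair.data, dtype=np.float64)
    if pooling == "union":
        return float(data[union].mean())
    if pooling == "regional":
        if not pons.any() or not frontal.any():
            raise ReferenceRegionError("regional pooling needs both masks nonempty")
        return float((data[pons].mean() + data[frontal].mean()) / 2.0)
    raise ReferenceRegionError(f"unknown pooling mode {pooling!r}")


def normalise_flair(
    flair: VolumeGrid, ref: float, scale_factor: float = DEFAULT_SCALE_FACTOR
) -> NFSIVolume:
    """Rescale a raw FLAIR volume to normalised units.

    Every voxel maps to ``raw * scale_factor / ref``; the map is linear and
    order-preserving, and invariant to any global gain applied to the input
    (the gain cancels through ``ref``).
    """
    if ref <= 0:
        raise ReferenceRegionError(f"reference mean must be positive, got {ref}")
    if scale_factor <= 0:
        raise ReferenceRegionError(f"scale factor must be positive, got {scale_factor}")
    values = np.asarray(flair.data, dtype=np.float64) * (scale_factor / ref)
    return NFSIVolume(
        values=flair.with_data(values),
        reference_mean=float(ref),
        scale_factor=float(scale_factor),
    )
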