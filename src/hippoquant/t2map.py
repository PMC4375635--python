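"""Voxel-wise T2 mapping from a dual-echo spin-echo pair.

The map is the closed-form two-point estimate

    T2 = (TE2 - TE1) / ln(S1 / S2)

valid only where S1 > S2 > 0.  Voxels violating that (background, noise
inversions, S1 == S2) are flagged invalid and carried as NaN plus an
explicit validity mask — never clamped to a number.  Computation is in
double precision; no spatial smoothing is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .grid import VolumeGrid
from .tissue import AcquisitionParams

__all__ = ["T2Map", "compute_t2_map"]


@dataclass
class T2Map:
    """A voxel-wise T2 map in ms with an explicit validity mask.

    ``values.data`` is NaN wherever ``valid`` is False; every valid voxel is
    strictly positive.
    """

    values: VolumeGrid
    valid: np.ndarray
    te1: float
    te2: float

    @property
    def data(self) -> np.ndarray:
        return self.values.data

    def save(self, path, mask_path=None) -> None:
        """Write the map (NaN-coded invalid voxels) and optionally the mask."""
        self.values.save(path)
        if mask_path is not None:
            self.values.with_data(self.valid.astype(np.int16)).save(mask_path)


def compute_t2_map(
    s1: VolumeGrid,
    s2: VolumeGrid,
    acq: AcquisitionParams | None = None,
    mask: VolumeGrid | np.ndarray | None = None,
    *,
    te1: float | None = None,
    te2: float | None = None,
) -> T2Map:
    """Compute the two-point T2 map of a dual-echo pair.

    Parameters
    ----------
    s1, s2:
        Early- and late-echo volumes on the same grid.
    acq:
        Acquisition parameters supplying TE1/TE2 (ms); alternatively pass
        ``te1``/``te2`` explicitly.
    mask:
        Optional volume; voxels where it is 0/False are marked invalid.
    """
    if te1 is None or te2 is None:
        acq = acq or AcquisitionParams()
        te1 = acq.te1 if te1 is None else te1
        te2 = acq.te2 if te2 is None else te2
    if not te2 > te1 > 0:
        raise ConfigurationError(f"need te2 > te1 > 0, got te1={te1}, te2={te2}")
    s1.require_same_grid(s2, "dual-echo pair")

    a1 = np.asarray(s1.data, dtype=np.float64)
    a2 = np.asarray(s2.data, dtype=np.float64)
    valid = (a1 > a2) & (a2 > 0)
    if mask is not None:
        mdata = mask.data if isinstance(mask, VolumeGrid) else np.asarray(mask)
        if isinstance(mask, VolumeGrid):
            s1.require_same_grid(mask, "mask")
        elif mdata.shape != a1.shape:
            raise ConfigurationError("mask shape does not match the echo volumes")
        valid &= mdata.astype(bool)

    t2 = np.full_like(a1, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        np.divide(te2 - te1, np.log(a1 / a2), out=t2, where=valid)
    t2[~valid] = np.nan
    return T2Map(values=s1.with_data(t2), valid=valid, te1=float(te1), te2=float(te2))
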