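"""Ovoid hippocampal ROI placement, validation and measurement.

The measurement protocol reduces a scalar volume (T2 map or nFSI) to one
number per hippocampus: an ovoid ROI is placed on 4-5 consecutive coronal
slices inside the hippocampus, as large as can be accommodated while
staying at least one voxel away from CSF (and choroid plexus), with a
minimum in-plane area of 18 mm^2 per slice; the voxel mean is taken per
slice and the slice means are averaged with equal weights.

Placement is automated here: per slice the largest inscribed ellipse of the
hippocampus cross-section (minus the dilated exclusion mask) is found by a
deterministic search over candidate centers (distance-transform peak and
its neighbourhood) and candidate shapes (region principal axes and a
circle).  For each candidate the maximal scale is exact: the elliptical
norm of the nearest non-allowed pixel bounds the ellipse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import MeasurementError, PlacementError
from .grid import VolumeGrid
from .nfsi import NFSIVolume
from .t2map import T2Map
from .tissue import EXCLUSION_CLASSES, Tissue

__all__ = [
    "ROIPolicy",
    "ROISet",
    "HippocampusMeasure",
    "auto_place_ovoid",
    "validate_roi",
    "measure_hippocampus",
    "largest_inscribed_ellipse",
]


@dataclass(frozen=True)
class ROIPolicy:
    """Placement policy: minimum slice area, slice-count range, CSF margin."""

    min_area_mm2: float = 18.0
    min_slices: int = 4
    max_slices: int = 5
    exclusion_margin: int = 1
    max_invalid_fraction: float = 0.0


@dataclass
class ROISet:
    """Per-slice 2-D ovoid masks for one hippocampus.

    ``slices`` holds (slice_index, boolean in-plane mask) pairs with
    strictly consecutive indices.
    """

    subject_id: str
    side: str
    slices: list[tuple[int, np.ndarray]]
    pixel_area: float

    @property
    def slice_indices(self) -> list[int]:
        return [idx for idx, _ in self.slices]

    @property
    def areas_mm2(self) -> list[float]:
        return [float(mask.sum()) * self.pixel_area for _, mask in self.slices]

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    def to_label_volume(self, like: VolumeGrid, label: int = 1) -> VolumeGrid:
        """Rasterise the ROI into an integer label volume on ``like``'s grid."""
        out = np.zeros(like.shape, dtype=np.int16)
        for idx, mask in self.slices:
            out[:, :, idx][mask] = label
        return like.with_data(out)


@dataclass
class HippocampusMeasure:
    """One scalar per hippocampus per modality (slice-mean of slice means)."""

    subject_id: str
    side: str
    modality: str  # "t2" (ms) or "nfsi" (n.u.)
    value: float
    n_slices: int
    slice_values: list[float]


@dataclass
class ROIValidationReport:
    passed: bool
    reasons: list[str]
    per_slice: list[dict]


# ------------------------------------------------------- inscribed ellipse
_SIDE_LABEL = {"left": Tissue.HIPPOCAMPUS_LEFT, "right": Tissue.HIPPOCAMPUS_RIGHT}


def _ellipse_norm(
    xs: np.ndarray, ys: np.ndarray, center, angle: float, ratio: float
) -> np.ndarray:
    """Elliptical distance: 1.0 on the ellipse with semi-axes (1, ratio)."""
    cx, cy = center
    c, s = math.cos(angle), math.sin(angle)
    u = c * (xs - cx) + s * (ys - cy)
    v = -s * (xs - cx) + c * (ys - cy)
    return np.sqrt(u**2 + (v / ratio) ** 2)


def largest_inscribed_ellipse(allowed: np.ndarray) -> np.ndarray | None:
    """Largest ellipse-shaped pixel mask fully inside a 2-D boolean mask.

    Deterministic bounded search: centers come from the distance-transform
    peak and its 8-neighbourhood, orientations/axis ratios from the region's
    second moments plus a circle fallback; for each candidate the maximal
    semi-major axis is the smallest elliptical norm over non-allowed pixels
    (the array border counts as non-allowed).  Returns None for an empty
    mask.
    """
    allowed = np.asarray(allowed, dtype=bool)
    if not allowed.any():
        return None
    # pad with a forbidden border so the ellipse is confined to the array
    pad = np.zeros((allowed.shape[0] + 2, allowed.shape[1] + 2), dtype=bool)
    pad[1:-1, 1:-1] = allowed
    xs, ys = np.meshgrid(
        np.arange(pad.shape[0]), np.arange(pad.shape[1]), indexing="ij"
    )
    forb_x = xs[~pad].astype(float)
    forb_y = ys[~pad].astype(float)

    # shape candidates from the second moments of the allowed region
    axs, ays = np.nonzero(pad)
    mx, my = axs.mean(), ays.mean()
    cov = np.cov(np.vstack([axs, ays]).astype(float)) if axs.size > 1 else np.eye(2)
    evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
    major = evecs[:, int(np.argmax(evals))]
    angle0 = math.atan2(major[1], major[0])
    lam = np.sort(np.maximum(evals, 1e-9))[::-1]
    ratio0 = float(np.clip(math.sqrt(lam[1] / lam[0]), 0.2, 1.0))
    shapes = [(angle0, ratio0), (angle0, min(1.0, ratio0 * 1.3)),
              (angle0, max(0.2, ratio0 * 0.75)), (0.0, 1.0)]

    dt = ndimage.distance_transform_edt(pad)
    px, py = np.unravel_index(int(np.argmax(dt)), dt.shape)
    centers = [
        (px + dx, py + dy)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        if pad[px + dx, py + dy]
    ]
    if pad[int(round(mx)), int(round(my))]:
        centers.append((int(round(mx)), int(round(my))))

    best: np.ndarray | None = None
    best_count = 0
    for center in centers:
        for angle, ratio in shapes:
            norms = _ellipse_norm(forb_x, forb_y, center, angle, ratio)
            a_max = float(norms.min()) - 1e-9
            if a_max <= 0:
                continue
            all_norms = _ellipse_norm(
                xs.astype(float), ys.astype(float), center, angle, ratio
            )
            mask = all_norms <= a_max
            count = int(mask.sum())
            if count > best_count:
                best_count = count
                best = mask
    if best is None:
        return None
    return best[1:-1, 1:-1]


def _exclusion_array(
    labels: VolumeGrid, exclusion: VolumeGrid | np.ndarray | None
) -> np.ndarray:
    if exclusion is None:
        return np.isin(labels.data, [int(c) for c in EXCLUSION_CLASSES])
    arr = exclusion.data if isinstance(exclusion, VolumeGrid) else np.asarray(exclusion)
    return arr.astype(bool)


def auto_place_ovoid(
    labels: VolumeGrid,
    side: str,
    exclusion: VolumeGrid | np.ndarray | None = None,
    policy: ROIPolicy = ROIPolicy(),
    subject_id: str = "",
) -> ROISet:
    """Place ovoid ROIs on 4-5 consecutive slices of one hippocampus.

    ``exclusion`` defaults to the CSF + choroid-plexus voxels of the label
    volume.  Each slice ROI is the largest inscribed ellipse of the
    hippocampus cross-section after removing every voxel within
    ``policy.exclusion_margin`` voxels of the exclusion mask; slices whose
    best ellipse is below ``policy.min_area_mm2`` are unusable.  The
    consecutive window (preferring ``max_slices``, falling back to
    ``min_slices``) with the largest total area wins; ties go to the more
    anterior (higher-index) start.

    Raises
    ------
    PlacementError
        If no window of at least ``min_slices`` consecutive compliant
        slices exists.
    """
    if side not in _SIDE_LABEL:
        raise PlacementError(f"side must be 'left' or 'right', got {side!r}")
    target = int(_SIDE_LABEL[side])
    excl3 = _exclusion_array(labels, exclusion)
    pixel_area = labels.pixel_area
    min_pixels = policy.min_area_mm2 / pixel_area

    candidates: dict[int, np.ndarray] = {}
    for z in range(labels.n_slices):
        hmask = labels.slice(z) == target
        if not hmask.any():
            continue
        excl2 = excl3[:, :, z]
        if policy.exclusion_margin > 0 and excl2.any():
            excl2 = ndimage.binary_dilation(
                excl2, structure=np.ones((3, 3), dtype=bool),
                iterations=policy.exclusion_margin,
            )
        allowed = hmask & ~excl2
        ell = largest_inscribed_ellipse(allowed)
        if ell is not None and ell.sum() >= min_pixels:
            candidates[z] = ell

    best_window: tuple[float, int, list[int]] | None = None
    for length in range(policy.max_slices, policy.min_slices - 1, -1):
        for start in range(labels.n_slices - length + 1):
            window = list(range(start, start + length))
            if not all(z in candidates for z in window):
                continue
            area = sum(float(candidates[z].sum()) for z in window)
            key = (area, start, window)
            if best_window is None or (area, start) > (best_window[0], best_window[1]):
                best_window = key
        if best_window is not None:
            break
    if best_window is None:
        raise PlacementError(
            f"{subject_id or 'subject'}/{side}: cannot place >= {policy.min_slices} "
            f"consecutive ROIs of >= {policy.min_area_mm2} mm^2"
        )
    slices = [(z, candidates[z]) for z in best_window[2]]
    return ROISet(subject_id=subject_id, side=side, slices=slices, pixel_area=pixel_area)


def validate_roi(
    roi: ROISet,
    labels: VolumeGrid,
    exclusion: VolumeGrid | np.ndarray | None = None,
    policy: ROIPolicy = ROIPolicy(),
) -> ROIValidationReport:
    """Check an ROISet against the placement rules; always returns a report.

    Failure reasons: ``min-area``, ``exclusion-overlap``, ``containment``,
    ``non-consecutive``, ``slice-count``.
    """
    target = int(_SIDE_LABEL[roi.side])
    excl3 = _exclusion_array(labels, exclusion)
    reasons: list[str] = []
    per_slice: list[dict] = []
    for idx, mask in roi.slices:
        area = float(mask.sum()) * roi.pixel_area
        overlap = int((mask & excl3[:, :, idx]).sum())
        contained = bool((labels.slice(idx)[mask] == target).all()) if mask.any() else True
        per_slice.append(
            {"slice": idx, "area_mm2": area, "exclusion_overlap": overlap,
             "contained": contained}
        )
        if area < policy.min_area_mm2 and "min-area" not in reasons:
            reasons.append("min-area")
        if overlap > 0 and "exclusion-overlap" not in reasons:
            reasons.append("exclusion-overlap")
        if not contained and "containment" not in reasons:
            reasons.append("containment")
    idxs = roi.slice_indices
    if idxs != list(range(min(idxs), min(idxs) + len(idxs))):
        reasons.append("non-consecutive")
    if not (policy.min_slices <= len(idxs) <= policy.max_slices):
        reasons.append("slice-count")
    return ROIValidationReport(passed=not reasons, reasons=reasons, per_slice=per_slice)


def measure_hippocampus(
    volume: VolumeGrid | T2Map | NFSIVolume,
    roi: ROISet,
    modality: str,
    max_invalid_fraction: float = 0.0,
) -> HippocampusMeasure:
    """Reduce a scalar volume to one measure for a hippocampus.

    Per-slice voxel means are averaged with equal slice weights (not the
    pooled voxel mean), so slices with different ROI areas contribute
    equally.  For a T2 map, invalid voxels inside the ROI above
    ``max_invalid_fraction`` raise :class:`MeasurementError`.
    """
    valid: np.ndarray | None = None
    if isinstance(volume, T2Map):
        valid = volume.valid
        grid = volume.values
    elif isinstance(volume, NFSIVolume):
        grid = volume.values
    else:
        grid = volume

    slice_values: list[float] = []
    for idx, mask in roi.slices:
        vox = grid.data[:, :, idx][mask]
        if valid is not None:
            ok = valid[:, :, idx][mask]
            frac_invalid = 1.0 - ok.mean() if ok.size else 1.0
            if frac_invalid > max_invalid_fraction:
                raise MeasurementError(
                    f"{roi.subject_id}/{roi.side}: {frac_invalid:.1%} invalid T2 "
                    f"voxels inside slice {idx} ROI exceeds policy "
                    f"({max_invalid_fraction:.1%})"
                )
            vox = vox[ok]
        if vox.size == 0:
            raise MeasurementError(f"{roi.subject_id}/{roi.side}: empty ROI slice {idx}")
        slice_values.append(float(np.mean(vox)))
    return HippocampusMeasure(
        subject_id=roi.subject_id,
        side=roi.side,
        modality=modality,
        value=float(np.mean(slice_values)),
        n_slices=len(slice_values),
        slice_values=slice_values,
    )
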