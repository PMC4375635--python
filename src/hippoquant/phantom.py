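"""Synthetic MR phantom: geometry and signal simulation.

The phantom is an abstract head-like layout, not realistic anatomy: a
brain ellipse of white matter with a cortical gray-matter shell, two
elongated ellipsoidal hippocampi wrapped in a one-voxel CSF rim (so the ROI
stage has CSF to avoid), a pontine and two anterior-frontal white-matter
reference regions for FLAIR normalisation, and a couple of choroid-plexus
voxels at the posterior hippocampal margin.  Geometry is randomised
(position/orientation jitter) per subject under a dedicated seed; the label
inventory is identical across seeds.

Signal models
-------------
Dual-echo fast spin echo, per voxel::

    S(TE) = PD * exp(-TE / T2)

FLAIR (inversion recovery with TE readout), per voxel::

    S = PD * |1 - 2*exp(-TI/T1) + exp(-TR/T1)| * exp(-TE/T2)

Noise is additive Gaussian on the magnitude image by default; a Rician mode
(magnitude of complex Gaussian noise) is available.  At ROI-mean scale the
two are indistinguishable at the simulated SNR; Gaussian keeps noiseless
round-trip identities exact.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, SizingError
from .grid import VolumeGrid
from .tissue import AcquisitionParams, Tissue, TissueParams, default_tissue_table

__all__ = [
    "spin_echo_signal",
    "flair_signal",
    "build_label_volume",
    "simulate_dual_echo",
    "simulate_flair",
]


# --------------------------------------------------------------- closed forms
def spin_echo_signal(proton_density: float, t2: float, te: float) -> float:
    """Noiseless spin-echo magnitude signal PD * exp(-TE/T2)."""
    return proton_density * math.exp(-te / t2)


def flair_signal(
    proton_density: float, t1: float, t2: float, acq: AcquisitionParams
) -> float:
    """Noiseless FLAIR magnitude signal.

    Inversion-recovery longitudinal attenuation |1 - 2 e^(-TI/T1) + e^(-TR/T1)|
    times T2 decay at the readout echo time.
    """
    inv = abs(
        1.0
        - 2.0 * math.exp(-acq.ti_flair / t1)
        + math.exp(-acq.tr_flair / t1)
    )
    return proton_density * inv * math.exp(-acq.te_flair / t2)


# ------------------------------------------------------------------ geometry
_MIN_MATRIX = 48
_MIN_SLICES = 8


def _ellipse_mask_2d(
    xx: np.ndarray,
    yy: np.ndarray,
    center: tuple[float, float],
    semi_axes: tuple[float, float],
    angle: float = 0.0,
) -> np.ndarray:
    """Rotated-ellipse mask on pixel-center coordinate grids."""
    cx, cy = center
    a, b = semi_axes
    c, s = math.cos(angle), math.sin(angle)
    u = c * (xx - cx) + s * (yy - cy)
    v = -s * (xx - cx) + c * (yy - cy)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def build_label_volume(
    acq: AcquisitionParams | None = None, geometry_seed: int = 0
) -> VolumeGrid:
    """Build one subject's integer label volume.

    The hippocampi are ellipsoids elongated along the slice axis, spanning
    at least five consecutive coronal slices, each surrounded by a one-voxel
    3-D CSF rim.  Positions and in-plane orientation are jittered by
    ``geometry_seed``; identical seeds give identical volumes.
    """
    acq = acq or AcquisitionParams()
    nx, ny = acq.matrix
    nz = acq.n_slices
    if nx < _MIN_MATRIX or ny < _MIN_MATRIX or nz < _MIN_SLICES:
        raise SizingError(
            f"matrix {acq.matrix} x {nz} slices too small; need >= "
            f"{_MIN_MATRIX} x {_MIN_MATRIX} x {_MIN_SLICES}"
        )
    rng = np.random.default_rng(geometry_seed)
    labels = np.zeros((nx, ny, nz), dtype=np.int16)
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")

    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    brain = _ellipse_mask_2d(xx, yy, (cx, cy), (0.45 * nx, 0.42 * ny))
    interior = ndimage.binary_erosion(brain, iterations=2)
    for z in range(nz):
        labels[:, :, z][brain] = Tissue.WHITE_MATTER
        labels[:, :, z][brain & ~interior] = Tissue.GRAY_MATTER

    z_lo, z_hi = 2, nz - 3  # reference regions span the interior slices

    def _fill_cylinder(center, semi, label):
        mask = _ellipse_mask_2d(xx, yy, center, semi)
        for z in range(z_lo, z_hi + 1):
            labels[:, :, z][mask] = label

    jit = lambda w: float(rng.uniform(-w, w))  # noqa: E731
    _fill_cylinder(
        (0.38 * nx + jit(1.0), 0.20 * ny + jit(1.0)), (4.5, 3.0), Tissue.FRONTAL_WM
    )
    _fill_cylinder(
        (0.62 * nx + jit(1.0), 0.20 * ny + jit(1.0)), (4.5, 3.0), Tissue.FRONTAL_WM
    )
    _fill_cylinder(
        (0.50 * nx + jit(1.0), 0.80 * ny + jit(1.0)), (6.0, 3.5), Tissue.PONS_WM
    )

    # hippocampal ellipsoids, elongated through-plane; sized so the largest
    # inscribed ellipse clears 18 mm^2 on >= 5 slices after the CSF margin
    semi_inplane = (8.5, 5.0)
    semi_z = 4.2
    cz = (nz - 1) / 2.0 + jit(0.5)
    hippo_masks = {}
    for side, xfrac, label in (
        ("left", 0.32, Tissue.HIPPOCAMPUS_LEFT),
        ("right", 0.68, Tissue.HIPPOCAMPUS_RIGHT),
    ):
        hx = xfrac * nx + jit(1.5)
        hy = 0.56 * ny + jit(1.5)
        angle = float(rng.uniform(-0.26, 0.26))  # +-15 degrees in-plane
        mask3 = np.zeros((nx, ny, nz), dtype=bool)
        for z in range(nz):
            f2 = 1.0 - ((z - cz) / semi_z) ** 2
            if f2 <= 0:
                continue
            f = math.sqrt(f2)
            mask3[:, :, z] = _ellipse_mask_2d(
                xx, yy, (hx, hy), (semi_inplane[0] * f, semi_inplane[1] * f), angle
            )
        hippo_masks[label] = mask3

    hippo_union = hippo_masks[Tissue.HIPPOCAMPUS_LEFT] | hippo_masks[Tissue.HIPPOCAMPUS_RIGHT]
    rim = ndimage.binary_dilation(hippo_union, structure=np.ones((3, 3, 3))) & ~hippo_union
    labels[rim] = Tissue.CSF
    for label, mask3 in hippo_masks.items():
        labels[mask3] = label

    # two choroid-plexus voxels per side: rim voxels nearest the hippocampal
    # center on the central slice, on the medial/posterior margin
    zc = int(round(cz))
    for label in (Tissue.HIPPOCAMPUS_LEFT, Tissue.HIPPOCAMPUS_RIGHT):
        hmask = hippo_masks[label][:, :, zc]
        hxs, hys = np.nonzero(hmask)
        hcx, hcy = hxs.mean(), hys.mean()
        rim_slice = (labels[:, :, zc] == Tissue.CSF)
        rxs, rys = np.nonzero(rim_slice)
        # only rim voxels inferior (larger y) to this hippocampus center
        sel = (rys > hcy) & (np.abs(rxs - hcx) < semi_inplane[0] + 2)
        if sel.sum() >= 2:
            d = (rxs[sel] - hcx) ** 2 + (rys[sel] - hcy) ** 2
            order = np.argsort(d, kind="stable")[:2]
            labels[rxs[sel][order], rys[sel][order], zc] = Tissue.CHOROID_PLEXUS

    present = set(np.unique(labels).tolist())
    required = {int(t) for t in Tissue if t != Tissue.CHOROID_PLEXUS}
    if not required <= present:
        missing = {Tissue(t).name for t in required - present}
        raise SizingError(f"phantom geometry lost tissue classes: {missing}")
    return VolumeGrid(data=labels, spacing=acq.voxel_size)


# ---------------------------------------------------------------- simulators
def _lookup_maps(
    labels: VolumeGrid,
    tissues: dict[Tissue, TissueParams],
    t2_overrides: dict[Tissue, float] | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel PD, T1 and T2 arrays from the label volume."""
    lab = labels.data.astype(np.int64)
    present = np.unique(lab)
    max_label = int(present.max(initial=0))
    pd_lut = np.zeros(max_label + 1)
    t1_lut = np.ones(max_label + 1)
    t2_lut = np.ones(max_label + 1)
    for value in present:
        try:
            cls = Tissue(int(value))
            params = tissues[cls]
        except (ValueError, KeyError):
            raise ConfigurationError(
                f"label {int(value)} present in volume but has no tissue parameters"
            ) from None
        pd_lut[value] = params.proton_density
        t1_lut[value] = params.t1
        t2_lut[value] = params.t2
        if t2_overrides and cls in t2_overrides:
            t2_lut[value] = float(t2_overrides[cls])
    return pd_lut[lab], t1_lut[lab], t2_lut[lab]


def _add_noise(
    signal: np.ndarray, sigma: float, rng: np.random.Generator, model: str
) -> np.ndarray:
    if sigma == 0:
        return signal
    if model == "gaussian":
        return signal + rng.normal(0.0, sigma, size=signal.shape)
    if model == "rician":
        re = signal + rng.normal(0.0, sigma, size=signal.shape)
        im = rng.normal(0.0, sigma, size=signal.shape)
        return np.sqrt(re**2 + im**2)
    raise ConfigurationError(f"unknown noise model {model!r}")


def simulate_dual_echo(
    labels: VolumeGrid,
    tissues: dict[Tissue, TissueParams] | None = None,
    acq: AcquisitionParams | None = None,
    t2_overrides: dict[Tissue, float] | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    noise_model: str = "gaussian",
) -> tuple[VolumeGrid, VolumeGrid]:
    """Simulate the early/late echo pair (S1, S2) of the dual-echo sequence.

    With ``noise_sigma == 0`` the voxel-wise T2-map formula applied to
    (S1, S2) recovers each voxel's assigned T2 exactly.
    """
    acq = acq or AcquisitionParams()
    tissues = tissues or default_tissue_table()
    if noise_sigma < 0:
        raise ConfigurationError("noise_sigma must be >= 0")
    pd, _, t2 = _lookup_maps(labels, tissues, t2_overrides)
    s1 = pd * np.exp(-acq.te1 / t2)
    s2 = pd * np.exp(-acq.te2 / t2)
    ss = np.random.SeedSequence(seed)
    rng1, rng2 = (np.random.default_rng(c) for c in ss.spawn(2))
    s1 = _add_noise(s1, noise_sigma, rng1, noise_model)
    s2 = _add_noise(s2, noise_sigma, rng2, noise_model)
    return labels.with_data(s1), labels.with_data(s2)


def simulate_flair(
    labels: VolumeGrid,
    tissues: dict[Tissue, TissueParams] | None = None,
    acq: AcquisitionParams | None = None,
    intensity_overrides: dict[Tissue, float] | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    noise_model: str = "gaussian",
) -> VolumeGrid:
    """Simulate the T2-FLAIR volume.

    ``intensity_overrides`` multiplies the noiseless signal of a tissue
    class; the cohort sampler uses it to raise hippocampal FLAIR signal
    independently of the tissue's T2.
    """
    acq = acq or AcquisitionParams()
    tissues = tissues or default_tissue_table()
    if noise_sigma < 0:
        raise ConfigurationError("noise_sigma must be >= 0")
    pd, t1, t2 = _lookup_maps(labels, tissues, None)
    inv = np.abs(
        1.0 - 2.0 * np.exp(-acq.ti_flair / t1) + np.exp(-acq.tr_flair / t1)
    )
    signal = pd * inv * np.exp(-acq.te_flair / t2)
    if intensity_overrides:
        lab = labels.data
        for cls, factor in intensity_overrides.items():
            signal = np.where(lab == int(cls), signal * float(factor), signal)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    signal = _add_noise(signal, noise_sigma, rng, noise_model)
    return labels.with_data(signal)
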