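"""Tissue classes, MR tissue properties and acquisition parameters.

The phantom is built from a small set of tissue classes, each with a proton
density (arbitrary signal units), T1 and T2 (ms).  The acquisition
parameters default to the clinical protocol the pipeline models: a dual-echo
fast spin echo pair at TE 30/80 ms and a T2-FLAIR at TE 140 / TR 11000 /
TI 2250 ms, coronal-oblique, 0.94 x 0.94 x 5 mm voxels.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

from .errors import ConfigurationError


class Tissue(IntEnum):
    """Integer labels used in phantom label volumes."""

    BACKGROUND = 0
    WHITE_MATTER = 1
    GRAY_MATTER = 2
    CSF = 3
    HIPPOCAMPUS_LEFT = 4
    HIPPOCAMPUS_RIGHT = 5
    PONS_WM = 6
    FRONTAL_WM = 7
    CHOROID_PLEXUS = 8


#: tissue classes that are fluid (excluded from ROIs, nulled on FLAIR)
FLUID_CLASSES = (Tissue.CSF,)

#: classes used to build the ROI exclusion mask by default
EXCLUSION_CLASSES = (Tissue.CSF, Tissue.CHOROID_PLEXUS)


@dataclass(frozen=True)
class TissueParams:
    """MR properties of one tissue class.

    proton_density is in arbitrary signal units (>= 0, and 0 only for
    background); t1 and t2 are in ms and strictly positive.
    """

    tissue_class: Tissue
    proton_density: float
    t1: float
    t2: float

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.t2 <= 0:
            raise ConfigurationError(
                f"{self.tissue_class.name}: T1 and T2 must be positive"
            )
        if self.tissue_class == Tissue.BACKGROUND:
            if self.proton_density != 0:
                raise ConfigurationError("background proton density must be 0")
        elif self.proton_density <= 0:
            raise ConfigurationError(
                f"{self.tissue_class.name}: proton density must be positive"
            )


def default_tissue_table() -> dict[Tissue, TissueParams]:
    """Default tissue properties.

    T2 values are typical 3 T parenchymal values with CSF far above every
    parenchymal tissue.  CSF T1 is set to 3450 ms, the value nulled by the
    default FLAIR timing (TI 2250 / TR 11000 ms), so fluid attenuation holds
    exactly in the simulated FLAIR.  The pons reference region is given a
    slightly shorter T2 than frontal WM so the two reference pooling modes
    are distinguishable.
    """
    rows = [
        TissueParams(Tissue.BACKGROUND, 0.0, 1.0, 1.0),
        TissueParams(Tissue.WHITE_MATTER, 700.0, 850.0, 80.0),
        TissueParams(Tissue.GRAY_MATTER, 800.0, 1300.0, 95.0),
        TissueParams(Tissue.CSF, 1000.0, 3450.0, 2000.0),
        TissueParams(Tissue.HIPPOCAMPUS_LEFT, 780.0, 1200.0, 99.0),
        TissueParams(Tissue.HIPPOCAMPUS_RIGHT, 780.0, 1200.0, 99.0),
        TissueParams(Tissue.PONS_WM, 700.0, 850.0, 76.0),
        TissueParams(Tissue.FRONTAL_WM, 700.0, 850.0, 80.0),
        TissueParams(Tissue.CHOROID_PLEXUS, 900.0, 1500.0, 300.0),
    ]
    table = {p.tissue_class: p for p in rows}
    _check_csf_invariant(table)
    return table


def _check_csf_invariant(table: dict[Tissue, TissueParams]) -> None:
    """CSF T2 must exceed every parenchymal T2."""
    csf = table.get(Tissue.CSF)
    if csf is None:
        return
    for cls, p in table.items():
        if cls in (Tissue.CSF, Tissue.BACKGROUND):
            continue
        if p.t2 >= csf.t2:
            raise ConfigurationError(
                f"CSF T2 ({csf.t2}) must exceed {cls.name} T2 ({p.t2})"
            )


@dataclass(frozen=True)
class AcquisitionParams:
    """Sequence timing and geometry of the simulated protocol.

    Defaults follow the modelled clinical protocol (dual-echo FSE TE 30/80,
    FLAIR TE 140 / TR 11000 / TI 2250, voxel 0.94 x 0.94 x 5 mm).  The
    default matrix is a compact 64 x 64 x 12 grid that contains the whole
    phantom geometry; pass ``matrix=(256, 256), n_slices=32`` for the
    full-size protocol grid.
    """

    te1: float = 30.0
    te2: float = 80.0
    te_flair: float = 140.0
    tr_flair: float = 11000.0
    ti_flair: float = 2250.0
    voxel_size: tuple[float, float, float] = (0.94, 0.94, 5.0)
    n_slices: int = 12
    matrix: tuple[int, int] = (64, 64)

    def __post_init__(self) -> None:
        if not (self.te2 > self.te1 > 0):
            raise ConfigurationError(
                f"echo times must satisfy te2 > te1 > 0 (got {self.te1}, {self.te2})"
            )
        if self.te_flair <= 0 or self.tr_flair <= 0 or self.ti_flair <= 0:
            raise ConfigurationError("FLAIR timing parameters must be positive")
        if self.n_slices < 1 or any(m < 1 for m in self.matrix):
            raise ConfigurationError("matrix and n_slices must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ConfigurationError("voxel size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.matrix[0], self.matrix[1], self.n_slices)

    @property
    def pixel_area(self) -> float:
        return self.voxel_size[0] * self.voxel_size[1]
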