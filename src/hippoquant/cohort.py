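"""Synthetic cohort generation: ground truth, volumes and ROIs per subject.

The generator emulates the structure of a surgical temporal-lobe-epilepsy
study: healthy controls whose hippocampal T2 values scatter around a normal
mean, and patients with unilateral hippocampal sclerosis whose ipsilateral
T2 is drawn above the normal range, a fraction of whom also have an
abnormal contralateral hippocampus (bilateral disease).  Hippocampal nFSI
is drawn on a separate, partially overlapping scale so that only a fraction
of patients are detectable by FLAIR normalisation — the dissociation the
pipeline is built to quantify.

All randomness flows from the single ``CohortSpec.seed``, split into
deterministic substreams (allocation, parameter draws, geometry, noise), so
identical specs give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CohortValidationError
from .grid import VolumeGrid
from .phantom import build_label_volume, flair_signal, simulate_dual_echo, simulate_flair
from .roi import ROIPolicy, ROISet, auto_place_ovoid
from .errors import PlacementError
from .nfsi import DEFAULT_SCALE_FACTOR
from .tissue import AcquisitionParams, Tissue, TissueParams, default_tissue_table

__all__ = ["CohortSpec", "SubjectGroundTruth", "SubjectData", "SyntheticCohort",
           "sample_cohort", "draw_control_values"]


@dataclass(frozen=True)
class CohortSpec:
    """Cohort structure and the distributions the generator draws from.

    Control hippocampal T2 is Normal(mean, sd) truncated at +-3 SD with
    defaults mean 99 / SD 5 ms; the pooled control sample is then affinely
    standardized to those exact sample moments (moment-matched sampling),
    so the fitted mean + 2 SD normal limit is 109 ms by construction in
    every default cohort, not merely in expectation.  Sclerotic
    (ipsilateral) T2 is Uniform(109.4, 124.4) ms, strictly above that
    limit.  Control nFSI is drawn the same way (defaults 1550 / 66.5 n.u.,
    limit 1683 n.u.) with one planted control value at
    ``control_nfsi_outlier`` (1750 n.u.) before standardization, emulating
    the single healthy outlier such cohorts show; patient ipsilateral nFSI
    is drawn above the normal limit for a ``patient_nfsi_detectable_fraction``
    of patients and inside the control range otherwise.  Count-valued
    fractions (left-HS, bilateral, nFSI-detectable) are realised exactly:
    round(fraction * n_patients) subjects, chosen at random.
    """

    n_controls: int = 14
    n_patients: int = 27
    control_t2_mean: float = 99.0
    control_t2_sd: float = 5.0
    sclerotic_t2_low: float = 109.4
    sclerotic_t2_high: float = 124.4
    control_nfsi_mean: float = 1550.0
    control_nfsi_sd: float = 66.5
    control_nfsi_outlier: float | None = 1750.0
    moment_match_controls: bool = True
    patient_nfsi_detectable_fraction: float = 16.0 / 27.0
    patient_nfsi_high_range: tuple[float, float] = (1740.0, 1960.0)
    patient_nfsi_low_range: tuple[float, float] = (1480.0, 1640.0)
    bilateral_fraction: float = 6.0 / 27.0
    left_hs_fraction: float = 14.0 / 27.0
    nfsi_scale: float = DEFAULT_SCALE_FACTOR
    noise_sigma: float = 0.0
    noise_model: str = "gaussian"
    seed: int = 42

    def validate(self) -> None:
        if self.n_controls < 0 or self.n_patients < 0:
            raise CohortValidationError("cohort sizes must be non-negative")
        for name in ("patient_nfsi_detectable_fraction", "bilateral_fraction",
                     "left_hs_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CohortValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sigma < 0:
            raise CohortValidationError("noise_sigma must be >= 0")
        if self.sclerotic_t2_low >= self.sclerotic_t2_high:
            raise CohortValidationError("sclerotic T2 range must be non-empty")
        limit = self.control_t2_mean + 2 * self.control_t2_sd
        if self.sclerotic_t2_low <= limit:
            raise CohortValidationError(
                f"sclerotic_t2_low ({self.sclerotic_t2_low}) must exceed the "
                f"control mean + 2 SD ({limit}) for T2 separability"
            )


@dataclass
class SubjectGroundTruth:
    """Assigned (noise-free) per-subject parameters."""

    subject_id: str
    group: str  # "control" | "patient"
    hs_side: str  # "none" | "left" | "right"
    true_t2_left: float
    true_t2_right: float
    true_nfsi_left: float
    true_nfsi_right: float
    bilateral: bool = False

    def __post_init__(self) -> None:
        if self.group == "control" and self.hs_side != "none":
            raise CohortValidationError("controls must have hs_side == 'none'")
        if self.group == "patient" and self.hs_side not in ("left", "right"):
            raise CohortValidationError("patients need a designated hs_side")


@dataclass
class SubjectData:
    """One simulated subject: ground truth, volumes and auto-placed ROIs."""

    ground_truth: SubjectGroundTruth
    labels: VolumeGrid
    s1: VolumeGrid
    s2: VolumeGrid
    flair: VolumeGrid
    rois: dict[str, ROISet | None]
    placement_failures: list[str] = field(default_factory=list)

    @property
    def subject_id(self) -> str:
        return self.ground_truth.subject_id


@dataclass
class SyntheticCohort:
    spec: CohortSpec
    acq: AcquisitionParams
    subjects: list[SubjectData]

    @property
    def ground_truth(self) -> list[SubjectGroundTruth]:
        return [s.ground_truth for s in self.subjects]

    def manifest(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            gt = s.ground_truth
            rows.append(
                {
                    "subject_id": gt.subject_id,
                    "group": gt.group,
                    "hs_side": gt.hs_side,
                    "bilateral": gt.bilateral,
                    "true_t2_left": gt.true_t2_left,
                    "true_t2_right": gt.true_t2_right,
                    "true_nfsi_left": gt.true_nfsi_left,
                    "true_nfsi_right": gt.true_nfsi_right,
                }
            )
        return pd.DataFrame(rows)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int, n_sigma: float = 3.0
) -> np.ndarray:
    """Normal draws rejected outside mean +- n_sigma * sd."""
    if sd == 0:
        return np.full(n, mean)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=n - filled)
        keep = draw[np.abs(draw - mean) <= n_sigma * sd]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def standardize_sample(values: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Affinely rescale a sample to exact (mean, sample-SD) moments.

    Order and all sample z-scores are preserved; only the two pooled
    moments are pinned.  Degenerate samples (size < 2 or zero spread) are
    shifted to the target mean.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        return np.full_like(values, mean)
    raw_sd = values.std(ddof=1)
    if raw_sd == 0:
        return values - values.mean() + mean
    return (values - values.mean()) / raw_sd * sd + mean


def draw_control_values(
    rng: np.random.Generator,
    spec: CohortSpec,
    n_hippocampi: int,
    modality: str = "t2",
    moment_match: bool = False,
) -> np.ndarray:
    """Draw control hippocampal values from the generator's distribution.

    Used for cheap distribution-level replicates (e.g. bootstrap
    calibration of the normal limit) without simulating images.  With
    ``moment_match`` the sample is standardized to the exact control
    moments, as :func:`sample_cohort` does for the control cohort.
    """
    if modality == "t2":
        mean, sd = spec.control_t2_mean, spec.control_t2_sd
    elif modality == "nfsi":
        mean, sd = spec.control_nfsi_mean, spec.control_nfsi_sd
    else:
        raise CohortValidationError(f"unknown modality {modality!r}")
    draws = _truncated_normal(rng, mean, sd, n_hippocampi)
    if moment_match:
        draws = standardize_sample(draws, mean, sd)
    return draws


def _exact_count(fraction: float, n: int) -> int:
    return int(round(fraction * n))


def sample_ground_truth(spec: CohortSpec = CohortSpec()) -> list[SubjectGroundTruth]:
    """Sample only the per-subject ground-truth parameters of a cohort.

    Identical to the ground truth :func:`sample_cohort` would assign for the
    same spec, without simulating any volumes — useful for large-n
    distributional checks.
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    alloc_ss, draw_ss, _, _ = root.spawn(4)
    return _draw_ground_truth(
        spec, np.random.default_rng(alloc_ss), np.random.default_rng(draw_ss)
    )


def _draw_ground_truth(
    spec: CohortSpec,
    alloc_rng: np.random.Generator,
    draw_rng: np.random.Generator,
) -> list[SubjectGroundTruth]:
    # ---- exact allocation of patient strata and the control outlier
    n_pat = spec.n_patients
    sides = np.array(["right"] * n_pat, dtype=object)
    n_left = _exact_count(spec.left_hs_fraction, n_pat)
    left_idx = alloc_rng.choice(n_pat, size=n_left, replace=False) if n_pat else []
    sides[list(left_idx)] = "left"
    n_bilat = _exact_count(spec.bilateral_fraction, n_pat)
    bilat_idx = set(
        alloc_rng.choice(n_pat, size=n_bilat, replace=False).tolist() if n_pat else []
    )
    n_det = _exact_count(spec.patient_nfsi_detectable_fraction, n_pat)
    det_idx = set(
        alloc_rng.choice(n_pat, size=n_det, replace=False).tolist() if n_pat else []
    )
    outlier_subject = (
        int(alloc_rng.integers(spec.n_controls)) if spec.n_controls else -1
    )
    outlier_side = str(alloc_rng.choice(["left", "right"]))

    # ---- parameter draws; control samples are moment-matched pooled
    truths: list[SubjectGroundTruth] = []
    n_ctl = spec.n_controls
    ctl_t2 = np.empty((n_ctl, 2))
    ctl_nf = np.empty((n_ctl, 2))
    for i in range(n_ctl):
        ctl_t2[i] = draw_control_values(draw_rng, spec, 2, "t2")
        ctl_nf[i] = draw_control_values(draw_rng, spec, 2, "nfsi")
    if 0 <= outlier_subject < n_ctl and spec.control_nfsi_outlier is not None:
        ctl_nf[outlier_subject, 0 if outlier_side == "left" else 1] = (
            spec.control_nfsi_outlier
        )
    if spec.moment_match_controls and n_ctl:
        ctl_t2 = standardize_sample(
            ctl_t2.ravel(), spec.control_t2_mean, spec.control_t2_sd
        ).reshape(n_ctl, 2)
        ctl_nf = standardize_sample(
            ctl_nf.ravel(), spec.control_nfsi_mean, spec.control_nfsi_sd
        ).reshape(n_ctl, 2)
    for i in range(n_ctl):
        truths.append(
            SubjectGroundTruth(
                subject_id=f"control-{i + 1:02d}",
                group="control",
                hs_side="none",
                true_t2_left=float(ctl_t2[i, 0]),
                true_t2_right=float(ctl_t2[i, 1]),
                true_nfsi_left=float(ctl_nf[i, 0]),
                true_nfsi_right=float(ctl_nf[i, 1]),
            )
        )
    for i in range(n_pat):
        side = sides[i]
        ipsi_t2 = float(draw_rng.uniform(spec.sclerotic_t2_low, spec.sclerotic_t2_high))
        if i in bilat_idx:
            contra_t2 = float(
                draw_rng.uniform(spec.sclerotic_t2_low, spec.sclerotic_t2_high)
            )
        else:
            contra_t2 = float(draw_control_values(draw_rng, spec, 1, "t2")[0])
        if i in det_idx:
            ipsi_nf = float(draw_rng.uniform(*spec.patient_nfsi_high_range))
        else:
            ipsi_nf = float(draw_rng.uniform(*spec.patient_nfsi_low_range))
        contra_nf = float(draw_control_values(draw_rng, spec, 1, "nfsi")[0])
        t2_l, t2_r = (ipsi_t2, contra_t2) if side == "left" else (contra_t2, ipsi_t2)
        nf_l, nf_r = (ipsi_nf, contra_nf) if side == "left" else (contra_nf, ipsi_nf)
        truths.append(
            SubjectGroundTruth(
                subject_id=f"patient-{i + 1:02d}",
                group="patient",
                hs_side=str(side),
                true_t2_left=t2_l,
                true_t2_right=t2_r,
                true_nfsi_left=nf_l,
                true_nfsi_right=nf_r,
                bilateral=i in bilat_idx,
            )
        )
    return truths


def sample_cohort(
    spec: CohortSpec = CohortSpec(),
    acq: AcquisitionParams | None = None,
    tissues: dict[Tissue, TissueParams] | None = None,
    roi_policy: ROIPolicy = ROIPolicy(),
) -> SyntheticCohort:
    """Sample a full synthetic cohort (ground truth + volumes + ROIs).

    The hippocampal FLAIR intensity override for each side is solved from
    the closed-form signal equations so that, on noiseless volumes, the
    measured nFSI equals the drawn ground-truth value exactly.
    """
    spec.validate()
    acq = acq or AcquisitionParams()
    tissues = tissues or default_tissue_table()

    root = np.random.SeedSequence(spec.seed)
    alloc_ss, draw_ss, geo_ss, noise_ss = root.spawn(4)
    truths = _draw_ground_truth(
        spec, np.random.default_rng(alloc_ss), np.random.default_rng(draw_ss)
    )
    geo_rng = np.random.default_rng(geo_ss)
    noise_rng = np.random.default_rng(noise_ss)

    # ---- simulate volumes and place ROIs
    hippo_l = tissues[Tissue.HIPPOCAMPUS_LEFT]
    hippo_r = tissues[Tissue.HIPPOCAMPUS_RIGHT]
    s_pons = flair_signal(
        tissues[Tissue.PONS_WM].proton_density, tissues[Tissue.PONS_WM].t1,
        tissues[Tissue.PONS_WM].t2, acq,
    )
    s_frontal = flair_signal(
        tissues[Tissue.FRONTAL_WM].proton_density, tissues[Tissue.FRONTAL_WM].t1,
        tissues[Tissue.FRONTAL_WM].t2, acq,
    )
    base_l = flair_signal(hippo_l.proton_density, hippo_l.t1, hippo_l.t2, acq)
    base_r = flair_signal(hippo_r.proton_density, hippo_r.t1, hippo_r.t2, acq)

    subjects: list[SubjectData] = []
    for gt in truths:
        geometry_seed = int(geo_rng.integers(2**31))
        noise_seed = int(noise_rng.integers(2**31))
        labels = build_label_volume(acq, geometry_seed)
        lab = labels.data
        n_p = int((lab == Tissue.PONS_WM).sum())
        n_f = int((lab == Tissue.FRONTAL_WM).sum())
        ref = (n_p * s_pons + n_f * s_frontal) / (n_p + n_f)

        t2_overrides = {
            Tissue.HIPPOCAMPUS_LEFT: gt.true_t2_left,
            Tissue.HIPPOCAMPUS_RIGHT: gt.true_t2_right,
        }
        s1, s2 = simulate_dual_echo(
            labels, tissues, acq, t2_overrides, spec.noise_sigma, noise_seed,
            noise_model=spec.noise_model,
        )
        overrides = {
            Tissue.HIPPOCAMPUS_LEFT: gt.true_nfsi_left * ref / (spec.nfsi_scale * base_l),
            Tissue.HIPPOCAMPUS_RIGHT: gt.true_nfsi_right * ref / (spec.nfsi_scale * base_r),
        }
        flair = simulate_flair(
            labels, tissues, acq, overrides, spec.noise_sigma, noise_seed + 1,
            noise_model=spec.noise_model,
        )

        rois: dict[str, ROISet | None] = {}
        failures: list[str] = []
        for side in ("left", "right"):
            try:
                rois[side] = auto_place_ovoid(
                    labels, side, exclusion=None, policy=roi_policy,
                    subject_id=gt.subject_id,
                )
            except PlacementError as exc:
                rois[side] = None
                failures.append(str(exc))
        subjects.append(
            SubjectData(
                ground_truth=gt, labels=labels, s1=s1, s2=s2, flair=flair,
                rois=rois, placement_failures=failures,
            )
        )
    return SyntheticCohort(spec=spec, acq=acq, subjects=subjects)
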