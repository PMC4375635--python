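"""End-to-end pipeline: simulate -> T2 map -> nFSI -> ROI stats -> classify.

`PipelineConfig` gathers every stage's parameters, round-trips losslessly
through YAML, and `run_pipeline` orchestrates the stages, returning (and
optionally writing) a summary whose every number comes from a stage
artifact.  Runs are deterministic under a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortSpec, SubjectData, SyntheticCohort, sample_cohort
from .nfsi import DEFAULT_SCALE_FACTOR, normalise_flair, reference_mean
from .normative import (
    DiagnosticPerformance,
    NormativeLimits,
    bilateral_rate,
    evaluate,
    fit_limits,
    lateralise,
)
from .roi import HippocampusMeasure, ROIPolicy, measure_hippocampus
from .t2map import compute_t2_map
from .tissue import AcquisitionParams, Tissue

log = logging.getLogger("hippoquant")

__all__ = ["NFSIConfig", "PipelineConfig", "RunReport", "run_pipeline",
           "measure_subject", "measure_cohort"]


@dataclass(frozen=True)
class NFSIConfig:
    scale_factor: float = DEFAULT_SCALE_FACTOR
    pooling: str = "union"  # or "regional"


@dataclass(frozen=True)
class PipelineConfig:
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    roi_policy: ROIPolicy = field(default_factory=ROIPolicy)
    nfsi: NFSIConfig = field(default_factory=NFSIConfig)
    seed: int | None = None  # overrides cohort.seed when set

    def effective_cohort(self) -> CohortSpec:
        spec = self.cohort
        if self.seed is not None:
            spec = replace(spec, seed=self.seed)
        if spec.nfsi_scale != self.nfsi.scale_factor:
            spec = replace(spec, nfsi_scale=self.nfsi.scale_factor)
        return spec

    # ------------------------------------------------------------- YAML I/O
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def build(klass, sub):
            if sub is None:
                return klass()
            fields = {f.name for f in dataclasses.fields(klass)}
            kwargs = {k: v for k, v in sub.items() if k in fields}
            for key in ("voxel_size", "matrix", "patient_nfsi_high_range",
                        "patient_nfsi_low_range"):
                if key in kwargs and kwargs[key] is not None:
                    kwargs[key] = tuple(kwargs[key])
            return klass(**kwargs)

        return cls(
            acquisition=build(AcquisitionParams, d.get("acquisition")),
            cohort=build(CohortSpec, d.get("cohort")),
            roi_policy=build(ROIPolicy, d.get("roi_policy")),
            nfsi=build(NFSIConfig, d.get("nfsi")),
            seed=d.get("seed"),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


# ------------------------------------------------------------- measurement
def measure_subject(
    subject: SubjectData,
    acq: AcquisitionParams,
    nfsi_cfg: NFSIConfig = NFSIConfig(),
    roi_policy: ROIPolicy = ROIPolicy(),
) -> list[HippocampusMeasure]:
    """Both-modality, both-side ROI measures for one subject."""
    t2 = compute_t2_map(subject.s1, subject.s2, acq)
    lab = subject.labels.data
    ref = reference_mean(
        subject.flair, lab == Tissue.PONS_WM, lab == Tissue.FRONTAL_WM,
        pooling=nfsi_cfg.pooling,
    )
    nf = normalise_flair(subject.flair, ref, nfsi_cfg.scale_factor)
    measures: list[HippocampusMeasure] = []
    for side in ("left", "right"):
        roi = subject.rois.get(side)
        if roi is None:
            continue
        measures.append(
            measure_hippocampus(t2, roi, "t2", roi_policy.max_invalid_fraction)
        )
        measures.append(measure_hippocampus(nf, roi, "nfsi"))
    return measures


def measure_cohort(
    cohort: SyntheticCohort,
    nfsi_cfg: NFSIConfig = NFSIConfig(),
    roi_policy: ROIPolicy = ROIPolicy(),
) -> pd.DataFrame:
    """Tidy table of all hippocampal measures in a cohort."""
    rows = []
    for subject in cohort.subjects:
        for m in measure_subject(subject, cohort.acq, nfsi_cfg, roi_policy):
            rows.append(
                {
                    "subject_id": m.subject_id,
                    "group": subject.ground_truth.group,
                    "side": m.side,
                    "modality": m.modality,
                    "value": m.value,
                    "n_slices": m.n_slices,
                }
            )
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ report
@dataclass
class RunReport:
    config: PipelineConfig
    manifest: pd.DataFrame
    measures: list[HippocampusMeasure]
    limits: dict[str, NormativeLimits]
    classifications: dict[str, list]
    performance: dict[str, dict[str, DiagnosticPerformance]]
    bilateral: dict[str, object]
    notes: list[str]

    def summary(self) -> dict:
        out: dict = {"limits": {}, "performance": {}, "bilateral_rate": {}, "notes": self.notes}
        for mod, lim in self.limits.items():
            out["limits"][mod] = {
                "control_mean": lim.control_mean,
                "control_sd": lim.control_sd,
                "upper_limit": lim.upper_limit,
                "n_control_hippocampi": lim.n_control_hippocampi,
            }
        for mod, units in self.performance.items():
            out["performance"][mod] = {u: p.as_dict() for u, p in units.items()}
        for mod, br in self.bilateral.items():
            out["bilateral_rate"][mod] = {
                "n_contralateral_abnormal": br.n_contralateral_abnormal,
                "n_patients": br.n_patients,
                "percent": round(br.percent, 1),
                "percent_rounded": br.percent_rounded,
            }
        return out


def run_pipeline(
    config: PipelineConfig = PipelineConfig(),
    out_dir: str | Path | None = None,
    write_volumes: bool = False,
) -> RunReport:
    """Run the full pipeline on a freshly simulated cohort.

    With ``out_dir`` set, writes the cohort manifest, measures and
    classification CSVs, limits and performance JSON, the effective config,
    a T2-vs-nFSI scatter figure, and (optionally) every simulated volume.
    """
    spec = config.effective_cohort()
    cohort = sample_cohort(spec, config.acquisition, roi_policy=config.roi_policy)
    notes = [
        f"placement-failure: {msg}"
        for s in cohort.subjects
        for msg in s.placement_failures
    ]

    measures: list[HippocampusMeasure] = []
    by_subject: dict[str, dict[str, dict[str, HippocampusMeasure]]] = {}
    for subject in cohort.subjects:
        for m in measure_subject(subject, cohort.acq, config.nfsi, config.roi_policy):
            measures.append(m)
            by_subject.setdefault(m.subject_id, {}).setdefault(m.modality, {})[m.side] = m

    control_measures = [
        m for m in measures
        if m.subject_id in {s.subject_id for s in cohort.subjects
                            if s.ground_truth.group == "control"}
    ]

    limits: dict[str, NormativeLimits] = {}
    classifications: dict[str, list] = {}
    performance: dict[str, dict[str, DiagnosticPerformance]] = {}
    bilateral: dict[str, object] = {}
    truth = cohort.ground_truth
    for modality in ("t2", "nfsi"):
        lim = fit_limits(control_measures, modality)
        limits[modality] = lim
        cls = []
        for sid, mods in by_subject.items():
            sides = mods.get(modality, {})
            if "left" in sides and "right" in sides:
                cls.append(lateralise(sides["left"], sides["right"], lim))
        classifications[modality] = cls
        if spec.n_patients > 0:
            performance[modality] = {
                unit: evaluate(cls, truth, modality, unit)
                for unit in ("hippocampus", "subject")
            }
            bilateral[modality] = bilateral_rate(cls, truth)
        else:
            notes.append(f"no patients: {modality} performance not computed")

    report = RunReport(
        config=config, manifest=cohort.manifest(), measures=measures,
        limits=limits, classifications=classifications,
        performance=performance, bilateral=bilateral, notes=notes,
    )
    if out_dir is not None:
        _write_outputs(report, cohort, Path(out_dir), write_volumes)
    return report


# ------------------------------------------------------------------ writers
def _write_outputs(
    report: RunReport, cohort: SyntheticCohort, out: Path, write_volumes: bool
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    report.config.to_yaml(out / "config.yaml")
    report.manifest.to_csv(out / "manifest.csv", index=False)
    pd.DataFrame(
        [
            {"subject_id": m.subject_id, "side": m.side, "modality": m.modality,
             "value": m.value, "n_slices": m.n_slices}
            for m in report.measures
        ]
    ).to_csv(out / "measures.csv", index=False)
    rows = []
    for mod, cls in report.classifications.items():
        for c in cls:
            rows.append(
                {"subject_id": c.subject_id, "modality": mod,
                 "left_abnormal": c.left_abnormal, "right_abnormal": c.right_abnormal,
                 "call": c.call}
            )
    pd.DataFrame(rows).to_csv(out / "classifications.csv", index=False)
    (out / "summary.json").write_text(json.dumps(report.summary(), indent=2))
    try:
        _write_scatter(report, out / "scatter.svg")
    except Exception as exc:  # plotting must never sink a run
        log.warning("scatter plot failed: %s", exc)
    if write_volumes:
        vol_dir = out / "volumes"
        vol_dir.mkdir(exist_ok=True)
        for s in cohort.subjects:
            sid = s.subject_id
            s.labels.save(vol_dir / f"{sid}_labels.nii.gz")
            s.s1.save(vol_dir / f"{sid}_echo1.nii.gz")
            s.s2.save(vol_dir / f"{sid}_echo2.nii.gz")
            s.flair.save(vol_dir / f"{sid}_flair.nii.gz")
            roi_vol = np.zeros(s.labels.shape, dtype=np.int16)
            for label, side in ((1, "left"), (2, "right")):
                roi = s.rois.get(side)
                if roi is not None:
                    roi_vol += roi.to_label_volume(s.labels, label).data
            s.labels.with_data(roi_vol).save(vol_dir / f"{sid}_roi.nii.gz")


def _write_scatter(report: RunReport, path: Path) -> None:
    """T2 (x) vs nFSI (y) scatter with the mean+2SD threshold lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = dict(zip(report.manifest["subject_id"], report.manifest["group"]))
    points: dict[str, dict[str, dict[str, float]]] = {}
    for m in report.measures:
        points.setdefault(m.subject_id, {}).setdefault(m.side, {})[m.modality] = m.value
    fig, ax = plt.subplots(figsize=(6, 5))
    for group, color, marker in (("control", "tab:blue", "o"), ("patient", "tab:red", "^")):
        xs, ys = [], []
        for sid, sides in points.items():
            if groups.get(sid) != group:
                continue
            for vals in sides.values():
                if "t2" in vals and "nfsi" in vals:
                    xs.append(vals["t2"])
                    ys.append(vals["nfsi"])
        ax.scatter(xs, ys, c=color, marker=marker, s=18, label=group, alpha=0.75)
    if "t2" in report.limits:
        ax.axvline(report.limits["t2"].upper_limit, ls="--", c="red", lw=1)
    if "nfsi" in report.limits:
        ax.axhline(report.limits["nfsi"].upper_limit, ls="--", c="red", lw=1)
    ax.set_xlabel("hippocampal T2 (ms)")
    ax.set_ylabel("hippocampal nFSI (n.u.)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
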