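# hippoquant

Quantitative hippocampal MRI for epilepsy imaging: a pipeline comparing
**dual-echo T2 relaxometry** with **normalised FLAIR signal intensity
(nFSI)** for detecting hippocampal sclerosis (HS), together with a
synthetic phantom/cohort generator that supplies ground truth for every
stage.

HS — neuronal loss and gliosis of the hippocampus, the commonest lesion in
drug-resistant temporal lobe epilepsy — raises the tissue's T2 relaxation
time and its FLAIR signal.  Quantifying that elevation objectively matters
both for detecting subtle disease and for confirming that the contralateral
hippocampus is normal before resective surgery.  This package implements
and compares the two candidate measurements:

* **T2 mapping** from a dual-echo fast spin-echo pair:
  `T2 = (TE2 − TE1) / ln(S1/S2)` per voxel (TE1 = 30 ms, TE2 = 80 ms);
* **nFSI**: FLAIR intensity divided by the mean signal of white-matter
  reference regions (pons + anterior frontal lobes) and expressed in
  normalised units.

Both are reduced to one value per hippocampus by the same ROI protocol
(ovoid ROIs ≥ 18 mm² on 4–5 consecutive coronal slices, avoiding CSF;
mean of slice means), classified against control-derived normal limits
(mean + 2 SD, strict exceedance), lateralised, and scored as
sensitivity/specificity against ground truth.

## Worked example

```python
from hippoquant import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig())   # default cohort: 14 controls, 27 patients
s = report.summary()
print("T2   limit %.1f ms   sens %.1f%%  spec %.1f%%" % (
    s["limits"]["t2"]["upper_limit"],
    s["performance"]["t2"]["hippocampus"]["sensitivity"],
    s["performance"]["t2"]["subject"]["specificity"]))
print("nFSI limit %.0f n.u. sens %.1f%%  spec %.1f%%" % (
    s["limits"]["nfsi"]["upper_limit"],
    s["performance"]["nfsi"]["hippocampus"]["sensitivity"],
    s["performance"]["nfsi"]["subject"]["specificity"]))
print("contralateral T2 abnormal: %d/%d (%d%%)" % (
    s["bilateral_rate"]["t2"]["n_contralateral_abnormal"],
    s["bilateral_rate"]["t2"]["n_patients"],
    s["bilateral_rate"]["t2"]["percent_rounded"]))
```

prints

```
T2   limit 109.0 ms   sens 100.0%  spec 100.0%
nFSI limit 1683 n.u. sens 59.3%  spec 92.9%
contralateral T2 abnormal: 6/27 (22%)
```

Reading: the control-derived T2 normal limit is 109 ms and every sclerotic
hippocampus (T2 range ≈ 109.4–124.4 ms) exceeds it while no control does —
perfect separation.  The nFSI limit is 1683 normalised units, but 11 of the
27 sclerotic hippocampi fall below it and one control exceeds it, so nFSI
reaches only ~59% sensitivity at ~93% specificity: T2 mapping outperforms
normalised FLAIR.  Six patients (22%) also have an abnormal contralateral
hippocampus, consistent with bilateral disease.

A command-line interface wraps each stage:

```bash
hippoquant run-all --out results/run          # full pipeline + scatter plot
hippoquant simulate --out results/sim         # write NIfTI volumes + manifest
hippoquant t2map --echo1 s1.nii.gz --echo2 s2.nii.gz --te1 30 --te2 80 --out t2.nii.gz
hippoquant nfsi --flair flair.nii.gz --pons pons.nii.gz --frontal frontal.nii.gz --out nfsi.nii.gz
hippoquant roi-stats --volume t2.nii.gz --roi roi.nii.gz --modality t2 --out measures.csv
hippoquant classify --measures measures.csv --manifest manifest.csv --out report/
```

See `docs/methods.md` for the signal models, the ROI placement algorithm,
the generator's calibration and its limitations.

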