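# Methods

`hippoquant` implements a quantitative-MRI comparison that matters in the
presurgical work-up of drug-resistant temporal lobe epilepsy: can normalised
FLAIR signal intensity (nFSI), computed from a routinely acquired clinical
sequence, replace dual-echo T2 relaxometry for detecting hippocampal
sclerosis (HS)?  The package provides the full analysis pipeline — T2-map
computation, FLAIR normalisation, hippocampal ROI quantification, normative
mean + 2 SD classification, and sensitivity/specificity evaluation — plus a
synthetic phantom/cohort generator that provides ground truth for every
stage.

## Signal models

**Dual-echo T2 estimation.**  A fast spin-echo pair acquired at two echo
times (TE1 = 30 ms, TE2 = 80 ms) gives, under monoexponential transverse
decay `S(TE) = PD·exp(−TE/T2)`, the closed-form voxel-wise estimate

    T2 = (TE2 − TE1) / ln(S1 / S2).

The estimate is valid only where `S1 > S2 > 0`.  Voxels violating that
(background, noise inversions, `S1 = S2`) are flagged invalid and carried
as NaN plus an explicit validity mask, never clamped: the downstream ROI
measurement refuses ROIs whose invalid-voxel fraction exceeds a policy
threshold (default 0%), mirroring the practice of placing ROIs only in
artefact-free tissue.  Note the estimate is a strictly *decreasing*
function of `S1/S2`: a steeper drop between the echoes means faster decay
and a shorter T2.  No spatial smoothing is applied; computation is in
double precision, with NIfTI output stored as 32-bit float.

**FLAIR.**  The inversion-recovery sequence (TE 140 ms, TR 11 000 ms,
TI 2250 ms) is simulated as

    S = PD · |1 − 2·exp(−TI/T1) + exp(−TR/T1)| · exp(−TE/T2).

FLAIR is not quantitative, so hippocampal FLAIR measures are expressed as
nFSI: each voxel is divided by the mean raw FLAIR intensity over
white-matter reference regions (pons plus anterior frontal lobes, pooled at
the voxel level by default; a regional-mean mode is available) and
multiplied by a conventional scale factor (default 1500 n.u. assigned to
the reference mean).  The transform is a plain linear ratio — no histogram
matching, z-scoring or bias-field correction — which makes nFSI invariant
to any global scanner gain, the one property the normalisation exists to
provide.  Because the normalisation arithmetic of the original nFSI
literature is conventional rather than physical, absolute normalised units
are calibration-dependent; the package's scale is chosen so the control
normal limit falls near 1683 n.u.

## ROI protocol

Each hippocampus is reduced to one number per modality following the
clinical protocol: ovoid ROIs on 4–5 consecutive coronal-oblique slices
(5 mm thick, 0.94 × 0.94 mm in-plane), each at least 18 mm², as large as
can be accommodated inside the hippocampus while avoiding CSF and
CSF partial-volume voxels; per-slice voxel means are averaged across slices
with *equal slice weights* (mean of slice means, not the pooled voxel
mean).  Placement is automated: per slice the pipeline takes the largest
inscribed ellipse of the hippocampus cross-section after removing every
voxel within one voxel (3 × 3 structuring element) of the exclusion mask
(CSF + choroid plexus).  The search is deterministic and exact for a fixed
candidate set: centers come from the distance-transform peak and its
8-neighbourhood plus the region centroid, orientations/axis ratios from
the region's second moments plus a circle, and for each candidate the
maximal semi-axis is the smallest elliptical norm over non-allowed pixels.
The 5-slice window (falling back to 4) with the largest total area wins;
ties go to the more anterior start.  Per-slice independent placement is
assumed, with "ovoid" enforced as an ellipse-shaped pixel mask.

## Normative classification

Normal limits are fitted on all control hippocampi pooled (left + right,
n = 28 under defaults) as mean + 2 sample SD (n − 1 denominator).  A
hippocampus is abnormal when its measure *strictly* exceeds the limit — a
value exactly at the limit is normal, which is what keeps a borderline
control (e.g. 108.8 ms under a 109 ms limit) on the normal side.  Subjects
are lateralised per side (left / right / bilateral / normal; no
winner-takes-all by magnitude).  Diagnostic accuracy is reported for two
units of analysis: hippocampus (TP/FN over patients' ipsilateral
hippocampi, TN/FP over the 28 control hippocampi) and subject (a control
is a false positive when either side is flagged).  The headline operating
point pairs hippocampus-unit sensitivity with subject-unit specificity,
the combination under which a cohort with one control outlier yields
13/14 ≈ 93% specificity; both units are always emitted.  The
contralateral-abnormality (bilateral-disease) rate is the percentage of
patients whose contralateral hippocampus is flagged.

## Synthetic phantom and cohort generator

The phantom is an abstract head-like layout, not anatomy: a white-matter
brain ellipse with a cortical gray-matter shell, two ellipsoidal hippocampi
elongated along the slice axis (spanning ≥ 5 slices) each wrapped in a
one-voxel CSF rim so the ROI stage has fluid to avoid, a pontine and two
anterior-frontal reference cylinders, and two choroid-plexus voxels at the
posterior hippocampal margin.  Per-subject geometry (positions,
orientation) is jittered under a dedicated seed; the label inventory is
constant.  The default grid is 64 × 64 × 12 at the protocol voxel size —
large enough to contain every structure and the full ROI protocol while
keeping multi-hundred-cohort calibration runs cheap; the full 256 × 256 ×
32 protocol grid is available by configuration.

Tissue parameters (PD, T1, T2) are typical 3 T values.  T1 values only
need to make FLAIR contrast qualitatively right; CSF T1 is set to 3450 ms,
the value the default TI/TR pair nulls exactly, so simulated CSF is < 5%
of white-matter FLAIR signal as in a properly timed acquisition.

The default cohort reproduces the structure of a surgical HS study: 14
healthy controls and 27 patients (14 left, 13 right — realised exactly by
deterministic allocation of `round(fraction · n)` subjects to
randomly chosen indices, rather than per-subject coin flips).  Draws:

* **Control T2**: Normal(99, 5) ms truncated at ±3 SD, then the pooled
  28-hippocampus sample is affinely standardized to those exact sample
  moments (*moment-matched sampling*).  The fitted mean + 2 SD limit is
  therefore 109 ms by construction in every default cohort, reproducing
  the reported normal limit exactly rather than merely in expectation, and
  guaranteeing separability from the sclerotic range — which makes the
  pipeline's perfect T2 operating point attributable to the generative
  model rather than to control sampling luck.  Standardization is affine,
  so draw shapes, ordering and every sample z-score are untouched.
* **Sclerotic (ipsilateral) T2**: Uniform(109.4, 124.4) ms, strictly above
  the 109 ms limit.  A bilateral fraction (6/27) of patients draws the
  contralateral T2 from the same support; the rest draw it from the
  control distribution.
* **Control nFSI**: same moment-matched scheme with mean 1550 and SD 66.5
  n.u. (limit 1683 n.u.), after planting a single control hippocampus at
  1750 n.u. — the one healthy outlier such cohorts show, which is what
  produces the 13/14 subject-unit specificity.
* **Patient ipsilateral nFSI**: a detectable fraction (16/27, exact
  allocation) draws Uniform(1740, 1960) n.u., the rest Uniform(1480, 1640)
  n.u.; the non-detectable range deliberately overlaps the control
  distribution, encoding the core empirical finding that hippocampal nFSI
  distributions of patients and controls overlap while T2 separates.

Hippocampal FLAIR elevation is injected through a per-class multiplicative
intensity override solved from the closed-form signal equations (at the
tissue-default T2), so that measured nFSI equals the drawn ground-truth
value exactly on noiseless volumes and T2/nFSI abnormality are
independently controllable — matching the partially dissociated scatter of
real cohorts.

**Noise.**  The default cohort is noiseless: between-subject variability is
carried entirely by the parameter draws, which keeps round-trip identities
exact (measured T2 equals assigned T2 to machine precision).  Additive
Gaussian magnitude noise and a Rician mode (magnitude of complex Gaussian
noise) are available; at ROI-mean SNR the two are indistinguishable, which
is why Gaussian is the default.

**Determinism.**  A single cohort seed is split into per-purpose
substreams (allocation, parameter draws, geometry, noise) via
`numpy.random.SeedSequence.spawn`, so identical specs give bit-identical
cohorts and any stage is reproducible in isolation.

## What the synthetic data do and do not show

The generator emulates the *statistical* structure of the study —
distributional locations, overlap, counts, and the acquisition's timing
and voxel geometry — not real anatomy, bias fields, motion, partial-volume
mixtures at tissue interfaces, or rater variability of manual segmentation
(ROI placement here is algorithmic).  Passing tests therefore validate the
pipeline's contracts (exact formula inversion, normalisation invariances,
equal-slice-weight averaging, threshold logic, confusion-matrix
arithmetic) and the generator's calibration; they do not certify
diagnostic performance on real MRI.

## Numerical choices and degenerate inputs

* T2-map validity is a mask, not a clamp; ROIs containing invalid voxels
  fail measurement loudly with subject and side named.
* `mean + 2·SD` uses the sample SD (n − 1): the standard convention for
  normative limits; at least 2 control hippocampi are required.
* Values exactly at a normal limit are classified normal (strict `>`).
* Moment standardization degenerates gracefully: samples of size < 2 or
  zero spread are shifted to the target mean.
* Ellipse-containment uses pixel centers; the array border counts as
  forbidden, so ROIs can never leave the grid.
* ROI window ties are broken by larger total area, then more anterior
  start; empty exclusion masks behave identically to omitting the mask.
* Cohorts with `n_patients = 0` fit limits but skip performance records
  with an explicit note; ROI placement failures are reported per subject
  and never abort a cohort.

## Problem sizes

Default analyses use the 64 × 64 × 12 grid, a 41-subject study cohort, and
200 control-only replicate cohorts (2 800 simulated subjects) for the
calibration averages; these sizes make the full acceptance computation a
few minutes on one CPU while leaving all statistical conclusions unchanged
at larger grids, which only refine the (already machine-precision)
noiseless measurements.

## Known limitations

* The nFSI scale is conventional: absolute normalised units depend on the
  chosen scale factor and reference-region definition, so only
  within-pipeline comparisons are meaningful.
* The two-point T2 estimate ignores multi-compartment decay, stimulated
  echoes and B1 inhomogeneity; it is exact only for the monoexponential
  model it inverts (which the phantom satisfies by construction).
* Moment-matched control sampling pins the pooled control moments; the
  sampling variability of the *limit* itself (which a real 14-subject
  cohort would show) is deliberately absent from default cohorts.  Set
  `moment_match_controls=False` to study it.
* The automated inscribed-ellipse ROI is a surrogate for expert manual
  segmentation, evaluated only on phantoms.
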