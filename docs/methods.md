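# Methods

`strokemismatch` estimates the perfusion–diffusion (PWI–DWI) mismatch in
acute ischemic stroke MRI and renders the imaging-based thrombolysis
eligibility decision, together with the validation machinery needed to
compare the automated decision against clinical practice or human raters.
This note records the model, the tunable parameters, the synthetic data the
package is validated on, and the design choices made where the problem was
genuinely open.

## The imaging model

Two acute MR acquisitions enter the pipeline, assumed co-registered to the
perfusion grid (geometry is *checked*, never corrected — registration is a
separate concern and out of scope):

- **Diffusion pair** (b = 0 and b = 1000 s/mm²). The apparent diffusion
  coefficient is the two-point monoexponential fit,
  ADC = ln(S₀/S_b)/b (mm²/s). Non-positive signals give NaN, never ±inf.
  Acutely infarcted tissue shows restricted diffusion (ADC roughly
  0.4–0.6 × 10⁻³ mm²/s against ~0.9 × 10⁻³ in normal parenchyma) and DWI
  hyperintensity.
- **DSC perfusion series** (4D, TR and TE supplied by the caller; NIfTI
  timing headers are not trusted). Signal is converted to contrast
  concentration by C(t) = −ln(S(t)/S₀)/TE with S₀ the per-voxel mean of the
  pre-bolus baseline samples. The perfusion statistic is **TTP**, the time
  of the concentration peak measured from series start on the TR grid, with
  plateau ties broken to the earliest sample (the conservative, shortest
  delay). No deconvolution is performed (no MTT/Tmax, no arterial input
  function): TTP is the only perfusion quantity downstream steps consume,
  and only contralateral TTP *differences* matter, so the series-start
  offset cancels.

## Pipeline

1. **Brain masking.** Otsu threshold on the b = 0 image, 3D morphological
   closing (ball radius 2 voxels), largest connected component, hole
   filling. This removes background, eyes and detached artefacts.
2. **Laterality detection.** The brain is split at the geometric mid-plane
   of its bounding box along the left–right axis (resolved from the NIfTI
   orientation). For each hemisphere the detector compares distribution
   *tails* against the other side: the 98th percentile of TTP (delay tail)
   and the 2nd percentile of ADC (restriction tail), each asymmetry
   normalised by the across-brain interquartile range of its map, then
   summed. Tails rather than medians are essential: a focal lesion occupies
   a minority of its hemisphere, so hemisphere medians are virtually
   unchanged by even a large stroke, whereas the tail statistics shift by
   the full lesion contrast once the lesion exceeds ~2 % of the hemisphere.
   A maximal score below 0.1 yields an explicit *undetermined* state; the
   pipeline then refuses to segment without an explicit side, rather than
   guessing.
3. **Contralateral reference.** Each voxel in the affected hemisphere is
   paired with its mirror across the mid-plane; reference mean and SD are
   computed over a 5³-voxel cube around the mirrored position restricted to
   the brain mask (NaN when the mirror falls outside the brain).
4. **Lesion delineation.**
   - DWI core: b = 1000 signal > reference mean + k·SD (k = 2) **and**
     ADC < 620 × 10⁻⁶ mm²/s. The dual criterion guards against T2
     shine-through, which is hyperintense but without restricted diffusion.
   - TTP lesion: TTP − reference mean > τ, τ = 4 s.
   - Shared cleanup, in a fixed order: threshold → binary opening →
     removal of clusters < 0.2 mL → hole filling. The opening uses a
     *spacing-aware* structuring element (a ball of physical radius
     `radius × min(spacing)` mm): with 5 mm slices a voxel-isotropic ball
     would erode a two-slice-thick lesion to nothing. Masks are clipped to
     the affected hemisphere unless midline crossing is explicitly allowed.
5. **Mismatch and decision.** Mismatch = TTP lesion ∧ ¬DWI core; volumes
   are voxel counts × voxel volume, so the conservation law
   `mismatch + (TTP ∩ DWI) = TTP` holds exactly. Imaging eligibility
   requires mismatch volume > 10 mL **and** mismatch ratio > 1.2, both
   strict. Two ratio conventions exist in the literature and both are
   implemented: `pwi_over_dwi` (TTP volume / core volume — the convention
   of the trials the 1.2 threshold originates from; the default) and
   `mismatch_over_core`. The convention is always recorded in the report.
   An empty core with nonzero mismatch gives an infinite ratio, serialised
   as `"inf"`.
6. **Contraindication screen** (reported separately, never fused with the
   imaging decision, because clinicians weigh the two hierarchically):
   systolic BP > 185 mmHg, diastolic BP > 110 mmHg, intracranial
   hemorrhage, anticoagulant use, INR > 1.7, onset-to-treatment > 4.5 h.
   All strict; an unknown field produces `unassessable:<field>`, never a
   silent pass.

## Evaluation layer

- **Consensus masks**: voxelwise rater votes; a voxel is consensus when at
  least `cutoff` (default 3) of the raters marked it. Cutoff 1 is the
  union, cutoff = n_raters the intersection; consensus volume is monotone
  non-increasing in the cutoff.
- **Confusion matrix** between predicted eligibility and actual treatment
  (TP both treat, TN both supportive, FP predicted-treat only, FN
  predicted-supportive only), with sensitivity/specificity/PPV/NPV as
  percentages; a zero denominator yields an explicit undefined marker.
- **Volumetric agreement**: Spearman rank correlation (average ranks on
  ties) plus Bland–Altman mean difference, SD and mean ± 2 SD limits.
- **Mismatch salvage**: the part of the acute mismatch not infarcted on
  follow-up; `salvage + (mismatch ∩ infarct) = mismatch` exactly.
- **Rank-sum test** (Wilcoxon–Mann–Whitney): exact enumeration when both
  groups have ≤ 20 observations and no ties, otherwise the normal
  approximation with continuity correction. The exact/asymptotic crossover
  is a numerical choice; its type-I error is verified by simulation to sit
  in [0.03, 0.07] at α = 0.05.
- **Group summaries**: medians and 25th/75th percentiles with linear
  interpolation between order statistics (the convention matters for small
  groups and is therefore pinned). ΔNIHSS = acute − 24 h, so positive
  means improvement.
- **CART**: greedy binary tree over presentation variables
  (contraindications, mismatch, NIHSS) split by Gini diversity index
  1 − Σp², candidate thresholds at midpoints of sorted distinct values,
  ties broken by variable order then lower threshold, no pruning
  (max depth 4, min leaf 5 by default) — a descriptive tree, matching how
  the analysis is used. Contraindications may be encoded as a count or a
  binary flag; mismatch as a volume or an eligibility flag.

## Synthetic phantom

The phantom emulates the acquisition the pipeline targets: a 64×64×20 grid
at 3×3×5 mm (5 mm slices), TR 1.5 s, TE 30 ms, 40 time points with 8
pre-bolus baseline samples, b = 0/1000 s/mm² diffusion pair.

- **Anatomy**: ellipsoidal brain; an oblate-ellipsoidal hypoperfused
  region centred at mid-hemisphere with an ischemic core nested inside.
  Lesion masks are built by ranking voxels by anisotropic distance from
  the lesion centre and taking exactly the number matching the requested
  volume, so the constructed truth volume is correct to within half a
  voxel.
- **Diffusion**: ADC 0.9 × 10⁻³ mm²/s normal, 0.5 × 10⁻³ in the core; a
  T2-style hyperintensity factor of 1.6 multiplies *both* diffusion images
  inside the core, so the measured ADC still equals the constructed one
  while the b = 1000 image shows the combined hyperintensity (factor ≈ 2.4
  over contralateral tissue).
- **Perfusion**: each voxel carries a gamma-variate bolus (shape α = 3,
  time constant β = 1.5 s, peak signal drop 40 %), with arrival delayed by
  `ttp_delay_s` (default 6 s) inside the hypoperfused region. Only two
  distinct arrival times exist, so two template curves are evaluated.
- **Noise**: additive Gaussian at 5 % of baseline signal on every image.
  This is a deliberate simplification (real magnitude MRI noise is Rician);
  at this SNR the difference is negligible away from the background, and
  background voxels are excluded by the brain mask.
- The same integer seed reproduces every output bit-identically.

What the phantom does *not* model: realistic anatomy, partial-volume
effects at lesion boundaries, motion, susceptibility artefacts, benign
oligemia (graded rather than binary delay), or DWI lesion reversal.
Passing the recovery suite therefore demonstrates correctness of the
estimation machinery under controlled contrast and noise, not clinical
segmentation accuracy.

The **cohort generator** produces per-patient records and mismatch results
consistent with prescribed confusion-cell sizes. Per-cell parameters
(mismatch-volume medians ≈ 96/73 mL in eligible cells and near 0 in
ineligible ones, NIHSS medians 11/6/8/5, contraindication prevalences
0.24/0.83/0.73/0.23 for TP/TN/FP/FN, salvage as a Beta-distributed fraction
of each patient's own mismatch) reflect typical published group statistics
for this decision problem. Eligible cells always satisfy both imaging
criteria and ineligible cells always fail at least one, so re-applying the
eligibility rule recovers the cells exactly — the generator is
self-consistent by construction, which the tests verify.

## Validation conditions and problem sizes

The recovery suite runs the *full* pipeline (maps → masking → laterality →
segmentation → mismatch) on 20 seeded phantoms with cores of 5–60 mL,
hypoperfusion of 20–150 mL and delays drawn from 4.5–9 s, and requires
median absolute mismatch-volume error ≤ 10 %, correct laterality in every
case, and Dice ≥ 0.8 per lesion. The delay lower bound sits one TR above
the 4 s segmentation threshold: TTP lives on the 1.5 s sampling grid, so a
delay within one sample of τ is not voxelwise decidable and a sub-TR margin
would test quantization noise rather than the method. Observed performance
under these conditions is far inside the bounds (median volume error ≈ 2 %,
minimum Dice ≈ 0.9). The rank-sum calibration uses 2000 null replicates at
n = 20 per group. These sizes keep the whole suite under a minute on one
CPU while leaving the statistics stable across seeds.

## Numerical and degenerate-input choices

- NaN is the universal in-memory sentinel for "undefined" map values;
  voxels outside the brain mask are never interpreted.
- Volumes use the spacing product (dx·dy·dz); no slice-gap correction.
- Laterality, TTP ties, CART ties and leaf-label ties all have fixed,
  documented tie-breaks, so every result is reproducible bit-for-bit from
  the config hash and seed recorded in each report.
- Constant images (brain masking), empty decision lists, zero confusion
  denominators, constant agreement vectors and empty groups all raise or
  return explicit undefined markers rather than fabricating values.

## Known limitations

- TTP cannot separate critically hypoperfused tissue from benign oligemia;
  like any TTP-threshold method the pipeline may overestimate the true
  tissue at risk. τ is exposed in the config for exactly this reason.
- The bounding-box mid-plane is a geometric, not anatomical, midline; data
  with strong head tilt should be reoriented upstream.
- Bilateral strokes violate the contralateral-reference assumption; the
  midline-crossing allowance only relaxes the clipping, not the reference.
- The CART is descriptive (no pruning or cross-validation) and should not
  be read as a validated prediction model.
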