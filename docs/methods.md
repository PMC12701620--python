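# Methods

This note documents the models, conventions and numerical choices behind
`petmass`, and what the synthetic-data tests do and do not establish about
real PET data.

## Coordinate and unit conventions

Volumes are 3D scalar grids of SUV (dimensionless) with per-axis voxel
spacing in mm; voxel `(i, j, k)` has its center at
`origin + (i, j, k) · spacing`, and every distance in the package is between
voxel centers, in mm. Volumes are reported in ml (cm³), surfaces in cm²,
TVSR and the massiveness distances in mm, TLG in g. Two unit identities are
enforced by construction and checked in tests:
`tvsr_mm = 10 · tmtv_ml / tmts_cm2` and `tlg_g = tmtv_ml · suv_mean`.

## Segmentation

A voxel is hypermetabolic iff its SUV is **strictly greater** than the
threshold (default 4.0); ties at the threshold are excluded. Components are
formed under 26-connectivity by default — diagonally touching nodal masses
merge, as a clinical reader would treat them — with 6-connectivity available
as a config switch. Labels are deterministic: sorted by descending voxel
count, ties broken by the lexicographically smallest voxel index. Boundary
voxels are mask voxels with at least one face neighbor outside the mask
(grid borders count as outside). Classification of components into
pathological vs. physiological uptake is out of scope: masks are assumed
pathological (synthetic ground truth, or a mask the user has vetted). A
minimum-component-size filter (default 1 = off) guards against single-voxel
noise components.

## Feature definitions and their open choices

* **SUVmax / SUVmean / TLG** — pooled over the union of all lesion voxels.
  Whether the mean should instead average per-lesion means is genuinely
  ambiguous in the literature; voxel-pooling was chosen because it makes TLG
  exactly volume-weighted.
* **TMTV** — voxel count × voxel volume.
* **TMTS** — exposed-face counting: every face separating a lesion voxel
  from a non-lesion voxel contributes its anisotropy-correct face area.
  This is deterministic and exactly checkable against a brute-force face
  count, at the cost of a known systematic overestimate versus a smooth
  (mesh) surface for curved shapes — e.g. the digitized sphere's
  face-counted surface exceeds 4πr² by roughly 50 %. Because the same
  convention is applied to every patient, ratios and rankings are unaffected.
* **Dmax** — maximum distance over all pairs of lesion voxels (all lesions
  pooled), not over lesion centroids: a single lesion then yields its own
  maximal diameter, which keeps Dmax defined for single-lesion patients.
  For clouds above 1500 voxels the maximum is found on the convex hull; the
  surviving pair arithmetic is identical to the direct computation.
* **TumBB** — axis-aligned bounding box over all lesion voxels, each voxel
  contributing its full extent (`max − min + 1` voxels per axis).
* **itErosion** — each component is resampled independently to an isotropic
  4 mm grid (nearest source voxel at each target voxel center) and eroded
  with a full 3×3×3 structuring element until it vanishes; the index is the
  unweighted mean of per-component counts. Per-component resampling avoids
  components merging or splitting on the coarse grid. A component that
  disappears on resampling contributes 1. A grid-aligned cuboid of minimum
  thickness `t` (in 4 mm voxels) takes exactly `⌈t/2⌉` erosions, which the
  tests use as a closed form. The structuring element (cube vs. 6-neighbor
  cross) is a config switch.
* **medPCD** — distances from each lesion's centroid to its boundary-voxel
  centers, pooled over all lesions before taking the median. Pooling (rather
  than a median of per-lesion medians) weights large lesions more, which is
  the reading consistent with "massiveness"; the per-lesion alternative is a
  config switch.
* **medEdgeD** — for each boundary voxel, the ray through the lesion's
  centroid is marched in steps of ¼ of the minimum spacing, with
  nearest-voxel membership lookup on the native grid; the chord ends at the
  first sample outside the component. The median is pooled like medPCD.
  "Distance between opposite edges" admits several operationalizations; the
  centroid-ray chord was chosen because it is well defined for arbitrary
  shapes, reduces to the diameter for a sphere (checked: 40 ± 4 mm at r =
  20 mm, 2 mm spacing), and degrades gracefully for non-convex lesions
  (the chord ends at the first exit, so it never exceeds the star-shaped
  extent through the centroid). A single-voxel lesion has its boundary voxel
  at the centroid; its chord is defined as 0.

Because the erosion and edge-distance definitions are declared conventions
rather than a published algorithm, population-level values from clinical
tables are not used as validation targets for these two features; validation
relies on closed forms and oracle equivalence instead.

## Synthetic phantoms

Voxel membership is voxel-center-inside-shape with no partial-volume effect,
so analytic volumes and brute-force voxel counts agree exactly with the
digitization. Shapes: sphere, cuboid, ellipsoid, union of spheres. Uptake is
uniform at `suv_peak` or "radial-linear" (linear fall-off to half the peak at
the surface, keeping the whole lesion above a 4.0 threshold when the peak is
8). Noise is additive Gaussian, clipped at 0 — the simplest perturbation
that exercises threshold robustness. Lesions extending outside the grid are
rejected with the lesion index named. What phantoms do *not* emulate:
scanner physics (PSF, scatter, reconstruction), respiratory motion,
physiological-uptake organs; passing the phantom tests shows the geometry
pipeline is correct, not that the features are robust to acquisition
variability.

## Simulated cohorts

Features come from a Gaussian copula with one latent factor per feature
family and loading λ = 0.9 (within-family rank correlations ≈ 0.8,
between-family ≈ 0); TLG loads equally on the activity and burden factors,
so it legitimately clusters with either. Marginals are log-normal calibrated
to the reference cohort's median and IQR per feature (e.g. medEdgeD
median 25.6 mm, IQR 20.42–34.26 mm); only these two quantile anchors are
matched — the true distributional shapes are unknown, so tails are not to be
trusted. nROI is rounded and floored at 1.

Survival: exponential event times with log-hazard linear in medEdgeD
(default per-mm hazard ratio 1.03, centered at the 25.6 mm reference so the
baseline rate applies to a typical patient). Baseline rates default to
0.035/y (OS) and 0.08/y (PFS), chosen to give the ~90 % 5-year overall
survival typical of advanced-stage Hodgkin lymphoma with correspondingly
more progression events. Censoring is administrative at 5 years plus an
independent uniform early-censoring fraction (default 5 %, a knob — clinical
reports give only a median follow-up, not a censoring law). Covariate
frequencies (treatment 63 % ABVD, ECOG ≥ 2 8 %, IPS ≥ 3 58 %, B signs 48 %,
bulky ≈ 18 %) match the reference cohort; bulky status is drawn from a
logistic model on the massiveness factor so that bulky patients have larger
medEdgeD, enabling the bulky-subgroup comparisons. Two deliberate
simplifications:

* the treatment effect defaults to 0 (knob `log_hr_beacopp`): a nonzero
  independent treatment effect would attenuate the *marginal* per-mm
  medEdgeD hazard ratio below its configured value, breaking the
  parameter-recovery contract the generator is calibrated to;
* only medEdgeD carries a direct effect; the other features are prognostic
  only through correlation, mirroring a multivariate analysis in which a
  single massiveness feature survives selection. An `effect_arm` knob
  restricts the effect to one treatment arm for subgroup experiments.

## Survival-analysis conventions

* **Horizon censoring** — times beyond the horizon (default 5 y) are set to
  the horizon with event = 0.
* **Feature clustering** — Spearman correlation; average-linkage
  hierarchical clustering on `1 − |ρ|`, cut to k = 4 clusters. Constant
  features are excluded with a warning.
* **Horizon ROC** — positives have the event by the horizon; negatives are
  event-free with follow-up reaching the horizon; patients censored earlier
  carry no label and are excluded (time-dependent ROC would use them but is
  out of scope). AUC is pairwise concordance with ties counting ½; its
  p-value against 0.5 uses the DeLong variance (the method is a convention
  choice — nothing in the chain depends on it). The cutoff maximizes
  sensitivity × specificity (not Youden's sum) over midpoints between
  adjacent observed values, test-positive being `value ≥ cutoff`; ties break
  toward higher specificity, then lower cutoff.
* **Kaplan–Meier** — median dichotomization (`high` = value ≥ cohort
  median), lifelines KM and two-group or k-group log-rank.
* **Cox models** — lifelines partial-likelihood fits with Wald CIs/p-values.
  Continuous features enter per natural unit (per mm, per SUV unit);
  categorical covariates are coded 0/1 (ECOG 2–4, IPS 3–7, BEACOPP = 1).
  Clinical tables sometimes label rows as dichotomized at a median while
  reporting what are numerically per-unit hazard ratios; `petmass` defaults
  to the continuous per-unit convention and leaves dichotomized entry to the
  caller. Fits with |coef| > 10 or convergence warnings are flagged
  (monotone-likelihood suspicion).
* **Stepwise backwards selection** — start from the full model, repeatedly
  drop the variable with the largest Wald p while it exceeds the retention
  threshold (default 0.15; a threshold of 1.0 therefore returns the full
  model). May return an empty model. No multiple-testing correction is
  applied across features, matching common practice in this literature.
* **Median follow-up** — reverse Kaplan–Meier (censoring as the event);
  "not reached" is returned as infinity.

## Problem sizes and calibration checks

The test suite verifies, among others: type-I error of the median-split
log-rank within [3 %, 7 %] and Cox null bias |E log HR| < 0.02 over 1000
replicates at n = 100; recovery of the per-mm hazard ratio within
[1.02, 1.04] in ≥ 90/100 seeds at n = 2000; recovery of the four feature
families by the Spearman clustering in ≥ 95/100 seeds at n = 500; and exact
equivalence of surface, Dmax, component-count and AUC computations with
brute-force oracles on 100 random phantoms/toy sets. The acceptance script
reports the same quantities at moderately reduced replicate counts (20 Cox
seeds, 50 clustering seeds, 400 null replicates), sized so a full run stays
fast while the binomial noise on the reported rates remains small.

## Known limitations

* Surface (and hence TVSR) uses the voxelized face-count convention;
  absolute values are not comparable to mesh-based surfaces.
* No partial-volume modelling anywhere; features from low-resolution or
  heavily smoothed volumes inherit the corresponding bias.
* The ROC stage discards early-censored patients rather than modelling them.
* The cohort generator matches medians/IQRs and rank correlations, not full
  joint distributions; statistical-power results on it do not transfer
  quantitatively to real cohorts.
* CSV headers carry units inside the column names (`tmtv_ml`,
  `med_edge_d_mm`) rather than a separate units row, so tables round-trip
  through standard CSV readers unchanged.
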