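# petmass

Quantitative 3D features from FDG-PET lesion masks, and the survival-analysis
chain used to rank them as prognostic markers in lymphoma.

In advanced-stage Hodgkin lymphoma, pretreatment FDG-PET carries prognostic
information beyond the classical clinical scores. Beyond the familiar burden
measures (total metabolic tumor volume, total lesion glycolysis), a family of
*massiveness/fragmentation* indices — how compact versus fragmented the total
tumor mass is — has been proposed as a stronger predictor of overall and
progression-free survival. `petmass` implements that computation end to end
for researchers who want to reproduce, stress-test or extend this kind of
analysis on their own volumes and cohorts:

* **segmentation** — absolute SUV thresholding (SUV > 4.0, strict) and
  26-connected component labelling of hypermetabolic lesions;
* **features** — the 12 parameters, in four correlated families:
  * activity: SUVmax, SUVmean, TLG = TMTV × SUVmean (g)
  * burden: TMTV (cm³), TMTS (cm², exposed-face surface), TVSR = TMTV/TMTS (mm)
  * dispersion: Dmax (mm, farthest voxel pair), TumBB (cm³, bounding box), nROI
  * massiveness: itErosion (mean erosion depth on a 4 mm grid), medEdgeD
    (median edge-to-opposite-edge chord, mm), medPCD (median
    centroid-to-periphery distance, mm);
* **survival analysis** — administrative censoring at 5 years, Spearman
  correlation with average-linkage feature clustering, horizon-anchored ROC
  with the sensitivity×specificity-product cutoff, median-split Kaplan–Meier
  with log-rank tests, univariate and stepwise-backwards multivariate Cox
  proportional-hazards models (e.g. hazard per mm of medEdgeD), subgroup and
  Student's-t comparisons, reverse-Kaplan–Meier median follow-up;
* **synthetic data** — digital phantoms with analytically known geometry, and
  simulated cohorts with a 4-latent-factor feature correlation structure and
  exponential proportional-hazards outcomes (per-mm hazard ratio 1.03 on
  medEdgeD by default), so the whole chain is testable without patient data.

## Worked example

```python
from petmass import (PhantomSpec, LesionSpec, make_phantom, threshold_segment,
                     label_components, extract_all)

spec = PhantomSpec(
    grid_shape=(40, 40, 40), spacing_mm=(2.0, 2.0, 2.0), background_suv=1.0,
    lesions=[LesionSpec(shape="sphere", center_mm=(40, 40, 40),
                        radius_mm=20.0, suv_peak=8.0)],
)
volume, truth = make_phantom(spec)
mask = threshold_segment(volume, 4.0)
lesions = label_components(mask, volume.spacing_mm)
print(extract_all(volume, lesions))
```

prints

```
FeatureVector(suv_max=8.0, suv_mean=8.0, tmtv_ml=33.352, tlg_g=266.816,
              tmts_cm2=76.08, tvsr_mm=4.3838..., dmax_mm=40.0, tumbb_ml=74.088,
              n_roi=1, it_erosion=3.0, med_edge_d_mm=39.5, med_pcd_mm=18.97...)
```

i.e. for a digitized 20 mm-radius sphere: metabolic volume 33.35 ml (analytic
4/3·π·20³ = 33.51 ml, the 0.5 % gap is voxelization), centroid-to-periphery
distance ≈ the radius, edge-to-opposite-edge chord ≈ the diameter, and three
erosions of the 4 mm grid to remove the mass.

On the statistics side:

```python
from petmass import simulate_cohort, CohortSimParams, cox_univariate
cohort = simulate_cohort(CohortSimParams(n_patients=2000, seed=1))
print(cox_univariate(cohort, "med_edge_d_mm", "pfs").table)
#                hazard_ratio    ci_low   ci_high       p_value
# med_edge_d_mm      1.034184  1.028053  1.040353  1.59e-28
```

recovering the simulated per-mm hazard ratio of 1.03.

A `petmass` command-line tool exposes the same stages
(`petmass simulate phantom|cohort`, `segment`, `features`, `analyze`, `run`);
`petmass run --seed 0 --out report/` simulates a cohort and writes the full
analysis report (correlation matrix, clusters, ROC/KM/Cox tables) as
deterministic CSVs plus a JSON run log.

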