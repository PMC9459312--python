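# dreho

Dynamic regional homogeneity (dReHo) analysis of resting-state 4D brain
volumes: sliding-window Kendall's-W concordance mapping, Gaussian-random-field
(GRF) cluster-corrected group inference, clinical correlation, and
leave-one-out cross-validated linear-SVM classification — plus a synthetic
two-group cohort generator with known injected effects, so the whole chain is
testable without patient data.

## Who this is for

Researchers analyzing resting-state fMRI who want the *dynamic* variant of
regional homogeneity: instead of assuming local BOLD synchrony is stationary
over the scan, the statistic is recomputed in overlapping sliding windows and
each voxel is summarized by how much its local synchrony fluctuates.

## The statistic

Regional homogeneity assigns each voxel Kendall's coefficient of concordance
over its neighborhood's time series (K = 7, 19 or 27 voxels including the
center):

    W = 12 S / (K^2 (n^3 - n) - K ΣT),   S = Σ_i (R_i - R̄)^2

with R_i the cross-series rank sum at time i and ΣT the usual tie
correction. W lies in (0, 1]; 1 means all K series share one rank ordering;
the null expectation for independent series is 1/K. Dynamic ReHo computes W
inside sliding windows (default: 30 TR length, 1 TR step, TR = 2 s) and maps
the across-window standard deviation, which is then divided by its
whole-brain mean and smoothed with a 6 mm FWHM Gaussian kernel. Group
differences are tested voxelwise by OLS with age, education and mean
framewise displacement as nuisance covariates, corrected at cluster level by
GRF theory (two-tailed, voxel p < 0.01, cluster p < 0.05); surviving
cluster means feed Pearson correlations against clinical measures and a
LOOCV linear SVM (patient vs control).

## Worked example

Simulate a 10-vs-10 cohort with one injected coherence-modulated sphere
(radius 2 voxels, patients' modulation depth 0.3 above controls'), run the
full chain, and fit the group model:

```python
import numpy as np
from dreho import (
    CohortSpec, EffectRegion, PrepConfig, WindowSpec, SmoothSpec,
    DReHoStudy, dreho_map, gaussian_smooth, preprocess,
)
from dreho.inference import erode_mask
from dreho.reho import normalize_map
from dreho.synthetic import cohort_dataframe, generate_clinical_table, generate_scan
from dreho.volume import ScalarMap

spec = CohortSpec(
    n_patients=10, n_controls=10,
    grid_shape=(16, 16, 12), n_volumes=160,
    effect_regions=[EffectRegion(center=(8, 8, 6), radius=2, sign=+1, amplitude=0.3)],
    base_depth=0.25, seed=42,
)
records = generate_clinical_table(spec)
maps = []
for rec in records:
    scan = generate_scan(rec, spec)                      # synthetic 4D volume
    vol = preprocess(scan.volume, PrepConfig())          # discard, detrend, band-pass
    m = dreho_map(vol, ws=WindowSpec(length_tr=30, step_tr=1))
    m = normalize_map(m, "mean-div")
    maps.append(gaussian_smooth(m, SmoothSpec(fwhm_mm=6.0)))

inner = erode_mask(maps[0].mask, 2)                      # inference inside the boundary
maps = [ScalarMap(m.data, m.affine, inner, m.label) for m in maps]
res = DReHoStudy(maps, cohort_dataframe(records)).fit()
print(res.summary())
report = res.classify()
print(f"LOOCV linear SVM: accuracy {report.accuracy:.1f}%, AUC {report.auc:.2f}")
print(res.correlate(["odi", "moca_total"]).to_string(index=False))
```

Output:

```
dReHo group-difference study (voxelwise OLS, GRF cluster correction)
====================================================================
subjects: 20 (patients 10, controls 10)
design columns: group, age, education, motion_summary, intercept
degrees of freedom: 15
estimated smoothness FWHM (vox): 2.21, 2.24, 2.17; resels 55.8
voxel p 0.01 (two-tailed), cluster p 0.05, connectivity 26
cluster extent threshold k = 10 voxels
surviving clusters: 1

 label  n_voxels  sign   peak_t  peak_x_mm  peak_y_mm  peak_z_mm
     1        51     1 6.981774       21.0       24.0       21.0

LOOCV linear SVM: accuracy 95.0%, AUC 0.98
  cluster   variable        r        p  n
cluster_1        odi 0.457668 0.183512 10
cluster_1 moca_total 0.748412 0.012771 10
```

Reading it: exactly one cluster survives correction; its peak at
(21, 24, 21) mm sits inside the injected sphere (centered at (24, 24, 18) mm),
with a positive t — patients more temporally variable, as injected. The
cluster's per-subject means separate the groups at 95% LOOCV accuracy, and
the patients-only Pearson screen shows which clinical covariates track the
cluster mean in this simulated cohort.

The same chain is scriptable from a shell:

```
dreho simulate --out data/ --n-patients 10 --n-controls 10 --seed 7
dreho run --out runs/demo --windows 25,30,35 --seed 7
```

`dreho run` writes per-window t-maps, cluster tables, correlation tables,
classifier reports, JSON sidecars carrying every parameter and the config
hash, and a Dice-overlap report between window lengths.

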