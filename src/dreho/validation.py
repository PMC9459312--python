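"""Monte-Carlo validation studies: null calibration and effect recovery.

These run the actual analysis chain on simulated cohorts at desk scale:

* :func:`null_fwe_rate` — family-wise error of the GLM → smoothness → GRF
  extent-threshold → cluster-extraction chain on smoothed-noise cohorts.
* :func:`effect_recovery_study` — end-to-end recovery (synthesis → prep →
  dReHo map → normalization → smoothing → inference) of a single injected
  coherence-modulated sphere.
* :func:`depth_accuracy_curve` — LOOCV SVM accuracy on region-mean dReHo
  features as the injected modulation depth grows.

Problem sizes default to values chosen so each study runs in minutes on one
CPU; they are arguments, not constants, so larger replications are one call
away.
"""

from __future__ import annotations

import numpy as np

from .classify import FeatureMatrix, loocv_linear_svm
from .inference import (
    InferenceSpec,
    erode_mask,
    estimate_smoothness,
    extract_clusters,
    grf_cluster_extent_threshold,
    voxelwise_glm_ttest,
)
from .model import DReHoStudy
from .prep import PrepConfig, preprocess
from .reho import NeighborhoodSpec, SmoothSpec, WindowSpec, dreho_map, gaussian_smooth, normalize_map
from .synthetic import CohortSpec, EffectRegion, cohort_dataframe, generate_clinical_table, generate_scan
from .volume import ScalarMap


def null_fwe_rate(
    n_cohorts: int = 500,
    grid: tuple[int, int, int] = (16, 16, 16),
    n_per_group: int = 20,
    fwhm_mm: float = 6.0,
    voxel_size_mm: float = 3.0,
    spec: InferenceSpec | None = None,
    seed: int = 0,
) -> float:
    """Fraction of null cohorts with any surviving cluster (empirical FWE).

    Each cohort is ``2 * n_per_group`` smoothed white-noise maps split into
    two arbitrary groups; any cluster surviving the GRF extent threshold is a
    family-wise false positive.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 301)))
    spec = spec or InferenceSpec()
    mask = np.ones(grid, dtype=bool)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    n = 2 * n_per_group
    design = np.column_stack(
        [np.r_[np.ones(n_per_group), np.zeros(n_per_group)], np.ones(n)]
    )
    smooth = SmoothSpec(fwhm_mm)
    hits = 0
    for _ in range(n_cohorts):
        stack = np.array(
            [
                gaussian_smooth(ScalarMap(rng.standard_normal(grid), affine, mask), smooth).data
                for _ in range(n)
            ]
        )
        stat = voxelwise_glm_ttest(stack, design, mask=mask, affine=affine)
        stat.fwhm_vox = estimate_smoothness(stat.residuals, mask)
        k = grf_cluster_extent_threshold(stat, spec)
        hits += bool(extract_clusters(stat, spec, k))
    return hits / n_cohorts


def _recovery_spec(seed: int, amplitude: float, **overrides) -> CohortSpec:
    defaults = dict(
        n_patients=10,
        n_controls=10,
        grid_shape=(16, 16, 12),
        n_volumes=160,
        effect_regions=[
            EffectRegion(center=(8, 8, 6), radius=2, sign=+1, amplitude=amplitude)
        ],
        base_depth=0.25,
        seed=seed,
    )
    defaults.update(overrides)
    return CohortSpec(**defaults)


def _cohort_maps(spec: CohortSpec, window: WindowSpec, erosion: int = 2):
    """Generate, preprocess and map one cohort; returns (table, maps, spec)."""
    records = generate_clinical_table(spec)
    prep_cfg = PrepConfig()
    maps = []
    for rec in records:
        scan = generate_scan(rec, spec)
        vol = preprocess(scan.volume, prep_cfg)
        m = dreho_map(vol, NeighborhoodSpec(), window, metric="sd")
        m = normalize_map(m, "mean-div")
        maps.append(gaussian_smooth(m, SmoothSpec(6.0)))
    if erosion:
        inner = erode_mask(maps[0].mask, erosion)
        maps = [ScalarMap(m.data, m.affine, inner, m.label) for m in maps]
    return cohort_dataframe(records), maps


def effect_recovery_study(
    n_cohorts: int = 20,
    amplitude: float = 0.3,
    seed: int = 0,
    window: WindowSpec | None = None,
    **spec_overrides,
) -> dict:
    """Recovery of a single injected sphere over seeded cohorts.

    A cohort counts as an exact recovery when inference yields exactly one
    surviving cluster, of the injected sign, overlapping the injected sphere.
    """
    window = window or WindowSpec(30, 1)
    exact = 0
    any_overlap = 0
    for c in range(n_cohorts):
        spec = _recovery_spec(seed * 10_000 + c, amplitude, **spec_overrides)
        table, maps = _cohort_maps(spec, window)
        res = DReHoStudy(maps, table).fit()
        gt = spec.ground_truth_effect()
        overlapping = [
            cl for cl in res.clusters if cl.sign == 1 and (cl.voxels & (gt != 0)).any()
        ]
        any_overlap += bool(overlapping)
        exact += len(res.clusters) == 1 and len(overlapping) == 1
    return {
        "n_cohorts": n_cohorts,
        "exact_recovery_rate": exact / n_cohorts,
        "overlap_recovery_rate": any_overlap / n_cohorts,
    }


def depth_accuracy_curve(
    depths: tuple[float, ...] = (0.1, 0.2, 0.3),
    n_cohorts: int = 20,
    seed: int = 0,
    window: WindowSpec | None = None,
    **spec_overrides,
) -> list[float]:
    """Mean LOOCV linear-SVM accuracy per injected depth.

    The classification feature is each subject's mean dReHo over the injected
    region (the generator's known effect support), so the curve isolates how
    class separation grows with modulation depth. Cohorts are deliberately
    small; monotonicity is assessed on the across-cohort mean.
    """
    window = window or WindowSpec(30, 1)
    overrides = dict(
        grid_shape=(12, 12, 10),
        n_volumes=110,
        n_patients=8,
        n_controls=8,
        effect_regions=None,  # replaced per depth below
    )
    overrides.update(spec_overrides)
    accuracies = []
    for depth in depths:
        accs = []
        for c in range(n_cohorts):
            ov = dict(overrides)
            ov["effect_regions"] = [
                EffectRegion(center=(6, 6, 5), radius=2, sign=+1, amplitude=depth)
            ]
            spec = _recovery_spec(seed * 10_000 + c, depth, **ov)
            table, maps = _cohort_maps(spec, window, erosion=0)
            region = spec.region_masks()[0]
            feats = np.array([m.data[region & maps[0].mask].mean() for m in maps])
            labels = (table["group"] == "patient").astype(int).to_numpy()
            report = loocv_linear_svm(FeatureMatrix(feats[:, None], labels))
            accs.append(report.accuracy)
        accuracies.append(float(np.mean(accs)))
    return accuracies
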