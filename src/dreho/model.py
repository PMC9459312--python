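"""Model/Results interface for a dReHo group study.

:class:`DReHoStudy` holds per-subject dReHo maps and the between-subject
design (group + nuisance covariates); :meth:`DReHoStudy.fit` estimates the
voxelwise GLM, residual smoothness, the GRF cluster-extent threshold and the
surviving clusters, returning a :class:`DReHoStudyResults` that carries the
t-map, the cluster table, per-subject cluster means, and the downstream
correlation and classification analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import association, classify
from .inference import (
    InferenceSpec,
    StatMap,
    build_design,
    cluster_means,
    cluster_table,
    estimate_smoothness,
    extract_clusters,
    grf_cluster_extent_threshold,
    voxelwise_glm_ttest,
)
from .volume import ScalarMap


class DReHoStudy:
    """Two-group voxelwise study of dReHo maps.

    Parameters
    ----------
    maps : list of ScalarMap
        One (normalized, smoothed) dReHo map per subject, shared grid/mask.
    table : DataFrame
        One row per subject, aligned with ``maps``; must contain ``group``
        plus the nuisance covariate columns.
    covariates : tuple of str
        Nuisance columns entered in the design (default: age, education,
        motion summary).
    """

    def __init__(
        self,
        maps: list[ScalarMap],
        table: pd.DataFrame,
        covariates: tuple[str, ...] = ("age", "education", "motion_summary"),
        spec: InferenceSpec | None = None,
    ) -> None:
        if len(maps) != len(table):
            raise ValueError("one table row per map required")
        self.maps = maps
        self.table = table.reset_index(drop=True)
        self.covariates = covariates
        self.spec = spec or InferenceSpec()
        self.design, self.design_names = build_design(
            self.table, covariates=covariates
        )

    @classmethod
    def from_dataframe(cls, maps, table, **kwargs) -> "DReHoStudy":
        return cls(maps, table, **kwargs)

    def fit(self) -> "DReHoStudyResults":
        stat = voxelwise_glm_ttest(self.maps, self.design)
        stat.fwhm_vox = estimate_smoothness(stat.residuals, stat.mask)
        k = grf_cluster_extent_threshold(stat, self.spec)
        clusters = extract_clusters(stat, self.spec, k)
        means = cluster_means(self.maps, clusters) if clusters else np.empty(
            (len(self.maps), 0)
        )
        return DReHoStudyResults(self, stat, k, clusters, means)


class DReHoStudyResults:
    """Estimates and diagnostics from a fitted :class:`DReHoStudy`."""

    def __init__(self, model, stat: StatMap, extent_k: int, clusters, means) -> None:
        self.model = model
        self.stat = stat
        self.extent_k = extent_k
        self.clusters = clusters
        self.cluster_mean_values = means

    @property
    def tmap(self) -> np.ndarray:
        return self.stat.t

    @property
    def dof(self) -> int:
        return self.stat.dof

    @property
    def fwhm_vox(self) -> np.ndarray:
        return self.stat.fwhm_vox

    @property
    def resels(self) -> float:
        return self.stat.resels

    def cluster_table(self) -> pd.DataFrame:
        return cluster_table(self.clusters)

    def cluster_names(self) -> list[str]:
        return [f"cluster_{c.label}" for c in self.clusters]

    def correlate(
        self, variables: list[str], group: str = "patient", fdr: bool = False
    ) -> pd.DataFrame:
        """Pearson screen of cluster means vs clinical variables (patients only
        by default, matching the usual within-patient correlation analysis)."""
        if not self.clusters:
            raise ValueError("no surviving clusters to correlate")
        sel = (self.model.table["group"] == group).to_numpy()
        return association.correlate_clusters(
            self.cluster_mean_values[sel],
            self.model.table[sel],
            variables,
            cluster_names=self.cluster_names(),
            fdr=fdr,
        )

    def classify(self, C: float = 1.0, standardize: bool = True):
        """LOOCV linear SVM on the cluster-mean features."""
        if not self.clusters:
            raise ValueError("no surviving clusters to classify on")
        labels = (self.model.table["group"] == "patient").astype(int).to_numpy()
        fm = classify.FeatureMatrix(
            self.cluster_mean_values, labels, self.cluster_names()
        )
        return classify.loocv_linear_svm(fm, C=C, standardize=standardize)

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            "dReHo group-difference study (voxelwise OLS, GRF cluster correction)",
            "=" * 68,
            f"subjects: {len(self.model.table)} "
            f"(patients {(self.model.table['group'] == 'patient').sum()}, "
            f"controls {(self.model.table['group'] == 'control').sum()})",
            f"design columns: {', '.join(self.model.design_names)}",
            f"degrees of freedom: {self.dof}",
            f"estimated smoothness FWHM (vox): "
            + ", ".join(f"{f:.2f}" for f in self.fwhm_vox)
            + f"; resels {self.resels:.1f}",
            f"voxel p {spec.voxel_p} ({'two' if spec.two_tailed else 'one'}-tailed), "
            f"cluster p {spec.cluster_p}, connectivity {spec.connectivity}",
            f"cluster extent threshold k = {self.extent_k} voxels",
            f"surviving clusters: {len(self.clusters)}",
        ]
        if self.clusters:
            lines.append("")
            lines.append(self.cluster_table().to_string(index=False))
        return "\n".join(lines)
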