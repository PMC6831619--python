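"""Model/Results interface over the searchlight decoding pipeline.

`SearchlightGroupDecoder` is constructed from subject maps (or a masked
feature matrix) and holds the design choices — searchlight radius, SVM
regularization, class convention. `fit()` runs the leave-one-out
decoding at every searchlight and returns `SearchlightResults`, which
carries the AUC/sensitivity/specificity maps and the per-centre held-out
decision values. `SearchlightResults.permutation_inference()` adds the
label-permutation null, voxelwise p-values, cluster-size correction and
permutation-z peaks, returning a `SearchlightInference` with a summary
table; `correlate_behavior()` links peak decision values to a behavioral
score with the within-group permutation control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import behavior as _behavior
from . import inference as _inference
from . import searchlight as _searchlight
from .searchlight import ClassifierMap, SearchlightSpec
from .volumes import AnalysisMask, SubjectFeatureMap, stack_masked


class SearchlightGroupDecoder:
    """Searchlight group-decoding model for two-group subject maps.

    Parameters
    ----------
    features : (n_subjects, n_mask_voxels) array
        Subject values at the mask voxels (C-order over the mask).
    labels : sequence of group names or ±1
        Class convention: amusic = +1, control = −1.
    mask : AnalysisMask
    radius_mm : float
        Searchlight radius in world mm, inclusive (default 12, the value
        used for every modality in the study design this emulates).
    C : float
        SVM soft-margin constant (default 1, untuned).
    feature_scaling : bool
        Optional per-fold z-scoring fit on training folds only.
    """

    def __init__(
        self,
        features: np.ndarray,
        labels: Sequence[str] | np.ndarray,
        mask: AnalysisMask,
        radius_mm: float = 12.0,
        C: float = 1.0,
        feature_scaling: bool = False,
        subject_ids: Sequence[str] | None = None,
        modality: str = "",
        tol: float = 1e-3,
    ):
        self.features = np.asarray(features, dtype=float)
        labels_arr = np.asarray(labels)
        self.y = (
            labels_arr.astype(float)
            if labels_arr.dtype.kind in "fib"
            else _searchlight.labels_to_signs(list(labels))
        )
        if self.features.shape[0] != len(self.y):
            raise ValueError("one feature row per subject required")
        if self.features.shape[1] != mask.n_voxels:
            raise ValueError(
                f"feature columns ({self.features.shape[1]}) must match mask "
                f"voxels ({mask.n_voxels})"
            )
        self.mask = mask
        self.radius_mm = float(radius_mm)
        self.C = float(C)
        self.feature_scaling = bool(feature_scaling)
        self.tol = float(tol)
        self.subject_ids = (
            list(subject_ids)
            if subject_ids is not None
            else [f"sub-{i + 1:02d}" for i in range(len(self.y))]
        )
        self.modality = modality
        self.spec: SearchlightSpec = _searchlight.build_searchlights(mask, self.radius_mm)

    @classmethod
    def from_maps(
        cls,
        maps: Sequence[SubjectFeatureMap],
        mask: AnalysisMask,
        **kwargs,
    ) -> "SearchlightGroupDecoder":
        features = stack_masked(maps, mask)
        return cls(
            features,
            [m.group for m in maps],
            mask,
            subject_ids=[m.subject_id for m in maps],
            modality=maps[0].modality if maps else "",
            **kwargs,
        )

    def fit(self, store_decisions: bool = True) -> "SearchlightResults":
        """Run the leave-one-out decoding at every searchlight centre."""
        if not self.feature_scaling:
            grams = _searchlight.precompute_grams(self.features, self.spec)
            cm = _searchlight.run_searchlight_grams(
                grams,
                self.y,
                self.spec,
                self.subject_ids,
                C=self.C,
                tol=self.tol,
                store_decisions=store_decisions,
                modality=self.modality,
            )
            return SearchlightResults(self, cm, grams=grams)
        maps = None
        cm = _searchlight.run_searchlight(
            self._as_maps(),
            self.spec,
            C=self.C,
            feature_scaling=True,
            tol=self.tol,
            store_decisions=store_decisions,
        )
        return SearchlightResults(self, cm, grams=None)

    def _as_maps(self) -> list[SubjectFeatureMap]:
        sel = self.mask.data
        out = []
        conv = {1.0: "amusic", -1.0: "control"}
        for i, sid in enumerate(self.subject_ids):
            vol = np.full(self.mask.grid.shape, np.nan)
            vol[sel] = self.features[i]
            out.append(
                SubjectFeatureMap(
                    subject_id=sid,
                    group=conv[self.y[i]],
                    modality=self.modality or "wm",
                    values=vol,
                    grid=self.mask.grid,
                )
            )
        return out


@dataclass
class SearchlightResults:
    """Fitted searchlight maps plus the decision-value store."""

    model: SearchlightGroupDecoder
    classifier_map: ClassifierMap
    grams: np.ndarray | None = None

    @property
    def auc(self) -> np.ndarray:
        return self.classifier_map.auc

    @property
    def sensitivity(self) -> np.ndarray:
        return self.classifier_map.sensitivity

    @property
    def specificity(self) -> np.ndarray:
        return self.classifier_map.specificity

    def volume(self, which: str = "auc") -> np.ndarray:
        return self.classifier_map.volume(which)

    def summary(self) -> str:
        cm = self.classifier_map
        lines = [
            "Searchlight group decoding (leave-one-out linear SVM)",
            f"  subjects: {len(cm.y)} "
            f"({int((cm.y > 0).sum())} amusic / {int((cm.y < 0).sum())} control)",
            f"  searchlights: {cm.spec.n_centers} "
            f"(radius {cm.spec.radius_mm:g} mm, C = {self.model.C:g})",
            f"  AUC: max {cm.auc.max():.3f}, mean {cm.auc.mean():.3f}",
            f"  sensitivity at max-AUC centre: {cm.sensitivity[cm.auc.argmax()]:.3f}",
            f"  specificity at max-AUC centre: {cm.specificity[cm.auc.argmax()]:.3f}",
        ]
        return "\n".join(lines)

    def permutation_inference(
        self,
        n_perm: int = 1000,
        seed: int = 0,
        voxel_alpha: float = 0.05,
        connectivity: int = 26,
        include_observed: bool = True,
    ) -> "SearchlightInference":
        """Label-permutation null, voxelwise p, cluster correction, peaks."""
        if self.grams is None:
            raise ValueError(
                "permutation inference requires the Gram fast path "
                "(feature_scaling=False)"
            )
        null = _inference.permutation_null(
            self.grams,
            self.model.y,
            self.classifier_map.spec,
            n_perm=n_perm,
            seed=seed,
            C=self.model.C,
            tol=self.model.tol,
            include_observed=include_observed,
            alpha=voxel_alpha,
        )
        p_map = _inference.voxelwise_p(self.classifier_map, null)
        clusters = _inference.cluster_correct(
            p_map, self.classifier_map, null,
            voxel_alpha=voxel_alpha, connectivity=connectivity,
        )
        significant = [c for c in clusters if c.corrected_p < voxel_alpha]
        if significant:
            _inference.find_peak(self.classifier_map, null, significant)
        return SearchlightInference(
            results=self,
            null=null,
            p_map=p_map,
            clusters=clusters,
            voxel_alpha=voxel_alpha,
            connectivity=connectivity,
        )


@dataclass
class SearchlightInference:
    """Permutation inference attached to fitted searchlight results."""

    results: SearchlightResults
    null: _inference.PermutationNullStore
    p_map: np.ndarray
    clusters: list
    voxel_alpha: float
    connectivity: int

    @property
    def significant_clusters(self) -> list:
        return [c for c in self.clusters if c.corrected_p < self.voxel_alpha]

    def z_map(self) -> np.ndarray:
        return _inference.permutation_z(self.results.classifier_map, self.null)

    def cluster_table(self) -> pd.DataFrame:
        return _inference.cluster_table(
            self.clusters,
            modality=self.results.classifier_map.modality,
            connectivity=self.connectivity,
        )

    def summary(self) -> str:
        lines = [
            "Permutation inference "
            f"({self.null.n_perm} relabelings"
            f"{', exhaustive' if self.null.exhaustive else ''}, "
            f"voxel alpha {self.voxel_alpha:g}, "
            f"{self.connectivity}-connectivity, "
            f"add-one convention {'on' if self.null.include_observed else 'off'})",
            f"  suprathreshold clusters: {len(self.clusters)}; "
            f"significant (corrected p < {self.voxel_alpha:g}): "
            f"{len(self.significant_clusters)}",
        ]
        for c in self.significant_clusters:
            mm = c.peak_mm if c.peak_mm is not None else ("?", "?", "?")
            lines.append(
                f"    cluster k={c.size_k}, corrected p={c.corrected_p:.4f}, "
                f"peak ({mm[0]:.0f}, {mm[1]:.0f}, {mm[2]:.0f}) mm, "
                f"AUC {100 * c.mean_auc:.2f}% ± {100 * c.sem_auc:.2f} SEM"
            )
        return "\n".join(lines)

    def correlate_behavior(
        self,
        behavior_table: pd.DataFrame,
        behavior_name: str = "pitch_memory_score",
        cluster_index: int = 0,
        n_perm: int = 10_000,
        seed: int = 0,
        allow_circular: bool = False,
    ) -> _behavior.BrainBehaviorResult:
        """Peak decision values vs behavior for a significant cluster."""
        sig = self.significant_clusters
        if not sig:
            raise ValueError("no significant cluster to take a peak from")
        peak = sig[cluster_index].peak_position
        res = _behavior.peak_decision_behavior(
            self.results.classifier_map,
            peak,
            behavior_table,
            behavior_name=behavior_name,
            allow_circular=allow_circular,
        )
        _behavior.withingroup_perm_p(res, n_perm=n_perm, seed=seed)
        return res
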