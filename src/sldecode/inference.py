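"""Permutation-based voxelwise significance and cluster-size correction.

The null distribution is built by randomly reordering the group labels
and repeating the whole searchlight analysis (default 1000 relabelings;
group sizes are preserved because the relabelings are permutations of
the observed label vector). Voxelwise one-sided p-values compare the
observed AUC with the null AUCs at the same centre. Family-wise
correction follows the max-cluster-size recipe: each permutation's own
p-map (ranked against the pooled null) is thresholded at the same voxel
alpha, and the size of its largest connected suprathreshold cluster
enters the null; an observed cluster's corrected p is the fraction of
null max-sizes at least as large.

Conventions, echoed in every report: 26-neighbor connectivity by default
(configurable 6/18/26), pooled-null ranking for the permutation p-maps,
add-one (include-observed) convention so no p is exactly zero, one-sided
testing for above-chance decoding, deterministic first-index tie-break
for peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .searchlight import ClassifierMap, SearchlightSpec, run_searchlight_grams
from .volumes import AnalysisMask

CONNECTIVITY_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class PermutationNullStore:
    """Null AUC maps from label permutations of one searchlight analysis."""

    null_auc: np.ndarray  # (n_perm, n_centers)
    perm_labels: np.ndarray  # (n_perm, n_subjects) of ±1
    rng_seed: int
    include_observed: bool = True
    exhaustive: bool = False

    @property
    def n_perm(self) -> int:
        return self.null_auc.shape[0]


def balanced_relabelings(
    y: np.ndarray, n_perm: int, seed: int
) -> tuple[np.ndarray, bool]:
    """Label permutations preserving group sizes.

    Sampled with replacement from the permutation space; when the number
    of distinct balanced assignments is at most ``n_perm``, the space is
    enumerated exhaustively instead.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    n_pos = int((y > 0).sum())
    n_assign = comb(n, n_pos)
    if n_assign <= n_perm:
        from itertools import combinations

        labels = np.full((n_assign, n), -1.0)
        for r, pos in enumerate(combinations(range(n), n_pos)):
            labels[r, list(pos)] = 1.0
        return labels, True
    rng = np.random.default_rng(seed)
    labels = np.empty((n_perm, n))
    for r in range(n_perm):
        labels[r] = rng.permutation(y)
    return labels, False


def permutation_null(
    grams: np.ndarray,
    y: np.ndarray,
    spec: SearchlightSpec,
    n_perm: int = 1000,
    seed: int = 0,
    C: float = 1.0,
    tol: float = 1e-3,
    include_observed: bool = True,
    alpha: float = 0.05,
) -> PermutationNullStore:
    """Repeat the searchlight analysis under label permutations.

    Operates on the precomputed Gram stack of the observed analysis (the
    kernel does not depend on labels, so it is shared across
    permutations).
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    if (n_perm + 1) * alpha < 1:
        warnings.warn(
            f"{n_perm} permutations cannot resolve p < {alpha}", stacklevel=2
        )
    labels, exhaustive = balanced_relabelings(y, n_perm, seed)
    n_used = labels.shape[0]
    null_auc = np.empty((n_used, spec.n_centers))
    ids = [f"s{i}" for i in range(len(y))]
    for r in range(n_used):
        cm = run_searchlight_grams(
            grams, labels[r], spec, ids, C=C, tol=tol, store_decisions=False
        )
        null_auc[r] = cm.auc
    return PermutationNullStore(
        null_auc=null_auc,
        perm_labels=labels,
        rng_seed=seed,
        include_observed=include_observed,
        exhaustive=exhaustive,
    )


def voxelwise_p(observed: ClassifierMap, null: PermutationNullStore) -> np.ndarray:
    """One-sided per-centre p-values: P(null AUC >= observed AUC).

    With the include-observed convention the observed labeling counts as
    one additional null sample, so p >= 1/(n_perm + 1).
    """
    if null.null_auc.shape[1] != observed.spec.n_centers:
        raise ValueError("null store and observed map cover different centers")
    inc = int(null.include_observed)
    count = (null.null_auc >= observed.auc[None, :]).sum(axis=0)
    return (count + inc) / (null.n_perm + inc)


def _perm_p_maps(null: PermutationNullStore, observed: ClassifierMap) -> np.ndarray:
    """Each permutation's p-map, ranked against the pooled null.

    The pooled reference contains all permutation maps plus (with the
    include-observed convention) the observed map; each permutation's own
    value is part of the reference, so its p is never zero.
    """
    ref = null.null_auc
    if null.include_observed:
        ref = np.vstack([ref, observed.auc[None, :]])
    n_ref = ref.shape[0]
    srt = np.sort(ref, axis=0)
    p = np.empty_like(null.null_auc)
    for v in range(ref.shape[1]):
        # count of reference values >= query, via left insertion point
        pos = np.searchsorted(srt[:, v], null.null_auc[:, v], side="left")
        p[:, v] = (n_ref - pos) / n_ref
    return p


def _label_clusters(
    binary_vec: np.ndarray, spec: SearchlightSpec, connectivity: int
) -> tuple[np.ndarray, int]:
    structure = CONNECTIVITY_STRUCTURES[connectivity]
    vol = np.zeros(spec.mask.grid.shape, dtype=bool)
    c = spec.centers
    vol[c[:, 0], c[:, 1], c[:, 2]] = binary_vec
    lab, n = ndimage.label(vol, structure=structure)
    return lab, n


def _max_cluster_size(
    binary_vec: np.ndarray, spec: SearchlightSpec, connectivity: int
) -> int:
    lab, n = _label_clusters(binary_vec, spec, connectivity)
    if n == 0:
        return 0
    return int(np.bincount(lab.ravel())[1:].max())


@dataclass
class ClusterResult:
    """One suprathreshold cluster with its corrected p and summaries."""

    cluster_id: int
    voxel_indices: np.ndarray  # (k, 3) voxel coordinates
    center_positions: np.ndarray  # positions into spec.centers
    size_k: int
    corrected_p: float
    mean_auc: float
    sem_auc: float
    mean_sensitivity: float
    sem_sensitivity: float
    mean_specificity: float
    sem_specificity: float
    peak_position: int | None = None  # position into spec.centers
    peak_voxel: np.ndarray | None = None
    peak_mm: np.ndarray | None = None
    peak_z: float | None = None

    def __post_init__(self):
        if self.size_k != len(self.voxel_indices):
            raise ValueError("size_k must equal the number of cluster voxels")
        # the default add-one convention keeps corrected_p strictly positive;
        # zero is attainable only with include_observed disabled
        if not 0 <= self.corrected_p <= 1:
            raise ValueError("corrected_p must be in [0, 1]")


def corrected_p_from_null(
    null_max_sizes: np.ndarray, observed_size: int, include_observed: bool = True
) -> float:
    """Cluster-corrected p: fraction of null max-sizes >= the observed size.

    With the add-one (include-observed) convention the observed analysis
    counts as one extra null sample, so the smallest attainable p is
    1/(n_perm + 1).
    """
    null_max_sizes = np.asarray(null_max_sizes)
    count = int((null_max_sizes >= observed_size).sum())
    inc = int(include_observed)
    return (count + inc) / (len(null_max_sizes) + inc)


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        return 0.0
    return float(x.std(ddof=1) / np.sqrt(len(x)))


def cluster_correct(
    p_map: np.ndarray,
    observed: ClassifierMap,
    null: PermutationNullStore,
    voxel_alpha: float = 0.05,
    connectivity: int = 26,
) -> list[ClusterResult]:
    """Family-wise cluster-size correction of a voxelwise p-map.

    Observed clusters are connected components of {p < voxel_alpha}; the
    null is the per-permutation largest cluster size obtained by
    thresholding each permutation's pooled-null p-map at the same alpha;
    corrected p uses the same add-one convention as the voxelwise step.
    Returns clusters sorted by corrected p (no suprathreshold voxels ->
    empty list).
    """
    if connectivity not in CONNECTIVITY_STRUCTURES:
        raise ValueError("connectivity must be one of 6, 18, 26")
    spec = observed.spec
    p_map = np.asarray(p_map, dtype=float)
    if p_map.shape != (spec.n_centers,):
        raise ValueError("p_map must be a per-centre vector")

    perm_p = _perm_p_maps(null, observed)
    null_max = np.array(
        [
            _max_cluster_size(perm_p[r] < voxel_alpha, spec, connectivity)
            for r in range(null.n_perm)
        ]
    )

    supra = p_map < voxel_alpha
    if not supra.any():
        return []
    lab, n_clusters = _label_clusters(supra, spec, connectivity)
    c = spec.centers
    labels_at_centers = lab[c[:, 0], c[:, 1], c[:, 2]]
    results = []
    for cid in range(1, n_clusters + 1):
        pos = np.where(labels_at_centers == cid)[0]
        size = len(pos)
        corrected = corrected_p_from_null(null_max, size, null.include_observed)
        results.append(
            ClusterResult(
                cluster_id=cid,
                voxel_indices=c[pos],
                center_positions=pos,
                size_k=size,
                corrected_p=float(corrected),
                mean_auc=float(observed.auc[pos].mean()),
                sem_auc=_sem(observed.auc[pos]),
                mean_sensitivity=float(observed.sensitivity[pos].mean()),
                sem_sensitivity=_sem(observed.sensitivity[pos]),
                mean_specificity=float(observed.specificity[pos].mean()),
                sem_specificity=_sem(observed.specificity[pos]),
            )
        )
    results.sort(key=lambda r: (r.corrected_p, -r.size_k))
    return results


def permutation_z(observed: ClassifierMap, null: PermutationNullStore) -> np.ndarray:
    """Per-centre permutation z: (observed AUC − null mean) / null SD.

    Centres with zero null SD get NaN (excluded from peak search) and a
    warning reporting their count.
    """
    mu = null.null_auc.mean(axis=0)
    sd = null.null_auc.std(axis=0, ddof=1)
    n_degenerate = int((sd == 0).sum())
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} centres have zero null SD; excluded from peaks",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (observed.auc - mu) / sd
    return np.where(sd == 0, np.nan, z)


def find_peak(
    observed: ClassifierMap,
    null: PermutationNullStore,
    clusters: Sequence[ClusterResult],
) -> list[ClusterResult]:
    """Attach the permutation-z peak (deterministic tie-break) to clusters.

    The peak is the argmax of the permutation z within the cluster; ties
    are broken toward the smaller linear voxel index (the order of
    spec.centers, which is C-order over the grid).
    """
    if not clusters:
        raise ValueError("find_peak requires at least one cluster")
    z = permutation_z(observed, null)
    grid = observed.spec.mask.grid
    out = []
    for cl in clusters:
        zc = z[cl.center_positions]
        finite = np.isfinite(zc)
        if not finite.any():
            raise ValueError(f"cluster {cl.cluster_id}: no centre has a valid z")
        zmax = np.nanmax(zc)
        # first index attaining the max -> smallest linear voxel index
        local = int(np.flatnonzero(finite & (zc == zmax))[0])
        pos = int(cl.center_positions[local])
        cl.peak_position = pos
        cl.peak_voxel = observed.spec.centers[pos]
        cl.peak_mm = np.atleast_1d(grid.voxel_to_world(cl.peak_voxel))
        cl.peak_z = float(zmax)
        out.append(cl)
    return out


def cluster_table(
    clusters: Sequence[ClusterResult], modality: str = "", connectivity: int = 26
) -> pd.DataFrame:
    """Report table: one row per cluster, peak coordinates in mm."""
    rows = []
    for cl in clusters:
        mm = cl.peak_mm if cl.peak_mm is not None else (np.nan, np.nan, np.nan)
        rows.append(
            {
                "modality": modality,
                "x_mm": float(mm[0]),
                "y_mm": float(mm[1]),
                "z_mm": float(mm[2]),
                "cluster_size_k": cl.size_k,
                "corrected_p": cl.corrected_p,
                "mean_auc": cl.mean_auc,
                "sem_auc": cl.sem_auc,
                "mean_sensitivity": cl.mean_sensitivity,
                "mean_specificity": cl.mean_specificity,
                "peak_z": cl.peak_z,
                "connectivity": connectivity,
            }
        )
    return pd.DataFrame(rows)
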