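"""Whole-brain searchlight decoding with leave-one-out linear SVM.

A sphere of fixed world-mm radius is centred on every mask voxel (spheres
at mask edges are truncated, never discarded). Within each sphere, the
in-mask voxel values of all subjects form the feature matrix of a linear
soft-margin SVM; each subject's signed decision value comes from the fold
where that subject was held out. The sphere's summary statistics — AUC of
the pooled held-out decision values, sensitivity and specificity of the
sign predictions — are assigned to the centre voxel.

Class convention, fixed globally so decision values are comparable across
searchlights: amusic = +1, control = −1. A positive decision value
predicts amusic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import _svm
from .volumes import AnalysisMask, SubjectFeatureMap, VolumeGrid, stack_masked

POSITIVE_GROUP = "amusic"
NEGATIVE_GROUP = "control"


def labels_to_signs(groups: Sequence[str]) -> np.ndarray:
    """Map group labels to the fixed ±1 convention (amusic = +1)."""
    y = np.empty(len(groups))
    for i, g in enumerate(groups):
        if g == POSITIVE_GROUP:
            y[i] = 1.0
        elif g == NEGATIVE_GROUP:
            y[i] = -1.0
        else:
            raise ValueError(f"unknown group {g!r}")
    return y


@dataclass
class SearchlightSpec:
    """Sphere layout: per mask voxel, the in-mask voxels within radius.

    ``centers`` are all mask voxels (C-order); ``indices``/``indptr`` is a
    CSR layout of each centre's neighbor list, as positions into the mask
    voxel enumeration. Every centre is a member of its own sphere.
    """

    radius_mm: float
    mask: AnalysisMask
    centers: np.ndarray  # (n_centers, 3) voxel indices
    indices: np.ndarray  # flat neighbor positions
    indptr: np.ndarray  # (n_centers + 1,)

    @property
    def n_centers(self) -> int:
        return len(self.centers)

    def neighbors(self, c: int) -> np.ndarray:
        """Neighbor positions (into the mask voxel list) of centre c."""
        return self.indices[self.indptr[c] : self.indptr[c + 1]]

    def sphere_sizes(self) -> np.ndarray:
        return np.diff(self.indptr)


def build_searchlights(mask: AnalysisMask, radius_mm: float = 12.0) -> SearchlightSpec:
    """Construct spheres of ``radius_mm`` (inclusive, world mm) on the mask.

    Valid for any affine: candidate integer offsets o satisfy
    ||A_lin o|| <= radius, and each centre keeps the offsets that land on
    in-mask voxels. Neighbor lists are ordered by distance, then C-order.
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be > 0")
    grid = mask.grid
    lin = grid.affine[:3, :3]
    # bounding box of integer offsets
    step = np.linalg.norm(lin, axis=0).min()
    reach = int(np.floor(radius_mm / step)) + 1
    rng_off = np.arange(-reach, reach + 1)
    oi, oj, ok = np.meshgrid(rng_off, rng_off, rng_off, indexing="ij")
    offsets = np.column_stack([oi.ravel(), oj.ravel(), ok.ravel()])
    d = np.linalg.norm(offsets @ lin.T, axis=1)
    keep = d <= radius_mm + 1e-9
    offsets = offsets[keep]
    d = d[keep]
    order = np.lexsort((offsets[:, 2], offsets[:, 1], offsets[:, 0], d))
    offsets = offsets[order]

    centers = mask.indices
    pos_of_voxel = -np.ones(grid.shape, dtype=np.int64)
    pos_of_voxel[centers[:, 0], centers[:, 1], centers[:, 2]] = np.arange(len(centers))

    shape = np.array(grid.shape)
    indptr = np.zeros(len(centers) + 1, dtype=np.int64)
    chunks = []
    for o in offsets:
        cand = centers + o
        ok_ = np.all((cand >= 0) & (cand < shape), axis=1)
        pos = np.full(len(centers), -1, dtype=np.int64)
        pos[ok_] = pos_of_voxel[cand[ok_, 0], cand[ok_, 1], cand[ok_, 2]]
        chunks.append(pos)
    # chunks[k][c] = neighbor position of offset k for centre c (-1 if absent)
    neigh = np.stack(chunks, axis=1)  # (n_centers, n_offsets)
    valid = neigh >= 0
    indptr[1:] = np.cumsum(valid.sum(axis=1))
    indices = neigh[valid]
    return SearchlightSpec(
        radius_mm=float(radius_mm),
        mask=mask,
        centers=centers,
        indices=np.ascontiguousarray(indices),
        indptr=indptr,
    )


@dataclass
class DecisionValueTable:
    """Held-out decision values for one classification problem."""

    subject_ids: list[str]
    decision_values: np.ndarray
    y_true: np.ndarray  # ±1

    def __post_init__(self):
        self.decision_values = np.asarray(self.decision_values, dtype=float)
        self.y_true = np.asarray(self.y_true, dtype=float)
        if len(self.subject_ids) != len(self.decision_values):
            raise ValueError("one decision value per subject required")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicate subject ids")

    @property
    def y_pred(self) -> np.ndarray:
        """Predicted sign: amusic (+1) iff decision value > 0."""
        return np.where(self.decision_values > 0, 1.0, -1.0)

    def to_frame(self) -> pd.DataFrame:
        conv = {1.0: POSITIVE_GROUP, -1.0: NEGATIVE_GROUP}
        return pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "decision_value": self.decision_values,
                "true_group": [conv[v] for v in self.y_true],
                "predicted_group": [conv[v] for v in self.y_pred],
            }
        )


def loo_decision_values(
    features: np.ndarray,
    labels: Sequence[str] | np.ndarray,
    C: float = 1.0,
    subject_ids: Sequence[str] | None = None,
    feature_scaling: bool = False,
    tol: float = _svm.DEFAULT_TOL,
) -> DecisionValueTable:
    """Leave-one-out decision values of a linear soft-margin SVM.

    No feature scaling is applied by default; with ``feature_scaling`` a
    z-scoring is fit on each training fold only (no leakage into the held
    out subject). Constant feature columns are permitted.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise ValueError("features must be (subjects, voxels)")
    if not np.isfinite(x).all():
        raise ValueError("features contain NaN/inf")
    labels_arr = np.asarray(labels)
    y = labels_arr.astype(float) if labels_arr.dtype.kind in "fib" else labels_to_signs(list(labels))
    n = len(y)
    if x.shape[0] != n:
        raise ValueError("features/labels length mismatch")
    for sign in (1.0, -1.0):
        if (y == sign).sum() < 3:
            raise ValueError(
                "need >= 3 subjects per class so every training fold keeps >= 2"
            )
    if subject_ids is None:
        subject_ids = [f"sub-{i + 1:02d}" for i in range(n)]

    if not feature_scaling:
        k = x @ x.T
        d = _svm.loo_decision_values_gram(k, y, C=C, tol=tol)
    else:
        d = np.empty(n)
        for h in range(n):
            tr = np.r_[0:h, h + 1 : n]
            mu = x[tr].mean(axis=0)
            sd = x[tr].std(axis=0)
            sd[sd == 0] = 1.0
            xt = (x[tr] - mu) / sd
            xh = (x[h] - mu) / sd
            k = xt @ xt.T
            alpha, rho = _svm.svm_fit_gram(k, y[tr], C=C, tol=tol)
            d[h] = float(np.sum(alpha * y[tr] * (xt @ xh))) - rho
    return DecisionValueTable(list(subject_ids), d, y)


def auc_from_decisions(table: DecisionValueTable) -> float:
    """Rank-based AUC of pooled held-out decision values (ties half-credit)."""
    y = table.y_true
    if not ((y > 0).any() and (y < 0).any()):
        raise ValueError("AUC needs both classes present")
    auc, _, _ = _svm._auc_sens_spec(table.decision_values, y)
    return float(auc)


def sens_spec(table: DecisionValueTable) -> tuple[float, float]:
    """(sensitivity, specificity) of the sign predictions."""
    y = table.y_true
    if not ((y > 0).any() and (y < 0).any()):
        raise ValueError("sensitivity/specificity need both classes")
    _, sens, spec = _svm._auc_sens_spec(table.decision_values, y)
    return float(sens), float(spec)


@dataclass
class ClassifierMap:
    """Searchlight summary maps plus the per-centre decision value store."""

    spec: SearchlightSpec
    auc: np.ndarray  # (n_centers,)
    sensitivity: np.ndarray
    specificity: np.ndarray
    decision_values: np.ndarray | None  # (n_centers, n_subjects) or None
    subject_ids: list[str]
    y: np.ndarray
    modality: str = ""

    def volume(self, which: str = "auc") -> np.ndarray:
        """Embed a per-centre statistic into a 3D volume (NaN off-mask)."""
        vec = {"auc": self.auc, "sensitivity": self.sensitivity, "specificity": self.specificity}[which]
        out = np.full(self.spec.mask.grid.shape, np.nan)
        c = self.spec.centers
        out[c[:, 0], c[:, 1], c[:, 2]] = vec
        return out

    def table_at(self, center_index: int) -> DecisionValueTable:
        if self.decision_values is None:
            raise ValueError("decision values were not stored")
        return DecisionValueTable(
            self.subject_ids, self.decision_values[center_index], self.y
        )


def precompute_grams(
    features: np.ndarray, spec: SearchlightSpec
) -> np.ndarray:
    """(n_centers, n, n) Gram stack, one kernel per searchlight sphere."""
    data_t = np.ascontiguousarray(features.T)  # (n_voxels, n_subjects)
    return _svm.grams_from_data(data_t, spec.indices, spec.indptr)


def run_searchlight_grams(
    grams: np.ndarray,
    y: np.ndarray,
    spec: SearchlightSpec,
    subject_ids: list[str],
    C: float = 1.0,
    tol: float = _svm.DEFAULT_TOL,
    store_decisions: bool = True,
    modality: str = "",
) -> ClassifierMap:
    """Searchlight analysis from a precomputed Gram stack (fast path)."""
    auc, sens, spc, dvals = _svm.searchlight_stats(
        grams, np.asarray(y, dtype=float), float(C), float(tol), 1_000_000, store_decisions
    )
    return ClassifierMap(
        spec=spec,
        auc=auc,
        sensitivity=sens,
        specificity=spc,
        decision_values=dvals if store_decisions else None,
        subject_ids=subject_ids,
        y=np.asarray(y, dtype=float),
        modality=modality,
    )


def run_searchlight(
    maps: Sequence[SubjectFeatureMap],
    spec: SearchlightSpec,
    C: float = 1.0,
    feature_scaling: bool = False,
    tol: float = _svm.DEFAULT_TOL,
    store_decisions: bool = True,
) -> ClassifierMap:
    """Full searchlight decoding of subject maps on a sphere spec.

    Deterministic given its inputs. With ``feature_scaling`` the slower
    per-fold path is used (training-fold z-scoring cannot be expressed on
    a shared Gram matrix).
    """
    features = stack_masked(maps, spec.mask)
    y = labels_to_signs([m.group for m in maps])
    for sign, name in ((1.0, POSITIVE_GROUP), (-1.0, NEGATIVE_GROUP)):
        if (y == sign).sum() < 3:
            raise ValueError(f"need >= 3 {name} subjects")
    ids = [m.subject_id for m in maps]
    modality = maps[0].modality if maps else ""
    if not feature_scaling:
        grams = precompute_grams(features, spec)
        return run_searchlight_grams(
            grams, y, spec, ids, C=C, tol=tol,
            store_decisions=store_decisions, modality=modality,
        )
    n_centers = spec.n_centers
    auc = np.empty(n_centers)
    sens = np.empty(n_centers)
    spc = np.empty(n_centers)
    dvals = np.empty((n_centers, len(y))) if store_decisions else None
    for c in range(n_centers):
        try:
            tbl = loo_decision_values(
                features[:, spec.neighbors(c)], y, C=C,
                subject_ids=ids, feature_scaling=True, tol=tol,
            )
        except Exception as exc:  # noqa: BLE001 - annotate the offending centre
            raise RuntimeError(f"searchlight centre {c} failed: {exc}") from exc
        auc[c] = auc_from_decisions(tbl)
        sens[c], spc[c] = sens_spec(tbl)
        if dvals is not None:
            dvals[c] = tbl.decision_values
    return ClassifierMap(
        spec=spec, auc=auc, sensitivity=sens, specificity=spc,
        decision_values=dvals, subject_ids=ids, y=y, modality=modality,
    )
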