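"""Voxel grids, analysis masks, sphere geometry, and volume/manifest I/O.

Conventions used throughout the package: voxel indices are 0-based;
world coordinates are millimetres in the affine's (MNI-like) frame; all
radii are in mm and compared inclusively (a voxel whose centre lies
exactly on the sphere surface belongs to the sphere). NaN is permitted
outside an analysis mask and never read; NaN inside the mask is rejected
at load time.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence
import warnings

import numpy as np
import pandas as pd
import nibabel as nib
from scipy import ndimage

GROUPS = ("amusic", "control")
MODALITIES = (
    "wm",
    "gm",
    "rsfc_left_seed",
    "rsfc_right_seed",
    "pitch_memory",
    "pitch_localizer",
    "verbal_memory",
)


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D sampling grid: array shape plus a voxel-to-world affine.

    The affine maps 0-based voxel indices (i, j, k, 1) to world mm, as in
    the NIfTI convention. ``voxel_size_mm`` is derived from the column
    norms of the affine's linear part.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self):
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {aff.shape}")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine linear part is singular")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "affine", aff)

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @classmethod
    def isotropic(cls, shape: Sequence[int], voxel_size_mm: float) -> "VolumeGrid":
        """Axis-aligned isotropic grid with the world origin at the grid centre."""
        shape = tuple(int(s) for s in shape)
        aff = np.eye(4)
        aff[:3, :3] *= float(voxel_size_mm)
        aff[:3, 3] = -(np.array(shape) - 1) / 2.0 * float(voxel_size_mm)
        return cls(shape, aff)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return (ijk @ self.affine[:3, :3].T + self.affine[:3, 3]).squeeze()

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return (xyz @ inv[:3, :3].T + inv[:3, 3]).squeeze()

    def matches(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


@dataclass
class AnalysisMask:
    """Binary analysis mask on a grid, with a free-text provenance note."""

    data: np.ndarray
    grid: VolumeGrid
    provenance: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.data.shape} != grid shape {self.grid.shape}"
            )
        if not self.data.any():
            raise ValueError("analysis mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def indices(self) -> np.ndarray:
        """(N, 3) int array of in-mask voxel indices, C-order sorted."""
        return np.argwhere(self.data)

    def world_coords(self) -> np.ndarray:
        return np.atleast_2d(self.grid.voxel_to_world(self.indices))


@dataclass
class SubjectFeatureMap:
    """One subject's 3D feature map (a brain map entering the decoder)."""

    subject_id: str
    group: str
    modality: str
    values: np.ndarray
    grid: VolumeGrid
    site: str | None = None

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"{self.subject_id}: values shape {self.values.shape} "
                f"!= grid shape {self.grid.shape}"
            )

    def check_finite(self, mask: AnalysisMask) -> None:
        if not np.isfinite(self.values[mask.data]).all():
            raise ValueError(
                f"subject {self.subject_id}: non-finite values inside the mask"
            )


# ---------------------------------------------------------------------------
# mask construction


def gm_group_mask(
    gm_probability_maps: Iterable[np.ndarray],
    wm_mean: np.ndarray,
    csf_mean: np.ndarray,
    grid: VolumeGrid,
    threshold: float = 0.3,
) -> AnalysisMask:
    """Group gray-matter mask from averaged tissue probability maps.

    A voxel enters the mask when the average gray-matter probability
    exceeds ``threshold`` (strictly) and exceeds both the average
    white-matter and CSF probabilities, the standard recipe for a
    gray-matter analysis mask from VBM-style segmentations.
    """
    gm_maps = [np.asarray(g, dtype=float) for g in gm_probability_maps]
    gm_mean = np.mean(gm_maps, axis=0)
    wm_mean = np.asarray(wm_mean, dtype=float)
    csf_mean = np.asarray(csf_mean, dtype=float)
    for name, arr in (("gm", gm_mean), ("wm", wm_mean), ("csf", csf_mean)):
        if arr.shape != grid.shape:
            raise ValueError(f"{name} mean shape {arr.shape} != grid {grid.shape}")
        if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
            raise ValueError(f"{name} probabilities outside [0, 1]")
    mask = (gm_mean > threshold) & (gm_mean > wm_mean) & (gm_mean > csf_mean)
    if not mask.any():
        raise ValueError(
            "gray-matter group mask is empty; review the probability maps "
            f"and the threshold ({threshold})"
        )
    return AnalysisMask(mask, grid, provenance=f"gm_group_mask(threshold={threshold})")


def erode_mask(mask: AnalysisMask, voxels_per_axis: int = 3) -> AnalysisMask:
    """Binary erosion with a cube of half-width ``voxels_per_axis`` per axis.

    Erosion by 0 is the identity. An erosion that empties the mask emits a
    warning (with the voxel count) rather than an error, since callers may
    legitimately probe aggressive erosions.
    """
    k = int(voxels_per_axis)
    if k < 0:
        raise ValueError("voxels_per_axis must be >= 0")
    if k == 0:
        return AnalysisMask(mask.data.copy(), mask.grid, mask.provenance)
    structure = np.ones((2 * k + 1,) * 3, dtype=bool)
    eroded = ndimage.binary_erosion(mask.data, structure=structure, border_value=0)
    if not eroded.any():
        warnings.warn(
            f"erosion by {k} voxels/axis emptied the mask "
            f"({mask.n_voxels} voxels before erosion)",
            stacklevel=2,
        )
        out = AnalysisMask.__new__(AnalysisMask)
        out.data = eroded
        out.grid = mask.grid
        out.provenance = f"{mask.provenance} eroded_by={k} (EMPTY)"
        return out
    return AnalysisMask(eroded, mask.grid, f"{mask.provenance} eroded_by={k}")


def sphere_indices(
    center_mm: Sequence[float],
    radius_mm: float,
    grid: VolumeGrid,
    mask: AnalysisMask,
) -> np.ndarray:
    """In-mask voxels whose centre lies within ``radius_mm`` of ``center_mm``.

    Distances are Euclidean in world mm and the comparison is inclusive.
    Returns an (N, 3) index array; raises if the sphere misses the mask
    entirely (e.g. a connectivity seed specified outside the brain).
    """
    if radius_mm < 0:
        raise ValueError("radius_mm must be >= 0")
    center = np.asarray(center_mm, dtype=float)
    coords = mask.world_coords()
    d2 = np.sum((coords - center) ** 2, axis=1)
    keep = d2 <= float(radius_mm) ** 2 + 1e-9
    if not keep.any():
        raise ValueError(
            f"sphere at {center.tolist()} mm (radius {radius_mm} mm) contains "
            "no in-mask voxels; the seed lies outside the mask"
        )
    return mask.indices[keep]


# ---------------------------------------------------------------------------
# NIfTI / manifest I/O

MANIFEST_COLUMNS = ("subject_id", "group", "modality", "path")


def save_volume(path: str | Path, values: np.ndarray, grid: VolumeGrid) -> None:
    values = np.asarray(values)
    dtype = np.uint8 if values.dtype == bool else np.float32
    img = nib.Nifti1Image(values.astype(dtype), grid.affine)
    nib.save(img, str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, VolumeGrid]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4:
        grid = VolumeGrid(data.shape[:3], img.affine)
    else:
        grid = VolumeGrid(data.shape, img.affine)
    return data, grid


def load_mask(path: str | Path, provenance: str = "") -> AnalysisMask:
    data, grid = load_volume(path)
    return AnalysisMask(data > 0, grid, provenance or str(path))


def read_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    return manifest


def read_subject_maps(
    paths: Sequence[str | Path] | None,
    manifest: pd.DataFrame,
    mask: AnalysisMask | None = None,
) -> list[SubjectFeatureMap]:
    """Load per-subject volumes listed in a manifest, in manifest order.

    ``paths`` may be None to use the manifest's ``path`` column. All
    volumes must share one grid; a volume on a different grid is rejected
    with both shapes/affines in the message. When a mask is supplied,
    values inside it must be finite (NaN outside is allowed and ignored).
    """
    if paths is None:
        paths = list(manifest["path"])
    paths = [Path(p) for p in paths]
    if len(paths) != len(manifest):
        raise ValueError(
            f"{len(paths)} paths but {len(manifest)} manifest rows"
        )
    by_id = dict(zip(manifest["subject_id"], range(len(manifest))))
    maps: list[SubjectFeatureMap] = []
    ref_grid: VolumeGrid | None = None
    for path, (_, row) in zip(paths, manifest.iterrows()):
        sid = str(row["subject_id"])
        if sid not in by_id:
            raise ValueError(f"subject {sid!r} not present in manifest")
        values, grid = load_volume(path)
        if ref_grid is None:
            ref_grid = grid
        elif not grid.matches(ref_grid):
            raise ValueError(
                f"grid mismatch for {path}: shape {grid.shape} affine\n"
                f"{grid.affine}\nvs reference shape {ref_grid.shape} affine\n"
                f"{ref_grid.affine}"
            )
        m = SubjectFeatureMap(
            subject_id=sid,
            group=str(row["group"]),
            modality=str(row["modality"]),
            values=values,
            grid=grid,
            site=str(row["site"]) if "site" in row and pd.notna(row.get("site")) else None,
        )
        if mask is not None:
            if not mask.grid.matches(grid):
                raise ValueError(
                    f"mask grid {mask.grid.shape} does not match volume grid "
                    f"{grid.shape} for {path}"
                )
            m.check_finite(mask)
        maps.append(m)
    return maps


def stack_masked(maps: Sequence[SubjectFeatureMap], mask: AnalysisMask) -> np.ndarray:
    """(n_subjects, n_mask_voxels) feature matrix in mask C-order."""
    sel = mask.data
    out = np.empty((len(maps), int(sel.sum())))
    for i, m in enumerate(maps):
        if not m.grid.matches(mask.grid):
            raise ValueError(f"map {m.subject_id} is not on the mask grid")
        out[i] = m.values[sel]
    if not np.isfinite(out).all():
        bad = [maps[i].subject_id for i in np.where(~np.isfinite(out).all(axis=1))[0]]
        raise ValueError(f"non-finite values inside the mask for subjects {bad}")
    return out
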