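"""Synthetic cohorts with the statistical structure the decoder assumes.

The generator emulates a two-group neuroimaging case-control design
(n = 18 per group by default, mirroring a typical amusia cohort): each
subject carries a latent symptom-severity variable s ~ Normal(mu_group, 1)
whose group means differ by an effect size delta; the subject's brain map
is smooth Gaussian noise (unit voxel variance) plus s times a fixed
multivariate weight pattern W supported on a sphere at a known
coordinate; behavioral scores are affine functions of s plus noise. A
"verbal" no-effect modality (delta = 0, zero behavior coupling) serves as
the negative control.

Severity drives both the discriminative map pattern and behavior, so the
full chain — decoding, permutation inference, decision-value/behavior
correlation — can be tested against ground truth.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import AnalysisMask, SubjectFeatureMap, VolumeGrid, sphere_indices

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: group means used for the MBEA-like diagnostic score (max 30, cut-off 23)
_MBEA_MEANS = {"amusic": 20.9, "control": 26.7}
_MBEA_SDS = {"amusic": 1.5, "control": 1.4}
#: lognormal-ish pitch-discrimination thresholds in semitones (worse = larger)
_PDT_LOGMEAN = {"amusic": -0.45, "control": -1.65}
_PDT_LOGSD = {"amusic": 0.75, "control": 0.55}


@dataclass
class SyntheticCohortConfig:
    """Study-design parameters for one synthetic cohort.

    effect_size is the shift (in SD units of latent severity) between the
    amusic and control group means; the no-effect modalities force it to
    zero. behavior_coupling is the slope of the pitch-memory score on
    latent severity; the synthetic score is a severity-aligned impairment
    index (higher = worse performance), so the default coupling is
    positive and the one-sided brain-behavior permutation test points in
    its conventional direction.
    """

    n_per_group: int = 18
    grid: VolumeGrid = field(default_factory=lambda: VolumeGrid.isotropic((30, 36, 30), 3.0))
    roi_center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    roi_radius_mm: float = 12.0
    effect_size: float = 2.0
    pattern_seed: int = 2001
    noise_seed: int = 2002
    behavior_seed: int = 2003
    smoothness_fwhm_mm: float = 6.0
    noise_amplitude: float = 1.0
    behavior_intercept: float = 2.5
    behavior_coupling: float = 0.4
    behavior_noise_sd: float = 0.45
    modality: str = "pitch_localizer"
    site_effect: float = 0.0
    mask: AnalysisMask | None = None

    def __post_init__(self):
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.behavior_noise_sd <= 0:
            raise ValueError("behavior_noise_sd must be > 0")
        if min(self.grid.shape) < 2:
            raise ValueError(f"degenerate grid shape {self.grid.shape}")
        if self.n_per_group < 3:
            raise ValueError("need at least 3 subjects per group")
        if self.modality == "verbal_memory":
            # negative-control modality: no group effect, no behavior coupling
            self.effect_size = 0.0
            self.behavior_coupling = 0.0


@dataclass
class BehaviorRecord:
    """One subject's behavioral scores (synthetic cohorts carry the latent)."""

    subject_id: str
    group: str
    mbea_mean: float
    pdt_semitones: float
    pitch_memory_score: float
    severity_latent: float

    def __post_init__(self):
        if not 0.0 <= self.mbea_mean <= 30.0:
            raise ValueError(f"mbea_mean {self.mbea_mean} outside [0, 30]")
        if self.pdt_semitones <= 0:
            raise ValueError("pdt_semitones must be > 0")
        if (self.group == "amusic") != (self.mbea_mean < 23.0):
            raise ValueError(
                f"{self.subject_id}: group {self.group} inconsistent with "
                f"MBEA {self.mbea_mean} (amusic iff < 23)"
            )


@dataclass
class CohortTruth:
    """Ground-truth sidecar: where the signal is and how it was made."""

    roi_center_mm: tuple[float, float, float]
    roi_radius_mm: float
    roi_voxels: np.ndarray
    weights: np.ndarray  # unit-norm pattern over roi_voxels
    seeds: dict
    effect_size: float

    @property
    def weight_checksum(self) -> str:
        return hashlib.sha256(np.ascontiguousarray(self.weights).tobytes()).hexdigest()[:16]


def default_mask(grid: VolumeGrid) -> AnalysisMask:
    """Ellipsoidal 'brain' inscribed in the grid (crude but convex and 3D)."""
    shape = np.array(grid.shape, dtype=float)
    center = (shape - 1) / 2.0
    semi = np.maximum(shape / 2.0 - 0.5, 0.5)
    ii, jj, kk = np.indices(grid.shape)
    r2 = (
        ((ii - center[0]) / semi[0]) ** 2
        + ((jj - center[1]) / semi[1]) ** 2
        + ((kk - center[2]) / semi[2]) ** 2
    )
    return AnalysisMask(r2 <= 1.0, grid, provenance="synthetic ellipsoid mask")


def smooth_unit_noise(
    shape: Sequence[int],
    voxel_size_mm: np.ndarray,
    fwhm_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """White Gaussian noise convolved with a Gaussian kernel, unit variance.

    Wrap-around boundary keeps the field stationary, so one global
    standard deviation rescales to unit marginal voxel variance.
    """
    field_ = rng.standard_normal(tuple(shape))
    if fwhm_mm > 0:
        sigma_vox = fwhm_mm * _FWHM_TO_SIGMA / np.asarray(voxel_size_mm, dtype=float)
        field_ = ndimage.gaussian_filter(field_, sigma=sigma_vox, mode="wrap")
    sd = field_.std()
    if sd > 0:
        field_ = field_ / sd
    return field_


def _severity(config: SyntheticCohortConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_per_group
    s = rng.standard_normal(2 * n)
    s[:n] += config.effect_size  # amusics first, shifted up by delta
    return s


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, low: float, high: float, size: int
) -> np.ndarray:
    out = np.empty(size)
    for i in range(size):
        for _ in range(1000):
            x = rng.normal(mean, sd)
            if low <= x < high:
                out[i] = x
                break
        else:
            out[i] = np.clip(x, low, min(high - 1e-6, high))
    return out


def generate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[list[SubjectFeatureMap], list[BehaviorRecord], AnalysisMask, CohortTruth]:
    """Generate index-aligned subject maps, behavior records, mask and truth.

    Identical configs (including seeds) produce bit-identical outputs.
    Changing only ``noise_seed`` leaves the pattern W and the ROI truth
    unchanged.
    """
    grid = config.grid
    mask = config.mask if config.mask is not None else default_mask(grid)
    if not mask.grid.matches(grid):
        raise ValueError("mask grid does not match config grid")

    roi_voxels = sphere_indices(config.roi_center_mm, config.roi_radius_mm, grid, mask)

    pattern_rng = np.random.default_rng(config.pattern_seed)
    w = pattern_rng.standard_normal(len(roi_voxels))
    w /= np.linalg.norm(w)

    noise_rng = np.random.default_rng(config.noise_seed)
    behavior_rng = np.random.default_rng(config.behavior_seed)

    n = config.n_per_group
    groups = ["amusic"] * n + ["control"] * n
    severity = _severity(config, behavior_rng)

    maps: list[SubjectFeatureMap] = []
    riter = roi_voxels.T
    for i, group in enumerate(groups):
        vol = config.noise_amplitude * smooth_unit_noise(
            grid.shape, grid.voxel_size_mm, config.smoothness_fwhm_mm, noise_rng
        )
        vol[riter[0], riter[1], riter[2]] += severity[i] * w
        if config.site_effect != 0.0 and i % 2 == 1:
            vol += config.site_effect
        maps.append(
            SubjectFeatureMap(
                subject_id=f"sub-{i + 1:02d}",
                group=group,
                modality=config.modality,
                values=vol,
                grid=grid,
                site=("siteB" if (config.site_effect != 0.0 and i % 2 == 1) else "siteA"),
            )
        )

    records: list[BehaviorRecord] = []
    for i, group in enumerate(groups):
        mbea_lo, mbea_hi = (0.0, 23.0) if group == "amusic" else (23.0, 30.0)
        mbea = _truncated_normal(
            behavior_rng, _MBEA_MEANS[group], _MBEA_SDS[group], mbea_lo, mbea_hi, 1
        )[0]
        pdt = float(
            np.exp(behavior_rng.normal(_PDT_LOGMEAN[group], _PDT_LOGSD[group]))
        )
        score = (
            config.behavior_intercept
            + config.behavior_coupling * severity[i]
            + behavior_rng.normal(0.0, config.behavior_noise_sd)
        )
        records.append(
            BehaviorRecord(
                subject_id=f"sub-{i + 1:02d}",
                group=group,
                mbea_mean=float(mbea),
                pdt_semitones=pdt,
                pitch_memory_score=float(score),
                severity_latent=float(severity[i]),
            )
        )

    truth = CohortTruth(
        roi_center_mm=tuple(config.roi_center_mm),
        roi_radius_mm=config.roi_radius_mm,
        roi_voxels=roi_voxels,
        weights=w,
        seeds={
            "pattern_seed": config.pattern_seed,
            "noise_seed": config.noise_seed,
            "behavior_seed": config.behavior_seed,
        },
        effect_size=config.effect_size,
    )
    return maps, records, mask, truth


def behavior_table(records: Sequence[BehaviorRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


# ---------------------------------------------------------------------------
# resting-state time series


def generate_rs_timeseries(
    config: SyntheticCohortConfig,
    coupling: dict[str, float],
    n_volumes: int = 280,
    tr_s: float = 2.382,
    seed_center_mm: Sequence[float] = (0.0, 0.0, 0.0),
    seed_radius_mm: float = 5.0,
    target_center_mm: Sequence[float] | None = None,
    target_radius_mm: float = 9.0,
    nuisance_amplitude: float = 0.5,
) -> tuple[list[dict], AnalysisMask, dict]:
    """Per-subject 4D resting scans with seed/target coupling and nuisance mixing.

    Seed-region voxels share a latent signal; target ("DMN") voxels carry
    that signal scaled by the subject's group coupling plus independent
    noise; nuisance series (6 motion + WM + CSF) are mixed linearly into
    every voxel so nuisance regression has something real to remove.

    Returns (subjects, mask, truth) where each subject dict carries
    ``bold`` (x, y, z, t), ``nuisance`` (DataFrame, t x 8), group and id.
    """
    if n_volumes < 20:
        raise ValueError("n_volumes must be >= 20")
    grid = config.grid
    mask = config.mask if config.mask is not None else default_mask(grid)
    if target_center_mm is None:
        # opposite corner of the mask bounding box from the seed
        extent = (np.array(grid.shape) - 1) * grid.voxel_size_mm
        target_center_mm = tuple(np.asarray(seed_center_mm) + extent * 0.25)

    seed_vox = sphere_indices(seed_center_mm, seed_radius_mm, grid, mask)
    target_vox = sphere_indices(target_center_mm, target_radius_mm, grid, mask)
    seed_set = {tuple(v) for v in seed_vox}
    target_vox = np.array([v for v in target_vox if tuple(v) not in seed_set])
    if len(target_vox) == 0:
        raise ValueError("target sphere lies entirely inside the seed sphere")

    rng = np.random.default_rng(config.noise_seed)
    n = config.n_per_group
    groups = ["amusic"] * n + ["control"] * n
    subjects = []
    nuis_cols = [f"motion_{k}" for k in range(1, 7)] + ["wm", "csf"]
    for i, group in enumerate(groups):
        c = float(coupling[group])
        latent = rng.standard_normal(n_volumes)
        nuis = rng.standard_normal((n_volumes, 8))
        bold = rng.standard_normal(grid.shape + (n_volumes,))
        loadings = nuisance_amplitude * rng.standard_normal((8,))
        bold += (nuis @ loadings).reshape((1, 1, 1, n_volumes))
        for v in seed_vox:
            bold[v[0], v[1], v[2], :] += 2.0 * latent
        scale = c / np.sqrt(max(1e-12, 1.0 - min(c**2, 0.99)))
        for v in target_vox:
            bold[v[0], v[1], v[2], :] += scale * latent
        subjects.append(
            {
                "subject_id": f"sub-{i + 1:02d}",
                "group": group,
                "bold": bold,
                "nuisance": pd.DataFrame(nuis, columns=nuis_cols),
                "tr_s": tr_s,
            }
        )
    truth = {
        "seed_voxels": seed_vox,
        "target_voxels": target_vox,
        "coupling": dict(coupling),
    }
    return subjects, mask, truth


# ---------------------------------------------------------------------------
# sparse-sampling localizer scans


def generate_localizer_scans(
    design,
    true_hrf: np.ndarray,
    tone_noise_contrast_map: np.ndarray,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Sparse-design auditory scans with a known tones-vs-noise preference.

    Each scan is a condition-amplitude pattern weighted by the true HRF at
    the scan's post-onset lag, plus white noise. The supplied 3D contrast
    map sets each voxel's (tones − noise) preference summed over the two
    frequency ranges; fitting the matching GLM recovers it.

    design: a ``SparseDesign`` (see the first-level module).
    """
    from .firstlevel import condition_regressors

    true_hrf = np.asarray(true_hrf, dtype=float)
    cmap = np.asarray(tone_noise_contrast_map, dtype=float)
    regs = condition_regressors(design, true_hrf)  # dict cond -> (n_scans,)
    conds = [c for c in regs if c != "silence"]
    if not conds:
        raise ValueError("design contains no non-silence condition blocks")
    rng = np.random.default_rng(seed)
    n_scans = design.n_scans
    scans = rng.standard_normal(cmap.shape + (n_scans,)) * float(noise_sd)
    # tones carry +contrast/2 per frequency range, noises 0, so
    # (LT - LN) + (HT - HN) equals the supplied map
    amp = {
        "low_tones": cmap / 2.0,
        "high_tones": cmap / 2.0,
        "low_noise": np.zeros_like(cmap),
        "high_noise": np.zeros_like(cmap),
    }
    for cond in conds:
        a = amp.get(cond)
        if a is None:
            continue
        scans += a[..., None] * regs[cond][None, None, None, :]
    return scans
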