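"""First-level map construction from time series.

Two map types feed the group decoder: seed-based resting-state
connectivity Z-maps (Fisher r-to-z of partial correlations after
nuisance regression and band-pass filtering) and sparse-sampling GLM
contrast z-maps with an FIR ("candlestick") estimate of the hemodynamic
response. Both follow ordinary least squares throughout; the t-to-z
conversion uses the exact CDF mapping because sparse designs leave few
residual degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

CONDITIONS = ("low_tones", "high_tones", "low_noise", "high_noise", "silence")


@dataclass
class SparseDesign:
    """One-scan-per-stimulus sparse design with block structure.

    ``block_onset_scans[b]`` is the scan index at which block b starts;
    ``condition_per_block[b]`` its condition; ``scans_per_block`` stimuli
    (hence scans) follow each onset contiguously. ``candlestick_lags`` is
    how many post-onset scans the FIR model assigns a separate regressor.
    """

    n_scans: int
    block_onset_scans: np.ndarray
    condition_per_block: list[str]
    scans_per_block: int = 6
    candlestick_lags: int = 6
    tr_s: float = 3.4

    def __post_init__(self):
        self.block_onset_scans = np.asarray(self.block_onset_scans, dtype=int)
        if self.candlestick_lags < 1:
            raise ValueError("candlestick_lags must be >= 1")
        if len(self.block_onset_scans) != len(self.condition_per_block):
            raise ValueError("one condition per block onset required")
        unknown = set(self.condition_per_block) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions: {sorted(unknown)}")

    @classmethod
    def blocked(
        cls,
        n_blocks_per_condition: int = 5,
        scans_per_block: int = 6,
        candlestick_lags: int = 6,
        order_seed: int = 0,
        conditions: Sequence[str] = CONDITIONS,
    ) -> "SparseDesign":
        """Pseudorandom blocked design (default: five blocks per condition,
        including silence baseline blocks, six scans per block)."""
        rng = np.random.default_rng(order_seed)
        blocks = [c for c in conditions for _ in range(n_blocks_per_condition)]
        order = rng.permutation(len(blocks))
        condition_per_block = [blocks[k] for k in order]
        onsets = np.arange(len(blocks)) * scans_per_block
        return cls(
            n_scans=len(blocks) * scans_per_block,
            block_onset_scans=onsets,
            condition_per_block=condition_per_block,
            scans_per_block=scans_per_block,
            candlestick_lags=candlestick_lags,
        )


@dataclass
class HRFEstimate:
    """FIR estimate of the hemodynamic response over candlestick lags."""

    weights: np.ndarray
    n_voxels_used: int
    region_note: str = ""

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.isfinite(self.weights).all():
            raise ValueError("HRF weights must be finite")


# ---------------------------------------------------------------------------
# band-pass filtering


def bandpass(
    ts: np.ndarray, tr_s: float, low_hz: float = 0.01, high_hz: float = 0.08
) -> np.ndarray:
    """Zero-phase frequency-domain band-pass of a (time x voxels) array.

    A hard FFT mask keeps bins with low_hz <= f <= high_hz; DC is always
    removed. Pass-band sinusoids retain their amplitude, stop-band ones
    are suppressed to the leakage floor.
    """
    ts = np.asarray(ts, dtype=float)
    single = ts.ndim == 1
    if single:
        ts = ts[:, None]
    n = ts.shape[0]
    nyquist = 1.0 / (2.0 * tr_s)
    if high_hz >= nyquist:
        raise ValueError(
            f"high_hz {high_hz} must be below the Nyquist frequency {nyquist:.4f} "
            f"for TR {tr_s} s"
        )
    freqs = np.fft.rfftfreq(n, d=tr_s)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    keep[0] = False
    spec = np.fft.rfft(ts, axis=0)
    spec[~keep] = 0.0
    out = np.fft.irfft(spec, n=n, axis=0)
    return out[:, 0] if single else out


# ---------------------------------------------------------------------------
# nuisance regression and seed connectivity


def _residualize(y: np.ndarray, nuisance: np.ndarray | None) -> np.ndarray:
    """OLS residuals of columns of y on [intercept, nuisance]."""
    n = y.shape[0]
    x = np.ones((n, 1)) if nuisance is None else np.column_stack(
        [np.ones(n), np.asarray(nuisance, dtype=float)]
    )
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def seed_connectivity_map(
    ts4d: np.ndarray,
    seed_voxels: np.ndarray,
    nuisance: np.ndarray | None,
    mask,
) -> np.ndarray:
    """Seed-based connectivity Z-map from a (x, y, z, t) array.

    The seed series is the mean over seed voxels; the nuisance series
    (plus intercept) are regressed out of the seed and of every voxel
    series (partial correlation); the Pearson correlation of the
    residuals is Fisher-transformed, z = atanh(r), with r clamped to
    ±(1 − 1e-7). Voxels outside the mask are NaN; constant voxel series
    yield z = 0 with a single warning reporting their count.
    """
    ts4d = np.asarray(ts4d, dtype=float)
    n_t = ts4d.shape[-1]
    seed_voxels = np.asarray(seed_voxels, dtype=int)
    if len(seed_voxels) == 0:
        raise ValueError("seed voxel set is empty")
    k = 0 if nuisance is None else np.asarray(nuisance).shape[1]
    if n_t < 2 * (k + 2):
        raise ValueError(
            f"need at least {2 * (k + 2)} time points for {k} nuisance "
            f"regressors, got {n_t}"
        )

    sel = mask.data
    vox_ts = ts4d[sel]  # (n_vox, t)
    seed_ts = ts4d[seed_voxels[:, 0], seed_voxels[:, 1], seed_voxels[:, 2], :].mean(axis=0)

    resid = _residualize(
        np.column_stack([seed_ts, vox_ts.T]), nuisance
    )
    seed_r = resid[:, 0]
    vox_r = resid[:, 1:]

    seed_sd = seed_r.std()
    vox_sd = vox_r.std(axis=0)
    n_constant = int((vox_sd == 0).sum())
    if seed_sd == 0:
        raise ValueError("seed series is constant after nuisance regression")
    if n_constant:
        warnings.warn(
            f"{n_constant} constant voxel series set to z = 0", stacklevel=2
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (vox_r * seed_r[:, None]).mean(axis=0) / (vox_sd * seed_sd)
    r = np.where(vox_sd == 0, 0.0, r)
    r = np.clip(r, -(1 - 1e-7), 1 - 1e-7)
    z = np.arctanh(r)

    out = np.full(mask.grid.shape, np.nan)
    out[sel] = z
    return out


# ---------------------------------------------------------------------------
# FIR HRF estimation


def candlestick_matrix(design: SparseDesign) -> np.ndarray:
    """(n_scans, lags) indicator matrix: 1 when a scan sits a fixed number
    of scans after any stimulus block onset (silence blocks excluded)."""
    x = np.zeros((design.n_scans, design.candlestick_lags))
    for onset, cond in zip(design.block_onset_scans, design.condition_per_block):
        if cond == "silence":
            continue
        for lag in range(design.candlestick_lags):
            t = onset + lag
            if t < design.n_scans:
                x[t, lag] = 1.0
    return x


def condition_regressors(design: SparseDesign, hrf: np.ndarray) -> dict[str, np.ndarray]:
    """Per-condition regressors: HRF weights placed at each block's lags."""
    hrf = np.asarray(hrf, dtype=float)
    regs = {c: np.zeros(design.n_scans) for c in set(design.condition_per_block)}
    for onset, cond in zip(design.block_onset_scans, design.condition_per_block):
        for lag in range(len(hrf)):
            t = onset + lag
            if t < design.n_scans:
                regs[cond][t] += hrf[lag]
    return regs


def estimate_hrf_fir(
    scans: np.ndarray,
    design: SparseDesign,
    region_voxels: np.ndarray,
    top_fraction: float = 0.10,
) -> HRFEstimate:
    """FIR (candlestick) HRF estimate from the best-explained region voxels.

    Each region voxel's series is fit by OLS on [intercept, candlesticks];
    voxels are ranked by the candlestick R² and the FIR weights averaged
    over the best ``top_fraction`` (at least one voxel).
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    region_voxels = np.asarray(region_voxels, dtype=int)
    cand = candlestick_matrix(design)
    if np.linalg.matrix_rank(cand) < cand.shape[1]:
        counts = cand.sum(axis=0)
        raise ValueError(
            f"candlestick design rank-deficient (per-lag scan counts {counts.tolist()})"
        )
    y = scans[region_voxels[:, 0], region_voxels[:, 1], region_voxels[:, 2], :].T
    x = np.column_stack([np.ones(cand.shape[0]), cand])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta
    resid = y - fitted
    y_c = y - y.mean(axis=0)
    tss = (y_c**2).sum(axis=0)
    rss = (resid**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(tss > 0, 1.0 - rss / tss, 0.0)
    n_used = int(np.ceil(top_fraction * len(region_voxels)))
    top = np.argsort(-r2, kind="stable")[:n_used]
    weights = beta[1:, top].mean(axis=1)
    return HRFEstimate(
        weights=weights,
        n_voxels_used=n_used,
        region_note=f"top {top_fraction:.0%} of {len(region_voxels)} region voxels",
    )


# ---------------------------------------------------------------------------
# GLM contrast z-maps


def _t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Exact-CDF mapping of t statistics to z scores, symmetric in the tails."""
    t = np.asarray(t, dtype=float)
    sf = stats.t.sf(np.abs(t), df)
    sf = np.clip(sf, 1e-300, 1.0)
    return np.sign(t) * stats.norm.isf(sf)


def wm_principal_components(
    scans: np.ndarray, wm_voxels: np.ndarray, n_pcs: int = 10
) -> np.ndarray:
    """First principal-component time series of white-matter voxel responses.

    Series are centred and variance-normalized per voxel before the SVD so
    a few high-variance voxels cannot dominate the components.
    """
    wm_voxels = np.asarray(wm_voxels, dtype=int)
    w = scans[wm_voxels[:, 0], wm_voxels[:, 1], wm_voxels[:, 2], :].T.astype(float)
    w = w - w.mean(axis=0)
    sd = w.std(axis=0)
    sd[sd == 0] = 1.0
    w = w / sd
    u, s, _ = np.linalg.svd(w, full_matrices=False)
    return u[:, :n_pcs] * s[:n_pcs]


def glm_contrast_zmap(
    scans: np.ndarray,
    design: SparseDesign,
    hrf: HRFEstimate,
    wm_voxels: np.ndarray,
    mask,
    n_pcs: int = 10,
    use_t_cdf: bool = True,
    return_contrast: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Tones-minus-noise contrast z-map from a sparse-design run.

    Condition regressors place the FIR HRF at each block's lags; nuisance
    regressors are an intercept, a linear trend, and the first ``n_pcs``
    white-matter principal components. Per voxel, OLS estimates the four
    condition betas; the contrast (LT − LN) + (HT − HN) is tested with the
    residual degrees of freedom and mapped to z (exact t CDF by default,
    large-sample normal approximation with ``use_t_cdf=False``).
    """
    conds = ("low_tones", "low_noise", "high_tones", "high_noise")
    present = set(design.condition_per_block)
    missing = [c for c in conds if c not in present]
    if missing:
        raise ValueError(f"design lacks condition blocks for {missing}")
    n_scans = design.n_scans
    if n_pcs >= n_scans:
        raise ValueError("n_pcs must be below the number of scans")

    regs = condition_regressors(design, hrf.weights)
    cond_x = np.column_stack([regs[c] for c in conds])
    if np.allclose(cond_x.std(axis=0), 0.0):
        raise ValueError("condition regressors have no variance (silence-only design?)")
    trend = np.linspace(-1, 1, n_scans)
    pcs = wm_principal_components(scans, wm_voxels, n_pcs) if n_pcs > 0 else np.empty((n_scans, 0))
    x = np.column_stack([cond_x, np.ones(n_scans), trend, pcs])
    rank = np.linalg.matrix_rank(x)
    df = n_scans - rank
    if df <= 0:
        raise ValueError(f"no residual degrees of freedom (n={n_scans}, rank={rank})")

    sel = mask.data
    y = scans[sel].T  # (t, n_vox)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    sigma2 = (resid**2).sum(axis=0) / df

    cvec = np.zeros(x.shape[1])
    cvec[0] = 1.0  # LT
    cvec[1] = -1.0  # LN
    cvec[2] = 1.0  # HT
    cvec[3] = -1.0  # HN
    xtx_inv = np.linalg.pinv(x.T @ x)
    cvar = float(cvec @ xtx_inv @ cvec)
    con = cvec @ beta
    with np.errstate(invalid="ignore", divide="ignore"):
        tval = con / np.sqrt(sigma2 * cvar)
    tval = np.nan_to_num(tval, nan=0.0)
    z = _t_to_z(tval, df) if use_t_cdf else tval

    out = np.full(mask.grid.shape, np.nan)
    out[sel] = z
    if return_contrast:
        con_vol = np.full(mask.grid.shape, np.nan)
        con_vol[sel] = con
        return out, con_vol
    return out
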