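"""Band-pass, seed connectivity, FIR HRF estimation, GLM z-maps."""

import numpy as np
import pytest
from scipy import stats

from sldecode.firstlevel import (
    HRFEstimate,
    SparseDesign,
    _residualize,
    bandpass,
    candlestick_matrix,
    condition_regressors,
    estimate_hrf_fir,
    glm_contrast_zmap,
    seed_connectivity_map,
)
from sldecode.volumes import AnalysisMask, VolumeGrid

TR = 2.382


class TestBandpass:
    def _sine(self, freq_target, n=280):
        # exact FFT bin closest to the target frequency (periodic in the
        # record, so the hard mask acts without spectral leakage)
        k = round(freq_target * n * TR)
        freq = k / (n * TR)
        t = np.arange(n) * TR
        return np.sin(2 * np.pi * freq * t)

    def test_passband_amplitude_preserved(self):
        x = self._sine(0.04)
        y = bandpass(x, TR)
        ratio = np.abs(np.fft.rfft(y)).max() / np.abs(np.fft.rfft(x)).max()
        assert ratio > 0.95

    def test_stopband_suppressed(self):
        x = self._sine(0.2)
        y = bandpass(x, TR)
        assert np.abs(y).max() <= 0.05 * np.abs(x).max()

    def test_constant_series_zeroed(self):
        y = bandpass(np.full(100, 7.3), TR)
        assert np.allclose(y, 0.0, atol=1e-10)

    def test_high_cut_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(np.zeros(50), tr_s=10.0, high_hz=0.08)


class TestSeedConnectivity:
    def _setup(self, rng, n_t=280, shape=(5, 5, 4)):
        grid = VolumeGrid.isotropic(shape, 3.0)
        mask = AnalysisMask(np.ones(shape, bool), grid)
        ts = rng.standard_normal(shape + (n_t,))
        return grid, mask, ts

    def test_identical_series_reach_clamped_maximum(self, rng):
        _, mask, ts = self._setup(rng)
        seed = np.array([[0, 0, 0]])
        ts[1, 1, 1, :] = ts[0, 0, 0, :]
        z = seed_connectivity_map(ts, seed, None, mask)
        assert z[1, 1, 1] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_pure_nuisance_voxel_removed(self, rng):
        _, mask, ts = self._setup(rng)
        nuis = rng.standard_normal((280, 8))
        ts[2, 2, 2, :] = 3.0 * nuis[:, 0] - 1.5 * nuis[:, 4]
        z = seed_connectivity_map(ts, np.array([[0, 0, 0]]), nuis, mask)
        assert abs(z[2, 2, 2]) < 0.05

    def test_null_z_variance_matches_fisher(self, rng):
        """Independent voxels: z approx Normal(0, 1/sqrt(n-3-k))."""
        _, mask, ts = self._setup(rng, shape=(12, 12, 8))
        nuis = rng.standard_normal((280, 8))
        z = seed_connectivity_map(ts, np.array([[0, 0, 0]]), nuis, mask)
        zv = z[mask.data]
        zv = zv[np.abs(zv) < np.arctanh(1 - 1e-6)]  # drop the seed voxel itself
        # residual df after intercept + 8 nuisance: n - 9; Fisher var ~ 1/(df-3)
        expected_sd = 1 / np.sqrt(280 - 9 - 3)
        assert zv.std() == pytest.approx(expected_sd, rel=0.1)
        assert abs(zv.mean()) < 0.02

    def test_scale_invariance_of_single_voxel(self, rng):
        _, mask, ts = self._setup(rng, n_t=100)
        nuis = rng.standard_normal((100, 3))
        z1 = seed_connectivity_map(ts, np.array([[0, 0, 0]]), nuis, mask)
        ts2 = ts.copy()
        ts2[3, 3, 3, :] = 5.0 * ts2[3, 3, 3, :] - 2.0
        z2 = seed_connectivity_map(ts2, np.array([[0, 0, 0]]), nuis, mask)
        assert z2[3, 3, 3] == pytest.approx(z1[3, 3, 3], abs=1e-10)

    def test_constant_voxel_warns_and_zeroes(self, rng):
        _, mask, ts = self._setup(rng, n_t=100)
        ts[4, 4, 3, :] = 2.5
        with pytest.warns(UserWarning, match="constant"):
            z = seed_connectivity_map(ts, np.array([[0, 0, 0]]), None, mask)
        assert z[4, 4, 3] == 0.0

    def test_too_few_timepoints_rejected(self, rng):
        _, mask, ts = self._setup(rng, n_t=18)
        nuis = rng.standard_normal((18, 8))
        with pytest.raises(ValueError, match="time points"):
            seed_connectivity_map(ts, np.array([[0, 0, 0]]), nuis, mask)


class TestResidualize:
    def test_idempotent(self, rng):
        y = rng.standard_normal((120, 7))
        nuis = rng.standard_normal((120, 5))
        r1 = _residualize(y, nuis)
        r2 = _residualize(r1, nuis)
        assert np.linalg.norm(r2 - r1) < 1e-10


class TestHrfFir:
    def _design(self):
        return SparseDesign.blocked(order_seed=4)

    def test_known_hrf_recovered(self, rng):
        design = self._design()
        hrf_true = np.array([0.15, 0.7, 1.0, 0.75, 0.4, 0.15])
        cand = candlestick_matrix(design)
        shape = (6, 6, 4)
        region = np.argwhere(np.ones(shape, bool))
        scans = np.zeros(shape + (design.n_scans,))
        amp = rng.uniform(0.5, 2.0, size=shape)
        scans += amp[..., None] * (cand @ hrf_true)[None, None, None, :]
        scans += 0.05 * rng.standard_normal(scans.shape)
        est = estimate_hrf_fir(scans, design, region, top_fraction=0.10)
        r = np.corrcoef(est.weights, hrf_true)[0, 1]
        assert r > 0.95
        assert est.n_voxels_used == int(np.ceil(0.10 * len(region)))

    def test_top_fraction_one_is_plain_mean(self, rng):
        design = self._design()
        shape = (3, 3, 2)
        region = np.argwhere(np.ones(shape, bool))
        scans = rng.standard_normal(shape + (design.n_scans,))
        est = estimate_hrf_fir(scans, design, region, top_fraction=1.0)
        cand = candlestick_matrix(design)
        x = np.column_stack([np.ones(cand.shape[0]), cand])
        y = scans[region[:, 0], region[:, 1], region[:, 2], :].T
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        assert np.allclose(est.weights, beta[1:].mean(axis=1), atol=1e-10)

    def test_pure_noise_is_finite(self, rng):
        design = self._design()
        shape = (4, 4, 2)
        region = np.argwhere(np.ones(shape, bool))
        scans = rng.standard_normal(shape + (design.n_scans,))
        est = estimate_hrf_fir(scans, design, region)
        assert np.isfinite(est.weights).all()

    def test_rank_deficient_design_rejected(self):
        # the run ends before lags 4-5 ever occur: all-zero candlestick columns
        design = SparseDesign(
            n_scans=4,
            block_onset_scans=np.array([0]),
            condition_per_block=["low_tones"],
            candlestick_lags=6,
        )
        cand = candlestick_matrix(design)
        assert np.linalg.matrix_rank(cand) < cand.shape[1]
        with pytest.raises(ValueError, match="rank-deficient"):
            estimate_hrf_fir(
                np.zeros((2, 2, 2, 4)), design, np.argwhere(np.ones((2, 2, 2), bool))
            )


class TestGlmContrast:
    def _design(self, seed=0):
        return SparseDesign.blocked(order_seed=seed)

    def test_matches_bruteforce_normal_equations(self, rng):
        """5-voxel toy data: z equals the explicit normal-equations t->z."""
        design = self._design(seed=2)
        hrf = HRFEstimate(np.array([0.2, 0.8, 1.0, 0.6, 0.3, 0.1]), 1)
        shape = (5, 1, 1)
        grid = VolumeGrid.isotropic(shape, 3.0)
        mask = AnalysisMask(np.ones(shape, bool), grid)
        n = design.n_scans
        scans = rng.standard_normal(shape + (n,))
        wm_shape = (3, 1, 1)
        wm_scans = rng.standard_normal(wm_shape + (n,))
        full = np.concatenate([scans, wm_scans], axis=0)
        full_mask = AnalysisMask(
            np.r_[np.ones(5), np.zeros(3)].astype(bool).reshape(8, 1, 1),
            VolumeGrid.isotropic((8, 1, 1), 3.0),
        )
        wm_voxels = np.argwhere(~full_mask.data)
        z = glm_contrast_zmap(full, design, hrf, wm_voxels, full_mask, n_pcs=2)

        # brute-force oracle
        from sldecode.firstlevel import condition_regressors, wm_principal_components, _t_to_z

        regs = condition_regressors(design, hrf.weights)
        conds = ("low_tones", "low_noise", "high_tones", "high_noise")
        x = np.column_stack(
            [regs[c] for c in conds]
            + [np.ones(n), np.linspace(-1, 1, n)]
        )
        pcs = wm_principal_components(full, wm_voxels, 2)
        x = np.column_stack([x, pcs])
        cvec = np.array([1.0, -1.0, 1.0, -1.0] + [0.0] * (x.shape[1] - 4))
        df = n - np.linalg.matrix_rank(x)
        for v in range(5):
            yv = full[v, 0, 0]
            beta = np.linalg.solve(x.T @ x, x.T @ yv)
            resid = yv - x @ beta
            s2 = resid @ resid / df
            tval = (cvec @ beta) / np.sqrt(s2 * cvec @ np.linalg.solve(x.T @ x, cvec))
            assert z[v, 0, 0] == pytest.approx(float(_t_to_z(tval, df)), abs=1e-8)

    def test_null_z_unit_variance(self, rng):
        design = self._design(seed=3)
        hrf = HRFEstimate(np.array([0.2, 0.8, 1.0, 0.6, 0.3, 0.1]), 1)
        shape = (20, 20, 14)
        grid = VolumeGrid.isotropic(shape, 3.0)
        mdata = np.zeros(shape, bool)
        mdata[:, :, :13] = True
        mask = AnalysisMask(mdata, grid)
        wm_voxels = np.argwhere(~mdata)[:60]
        scans = rng.standard_normal(shape + (design.n_scans,))
        z = glm_contrast_zmap(scans, design, hrf, wm_voxels, mask, n_pcs=10)
        zv = z[mask.data]
        assert len(zv) >= 5000
        assert zv.var() == pytest.approx(1.0, abs=0.1)

    def test_median_z_monotone_in_amplitude(self, rng):
        from sldecode.synthetic import generate_localizer_scans

        design = self._design(seed=5)
        hrf_true = np.array([0.2, 0.8, 1.0, 0.6, 0.3, 0.1])
        shape = (6, 6, 4)
        grid = VolumeGrid.isotropic(shape, 3.0)
        mdata = np.ones(shape, bool)
        mdata[:, :, -1] = False
        mask = AnalysisMask(mdata, grid)
        wm_voxels = np.argwhere(~mdata)[:30]
        medians = []
        for amp in (0.0, 0.5, 1.0, 2.0):
            scans = generate_localizer_scans(
                design, hrf_true, np.full(shape, amp), noise_sd=1.0, seed=11
            )
            z = glm_contrast_zmap(
                scans, design, HRFEstimate(hrf_true, 1), wm_voxels, mask, n_pcs=5
            )
            medians.append(np.median(z[mask.data]))
        assert all(b > a for a, b in zip(medians, medians[1:]))

    def test_self_contrast_is_zero(self, rng):
        """Contrasting a condition with itself yields identically zero."""
        design = self._design(seed=6)
        regs = condition_regressors(design, np.array([0.2, 0.8, 1.0, 0.6, 0.3, 0.1]))
        # the (LT-LN)+(HT-HN) machinery with LN:=LT, HN:=HT gives c == 0;
        # verified directly on the contrast of the fitted betas
        n = design.n_scans
        x = np.column_stack([regs["low_tones"], regs["low_tones"],
                             regs["high_tones"], regs["high_tones"], np.ones(n)])
        rngl = np.random.default_rng(0)
        y = rngl.standard_normal(n)
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        c = (beta[0] - beta[1]) + (beta[2] - beta[3])
        # with duplicated regressors lstsq splits weight evenly -> c == 0
        assert c == pytest.approx(0.0, abs=1e-8)

    def test_df_and_pc_guards(self, rng):
        design = self._design(seed=7)
        hrf = HRFEstimate(np.ones(6), 1)
        shape = (2, 2, 2)
        mask = AnalysisMask(np.ones(shape, bool), VolumeGrid.isotropic(shape, 3.0))
        wm_voxels = np.argwhere(np.ones((2, 2, 2), bool))
        scans = rng.standard_normal(shape + (design.n_scans,))
        with pytest.raises(ValueError, match="n_pcs"):
            glm_contrast_zmap(scans, design, hrf, wm_voxels, mask, n_pcs=design.n_scans)
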