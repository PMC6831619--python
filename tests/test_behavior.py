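"""Group behavioral statistics and brain-behavior coupling."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sldecode.behavior import (
    BrainBehaviorResult,
    compare_correlations,
    mcnemar_compare,
    peak_decision_behavior,
    pooled_t,
    withingroup_perm_p,
)


class TestPooledT:
    def test_reference_group_comparison(self):
        """Pitch-discrimination thresholds 0.90 (0.88) vs 0.22 (0.15),
        n = 18 per group: t(34) = 3.23, p = 0.002."""
        t, df, p = pooled_t(0.90, 0.88, 18, 0.22, 0.15, 18)
        assert df == 34
        assert t == pytest.approx(3.23, abs=0.005)
        # exact two-sided p at t = 3.23, df = 34 (prints as 0.002 at coarser precision)
        assert p == pytest.approx(0.0027, abs=0.0005)

    def test_equal_means_give_zero(self):
        t, df, p = pooled_t(1.0, 0.5, 10, 1.0, 0.7, 12)
        assert t == 0.0
        assert p == 1.0

    def test_identical_vectors(self):
        t, df, p = pooled_t(x1=[1, 2, 3], x2=[1, 2, 3])
        assert t == 0.0
        assert df == 4

    def test_summary_equals_raw(self, rng):
        x1 = rng.standard_normal(18) + 0.5
        x2 = rng.standard_normal(18)
        t_raw, df_raw, _ = pooled_t(x1=x1, x2=x2)
        t_sum, df_sum, _ = pooled_t(
            x1.mean(), x1.std(ddof=1), 18, x2.mean(), x2.std(ddof=1), 18
        )
        assert t_raw == pytest.approx(t_sum)
        assert df_raw == df_sum

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="pooled variance"):
            pooled_t(1.0, 0.0, 5, 2.0, 0.0, 5)


def _result(d, b, groups, name="pitch_memory_score"):
    r, p = stats.pearsonr(d, b)
    return BrainBehaviorResult(
        peak_position=0,
        subject_ids=[f"s{i}" for i in range(len(d))],
        decision_values=np.asarray(d, float),
        behavior=np.asarray(b, float),
        groups=list(groups),
        behavior_name=name,
        pearson_r=float(r),
        df=len(d) - 2,
        parametric_p=float(p),
    )


class _FakeMap:
    """Minimal ClassifierMap stand-in exposing table_at + modality."""

    def __init__(self, d, ids, y, modality="pitch_localizer"):
        self._d = np.asarray(d, float)
        self._ids = ids
        self._y = np.asarray(y, float)
        self.modality = modality

    def table_at(self, pos):
        from sldecode.searchlight import DecisionValueTable

        return DecisionValueTable(self._ids, self._d, self._y)


class TestPeakDecisionBehavior:
    def _table(self, ids, scores, groups):
        return pd.DataFrame(
            {"subject_id": ids, "group": groups, "pitch_memory_score": scores}
        )

    def test_behavior_equal_to_decisions_gives_r_one(self):
        ids = [f"s{i}" for i in range(8)]
        d = np.arange(8, dtype=float) - 3.5
        y = np.r_[np.ones(4), -np.ones(4)]
        cm = _FakeMap(d, ids, y)
        res = peak_decision_behavior(cm, 0, self._table(ids, d, ["amusic"] * 4 + ["control"] * 4))
        assert res.pearson_r == pytest.approx(1.0)
        assert res.df == 6

    def test_circular_behavior_refused(self):
        ids = [f"s{i}" for i in range(8)]
        d = np.arange(8, dtype=float)
        y = np.r_[np.ones(4), -np.ones(4)]
        cm = _FakeMap(d, ids, y, modality="pitch_memory")
        tbl = self._table(ids, d, ["amusic"] * 4 + ["control"] * 4)
        with pytest.raises(ValueError, match="circular"):
            peak_decision_behavior(cm, 0, tbl, behavior_name="pitch_memory_score")
        res = peak_decision_behavior(
            cm, 0, tbl, behavior_name="pitch_memory_score", allow_circular=True
        )
        assert res.pearson_r == pytest.approx(1.0)

    def test_missing_behavior_subjects_dropped_with_warning(self):
        ids = [f"s{i}" for i in range(8)]
        d = np.arange(8, dtype=float)
        y = np.r_[np.ones(4), -np.ones(4)]
        cm = _FakeMap(d, ids, y)
        tbl = self._table(ids, list(d), ["amusic"] * 4 + ["control"] * 4)
        tbl.loc[2, "pitch_memory_score"] = np.nan
        with pytest.warns(UserWarning, match="s2"):
            res = peak_decision_behavior(cm, 0, tbl)
        assert len(res.behavior) == 7

    def test_constant_behavior_rejected(self):
        ids = [f"s{i}" for i in range(8)]
        d = np.arange(8, dtype=float)
        y = np.r_[np.ones(4), -np.ones(4)]
        cm = _FakeMap(d, ids, y)
        tbl = self._table(ids, [1.0] * 8, ["amusic"] * 4 + ["control"] * 4)
        with pytest.raises(ValueError, match="constant"):
            peak_decision_behavior(cm, 0, tbl)


class TestWithingroupPermP:
    def test_constant_within_groups_gives_p_one(self):
        d = np.array([3.0, 2.0, 1.0, -1.0, -2.0, -3.0])
        b = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        res = _result(d, b, ["amusic"] * 3 + ["control"] * 3)
        p = withingroup_perm_p(res, n_perm=1000, seed=0)
        assert p == 1.0

    def test_exhaustive_matches_bruteforce(self, rng):
        d = rng.standard_normal(6)
        b = rng.standard_normal(6)
        groups = ["amusic"] * 3 + ["control"] * 3
        res = _result(d, b, groups)
        p = withingroup_perm_p(res, n_perm=1000, seed=0)
        assert res.n_permutations == 36
        # brute force over (3!)^2 within-group orderings
        def corr(x, y):
            return stats.pearsonr(x, y)[0]

        r_obs = corr(d, b)
        count = 0
        for p1 in permutations(range(3)):
            for p2 in permutations(range(3, 6)):
                perm = list(p1) + list(p2)
                if corr(d, b[perm]) >= r_obs - 1e-12:
                    count += 1
        assert p == pytest.approx(count / 36)

    def test_single_group_reduces_to_ordinary_permutation_test(self, rng):
        d = rng.standard_normal(7)
        b = 0.8 * d + 0.3 * rng.standard_normal(7)
        groups = ["amusic"] * 7
        res = _result(d, b, groups)
        p = withingroup_perm_p(res, n_perm=2000, seed=1)
        # ordinary one-sided permutation test of the correlation
        assert res.n_permutations == 2000 or res.n_permutations == 5040
        r_obs = stats.pearsonr(d, b)[0]
        rng2 = np.random.default_rng(99)
        count = sum(
            stats.pearsonr(d, rng2.permutation(b))[0] >= r_obs - 1e-12
            for _ in range(2000)
        )
        p_ref = (count + 1) / 2001
        assert p == pytest.approx(p_ref, abs=0.03)

    def test_group_indicator_only_p_is_uniformish(self, rng):
        """Behavior carrying only the group mean difference: the
        within-group permutation p is not systematically small."""
        ps = []
        for rep in range(100):
            d = np.r_[rng.standard_normal(8) + 1.5, rng.standard_normal(8) - 1.5]
            b = np.r_[np.full(8, 1.0), np.full(8, 0.0)] + 0.2 * rng.standard_normal(16)
            res = _result(d, b, ["amusic"] * 8 + ["control"] * 8)
            ps.append(withingroup_perm_p(res, n_perm=99, seed=rep))
        assert 0.3 < np.mean(ps) < 0.7

    def test_pearson_r_affine_invariance(self, rng):
        d = rng.standard_normal(10)
        b = rng.standard_normal(10)
        groups = ["amusic"] * 5 + ["control"] * 5
        r1 = _result(d, b, groups).pearson_r
        r2 = _result(3 * d + 7, 0.5 * b - 2, groups).pearson_r
        assert r1 == pytest.approx(r2)


class TestCompareCorrelations:
    def test_equal_correlations(self):
        z, p = compare_correlations(0.4, 30, 0.4, 50)
        assert z == 0.0
        assert p == 1.0

    def test_closed_form_oracle(self):
        """r1 = 0.64 (n=22) vs r2 = -0.09 (n=36): Fisher-z formula."""
        z, p = compare_correlations(0.64, 22, -0.09, 36)
        z_expected = (np.arctanh(0.64) - np.arctanh(-0.09)) / np.sqrt(
            1 / 19 + 1 / 33
        )
        assert z == pytest.approx(z_expected)
        assert p == pytest.approx(2 * stats.norm.sf(abs(z_expected)))
        assert p < 0.05  # the comparison is significant at these values

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="n >= 4"):
            compare_correlations(0.5, 3, 0.2, 30)


class TestMcnemar:
    def test_symmetric_discordance_gives_p_one_region(self):
        a = np.r_[np.ones(5), np.zeros(5), np.ones(10)].astype(bool)
        b = np.r_[np.zeros(5), np.ones(5), np.ones(10)].astype(bool)
        stat, p = mcnemar_compare(a, b)
        assert p == 1.0

    def test_exact_binomial_oracle(self):
        """b=9, c=1 discordant: exact p = 2 P(X <= 1 | n=10) = 0.0215."""
        a = np.r_[np.ones(9), np.zeros(1), np.ones(6)].astype(bool)
        b = np.r_[np.zeros(9), np.ones(1), np.ones(6)].astype(bool)
        stat, p = mcnemar_compare(a, b, n_comparisons_for_correction=1)
        assert p == pytest.approx(2 * stats.binom.cdf(1, 10, 0.5), abs=1e-10)
        assert p == pytest.approx(0.0215, abs=0.0001)

    def test_identical_vectors_give_p_one(self):
        a = np.array([True, False, True, True])
        stat, p = mcnemar_compare(a, a.copy())
        assert p == 1.0

    def test_bonferroni_correction_applied(self):
        a = np.r_[np.ones(9), np.zeros(1), np.ones(6)].astype(bool)
        b = np.r_[np.zeros(9), np.ones(1), np.ones(6)].astype(bool)
        _, p1 = mcnemar_compare(a, b, 1)
        _, p10 = mcnemar_compare(a, b, 10)
        assert p10 == pytest.approx(min(1.0, 10 * p1))
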