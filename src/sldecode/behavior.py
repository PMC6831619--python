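"""Behavioral statistics and brain-behavior coupling.

Includes the pooled two-sample t-test for group comparisons of summary
scores, the Pearson correlation between peak-searchlight decision values
and an independent behavioral score, and — because the diagnostic score
that defines the groups correlates with most behavior — a within-group
permutation null for that correlation: behavior is shuffled only among
subjects of the same group, so any correlation that survives cannot be
explained by group membership alone. Classifier comparisons use exact
McNemar tests on paired per-subject correctness and Fisher-z comparison
of correlation coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _permutations
from math import factorial
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: behavior collected during a modality's own scan (correlating a
#: classifier's decision values with it would be circular)
IN_SCANNER_BEHAVIOR = {
    "pitch_memory": "pitch_memory_score",
    "verbal_memory": "verbal_memory_score",
}


def pooled_t(
    mean1=None, sd1=None, n1=None, mean2=None, sd2=None, n2=None,
    x1: Sequence[float] | None = None, x2: Sequence[float] | None = None,
) -> tuple[float, int, float]:
    """Two-sample pooled-variance t-test from summaries or raw vectors.

    Returns (t, df, two-sided p). Raw vectors take precedence when given.
    """
    if x1 is not None or x2 is not None:
        x1 = np.asarray(x1, dtype=float)
        x2 = np.asarray(x2, dtype=float)
        mean1, sd1, n1 = x1.mean(), x1.std(ddof=1), len(x1)
        mean2, sd2, n2 = x2.mean(), x2.std(ddof=1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    df = int(n1 + n2 - 2)
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if sp2 <= 0:
        raise ValueError("zero pooled variance")
    t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


@dataclass
class BrainBehaviorResult:
    """Correlation between peak decision values and a behavioral score."""

    peak_position: int
    subject_ids: list[str]
    decision_values: np.ndarray
    behavior: np.ndarray
    groups: list[str]
    behavior_name: str
    pearson_r: float
    df: int
    parametric_p: float
    withingroup_perm_p: float | None = None
    n_permutations: int | None = None
    seed: int | None = None

    def summary(self) -> str:
        lines = [
            f"decision values at peak centre {self.peak_position} "
            f"vs {self.behavior_name} (n = {len(self.behavior)})",
            f"  r({self.df}) = {self.pearson_r:.3f}, parametric p = {self.parametric_p:.4g}",
        ]
        if self.withingroup_perm_p is not None:
            lines.append(
                f"  within-group permutation p = {self.withingroup_perm_p:.4g} "
                f"({self.n_permutations} permutations, seed {self.seed})"
            )
        return "\n".join(lines)


def peak_decision_behavior(
    observed,
    peak_position: int,
    behavior_table: pd.DataFrame,
    behavior_name: str = "pitch_memory_score",
    allow_circular: bool = False,
) -> BrainBehaviorResult:
    """Correlate a peak searchlight's held-out decision values with behavior.

    ``observed`` is a ClassifierMap with stored decision values. Subjects
    missing the behavior are dropped (their ids noted). Refuses to
    correlate a modality's decision values with behavior collected during
    that modality's own scan unless ``allow_circular`` is set.
    """
    metric_in_scanner = IN_SCANNER_BEHAVIOR.get(observed.modality)
    if metric_in_scanner == behavior_name and not allow_circular:
        raise ValueError(
            f"behavior {behavior_name!r} was collected during the "
            f"{observed.modality!r} scan; correlating it with that "
            "modality's decision values is circular (pass allow_circular=True "
            "to override)"
        )
    tbl = observed.table_at(peak_position).to_frame()
    merged = tbl.merge(
        behavior_table[["subject_id", "group", behavior_name]],
        on="subject_id",
        how="left",
    )
    missing = merged.loc[merged[behavior_name].isna(), "subject_id"].tolist()
    if missing:
        import warnings

        warnings.warn(f"dropping subjects without behavior: {missing}", stacklevel=2)
        merged = merged.dropna(subset=[behavior_name])
    b = merged[behavior_name].to_numpy(dtype=float)
    d = merged["decision_value"].to_numpy(dtype=float)
    if len(b) < 4:
        raise ValueError("need at least 4 subjects with behavior")
    if np.ptp(b) == 0:
        raise ValueError("behavior is constant; correlation undefined")
    r, p = stats.pearsonr(d, b)
    return BrainBehaviorResult(
        peak_position=int(peak_position),
        subject_ids=merged["subject_id"].tolist(),
        decision_values=d,
        behavior=b,
        groups=merged["group"].tolist(),
        behavior_name=behavior_name,
        pearson_r=float(r),
        df=len(b) - 2,
        parametric_p=float(p),
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


def withingroup_perm_p(
    result: BrainBehaviorResult, n_perm: int = 10_000, seed: int = 0
) -> float:
    """One-sided within-group permutation p for an observed correlation.

    Behavior values are shuffled only among subjects of the same group;
    p is the fraction of permuted r at least as large as the observed r
    (add-one convention for sampled permutations; exact enumeration when
    the within-group permutation space is no larger than ``n_perm``, in
    which case p is the exact fraction over the space, identity
    included). The result object is updated in place and the p returned.
    """
    groups = np.asarray(result.groups)
    b = result.behavior
    d = result.decision_values
    uniq = list(dict.fromkeys(groups))
    for g in uniq:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    r_obs = _pearson(d, b)

    idx_by_group = [np.where(groups == g)[0] for g in uniq]
    space = 1
    for idx in idx_by_group:
        space *= factorial(len(idx))
        if space > n_perm:
            break

    if space <= n_perm:
        # exhaustive enumeration of within-group orderings
        count = 0
        total = 0
        perms_by_group = [list(_permutations(idx)) for idx in idx_by_group]

        def _recurse(gi: int, perm: np.ndarray):
            nonlocal count, total
            if gi == len(perms_by_group):
                total += 1
                if _pearson(d, b[perm]) >= r_obs - 1e-12:
                    count += 1
                return
            for p_ in perms_by_group[gi]:
                perm[idx_by_group[gi]] = p_
                _recurse(gi + 1, perm)

        _recurse(0, np.arange(len(b)))
        p = count / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        count = 0
        perm = np.arange(len(b))
        for _ in range(n_perm):
            for idx in idx_by_group:
                perm[idx] = rng.permutation(idx)
            if _pearson(d, b[perm]) >= r_obs - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
        n_used = n_perm

    result.withingroup_perm_p = float(p)
    result.n_permutations = n_used
    result.seed = seed
    return float(p)


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Independent-samples comparison of two Pearson correlations.

    Fisher z-transforms both correlations and forms
    z = (z1 − z2) / sqrt(1/(n1−3) + 1/(n2−3)); two-sided p from the
    standard normal. Overlapping samples are treated as independent
    (documented limitation).
    """
    for r, n in ((r1, n1), (r2, n2)):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1")
        if n < 4:
            raise ValueError("need n >= 4 per correlation")
    z1 = np.arctanh(r1)
    z2 = np.arctanh(r2)
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (z1 - z2) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def mcnemar_compare(
    correct_a: Sequence[bool],
    correct_b: Sequence[bool],
    n_comparisons_for_correction: int = 1,
) -> tuple[float, float]:
    """McNemar test on paired per-subject correctness, Bonferroni-corrected.

    Exact binomial on the discordant pairs (continuity-corrected chi² when
    there are >= 25 discordant pairs). Returns (statistic, corrected p);
    the statistic is the discordant count b (a right, b wrong) for the
    exact test, the chi² value otherwise. Zero discordant pairs -> p = 1.
    """
    a = np.asarray(correct_a, dtype=bool)
    b = np.asarray(correct_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("paired correctness vectors must have equal length")
    n_ab = int((a & ~b).sum())  # a right, b wrong
    n_ba = int((~a & b).sum())
    n_disc = n_ab + n_ba
    if n_disc == 0:
        return 0.0, 1.0
    if n_disc < 25:
        p = min(1.0, 2.0 * stats.binom.cdf(min(n_ab, n_ba), n_disc, 0.5))
        statistic = float(n_ab)
    else:
        chi2 = (abs(n_ab - n_ba) - 1.0) ** 2 / n_disc
        p = float(stats.chi2.sf(chi2, 1))
        statistic = float(chi2)
    p_corr = min(1.0, p * max(1, int(n_comparisons_for_correction)))
    return statistic, float(p_corr)
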