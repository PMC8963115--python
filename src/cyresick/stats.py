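"""Opinion-score contrasts, the three-step feature analysis, and group tests.

Scene-factor analysis works on mean opinion scores (MOS): per-condition
means of the 1-5 ratings after interquartile-range outlier removal, compared
with paired t-tests and Bonferroni-adjusted p-values.  Physiological
features are screened by a three-step procedure — a one-way ANOVA over the
five score groups, pairwise t-tests between groups, and an ordinary
least-squares fit of the group means on the score levels — keeping features
that are both significant and monotone.  Individual-characteristic analyses
compare questionnaire subscale scores between two participant groups with
independent two-sample t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .scenes import ContrastSpec

__all__ = [
    "ContrastResult",
    "ThreeStepResult",
    "mos",
    "iqr_filter",
    "contrast_test",
    "percent_increase",
    "ratio_percent",
    "significance_stars",
    "bonferroni",
    "three_step",
    "group_compare",
]

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for threshold, stars in STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return "ns"


def bonferroni(p: float, family_size: int) -> float:
    """Bonferroni-adjusted p-value: min(1, p * m).  Never decreases p."""
    if family_size < 1:
        raise ValueError("family size must be at least 1")
    return min(1.0, float(p) * family_size)


def iqr_filter(values) -> np.ndarray:
    """Drop values outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR]."""
    values = np.asarray(values, dtype=float)
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return values[(values >= lo) & (values <= hi)]


def mos(ratings) -> float:
    """Mean opinion score after IQR outlier removal."""
    ratings = np.asarray(ratings, dtype=float)
    if ratings.size < 4:
        raise ValueError("MOS requires at least 4 ratings")
    kept = iqr_filter(ratings)
    if kept.size == 0:
        raise ValueError("IQR rule removed every rating (degenerate input)")
    return float(kept.mean())


def percent_increase(a: float, b: float, decimals: int = 1) -> float:
    """Relative increase of a over b, in percent: 100 * (a - b) / b."""
    if b <= 0:
        raise ValueError("reference value must be positive")
    return round(100.0 * (a - b) / b, decimals)


def ratio_percent(a: float, b: float) -> int:
    """Ratio of a to b as an integer percentage: round(100 * a / b)."""
    if b <= 0:
        raise ValueError("reference value must be positive")
    return int(round(100.0 * a / b))


@dataclass(frozen=True)
class ContrastResult:
    factor: str
    label_a: str
    label_b: str
    mean_a: float
    mean_b: float
    percent_diff: float
    t_stat: float
    p_raw: float
    p_adjusted: float
    n: int

    @property
    def stars(self) -> str:
        return significance_stars(self.p_adjusted)


def contrast_test(spec: ContrastSpec, scores: pd.DataFrame,
                  family_size: int = 1, remove_outliers: bool = True) -> ContrastResult:
    """Paired t-test between the two conditions of a single-factor contrast.

    ``scores`` is the participants x scenes rating matrix.  Scene replicates
    within a condition (the background twins) are averaged per participant
    before testing; condition means are MOS values with the IQR rule applied
    per condition.  The Bonferroni family defaults to 1 (a lone comparison)
    and should be set to the number of pairwise comparisons within the
    factor under test.
    """
    missing = (set(spec.condition_a) | set(spec.condition_b)) - set(scores.columns)
    if missing:
        raise ValueError(f"score matrix lacks scenes {sorted(missing)}")
    a = scores[list(spec.condition_a)].mean(axis=1, skipna=False)
    b = scores[list(spec.condition_b)].mean(axis=1, skipna=False)
    if a.isna().any() or b.isna().any():
        raise ValueError("conditions must be rated by every participant (paired)")
    if np.allclose(a, b):
        t_stat, p_raw = 0.0, 1.0
    else:
        t_stat, p_raw = spstats.ttest_rel(a, b)
    filt = iqr_filter if remove_outliers else np.asarray
    mean_a = float(np.mean(filt(a.to_numpy())))
    mean_b = float(np.mean(filt(b.to_numpy())))
    return ContrastResult(
        factor=spec.factor,
        label_a=spec.label_a,
        label_b=spec.label_b,
        mean_a=mean_a,
        mean_b=mean_b,
        percent_diff=percent_increase(mean_a, mean_b),
        t_stat=float(t_stat),
        p_raw=float(p_raw),
        p_adjusted=bonferroni(p_raw, family_size),
        n=len(a),
    )


def run_factor_analysis(registry, scores: pd.DataFrame) -> pd.DataFrame:
    """Run every registered contrast; Bonferroni family = comparisons per factor."""
    family = {}
    for spec in registry:
        family[spec.factor] = family.get(spec.factor, 0) + 1
    rows = []
    for spec in registry:
        r = contrast_test(spec, scores, family_size=family[spec.factor])
        rows.append({
            "factor": r.factor, "condition_a": r.label_a, "condition_b": r.label_b,
            "mean_a": r.mean_a, "mean_b": r.mean_b, "percent_diff": r.percent_diff,
            "t": r.t_stat, "p_raw": r.p_raw, "p_adjusted": r.p_adjusted,
            "stars": r.stars, "n": r.n,
        })
    return pd.DataFrame(rows)


@dataclass
class ThreeStepResult:
    anova_p: float
    pairwise_p: dict          # (level_i, level_j) -> Bonferroni-adjusted p
    pairwise_p_raw: dict
    ols_intercept: float
    ols_slope: float
    r_squared: float
    group_means: dict         # level -> mean feature value
    group_sizes: dict

    def pairwise_stars(self) -> dict:
        return {k: significance_stars(v) for k, v in self.pairwise_p.items()}


ADJACENT_PAIRS = ((1, 2), (2, 3), (3, 4), (4, 5))


def three_step(feature, score, all_pairs: bool = False,
               fit_group_means: bool = True) -> ThreeStepResult:
    """ANOVA -> pairwise t-tests -> OLS screening of one feature.

    Trials are binned by their 1-5 score.  Step one is a one-way ANOVA over
    the populated groups; step two runs independent t-tests on group pairs
    (adjacent levels by default, all 10 pairs with ``all_pairs``), Bonferroni
    adjusted by the number of tests actually performed; step three fits the
    group means (or, with ``fit_group_means=False``, the raw trials) on the
    score levels by OLS, reporting intercept, slope and R^2.  Pairs with an
    under-populated group (< 2 trials) are reported as NaN.
    """
    feature = np.asarray(feature, dtype=float)
    score = np.asarray(score)
    if feature.shape != score.shape:
        raise ValueError("feature and score vectors must align")
    groups = {lvl: feature[score == lvl] for lvl in range(1, 6)}
    populated = {lvl: g for lvl, g in groups.items() if g.size >= 2}
    if len(populated) < 2:
        raise ValueError("need at least two populated score groups")
    anova_p = float(spstats.f_oneway(*populated.values()).pvalue)

    pairs = tuple(combinations(range(1, 6), 2)) if all_pairs else ADJACENT_PAIRS
    raw = {}
    for i, j in pairs:
        if i in populated and j in populated:
            raw[(i, j)] = float(spstats.ttest_ind(populated[i], populated[j]).pvalue)
        else:
            raw[(i, j)] = float("nan")
    n_tests = sum(1 for v in raw.values() if np.isfinite(v))
    adjusted = {
        k: (bonferroni(v, n_tests) if np.isfinite(v) else v) for k, v in raw.items()
    }

    import statsmodels.api as sm

    means = {lvl: float(g.mean()) for lvl, g in populated.items()}
    if fit_group_means:
        x = np.array(sorted(means))
        y = np.array([means[lvl] for lvl in sorted(means)])
    else:
        mask = np.isin(score, list(populated))
        x, y = score[mask].astype(float), feature[mask]
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return ThreeStepResult(
        anova_p=anova_p,
        pairwise_p=adjusted,
        pairwise_p_raw=raw,
        ols_intercept=float(fit.params[0]),
        ols_slope=float(fit.params[1]),
        r_squared=float(fit.rsquared),
        group_means=means,
        group_sizes={lvl: int(g.size) for lvl, g in populated.items()},
    )


SSQ_SUBSCALES = ("sN", "sO", "sD", "sT")


def group_compare(ssq_scores: pd.DataFrame, groups: pd.Series,
                  timepoints=None, subscales=SSQ_SUBSCALES) -> pd.DataFrame:
    """Independent two-sample t-tests of SSQ subscales between two groups.

    ``ssq_scores`` is tidy with columns participant_id, timepoint and the
    subscale columns; ``groups`` maps participant_id to exactly two labels.
    Returns one row per (timepoint, subscale) with group means, t, p and
    significance stars.
    """
    labels = sorted(groups.dropna().unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    if timepoints is None:
        timepoints = list(dict.fromkeys(ssq_scores["timepoint"]))
    merged = ssq_scores.merge(
        groups.rename("group"), left_on="participant_id", right_index=True
    )
    rows = []
    for tp in timepoints:
        chunk = merged[merged["timepoint"] == tp]
        ga = chunk[chunk["group"] == labels[0]]
        gb = chunk[chunk["group"] == labels[1]]
        if ga.empty or gb.empty:
            raise ValueError(f"empty group at timepoint {tp!r}")
        for sub in subscales:
            va, vb = ga[sub].to_numpy(float), gb[sub].to_numpy(float)
            if np.allclose(va.mean(), vb.mean()) and np.allclose(va.var(), vb.var()) \
                    and len(va) == len(vb) and np.allclose(np.sort(va), np.sort(vb)):
                t, p = 0.0, 1.0
            else:
                t, p = spstats.ttest_ind(va, vb)
            rows.append({
                "timepoint": tp, "subscale": sub,
                f"mean_{labels[0]}": float(va.mean()),
                f"mean_{labels[1]}": float(vb.mean()),
                "t": float(t), "p": float(p), "stars": significance_stars(p),
            })
    return pd.DataFrame(rows)
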