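"""Group-level statistics on the network AUC summaries.

- Baseline comparisons with screened test selection: two-sample t-test when
  both groups pass Shapiro normality and Levene variance homogeneity, else
  Kruskal-Wallis; count data by chi-square, or Fisher's exact test when any
  expected cell is below 5.  The screening outcome is recorded with each
  result.
- Two-sample t-tests on AUCs between patient groups and healthy subjects.
- Spearman rank correlation between AUCs and clinical motor scores (FMA-UL
  0..66, FMA-hand 0..14).
- Threshold-effect analysis: a lowess smooth for display plus segmented
  linear regression with an exhaustive breakpoint grid search; the number of
  breakpoints (0, 1, or 2) is chosen by the corrected small-sample
  information criterion (AICc), with searched breakpoints counted as model
  parameters.  Per-segment Spearman correlations use left-closed /
  right-open intervals (last segment closed).

Two-sided alpha = 0.05 throughout; no multiplicity correction is applied
across indicators at this stage (a documented limitation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as st
from statsmodels.nonparametric.smoothers_lowess import lowess


@dataclass
class GroupComparison:
    variable: str
    groups: tuple[str, ...]
    test: str                 # t | kruskal | chi2 | fisher
    statistic: float
    p: float
    screening: dict = field(default_factory=dict)


@dataclass
class ThresholdEffectFit:
    score_name: str
    breakpoints: list[float]
    slopes: list[float]            # per segment
    intercept: float
    smooth_x: np.ndarray
    smooth_y: np.ndarray
    aicc: dict[int, float]         # n_breakpoints -> criterion value
    score_range: tuple[float, float] = (np.nan, np.nan)

    @property
    def n_segments(self) -> int:
        return len(self.breakpoints) + 1

    def segment_bounds(self) -> list[tuple[float, float]]:
        lo, hi = self.score_range
        edges = [lo, *self.breakpoints, hi]
        return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]


def _normal_and_homogeneous(samples: list[np.ndarray], alpha: float = 0.05) -> dict:
    """Shapiro per group plus Levene; returns the screening record."""
    shapiro_p = []
    for s in samples:
        if len(s) < 3 or np.ptp(s) == 0:
            shapiro_p.append(0.0)  # cannot attest normality
        else:
            shapiro_p.append(float(st.shapiro(s).pvalue))
    try:
        levene_p = float(st.levene(*samples).pvalue)
    except ValueError:
        levene_p = 0.0
    return {
        "shapiro_p": shapiro_p,
        "levene_p": levene_p,
        "normal": all(p > alpha for p in shapiro_p),
        "homogeneous": levene_p > alpha,
    }


def compare_continuous(
    samples: dict[str, np.ndarray], variable: str = "", alpha: float = 0.05
) -> GroupComparison:
    """t-test when two screened-normal homogeneous groups, else Kruskal-Wallis."""
    names = tuple(samples)
    arrs = [np.asarray(samples[g], dtype=float) for g in names]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    screen = _normal_and_homogeneous(arrs, alpha)
    if len(arrs) == 2 and all(np.ptp(a) == 0 for a in arrs) \
            and np.mean(arrs[0]) == np.mean(arrs[1]):
        return GroupComparison(variable, names, "t", 0.0, 1.0, screen)
    if len(arrs) == 2 and screen["normal"] and screen["homogeneous"]:
        res = st.ttest_ind(arrs[0], arrs[1])
        return GroupComparison(variable, names, "t",
                               float(res.statistic), float(res.pvalue), screen)
    res = st.kruskal(*arrs)
    return GroupComparison(variable, names, "kruskal",
                           float(res.statistic), float(res.pvalue), screen)


def compare_counts(
    table: np.ndarray, variable: str = "", group_names: tuple[str, ...] = ()
) -> GroupComparison:
    """Chi-square on a contingency table; Fisher exact when any expected cell
    is 5 or fewer (the convention that reproduces the exact test on a
    17-vs-17 cohort with a 5-subject category)."""
    table = np.asarray(table, dtype=float)
    expected = st.contingency.expected_freq(table)
    if np.any(expected <= 5):
        if table.shape != (2, 2):
            raise ValueError("Fisher exact path requires a 2x2 table")
        res = st.fisher_exact(table)
        return GroupComparison(variable, group_names, "fisher",
                               float(res.statistic), float(res.pvalue),
                               {"expected_min": float(expected.min())})
    chi2, p, _, _ = st.chi2_contingency(table)
    return GroupComparison(variable, group_names, "chi2", float(chi2), float(p),
                           {"expected_min": float(expected.min())})


def compare_baseline(
    records: pd.DataFrame,
    continuous: tuple[str, ...] = ("age", "fma_ul", "fma_hand", "days_since_onset"),
    counts: tuple[str, ...] = ("sex",),
    group_col: str = "group",
    groups: tuple[str, ...] = ("LHS", "RHS"),
) -> pd.DataFrame:
    """Baseline characteristics table across the given groups."""
    out = []
    sub = records[records[group_col].isin(groups)]
    for var in continuous:
        if var not in sub.columns:
            continue
        samples = {g: sub.loc[sub[group_col] == g, var].dropna().to_numpy(float)
                   for g in groups}
        if any(len(v) < 2 for v in samples.values()):
            continue
        out.append(compare_continuous(samples, variable=var))
    for var in counts:
        if var not in sub.columns:
            continue
        levels = sorted(sub[var].dropna().unique())
        if len(levels) < 2:
            continue  # degenerate: no contrast to test
        table = np.array([
            [(sub[(sub[group_col] == g) & (sub[var] == lv)]).shape[0]
             for lv in levels] for g in groups])
        try:
            out.append(compare_counts(table, variable=var, group_names=groups))
        except ValueError:
            continue  # e.g. sparse non-2x2 table at tiny cohort sizes
    return pd.DataFrame([{
        "variable": c.variable, "groups": "/".join(c.groups), "test": c.test,
        "statistic": c.statistic, "p": c.p, "screening": c.screening,
    } for c in out])


def compare_auc(
    auc_values_a: np.ndarray, auc_values_b: np.ndarray,
    indicator: str = "", groups: tuple[str, str] = ("patient", "HS"),
) -> GroupComparison:
    """Two independent-samples t-test on AUC values."""
    a = np.asarray(auc_values_a, dtype=float)
    b = np.asarray(auc_values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 subjects")
    res = st.ttest_ind(a, b)
    return GroupComparison(indicator, groups, "t",
                           float(res.statistic), float(res.pvalue), {})


def spearman_with_fma(
    auc_values: np.ndarray, scores: np.ndarray
) -> tuple[float, float]:
    """Spearman rank correlation (ties mid-ranked) of AUCs against a score."""
    a = np.asarray(auc_values, dtype=float)
    s = np.asarray(scores, dtype=float)
    if a.size != s.size or a.size < 3:
        raise ValueError("need >= 3 paired observations")
    res = st.spearmanr(a, s)
    return float(res.statistic), float(res.pvalue)


def _piecewise_design(x: np.ndarray, breaks: tuple[float, ...]) -> np.ndarray:
    cols = [np.ones_like(x), x]
    for b in breaks:
        cols.append(np.maximum(x - b, 0.0))
    return np.column_stack(cols)


def _aicc(rss: float, n: int, k: int) -> float:
    """k = fitted parameters including sigma and any searched breakpoints."""
    if n - k - 1 <= 0:
        return np.inf
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_threshold_effect(
    auc_values: np.ndarray,
    scores: np.ndarray,
    max_breakpoints: int = 2,
    min_segment: int = 4,
    score_name: str = "FMA-UL",
    lowess_frac: float = 0.6,
) -> ThresholdEffectFit:
    """Smooth-curve plus segmented-linear threshold-effect analysis.

    Breakpoint candidates are the observed score values; models with 0..
    ``max_breakpoints`` breakpoints (each segment holding at least
    ``min_segment`` points) compete on AICc.
    """
    y = np.asarray(auc_values, dtype=float)
    x = np.asarray(scores, dtype=float)
    if y.size != x.size or y.size < 8:
        raise ValueError("need >= 8 paired observations")
    order = np.argsort(x)
    x, y = x[order], y[order]
    n = x.size

    smooth = lowess(y, x, frac=lowess_frac, return_sorted=True)
    smooth_x, smooth_y = smooth[:, 0], smooth[:, 1]

    # floor the RSS at a scale-relative tolerance so exactly-representable
    # data (constant, perfectly linear) cannot win extra breakpoints through
    # log-of-rounding-error comparisons
    rss_floor = 1e-12 * float(np.sum((y - y.mean()) ** 2)) \
        + 1e-20 * n * (1.0 + float(np.mean(y ** 2)))

    def fit(breaks: tuple[float, ...]) -> tuple[float, np.ndarray]:
        X = _piecewise_design(x, breaks)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = max(float(np.sum((y - X @ beta) ** 2)), rss_floor)
        return rss, beta

    candidates = np.unique(x)[1:-1]

    def seg_ok(breaks: tuple[float, ...]) -> bool:
        edges = [-np.inf, *breaks, np.inf]
        for i in range(len(edges) - 1):
            in_seg = (x >= edges[i]) & (x < edges[i + 1]) if i < len(edges) - 2 \
                else (x >= edges[i])
            if in_seg.sum() < min_segment:
                return False
        return True

    best: dict[int, tuple[float, tuple[float, ...], np.ndarray]] = {}
    rss0, beta0 = fit(())
    best[0] = (_aicc(rss0, n, 3), (), beta0)
    if max_breakpoints >= 1:
        found = None
        for b in candidates:
            if not seg_ok((b,)):
                continue
            rss, beta = fit((b,))
            crit = _aicc(rss, n, 5)
            if found is None or crit < found[0]:
                found = (crit, (float(b),), beta)
        if found:
            best[1] = found
    if max_breakpoints >= 2:
        found = None
        for b1, b2 in combinations(candidates, 2):
            if not seg_ok((b1, b2)):
                continue
            rss, beta = fit((b1, b2))
            crit = _aicc(rss, n, 7)
            if found is None or crit < found[0]:
                found = (crit, (float(b1), float(b2)), beta)
        if found:
            best[2] = found

    n_bp = min(best, key=lambda k: best[k][0])
    _, breaks, beta = best[n_bp]
    slopes = [float(beta[1])]
    for i in range(len(breaks)):
        slopes.append(slopes[-1] + float(beta[2 + i]))
    return ThresholdEffectFit(
        score_name=score_name, breakpoints=list(breaks), slopes=slopes,
        intercept=float(beta[0]), smooth_x=smooth_x, smooth_y=smooth_y,
        aicc={k: v[0] for k, v in best.items()},
        score_range=(float(x.min()), float(x.max())),
    )


def segment_correlations(
    fit: ThresholdEffectFit, auc_values: np.ndarray, scores: np.ndarray
) -> list[dict]:
    """Spearman r within each fitted segment; [a, b) intervals, last closed.

    Segments with fewer than 3 points are reported with r = NaN and
    ``defined = False`` rather than a fabricated value.
    """
    y = np.asarray(auc_values, dtype=float)
    x = np.asarray(scores, dtype=float)
    out = []
    bounds = fit.segment_bounds()
    for i, (lo, hi) in enumerate(bounds):
        last = i == len(bounds) - 1
        mask = (x >= lo) & ((x <= hi) if last else (x < hi))
        seg = {"lo": lo, "hi": hi, "n": int(mask.sum()), "closed_right": last}
        if mask.sum() >= 3 and np.ptp(x[mask]) > 0:
            r, p = spearman_with_fma(y[mask], x[mask])
            seg.update({"r": r, "p": p, "defined": True})
        else:
            seg.update({"r": np.nan, "p": np.nan, "defined": False})
        out.append(seg)
    return out
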