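"""Feature-trajectory statistics: Kruskal-Wallis, Dunn's post-hoc, stars.

Each feature is compared across the nine acquisition time points with the
rank-based Kruskal-Wallis test (tie-corrected, chi-square approximation) and
Dunn's pairwise post-hoc z-tests on mean ranks, Holm-adjusted by default.
Significance stars follow the usual convention: * p<0.05, ** p<0.01,
*** p<0.001, strict inequalities.
"""

from __future__ import annotations

from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "kruskal_wallis",
    "dunn_posthoc",
    "significance_stars",
    "trajectory_report",
    "group_feature_by_time",
]


def kruskal_wallis(groups: Dict[object, Sequence[float]]) -> Tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    ``groups`` maps group key -> values. All-identical data across groups is
    the degenerate no-signal case and returns (H=0, p=1).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    if sum(a.size for a in arrays) < 3:
        raise ValueError("need at least 3 values in total")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def _rank_with_ties(pooled: np.ndarray) -> Tuple[np.ndarray, float]:
    """Midranks and the Dunn tie-correction term sum(t^3 - t)."""
    ranks = sps.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    return ranks, tie_term


def dunn_posthoc(
    groups: Dict[object, Sequence[float]], correction: str = "holm"
) -> pd.DataFrame:
    """Dunn's pairwise post-hoc test on mean ranks with tie correction.

    Returns a symmetric DataFrame of adjusted two-sided p-values (unit
    diagonal). ``correction`` is "holm" (default), "bonferroni" or "none".
    """
    keys = list(groups.keys())
    if len(keys) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(groups[k], dtype=float) for k in keys]
    sizes = np.array([a.size for a in arrays])
    if np.any(sizes == 0):
        raise ValueError("every group must be non-empty")
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks, tie_term = _rank_with_ties(pooled)
    mean_ranks = []
    start = 0
    for size in sizes:
        mean_ranks.append(ranks[start : start + size].mean())
        start += size
    mean_ranks = np.asarray(mean_ranks)

    # pooled rank variance with tie correction
    base_var = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    raw_p, pairs = [], []
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            if base_var <= 0:  # all values tied
                p = 1.0
            else:
                se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
                z = (mean_ranks[i] - mean_ranks[j]) / se
                p = 2.0 * sps.norm.sf(abs(z))
            raw_p.append(min(p, 1.0))
            pairs.append((i, j))

    if correction == "none":
        adj = np.asarray(raw_p)
    elif correction in ("holm", "bonferroni"):
        adj = multipletests(raw_p, method=correction)[1]
    else:
        raise ValueError(f"unknown correction {correction!r}")

    mat = pd.DataFrame(np.ones((len(keys), len(keys))), index=keys, columns=keys)
    for (i, j), p in zip(pairs, adj):
        mat.iat[i, j] = p
        mat.iat[j, i] = p
    return mat


def significance_stars(p: float) -> str:
    """Map a p-value to its star code: *** <0.001, ** <0.01, * <0.05, else ns."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def group_feature_by_time(table: pd.DataFrame, feature: str) -> Dict[float, np.ndarray]:
    """Split one feature column into per-time-point value arrays."""
    return {
        float(t): g[feature].to_numpy(dtype=float)
        for t, g in table.groupby("time_h", sort=True)
    }


def trajectory_report(
    table: pd.DataFrame,
    features: Sequence[str],
    correction: str = "holm",
    baseline_h: float | None = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-feature trajectory statistics across time points.

    For each feature: Kruskal-Wallis H and p across all time groups, Dunn
    adjusted p-values for every comparison against the baseline time point
    (default: the earliest), star codes, and per-group five-number summaries.

    Returns (comparisons, box_summaries) as plot-ready DataFrames.
    """
    times = sorted(table["time_h"].unique())
    if len(times) < 2:
        raise ValueError("need at least 2 time points")
    t0 = float(baseline_h) if baseline_h is not None else float(times[0])
    if t0 not in [float(t) for t in times]:
        raise ValueError(f"baseline time {t0} not among time points {times}")

    comp_rows, box_rows = [], []
    for feat in features:
        groups = group_feature_by_time(table, feat)
        h, p_kw = kruskal_wallis(groups)
        dunn = dunn_posthoc(groups, correction=correction)
        for t in groups:
            if t == t0:
                continue
            p_adj = float(dunn.loc[t0, t])
            comp_rows.append(
                {
                    "feature": feat,
                    "comparison": f"{t0:g}h_vs_{t:g}h",
                    "H": h,
                    "kw_p": p_kw,
                    "p_adj": p_adj,
                    "stars": significance_stars(p_adj),
                }
            )
        for t, vals in groups.items():
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            iqr = q3 - q1
            lo_w = vals[vals >= q1 - 1.5 * iqr].min()
            hi_w = vals[vals <= q3 + 1.5 * iqr].max()
            box_rows.append(
                {
                    "feature": feat,
                    "time_h": t,
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                    "whisker_low": lo_w,
                    "whisker_high": hi_w,
                    "n_outliers": int(np.sum((vals < lo_w) | (vals > hi_w))),
                }
            )
    return pd.DataFrame(comp_rows), pd.DataFrame(box_rows)
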