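"""Feature-table cleaning, class labeling, and spline regression targets.

The infarct volume ratio is observed only 3 times per time point (one stained
brain per animal), while the echo feature table has 80 rows per time point.
A natural cubic spline through the per-time mean ratios turns the sparse
staining observations into a smooth severity target defined at every
acquisition time, which is then attached to each feature row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from sklearn.base import BaseEstimator, TransformerMixin

from .features import FEATURE_NAMES
from .simulate import EARLY_LABEL, LATE_LABEL, InfarctObservation

__all__ = [
    "FeatureTableCleaner",
    "clean_features",
    "assign_class_labels",
    "SplineTarget",
    "fit_infarct_spline",
    "attach_targets",
]


class FeatureTableCleaner(BaseEstimator, TransformerMixin):
    """Replace per-column z-score outliers with the median, then mean-fill NaNs.

    For every numeric feature column the z-scores are computed from that
    column's mean and standard deviation; entries with ``|z| > z_threshold``
    are replaced by the column median (medians taken before any replacement),
    and any remaining missing entries are filled with the column mean. One
    pass, no iteration, so the operation is idempotent on its own output.

    Fitted on a table, the learned statistics (``medians_``, ``fill_means_``,
    ``means_``, ``sds_``) can be re-applied to new rows sklearn-style; the
    module-level :func:`clean_features` fits and transforms in one call, which
    is the within-table cleaning used by the pipeline.
    """

    def __init__(self, z_threshold: float = 3.0, columns: Sequence[str] | None = None):
        self.z_threshold = z_threshold
        self.columns = columns

    def fit(self, X: pd.DataFrame, y=None):
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be > 0")
        cols = list(self.columns) if self.columns is not None else [
            c for c in X.columns if c in FEATURE_NAMES
        ]
        if not cols:
            cols = [c for c in X.columns if pd.api.types.is_numeric_dtype(X[c])]
        missing = [c for c in cols if c not in X.columns]
        if missing:
            raise ValueError(f"columns not in table: {missing}")
        for c in cols:
            if X[c].isna().all():
                raise ValueError(f"column {c!r} is entirely missing; cannot clean")
        self.columns_ = cols
        self.means_ = X[cols].mean()
        self.sds_ = X[cols].std(ddof=1)
        self.medians_ = X[cols].median()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        for c in self.columns_:
            col = out[c].astype(float)
            sd = self.sds_[c]
            if not np.isfinite(sd) or sd == 0:
                warnings.warn(
                    f"column {c!r} has zero/undefined SD; outlier step skipped",
                    stacklevel=2,
                )
            else:
                z = (col - self.means_[c]) / sd
                col = col.mask(z.abs() > self.z_threshold, self.medians_[c])
            # mean-fill uses the post-replacement column mean so a cleaned
            # table re-cleans to itself
            col = col.fillna(col.mean())
            out[c] = col
        return out


def clean_features(
    table: pd.DataFrame,
    z_threshold: float = 3.0,
    columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One-shot z-score outlier replacement + mean imputation on a table."""
    cleaner = FeatureTableCleaner(z_threshold=z_threshold, columns=columns)
    return cleaner.fit(table).transform(table)


def assign_class_labels(table: pd.DataFrame, boundary_h: float = 4.5) -> pd.DataFrame:
    """Label rows early (cytotoxic) vs late (vasogenic) edema by time post-onset.

    Rows with ``time_h <= boundary_h`` are labeled early; the boundary must
    fall strictly inside the observed time range and both classes must be
    non-empty (a degenerate single-class labeling is a configuration error).
    """
    times = table["time_h"].to_numpy(dtype=float)
    if boundary_h < times.min() or boundary_h >= times.max():
        raise ValueError(
            f"boundary_h={boundary_h} outside observed time range "
            f"[{times.min()}, {times.max()})"
        )
    labels = np.where(times <= boundary_h, EARLY_LABEL, LATE_LABEL)
    if len(set(labels)) < 2:
        raise ValueError("class boundary leaves one class empty")
    out = table.copy()
    out["class_label"] = labels
    return out


@dataclass(frozen=True)
class SplineTarget:
    """Natural cubic spline through per-time mean infarct ratios."""

    knot_times_h: np.ndarray
    knot_means: np.ndarray
    _spline: CubicSpline

    def evaluate(self, time_h, clamp: bool = True) -> np.ndarray:
        """Evaluate inside the knot range; clamped to [0, 1] unless disabled."""
        t = np.asarray(time_h, dtype=float)
        lo, hi = self.knot_times_h[0], self.knot_times_h[-1]
        if np.any(t < lo) or np.any(t > hi):
            bad = np.atleast_1d(t)[(np.atleast_1d(t) < lo) | (np.atleast_1d(t) > hi)]
            raise ValueError(f"times outside spline domain [{lo}, {hi}]: {bad.tolist()}")
        vals = self._spline(t)
        if clamp:
            vals = np.clip(vals, 0.0, 1.0)
        return float(vals) if np.isscalar(time_h) else vals

    def __call__(self, time_h) -> np.ndarray:
        return self.evaluate(time_h, clamp=True)


def fit_infarct_spline(observations: Sequence[InfarctObservation]) -> SplineTarget:
    """Fit a natural cubic spline through the per-time mean infarct ratios.

    Observations are grouped by time (duplicates averaged, times sorted); at
    least two distinct time points are required. The interpolant passes
    exactly through every knot mean.
    """
    if not observations:
        raise ValueError("no observations")
    df = pd.DataFrame(
        {"time_h": [o.time_h for o in observations], "ratio": [o.ratio for o in observations]}
    )
    grouped = df.groupby("time_h", sort=True)["ratio"].mean()
    times = grouped.index.to_numpy(dtype=float)
    means = grouped.to_numpy(dtype=float)
    if times.size < 2:
        raise ValueError("need at least 2 distinct time points for a spline")
    spline = CubicSpline(times, means, bc_type="natural")
    return SplineTarget(knot_times_h=times, knot_means=means, _spline=spline)


def attach_targets(table: pd.DataFrame, spline: SplineTarget) -> pd.DataFrame:
    """Attach ``target_ratio`` = spline(time_h) to every feature row."""
    out = table.copy()
    out["target_ratio"] = spline(out["time_h"].to_numpy(dtype=float))
    return out
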