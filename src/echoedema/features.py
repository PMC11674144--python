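"""The 22 time- and frequency-domain echo-signal features.

Thirteen time-domain statistics are computed on the DC-removed waveform and
nine frequency-domain statistics on its one-sided spectrum. The definitions
are the classical vibration/ultrasound feature set with two deliberate
conventions kept exactly as used in this analysis rather than "corrected" to
textbook forms:

* kurtosis and skewness use a 1/N central-moment numerator over a standard
  deviation computed with 1/(N-1) (Pearson, non-excess kurtosis);
* impulse factor and crest factor are built on the peak-to-peak amplitude
  (F4/F5 and F4/F10), not on the maximum.

``N`` is context dependent: the sample count for time-domain features and the
one-sided bin count for the frequency-domain averages (mean magnitude,
average power).
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .signal_processing import Spectrum, compute_spectrum, remove_dc
from .simulate import EchoRecord

__all__ = [
    "FEATURE_NAMES",
    "TIME_DOMAIN_NAMES",
    "FREQUENCY_DOMAIN_NAMES",
    "DEFAULT_SELECTED_16",
    "time_domain_features",
    "frequency_domain_features",
    "extract_features",
    "extract_feature_table",
    "select_features",
    "EchoFeatureExtractor",
]

TIME_DOMAIN_NAMES: List[str] = [
    "maximum",            # F1
    "minimum",            # F2
    "mean",               # F3
    "peak_to_peak",       # F4
    "absolute_average",   # F5
    "variance",           # F6
    "standard_deviation", # F7
    "kurtosis",           # F8
    "skewness",           # F9
    "root_mean_square",   # F10
    "shape_factor",       # F11
    "impulse_factor",     # F12
    "crest_factor",       # F13
]

FREQUENCY_DOMAIN_NAMES: List[str] = [
    "mean_magnitude_freq",    # F14
    "centroid_frequency",     # F15
    "mean_squared_frequency", # F16
    "variance_frequency",     # F17 = sqrt(F16)
    "frequency_variance",     # F18
    "mean_frequency",         # F19
    "total_power",            # F20
    "average_power",          # F21
    "peak_frequency",         # F22
]

FEATURE_NAMES: List[str] = TIME_DOMAIN_NAMES + FREQUENCY_DOMAIN_NAMES

#: the 16 features with significant 0 h vs 24 h differences used for modeling
DEFAULT_SELECTED_16: List[str] = [
    "maximum",
    "minimum",
    "peak_to_peak",
    "absolute_average",
    "variance",
    "standard_deviation",
    "kurtosis",
    "skewness",
    "root_mean_square",
    "shape_factor",
    "impulse_factor",
    "crest_factor",
    "mean_magnitude_freq",
    "mean_frequency",
    "total_power",
    "average_power",
]

METADATA_COLUMNS = ["subject_id", "time_h", "replicate", "degenerate"]


def time_domain_features(samples: np.ndarray) -> Dict[str, float]:
    """The 13 time-domain statistics of a waveform.

    A constant signal (zero RMS / zero SD / zero mean absolute amplitude) is
    degenerate: the ratio features are reported as NaN, never infinity, and
    the caller flags the record.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("samples must be finite")
    n = x.size
    f1 = float(x.max())
    f2 = float(x.min())
    f3 = float(x.mean())
    f4 = f1 - f2
    f5 = float(np.abs(x).mean())
    dev = x - f3
    f6 = float(np.sum(dev**2) / (n - 1))
    f7 = math.sqrt(f6)
    f10 = math.sqrt(float(np.mean(x**2)))
    if f7 > 0:
        f8 = float(np.mean(dev**4)) / f7**4
        f9 = float(np.mean(dev**3)) / f7**3
    else:
        f8 = math.nan
        f9 = math.nan
    f11 = f10 / f5 if f5 > 0 else math.nan
    f12 = f4 / f5 if f5 > 0 else math.nan
    f13 = f4 / f10 if f10 > 0 else math.nan
    return dict(
        zip(
            TIME_DOMAIN_NAMES,
            [f1, f2, f3, f4, f5, f6, f7, f8, f9, f10, f11, f12, f13],
        )
    )


def frequency_domain_features(spectrum: Spectrum) -> Dict[str, float]:
    """The 9 frequency-domain statistics of a one-sided spectrum.

    Magnitude-weighted moments (centroid, mean-squared frequency, frequency
    variance) and the power-weighted mean frequency; peak frequency ties break
    to the lowest frequency. An all-zero spectrum is degenerate: the weighted
    moments come back NaN.
    """
    f = np.asarray(spectrum.freqs, dtype=float)
    a = np.asarray(spectrum.magnitude, dtype=float)
    p = np.asarray(spectrum.power, dtype=float)
    nb = spectrum.n_bins
    sum_a = float(a.sum())
    sum_p = float(p.sum())
    f14 = sum_a / nb
    f20 = sum_p
    f21 = sum_p / nb
    if sum_a > 0 and sum_p > 0:
        f15 = float((f * a).sum()) / sum_a
        f16 = float((f**2 * a).sum()) / sum_a
        f17 = math.sqrt(f16)
        f18 = float(((f - f15) ** 2 * a).sum()) / sum_a
        f19 = float((f * p).sum()) / sum_p
        f22 = float(f[int(np.argmax(p))])  # argmax returns the first (lowest-f) maximum
    else:
        f15 = f16 = f17 = f18 = f19 = f22 = math.nan
    return dict(
        zip(
            FREQUENCY_DOMAIN_NAMES,
            [f14, f15, f16, f17, f18, f19, f20, f21, f22],
        )
    )


def extract_features(record: EchoRecord) -> Dict[str, float]:
    """All 22 features of one record: DC removal, time stats, spectrum stats.

    Returns the feature dict plus a boolean ``degenerate`` entry; degenerate
    records (e.g. an all-zero waveform) carry NaNs in the ratio/moment
    features instead of raising.
    """
    x = remove_dc(record.samples)
    feats = time_domain_features(x)
    spec = compute_spectrum(x, record.sampling_rate_hz)
    feats.update(frequency_domain_features(spec))
    feats["degenerate"] = any(
        isinstance(v, float) and math.isnan(v) for v in feats.values()
    )
    return feats


def extract_feature_table(records: Iterable[EchoRecord]) -> pd.DataFrame:
    """Feature table: one row per record, provenance columns + 22 features."""
    rows = []
    for rec in records:
        row = {
            "subject_id": rec.subject_id,
            "time_h": rec.time_h,
            "replicate": rec.replicate,
        }
        row.update(extract_features(rec))
        rows.append(row)
    df = pd.DataFrame(rows)
    return df[["subject_id", "time_h", "replicate"] + FEATURE_NAMES + ["degenerate"]]


def select_features(table: pd.DataFrame, feature_set: Sequence[str]) -> pd.DataFrame:
    """Column-subset the feature table, preserving rows and metadata columns."""
    names = list(feature_set)
    if not names:
        raise ValueError("feature set must not be empty")
    unknown = [n for n in names if n not in table.columns]
    if unknown:
        raise ValueError(f"unknown feature name(s): {unknown}")
    meta = [c for c in table.columns if c in METADATA_COLUMNS or c in ("class_label", "target_ratio")]
    return table[meta + names].copy()


class EchoFeatureExtractor(BaseEstimator, TransformerMixin):
    """Stateless sklearn-style transformer from echo records to a feature table.

    ``transform`` accepts a sequence of :class:`EchoRecord` and returns the
    numeric feature matrix (DataFrame); ``fit`` is a no-op kept for pipeline
    compatibility.
    """

    def __init__(self, feature_set: Sequence[str] | None = None):
        self.feature_set = feature_set

    def fit(self, X, y=None):  # noqa: D102 - sklearn protocol
        self.feature_names_ = list(self.feature_set) if self.feature_set else list(FEATURE_NAMES)
        unknown = [n for n in self.feature_names_ if n not in FEATURE_NAMES]
        if unknown:
            raise ValueError(f"unknown feature name(s): {unknown}")
        return self

    def transform(self, X: Sequence[EchoRecord]) -> pd.DataFrame:
        if not hasattr(self, "feature_names_"):
            self.fit(X)
        table = extract_feature_table(X)
        return table[self.feature_names_]

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)
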