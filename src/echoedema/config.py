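"""Configuration objects for cohort simulation and the end-to-end pipeline.

All knobs that govern a run live here so that a run directory can carry an
exact, re-executable snapshot of its configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

__all__ = ["CohortConfig", "PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a configuration value violates its contract."""


DEFAULT_TIME_POINTS_H = (0.0, 1.0, 2.0, 3.0, 6.0, 9.0, 12.0, 18.0, 24.0)


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a simulated longitudinal echo cohort.

    The defaults mirror a 20-subject stroke-model study sampled at nine time
    points over 24 h with four repeat measurements per time point (720 records)
    and three infarct-volume-ratio observations per time point (27 total).

    Parameters
    ----------
    n_subjects : int
        Number of subjects in the cohort.
    time_points_h : sequence of float
        Measurement times in hours, strictly increasing, starting at 0.
    n_replicates : int
        Repeat echo measurements per subject and time point.
    sampling_rate_hz : float
        Waveform sampling rate. The acquisition hardware this emulates ran at
        500 MSa/s; the default is reduced tenfold to keep arrays desk-scale
        while preserving >20x oversampling of the 2.25 MHz carrier.
    record_duration_s : float
        Length of the acquired echo window in seconds.
    center_frequency_hz : float
        Transducer center frequency (2.25 MHz flat probe).
    amplitude_decline_gamma : float
        Fractional loss of echo amplitude at full edema severity, in [0, 1].
        Vasogenic edema lowers tissue density and acoustic impedance, hence
        weaker echoes as severity grows.
    severity_midpoint_h, severity_rate : float
        Logistic severity curve parameters: severity is flat near 0 for the
        first ~3 h, then rises through 24 h.
    noise_sd : float
        Standard deviation of additive measurement noise (amplitude units).
    artifact_prob : float
        Probability that a record carries a low-frequency movement/respiration
        baseline excursion.
    infarct_max_ratio : float
        Asymptotic infarct volume ratio reached at 24 h (default 0.482).
    infarct_noise_sd : float
        Standard deviation of the per-animal infarct-ratio observation noise.
    seed : int
        Root seed; the whole cohort is a pure function of the config.
    """

    n_subjects: int = 20
    time_points_h: Sequence[float] = DEFAULT_TIME_POINTS_H
    n_replicates: int = 4
    sampling_rate_hz: float = 5e7
    record_duration_s: float = 4e-5
    center_frequency_hz: float = 2.25e6
    amplitude_decline_gamma: float = 0.8
    severity_midpoint_h: float = 6.0
    severity_rate: float = 1.0
    noise_sd: float = 0.05
    artifact_prob: float = 0.05
    infarct_max_ratio: float = 0.482
    infarct_noise_sd: float = 0.03
    subject_effect_sd: float = 0.1
    n_infarct_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        tp = tuple(float(t) for t in self.time_points_h)
        object.__setattr__(self, "time_points_h", tp)
        if len(tp) == 0 or tp[0] != 0.0:
            raise ConfigError("time_points_h must start at 0")
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ConfigError("time_points_h must be strictly increasing")
        if self.n_subjects < 1 or self.n_replicates < 1:
            raise ConfigError("n_subjects and n_replicates must be >= 1")
        if not 0.0 <= self.amplitude_decline_gamma <= 1.0:
            raise ConfigError("amplitude_decline_gamma must be in [0, 1]")
        if not 0.0 <= self.infarct_max_ratio <= 1.0:
            raise ConfigError("infarct_max_ratio must be in [0, 1]")
        if not 0.0 <= self.artifact_prob <= 1.0:
            raise ConfigError("artifact_prob must be in [0, 1]")
        if self.noise_sd < 0 or self.infarct_noise_sd < 0:
            raise ConfigError("noise scales must be non-negative")
        if self.record_duration_s * self.sampling_rate_hz < 64:
            raise ConfigError(
                "record_duration_s * sampling_rate_hz must give >= 64 samples"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.record_duration_s * self.sampling_rate_hz))

    @property
    def n_records(self) -> int:
        return self.n_subjects * len(self.time_points_h) * self.n_replicates

    def to_dict(self) -> dict:
        d = asdict(self)
        d["time_points_h"] = list(self.time_points_h)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        return cls(**d)


@dataclass
class PipelineConfig:
    """End-to-end run configuration: cohort, cleaning, labeling, modeling."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    z_threshold: float = 3.0
    boundary_h: float = 4.5
    feature_set: str = "default16"
    classifiers: Sequence[str] = ("svm", "logistic_regression", "decision_tree", "random_forest")
    regressors: Sequence[str] = ("svm", "random_forest", "linear", "fnn")
    folds: int = 10
    seed: int = 0
    fold_wise_standardization: bool = True
    group_by_subject: bool = False

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise ConfigError("z_threshold must be > 0")
        if self.folds < 2:
            raise ConfigError("folds must be >= 2")
        self.classifiers = tuple(self.classifiers)
        self.regressors = tuple(self.regressors)

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort.to_dict(),
            "z_threshold": self.z_threshold,
            "boundary_h": self.boundary_h,
            "feature_set": self.feature_set,
            "classifiers": list(self.classifiers),
            "regressors": list(self.regressors),
            "folds": self.folds,
            "seed": self.seed,
            "fold_wise_standardization": self.fold_wise_standardization,
            "group_by_subject": self.group_by_subject,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        cohort = d.pop("cohort", {})
        if not isinstance(cohort, CohortConfig):
            cohort = CohortConfig.from_dict(cohort)
        return cls(cohort=cohort, **d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
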