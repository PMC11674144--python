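"""Synthetic A-mode echo cohorts for a rodent cerebral-edema time course.

No public dataset of raw intracranial echo waveforms exists for this problem,
so the package carries a forward model that reproduces the phenomenology the
downstream analysis depends on: echo amplitude is stable for the first ~3 h
after ischemia onset and then declines through 24 h as vasogenic edema lowers
tissue density and acoustic impedance, while the infarct volume ratio rises
toward ~0.482 at 24 h.

The waveform model is a sum of Gaussian-modulated cosine pulses (a strong
skull interface echo followed by randomly placed parenchyma reflectors) whose
global amplitude scale is ``a0 * (1 - gamma * severity) * exp(subject_effect)``,
plus white measurement noise and, with small probability, a low-frequency
movement/respiration baseline excursion. Because the noise floor is fixed
while the echo amplitude declines, both amplitude-linked features (maximum,
RMS, total power, ...) and scale-invariant shape features (kurtosis, crest
factor, mean frequency, ...) drift with severity, as observed in vivo.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np

from .config import CohortConfig, ConfigError

__all__ = [
    "EchoRecord",
    "InfarctObservation",
    "HemisphereVolumes",
    "severity_curve",
    "generate_echo",
    "generate_cohort",
    "infarct_ratio",
    "generate_infarct_observations",
    "write_cohort",
    "class_label_for_time",
]

# fraction of each pulse added as its (positive) envelope: gives healthy
# high-SNR records a small positive skew that washes out as SNR drops
ENVELOPE_MIX = 0.3
PULSE_BASE_AMPLITUDE = 1.0
N_SCATTERERS = 12
EARLY_LABEL = "early_cytotoxic"
LATE_LABEL = "late_vasogenic"


@dataclass(frozen=True)
class EchoRecord:
    """One sampled echo waveform with its provenance."""

    subject_id: str
    time_h: float
    replicate: int
    samples: np.ndarray
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        object.__setattr__(self, "samples", samples)


@dataclass(frozen=True)
class InfarctObservation:
    """One TTC-staining infarct volume ratio at a time point."""

    time_h: float
    ratio: float
    replicate: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.ratio <= 1.0:
            raise ValueError("ratio must be in [0, 1]")


@dataclass(frozen=True)
class HemisphereVolumes:
    """Hemisphere volumes from staining, in mm^3."""

    contralateral_volume: float
    unstained_ipsilateral_volume: float


def severity_curve(time_h: float, config: CohortConfig) -> float:
    """Edema severity in [0, 1] as a logistic function of hours post-onset.

    Anchored near 0 at onset (<= 0.05 at t=0 with defaults), flat through the
    first ~3 h, and saturating (>= 0.95) by 24 h; monotone non-decreasing.
    """
    t = np.asarray(time_h, dtype=float)
    if np.any(t < 0):
        raise ConfigError("time_h must be non-negative")
    s = 1.0 / (1.0 + np.exp(-config.severity_rate * (t - config.severity_midpoint_h)))
    return float(s) if np.isscalar(time_h) else s


def _pulse_train(
    n: int,
    fs: float,
    fc: float,
    positions: np.ndarray,
    amplitudes: np.ndarray,
    phases: np.ndarray,
    widths: np.ndarray,
) -> np.ndarray:
    """Sum of Gabor pulses plus a small positive envelope component."""
    t = np.arange(n) / fs
    wave = np.zeros(n)
    for t0, amp, phi, sigma in zip(positions, amplitudes, phases, widths):
        env = amp * np.exp(-0.5 * ((t - t0) / sigma) ** 2)
        wave += env * (np.cos(2 * np.pi * fc * (t - t0) + phi) + ENVELOPE_MIX)
    return wave


def generate_echo(
    severity: float,
    subject_effect: float,
    config: CohortConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one echo waveform at the given severity.

    The expected pulse amplitude decreases strictly with severity:
    ``a = a0 * (1 - amplitude_decline_gamma * severity) * exp(subject_effect)``.
    """
    if not 0.0 <= severity <= 1.0:
        raise ConfigError("severity must be in [0, 1]")
    n = config.n_samples
    fs = config.sampling_rate_hz
    duration = config.record_duration_s
    scale = (
        PULSE_BASE_AMPLITUDE
        * (1.0 - config.amplitude_decline_gamma * severity)
        * np.exp(subject_effect)
    )

    # skull interface echo: early, strong, fixed-ish position
    skull_pos = np.array([duration * (0.08 + 0.02 * rng.random())])
    skull_amp = np.array([scale])
    # parenchyma scatterers: much weaker than the bone-tissue interface
    # (soft-tissue backscatter vs a large impedance step), spread over the record
    scat_pos = rng.uniform(0.15 * duration, 0.95 * duration, size=N_SCATTERERS)
    scat_amp = scale * rng.uniform(0.08, 0.25, size=N_SCATTERERS)

    positions = np.concatenate([skull_pos, scat_pos])
    amplitudes = np.concatenate([skull_amp, scat_amp])
    phases = rng.uniform(0, 2 * np.pi, size=positions.size)
    # pulse width ~ a few carrier cycles
    widths = rng.uniform(1.5, 3.0, size=positions.size) / config.center_frequency_hz

    wave = _pulse_train(n, fs, config.center_frequency_hz, positions, amplitudes, phases, widths)
    wave += rng.normal(0.0, config.noise_sd, size=n)

    if rng.random() < config.artifact_prob:
        # movement/respiration: slow half-sine baseline excursion
        t = np.arange(n) / n
        start = rng.uniform(0.0, 0.5)
        span = rng.uniform(0.3, 0.5)
        mask = (t >= start) & (t <= start + span)
        excursion = rng.uniform(0.3, 0.8) * rng.choice([-1.0, 1.0])
        wave[mask] += excursion * np.sin(np.pi * (t[mask] - start) / span)
    return wave


def class_label_for_time(time_h: float, boundary_h: float = 4.5) -> str:
    """Early (cytotoxic) vs late (vasogenic) edema label by time post-onset."""
    return EARLY_LABEL if time_h <= boundary_h else LATE_LABEL


def generate_cohort(config: CohortConfig) -> List[EchoRecord]:
    """Generate the full cohort: n_subjects x time points x replicates records.

    Bit-for-bit reproducible for a fixed config (including seed). Each subject
    carries one random amplitude effect shared across all of its records.
    """
    rng = np.random.default_rng(config.seed)
    subject_effects = rng.normal(0.0, config.subject_effect_sd, size=config.n_subjects)
    records: List[EchoRecord] = []
    for i in range(config.n_subjects):
        subject_id = f"S{i + 1:02d}"
        for t in config.time_points_h:
            sev = severity_curve(t, config)
            for rep in range(1, config.n_replicates + 1):
                samples = generate_echo(sev, subject_effects[i], config, rng)
                records.append(
                    EchoRecord(
                        subject_id=subject_id,
                        time_h=float(t),
                        replicate=rep,
                        samples=samples,
                        sampling_rate_hz=config.sampling_rate_hz,
                    )
                )
    return records


def infarct_ratio(volumes: HemisphereVolumes) -> float:
    """Infarct volume ratio: (contralateral - unstained ipsilateral) / contralateral.

    May be negative when the unstained ipsilateral volume exceeds the
    contralateral hemisphere (possible with noisy volumetry); a warning is
    emitted rather than silently clamping.
    """
    if volumes.contralateral_volume <= 0:
        raise ValueError("contralateral_volume must be > 0")
    if volumes.unstained_ipsilateral_volume < 0:
        raise ValueError("unstained_ipsilateral_volume must be >= 0")
    r = (
        volumes.contralateral_volume - volumes.unstained_ipsilateral_volume
    ) / volumes.contralateral_volume
    if r < 0:
        warnings.warn(
            "infarct ratio is negative (unstained volume exceeds contralateral)",
            stacklevel=2,
        )
    return r


def generate_infarct_observations(config: CohortConfig) -> List[InfarctObservation]:
    """Three noisy infarct-ratio observations per time point, clamped to [0, 1].

    Each observation is ``infarct_max_ratio * severity(t) + noise`` so the
    per-time means track the severity curve and reach ~infarct_max_ratio at
    the last time point. Uses a seed stream separate from the waveform RNG so
    waveforms and staining observations are independently reproducible.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    obs: List[InfarctObservation] = []
    for t in config.time_points_h:
        mean = config.infarct_max_ratio * severity_curve(t, config)
        for rep in range(1, config.n_infarct_replicates + 1):
            r = mean + rng.normal(0.0, config.infarct_noise_sd)
            obs.append(
                InfarctObservation(
                    time_h=float(t), ratio=float(np.clip(r, 0.0, 1.0)), replicate=rep
                )
            )
    return obs


def write_cohort(
    records: Sequence[EchoRecord],
    observations: Sequence[InfarctObservation],
    out_dir: str | Path,
    boundary_h: float = 4.5,
    write_waveforms: bool = True,
) -> Tuple[Path, Path]:
    """Persist a cohort: per-record waveform CSVs, a manifest, and infarct CSV.

    Returns (manifest_path, infarct_path).
    """
    from .signal_processing import write_waveform

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    wf_dir = out_dir / "waveforms"
    manifest_path = out_dir / "manifest.csv"
    infarct_path = out_dir / "infarct_observations.csv"

    if write_waveforms:
        wf_dir.mkdir(exist_ok=True)
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "time_h", "replicate", "file", "class_label"])
        for rec in records:
            fname = f"waveforms/{rec.subject_id}_t{rec.time_h:g}_r{rec.replicate}.csv"
            if write_waveforms:
                write_waveform(rec, out_dir / fname)
            writer.writerow(
                [
                    rec.subject_id,
                    f"{rec.time_h:g}",
                    rec.replicate,
                    fname,
                    class_label_for_time(rec.time_h, boundary_h),
                ]
            )
    with open(infarct_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_h", "replicate", "ratio"])
        for ob in observations:
            writer.writerow([f"{ob.time_h:g}", ob.replicate, repr(ob.ratio)])
    return manifest_path, infarct_path
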