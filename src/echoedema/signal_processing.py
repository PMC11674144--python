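"""Waveform I/O, DC removal and one-sided spectra.

The spectral convention is the mean-power one: the one-sided amplitude of an
on-bin tone equals its waveform amplitude, its per-bin power equals A^2/2, and
the summed power equals the mean square of the (zero-mean) signal — i.e.
Parseval holds exactly under this scaling. Downstream features are either
scale-covariant or scale-invariant, so any consistent convention would give
the same standardized feature table; this one makes the power features read
directly in mean-square amplitude units.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .simulate import EchoRecord

__all__ = ["Spectrum", "remove_dc", "compute_spectrum", "read_waveform", "write_waveform"]


class WaveformFormatError(ValueError):
    """Raised for malformed waveform CSV files."""


@dataclass(frozen=True)
class Spectrum:
    """One-sided magnitude and power spectra on an ascending frequency axis."""

    freqs: np.ndarray
    magnitude: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.freqs) == len(self.magnitude) == len(self.power)):
            raise ValueError("freqs, magnitude and power must have equal length")

    @property
    def n_bins(self) -> int:
        return len(self.freqs)


def remove_dc(samples: np.ndarray) -> np.ndarray:
    """Subtract the arithmetic mean; length preserved, result zero-mean."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("samples must be non-empty")
    if not np.all(np.isfinite(samples)):
        raise ValueError("samples must be finite")
    return samples - samples.mean()


def compute_spectrum(samples: np.ndarray, sampling_rate_hz: float) -> Spectrum:
    """One-sided spectrum of a real signal.

    A(f_k) = (2/N)|X_k| for interior bins and (1/N)|X_k| at DC and Nyquist;
    P(f_k) = A^2/2 interior, A^2 at the edges. With this scaling
    sum(P) == mean(x^2) exactly (Parseval).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError("need at least 2 samples")
    if not np.all(np.isfinite(samples)):
        raise ValueError("samples must be finite")
    n = samples.size
    spec = np.fft.rfft(samples)
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate_hz)
    magnitude = (2.0 / n) * np.abs(spec)
    power = magnitude**2 / 2.0
    # DC bin, and the Nyquist bin when n is even, are not doubled
    edge = [0, -1] if n % 2 == 0 else [0]
    magnitude[edge] /= 2.0
    power[edge] = magnitude[edge] ** 2
    return Spectrum(freqs=freqs, magnitude=magnitude, power=power)


def write_waveform(record: EchoRecord, path: str | Path) -> None:
    """Write one record as CSV: a sampling-rate header line then time,amplitude."""
    path = Path(path)
    t = np.arange(record.samples.size) / record.sampling_rate_hz
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz={record.sampling_rate_hz!r}\n")
        fh.write("time_s,amplitude\n")
        for ti, xi in zip(t, record.samples):
            fh.write(f"{float(ti)!r},{float(xi)!r}\n")


def read_waveform(
    path: str | Path,
    subject_id: str = "unknown",
    time_h: float = 0.0,
    replicate: int = 1,
) -> EchoRecord:
    """Read a waveform CSV written by :func:`write_waveform`.

    Round-trips samples to within float round-off and preserves the sampling
    rate exactly. Malformed headers or non-numeric rows raise
    :class:`WaveformFormatError` naming the offending line.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("# sampling_rate_hz="):
        raise WaveformFormatError(f"{path}: line 1: missing sampling_rate_hz header")
    try:
        fs = float(lines[0].split("=", 1)[1])
    except ValueError as exc:
        raise WaveformFormatError(f"{path}: line 1: unreadable sampling rate") from exc
    if len(lines) < 2 or lines[1].strip() != "time_s,amplitude":
        raise WaveformFormatError(f"{path}: line 2: expected 'time_s,amplitude' header")
    amps = []
    for lineno, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise WaveformFormatError(f"{path}: line {lineno}: expected two columns")
        try:
            amps.append(float(parts[1]))
        except ValueError as exc:
            raise WaveformFormatError(
                f"{path}: line {lineno}: non-numeric amplitude {parts[1]!r}"
            ) from exc
    if not amps:
        raise WaveformFormatError(f"{path}: no data rows")
    return EchoRecord(
        subject_id=subject_id,
        time_h=time_h,
        replicate=replicate,
        samples=np.array(amps),
        sampling_rate_hz=fs,
    )
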