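"""Calibrated acoustic test stimuli.

Pressure waveforms are represented in pascal, with sound level in dB SPL
re 20 uPa.  Tones and white noise are normalised to the exact target RMS
pressure after windowing, so level arithmetic is exact: raising the level
by ``d`` dB scales the samples by ``10**(d/20)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.io import wavfile

__all__ = [
    "P_REF",
    "Stimulus",
    "synthesize_tone",
    "synthesize_white_noise",
    "write_wav",
    "read_wav",
]

#: Reference pressure for dB SPL, in pascal.
P_REF = 20e-6


def spl_to_pa(level_db_spl: float) -> float:
    """RMS pressure (Pa) of a sound at ``level_db_spl`` dB SPL."""
    return P_REF * 10.0 ** (level_db_spl / 20.0)


@dataclass(frozen=True)
class Stimulus:
    """A sampled pressure waveform with a calibrated level.

    Attributes
    ----------
    samples : ndarray
        Pressure waveform in Pa.
    sample_rate : float
        Sampling rate in Hz.
    frequency : float or None
        Tone frequency in Hz, or None for noise.
    level : float
        Calibrated overall level in dB SPL re 20 uPa.
    duration : float
        Nominal duration in seconds.
    """

    samples: np.ndarray = field(repr=False)
    sample_rate: float
    frequency: float | None
    level: float
    duration: float

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))

    @property
    def measured_level(self) -> float:
        """Level in dB SPL computed from the actual samples."""
        return 20.0 * np.log10(self.rms / P_REF)

    def scaled_to(self, level: float) -> "Stimulus":
        """Same waveform rescaled exactly to a new dB SPL level."""
        gain = 10.0 ** ((level - self.level) / 20.0)
        return replace(self, samples=self.samples * gain, level=level)


def _cosine_ramp(n_samples: int, sample_rate: float, ramp: float) -> np.ndarray:
    env = np.ones(n_samples)
    n_ramp = int(round(ramp * sample_rate))
    if n_ramp > 0:
        r = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        env[:n_ramp] = r
        env[-n_ramp:] = r[::-1]
    return env


def _finalize(x: np.ndarray, level: float, sample_rate: float, ramp: float) -> np.ndarray:
    if ramp < 0:
        raise ValueError("ramp must be non-negative")
    if ramp > 0:
        if 2 * ramp * sample_rate > x.size:
            raise ValueError("ramps longer than the stimulus")
        x = x * _cosine_ramp(x.size, sample_rate, ramp)
    rms = np.sqrt(np.mean(x**2))
    return x * (spl_to_pa(level) / rms)


def synthesize_tone(
    frequency: float,
    level: float,
    duration: float,
    sample_rate: float = 44100.0,
    ramp: float = 0.01,
) -> Stimulus:
    """Pure tone at ``frequency`` Hz and ``level`` dB SPL.

    A raised-cosine on/off ramp of ``ramp`` seconds (default 10 ms) avoids
    spectral splatter; set ``ramp=0`` to disable.  The waveform is
    normalised so its overall RMS matches the requested level exactly.
    """
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if sample_rate <= 2 * frequency:
        raise ValueError(
            f"sample_rate {sample_rate} Hz cannot represent a {frequency} Hz tone"
        )
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    x = np.sin(2.0 * np.pi * frequency * t)
    return Stimulus(
        samples=_finalize(x, level, sample_rate, ramp),
        sample_rate=sample_rate,
        frequency=frequency,
        level=level,
        duration=duration,
    )


def synthesize_white_noise(
    level: float,
    duration: float,
    sample_rate: float = 44100.0,
    seed: int = 0,
    ramp: float = 0.01,
) -> Stimulus:
    """Flat-spectrum Gaussian noise at a calibrated overall RMS level.

    Bit-reproducible for a fixed ``seed``.
    """
    if duration <= 0 or sample_rate <= 0:
        raise ValueError("duration and sample_rate must be positive")
    n = int(round(duration * sample_rate))
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    return Stimulus(
        samples=_finalize(x, level, sample_rate, ramp),
        sample_rate=sample_rate,
        frequency=None,
        level=level,
        duration=duration,
    )


def write_wav(stimulus: Stimulus, path, pa_per_fullscale: float | None = None) -> None:
    """Export as float32 PCM WAV with a Pa-per-full-scale sidecar (YAML)."""
    if pa_per_fullscale is None:
        pa_per_fullscale = float(np.max(np.abs(stimulus.samples))) or 1.0
    wavfile.write(
        str(path),
        int(stimulus.sample_rate),
        (stimulus.samples / pa_per_fullscale).astype(np.float32),
    )
    sidecar = {
        "pa_per_fullscale": float(pa_per_fullscale),
        "level_db_spl": float(stimulus.level),
        "frequency_hz": None if stimulus.frequency is None else float(stimulus.frequency),
    }
    with open(str(path) + ".yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh)


def read_wav(path) -> Stimulus:
    """Import a WAV written by :func:`write_wav` (requires its sidecar)."""
    with open(str(path) + ".yaml") as fh:
        sidecar = yaml.safe_load(fh)
    rate, data = wavfile.read(str(path))
    samples = np.asarray(data, dtype=float) * sidecar["pa_per_fullscale"]
    level = 20.0 * np.log10(np.sqrt(np.mean(samples**2)) / P_REF)
    return Stimulus(
        samples=samples,
        sample_rate=float(rate),
        frequency=sidecar.get("frequency_hz"),
        level=level,
        duration=samples.size / rate,
    )
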