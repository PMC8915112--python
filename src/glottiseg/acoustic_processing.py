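"""Acoustic conditioning: anti-alias low-pass, decimation, amplitude spectrum.

The voice signal is recorded at 22,050 Hz, exactly 7x the 3150 fps video
rate.  Before its spectrum can be compared with the glottovibrogram
spectrum, it is low-pass filtered (4th-order Butterworth, 1500 Hz cutoff,
applied forward-backward so no group delay shifts it against the video)
and decimated by keeping every 7th sample.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal
from scipy.io import wavfile

from .errors import FormatError, ParameterError

log = logging.getLogger(__name__)

DEFAULT_AUDIO_RATE_HZ = 22050.0
DEFAULT_CUTOFF_HZ = 1500.0
DEFAULT_FILTER_ORDER = 4
DEFAULT_DECIMATION = 7


@dataclass(frozen=True)
class AcousticRecording:
    """Mono voice signal normalized to [-1, 1] with its sampling rate."""

    samples: np.ndarray
    rate_hz: float = DEFAULT_AUDIO_RATE_HZ

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise FormatError("samples must be a 1-D series")
        if samples.size < 2:
            raise FormatError("need at least 2 samples")
        if self.rate_hz <= 0:
            raise FormatError("rate_hz must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class AmplitudeSpectrum:
    """Moduli of 1/N-scaled Fourier coefficients over bins 0..N/2-1."""

    moduli: np.ndarray
    bin_hz: float

    def __post_init__(self) -> None:
        moduli = np.asarray(self.moduli, dtype=np.float64)
        if moduli.ndim != 1 or moduli.size < 1:
            raise ParameterError("moduli must be a non-empty 1-D series")
        if moduli.min() < 0:
            raise ParameterError("moduli must be non-negative")
        object.__setattr__(self, "moduli", moduli)

    @property
    def n_bins(self) -> int:
        return self.moduli.size

    def dominant_bin(self, skip_dc: bool = True) -> int:
        """Index of the largest modulus (by default ignoring bin 0)."""
        start = 1 if skip_dc else 0
        return start + int(np.argmax(self.moduli[start:]))

    def frequencies_hz(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.bin_hz


def lowpass_butterworth(
    rec: AcousticRecording,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_FILTER_ORDER,
) -> AcousticRecording:
    """Zero-phase Butterworth low-pass (applied forward and backward)."""
    nyquist = rec.rate_hz / 2.0
    if not (0 < cutoff_hz < nyquist):
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz must lie in (0, {nyquist}) Hz"
        )
    if rec.n_samples < 14:  # two frames' worth at 7 samples per frame
        raise ParameterError("recording too short to filter")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=rec.rate_hz, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples)
    return AcousticRecording(filtered, rec.rate_hz)


def decimate_by(
    rec: AcousticRecording, factor: int = DEFAULT_DECIMATION
) -> AcousticRecording:
    """Keep every ``factor``-th sample; the caller must low-pass first."""
    if factor < 1:
        raise ParameterError("decimation factor must be >= 1")
    return AcousticRecording(rec.samples[::factor].copy(), rec.rate_hz / factor)


def amplitude_spectrum(
    series: np.ndarray, rate_hz: float = 1.0, window: str = "rect"
) -> AmplitudeSpectrum:
    """Moduli of the 1/N-scaled DFT over the one-sided bins 0..N/2-1.

    The bare (rectangular) DFT is the default; ``window="hann"`` applies
    a Hann taper first for callers that prefer reduced leakage.
    """
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ParameterError("need a 1-D series of length >= 2")
    if window == "hann":
        x = x * np.hanning(x.size)
    elif window != "rect":
        raise ParameterError(f"unknown window {window!r}")
    n = x.size
    coeffs = np.fft.rfft(x) / n
    return AmplitudeSpectrum(np.abs(coeffs[: n // 2]), rate_hz / n)


def condition_audio(
    rec: AcousticRecording,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_FILTER_ORDER,
    factor: int = DEFAULT_DECIMATION,
) -> AcousticRecording:
    """Low-pass then decimate to the video frame rate."""
    return decimate_by(lowpass_butterworth(rec, cutoff_hz, order), factor)


def read_wav(path: str | Path) -> AcousticRecording:
    """Read a PCM or float WAV file as a normalized mono recording."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", wavfile.WavFileWarning)
        rate, data = wavfile.read(str(path))
    if data.ndim == 2:
        log.warning("stereo WAV %s: averaging channels to mono", path)
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max)
        data = data.astype(np.float64) / scale
    else:
        data = data.astype(np.float64)
    return AcousticRecording(data, float(rate))


def write_wav(path: str | Path, rec: AcousticRecording) -> None:
    """Write a recording as 16-bit PCM WAV."""
    clipped = np.clip(rec.samples, -1.0, 1.0)
    pcm = np.round(clipped * 32767).astype(np.int16)
    wavfile.write(str(path), int(round(rec.rate_hz)), pcm)
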