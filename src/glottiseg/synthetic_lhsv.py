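"""Synthetic synchronized glottal video + voice audio with known ground truth.

The generator emulates what the real instrument records: an oscillating
dark glottal gap between bright textured folds, imaged at 3150 frames/s,
with a harmonic voice signal at the same fundamental frequency sampled at
exactly 7x the frame rate.  Everything is analytic, so the true masks,
waveforms and vibratory quotients are known and the whole pipeline can be
validated without clinical data.

The aperture drive is a clipped sinusoid

    w(l, t) = max(0, A(l) (sin(2 pi f0 t / fv) - c)) + gap(l)

with ``c = cos(pi * OQ)`` so the open fraction of each cycle equals the
requested open quotient exactly.  ``A(l)`` encodes the closure-type
profile along the glottal axis (type A flat, type E spindle, ...) and
``gap(l)`` a never-closing residual that drives MRGA above zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage, signal

from .acoustic_processing import AcousticRecording
from .errors import ParameterError
from .glottal_geometry import GlottalAreaWaveform, GlottalGapWaveform
from .param_segmentation import BinaryMaskSequence
from .vibratory_indices import GlottalIndices
from .video_preprocess import VideoSequence

CLOSURE_TYPES = ("A", "B", "C", "D", "E")


@dataclass(frozen=True)
class ImageModel:
    """Rendering parameters for the synthetic frames.

    Frames are deliberately smaller than the 480 x 400 clinical format:
    the glottis occupies a comparable fraction of the field of view, and
    the smaller canvas keeps full grid sweeps affordable.
    """

    height: int = 120
    width: int = 88
    tissue_level: float = 170.0
    glottis_level: float = 35.0
    vignette_strength: float = 0.35
    texture_scale_px: int = 16
    texture_amp: float = 10.0
    noise_sd: float = 3.0


@dataclass(frozen=True)
class AudioModel:
    """Harmonic source plus vocal-tract resonances for the voice signal.

    ``source="glottal-pulse"`` takes the harmonic amplitudes and phases
    from the Fourier series of the clipped-sine glottal pulse itself, the
    physical origin of voiced sound; ``source="rolloff"`` uses a plain
    geometric decay of ``rolloff_db_per_harmonic`` instead.
    """

    harmonic_count: int = 8
    source: str = "glottal-pulse"
    rolloff_db_per_harmonic: float = 6.0
    resonances_hz: tuple[tuple[float, float], ...] = ((280.0, 60.0), (2100.0, 150.0))
    snr_db: float = 30.0


@dataclass(frozen=True)
class PhonationModel:
    """Complete description of one synthetic phonation recording."""

    f0_hz: float = 150.0
    duration_frames: int = 512
    frame_rate_hz: float = 3150.0
    audio_rate_hz: float = 22050.0
    closure_type: str = "E"
    target_oq: float = 0.7
    amplitude_px: float = 9.0
    glottal_length_px: int = 56
    posterior_gap_px: float = 0.0
    image: ImageModel = field(default_factory=ImageModel)
    audio: AudioModel = field(default_factory=AudioModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.audio_rate_hz - 7 * self.frame_rate_hz) > 1e-9:
            raise ParameterError("audio_rate_hz must equal 7 x frame_rate_hz")
        if not (0 < self.target_oq <= 1):
            raise ParameterError("target_oq must lie in (0, 1]")
        if self.closure_type not in CLOSURE_TYPES:
            raise ParameterError(f"closure_type must be one of {CLOSURE_TYPES}")
        if self.image.glottis_level >= self.image.tissue_level:
            raise ParameterError("glottis must be darker than tissue")
        if self.duration_frames < 2:
            raise ParameterError("need at least 2 frames")
        if self.f0_hz * self.audio.harmonic_count >= self.audio_rate_hz / 2:
            raise ParameterError("highest harmonic exceeds the audio Nyquist")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SyntheticRecording:
    """A rendered recording with every ground-truth quantity attached."""

    model: PhonationModel
    video: VideoSequence
    audio: AcousticRecording
    truth_masks: BinaryMaskSequence
    truth_widths: np.ndarray  # (N, L) analytic half-widths + gap, pixels
    truth_gaw: GlottalAreaWaveform
    truth_ggw: GlottalGapWaveform
    truth_indices: GlottalIndices


def closure_profiles(model: PhonationModel) -> tuple[np.ndarray, np.ndarray]:
    """Amplitude profile A(l)/amplitude_px and residual gap(l), both length L.

    Level 0 is the anterior end (top image row), level L-1 the posterior
    end.  The five presets follow the standard closure-type taxonomy:
    A rectangle (uniform), B hourglass (pinched middle), C triangle and
    D V-shaped (wedges of opposite orientation), E spindle (bowed folds,
    widest mid-glottis).
    """
    L = model.glottal_length_px
    u = (np.arange(L) + 0.5) / L
    kind = model.closure_type
    if kind == "A":
        profile = np.ones(L)
        gap = np.ones(L)
    elif kind == "B":
        profile = 0.35 + 0.65 * np.abs(2 * u - 1)
        gap = np.abs(2 * u - 1)
    elif kind == "C":
        profile = 0.1 + 0.9 * u
        gap = u
    elif kind == "D":
        profile = 0.1 + 0.9 * (1 - u)
        gap = 1 - u
    else:  # E
        profile = np.sin(np.pi * u)
        gap = np.sin(np.pi * u)
    return model.amplitude_px * profile, model.posterior_gap_px * gap


def aperture_field(model: PhonationModel) -> np.ndarray:
    """Analytic half-width grid ``w[t, l]`` in pixels.

    The clipped-sine drive is scaled so the peak half-width equals the
    profile amplitude, and the clipping level ``c = cos(pi * OQ)`` makes
    the open fraction of each cycle equal ``target_oq``.
    """
    amp, gap = closure_profiles(model)
    c = np.cos(np.pi * model.target_oq)
    t = np.arange(model.duration_frames)
    drive = np.sin(2 * np.pi * model.f0_hz * t / model.frame_rate_hz)
    pulse = np.maximum(0.0, drive - c) / (1.0 - c)
    return pulse[:, None] * amp[None, :] + gap[None, :]


def _tissue_background(model: PhonationModel, rng: np.random.Generator) -> np.ndarray:
    img = model.image
    h, w = img.height, img.width
    scale = max(img.texture_scale_px, 2)
    coarse = rng.normal(0.0, 1.0, (h // scale + 2, w // scale + 2))
    texture = ndimage.zoom(coarse, scale, order=1)[:h, :w]
    texture *= img.texture_amp / max(texture.std(), 1e-9)
    rows = np.arange(h)[:, None] - (h - 1) / 2
    cols = np.arange(w)[None, :] - (w - 1) / 2
    r2 = (rows / (h / 2)) ** 2 + (cols / (w / 2)) ** 2
    vignette = 1.0 - img.vignette_strength * np.clip(r2, 0, 1)
    return img.tissue_level * vignette + texture


def render_video(
    widths: np.ndarray, model: PhonationModel, rng: np.random.Generator
) -> tuple[VideoSequence, BinaryMaskSequence]:
    """Rasterize the aperture field into frames and ground-truth masks.

    Each glottal level occupies one image row; a pixel is glottal when its
    column centre lies within the half-width of the vertical midline.  The
    truth mask is this rasterization before noise.
    """
    img = model.image
    n, L = widths.shape
    if widths.max() > img.width / 2:
        raise ParameterError("aperture exceeds half the frame width")
    row0 = (img.height - L) // 2
    if row0 < 0:
        raise ParameterError("glottal_length_px exceeds the frame height")
    # quarter-pixel midline offset: keeps the rasterized width from moving
    # in even-only steps, which would double the quantization of the GGW
    offsets = np.abs(np.arange(img.width) + 0.5 - (img.width / 2 + 0.25))

    background = _tissue_background(model, rng)
    masks = np.zeros((n, img.height, img.width), dtype=bool)
    masks[:, row0 : row0 + L, :] = (
        offsets[None, None, :] < widths[:, :, None]
    )
    frames = np.where(masks, img.glottis_level, background[None, :, :])
    frames = frames + rng.normal(0.0, img.noise_sd, frames.shape)
    frames = np.clip(np.floor(frames + 0.5), 0, 255).astype(np.uint8)
    return (
        VideoSequence(frames, model.frame_rate_hz),
        BinaryMaskSequence(masks),
    )


def _pulse_harmonics(model: PhonationModel, k_max: int) -> np.ndarray:
    """Complex Fourier-series coefficients 1..k_max of the glottal pulse."""
    m = 4096
    tau = np.arange(m) / m
    c = np.cos(np.pi * model.target_oq)
    pulse = np.maximum(0.0, np.sin(2 * np.pi * tau) - c) / (1.0 - c)
    coeffs = np.fft.rfft(pulse) / m
    return coeffs[1 : k_max + 1]


def synthesize_audio(
    model: PhonationModel, rng: np.random.Generator
) -> AcousticRecording:
    """Harmonic voice signal shaped by resonators, with additive noise.

    The harmonic source follows :class:`AudioModel.source`; each
    (frequency, bandwidth) resonance is a unit-peak second-order IIR
    section standing in for a vocal-tract formant.  White noise is added
    at the requested SNR and the result is peak-normalized to 0.9.
    """
    au = model.audio
    n = 7 * model.duration_frames
    t = np.arange(n) / model.audio_rate_hz
    s = np.zeros(n)
    if au.source == "glottal-pulse":
        coeffs = _pulse_harmonics(model, au.harmonic_count)
        amps = 2 * np.abs(coeffs)
        phases = np.angle(coeffs)
    elif au.source == "rolloff":
        k = np.arange(au.harmonic_count)
        amps = 10 ** (-au.rolloff_db_per_harmonic * k / 20)
        phases = rng.uniform(0, 2 * np.pi, au.harmonic_count)
    else:
        raise ParameterError(f"unknown audio source {au.source!r}")
    for k in range(1, au.harmonic_count + 1):
        s += amps[k - 1] * np.sin(2 * np.pi * k * model.f0_hz * t + phases[k - 1])
    for freq, bandwidth in au.resonances_hz:
        if freq >= model.audio_rate_hz / 2:
            continue
        b, a = signal.iirpeak(freq, freq / bandwidth, fs=model.audio_rate_hz)
        s = s + signal.lfilter(b, a, s)  # source plus resonant emphasis
    rms = np.sqrt(np.mean(s**2))
    noise_rms = rms / 10 ** (au.snr_db / 20)
    s = s + rng.normal(0.0, noise_rms, n)
    s *= 0.9 / np.max(np.abs(s))
    return AcousticRecording(s, model.audio_rate_hz)


def ground_truth_indices(model: PhonationModel) -> GlottalIndices:
    """Analytic quotients implied by the clipped-sine drive.

    With cycles delimited at area minima and a symmetric pulse, opening
    and closing phases are mirror images: SQ = 1 and CQ = OQ / 2.  A
    never-closing residual gap at the mid level forces OQ = 1 (and the
    closing phase then runs from the pulse peak to the cycle end, so
    CQ = 1/2).  MRGA is the area ratio of the residual gap to the peak.
    """
    amp, gap = closure_profiles(model)
    mid = model.glottal_length_px // 2
    never_closes = gap[mid] > 0
    oq = 1.0 if never_closes else model.target_oq
    cq = 0.5 if never_closes else model.target_oq / 2
    min_area = 2 * gap.sum()
    max_area = max(2 * (amp + gap).sum(), 1e-12)
    n_cycles = int(
        model.duration_frames * model.f0_hz / model.frame_rate_hz
    )
    return GlottalIndices(
        CQ=cq,
        OQ=oq,
        SQ=1.0,
        MRGA=float(min_area / max_area),
        n_cycles=n_cycles,
    )


def simulate(model: PhonationModel | None = None) -> SyntheticRecording:
    """Generate a complete synchronized recording; bit-reproducible per seed."""
    if model is None:
        model = PhonationModel()
    rng = np.random.default_rng(model.seed)
    widths = aperture_field(model)
    video, truth_masks = render_video(widths, model, rng)
    audio = synthesize_audio(model, rng)
    mid = model.glottal_length_px // 2
    truth_gaw = GlottalAreaWaveform((2 * widths).sum(axis=1))
    truth_ggw = GlottalGapWaveform(2 * widths[:, mid], mid)
    return SyntheticRecording(
        model=model,
        video=video,
        audio=audio,
        truth_masks=truth_masks,
        truth_widths=widths,
        truth_gaw=truth_gaw,
        truth_ggw=truth_ggw,
        truth_indices=ground_truth_indices(model),
    )
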