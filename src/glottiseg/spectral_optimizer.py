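"""Acoustic selection of segmentation parameters.

The method's central assumption: a correct segmentation of the vibrating
vocal folds oscillates at the voice fundamental frequency, so the
amplitude spectrum of its glottovibrogram should resemble the amplitude
spectrum of the synchronously recorded voice.  Every (alpha, beta)
candidate is scored by the absolute bin-wise difference between the two
spectra, and the minimizer is selected:

    F(f)   = (1/N) sum_l sum_t g(t, l) exp(-j 2 pi t f / N)
    d      = sum_f | |F(f)| - |S(f)| |
    winner = argmin_{alpha, beta} d

The literal difference compares pixel widths against sound pressure, two
physically different scales, so by default both modulus vectors are
normalized to unit L1 mass with the DC bin dropped ("unit-l1-nodc");
``normalization="none"`` reproduces the bare difference.

The sweep is streamed: the median background is computed once per alpha
and shared by all betas, and losing candidates' masks are discarded as
soon as they are scored, so memory stays flat over the grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import groupby

import numpy as np

from .acoustic_processing import (
    AcousticRecording,
    AmplitudeSpectrum,
    amplitude_spectrum,
    condition_audio,
)
from .errors import (
    DegenerateCandidateError,
    OptimizationFailedError,
    ParameterError,
)
from .glottal_geometry import (
    DEFAULT_LEVELS,
    Glottovibrogram,
    clean_mask_sequence,
    glottovibrogram,
)
from .param_segmentation import (
    BinaryMaskSequence,
    SegmentationParams,
    coarse_grid,
    median_background,
)
from .video_preprocess import (
    RegionOfInterest,
    VideoSequence,
    detect_roi,
    total_variation_map,
)

log = logging.getLogger(__name__)

#: Candidates whose raw masks are empty in more than this fraction of
#: frames segment (almost) nothing and are excluded from the argmin.
EMPTY_FRAME_TOLERANCE = 0.90


@dataclass(frozen=True)
class CostMap:
    """Spectral distance per (alpha, beta); unusable candidates are NaN."""

    entries: dict[tuple[int, int], float]
    usable: dict[tuple[int, int], bool]

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(alpha, beta, cost, usable) columns in grid order."""
        keys = sorted(self.entries)
        a = np.array([k[0] for k in keys])
        b = np.array([k[1] for k in keys])
        c = np.array([self.entries[k] for k in keys])
        u = np.array([self.usable[k] for k in keys])
        return a, b, c, u


@dataclass(frozen=True)
class OptimizationResult:
    """The winning candidate and the full cost map behind it."""

    best_params: SegmentationParams
    best_cost: float
    best_masks: BinaryMaskSequence
    best_gvg: Glottovibrogram
    cost_map: CostMap
    audio_spectrum: AmplitudeSpectrum
    best_spectrum: AmplitudeSpectrum
    roi: RegionOfInterest
    n_samples: int


def glottovibrogram_spectrum(
    gvg: Glottovibrogram, rate_hz: float = 1.0
) -> AmplitudeSpectrum:
    """Amplitude spectrum of the glottovibrogram.

    The complex Fourier sums of the L level rows are added *before* the
    modulus, which equals the 1/N-scaled DFT of the level-summed width
    series; in-phase rows therefore reinforce and antiphase rows cancel.
    """
    if gvg.n_frames < 2:
        raise ParameterError("glottovibrogram needs at least 2 frames")
    return amplitude_spectrum(gvg.widths.sum(axis=1), rate_hz)


def _normalize(moduli: np.ndarray, mode: str) -> np.ndarray:
    if mode == "none":
        return moduli
    if mode == "unit-l1-nodc":
        trimmed = moduli[1:]
        total = trimmed.sum()
        if total <= 0:
            raise DegenerateCandidateError("zero-sum spectrum under normalization")
        return trimmed / total
    raise ParameterError(f"unknown normalization mode {mode!r}")


def spectral_cost(
    F: AmplitudeSpectrum,
    S: AmplitudeSpectrum,
    normalization: str = "unit-l1-nodc",
) -> float:
    """Sum of absolute bin-wise modulus differences between two spectra."""
    if F.n_bins != S.n_bins:
        raise ParameterError(
            f"bin counts differ: {F.n_bins} vs {S.n_bins}"
        )
    f = _normalize(F.moduli, normalization)
    s = _normalize(S.moduli, normalization)
    return float(np.abs(f - s).sum())


def optimize_segmentation(
    video: VideoSequence,
    audio: AcousticRecording,
    grid: list[SegmentationParams] | None = None,
    *,
    roi: RegionOfInterest | None = None,
    n_levels: int = DEFAULT_LEVELS,
    normalization: str = "unit-l1-nodc",
) -> OptimizationResult:
    """Sweep the (alpha, beta) grid and return the spectral argmin.

    Audio and video are truncated to a common length
    ``N = min(frames, samples // 7)`` so both spectra share their bins.
    Candidates that segment almost nothing (empty masks in more than 90%
    of frames) or whose spectrum has no mass after normalization are
    marked unusable.  Ties are broken toward the smallest (alpha, beta).
    """
    if grid is None:
        grid = coarse_grid()
    if not grid:
        raise ParameterError("parameter grid is empty")
    grid = sorted(set(grid), key=lambda p: (p.alpha, p.beta))

    factor = max(int(round(audio.rate_hz / video.frame_rate_hz)), 1)
    n = min(video.n_frames, audio.n_samples // factor)
    if n < 2:
        raise ParameterError("audio and video do not overlap for 2 frames")

    if roi is None:
        roi = detect_roi(total_variation_map(video))

    voice = condition_audio(audio, factor=factor)
    S = amplitude_spectrum(voice.samples[:n], voice.rate_hz)
    try:
        _normalize(S.moduli, normalization)
    except DegenerateCandidateError as exc:
        raise OptimizationFailedError("audio spectrum has no mass") from exc

    frames = np.ascontiguousarray(
        video.frames[:n, roi.row_start : roi.row_end, roi.col_start : roi.col_end]
    )
    local_roi = RegionOfInterest(0, roi.height, 0, roi.width)

    entries: dict[tuple[int, int], float] = {}
    usable: dict[tuple[int, int], bool] = {}
    best_key: tuple[int, int] | None = None
    best_cost = np.inf

    for alpha, group in groupby(grid, key=lambda p: p.alpha):
        betas = [p.beta for p in group]
        diff = np.empty(frames.shape, dtype=np.int16)
        for t in range(n):
            med = median_background(frames[t], alpha)
            diff[t] = med.astype(np.int16) - frames[t].astype(np.int16)
        for beta in betas:
            key = (alpha, beta)
            raw = diff >= beta
            nonempty = raw.any(axis=(1, 2)).sum()
            if nonempty < (1 - EMPTY_FRAME_TOLERANCE) * n:
                entries[key] = np.nan
                usable[key] = False
                continue
            cleaned = clean_mask_sequence(BinaryMaskSequence(raw), local_roi)
            if not cleaned.masks.any():
                entries[key] = np.nan
                usable[key] = False
                continue
            gvg = glottovibrogram(cleaned, n_levels)
            F = glottovibrogram_spectrum(gvg, video.frame_rate_hz)
            try:
                cost = spectral_cost(F, S, normalization)
            except DegenerateCandidateError:
                entries[key] = np.nan
                usable[key] = False
                continue
            entries[key] = cost
            usable[key] = True
            if cost < best_cost:  # grid order breaks ties toward small (a, b)
                best_cost = cost
                best_key = key

    if best_key is None:
        raise OptimizationFailedError("every candidate on the grid was degenerate")

    best_params = SegmentationParams(*best_key)
    log.info(
        "selected alpha=%d beta=%d with cost %.6g",
        best_params.alpha,
        best_params.beta,
        best_cost,
    )

    # rebuild the winner's masks in full-frame coordinates
    diff = np.empty(frames.shape, dtype=np.int16)
    for t in range(n):
        med = median_background(frames[t], best_params.alpha)
        diff[t] = med.astype(np.int16) - frames[t].astype(np.int16)
    raw = diff >= best_params.beta
    cleaned_local = clean_mask_sequence(
        BinaryMaskSequence(raw, best_params), local_roi
    )
    full = np.zeros((n,) + tuple(video.frames.shape[1:]), dtype=bool)
    full[:, roi.row_start : roi.row_end, roi.col_start : roi.col_end] = (
        cleaned_local.masks
    )
    best_masks = BinaryMaskSequence(full, best_params)
    best_gvg = glottovibrogram(best_masks, n_levels)
    best_spectrum = glottovibrogram_spectrum(best_gvg, video.frame_rate_hz)

    return OptimizationResult(
        best_params=best_params,
        best_cost=best_cost,
        best_masks=best_masks,
        best_gvg=best_gvg,
        cost_map=CostMap(entries, usable),
        audio_spectrum=S,
        best_spectrum=best_spectrum,
        roi=roi,
        n_samples=n,
    )
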