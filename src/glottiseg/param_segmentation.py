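"""Two-parameter median-difference thresholding and its (alpha, beta) grid.

A pixel belongs to the glottal gap when it is much darker than its
neighbourhood.  The neighbourhood brightness is estimated with an
``alpha x alpha`` median filter; subtracting the pixel itself and
thresholding the difference at ``beta`` yields a binary mask:

    mask(x, y) = 1  iff  med_alpha(x, y) - I(x, y) >= beta

``alpha`` (odd, in [1, 255]) controls how large a structure can be
detected; ``beta`` (in [1, 255]) controls how much darker than its
surroundings a pixel must be.  Sweeping both produces the candidate pool
from which the acoustically best segmentation is later selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
from skimage.filters import rank

from .errors import ParameterError
from .video_preprocess import RegionOfInterest, VideoSequence

log = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class SegmentationParams:
    """One (alpha, beta) point of the segmentation family."""

    alpha: int
    beta: int

    def __post_init__(self) -> None:
        if not (1 <= self.alpha <= 255) or self.alpha % 2 == 0:
            raise ParameterError(
                f"alpha must be an odd integer in [1, 255], got {self.alpha}"
            )
        if not (1 <= self.beta <= 255):
            raise ParameterError(f"beta must be in [1, 255], got {self.beta}")


@dataclass(frozen=True)
class BinaryMaskSequence:
    """Per-frame binary segmentation masks with the parameters that made them."""

    masks: np.ndarray  # (N, H, W) bool
    params: SegmentationParams | None = None

    def __post_init__(self) -> None:
        masks = np.asarray(self.masks)
        if masks.ndim != 3:
            raise ParameterError("masks must be (N, H, W)")
        if masks.dtype != bool:
            uniq = np.unique(masks)
            if not np.isin(uniq, [0, 1]).all():
                raise ParameterError("masks must be strictly binary")
            masks = masks.astype(bool)
        object.__setattr__(self, "masks", masks)

    @property
    def n_frames(self) -> int:
        return self.masks.shape[0]


def median_background(image: np.ndarray, alpha: int) -> np.ndarray:
    """Exact ``alpha x alpha`` median of ``image`` with reflect padding.

    Runs a histogram-based rank filter on the reflect-padded image so that
    border pixels see the same mirrored neighbourhood a direct per-pixel
    sort would.
    """
    image = np.asarray(image)
    if image.dtype != np.uint8:
        if image.min() < 0 or image.max() > 255:
            raise ParameterError("image intensities must lie in [0, 255]")
        image = image.astype(np.uint8)
    if alpha == 1:
        return image.copy()
    pad = alpha // 2
    padded = np.pad(image, pad, mode="reflect")
    footprint = np.ones((alpha, alpha), dtype=bool)
    med = rank.median(padded, footprint=footprint)
    return med[pad : pad + image.shape[0], pad : pad + image.shape[1]]


def median_threshold(image: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Binary mask: 1 where the median background exceeds the pixel by >= beta."""
    med = median_background(image, params.alpha)
    image = np.asarray(image)
    return (med.astype(np.int16) - image.astype(np.int16)) >= params.beta


def segment_sequence(
    video: VideoSequence,
    params: SegmentationParams,
    roi: RegionOfInterest | None = None,
) -> BinaryMaskSequence:
    """Apply :func:`median_threshold` frame-wise inside the ROI.

    The median filter runs on the ROI crop (reflect padding at the ROI
    border); pixels outside the ROI are forced to 0.
    """
    n, h, w = video.frames.shape
    if roi is None:
        roi = RegionOfInterest(0, h, 0, w)
    if roi.row_end > h or roi.col_end > w:
        raise ParameterError("ROI does not fit inside the frames")
    if params.alpha == 1:
        log.warning(
            "alpha=1 gives med - I = 0 everywhere; masks will be empty for beta >= 1"
        )
    masks = np.zeros((n, h, w), dtype=bool)
    for t in range(n):
        crop = roi.crop(video.frames[t])
        masks[t, roi.row_start : roi.row_end, roi.col_start : roi.col_end] = (
            median_threshold(crop, params)
        )
    return BinaryMaskSequence(masks, params)


def parameter_grid(
    alpha_values: list[int] | np.ndarray, beta_values: list[int] | np.ndarray
) -> list[SegmentationParams]:
    """Cartesian product of alpha and beta values, ordered by (alpha, beta)."""
    alphas = sorted(int(a) for a in alpha_values)
    betas = sorted(int(b) for b in beta_values)
    if not alphas or not betas:
        raise ParameterError("alpha and beta value lists must be non-empty")
    return [SegmentationParams(a, b) for a, b in product(alphas, betas)]


def coarse_alpha_values(n: int = 32, lo: int = 1, hi: int = 255) -> np.ndarray:
    """``n`` distinct odd window sizes, approximately log-spaced over [lo, hi].

    Log spacing samples the small scales densely (where segmentation is
    most sensitive) while still reaching the largest windows.  Collisions
    after rounding to odd are bumped to the next free odd value so the
    count is exact.
    """
    vals = np.geomspace(lo, hi, n)
    odd = (2 * np.round((vals - 1) / 2) + 1).astype(int)
    out: list[int] = []
    prev = -1
    for v in odd:
        v = max(int(v), prev + 2)
        out.append(v)
        prev = v
    if out[-1] > hi:
        raise ParameterError(f"cannot fit {n} odd values in [{lo}, {hi}]")
    return np.array(out)


def coarse_beta_values(n: int = 32, lo: int = 1, hi: int = 255) -> np.ndarray:
    """``n`` distinct integer thresholds, linearly spaced over [lo, hi]."""
    vals = np.unique(np.round(np.linspace(lo, hi, n)).astype(int))
    if len(vals) != n:
        raise ParameterError(f"cannot fit {n} integers in [{lo}, {hi}]")
    return vals


def coarse_grid() -> list[SegmentationParams]:
    """Default 32 x 32 sweep: log-spaced odd alphas, linear betas."""
    return parameter_grid(coarse_alpha_values(), coarse_beta_values())


def full_grid() -> list[SegmentationParams]:
    """The exhaustive sweep: all odd alphas and all betas in [1, 255]."""
    return parameter_grid(np.arange(1, 256, 2), np.arange(1, 256))


def full_grid_size(alpha_range: int = 255, beta_range: int = 255) -> int:
    """Number of (alpha, beta) pairs when both run over the full range.

    The nominal parameter space is the full integer square, 255 x 255 =
    65,025 combinations (the swept family restricts alpha to odd values).
    """
    return alpha_range * beta_range
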