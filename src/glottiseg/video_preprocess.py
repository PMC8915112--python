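"""Video pre-processing: grayscale conversion, motion-based ROI, axis alignment.

During sustained phonation the vocal folds are the only rapidly moving
structure in the field of view.  Summing absolute inter-frame intensity
differences therefore produces a *total-variation map* whose bright region
marks the glottis; its bounding box gives the region of interest (ROI), and
the principal axis of the bright component gives the angle needed to stand
the glottal main axis upright.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import measure, transform

from .errors import FormatError, InsufficientFramesError, NoMotionError

#: ITU-R BT.601 luma weights, the standard video grayscale conversion.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

DEFAULT_FRAME_RATE_HZ = 3150.0


@dataclass(frozen=True)
class VideoSequence:
    """Ordered grayscale frames plus the acquisition frame rate.

    ``frames`` is an ``(N, H, W)`` uint8 array; intensities live in
    [0, 255].  At least two frames are required so that temporal
    differences exist.
    """

    frames: np.ndarray
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise FormatError(
                f"expected (N, H, W) grayscale frames, got shape {frames.shape}"
            )
        if frames.shape[0] < 2:
            raise InsufficientFramesError(
                f"need at least 2 frames, got {frames.shape[0]}"
            )
        if frames.min() < 0 or frames.max() > 255:
            raise FormatError("frame intensities must lie in [0, 255]")
        if self.frame_rate_hz <= 0:
            raise FormatError("frame_rate_hz must be positive")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass(frozen=True)
class TotalVariationMap:
    """Per-pixel sum of absolute temporal differences (non-negative)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise FormatError("TV map must be 2-D")
        if values.min() < 0:
            raise FormatError("TV map entries must be non-negative")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class RegionOfInterest:
    """Half-open frame window ``[row_start, row_end) x [col_start, col_end)``.

    ``rotation_deg`` records the in-plane angle (degrees, counter-clockwise)
    already applied to the frames so that the glottal major axis is vertical.
    """

    row_start: int
    row_end: int
    col_start: int
    col_end: int
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.row_start < self.row_end):
            raise ValueError("invalid ROI rows")
        if not (0 <= self.col_start < self.col_end):
            raise ValueError("invalid ROI cols")

    @property
    def height(self) -> int:
        return self.row_end - self.row_start

    @property
    def width(self) -> int:
        return self.col_end - self.col_start

    def crop(self, image: np.ndarray) -> np.ndarray:
        return image[self.row_start : self.row_end, self.col_start : self.col_end]


def rgb_to_grayscale(
    rgb_frames: np.ndarray, frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ
) -> VideoSequence:
    """Convert ``(N, H, W, 3)`` RGB frames to 8-bit grayscale.

    Uses the BT.601 weighted sum 0.299 R + 0.587 G + 0.114 B, rounded half
    away from zero.  Already-grayscale ``(N, H, W)`` input is validated and
    passed through unchanged.
    """
    arr = np.asarray(rgb_frames)
    if arr.ndim == 3:  # already single-channel
        return VideoSequence(arr.astype(np.uint8, copy=False), frame_rate_hz)
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise FormatError(
            f"expected (N, H, W, 3) RGB frames, got shape {arr.shape}"
        )
    if arr.min() < 0 or arr.max() > 255:
        raise FormatError("channel values must lie in [0, 255]")
    gray = arr.astype(np.float64) @ _LUMA_WEIGHTS
    # round half away from zero; values are non-negative so floor(x + 0.5)
    gray = np.floor(gray + 0.5)
    gray = np.clip(gray, 0, 255).astype(np.uint8)
    return VideoSequence(gray, frame_rate_hz)


def total_variation_map(video: VideoSequence) -> TotalVariationMap:
    """Sum of |I(x, y, t+1) - I(x, y, t)| over t, in a widened dtype."""
    frames = video.frames.astype(np.int64)
    tv = np.abs(np.diff(frames, axis=0)).sum(axis=0)
    return TotalVariationMap(tv)


def _largest_component(binary: np.ndarray) -> np.ndarray:
    """Boolean mask of the largest 8-connected component of ``binary``."""
    labels = measure.label(binary, connectivity=2)
    if labels.max() == 0:
        return np.zeros_like(binary, dtype=bool)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return labels == sizes.argmax()


def detect_roi(
    tv: TotalVariationMap,
    threshold_fraction: float = 0.25,
    margin_px: int = 10,
) -> RegionOfInterest:
    """Bounding box of the dominant motion region.

    The TV map is thresholded at ``threshold_fraction`` of its maximum, the
    largest 8-connected component is kept, and its bounding box is expanded
    by ``margin_px`` and clipped to the frame.
    """
    if not (0.0 < threshold_fraction < 1.0):
        raise ValueError("threshold_fraction must be in (0, 1)")
    if margin_px < 0:
        raise ValueError("margin_px must be non-negative")
    values = tv.values
    vmax = values.max()
    if vmax <= 0:
        raise NoMotionError("total-variation map is identically zero")
    component = _largest_component(values >= threshold_fraction * vmax)
    rows, cols = np.nonzero(component)
    h, w = values.shape
    return RegionOfInterest(
        row_start=max(int(rows.min()) - margin_px, 0),
        row_end=min(int(rows.max()) + 1 + margin_px, h),
        col_start=max(int(cols.min()) - margin_px, 0),
        col_end=min(int(cols.max()) + 1 + margin_px, w),
    )


def principal_axis_angle(component: np.ndarray) -> float:
    """Angle (degrees) to rotate so the component's major axis is vertical.

    Derived from second-order central moments.  Returns a value in
    (-90, 90]; an isotropic component (no preferred axis) maps to 0.
    """
    rows, cols = np.nonzero(component)
    r = rows - rows.mean()
    c = cols - cols.mean()
    mu_rr = np.mean(r * r)
    mu_cc = np.mean(c * c)
    mu_rc = np.mean(r * c)
    if math.isclose(mu_rr, mu_cc, abs_tol=1e-9) and math.isclose(
        mu_rc, 0.0, abs_tol=1e-9
    ):
        return 0.0  # isotropic: tie broken to no rotation
    # angle of the major axis measured from the row (vertical) axis,
    # counter-clockwise in image coordinates
    theta = 0.5 * math.atan2(2.0 * mu_rc, mu_rr - mu_cc)
    angle = math.degrees(theta)
    if angle > 90.0:
        angle -= 180.0
    elif angle <= -90.0:
        angle += 180.0
    return angle


def align_vertical(
    video: VideoSequence,
    tv: TotalVariationMap | None = None,
    threshold_fraction: float = 0.25,
    margin_px: int = 10,
) -> tuple[VideoSequence, RegionOfInterest]:
    """Rotate the sequence so the glottal main axis is vertical.

    The rotation angle comes from the principal axis of the thresholded TV
    component; frames are rotated about the component centroid with
    bilinear interpolation, out-of-frame pixels filled with each frame's
    median intensity.  The ROI is recomputed on the rotated TV map.
    """
    if tv is None:
        tv = total_variation_map(video)
    values = tv.values
    vmax = values.max()
    if vmax <= 0:
        raise NoMotionError("total-variation map is identically zero")
    component = _largest_component(values >= threshold_fraction * vmax)
    angle = principal_axis_angle(component)

    if abs(angle) < 0.5:
        roi = detect_roi(tv, threshold_fraction, margin_px)
        return video, RegionOfInterest(
            roi.row_start, roi.row_end, roi.col_start, roi.col_end, 0.0
        )

    rows, cols = np.nonzero(component)
    center = (float(cols.mean()), float(rows.mean()))  # (x, y) for skimage
    rotated = np.empty_like(video.frames)
    for i, frame in enumerate(video.frames):
        fill = float(np.median(frame))
        out = transform.rotate(
            frame.astype(np.float64),
            -angle,
            center=center,
            order=1,
            mode="constant",
            cval=fill,
            preserve_range=True,
        )
        rotated[i] = np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)
    rotated_video = VideoSequence(rotated, video.frame_rate_hz)
    tv_rot = total_variation_map(rotated_video)
    roi = detect_roi(tv_rot, threshold_fraction, margin_px)
    return rotated_video, RegionOfInterest(
        roi.row_start, roi.row_end, roi.col_start, roi.col_end, -angle
    )
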