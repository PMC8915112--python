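"""Grayscale conversion, total-variation map, ROI and axis alignment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from glottiseg import (
    VideoSequence,
    align_vertical,
    detect_roi,
    rgb_to_grayscale,
    total_variation_map,
)
from glottiseg.errors import (
    FormatError,
    InsufficientFramesError,
    NoMotionError,
)
from glottiseg.video_preprocess import TotalVariationMap, principal_axis_angle


def _video_from_pixel_series(series):
    frames = np.zeros((len(series), 3, 3), dtype=np.uint8)
    frames[:, 1, 1] = series
    return VideoSequence(frames)


class TestGrayscale:
    @pytest.mark.parametrize(
        "rgb, expected",
        [
            ((100, 100, 100), 100),  # weights sum to 1: gray preserved
            ((255, 0, 0), 76),  # 0.299 * 255 = 76.245 rounds to 76
            ((0, 0, 0), 0),
            ((0, 255, 0), 150),  # 0.587 * 255 = 149.685
            ((0, 0, 255), 29),  # 0.114 * 255 = 29.07
        ],
    )
    def test_luma_weighting(self, rgb, expected):
        frames = np.zeros((2, 2, 2, 3), dtype=np.uint8)
        frames[..., 0], frames[..., 1], frames[..., 2] = rgb
        video = rgb_to_grayscale(frames)
        assert video.frames[0, 0, 0] == expected

    def test_rounds_half_away_from_zero(self):
        # 0.299*5 + 0.587*0 + 0.114*0 = 1.495 -> 1; 0.299*105 = 31.395 -> 31
        # and a true .5 case: 0.587*50 + 0.299*2 = 29.948; use channel mix
        frames = np.zeros((2, 1, 1, 3), dtype=np.uint8)
        frames[..., 0] = 250  # 0.299*250 = 74.75 -> 75
        assert rgb_to_grayscale(frames).frames[0, 0, 0] == 75

    def test_grayscale_passthrough(self):
        frames = np.random.default_rng(0).integers(
            0, 256, (3, 4, 5), dtype=np.uint8
        )
        video = rgb_to_grayscale(frames)
        np.testing.assert_array_equal(video.frames, frames)

    def test_wrong_channel_count(self):
        with pytest.raises(FormatError):
            rgb_to_grayscale(np.zeros((2, 4, 4, 2), dtype=np.uint8))


class TestTotalVariation:
    def test_constant_video_is_zero(self):
        video = VideoSequence(np.full((5, 4, 4), 17, dtype=np.uint8))
        assert total_variation_map(video).values.max() == 0

    def test_hand_computed_series(self):
        video = _video_from_pixel_series([0, 5, 3])
        assert total_variation_map(video).values[1, 1] == 7  # |5-0| + |3-5|

    def test_two_frames_equal_absolute_difference(self):
        rng = np.random.default_rng(1)
        frames = rng.integers(0, 256, (2, 6, 6), dtype=np.uint8)
        tv = total_variation_map(VideoSequence(frames))
        expected = np.abs(
            frames[1].astype(int) - frames[0].astype(int)
        )
        np.testing.assert_array_equal(tv.values, expected)

    def test_too_few_frames(self):
        with pytest.raises(InsufficientFramesError):
            VideoSequence(np.zeros((1, 4, 4), dtype=np.uint8))

    @given(
        arrays(np.uint8, st.tuples(st.integers(2, 6), st.just(4), st.just(4)))
    )
    @settings(deadline=None, max_examples=50)
    def test_reversal_invariance(self, frames):
        video = VideoSequence(frames)
        reversed_video = VideoSequence(frames[::-1].copy())
        np.testing.assert_array_equal(
            total_variation_map(video).values,
            total_variation_map(reversed_video).values,
        )

    @given(
        arrays(np.uint8, st.tuples(st.integers(4, 8), st.just(3), st.just(3))),
        st.integers(1, 6),
    )
    @settings(deadline=None, max_examples=50)
    def test_additive_over_shared_boundary(self, frames, split):
        split = min(split, frames.shape[0] - 3) + 1
        head = VideoSequence(frames[: split + 1])
        tail = VideoSequence(frames[split:])
        whole = VideoSequence(frames)
        np.testing.assert_array_equal(
            total_variation_map(head).values
            + total_variation_map(tail).values,
            total_variation_map(whole).values,
        )


class TestDetectRoi:
    def _map_with_block(self, shape=(40, 30), block=(5, 15, 10, 14), value=100):
        values = np.zeros(shape)
        r0, r1, c0, c1 = block
        values[r0:r1, c0:c1] = value
        return TotalVariationMap(values)

    def test_single_block_bounding_box(self):
        tv = self._map_with_block()
        roi = detect_roi(tv, margin_px=0)
        assert (roi.row_start, roi.row_end, roi.col_start, roi.col_end) == (
            5, 15, 10, 14,
        )

    def test_largest_component_wins(self):
        values = np.zeros((40, 40))
        values[2:12, 2:7] = 100  # 50 px
        values[30:32, 30:34] = 100  # 8 px
        roi = detect_roi(TotalVariationMap(values), margin_px=0)
        assert (roi.row_start, roi.row_end, roi.col_start, roi.col_end) == (
            2, 12, 2, 7,
        )

    def test_margin_and_clipping(self):
        tv = self._map_with_block()
        roi = detect_roi(tv, margin_px=100)
        assert (roi.row_start, roi.row_end, roi.col_start, roi.col_end) == (
            0, 40, 0, 30,
        )

    def test_all_zero_map_raises(self):
        with pytest.raises(NoMotionError):
            detect_roi(TotalVariationMap(np.zeros((10, 10))))

    def test_contains_argmax_of_largest_component(self):
        rng = np.random.default_rng(5)
        values = rng.random((30, 30))
        values[10:20, 5:15] += 10
        roi = detect_roi(TotalVariationMap(values), margin_px=0)
        r, c = np.unravel_index(np.argmax(values), values.shape)
        assert roi.row_start <= r < roi.row_end
        assert roi.col_start <= c < roi.col_end


def _blob_video(angle_deg: float, n_frames: int = 6):
    """Blinking elongated blob at the given tilt: motion along its axis."""
    h = w = 81
    rows, cols = np.mgrid[0:h, 0:w]
    r = rows - 40
    c = cols - 40
    theta = np.deg2rad(angle_deg)
    # major axis direction (from vertical, CCW in image coords)
    u = r * np.cos(theta) + c * np.sin(theta)
    v = -r * np.sin(theta) + c * np.cos(theta)
    blob = (np.abs(u) < 25) & (np.abs(v) < 4)
    frames = np.full((n_frames, h, w), 120, dtype=np.uint8)
    frames[::2][:, blob] = 30
    return VideoSequence(frames)


class TestAlignVertical:
    def test_already_vertical(self):
        video = _blob_video(0.0)
        _, roi = align_vertical(video)
        assert abs(roi.rotation_deg) <= 1.0

    @pytest.mark.parametrize("angle", [30.0, -20.0])
    def test_recovers_rotation(self, angle):
        video = _blob_video(angle)
        aligned, roi = align_vertical(video)
        assert abs(abs(roi.rotation_deg) - abs(angle)) <= 1.0
        # idempotence: a second pass should find (almost) no rotation
        _, roi2 = align_vertical(aligned)
        assert abs(roi2.rotation_deg) <= 1.0

    def test_aligned_blob_is_vertical(self):
        aligned, roi = align_vertical(_blob_video(30.0))
        tv = total_variation_map(aligned)
        comp = tv.values >= 0.25 * tv.values.max()
        assert abs(principal_axis_angle(comp)) <= 1.5

    def test_isotropic_blob_angle_zero(self):
        comp = np.zeros((21, 21), dtype=bool)
        rows, cols = np.mgrid[0:21, 0:21]
        comp[(rows - 10) ** 2 + (cols - 10) ** 2 <= 64] = True
        assert principal_axis_angle(comp) == 0.0

    def test_static_video_raises(self):
        video = VideoSequence(np.full((4, 8, 8), 9, dtype=np.uint8))
        with pytest.raises(NoMotionError):
            align_vertical(video)
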