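"""Glottovibrogram spectra, the spectral cost, and the grid optimizer."""

import numpy as np
import pytest

from glottiseg import (
    AcousticRecording,
    RegionOfInterest,
    VideoSequence,
    glottovibrogram_spectrum,
    optimize_segmentation,
    parameter_grid,
    spectral_cost,
)
from glottiseg.acoustic_processing import AmplitudeSpectrum
from glottiseg.errors import (
    DegenerateCandidateError,
    OptimizationFailedError,
    ParameterError,
)
from glottiseg.glottal_geometry import Glottovibrogram

from conftest import mean_dice


def _gvg(widths):
    widths = np.asarray(widths, dtype=float)
    rows = tuple((l, l + 1) for l in range(widths.shape[1]))
    return Glottovibrogram(widths, rows)


class TestGlottovibrogramSpectrum:
    def test_all_zero_map_gives_zero_spectrum(self):
        spec = glottovibrogram_spectrum(_gvg(np.zeros((32, 4))))
        np.testing.assert_allclose(spec.moduli, 0.0)

    def test_single_row_cosine_closed_form(self):
        # offset keeps widths non-negative; it only moves the DC bin
        n, k, amp = 64, 5, 3.0
        row = amp + amp * np.cos(2 * np.pi * k * np.arange(n) / n)
        spec = glottovibrogram_spectrum(_gvg(row[:, None]))
        assert spec.moduli[k] == pytest.approx(amp / 2, rel=1e-9)

    def test_in_phase_rows_add_coherently(self):
        n, k = 64, 5
        row = np.cos(2 * np.pi * k * np.arange(n) / n)
        single = glottovibrogram_spectrum(_gvg(row[:, None] + 2.0))
        double = glottovibrogram_spectrum(
            _gvg(np.stack([row + 2.0, row + 2.0], axis=1))
        )
        np.testing.assert_allclose(double.moduli, 2 * single.moduli, atol=1e-12)


class TestSpectralCost:
    def _spec(self, moduli):
        return AmplitudeSpectrum(np.asarray(moduli, dtype=float), 1.0)

    def test_identical_spectra_cost_zero(self):
        s = self._spec([1.0, 0.5, 0.25])
        assert spectral_cost(s, s) == 0.0
        assert spectral_cost(s, s, "none") == 0.0

    def test_literal_mode_hand_example(self):
        f = self._spec([1.0, 2.0])
        s = self._spec([0.0, 1.0])
        assert spectral_cost(f, s, "none") == pytest.approx(2.0)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        f = self._spec(rng.random(16))
        s = self._spec(rng.random(16))
        for mode in ("none", "unit-l1-nodc"):
            assert spectral_cost(f, s, mode) == pytest.approx(
                spectral_cost(s, f, mode)
            )

    def test_default_mode_scale_invariant(self):
        rng = np.random.default_rng(3)
        f = self._spec(rng.random(16))
        s = self._spec(rng.random(16))
        scaled = self._spec(7.5 * s.moduli)
        assert spectral_cost(f, s) == pytest.approx(spectral_cost(f, scaled))

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ParameterError):
            spectral_cost(self._spec([1, 2]), self._spec([1, 2, 3]))

    def test_zero_mass_spectrum_is_degenerate(self):
        f = self._spec([5.0, 0.0, 0.0])  # only DC: no mass after drop
        s = self._spec([0.0, 1.0, 1.0])
        with pytest.raises(DegenerateCandidateError):
            spectral_cost(f, s)


class TestOptimizer:
    def test_winner_tracks_true_aperture(self, small_recording):
        rec = small_recording
        grid = parameter_grid([5, 15, 31, 61], [20, 60, 120])
        res = optimize_segmentation(rec.video, rec.audio, grid)
        truth = rec.truth_masks.masks[: res.n_samples]
        assert mean_dice(truth, res.best_masks.masks) >= 0.80
        f0_bin = rec.model.f0_hz / res.best_spectrum.bin_hz
        assert abs(res.best_spectrum.dominant_bin() - f0_bin) <= 1.0

    def test_best_cost_reproducible_from_best_candidate(self, small_recording):
        rec = small_recording
        grid = parameter_grid([15, 31], [30, 90])
        res = optimize_segmentation(rec.video, rec.audio, grid)
        rerun = optimize_segmentation(
            rec.video, rec.audio, [res.best_params], roi=res.roi
        )
        assert rerun.best_cost == res.best_cost
        key = (res.best_params.alpha, res.best_params.beta)
        assert res.cost_map.entries[key] == res.best_cost

    def test_audio_amplitude_does_not_change_winner(self, small_recording):
        rec = small_recording
        grid = parameter_grid([15, 31], [30, 90])
        res1 = optimize_segmentation(rec.video, rec.audio, grid)
        louder = AcousticRecording(0.2 * rec.audio.samples, rec.audio.rate_hz)
        res2 = optimize_segmentation(rec.video, louder, grid)
        assert res1.best_params == res2.best_params

    def test_equal_costs_break_toward_smallest_params(self):
        """Candidates producing identical masks tie on cost; the winner
        must be the smallest (alpha, beta) of the tied set."""
        n, h, w = 64, 30, 30
        frames = np.full((n, h, w), 160, dtype=np.uint8)
        on = (np.arange(n) // 8) % 2 == 1
        frames[on, 12:18, 12:18] = 10
        video = VideoSequence(frames)
        t = np.arange(7 * n) / 22050.0
        audio = AcousticRecording(0.9 * np.sin(2 * np.pi * 196.875 * t))
        # contrast is 150: beta 40 and 60 give the same masks at both alphas
        grid = parameter_grid([15, 21], [40, 60])
        res = optimize_segmentation(video, audio, grid)
        costs = set(res.cost_map.entries.values())
        assert len(costs) == 1
        assert (res.best_params.alpha, res.best_params.beta) == (15, 40)

    def test_all_degenerate_grid_fails(self, small_recording):
        rec = small_recording
        # alpha=1 makes med - I identically zero: nothing is ever segmented
        grid = parameter_grid([1], [10, 50])
        with pytest.raises(OptimizationFailedError):
            optimize_segmentation(rec.video, rec.audio, grid)

    def test_oscillating_region_beats_static_dark_anatomy(self):
        """A candidate capturing the moving gap must outscore one locked
        onto a static dark blob of similar size."""
        rng = np.random.default_rng(0)
        n, h, w = 128, 60, 60
        frames = np.full((n, h, w), 160, dtype=np.uint8)
        t = np.arange(n)
        width = np.maximum(
            0.0, 8 * (np.sin(2 * np.pi * 150 * t / 3150.0) - 0.2)
        )
        cols = np.abs(np.arange(w) - 20.0)
        moving = np.zeros((n, h, w), dtype=bool)
        moving[:, 15:45, :] = cols[None, None, :] < width[:, None, None]
        frames[moving] = 30
        # static dark band, similar area, offset to the right
        frames[:, 22:38, 40:48] = 55
        video = VideoSequence(frames + rng.integers(0, 3, frames.shape).astype(np.uint8))

        audio_t = np.arange(7 * n) / 22050.0
        drive = np.maximum(0.0, np.sin(2 * np.pi * 150 * audio_t) - 0.2)
        audio = AcousticRecording(0.9 * (drive - drive.mean()) / drive.max())

        roi_moving = RegionOfInterest(10, 50, 5, 38)
        roi_static = RegionOfInterest(10, 50, 36, 56)
        grid = parameter_grid([31], [60])
        res_moving = optimize_segmentation(video, audio, grid, roi=roi_moving)
        try:
            res_static = optimize_segmentation(video, audio, grid, roi=roi_static)
        except OptimizationFailedError:
            # static content has no non-DC spectral mass at all: excluded
            return
        assert res_moving.best_cost < res_static.best_cost
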