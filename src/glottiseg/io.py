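"""File I/O: video readers, mask/map exports, CSV and figure writers.

Multi-page TIFF is the native interchange format for high-speed laryngeal
sequences; AVI/MP4 containers are handled through imageio when a suitable
decoder plugin is present.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .acoustic_processing import AmplitudeSpectrum
from .errors import FormatError
from .glottal_geometry import (
    GlottalAreaWaveform,
    GlottalGapWaveform,
    Glottovibrogram,
)
from .param_segmentation import BinaryMaskSequence
from .spectral_optimizer import CostMap
from .video_preprocess import (
    DEFAULT_FRAME_RATE_HZ,
    TotalVariationMap,
    VideoSequence,
    rgb_to_grayscale,
)

_TIFF_SUFFIXES = {".tif", ".tiff"}


def read_video(
    path: str | Path, frame_rate_hz: float | None = None
) -> VideoSequence:
    """Read a multi-page TIFF or AVI/MP4 sequence as 8-bit grayscale.

    The frame rate is taken from container metadata when available and
    overridden by ``frame_rate_hz``; TIFFs carry no rate, so the nominal
    3150 frames/s applies unless specified.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"video file not found: {path}")
    meta_fps = None
    if path.suffix.lower() in _TIFF_SUFFIXES:
        import tifffile

        frames = tifffile.imread(str(path))
    else:
        import imageio.v3 as iio

        try:
            frames = iio.imread(str(path))
            meta = iio.immeta(str(path), exclude_applied=False)
            meta_fps = meta.get("fps")
        except Exception as exc:
            raise FormatError(f"cannot decode video {path}: {exc}") from exc
    frames = np.asarray(frames)
    if frames.ndim == 2:
        raise FormatError(f"{path} holds a single frame; need a sequence")
    rate = frame_rate_hz or meta_fps or DEFAULT_FRAME_RATE_HZ
    if frames.ndim == 4:
        return rgb_to_grayscale(frames, rate)
    return VideoSequence(frames.astype(np.uint8, copy=False), rate)


def write_video_tiff(path: str | Path, video: VideoSequence) -> None:
    import tifffile

    tifffile.imwrite(str(path), video.frames, photometric="minisblack")


def write_masks_tiff(path: str | Path, masks: BinaryMaskSequence) -> None:
    """Masks stored as 8-bit pages with foreground 255."""
    import tifffile

    tifffile.imwrite(
        str(path),
        (masks.masks.astype(np.uint8) * 255),
        photometric="minisblack",
    )


def read_masks_tiff(path: str | Path) -> BinaryMaskSequence:
    import tifffile

    pages = np.asarray(tifffile.imread(str(path)))
    if pages.ndim == 2:
        pages = pages[None]
    return BinaryMaskSequence(pages > 127)


def write_tv_map(path_png: str | Path, path_csv: str | Path, tv: TotalVariationMap) -> None:
    """Export the total-variation map as 16-bit PNG plus CSV."""
    import imageio.v3 as iio

    values = tv.values
    vmax = max(values.max(), 1)
    scaled = np.clip(values / vmax * 65535, 0, 65535).astype(np.uint16)
    iio.imwrite(str(path_png), scaled)
    np.savetxt(str(path_csv), values, fmt="%d", delimiter=",")


def write_glottovibrogram_csv(path: str | Path, gvg: Glottovibrogram) -> None:
    """Rows are glottal levels, columns frames (heat-map orientation)."""
    np.savetxt(str(path), gvg.widths.T, fmt="%.4f", delimiter=",")


def write_glottovibrogram_png(path: str | Path, gvg: Glottovibrogram) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    im = ax.imshow(
        gvg.widths.T, aspect="auto", cmap="gray", interpolation="nearest"
    )
    ax.set_xlabel("frame")
    ax.set_ylabel("glottal level")
    fig.colorbar(im, ax=ax, label="gap width [px]")
    fig.tight_layout()
    fig.savefig(str(path), dpi=120)
    plt.close(fig)


def write_waveform_csv(
    path: str | Path, wave: GlottalAreaWaveform | GlottalGapWaveform
) -> None:
    series = wave.area if isinstance(wave, GlottalAreaWaveform) else wave.width
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame_index", "value"])
        for i, v in enumerate(series):
            writer.writerow([i, f"{v:.4f}"])


def write_spectrum_csv(path: str | Path, spectrum: AmplitudeSpectrum) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["bin_hz", "modulus"])
        for f, m in zip(spectrum.frequencies_hz(), spectrum.moduli):
            writer.writerow([f"{f:.4f}", f"{m:.8g}"])


def write_cost_map_csv(path: str | Path, cost_map: CostMap) -> None:
    a, b, c, u = cost_map.as_arrays()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["alpha", "beta", "cost", "usable"])
        for row in zip(a, b, c, u):
            writer.writerow([row[0], row[1], f"{row[2]:.8g}", int(row[3])])


def write_cost_map_png(
    path: str | Path, cost_map: CostMap, best: tuple[int, int] | None = None
) -> None:
    """Render the cost map as brightness with an asterisk at the minimum."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a, b, c, u = cost_map.as_arrays()
    alphas = np.unique(a)
    betas = np.unique(b)
    grid = np.full((len(betas), len(alphas)), np.nan)
    ai = {v: i for i, v in enumerate(alphas)}
    bi = {v: i for i, v in enumerate(betas)}
    for alpha, beta, cost, usable in zip(a, b, c, u):
        if usable:
            grid[bi[beta], ai[alpha]] = cost
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(grid, aspect="auto", cmap="gray", origin="lower")
    ax.set_xlabel("alpha index")
    ax.set_ylabel("beta index")
    fig.colorbar(im, ax=ax, label="cost")
    if best is not None:
        ax.plot(ai[best[0]], bi[best[1]], "r*", markersize=12)
    fig.tight_layout()
    fig.savefig(str(path), dpi=120)
    plt.close(fig)


def write_spectra_overlay_png(
    path: str | Path,
    video_spectrum: AmplitudeSpectrum,
    audio_spectrum: AmplitudeSpectrum,
) -> None:
    """Winning glottovibrogram spectrum over the voice spectrum (unit L1)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3))
    for spec, label in (
        (video_spectrum, "glottovibrogram |F|"),
        (audio_spectrum, "voice |S|"),
    ):
        m = spec.moduli[1:]
        total = m.sum() or 1.0
        ax.plot(spec.frequencies_hz()[1:], m / total, label=label)
    ax.set_xlabel("frequency [Hz]")
    ax.set_ylabel("normalized modulus")
    ax.legend()
    fig.tight_layout()
    fig.savefig(str(path), dpi=120)
    plt.close(fig)
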