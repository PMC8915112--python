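import numpy as np
import pytest

from glottiseg import PhonationModel, simulate


@pytest.fixture(scope="session")
def small_recording():
    """A short synthetic recording shared by fast pipeline tests."""
    return simulate(PhonationModel(duration_frames=128, seed=7))


@pytest.fixture(scope="session")
def gap_recording():
    """A recording with a never-closing residual gap (glottal insufficiency)."""
    return simulate(
        PhonationModel(duration_frames=128, seed=11, posterior_gap_px=2.0)
    )


def mean_dice(a: np.ndarray, b: np.ndarray) -> float:
    """Mean per-frame Dice overlap; empty-empty frames count as 1."""
    inter = (a & b).sum(axis=(1, 2))
    sa = a.sum(axis=(1, 2))
    sb = b.sum(axis=(1, 2))
    per_frame = np.where(sa + sb > 0, 2 * inter / np.maximum(sa + sb, 1), 1.0)
    return float(per_frame.mean())
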