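import numpy as np
import pytest

from femurshift import PhantomParams, TrialDesign


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def mini_design(seed: int = 0, n_frames: int = 48) -> TrialDesign:
    """A short trial that still has three identifiable dwells per stage."""
    up = n_frames * 5 // 12
    down = n_frames * 5 // 12
    return TrialDesign(
        n_frames=n_frames,
        ramp_up_frames=up,
        ramp_down_frames=down,
        rest_frames=n_frames - up - down,
        transition_frames=2,
        seed=seed,
    )


@pytest.fixture
def small_phantom() -> PhantomParams:
    return PhantomParams(image_height=80, image_width=112)


def two_region_image(H: int = 64, W: int = 96, lo: float = 60.0, hi: float = 180.0):
    """Vertical-edge two-region phantom plus its ground-truth mask."""
    img = np.full((H, W), lo)
    img[:, : W // 2] = hi
    truth = np.zeros((H, W), dtype=bool)
    truth[:, : W // 2] = True
    return img, truth


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())
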