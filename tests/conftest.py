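import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nanorods import Micrograph, SegmentationParams
from nanorods.synthetic import RodTruth, render_custom_scene

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

PS = 0.3482  # nm/px, native detector calibration


@pytest.fixture
def default_params():
    return SegmentationParams()


@pytest.fixture
def flat_image():
    return Micrograph(np.full((512, 512), 120.0), PS, source_id="flat")


@pytest.fixture
def single_capsule_scene():
    """One horizontal 300 x 18 nm capsule centred in a 512 x 1024 field."""
    rod = RodTruth(300.0, 18.0, 0.0, (256.0, 512.0))
    return render_custom_scene([rod], image_shape=(512, 1024), seed=101)


def brute_force_feret(coords: np.ndarray, pixel_size_nm: float) -> float:
    """Exhaustive O(n^2) maximum pairwise corner distance (test oracle)."""
    offsets = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
    pts = (coords[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max())) * pixel_size_nm


def random_blob(rng: np.random.Generator, max_px: int = 5000) -> np.ndarray:
    """Random connected pixel blob, returned as (N, 2) coordinates."""
    from scipy import ndimage as ndi

    n_seeds = int(rng.integers(1, 40))
    side = int(rng.integers(8, 64))
    mask = np.zeros((side + 10, side + 10), dtype=bool)
    pts = rng.integers(0, side, size=(n_seeds, 2))
    mask[pts[:, 0], pts[:, 1]] = True
    mask = ndi.binary_dilation(mask, iterations=int(rng.integers(1, 5)))
    coords = np.argwhere(mask)
    return coords[:max_px]
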