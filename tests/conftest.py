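import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from myotex import GrayImage, QuantizedRoi, RoiMask, normalize_mu3sigma

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def quantized_from_levels(levels: np.ndarray, mask=None, n_levels=None) -> QuantizedRoi:
    """Wrap an explicit level raster as a QuantizedRoi (test helper)."""
    levels = np.asarray(levels, dtype=np.int32)
    if mask is None:
        mask = levels > 0
    mask = np.asarray(mask, dtype=bool)
    ng = int(n_levels if n_levels is not None else max(4, levels.max()))
    return QuantizedRoi(
        levels_raster=np.where(mask, levels, 0),
        mask=mask,
        n_levels=ng,
        mu=float(levels[mask].mean()),
        sigma=float(levels[mask].std()),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_small_roi(rng):
    """An 8x8 fully-masked ROI with levels drawn in 1..6."""
    lev = rng.integers(1, 7, size=(8, 8))
    return quantized_from_levels(lev, np.ones((8, 8), bool), n_levels=6)


@pytest.fixture
def phantom_roi():
    """A quantized whole-wall ROI of a small default-texture phantom."""
    from myotex import PhantomSpec, generate_phantom

    spec = PhantomSpec(shape=(96, 96), center=(48.0, 48.0),
                       r_inner=18.0, r_outer=30.0, seed=11)
    image, masks = generate_phantom(spec)
    return normalize_mu3sigma(image, masks["whole_wall"], 64)
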