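import numpy as np
import pytest

from lobeseg.phantom import PhantomSpec, generate_phantom
from lobeseg.preprocess import preprocess_volume


@pytest.fixture(scope="session")
def small_phantom():
    """One small phantom pair shared by read-only tests."""
    spec = PhantomSpec(grid_shape=(24, 48, 48), spacing_mm=(4.0, 2.0, 2.0), seed=42)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def phantom_slices():
    """Preprocessed 256x256 slices of one mid-sized phantom."""
    spec = PhantomSpec(grid_shape=(24, 64, 64), spacing_mm=(4.0, 2.0, 2.0), seed=7)
    vol, lab = generate_phantom(spec)
    return preprocess_volume(vol, lab, volume_id="fixture")


@pytest.fixture(scope="session")
def lung_slices(phantom_slices):
    """The subset of fixture slices that actually contain lung labels."""
    sel = [s for s in phantom_slices if (s.mask > 0).mean() > 0.05]
    assert len(sel) >= 4
    return sel


@pytest.fixture
def rng():
    return np.random.default_rng(0)
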