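import numpy as np
import pytest

from bhcnet.data import MAGNIFICATIONS, SUBTYPES, SyntheticSpec, generate_synthetic_breakhis


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small synthetic dataset: 10 images per (subtype, magnification)."""
    root = tmp_path_factory.mktemp("breakhis_small")
    census = {s: {m: 10 for m in MAGNIFICATIONS} for s in SUBTYPES}
    spec = SyntheticSpec(census=census, image_size=32, seed=7)
    index = generate_synthetic_breakhis(spec, root)
    return root, index
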