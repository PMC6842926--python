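import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from voxsbml import fixtures, masks_to_model


@pytest.fixture(scope="session")
def nested_masks():
    return fixtures.nested_spheres(extents=(32, 32, 32), radii=(12.0, 6.0))


@pytest.fixture(scope="session")
def nested_result(nested_masks):
    return masks_to_model(nested_masks, name="nested")


@pytest.fixture(scope="session")
def nested_model(nested_result):
    return nested_result.model


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_label_grid(rng, max_extent=6, n_values=3):
    """A small random grid of sampled values for oracle comparisons."""
    shape = tuple(rng.integers(1, max_extent + 1, size=3))
    values = [0] + sorted(rng.choice(np.arange(1, 255), size=n_values - 1, replace=False).tolist())
    grid = rng.choice(values, size=shape).astype(np.uint8)
    return grid, values
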