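import numpy as np
import pytest

from npcctv.core import ImageGrid, StructureMask
from npcctv.phantom import PhantomSpec, generate_phantom, generate_scenario_suite
from npcctv.pipeline import run_pipeline


def make_grid(shape=(12, 12, 12), spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return ImageGrid(shape=shape, spacing=spacing, origin=origin)


def mask_from(grid, indices, name="m"):
    v = np.zeros(grid.shape, dtype=bool)
    for idx in indices:
        v[tuple(idx)] = True
    return StructureMask(name, grid, v)


def random_blob_mask(grid, rng, n_seeds=5, name="blob"):
    v = np.zeros(grid.shape, dtype=bool)
    idx = rng.integers(0, np.array(grid.shape), size=(n_seeds, 3))
    v[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return StructureMask(name, grid, v)


@pytest.fixture(scope="session")
def default_phantom():
    """T1 N0 phantom, non-invading left-sided primary."""
    return generate_phantom(PhantomSpec(seed=7, t_stage=1))


@pytest.fixture(scope="session")
def scenario_suite():
    return generate_scenario_suite(seed=3)


@pytest.fixture(scope="session")
def default_ctvs(default_phantom):
    sset, tumor = default_phantom
    return run_pipeline(sset, tumor)
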