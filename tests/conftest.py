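import numpy as np
import pytest

from eosdm import synthetic
from eosdm.grid import GridSpec, Raster
from eosdm.scene import Scene


@pytest.fixture(scope="session")
def truth():
    """Small default landscape shared by read-only tests."""
    return synthetic.generate_landscape(80, 80, seed=7)


@pytest.fixture(scope="session")
def scenes(truth):
    dates = [30, 75, 120, 150, 180, 210, 240, 280, 320, 350]
    return synthetic.generate_scene_collection(truth, dates, cloud_fraction=0.2, seed=3)


@pytest.fixture()
def flat_scene():
    """4x4 scene with hand-set constant bands."""
    grid = GridSpec(4, 4, 30.0)
    vals = {"blue": 0.05, "green": 0.12, "red": 0.1, "nir": 0.5, "swir1": 0.2, "swir2": 0.15}
    bands = {k: np.full(grid.shape, v) for k, v in vals.items()}
    return Scene(bands, grid, doy=180, sensor="TM")


def random_scene(seed, rows=6, cols=6, sensor="OLI"):
    rng = np.random.default_rng(seed)
    grid = GridSpec(rows, cols, 30.0)
    bands = {b: rng.uniform(0.01, 0.9, grid.shape) for b in ("blue", "green", "red", "nir", "swir1", "swir2")}
    return Scene(bands, grid, doy=int(rng.integers(1, 366)), sensor=sensor)
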