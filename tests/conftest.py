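import numpy as np
import pandas as pd
import pytest

from paleoiso.raster import RasterGrid
from paleoiso.synthetic import SyntheticConfig, generate_isotope_dataset, generate_sites


@pytest.fixture
def small_cfg():
    return SyntheticConfig(seed=7, grid_shape=(32, 32), n_sites=6)


@pytest.fixture
def sample_table(small_cfg):
    sites = generate_sites(small_cfg, margin_cells=2)
    samples, truth = generate_isotope_dataset(small_cfg, sites)
    return samples, truth


@pytest.fixture
def random_grid():
    rng = np.random.default_rng(11)
    return RasterGrid(values=rng.uniform(0, 100, size=(20, 20)))


def make_samples(rows):
    """Minimal schema-complete sample table from a list of dicts."""
    defaults = {
        "sample_id": "X",
        "site_id": "S1",
        "taxon": "Bos taurus",
        "category": "herbivore",
        "period": "EN",
        "culture": "Koros",
        "region": "Alfold",
        "d13C": -20.5,
        "d15N": 7.0,
        "collagen_yield": 5.0,
        "pct_C": 40.0,
        "pct_N": 14.0,
        "CN_atomic": 3.2,
        "is_infant": False,
        "source": "new",
    }
    out = []
    for i, row in enumerate(rows):
        rec = {**defaults, "sample_id": f"X{i}", **row}
        out.append(rec)
    return pd.DataFrame(out)
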