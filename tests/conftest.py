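import numpy as np
import pandas as pd
import pytest

from paleofd.spatial import build_weights
from paleofd.synthetic import SyntheticConfig


@pytest.fixture(scope="session")
def scattered_weights():
    """400 scattered cells with first-nearest-neighbor weights, eigs cached."""
    rng = np.random.default_rng(42)
    coords = rng.uniform(0, 1000, size=(400, 2))
    W = build_weights(coords)
    W.eigenvalues()
    return W


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale synthetic study used by several integration tests."""
    return SyntheticConfig(
        grid_nrows=8, grid_ncols=8, n_species=150, n_genera=25,
        richness_range=(10, 80), seed=3,
    )


@pytest.fixture()
def trait_frame():
    """Tiny hand-built complete trait table."""
    rng = np.random.default_rng(0)
    n = 40
    vals = 10.0 ** rng.normal(0.5, 0.4, size=(n, 4))
    df = pd.DataFrame(vals, columns=["sla", "seed_mass", "max_height", "stem_density"])
    df.insert(0, "species_id", [f"sp{i}" for i in range(n)])
    df.insert(1, "genus", [f"g{i % 8}" for i in range(n)])
    df.insert(2, "growth_form", [["forb", "tree", "graminoid", "shrub"][i % 4] for i in range(n)])
    return df
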