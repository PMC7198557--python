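import numpy as np
import pandas as pd
import pytest

from nicheclim import GridGeometry, ClimateStack, make_invasion_scenario


@pytest.fixture(scope="session")
def toy_geometry():
    return GridGeometry(n_rows=20, n_cols=30, cell_size=0.5, lon_min=0.0, lat_min=10.0)


@pytest.fixture(scope="session")
def toy_stack(toy_geometry):
    rng = np.random.default_rng(11)
    mask = np.ones(toy_geometry.shape, dtype=bool)
    mask[0, 0] = False  # one ocean cell
    layers = {
        "bio10": rng.uniform(0, 30, toy_geometry.shape),
        "bio19": rng.uniform(0, 1200, toy_geometry.shape),
    }
    return ClimateStack(geometry=toy_geometry, layers=layers, mask=mask)


@pytest.fixture(scope="session")
def default_world():
    """One seeded default invasion scenario shared by the slower tests."""
    return make_invasion_scenario(0.5, 0.0, seed=7)


def occurrence_csv(tmp_path, rows, name="occ.csv"):
    path = tmp_path / name
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
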