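import numpy as np
import pandas as pd
import pytest

from pasturegeo import PaddockLayout, VariogramModel, build_sampling_design

#: published spherical fit for soil pH in the 0-0.2 m layer, used throughout
#: as a generating truth (nugget 0.194, sill 0.404, range 83.90 m)
PH_SPHERICAL = dict(family="spherical", nugget=0.194, partial_sill=0.210,
                    range_m=83.90)


@pytest.fixture(scope="session")
def design():
    """The default 7-paddock, 196-point sampling design."""
    return build_sampling_design(PaddockLayout())


@pytest.fixture(scope="session")
def ph_model():
    return VariogramModel(**PH_SPHERICAL)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_table(rng):
    """Small irregular point table with one noisy variable."""
    n = 60
    df = pd.DataFrame({
        "point_id": [f"r{i}" for i in range(n)],
        "easting": rng.uniform(0, 200, n),
        "northing": rng.uniform(0, 120, n),
        "paddock": 1,
    })
    df["z"] = np.sin(df["easting"] / 30) + rng.normal(0, 0.3, n)
    return df
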