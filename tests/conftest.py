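import numpy as np
import pandas as pd
import pytest

from fossilclim.io import AQUATIC, MARKER, SPORE, TERRESTRIAL, AssemblageTable, ClimateTable
from fossilclim.synthetic import default_scenario


@pytest.fixture
def tiny_counts():
    """3-sample count table with one taxon per group."""
    data = pd.DataFrame(
        {
            "Pinus": [50.0, 30.0, 20.5],
            "Betula": [50.0, 60.0, 70.0],
            "Sphagnum": [10.0, 5.0, 0.0],
            "Pediastrum": [100.0, 0.0, 4.0],
            "Eucalyptus": [20.0, 25.0, 30.0],
        },
        index=["s1", "s2", "s3"],
    )
    groups = {
        "Pinus": TERRESTRIAL,
        "Betula": TERRESTRIAL,
        "Sphagnum": SPORE,
        "Pediastrum": AQUATIC,
        "Eucalyptus": MARKER,
    }
    return AssemblageTable(data, groups=groups, depths=[1.0, 2.0, 3.5])


@pytest.fixture
def two_sample_calibration():
    """The minimal weighted-averaging toy: two monospecific samples."""
    X = np.array([[100.0, 0.0], [0.0, 100.0]])
    y = np.array([10.0, 20.0])
    return X, y


@pytest.fixture(scope="session")
def small_scenario():
    """A cheap synthetic study shared by integration-style tests."""
    return default_scenario(seed=11, n_calibration=80, n_taxa=12, pollen_sum=250)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_climate(t_jul, t_jan=None, ids=None, coords=False, rng=None):
    t_jul = np.asarray(t_jul, float)
    if t_jan is None:
        t_jan = t_jul - 15.0
    ids = ids if ids is not None else [f"c{i}" for i in range(len(t_jul))]
    data = {"t_jul": t_jul, "t_jan": t_jan}
    if coords:
        r = rng or np.random.default_rng(1)
        data["lat"] = 60 + r.uniform(0, 10, len(t_jul))
        data["lon"] = 10 + r.uniform(0, 20, len(t_jul))
    return ClimateTable(pd.DataFrame(data, index=ids))
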