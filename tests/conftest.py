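import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from halospat import synthetic_data as sd
from halospat.env_sensors import SensorSeries


@pytest.fixture
def star_tree() -> TreeNode:
    """Three-tip star tree with branch lengths 1, 2, 3."""
    return TreeNode.read(io.StringIO("(A:1,B:2,C:3);"))


@pytest.fixture
def unit_star_tree() -> TreeNode:
    return TreeNode.read(io.StringIO("(A:1,B:1);"))


@pytest.fixture
def local_design() -> sd.DesignSpec:
    """The intra-nodule survey: 6 nodules x 3 slices x 3 positions."""
    return sd.DesignSpec(n_regions=1, sites_per_region=1, nodules_per_site=6,
                         slices_per_nodule=3)


def constant_series(n: int, rh: float = 90.0, temp: float = 20.0,
                    start: str = "2020-01-01") -> SensorSeries:
    time = pd.date_range(start, periods=n, freq="30min")
    return SensorSeries(time=time, rh=np.full(n, rh), temp=np.full(n, temp))


@pytest.fixture
def random_table():
    """Factory for random small count tables (no empty samples)."""

    def make(rng, n_samples=5, n_taxa=6, depth=200):
        probs = rng.dirichlet(np.ones(n_taxa), size=n_samples)
        counts = np.stack([rng.multinomial(depth, p) for p in probs])
        counts[:, 0] += 1  # guarantee positive totals
        return pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"t{j}" for j in range(n_taxa)],
        )

    return make
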