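import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from phylosym.containers import FeatureTable, SampleMetadata
from phylosym.simulate import SimConfig, simulate


@pytest.fixture
def four_tip_tree():
    """((A:1,B:1):1,(C:1,D:1):1); — the workhorse toy phylogeny."""
    return TreeNode.read(io.StringIO("((A:1,B:1):1,(C:1,D:1):1);"))


@pytest.fixture
def small_table():
    data = pd.DataFrame(
        [[5, 0, 2], [3, 1, 0], [0, 4, 0], [0, 0, 7]],
        index=["A", "B", "C", "D"],
        columns=["S1", "S2", "S3"],
    )
    return FeatureTable(data)


@pytest.fixture
def small_metadata():
    frame = pd.DataFrame(
        {
            "host_species": ["sp1", "sp1", "sp2"],
            "host_order": ["ord1", "ord1", "ord2"],
            "host_class": ["Mammalia", "Mammalia", "Mammalia"],
            "flight": ["flightless"] * 3,
            "diet_plant": [60.0, 60.0, 20.0],
            "diet_meat": [40.0, 40.0, 80.0],
        },
        index=pd.Index(["S1", "S2", "S3"], name="sample_id"),
    )
    return SampleMetadata(frame)


@pytest.fixture(scope="session")
def sim_small():
    """Small but full-featured simulation shared across tests (read-only)."""
    cfg = SimConfig(
        n_species=12,
        n_orders=3,
        samples_per_species=2,
        n_asvs=80,
        reads_per_sample=800,
        tree_depth=20.0,
        seed=42,
    )
    return simulate(cfg)


def random_distance_matrix(rng, n, ids=None):
    """Random symmetric matrix with zero diagonal (euclidean of random points)."""
    from scipy.spatial.distance import pdist, squareform
    from skbio import DistanceMatrix

    pts = rng.random((n, 3))
    return DistanceMatrix(squareform(pdist(pts)), ids=ids or [f"o{i}" for i in range(n)])
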