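import numpy as np
import pandas as pd
import pytest

from parcelcam.atlas import AtlasParcellation, ConnectivityGraph
from parcelcam.synthetic import EffectSpec, make_synthetic_atlas, simulate_graph_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_atlas():
    """Two disjoint rectangular parcels in a 6x6x6 volume."""
    label = np.zeros((6, 6, 6), dtype=np.int32)
    label[:3, :, :] = 1
    label[3:, :, :2] = 2
    table = pd.DataFrame({
        "parcel_id": [1, 2],
        "name": ["Block A", "Block B"],
        "hemisphere": ["left", "right"],
        "lobe": ["frontal", "frontal"],
        "group": ["cortical", "cortical"],
    })
    return AtlasParcellation(label_volume=label, parcel_table=table)


@pytest.fixture
def small_atlas():
    return make_synthetic_atlas(8, shape=(24, 24, 24), seed=7)


@pytest.fixture
def small_graph_cohort():
    """40 subjects, 12-node connectomes, strong planted effect."""
    effect = EffectSpec(effect_parcels=frozenset({1, 2, 3}),
                        effect_size=0.5, noise_sd=0.05, seed=11)
    return simulate_graph_cohort(n_nodes=12, n_subjects=40, effect=effect)


def make_graph(matrix, **kw):
    n = matrix.shape[0]
    return ConnectivityGraph(matrix=matrix, node_ids=np.arange(1, n + 1), **kw)
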