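import numpy as np
import pytest

from histoage.graph import graph_from_features
from histoage.model import HistoAgeNet, ModelConfig
from histoage.synthetic import SimConfig, simulate_feature_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """20 subjects, 6x6 grids, 16-d features — shared across fast tests."""
    cfg = SimConfig(n_subjects=20, grid_shape=(6, 6), feature_dim=16, seed=42)
    bags, record, truth = simulate_feature_cohort(cfg)
    return cfg, bags, record, truth


@pytest.fixture(scope="session")
def small_graphs(small_cohort):
    _cfg, bags, _record, _truth = small_cohort
    graphs = [graph_from_features(b.slide_id, b.X, b.coords, age=b.age) for b in bags]
    ages = np.array([b.age for b in bags])
    return graphs, ages


@pytest.fixture(scope="session")
def tiny_net(small_graphs):
    graphs, _ = small_graphs
    cfg = ModelConfig(input_dim=graphs[0].X.shape[1], hidden_dim=16)
    return HistoAgeNet(cfg, seed=0)
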