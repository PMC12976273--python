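import numpy as np
import pytest

from linkale.graph import AttributedGraph
from linkale.models import LinkPredictor, ModelConfig
from linkale.nn import Encoder


def random_graph(n: int, n_features: int = 3, p_edge: float = 0.25,
                 seed: int = 0, signal: bool = True) -> AttributedGraph:
    """Small random attributed digraph for unit tests."""
    rng = np.random.default_rng(seed)
    feats = rng.standard_normal((n, n_features))
    names = [f"f{i}" for i in range(n_features - 1)] + ["signal"]
    edges = [
        (i, j)
        for i in range(n)
        for j in range(n)
        if i != j and rng.random() < p_edge
    ]
    return AttributedGraph(
        node_features=feats,
        edges=np.array(edges, dtype=np.int64).reshape(-1, 2),
        feature_names=names,
        signal_feature="signal" if signal else None,
    )


def untrained_predictor(graph: AttributedGraph, architecture: str = "GCN",
                        n_layers: int = 2, hidden_dim: int = 8,
                        seed: int = 0, propagation: str = "full") -> LinkPredictor:
    """Random-weight link predictor: enough for contract and oracle tests."""
    cfg = ModelConfig(architecture=architecture, n_layers=n_layers,
                      hidden_dim=hidden_dim, seed=seed)
    enc = Encoder(architecture, cfg.layer_dims(graph.n_features), seed=seed)
    return LinkPredictor(enc, graph, cfg, graph.edges, propagation=propagation)


def path_graph(n: int, n_features: int = 4, seed: int = 0) -> AttributedGraph:
    """Bidirected path 0-1-...-(n-1): hop distances are easy to reason about."""
    rng = np.random.default_rng(seed)
    edges = []
    for i in range(n - 1):
        edges.append((i, i + 1))
        edges.append((i + 1, i))
    return AttributedGraph(
        node_features=rng.standard_normal((n, n_features)),
        edges=np.array(edges, dtype=np.int64),
        feature_names=[f"f{i}" for i in range(n_features)],
    )


@pytest.fixture(scope="session")
def tiny_graph() -> AttributedGraph:
    return random_graph(n=12, seed=3)
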