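"""Synthetic attributed graphs with a known feature-edge relationship.

Each node carries ``n_noise_features`` i.i.d. standard-normal noise features
and one signal feature drawn i.i.d. from Uniform[-1, 1]. For every source
node, a candidate-target set of size ``ceil(sparsity * (n - 1))`` is sampled
uniformly without replacement (excluding the source); each candidate pair
``(u, v)`` receives a directed edge independently with probability

    p = (x_u + x_v + 2) / 4,

where ``x_u`` and ``x_v`` are the signal feature values of source and
target. Edge formation therefore depends on the signal feature alone, with
constant true local effect dp/dx = 1/4 per endpoint, giving an analytic
ground-truth accumulated-effect curve for validating explanations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import AttributedGraph

SIGNAL_NAME = "signal"


class ConfigError(ValueError):
    """Raised for invalid generator configurations."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic graph generator.

    ``sparsity`` controls the candidate-target set size per source node,
    ``ceil(sparsity * (n_nodes - 1))``; expected edge density is roughly
    ``sparsity / 2`` because the mean edge probability is 1/2.
    """

    n_nodes: int = 1000
    n_noise_features: int = 5
    sparsity: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ConfigError("n_nodes must be at least 2")
        if not (0.0 < self.sparsity <= 1.0):
            raise ConfigError("sparsity must lie in (0, 1]")
        if self.n_noise_features < 0:
            raise ConfigError("n_noise_features must be non-negative")

    @property
    def candidates_per_node(self) -> int:
        return int(np.ceil(self.sparsity * (self.n_nodes - 1)))


@dataclass(frozen=True)
class GroundTruthCurve:
    """True accumulated local effect of the signal feature.

    ``values[j]`` is the accumulation of the constant local effect 1/4 from
    the minimum bin edge: ``(bin_edges[j] - bin_edges[0]) / 4``, anchored to
    zero at the first edge (uncentered convention).
    """

    bin_edges: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, float))
        object.__setattr__(self, "values", np.asarray(self.values, float))


def edge_probability(x_source: np.ndarray, x_target: np.ndarray) -> np.ndarray:
    """True edge probability ``(x_u + x_v + 2) / 4`` for candidate pairs."""
    return (np.asarray(x_source, float) + np.asarray(x_target, float) + 2.0) / 4.0


def generate_synthetic_graph(config: SyntheticConfig) -> AttributedGraph:
    """Generate an attributed directed graph; byte-reproducible from seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_nodes
    noise = rng.standard_normal((n, config.n_noise_features))
    signal = rng.uniform(-1.0, 1.0, size=n)
    features = np.column_stack([noise, signal])
    names = [f"noise_{i}" for i in range(config.n_noise_features)] + [SIGNAL_NAME]

    k = config.candidates_per_node
    # Candidate targets per source: uniform without replacement, source excluded.
    sources = np.repeat(np.arange(n), k)
    targets = np.empty(n * k, dtype=np.int64)
    for u in range(n):
        t = rng.choice(n - 1, size=k, replace=False)
        targets[u * k : (u + 1) * k] = np.where(t >= u, t + 1, t)
    p = edge_probability(signal[sources], signal[targets])
    keep = rng.random(n * k) < p
    edges = np.column_stack([sources[keep], targets[keep]])

    return AttributedGraph(
        node_features=features,
        edges=edges,
        feature_names=names,
        directed=True,
        signal_feature=SIGNAL_NAME,
        candidate_pairs=np.column_stack([sources, targets]),
    )


def ground_truth_ale(bin_edges: np.ndarray) -> GroundTruthCurve:
    """Uncentered true accumulated effect of the signal feature on the bins."""
    bin_edges = np.asarray(bin_edges, dtype=float)
    if bin_edges.ndim != 1 or bin_edges.size < 2:
        raise ValueError("bin_edges must be a 1-D vector of length >= 2")
    if np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin_edges must be strictly ascending")
    values = (bin_edges - bin_edges[0]) / 4.0
    return GroundTruthCurve(bin_edges=bin_edges, values=values)


def true_score_function(graph: AttributedGraph):
    """The generating probability as a pairwise scorer (bypasses any model).

    Returns a callable ``f(pairs, overrides) -> probabilities`` with the same
    signature contract as ``LinkPredictor.predict_links``: ``overrides`` maps
    node index to a full feature vector or ``{feature_index: value}``. Since
    the true score involves no message passing, modified nodes can never
    contaminate one another, making this the reference predictor for
    slope-recovery checks.
    """
    sig = graph.feature_index(SIGNAL_NAME)

    def score(pairs: np.ndarray, overrides: dict | None = None) -> np.ndarray:
        x = graph.node_features[:, sig].copy()
        if overrides:
            for node, val in overrides.items():
                if isinstance(val, dict):
                    if sig in val:
                        x[node] = val[sig]
                else:
                    x[node] = np.asarray(val, float)[sig]
        pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
        return edge_probability(x[pairs[:, 0]], x[pairs[:, 1]])

    return score
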