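"""GCN / GAT message-passing layers, batch normalization and the encoder.

Layers follow the standard formulations: GCN with symmetric degree
normalization and self-loops; single-head GAT with additive attention,
LeakyReLU(0.2) scoring and per-target softmax. Message passing runs over a
fixed edge list (the training graph), so a node's embedding after L layers
depends only on nodes within L directed hops — the receptive-field property
the explanation estimators rely on.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse as sp

from .autodiff import Tensor, segment_softmax


def glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> Tensor:
    limit = np.sqrt(6.0 / (shape[0] + shape[-1]))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


def add_self_loops(edges: np.ndarray, n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    src = np.concatenate([edges[:, 0], np.arange(n_nodes)])
    dst = np.concatenate([edges[:, 1], np.arange(n_nodes)])
    return src.astype(np.int64), dst.astype(np.int64)


def gcn_adjacency(edges: np.ndarray, n_nodes: int,
                  self_loop_weight: float = 1.0) -> sp.csr_matrix:
    """Normalized adjacency D^{-1/2} (A + s*I) D^{-1/2} with in-degree norm.

    ``self_loop_weight`` generalizes the "improved" GCN convention (s=2):
    larger values emphasize a node's own features over its neighborhood.
    """
    edges = edges.reshape(-1, 2)
    src = np.concatenate([edges[:, 0], np.arange(n_nodes)]).astype(np.int64)
    dst = np.concatenate([edges[:, 1], np.arange(n_nodes)]).astype(np.int64)
    ew = np.concatenate([np.ones(len(edges)), np.full(n_nodes, self_loop_weight)])
    deg = np.bincount(dst, weights=ew, minlength=n_nodes)
    dinv = 1.0 / np.sqrt(np.maximum(deg, 1e-12))
    w = ew * dinv[src] * dinv[dst]
    return sp.csr_matrix((w, (dst, src)), shape=(n_nodes, n_nodes))


class GCNConv:
    def __init__(self, rng: np.random.Generator, in_dim: int, out_dim: int):
        self.weight = glorot(rng, (in_dim, out_dim))
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    param_names = ("weight", "bias")

    def parameters(self) -> list[Tensor]:
        return [self.weight, self.bias]

    def __call__(self, x: Tensor, adj: sp.csr_matrix, src, dst, n) -> Tensor:
        return (x @ self.weight).spmm(adj) + self.bias


class GATConv:
    """Single-head graph attention layer (additive attention)."""

    def __init__(self, rng: np.random.Generator, in_dim: int, out_dim: int):
        self.weight = glorot(rng, (in_dim, out_dim))
        self.att_src = glorot(rng, (out_dim, 1))
        self.att_dst = glorot(rng, (out_dim, 1))
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    param_names = ("weight", "att_src", "att_dst", "bias")

    def parameters(self) -> list[Tensor]:
        return [self.weight, self.att_src, self.att_dst, self.bias]

    def __call__(self, x: Tensor, adj, src: np.ndarray, dst: np.ndarray, n: int) -> Tensor:
        h = x @ self.weight
        a_src = (h @ self.att_src).reshape(-1)
        a_dst = (h @ self.att_dst).reshape(-1)
        scores = (a_src.gather(src) + a_dst.gather(dst)).leaky_relu(0.2)
        alpha = segment_softmax(scores, dst, n)
        msgs = h.gather(src) * alpha.reshape(-1, 1)
        return msgs.scatter_add(dst, n) + self.bias


class BatchNorm:
    """Batch normalization over nodes with running statistics for inference."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def parameters(self) -> list[Tensor]:
        return [self.gamma, self.beta]

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data.ravel()
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var.data.ravel()
            )
        else:
            mu = Tensor(self.running_mean)
            var = Tensor(self.running_var)
        xhat = (x - mu) / (var + self.eps).sqrt()
        return xhat * self.gamma + self.beta


class Encoder:
    """Stack of message-passing layers, each followed by batch norm.

    A nonlinearity (ReLU for GCN, ELU for GAT) sits between layers but not
    after the last one; the decoder consumes the final embeddings directly.
    """

    def __init__(self, architecture: str, dims: list[int], seed: int,
                 self_loop_weight: float = 1.0):
        rng = np.random.default_rng(seed)
        conv_cls = {"GCN": GCNConv, "GAT": GATConv}[architecture]
        self.architecture = architecture
        self.self_loop_weight = self_loop_weight
        self.convs = [conv_cls(rng, dims[i], dims[i + 1]) for i in range(len(dims) - 1)]
        self.norms = [BatchNorm(dims[i + 1]) for i in range(len(dims) - 1)]

    @property
    def n_layers(self) -> int:
        return len(self.convs)

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for conv, norm in zip(self.convs, self.norms):
            out += conv.parameters() + norm.parameters()
        return out

    def prepare(self, edges: np.ndarray, n_nodes: int) -> dict:
        """Precompute the message-passing structure for an edge list."""
        edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        src, dst = add_self_loops(edges, n_nodes)
        return {
            "adj": gcn_adjacency(edges, n_nodes, self.self_loop_weight),
            "src": src,
            "dst": dst,
            "n": n_nodes,
        }

    def __call__(self, features: np.ndarray | Tensor, struct: dict,
                 training: bool = False, dropout: float = 0.0,
                 rng: np.random.Generator | None = None) -> Tensor:
        x = features if isinstance(features, Tensor) else Tensor(features)
        last = len(self.convs) - 1
        for i, (conv, norm) in enumerate(zip(self.convs, self.norms)):
            x = conv(x, struct["adj"], struct["src"], struct["dst"], struct["n"])
            x = norm(x, training)
            if i != last:
                x = x.relu() if self.architecture == "GCN" else x.elu()
                if training and dropout > 0.0 and rng is not None:
                    mask = (rng.random(x.shape) >= dropout) / (1.0 - dropout)
                    x = x * Tensor(mask)
        return x

    # ----------------------------------------------------------- state dict

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, (conv, norm) in enumerate(zip(self.convs, self.norms)):
            for name, t in zip(conv.param_names, conv.parameters()):
                state[f"conv{i}.{name}"] = t.data.copy()
            state[f"norm{i}.gamma"] = norm.gamma.data.copy()
            state[f"norm{i}.beta"] = norm.beta.data.copy()
            state[f"norm{i}.running_mean"] = norm.running_mean.copy()
            state[f"norm{i}.running_var"] = norm.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, (conv, norm) in enumerate(zip(self.convs, self.norms)):
            for name, t in zip(conv.param_names, conv.parameters()):
                t.data = state[f"conv{i}.{name}"].copy()
            norm.gamma.data = state[f"norm{i}.gamma"].copy()
            norm.beta.data = state[f"norm{i}.beta"].copy()
            norm.running_mean = state[f"norm{i}.running_mean"].copy()
            norm.running_var = state[f"norm{i}.running_var"].copy()
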