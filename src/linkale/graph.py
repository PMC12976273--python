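"""Attributed directed graphs: the container every pipeline stage consumes.

A graph is a node-feature table plus an ordered edge list. Synthetic graphs
additionally carry the candidate-pair structure produced by the generator
(the set of ordered pairs that were eligible to become edges), which the
training harness uses for structurally matched negative sampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class GraphError(ValueError):
    """Raised for malformed graphs or invalid graph operations."""


@dataclass
class AttributedGraph:
    """Directed graph with real-valued node features.

    Parameters
    ----------
    node_features:
        ``(n_nodes, n_features)`` float array, one row per node.
    edges:
        ``(n_edges, 2)`` integer array of ordered ``(source, target)`` pairs.
    feature_names:
        Unique column names, same length as the feature dimension.
    signal_feature:
        Name of the column flagged as the signal feature, if any.
    candidate_pairs:
        Optional ``(n_candidates, 2)`` array of ordered pairs that were
        eligible to receive an edge (a superset of ``edges`` for synthetic
        graphs). ``None`` for graphs without known candidate structure.
    """

    node_features: np.ndarray
    edges: np.ndarray
    feature_names: list[str]
    directed: bool = True
    signal_feature: str | None = None
    candidate_pairs: np.ndarray | None = None
    _edge_set: set[tuple[int, int]] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.node_features = np.asarray(self.node_features, dtype=float)
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if self.node_features.ndim != 2:
            raise GraphError("node_features must be a 2-D matrix")
        n = self.n_nodes
        if len(self.feature_names) != self.node_features.shape[1]:
            raise GraphError("feature_names length must match feature dimension")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise GraphError("feature names must be unique")
        if self.signal_feature is not None and self.signal_feature not in self.feature_names:
            raise GraphError(f"unknown signal feature {self.signal_feature!r}")
        if self.edges.size:
            if self.edges.min() < 0 or self.edges.max() >= n:
                raise GraphError("edge endpoint index out of range")
            if np.any(self.edges[:, 0] == self.edges[:, 1]):
                raise GraphError("self-loops are not allowed")
            uniq = {tuple(e) for e in self.edges}
            if len(uniq) != len(self.edges):
                raise GraphError("duplicate ordered edge pairs")
        if self.candidate_pairs is not None:
            self.candidate_pairs = np.asarray(
                self.candidate_pairs, dtype=np.int64
            ).reshape(-1, 2)

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    @property
    def n_features(self) -> int:
        return self.node_features.shape[1]

    def feature_index(self, name: str) -> int:
        try:
            return self.feature_names.index(name)
        except ValueError:
            raise GraphError(f"unknown feature {name!r}") from None

    def edge_set(self) -> set[tuple[int, int]]:
        if self._edge_set is None:
            self._edge_set = {(int(s), int(t)) for s, t in self.edges}
        return self._edge_set

    def feature_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.node_features, columns=self.feature_names)

    # ------------------------------------------------------------------ I/O

    def save(self, directory: str | Path, manifest: dict | None = None) -> None:
        """Write node table, edge list, optional candidate pairs and manifest.

        Layout: ``nodes.csv`` (header ``node_id,<features...>``),
        ``edges.csv`` (header ``source,target``), ``candidates.csv`` when
        candidate structure is present, ``manifest.json``.
        """
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        nodes = self.feature_frame()
        nodes.insert(0, "node_id", np.arange(self.n_nodes))
        nodes.to_csv(directory / "nodes.csv", index=False)
        pd.DataFrame(self.edges, columns=["source", "target"]).to_csv(
            directory / "edges.csv", index=False
        )
        if self.candidate_pairs is not None:
            pd.DataFrame(self.candidate_pairs, columns=["source", "target"]).to_csv(
                directory / "candidates.csv", index=False
            )
        meta = {
            "directed": self.directed,
            "signal_feature": self.signal_feature,
            "feature_names": self.feature_names,
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
        }
        if manifest:
            meta.update(manifest)
        (directory / "manifest.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "AttributedGraph":
        directory = Path(directory)
        nodes = pd.read_csv(directory / "nodes.csv")
        nodes = nodes.sort_values("node_id")
        feature_names = [c for c in nodes.columns if c != "node_id"]
        edges = pd.read_csv(directory / "edges.csv")[["source", "target"]].to_numpy()
        cand = None
        cand_path = directory / "candidates.csv"
        if cand_path.exists():
            cand = pd.read_csv(cand_path)[["source", "target"]].to_numpy()
        signal = None
        directed = True
        mpath = directory / "manifest.json"
        if mpath.exists():
            meta = json.loads(mpath.read_text())
            signal = meta.get("signal_feature")
            directed = meta.get("directed", True)
        return cls(
            node_features=nodes[feature_names].to_numpy(dtype=float),
            edges=edges,
            feature_names=feature_names,
            directed=directed,
            signal_feature=signal,
            candidate_pairs=cand,
        )
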