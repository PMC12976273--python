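"""Accumulated local effects (ALE) for link prediction, exact and approximate.

The ALE curve of a feature is built by dividing the feature's support into
bins, measuring how the model's prediction changes when the feature moves
from a bin's lower to its upper edge, and accumulating the per-bin average
changes. For link prediction, the feature of one endpoint (the *modified*
node ``v``) is varied while the other endpoint ``u`` ranges over a fixed
target set ``U``; predictions are averaged over both.

Two estimators are provided:

* **exact** — one node is modified per forward pass, so modified nodes can
  never influence one another through message passing. Costs ``2 * m``
  forward passes.
* **approximate** — all sampled nodes of a bin are modified simultaneously
  and scored in one forward pass per bin edge, costing ``2 * H`` passes
  independent of ``m``. Modified nodes inside each other's receptive fields
  contaminate the estimate; this disturbance is deliberately left
  uncorrected — quantifying it is the point of having both estimators.

Profiles store raw per-bin sums of prediction differences and the number of
differences per bin, which makes aggregation of many runs exact: pooled
sums and counts reproduce the profile a single large run would have given.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .graph import AttributedGraph

logger = logging.getLogger(__name__)


class DegenerateFeatureError(ValueError):
    """Raised when a feature has too few distinct values to bin."""


class IncompatibleProfilesError(ValueError):
    """Raised when profiles with different grids or features are combined."""


# ---------------------------------------------------------------------- bins


def make_bins(
    feature_values: np.ndarray, n_bins: int, strategy: str = "quantile"
) -> np.ndarray:
    """Ascending bin edges spanning [min, max] of the feature.

    ``quantile`` uses empirical quantiles with duplicate edges collapsed
    (which can reduce the number of bins); ``uniform`` uses equal-width
    bins. Assignment convention is half-open ``(z_{h-1}, z_h]`` with the
    minimum assigned to the first bin.
    """
    x = np.asarray(feature_values, dtype=float)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if np.unique(x).size < 2:
        raise DegenerateFeatureError("feature is constant; cannot build bins")
    if strategy == "quantile":
        edges = np.quantile(x, np.linspace(0.0, 1.0, n_bins + 1))
        edges = np.unique(edges)
    elif strategy == "uniform":
        edges = np.linspace(x.min(), x.max(), n_bins + 1)
    else:
        raise ValueError(f"unknown bin strategy {strategy!r}")
    if edges.size < 2:
        raise DegenerateFeatureError("feature support collapsed to a point")
    return edges


def assign_bins(values: np.ndarray, bin_edges: np.ndarray) -> np.ndarray:
    """Bin index per value, convention ``(z_{h-1}, z_h]``, minimum to bin 0."""
    idx = np.searchsorted(bin_edges, np.asarray(values, float), side="left") - 1
    return np.clip(idx, 0, len(bin_edges) - 2)


# ------------------------------------------------------------------- profile


@dataclass(frozen=True)
class ALEProfile:
    """Binned explanation curve with raw sufficient statistics.

    ``bin_sums[h]`` is the raw sum of prediction differences in bin ``h``;
    ``bin_counts[h]`` the number of (modified node, target) prediction
    differences that produced it. The accumulated curve is recomputed from
    these on demand, so a profile is fully reconstructible from
    ``(bin_edges, bin_sums, bin_counts)`` and aggregation of runs stays
    exact. ``normalization`` selects the per-bin denominator: ``per_bin``
    divides each bin's sum by its own count (standard ALE), ``global``
    divides by the total prediction budget ``m * k``.
    """

    feature_name: str
    bin_edges: np.ndarray
    bin_sums: np.ndarray
    bin_counts: np.ndarray
    m: int
    k: int
    normalization: str = "per_bin"
    method: str = ""
    seed: int | None = None
    mk_weight: int | None = None  # total m*k budget; summed on aggregation
    center_offset: float = 0.0
    model_fingerprint: str | None = None
    runtime_seconds: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, float))
        object.__setattr__(self, "bin_sums", np.asarray(self.bin_sums, float))
        object.__setattr__(
            self, "bin_counts", np.asarray(self.bin_counts, np.int64)
        )
        if self.normalization not in ("per_bin", "global"):
            raise ValueError("normalization must be 'per_bin' or 'global'")
        if not (len(self.bin_edges) - 1 == len(self.bin_sums) == len(self.bin_counts)):
            raise ValueError("bin arrays have inconsistent lengths")
        if self.mk_weight is None:
            object.__setattr__(self, "mk_weight", int(self.m) * int(self.k))

    @property
    def n_bins(self) -> int:
        return len(self.bin_sums)

    @property
    def values(self) -> np.ndarray:
        """Uncentered accumulated curve at each bin's right edge."""
        if self.normalization == "per_bin":
            with np.errstate(invalid="ignore", divide="ignore"):
                inc = np.where(self.bin_counts > 0, self.bin_sums, 0.0) / np.maximum(
                    self.bin_counts, 1
                )
        else:
            inc = self.bin_sums / float(self.mk_weight)
        return np.cumsum(inc) - self.center_offset

    # --------------------------------------------------------------- file IO

    def save(self, path: str | Path) -> None:
        payload = {
            "feature_name": self.feature_name,
            "bin_edges": [repr(float(v)) for v in self.bin_edges],
            "bin_sums": [repr(float(v)) for v in self.bin_sums],
            "bin_counts": [int(c) for c in self.bin_counts],
            "m": int(self.m),
            "k": int(self.k),
            "mk_weight": int(self.mk_weight),
            "values": [repr(float(v)) for v in self.values],
            "normalization": self.normalization,
            "method": self.method,
            "seed": self.seed,
            "center_offset": repr(float(self.center_offset)),
            "model_fingerprint": self.model_fingerprint,
            "runtime_seconds": self.runtime_seconds,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ALEProfile":
        d = json.loads(Path(path).read_text())
        return cls(
            feature_name=d["feature_name"],
            bin_edges=np.array([float(v) for v in d["bin_edges"]]),
            bin_sums=np.array([float(v) for v in d["bin_sums"]]),
            bin_counts=np.array(d["bin_counts"], dtype=np.int64),
            m=d["m"],
            k=d["k"],
            mk_weight=d.get("mk_weight"),
            normalization=d["normalization"],
            method=d.get("method", ""),
            seed=d.get("seed"),
            center_offset=float(d.get("center_offset", 0.0)),
            model_fingerprint=d.get("model_fingerprint"),
            runtime_seconds=d.get("runtime_seconds"),
        )


def model_fingerprint(model) -> str | None:
    """Stable hash of an encoder's weights, if the model exposes them."""
    try:
        state = model.encoder.state_dict()
    except AttributeError:
        return None
    h = hashlib.sha1()
    for key in sorted(state):
        h.update(key.encode())
        h.update(np.ascontiguousarray(state[key]).tobytes())
    return h.hexdigest()[:16]


# ------------------------------------------------------- tabular reference


def ale_tabular(
    predictor,
    data: pd.DataFrame,
    feature: str,
    bins: int | np.ndarray = 5,
    strategy: str = "quantile",
    normalization: str = "per_bin",
) -> ALEProfile:
    """Reference ALE estimator for a single-input (tabular) scorer.

    ``predictor`` maps a feature table (DataFrame) to a prediction vector.
    Each row contributes the difference between predictions at its bin's
    upper and lower edge, holding all other columns fixed.
    """
    if len(data) == 0:
        raise ValueError("empty data")
    if feature not in data.columns:
        raise KeyError(f"feature {feature!r} not in data")
    x = data[feature].to_numpy(dtype=float)
    edges = bins if not np.isscalar(bins) else make_bins(x, int(bins), strategy)
    edges = np.asarray(edges, float)
    which = assign_bins(x, edges)
    H = len(edges) - 1
    sums = np.zeros(H)
    counts = np.zeros(H, dtype=np.int64)
    for h in range(H):
        rows = data[which == h]
        if len(rows) == 0:
            logger.warning("empty bin %d in tabular ALE", h)
            continue
        hi = rows.assign(**{feature: edges[h + 1]})
        lo = rows.assign(**{feature: edges[h]})
        diff = np.asarray(predictor(hi), float) - np.asarray(predictor(lo), float)
        sums[h] = diff.sum()
        counts[h] = len(rows)
    return ALEProfile(
        feature_name=feature,
        bin_edges=edges,
        bin_sums=sums,
        bin_counts=counts,
        m=len(data),
        k=1,
        normalization=normalization,
        method="tabular",
    )


# ------------------------------------------------- link-prediction variants


def _resolve_bins(graph, feature, bins, strategy):
    fi = graph.feature_index(feature)
    x = graph.node_features[:, fi]
    if np.isscalar(bins):
        edges = make_bins(x, int(bins), strategy)
    else:
        edges = np.asarray(bins, float)
    return fi, x, edges


def _sample_nodes(graph, m, k, seed):
    """Shared subsampling for both estimators: same seed, same samples.

    The modified-node sample (size ``m``) and the target set ``U`` (size
    ``k``) are drawn uniformly without replacement from all nodes. ``m`` and
    ``k`` are clipped to the number of available nodes with a warning.
    """
    n = graph.n_nodes
    if m > n:
        logger.warning("m=%d exceeds n_nodes=%d; clipping", m, n)
        m = n
    if k > n - 1:
        logger.warning("k=%d exceeds n_nodes-1=%d; clipping", k, n - 1)
        k = n - 1
    rng = np.random.default_rng(seed)
    modified = rng.choice(n, size=m, replace=False)
    targets = rng.choice(n, size=k, replace=False)
    return modified, targets


def _pairs_for(v_nodes: np.ndarray, targets: np.ndarray, direction: str):
    """Query pairs for modified nodes against U, excluding self-pairs.

    Returns the pair array and, per pair, the index of its modified node in
    ``v_nodes``.
    """
    vv = np.repeat(v_nodes, len(targets))
    uu = np.tile(targets, len(v_nodes))
    owner = np.repeat(np.arange(len(v_nodes)), len(targets))
    keep = vv != uu
    vv, uu, owner = vv[keep], uu[keep], owner[keep]
    pairs = np.column_stack([vv, uu] if direction == "as_source" else [uu, vv])
    return pairs, owner


def _finalize(feature, edges, v_nodes, per_node_sums, per_node_counts, node_bins,
              H, m, k, normalization, method, seed, fingerprint, t0) -> ALEProfile:
    # Canonical accumulation order (bin, then node id): the result is
    # bit-identical however the modified nodes were iterated.
    order = np.lexsort((v_nodes, node_bins))
    sums = np.zeros(H)
    counts = np.zeros(H, dtype=np.int64)
    for i in order:
        sums[node_bins[i]] += per_node_sums[i]
        counts[node_bins[i]] += per_node_counts[i]
    for h in range(H):
        if counts[h] == 0:
            logger.warning("bin %d received no modified nodes", h)
    return ALEProfile(
        feature_name=feature,
        bin_edges=edges,
        bin_sums=sums,
        bin_counts=counts,
        m=m,
        k=k,
        normalization=normalization,
        method=method,
        seed=seed,
        model_fingerprint=fingerprint,
        runtime_seconds=time.perf_counter() - t0,
    )


def ale_exact(
    model,
    graph: AttributedGraph,
    feature: str,
    m: int,
    k: int,
    bins: int | np.ndarray = 5,
    seed: int = 0,
    direction: str = "as_source",
    strategy: str = "quantile",
    normalization: str = "per_bin",
    modified_nodes: np.ndarray | None = None,
    target_nodes: np.ndarray | None = None,
) -> ALEProfile:
    """Exact ALE: one modified node per forward pass (2*m passes).

    For each sampled node ``v`` falling in bin ``h``, the model is evaluated
    twice — once with ``v``'s feature set to the bin's upper edge, once to
    the lower edge, all other nodes untouched — against every target in
    ``U \\ {v}``. Because a single node is modified per pass, modified nodes
    never co-occur and cannot disturb each other's predictions.
    """
    t0 = time.perf_counter()
    fi, x, edges = _resolve_bins(graph, feature, bins, strategy)
    v_nodes, targets = _sample_nodes(graph, m, k, seed)
    if modified_nodes is not None:
        v_nodes = np.asarray(modified_nodes, dtype=np.int64)
    if target_nodes is not None:
        targets = np.asarray(target_nodes, dtype=np.int64)
    H = len(edges) - 1
    node_bins = assign_bins(x[v_nodes], edges)
    per_node_sums = np.zeros(len(v_nodes))
    per_node_counts = np.zeros(len(v_nodes), dtype=np.int64)
    for i, v in enumerate(v_nodes):
        h = node_bins[i]
        pairs, _ = _pairs_for(np.array([v]), targets, direction)
        if len(pairs) == 0:
            continue
        hi = model.predict_links(pairs, overrides={int(v): {fi: edges[h + 1]}})
        lo = model.predict_links(pairs, overrides={int(v): {fi: edges[h]}})
        per_node_sums[i] = float(np.sum(hi - lo))
        per_node_counts[i] = len(pairs)
    return _finalize(feature, edges, v_nodes, per_node_sums, per_node_counts,
                     node_bins, H, len(v_nodes), len(targets), normalization,
                     "exact", seed, model_fingerprint(model), t0)


def ale_approximate(
    model,
    graph: AttributedGraph,
    feature: str,
    m: int,
    k: int,
    bins: int | np.ndarray = 5,
    seed: int = 0,
    direction: str = "as_source",
    strategy: str = "quantile",
    normalization: str = "per_bin",
    modified_nodes: np.ndarray | None = None,
    target_nodes: np.ndarray | None = None,
) -> ALEProfile:
    """Approximate ALE: all of a bin's nodes modified at once (2*H passes).

    Sampling is identical to :func:`ale_exact` for the same seed. For each
    bin, every sampled node in that bin is set to the bin edge
    simultaneously and all (v, u) pairs are scored from a single forward
    pass per bin edge (plus at most one shared clean pass when the target
    set overlaps the modified sample; targets themselves are never directly
    modified). Modified nodes lying within each other's receptive fields
    distort the predictions; this message-passing contamination is the
    quantity the exact/approximate comparison measures and is intentionally
    not corrected. With one modified node, or on a graph with no message
    passing, the estimate coincides with the exact variant.
    """
    t0 = time.perf_counter()
    fi, x, edges = _resolve_bins(graph, feature, bins, strategy)
    v_nodes, targets = _sample_nodes(graph, m, k, seed)
    if modified_nodes is not None:
        v_nodes = np.asarray(modified_nodes, dtype=np.int64)
    if target_nodes is not None:
        targets = np.asarray(target_nodes, dtype=np.int64)
    H = len(edges) - 1
    node_bins = assign_bins(x[v_nodes], edges)
    per_node_sums = np.zeros(len(v_nodes))
    per_node_counts = np.zeros(len(v_nodes), dtype=np.int64)
    use_embeddings = hasattr(model, "embed") and hasattr(model, "score_from_embeddings")
    z_clean = None  # lazily computed unmodified embeddings (shared by all bins)
    for h in range(H):
        members = np.where(node_bins == h)[0]
        if members.size == 0:
            continue
        group = v_nodes[members]
        group_set = set(int(v) for v in group)
        pairs, owner = _pairs_for(group, targets, direction)
        if len(pairs) == 0:
            continue
        vcol, ucol = (0, 1) if direction == "as_source" else (1, 0)
        # Targets are never directly modified: a target that happens to be in
        # the modified group is scored with its clean embedding, so the only
        # disturbance the simultaneous modification introduces is the
        # message-passing cross-talk between modified nodes.
        if use_embeddings:
            dst_in_group = np.fromiter(
                (int(u) in group_set for u in pairs[:, ucol]), bool, len(pairs)
            )
            if dst_in_group.any() and z_clean is None:
                z_clean = model.embed({})
            preds = []
            for edge_val in (edges[h + 1], edges[h]):
                z_mod = model.embed({int(v): {fi: float(edge_val)} for v in group})
                z_dst = z_mod[pairs[:, ucol]]
                if dst_in_group.any():
                    z_dst = np.where(dst_in_group[:, None],
                                     z_clean[pairs[:, ucol]], z_dst)
                preds.append(
                    model.score_from_embeddings(z_mod[pairs[:, vcol]], z_dst)
                )
            hi, lo = preds
        else:
            # generic pairwise scorer: emulate clean targets by removing each
            # in-group target from its own pairs' override set
            hi = np.empty(len(pairs))
            lo = np.empty(len(pairs))
            for out, edge_val in ((hi, edges[h + 1]), (lo, edges[h])):
                base = {int(v): {fi: float(edge_val)} for v in group}
                plain = np.fromiter(
                    (int(u) not in group_set for u in pairs[:, ucol]), bool, len(pairs)
                )
                if plain.any():
                    out[plain] = model.predict_links(pairs[plain], overrides=base)
                for u in sorted(group_set & {int(u) for u in pairs[:, ucol]}):
                    sel = pairs[:, ucol] == u
                    ov = {kk: vv for kk, vv in base.items() if kk != u}
                    out[sel] = model.predict_links(pairs[sel], overrides=ov)
        diff = hi - lo
        for j, mi in enumerate(members):
            sel = owner == j
            per_node_sums[mi] = float(diff[sel].sum())
            per_node_counts[mi] = int(sel.sum())
    return _finalize(feature, edges, v_nodes, per_node_sums, per_node_counts,
                     node_bins, H, len(v_nodes), len(targets), normalization,
                     "approximate", seed, model_fingerprint(model), t0)


# --------------------------------------------------------------- aggregation


def aggregate_profiles(profiles: list[ALEProfile]) -> ALEProfile:
    """Pool profiles by summing raw sums and counts (exact aggregation).

    Equivalent to the ``k_i * m_i``-weighted average of the individual
    curves in global mode, and to dividing each bin's pooled sum by the
    pooled number of predictions in per-bin mode. Requires identical bin
    edges, feature and normalization across profiles. Summation is
    sequential in input order, so regrouping (aggregating aggregates) is
    bitwise-stable.
    """
    if not profiles:
        raise IncompatibleProfilesError("no profiles to aggregate")
    first = profiles[0]
    if len(profiles) == 1:
        return first
    sums = first.bin_sums.copy()
    counts = first.bin_counts.copy()
    m_total, mk_total = int(first.m), int(first.mk_weight)
    for p in profiles[1:]:
        if p.feature_name != first.feature_name:
            raise IncompatibleProfilesError("feature names differ")
        if p.normalization != first.normalization:
            raise IncompatibleProfilesError("normalization modes differ")
        if len(p.bin_edges) != len(first.bin_edges) or not np.array_equal(
            p.bin_edges, first.bin_edges
        ):
            raise IncompatibleProfilesError("bin edges differ")
        sums = sums + p.bin_sums
        counts = counts + p.bin_counts
        m_total += int(p.m)
        mk_total += int(p.mk_weight)
    return ALEProfile(
        feature_name=first.feature_name,
        bin_edges=first.bin_edges,
        bin_sums=sums,
        bin_counts=counts,
        m=m_total,
        k=first.k,
        mk_weight=mk_total,
        normalization=first.normalization,
        method="aggregate",
        seed=first.seed,
    )


def center_profile(profile: ALEProfile) -> ALEProfile:
    """Subtract the bin-count-weighted mean of the curve (idempotent).

    Centering eases comparison of a feature's effect to its average but is
    off by default throughout the package; the uncentered convention is
    used everywhere else.
    """
    w = profile.bin_counts.astype(float)
    if w.sum() == 0:
        w = np.ones_like(w)
    offset = float(np.average(profile.values, weights=w))
    return replace(profile, center_offset=profile.center_offset + offset)
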