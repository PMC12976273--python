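"""Independent brute-force reference implementations used as test oracles.

These are deliberately literal, slow transcriptions of the estimators'
defining sums — plain nested loops, one prediction per call — kept free of
any code shared with the package's vectorized implementations.
"""

from __future__ import annotations

import numpy as np


def in_bin(x: float, lo: float, hi: float, is_first: bool) -> bool:
    """Half-open membership (lo, hi], with the minimum going to the first bin."""
    if is_first and x <= lo:
        return True
    return lo < x <= hi


def brute_force_tabular_ale(predict_row, data, feature: str, edges: np.ndarray):
    """Literal tabular ALE: accumulate mean per-bin prediction differences.

    ``predict_row`` maps a dict of feature values to a scalar prediction.
    Returns the accumulated curve at each bin's right edge.
    """
    H = len(edges) - 1
    values = []
    acc = 0.0
    for h in range(H):
        diffs = []
        for _, row in data.iterrows():
            if in_bin(row[feature], edges[h], edges[h + 1], h == 0):
                hi_row = dict(row)
                hi_row[feature] = edges[h + 1]
                lo_row = dict(row)
                lo_row[feature] = edges[h]
                diffs.append(predict_row(hi_row) - predict_row(lo_row))
        if diffs:
            acc += sum(diffs) / len(diffs)
        values.append(acc)
    return np.array(values)


def brute_force_link_ale(
    model,
    graph,
    feature_idx: int,
    edges: np.ndarray,
    v_nodes: np.ndarray,
    targets: np.ndarray,
    normalization: str = "global",
    direction: str = "as_source",
):
    """Literal link-prediction ALE: triple loop over bins, targets, nodes.

    One node is modified per prediction call (the one-at-a-time reading of
    the estimator). Returns the accumulated curve at each bin's right edge:
    global mode divides every bin's sum by m*k; per-bin mode divides by the
    number of differences the bin actually received.
    """
    x = graph.node_features[:, feature_idx]
    H = len(edges) - 1
    m, k = len(v_nodes), len(targets)
    sums = np.zeros(H)
    counts = np.zeros(H, dtype=int)
    for h in range(H):
        for u in targets:
            for v in v_nodes:
                if u == v:
                    continue
                if not in_bin(x[v], edges[h], edges[h + 1], h == 0):
                    continue
                pair = [[v, u]] if direction == "as_source" else [[u, v]]
                f_hi = model.predict_links(pair, overrides={int(v): {feature_idx: float(edges[h + 1])}})[0]
                f_lo = model.predict_links(pair, overrides={int(v): {feature_idx: float(edges[h])}})[0]
                sums[h] += f_hi - f_lo
                counts[h] += 1
    values = []
    acc = 0.0
    for h in range(H):
        if normalization == "global":
            acc += sums[h] / (m * k)
        elif counts[h] > 0:
            acc += sums[h] / counts[h]
        values.append(acc)
    return np.array(values), sums, counts


def pairwise_auroc(scores_pos, scores_neg) -> float:
    """AUROC by enumerating all positive-negative pairs."""
    wins = 0.0
    for sp in scores_pos:
        for sn in scores_neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(scores_pos) * len(scores_neg))
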