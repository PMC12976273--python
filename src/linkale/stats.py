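"""Statistical comparison of explanation curves.

Three procedures: a chi-square test adapted to comparing two groups of
arbitrary curves point by point, a permutation test whose statistic is the
RMSE between the groups' aggregated (prediction-count-weighted) profiles,
and RMSE against a reference curve such as the synthetic ground truth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .ale import ALEProfile, IncompatibleProfilesError, aggregate_profiles
from .synthetic import GroundTruthCurve


@dataclass(frozen=True)
class CurveTestResult:
    test: str
    statistic: float
    p_value: float
    alpha: float
    reject: bool
    df: int | None = None
    critical_value: float | None = None
    n_permutations: int | None = None
    seed: int | None = None
    unit_variance_fallback: bool = False

    def save(self, path: str | Path) -> None:
        d = {k: v for k, v in asdict(self).items() if v is not None}
        Path(path).write_text(json.dumps(d, indent=2))


def chi2_critical(df: int, alpha: float) -> float:
    """Upper-tail critical value of the chi-square distribution."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    return float(sps.chi2.ppf(1.0 - alpha, df))


def _check_compatible(profiles: list[ALEProfile]) -> np.ndarray:
    edges = profiles[0].bin_edges
    for p in profiles[1:]:
        if len(p.bin_edges) != len(edges) or not np.allclose(p.bin_edges, edges):
            raise IncompatibleProfilesError("profiles have different bin edges")
    return edges


def _weighted_group_stats(group: list[ALEProfile]) -> tuple[np.ndarray, np.ndarray]:
    """Per-point mean and variance of curve values, weighted by bin counts."""
    Y = np.stack([p.values for p in group])           # (n, H)
    W = np.stack([p.bin_counts for p in group]).astype(float)
    W = np.where(W.sum(axis=0) > 0, W, 1.0)           # all-empty bins: equal weights
    wsum = W.sum(axis=0)
    mean = (W * Y).sum(axis=0) / wsum
    if len(group) < 2:
        return mean, np.zeros_like(mean)
    # reliability-weighted sample variance (Bessel-corrected)
    denom = wsum - (W**2).sum(axis=0) / wsum
    denom = np.where(denom > 0, denom, np.nan)
    var = (W * (Y - mean) ** 2).sum(axis=0) / denom
    return mean, np.nan_to_num(var)


def chi2_curve_test(
    group_a: list[ALEProfile],
    group_b: list[ALEProfile],
    alpha: float = 0.05,
) -> CurveTestResult:
    """Chi-square test for the difference between two groups of curves.

    The statistic sums, over the H curve points, the squared difference of
    the group means divided by the sum of the group variances; degrees of
    freedom equal the number of points. When both groups are singletons no
    variance is estimable and a unit-variance fallback is applied (flagged
    in the result).
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    _check_compatible(list(group_a) + list(group_b))
    mean_a, var_a = _weighted_group_stats(group_a)
    mean_b, var_b = _weighted_group_stats(group_b)
    fallback = len(group_a) < 2 and len(group_b) < 2
    if fallback:
        var_a = np.ones_like(var_a)
        var_b = np.ones_like(var_b)
    denom = var_a + var_b
    num = (mean_a - mean_b) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(num == 0.0, 0.0, num / denom)
    if np.any(~np.isfinite(terms)):
        raise ValueError(
            "zero pooled variance at a curve point with non-zero difference; "
            "use more profiles per group"
        )
    stat = float(terms.sum())
    df = len(mean_a)
    crit = chi2_critical(df, alpha)
    return CurveTestResult(
        test="chi2",
        statistic=stat,
        p_value=float(sps.chi2.sf(stat, df)),
        alpha=alpha,
        reject=stat > crit,
        df=df,
        critical_value=crit,
        unit_variance_fallback=fallback,
    )


def _aggregate_values_matrix(
    sums: np.ndarray, counts: np.ndarray, normalization: str, mk: np.ndarray
) -> np.ndarray:
    """Curve values of aggregated groups, vectorized over rows."""
    if normalization == "per_bin":
        with np.errstate(invalid="ignore", divide="ignore"):
            inc = np.where(counts > 0, sums, 0.0) / np.maximum(counts, 1)
    else:
        inc = sums / mk[:, None]
    return np.cumsum(inc, axis=-1)


def permutation_test(
    group_a: list[ALEProfile],
    group_b: list[ALEProfile],
    n_permutations: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    smoothed: bool = False,
) -> CurveTestResult:
    """Permutation test on the RMSE between aggregated group profiles.

    The observed statistic is the RMSE between the two groups' aggregated
    curves (count-weighted pooling). Group labels are permuted
    ``n_permutations`` times preserving group sizes; the p-value is the
    plain proportion of permuted statistics at least as large as the
    observed one (``smoothed`` adds the +1 correction).
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    profiles = list(group_a) + list(group_b)
    if len(profiles) < 2:
        raise ValueError("need at least two profiles in total")
    _check_compatible(profiles)
    norm = profiles[0].normalization
    sums = np.stack([p.bin_sums for p in profiles])
    counts = np.stack([p.bin_counts for p in profiles]).astype(float)
    mk = np.array([p.mk_weight for p in profiles], dtype=float)
    n_a, n_tot = len(group_a), len(profiles)

    def stat_for(masks: np.ndarray) -> np.ndarray:
        # masks: (r, n_tot) 0/1 selection of group A
        inv = 1.0 - masks
        va = _aggregate_values_matrix(masks @ sums, masks @ counts, norm, masks @ mk)
        vb = _aggregate_values_matrix(inv @ sums, inv @ counts, norm, inv @ mk)
        return np.sqrt(np.mean((va - vb) ** 2, axis=-1))

    observed = float(stat_for(np.r_[np.ones(n_a), np.zeros(n_tot - n_a)][None, :])[0])
    # permute over a canonical ordering of the pooled profiles so the
    # p-value depends only on the profiles, group sizes and seed — not on
    # the order profiles were listed in
    keys = [hashlib.sha1(np.ascontiguousarray(row).tobytes()).hexdigest()
            for row in np.hstack([sums, counts, mk[:, None]])]
    canon = np.argsort(keys)
    sums, counts, mk = sums[canon], counts[canon], mk[canon]
    rng = np.random.default_rng(seed)
    masks = np.zeros((n_permutations, n_tot), dtype=float)
    for r in range(n_permutations):
        masks[r, rng.choice(n_tot, size=n_a, replace=False)] = 1.0
    perm_stats = stat_for(masks)
    ge = int(np.sum(perm_stats >= observed))
    p = (ge + 1) / (n_permutations + 1) if smoothed else ge / n_permutations
    return CurveTestResult(
        test="permutation",
        statistic=observed,
        p_value=float(p),
        alpha=alpha,
        reject=p < alpha,
        n_permutations=n_permutations,
        seed=seed,
    )


def rmse_to_reference(
    profile: ALEProfile,
    reference: "GroundTruthCurve | ALEProfile",
    align: str = "anchor",
) -> float:
    """RMSE between a profile and a reference curve on the same grid.

    Both curves are taken in the uncentered convention, anchored to zero at
    the first bin edge (``align='anchor'``, the default); ``align='mean'``
    instead subtracts each curve's own mean before comparing. A
    ``GroundTruthCurve`` reference is evaluated at the profile's bin
    right-edges; an ``ALEProfile`` reference must share the bin grid.
    """
    pv = profile.values + profile.center_offset  # uncentered curve
    if isinstance(reference, ALEProfile):
        if len(reference.bin_edges) != len(profile.bin_edges) or not np.allclose(
            reference.bin_edges, profile.bin_edges
        ):
            raise IncompatibleProfilesError("reference grid differs from profile")
        rv = reference.values + reference.center_offset
    else:
        edges = np.asarray(reference.bin_edges, float)
        right = profile.bin_edges[1:]
        if right.min() < edges.min() - 1e-12 or right.max() > edges.max() + 1e-12:
            raise IncompatibleProfilesError("profile grid outside reference support")
        anchored = reference.values - reference.values[0]
        rv = np.interp(right, edges, anchored)
    if align == "mean":
        pv = pv - pv.mean()
        rv = rv - rv.mean()
    elif align != "anchor":
        raise ValueError("align must be 'anchor' or 'mean'")
    return float(np.sqrt(np.mean((pv - rv) ** 2)))
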