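"""Temporal-pattern analysis: breakpoints, anomalies, monotonic trend,
Ward clustering, and ecological temporal classes.

Breakpoints are fitted with a global multiple-changepoint segmentation of a
mean-shift model: dynamic programming finds, for each candidate number of
breaks, the segmentation minimizing the residual sum of squares subject to a
minimum segment length of 15% of the series, and the number of breaks is
chosen by BIC.  Anomalies are years whose within-lake z-score exceeds +/-1
(strict).  Monotonic trend is a two-sided Mann-Kendall test with
tie-corrected variance and continuity correction.

Lakes are clustered on their z-scored series (Euclidean distance, Ward
linkage); clusters receive one of six base classes from their members'
indicators, and clusters sharing a base-class family and event timing are
merged into ecological temporal classes regardless of event magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "BASE_CLASSES",
    "TemporalIndicators",
    "ClusterModel",
    "detect_breakpoints",
    "detect_anomalies",
    "mann_kendall",
    "cluster_series",
    "base_class",
    "refine_classes",
    "compute_indicators",
]

BASE_CLASSES = (
    "abrupt_temporary",        # >= 1 anomalous year, no breakpoint
    "abrupt_persistent",       # >= 1 breakpoint, no anomaly
    "abrupt_mixed",            # both anomalies and breakpoints
    "monotonic_increasing",
    "monotonic_decreasing",
    "no_pattern",
)

_ABRUPT = {"abrupt_temporary", "abrupt_persistent", "abrupt_mixed"}


@dataclass
class TemporalIndicators:
    """Breakpoints, anomalies, and Mann-Kendall trend for one series.

    Year indices are 1-based positions within the series; a breakpoint year
    is the last year of the segment preceding the shift.
    """

    lake_id: str
    breakpoint_years: list[int]
    anomaly_years: list[int]
    mk_S: int
    mk_tau: float
    mk_p: float
    trend: str  # increasing | decreasing | none


@dataclass
class ClusterModel:
    k: int
    labels: dict[str, int]
    linkage_matrix: np.ndarray
    lake_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# breakpoints


def _segment_costs(x: np.ndarray) -> np.ndarray:
    """cost[i, j] = RSS of a constant fit on x[i:j+1] (inclusive ends)."""
    n = x.size
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    length = (j - i + 1).astype(float)
    s = c1[j + 1] - c1[i]
    ss = c2[j + 1] - c2[i]
    with np.errstate(invalid="ignore", divide="ignore"):
        cost = ss - s * s / length
    cost[length < 1] = np.inf
    return np.maximum(cost, 0.0)


def detect_breakpoints(
    z: np.ndarray,
    min_seg_frac: float = 0.15,
    max_breaks: int | None = None,
) -> list[int]:
    """Globally optimal mean-shift segmentation; number of breaks by BIC.

    Returns the 1-based year indices of the last year of each segment except
    the final one (empty list when zero breaks is optimal).  Segments must
    span at least ceil(min_seg_frac * n) years; with fewer than two feasible
    segments no break is testable and the list is empty.
    """
    x = np.asarray(z, dtype=float)
    n = x.size
    h = math.ceil(min_seg_frac * n)
    if n < 2 * h:
        return []
    k_cap = n // h - 1
    if max_breaks is not None:
        k_cap = min(k_cap, max_breaks)
    if k_cap < 1:
        return []

    cost = _segment_costs(x)
    # dp[k][j] = min RSS of x[0:j+1] split into k+1 segments (k breaks),
    # each of length >= h; bp[k][j] = last break index achieving it.
    dp = np.full((k_cap + 1, n), np.inf)
    bp = np.full((k_cap + 1, n), -1, dtype=int)
    dp[0] = [cost[0, j] if j + 1 >= h else np.inf for j in range(n)]
    for k in range(1, k_cap + 1):
        for j in range(n):
            if j + 1 < (k + 1) * h:
                continue
            # previous segment ends at i, new segment is x[i+1 : j+1]
            lo, hi = k * h - 1, j - h
            best, arg = np.inf, -1
            for i in range(lo, hi + 1):
                v = dp[k - 1, i] + cost[i + 1, j]
                if v < best:
                    best, arg = v, i
            dp[k, j], bp[k, j] = best, arg

    n_eff = float(n)
    best_k, best_bic = 0, np.inf
    for k in range(k_cap + 1):
        rss = dp[k, n - 1]
        if not np.isfinite(rss):
            continue
        # parameters: k+1 segment means, 1 variance, and k break positions;
        # positions are searched over the whole series, so they are charged
        # twice (MDL-style) relative to regular parameters
        bic = n_eff * math.log(max(rss, 1e-12) / n_eff) + (3 * k + 2) * math.log(n_eff)
        if bic < best_bic:
            best_k, best_bic = k, bic

    breaks: list[int] = []
    j = n - 1
    for k in range(best_k, 0, -1):
        i = bp[k, j]
        breaks.append(i + 1)  # 1-based last year of the segment ending at i
        j = i
    return sorted(breaks)


# ---------------------------------------------------------------------------
# anomalies and trend


def detect_anomalies(z: np.ndarray, thresh: float = 1.0) -> list[int]:
    """1-based years whose z-score magnitude strictly exceeds ``thresh``."""
    z = np.asarray(z, dtype=float)
    return [int(i) + 1 for i in np.flatnonzero(np.abs(z) > thresh)]


def mann_kendall(x: np.ndarray, alpha: float = 0.05) -> tuple[int, float, float, str]:
    """Mann-Kendall trend test.

    S is the sum over ordered pairs of sign(x_j - x_i); tau is the tie-
    corrected Kendall tau-b; the two-sided p-value uses the normal
    approximation with tie-corrected variance and continuity correction.
    Returns (S, tau, p, trend) where trend is set only when p < alpha.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("Mann-Kendall needs at least 4 observations")
    sgn = np.sign(x[None, :] - x[:, None])
    S = int(np.triu(sgn, 1).sum())

    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var_s = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0

    n0 = n * (n - 1) / 2.0
    nt = np.sum(ties * (ties - 1) / 2.0)
    denom = math.sqrt((n0 - nt) * n0)
    tau = S / denom if denom > 0 else 0.0

    if var_s <= 0 or S == 0:
        p = 1.0
    else:
        zstat = (S - np.sign(S)) / math.sqrt(var_s)
        p = float(2.0 * stats.norm.sf(abs(zstat)))
    if p < alpha and S > 0:
        trend = "increasing"
    elif p < alpha and S < 0:
        trend = "decreasing"
    else:
        trend = "none"
    return S, float(tau), p, trend


def compute_indicators(
    lake_id: str,
    z: np.ndarray,
    min_seg_frac: float = 0.15,
    anomaly_thresh: float = 1.0,
    max_breaks: int | None = None,
    alpha: float = 0.05,
) -> TemporalIndicators:
    """All three indicators on one z-scored series."""
    S, tau, p, trend = mann_kendall(z, alpha=alpha)
    return TemporalIndicators(
        lake_id=lake_id,
        breakpoint_years=detect_breakpoints(z, min_seg_frac, max_breaks),
        anomaly_years=detect_anomalies(z, anomaly_thresh),
        mk_S=S,
        mk_tau=tau,
        mk_p=p,
        trend=trend,
    )


# ---------------------------------------------------------------------------
# clustering and classes


def cluster_series(z_matrix: np.ndarray, lake_ids: list[str], k: int = 16) -> ClusterModel:
    """Agglomerative clustering of z-scored series (Euclidean distance,
    Ward linkage) cut at k clusters."""
    z_matrix = np.asarray(z_matrix, dtype=float)
    n = z_matrix.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of lakes ({n})")
    if len(lake_ids) != n:
        raise ValueError("lake_ids must match z_matrix rows")
    Z = linkage(z_matrix, method="ward")
    flat = fcluster(Z, t=k, criterion="maxclust")
    return ClusterModel(k=k, labels=dict(zip(lake_ids, map(int, flat))), linkage_matrix=Z,
                        lake_ids=list(lake_ids))


def base_class(ind: TemporalIndicators) -> str:
    """One of the six base temporal classes from a lake's indicators."""
    has_anom = len(ind.anomaly_years) > 0
    has_break = len(ind.breakpoint_years) > 0
    if has_anom and has_break:
        return "abrupt_mixed"
    if has_break:
        return "abrupt_persistent"
    if has_anom:
        return "abrupt_temporary"
    if ind.trend == "increasing":
        return "monotonic_increasing"
    if ind.trend == "decreasing":
        return "monotonic_decreasing"
    return "no_pattern"


def classify_cluster_profile(
    profile: np.ndarray,
    min_seg_frac: float = 0.15,
    alpha: float = 0.05,
    anomaly_thresh: float = 1.0,
) -> tuple[str, int | None]:
    """Base class of a cluster's shared temporal pattern.

    The cluster mean z-profile (average of member lakes' z-scores, NOT
    re-standardized) retains only the synchronized part of the members'
    dynamics: idiosyncratic noise averages out, so a level shift or an
    extreme year in the profile reflects an event the member lakes share.
    Structural models compete by BIC -- constant, linear trend, a single
    regime shift (the persistent-change archetype; a multi-step staircase
    on a monotone profile is trend-like, not abrupt), constant plus
    single-year impulse, and shift plus impulse -- and the winner maps onto
    the base classes: a shift is persistent change, an impulse temporary
    change, a linear profile with a significant Mann-Kendall trend is
    monotonic, a constant (or nonsignificant linear) profile is no pattern.
    Impulse candidates must also exceed the anomaly threshold in profile
    units, so a mildly extreme year in a small cluster does not overfit.

    Returns (base_class, peak_year) with peak_year the 1-based year of the
    dominant event (None for trend / no-pattern clusters).
    """
    P = np.asarray(profile, dtype=float)
    n = P.size
    logn = math.log(n)

    def bic(rss: float, df: int) -> float:
        return n * math.log(max(rss, 1e-12) / n) + df * logn

    candidates: list[tuple[float, str, int | None]] = []

    rss_const = float(np.sum((P - P.mean()) ** 2))
    candidates.append((bic(rss_const, 2), "constant", None))

    t = np.arange(n, dtype=float)
    tc = t - t.mean()
    slope = (tc @ (P - P.mean())) / (tc @ tc)
    rss_lin = float(np.sum((P - P.mean() - slope * tc) ** 2))
    candidates.append((bic(rss_lin, 3), "linear", None))

    breaks = detect_breakpoints(P, min_seg_frac=min_seg_frac, max_breaks=1)
    step_resid, rss_step, peak_break = None, np.inf, None
    if breaks:
        b = breaks[0]
        fitted = np.concatenate([np.full(b, P[:b].mean()), np.full(n - b, P[b:].mean())])
        rss_step = float(np.sum((P - fitted) ** 2))
        step_resid = P - fitted
        peak_break = b
        # event positions are searched over the whole series, so they are
        # charged twice (MDL-style) relative to regular parameters
        candidates.append((bic(rss_step, 5), "step", peak_break))

    # single-year impulse on an otherwise constant profile
    j = int(np.argmax(np.abs(P - np.median(P))))
    rest = np.delete(P, j)
    if abs(P[j] - rest.mean()) > anomaly_thresh:
        rss_imp = float(np.sum((rest - rest.mean()) ** 2))
        candidates.append((bic(rss_imp, 5), "impulse", j + 1))

    if step_resid is not None:
        ji = int(np.argmax(np.abs(step_resid)))
        if abs(step_resid[ji]) > anomaly_thresh:
            rss_mix = float(rss_step - step_resid[ji] ** 2)
            candidates.append((bic(rss_mix, 8), "step_impulse", peak_break))

    _, model, peak = min(candidates, key=lambda c: c[0])
    if model == "step":
        return "abrupt_persistent", peak
    if model == "impulse":
        return "abrupt_temporary", peak
    if model == "step_impulse":
        return "abrupt_mixed", peak
    if model == "linear":
        _, _, p, trend = mann_kendall(P, alpha=alpha)
        if trend == "increasing":
            return "monotonic_increasing", None
        if trend == "decreasing":
            return "monotonic_decreasing", None
    return "no_pattern", None


def refine_classes(
    model: ClusterModel,
    z_by_lake: dict[str, np.ndarray],
    peak_window: int = 1,
    min_seg_frac: float = 0.15,
    alpha: float = 0.05,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Merge clusters into ecological temporal classes.

    Each cluster is classified from its mean z-profile (the synchronized
    pattern its members share; see :func:`classify_cluster_profile`), with a
    peak event year for abrupt classes.  Clusters with the same base class
    whose peak years fall within ``peak_window`` years of each other are
    merged, so magnitude differences alone never split a class; abrupt
    clusters with distinct peak years stay separate.  Trend and no-pattern
    clusters merge by base class alone.

    Returns (lake -> class label, class registry table).
    """
    members: dict[int, list[str]] = {}
    for lake, c in model.labels.items():
        members.setdefault(c, []).append(lake)

    summaries = []  # (cluster, base class, peak year)
    for c, lakes in sorted(members.items()):
        profile = np.mean([z_by_lake[lk] for lk in lakes], axis=0)
        cls, peak = classify_cluster_profile(profile, min_seg_frac=min_seg_frac, alpha=alpha)
        summaries.append((c, cls, peak))

    # union-find over clusters
    parent = {c: c for c, _, _ in summaries}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, (ci, cls_i, yi) in enumerate(summaries):
        for cj, cls_j, yj in summaries[i + 1 :]:
            if cls_i != cls_j:
                continue
            if cls_i in _ABRUPT:
                if yi is not None and yj is not None and abs(yi - yj) <= peak_window:
                    parent[find(cj)] = find(ci)
            else:
                parent[find(cj)] = find(ci)

    groups: dict[int, list[tuple[int, str, int | None]]] = {}
    for c, cls, y in summaries:
        groups.setdefault(find(c), []).append((c, cls, y))

    lake_class: dict[str, str] = {}
    registry_rows = []
    for root in sorted(groups):
        clusters = groups[root]
        cls = clusters[0][1]
        peak_years = sorted({y for _, _, y in clusters if y is not None})
        if cls in _ABRUPT and peak_years:
            label = f"{cls}@y{peak_years[0]}"
        else:
            label = cls
        lakes = [lk for c, _, _ in clusters for lk in members[c]]
        for lk in lakes:
            lake_class[lk] = label
        registry_rows.append(
            {
                "class_id": label,
                "family": "abrupt" if cls in _ABRUPT else cls,
                "base_class": cls,
                "peak_years": ";".join(map(str, peak_years)),
                "n_lakes": len(lakes),
            }
        )
    registry = pd.DataFrame(registry_rows)
    return lake_class, registry
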