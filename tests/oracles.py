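"""Independent brute-force oracles for the core numerical operations.

Each oracle re-derives the operation from its definition with naive loops,
deliberately sharing no code with the implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def naive_simplex(x: np.ndarray, E: int):
    """Simplex LOO by explicit scans: for each target, find the E+1 nearest
    embedded vectors (excluding any vector overlapping the target in time),
    weight exp(-d/d_min), average their next values."""
    x = np.asarray(x, dtype=float)
    n = x.size
    vecs, targets, times = [], [], []
    for t in range(E - 1, n - 1):
        vecs.append([x[t - j] for j in range(E)])
        targets.append(x[t + 1])
        times.append(t)
    preds = []
    for i in range(len(vecs)):
        cand = []
        for j in range(len(vecs)):
            if abs(times[i] - times[j]) < E:
                continue
            d = math.sqrt(sum((a - b) ** 2 for a, b in zip(vecs[i], vecs[j])))
            cand.append((d, targets[j]))
        cand.sort(key=lambda c: c[0])
        nbrs = cand[: E + 1]
        d_min = nbrs[0][0]
        if d_min < 1e-12:
            ws = [1.0 if d < 1e-12 else 0.0 for d, _ in nbrs]
        else:
            ws = [math.exp(-d / d_min) for d, _ in nbrs]
        preds.append(sum(w * y for w, (_, y) in zip(ws, nbrs)) / sum(ws))
    preds = np.asarray(preds)
    targets = np.asarray(targets)
    rho = np.corrcoef(preds, targets)[0, 1]
    mae = float(np.mean(np.abs(preds - targets)))
    return preds, rho, mae


def naive_smap(x: np.ndarray, E: int, theta: float, ridge: float = 1e-8):
    """S-map LOO by explicit weighted least squares per target."""
    x = np.asarray(x, dtype=float)
    n = x.size
    vecs, targets, times = [], [], []
    for t in range(E - 1, n - 1):
        vecs.append([x[t - j] for j in range(E)])
        targets.append(x[t + 1])
        times.append(t)
    m = len(vecs)
    V = np.asarray(vecs)
    y = np.asarray(targets)
    preds = np.empty(m)
    for i in range(m):
        keep = [j for j in range(m) if abs(times[i] - times[j]) >= E]
        d = np.array([np.linalg.norm(V[i] - V[j]) for j in keep])
        dbar = d.mean()
        w = np.exp(-theta * d / max(dbar, 1e-12))
        X = np.column_stack([np.ones(len(keep)), V[keep]])
        W = np.diag(w)
        G = X.T @ W @ X + ridge * np.eye(E + 1)
        beta = np.linalg.solve(G, X.T @ W @ y[keep])
        preds[i] = np.concatenate([[1.0], V[i]]) @ beta
    rho = np.corrcoef(preds, y)[0, 1]
    mae = float(np.mean(np.abs(preds - y)))
    return preds, rho, mae


def mk_all_pairs(x: np.ndarray):
    """Mann-Kendall S and tau-b by explicit pair enumeration."""
    x = np.asarray(x, dtype=float)
    n = x.size
    S = 0
    for i in range(n):
        for j in range(i + 1, n):
            S += int(np.sign(x[j] - x[i]))
    concordant_possible = n * (n - 1) / 2
    # tie corrections
    _, counts = np.unique(x, return_counts=True)
    nt = sum(c * (c - 1) / 2 for c in counts if c > 1)
    denom = math.sqrt((concordant_possible - nt) * concordant_possible)
    tau = S / denom if denom > 0 else 0.0
    return S, tau


def exhaustive_breakpoints(x: np.ndarray, min_seg_frac: float = 0.15, max_breaks: int = 2):
    """Globally optimal mean-shift segmentation by enumerating every
    admissible placement of 0..max_breaks breaks, scored with the same BIC
    form (n log(RSS/n) + (3k+2) log n; positions charged twice)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    h = math.ceil(min_seg_frac * n)

    def seg_rss(a, b):  # x[a:b]
        seg = x[a:b]
        return float(np.sum((seg - seg.mean()) ** 2))

    best_bic, best_breaks = np.inf, []
    for k in range(0, max_breaks + 1):
        # breaks are last indices of segments (0-based), so segment ends
        for combo in itertools.combinations(range(n - 1), k):
            bounds = [0] + [c + 1 for c in combo] + [n]
            if any(b - a < h for a, b in zip(bounds[:-1], bounds[1:])):
                continue
            rss = sum(seg_rss(a, b) for a, b in zip(bounds[:-1], bounds[1:]))
            bic = n * math.log(max(rss, 1e-12) / n) + (3 * k + 2) * math.log(n)
            if bic < best_bic:
                best_bic, best_breaks = bic, [c + 1 for c in combo]  # 1-based years
    return sorted(best_breaks)


def ward_merge_order(points: np.ndarray):
    """Brute-force Ward agglomeration: repeatedly merge the pair of clusters
    with the smallest increase in total within-cluster sum of squares.
    Returns the sequence of merged cluster member-frozensets."""
    clusters = [frozenset([i]) for i in range(len(points))]
    merges = []

    def ss(idx):
        pts = points[list(idx)]
        return float(np.sum((pts - pts.mean(axis=0)) ** 2))

    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            merged = clusters[a] | clusters[b]
            delta = ss(merged) - ss(clusters[a]) - ss(clusters[b])
            if best is None or delta < best[0]:
                best = (delta, a, b)
        _, a, b = best
        merged = clusters[a] | clusters[b]
        merges.append(merged)
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
    return merges
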