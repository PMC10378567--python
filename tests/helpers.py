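"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (per-pixel loops, exhaustive
enumeration) and independent of the library implementations it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def boundary_oracle(mask: np.ndarray) -> set[tuple[int, int]]:
    """Foreground pixels with at least one 4-connected background neighbour."""
    h, w = mask.shape
    out = set()
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                nr, nc = r + dr, c + dc
                if not (0 <= nr < h and 0 <= nc < w) or not mask[nr, nc]:
                    out.add((r, c))
                    break
    return out


def naive_lbp(img: np.ndarray) -> np.ndarray:
    """Double-loop LBP codes, bit i = 1 when neighbour i >= centre,
    neighbours clockwise from top-right."""
    offsets = [(-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0)]
    h, w = img.shape
    out = np.zeros((h - 2, w - 2), dtype=int)
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            code = 0
            for i, (dr, dc) in enumerate(offsets):
                if img[r + dr, c + dc] >= img[r, c]:
                    code |= 1 << i
            out[r - 1, c - 1] = code
    return out


def naive_gradients(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel central differences with edge replication; returns
    (magnitude, orientation in [0, 180))."""
    img = img.astype(float)
    h, w = img.shape
    mag = np.zeros((h, w))
    ang = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            gx = img[r, min(c + 1, w - 1)] - img[r, max(c - 1, 0)]
            gy = img[min(r + 1, h - 1), c] - img[max(r - 1, 0), c]
            mag[r, c] = np.hypot(gx, gy)
            ang[r, c] = np.degrees(np.arctan2(gy, gx)) % 180.0
    return mag, ang


def best_single_stump_accuracy(x: np.ndarray, y: np.ndarray) -> float:
    """Exhaustive search over all axis-aligned threshold stumps."""
    best = 0.0
    n = len(y)
    for j in range(x.shape[1]):
        vals = np.unique(x[:, j])
        thresholds = np.concatenate([vals, (vals[:-1] + vals[1:]) / 2]) if len(vals) > 1 else vals
        for thr in thresholds:
            for sign in (1, -1):
                pred = np.where(x[:, j] > thr, sign, -sign)
                best = max(best, float((pred == y).sum()) / n)
    return best


def exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exhaustive two-sided rank-sum test over all C(N, nA) assignments.

    Returns (W of group a, two-sided p)."""
    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    na, n = len(a), len(pooled)
    w = ranks[:na].sum()
    mean_w = na * (n + 1) / 2
    dev = abs(w - mean_w)
    hits = total = 0
    for idx in combinations(range(n), na):
        total += 1
        if abs(ranks[list(idx)].sum() - mean_w) >= dev - 1e-9:
            hits += 1
    return float(w), hits / total


def hand_metrics(tp: int, tn: int, fp: int, fn: int, alpha: float = 0.1) -> dict:
    """Direct formula evaluation; undefined denominators give NaN."""

    def rate(num, den):
        return num / den if den else float("nan")

    recall = rate(tp, tp + fn)
    spec = rate(tn, tn + fp)
    prec = rate(tp, tp + fp)
    if (prec + recall) > 0:
        f1 = 2 * prec * recall / (prec + recall)
    else:
        f1 = float("nan") if np.isnan(prec) or np.isnan(recall) else 0.0
    return {
        "accuracy": rate(tp + tn, tp + tn + fp + fn),
        "recall": recall,
        "specificity": spec,
        "precision": prec,
        "f1": f1,
        "dominance": recall - spec,
        "iba": (1 + alpha * (recall - spec)) * (recall * spec),
    }
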