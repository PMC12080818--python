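"""Independent brute-force oracles.

Everything here re-derives its quantity with plain per-pixel / per-band
Python loops and scalar math, independent of the package's vectorized code
paths, so agreement is a meaningful check.
"""

from __future__ import annotations

import math

import numpy as np


def naive_reconstruct(
    values: np.ndarray,
    metric: str = "cosine",
    mode: str = "similarity",
    w0: float = 1.0,
) -> np.ndarray:
    """Per-pixel loop reconstruction oracle (scalar math throughout)."""
    p = np.pad(values, ((1, 1), (1, 1), (0, 0)), mode="symmetric")
    out = np.empty_like(values, dtype=np.float64)
    rows, cols, _ = values.shape
    for r in range(rows):
        for c in range(cols):
            x0 = p[r + 1, c + 1]
            nbrs = [p[r, c + 1], p[r + 2, c + 1], p[r + 1, c], p[r + 1, c + 2]]
            raw = []
            for xi in nbrs:
                if metric == "euclidean":
                    d = math.sqrt(float(((x0 - xi) ** 2).sum()))
                    raw.append(1.0 / (1.0 + d) if mode == "similarity" else d)
                    continue
                n0 = math.sqrt(float((x0**2).sum()))
                ni = math.sqrt(float((xi**2).sum()))
                if n0 * ni == 0.0:
                    cos = 0.0
                else:
                    cos = float(np.dot(x0, xi)) / (n0 * ni)
                cos = max(-1.0, min(1.0, cos))
                if metric == "cosine":
                    raw.append(max(cos, 0.0) if mode == "similarity" else 1.0 - cos)
                else:  # sam
                    ang = math.acos(cos)
                    raw.append(max(math.cos(ang), 0.0) if mode == "similarity" else ang)
            eta = sum(raw)
            if eta > 0:
                w = [ri / eta for ri in raw]
            else:
                w = [0.25] * 4
            acc = np.zeros_like(x0)
            for wi, xi in zip(w, nbrs):
                acc = acc + wi * xi
            out[r, c] = acc / w0
    return out


def naive_window_scores(rx: np.ndarray, ry: np.ndarray) -> np.ndarray:
    """Triple-loop (pixel, window member, band) windowed-detector oracle."""
    px = np.pad(rx, ((1, 1), (1, 1), (0, 0)), mode="symmetric")
    py = np.pad(ry, ((1, 1), (1, 1), (0, 0)), mode="symmetric")
    rows, cols, bands = rx.shape
    out = np.empty((rows, cols))
    for r in range(rows):
        for c in range(cols):
            wx = px[r : r + 3, c : c + 3, :]
            wy = py[r : r + 3, c : c + 3, :]
            x0, y0 = wx[1, 1], wy[1, 1]
            nx = math.sqrt(float((x0**2).sum()))
            ny = math.sqrt(float((y0**2).sum()))
            if nx * ny == 0.0:
                w = 0.0
            else:
                cos = max(-1.0, min(1.0, float(np.dot(x0, y0)) / (nx * ny)))
                w = math.atan(cos**2)
            total = 0.0
            for i in range(3):
                for j in range(3):
                    for b in range(bands):
                        total += float(wy[i, j, b]) ** 2 - float(wx[i, j, b]) ** 2
            out[r, c] = abs(total) * w
    return out


def pairwise_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Exhaustive Mann-Whitney pair count: P(pos > neg) + 0.5 * P(tie)."""
    s = np.asarray(scores, dtype=np.float64).ravel()
    y = np.asarray(labels).ravel() != 0
    pos, neg = s[y], s[~y]
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (pos.size * neg.size))
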