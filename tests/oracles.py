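"""Independent brute-force oracles used by the test suite.

Every function here re-derives a quantity by naive enumeration (loops,
flood fill, exhaustive threshold sweeps) so the vectorised library
implementations can be checked against a computationally independent
path.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def bf_otsu(pixels: np.ndarray, n_levels: int = 256) -> int:
    """Exhaustive search over all thresholds for the between-class
    variance maximiser (class 0 = intensities <= t)."""
    flat = pixels.ravel().astype(np.int64)
    n = flat.size
    best_t, best_v = None, -1.0
    for t in range(n_levels):
        lo = flat[flat <= t]
        hi = flat[flat > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / n, hi.size / n
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v + 1e-12:
            best_v, best_t = v, t
    return best_t


def _reflect_get(mask: np.ndarray, r: int, c: int) -> int:
    """Reflect ('symmetric') border indexing, matching scipy's
    mode='reflect'."""
    h, w = mask.shape
    if r < 0:
        r = -r - 1
    if r >= h:
        r = 2 * h - r - 1
    if c < 0:
        c = -c - 1
    if c >= w:
        c = 2 * w - c - 1
    return int(mask[r, c])


def bf_dilate(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    h, w = mask.shape
    kh, kw = footprint.shape
    oy, ox = kh // 2, kw // 2
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            v = 0
            for i in range(kh):
                for j in range(kw):
                    if footprint[i, j]:
                        v = max(v, _reflect_get(mask, r + i - oy, c + j - ox))
            out[r, c] = v
    return out


def bf_erode(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    h, w = mask.shape
    kh, kw = footprint.shape
    oy, ox = kh // 2, kw // 2
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            v = 1
            for i in range(kh):
                for j in range(kw):
                    if footprint[i, j]:
                        v = min(v, _reflect_get(mask, r + i - oy, c + j - ox))
            out[r, c] = v
    return out


def bf_label(mask: np.ndarray, connectivity: int = 8):
    """Flood-fill labeling; returns a sorted list of (area, bbox)."""
    h, w = mask.shape
    if connectivity == 8:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and not seen[r0, c0]:
                q = deque([(r0, c0)])
                seen[r0, c0] = True
                pix = []
                while q:
                    r, c = q.popleft()
                    pix.append((r, c))
                    for dr, dc in nbrs:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] \
                                and not seen[rr, cc]:
                            seen[rr, cc] = True
                            q.append((rr, cc))
                rows = [p[0] for p in pix]
                cols = [p[1] for p in pix]
                bbox = (min(rows), min(cols),
                        max(rows) - min(rows) + 1, max(cols) - min(cols) + 1)
                comps.append((len(pix), bbox))
    return sorted(comps)


def bf_cubic_kernel(x: float, a: float = -0.5) -> float:
    x = abs(x)
    if x <= 1:
        return (a + 2) * x**3 - (a + 3) * x**2 + 1
    if x < 2:
        return a * x**3 - 5 * a * x**2 + 8 * a * x - 4 * a
    return 0.0


def bf_bicubic_upscale(pixels: np.ndarray, factor: int, hi: int = 255) -> np.ndarray:
    """Direct per-output-pixel evaluation of the separable Keys kernel
    with corner-aligned coordinates and clamped edges."""
    src = pixels.astype(float)
    h, w = src.shape
    oh, ow = h * factor, w * factor
    out = np.zeros((oh, ow))

    def coord(i, n_in, n_out):
        return 0.0 if (n_out == 1 or n_in == 1) else i * (n_in - 1) / (n_out - 1)

    for r in range(oh):
        y = coord(r, h, oh)
        for c in range(ow):
            x = coord(c, w, ow)
            acc, wsum = 0.0, 0.0
            for i in range(int(np.floor(y)) - 1, int(np.floor(y)) + 3):
                wy = bf_cubic_kernel(y - i)
                for j in range(int(np.floor(x)) - 1, int(np.floor(x)) + 3):
                    wx = bf_cubic_kernel(x - j)
                    ii = min(max(i, 0), h - 1)
                    jj = min(max(j, 0), w - 1)
                    acc += wy * wx * src[ii, jj]
                    wsum += wy * wx
            out[r, c] = acc / wsum
    return np.clip(np.floor(out + 0.5), 0, hi).astype(pixels.dtype)


def bf_auc_paircount(labels: np.ndarray, scores: np.ndarray) -> float:
    """P(score_pos > score_neg) + 0.5 * P(equal) by full enumeration."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def bf_aupr_sweep(labels: np.ndarray, scores: np.ndarray) -> float:
    """Step-interpolated PR area by exhaustive threshold enumeration
    over distinct scores, descending (predict positive iff score >= t)."""
    n_pos = int((labels == 1).sum())
    area, prev_recall = 0.0, 0.0
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        precision = tp / (tp + fp)
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def bf_confusion(labels: np.ndarray, scores: np.ndarray, threshold: float):
    tp = fp = tn = fn = 0
    for y, s in zip(labels, scores):
        pred = 1 if s > threshold else 0
        if pred == 1 and y == 1:
            tp += 1
        elif pred == 1 and y == 0:
            fp += 1
        elif pred == 0 and y == 0:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn
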