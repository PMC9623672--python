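"""Independent brute-force oracles used by the test suite.

Everything here is written as plain per-pixel Python loops (or calls into a
third-party geometry library), deliberately sharing no code with the package
implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np

DIRECTIONS = ((0, 1), (1, 1), (1, 0), (1, -1))
NEIGHBORS8 = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]


def glcm_matrix(bins: np.ndarray, direction, ng: int, symmetric: bool = True) -> np.ndarray:
    """Normalized (symmetric) co-occurrence matrix by exhaustive pair listing."""
    h, w = bins.shape
    dr, dc = direction
    counts = np.zeros((ng, ng))
    for r in range(h):
        for c in range(w):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and bins[r, c] > 0 and bins[rr, cc] > 0:
                counts[bins[r, c] - 1, bins[rr, cc] - 1] += 1
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    return counts / total if total else counts


def glrlm_matrix(bins: np.ndarray, direction, ng: int, max_len: int) -> np.ndarray:
    """Run-length counts by walking every scan line pixel by pixel."""
    h, w = bins.shape
    dr, dc = direction
    counts = np.zeros((ng, max_len))
    # starting points: pixels with no predecessor along (dr, dc)
    starts = [
        (r, c)
        for r in range(h)
        for c in range(w)
        if not (0 <= r - dr < h and 0 <= c - dc < w)
    ]
    for r0, c0 in starts:
        r, c = r0, c0
        prev, length = 0, 0
        while 0 <= r < h and 0 <= c < w:
            v = int(bins[r, c])
            if v == prev:
                length += 1
            else:
                if prev > 0:
                    counts[prev - 1, length - 1] += 1
                prev, length = v, 1
            r, c = r + dr, c + dc
        if prev > 0:
            counts[prev - 1, length - 1] += 1
    return counts


def glszm_matrix(bins: np.ndarray, ng: int, n_pixels: int) -> np.ndarray:
    """Size-zone counts by explicit BFS flood fill over 8-connectivity."""
    h, w = bins.shape
    seen = np.zeros((h, w), dtype=bool)
    counts = np.zeros((ng, n_pixels))
    for r in range(h):
        for c in range(w):
            if bins[r, c] > 0 and not seen[r, c]:
                level = int(bins[r, c])
                queue, seen[r, c], size = [(r, c)], True, 0
                while queue:
                    rr, cc = queue.pop()
                    size += 1
                    for dr, dc in NEIGHBORS8:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and not seen[nr, nc] and bins[nr, nc] == level:
                            seen[nr, nc] = True
                            queue.append((nr, nc))
                counts[level - 1, size - 1] += 1
    return counts


def gldm_matrix(bins: np.ndarray, ng: int, alpha: int = 0) -> np.ndarray:
    """Dependence counts (columns = dependence size, center included)."""
    h, w = bins.shape
    counts = np.zeros((ng, 9))
    for r in range(h):
        for c in range(w):
            if bins[r, c] == 0:
                continue
            dep = 0
            for dr, dc in NEIGHBORS8:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and bins[rr, cc] > 0:
                    if abs(int(bins[rr, cc]) - int(bins[r, c])) <= alpha:
                        dep += 1
            counts[bins[r, c] - 1, dep] += 1  # column dep = size dep+1
    return counts


def ngtdm_table(bins: np.ndarray, ng: int):
    """(n_i, s_i, n_valid) by per-pixel neighbor-mean enumeration."""
    h, w = bins.shape
    n = np.zeros(ng)
    s = np.zeros(ng)
    nvp = 0
    for r in range(h):
        for c in range(w):
            if bins[r, c] == 0:
                continue
            vals = [
                int(bins[r + dr, c + dc])
                for dr, dc in NEIGHBORS8
                if 0 <= r + dr < h and 0 <= c + dc < w and bins[r + dr, c + dc] > 0
            ]
            if not vals:
                continue
            nvp += 1
            n[bins[r, c] - 1] += 1
            s[bins[r, c] - 1] += abs(int(bins[r, c]) - sum(vals) / len(vals))
    return n, s, nvp


def first_order_naive(values, bins):
    """The 18 first-order features by textbook loop formulas."""
    x = sorted(float(v) for v in values)
    n = len(x)
    mean = sum(x) / n
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n

    def pct(q):
        # numpy's linear-interpolation percentile, re-derived
        idx = (n - 1) * q / 100.0
        lo = math.floor(idx)
        hi = math.ceil(idx)
        return x[lo] + (idx - lo) * (x[hi] - x[lo])

    p10, p25, p50, p75, p90 = (pct(q) for q in (10, 25, 50, 75, 90))
    counts = {}
    for b in bins:
        counts[int(b)] = counts.get(int(b), 0) + 1
    probs = [c / n for c in counts.values()]
    robust = [v for v in x if p10 <= v <= p90]
    rmean = sum(robust) / len(robust)
    energy = sum(v * v for v in x)
    return {
        "Energy": energy,
        "TotalEnergy": energy,
        "Entropy": -sum(p * math.log2(p) for p in probs),
        "Minimum": x[0],
        "10Percentile": p10,
        "90Percentile": p90,
        "Maximum": x[-1],
        "Mean": mean,
        "Median": p50,
        "InterquartileRange": p75 - p25,
        "Range": x[-1] - x[0],
        "MeanAbsoluteDeviation": sum(abs(v - mean) for v in x) / n,
        "RobustMeanAbsoluteDeviation": sum(abs(v - rmean) for v in robust) / len(robust),
        "RootMeanSquared": math.sqrt(energy / n),
        "Skewness": m3 / m2**1.5 if m2 > 0 else 0.0,
        "Kurtosis": m4 / m2**2 if m2 > 0 else 0.0,
        "Variance": m2,
        "Uniformity": sum(p * p for p in probs),
    }


def window_stat_naive(t, mask, feature, window, min_pixels, row, col):
    """One pixel of a local feature map, recomputed from the window contents."""
    h, w = t.shape
    lo = window // 2
    rows = range(max(0, row - lo), min(h, row + window - lo))
    cols = range(max(0, col - lo), min(w, col + window - lo))
    vals = [t[r, c] for r in rows for c in cols if mask[r, c]]
    if len(vals) < max(min_pixels, 1):
        return float("nan")
    n = len(vals)
    mean = sum(vals) / n
    if feature == "mean":
        return mean
    if feature == "skewness":
        m2 = sum((v - mean) ** 2 for v in vals) / n
        if m2 <= 1e-12:
            return 0.0
        m3 = sum((v - mean) ** 3 for v in vals) / n
        return m3 / m2**1.5
    if feature == "entropy":
        counts = {}
        for v in vals:
            key = math.floor(v * 10 + 0.5)
            counts[key] = counts.get(key, 0) + 1
        return -sum((c / n) * math.log2(c / n) for c in counts.values())
    if feature == "gradient_magnitude":
        gy, gx = np.gradient(t)
        g = np.sqrt(gx**2 + gy**2)
        gvals = [g[r, c] for r in rows for c in cols if mask[r, c]]
        return sum(gvals) / len(gvals)
    raise ValueError(feature)


def symmetric_convolve_naive(x, w, axis):
    """Same-size convolution with half-sample symmetric extension, by loops."""
    x = np.asarray(x, dtype=float)
    if axis == 1:
        return symmetric_convolve_naive(x.T, w, 0).T
    n = len(w)
    c = n // 2
    rows, cols = x.shape

    def ext(i):
        # half-sample symmetric: ...x1 x0 | x0 x1... xN-1 | xN-1 xN-2...
        while not 0 <= i < rows:
            i = -1 - i if i < 0 else 2 * rows - 1 - i
        return i

    out = np.zeros_like(x)
    for i in range(rows):
        for j in range(cols):
            out[i, j] = sum(w[k] * x[ext(i + c - k), j] for k in range(n))
    return out


def random_bin_image(rng, max_side=10, max_levels=5):
    """Random small discretized ROI: levels 1..L inside a random mask."""
    h = rng.integers(2, max_side + 1)
    w = rng.integers(2, max_side + 1)
    levels = rng.integers(2, max_levels + 1)
    bins = rng.integers(1, levels + 1, size=(h, w))
    mask = rng.random((h, w)) < 0.8
    if not mask.any():
        mask[h // 2, w // 2] = True
    return np.where(mask, bins, 0).astype(np.int32), mask
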