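"""Texture matrices and their features (GLCM, GLRLM, GLSZM, GLDM, NGTDM).

Each matrix summarizes the spatial arrangement of discretized gray levels
(temperature bins) inside the ROI:

* GLCM - co-occurrence of level pairs at distance 1 along the four in-plane
  directions; symmetrized, normalized per direction, features averaged over
  directions (24 features).
* GLRLM - lengths of consecutive equal-level runs per direction, features
  averaged over the four directions (16 features).
* GLSZM - sizes of 8-connected equal-level zones, direction-free
  (16 features).
* GLDM - per-pixel count of 8-neighbors within ``alpha`` levels of the center;
  feature formulas use the dependence size j = count + 1, so the center pixel
  itself anchors column 1 (14 features).
* NGTDM - per-level sums of |level - mean of in-mask 8-neighbors|
  (5 features).

Formulas follow the standardized image-biomarker definitions.  Degenerate
ROIs (single pixel, no neighbor pairs) fall back to the single-entry matrix so
every feature stays defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .settings import DiscretizedROI

__all__ = [
    "TextureMatrix",
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "GLSZM_NAMES",
    "GLDM_NAMES",
    "NGTDM_NAMES",
    "glcm",
    "glrlm",
    "glszm",
    "gldm",
    "ngtdm",
]

_DIRECTIONS = ((0, 1), (1, 1), (1, 0), (1, -1))  # 0, 45, 90, 135 degrees
_EIGHT = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class TextureMatrix:
    """A texture matrix (or one per direction) with its normalization state."""

    kind: str
    matrices: tuple[np.ndarray, ...]  # one per direction, or a singleton
    normalized: bool

    @property
    def matrix(self) -> np.ndarray:
        """The single (or direction-averaged) matrix."""
        stacked = np.stack(self.matrices)
        return stacked[0] if len(self.matrices) == 1 else stacked.mean(axis=0)


def _plog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


# ---------------------------------------------------------------------------
# GLCM

GLCM_NAMES = (
    "Autocorrelation",
    "JointAverage",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointEnergy",
    "JointEntropy",
    "MaximumProbability",
    "MCC",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
)


def _glcm_counts(bins: np.ndarray, ng: int, dr: int, dc: int) -> np.ndarray:
    """Raw co-occurrence counts for one offset (ordered pairs, one pass)."""
    h, w = bins.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = bins[r0:r1, c0:c1]
    b = bins[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    valid = (a > 0) & (b > 0)
    counts = np.zeros((ng, ng), dtype=np.int64)
    if valid.any():
        np.add.at(counts, (a[valid] - 1, b[valid] - 1), 1)
    return counts


def _glcm_features_one(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # == py for a symmetric matrix
    mu = float(np.sum(i * px))
    sigma2 = float(np.sum((i - mu) ** 2 * px))

    k_sum = np.arange(2, 2 * ng + 1, dtype=float)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel() - 2, p.ravel())
    k_diff = np.arange(0, ng, dtype=float)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())

    autocorr = float(np.sum(p * ii * jj))
    da = float(np.sum(k_diff * p_diff))
    hxy = float(-np.sum(_plog2(p)))
    px_py = np.outer(px, px)
    valid = px_py > 0
    hxy1 = float(-np.sum(p[valid] * np.log2(px_py[valid])))
    hxy2 = float(-np.sum(_plog2(px_py)))
    hx = float(-np.sum(_plog2(px)))
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    occupied = px > 0
    if occupied.sum() > 1:
        po = p[np.ix_(occupied, occupied)]
        pxo = px[occupied]
        q = np.einsum("ik,jk->ij", po / pxo[:, None], po / pxo[None, :])
        eig = np.sort(np.linalg.eigvals(q).real)
        mcc = float(np.sqrt(max(0.0, eig[-2])))
    else:
        mcc = 1.0

    off = ii != jj
    corr = (autocorr - mu * mu) / sigma2 if sigma2 > 0 else 1.0
    return {
        "Autocorrelation": autocorr,
        "JointAverage": mu,
        "ClusterProminence": float(np.sum(p * (ii + jj - 2 * mu) ** 4)),
        "ClusterShade": float(np.sum(p * (ii + jj - 2 * mu) ** 3)),
        "ClusterTendency": float(np.sum(p * (ii + jj - 2 * mu) ** 2)),
        "Contrast": float(np.sum(p * (ii - jj) ** 2)),
        "Correlation": float(corr),
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-np.sum(_plog2(p_diff))),
        "DifferenceVariance": float(np.sum((k_diff - da) ** 2 * p_diff)),
        "Id": float(np.sum(p / (1.0 + np.abs(ii - jj)))),
        "Idm": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "Idmn": float(np.sum(p / (1.0 + (ii - jj) ** 2 / ng**2))),
        "Idn": float(np.sum(p / (1.0 + np.abs(ii - jj) / ng))),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": float(np.sum(p[off] / (ii[off] - jj[off]) ** 2)),
        "JointEnergy": float(np.sum(p**2)),
        "JointEntropy": hxy,
        "MaximumProbability": float(p.max()),
        "MCC": mcc,
        "SumAverage": float(np.sum(k_sum * p_sum)),
        "SumEntropy": float(-np.sum(_plog2(p_sum))),
        "SumSquares": float(np.sum(p * (ii - mu) ** 2)),
    }


def glcm(droi: DiscretizedROI, symmetric: bool = True) -> tuple[TextureMatrix, dict[str, float]]:
    """Gray-level co-occurrence matrix and its 24 features.

    Counts at distance 1 over the four in-plane directions; with
    ``symmetric`` each direction's matrix is P + P^T.  Each direction is
    normalized separately, features are computed per direction and averaged.
    """
    ng = droi.ng
    mats, feats = [], []
    for dr, dc in _DIRECTIONS:
        counts = _glcm_counts(droi.bins, ng, dr, dc)
        if symmetric:
            counts = counts + counts.T
        total = counts.sum()
        if total == 0:
            continue
        p = counts / total
        mats.append(p)
        feats.append(_glcm_features_one(p))
    if not feats:  # no neighbor pairs in any direction: degenerate single entry
        p = np.zeros((ng, ng))
        p[0, 0] = 1.0
        mats, feats = [p], [_glcm_features_one(p)]
    avg = {k: float(np.mean([f[k] for f in feats])) for k in GLCM_NAMES}
    return TextureMatrix("GLCM", tuple(mats), True), avg


# ---------------------------------------------------------------------------
# GLRLM

GLRLM_NAMES = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "GrayLevelVariance",
    "RunVariance",
    "RunEntropy",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)


def _lines(bins: np.ndarray, dr: int, dc: int) -> list[np.ndarray]:
    """Extract the 1-D scan lines of the array along one direction."""
    h, w = bins.shape
    if (dr, dc) == (0, 1):
        return [bins[r] for r in range(h)]
    if (dr, dc) == (1, 0):
        return [bins[:, c] for c in range(w)]
    arr = bins if (dr, dc) == (1, 1) else bins[:, ::-1]
    return [np.diagonal(arr, offset=o) for o in range(-(h - 1), w)]


def _run_lengths(line: np.ndarray) -> list[tuple[int, int]]:
    """(level, length) runs of positive levels along one scan line."""
    runs = []
    prev, length = 0, 0
    for v in line:
        v = int(v)
        if v == prev:
            length += 1
        else:
            if prev > 0:
                runs.append((prev, length))
            prev, length = v, 1
    if prev > 0:
        runs.append((prev, length))
    return runs


def _sz_features(p_counts: np.ndarray, n_pixels: int, prefix_i: str, prefix_j: str) -> dict[str, float]:
    """Shared gray-level x size feature family (runs, zones, dependencies)."""
    ns = p_counts.sum()
    i = np.arange(1, p_counts.shape[0] + 1, dtype=float)
    j = np.arange(1, p_counts.shape[1] + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    pn = p_counts / ns
    mu_i = float(np.sum(pn * ii))
    mu_j = float(np.sum(pn * jj))
    si = p_counts.sum(axis=1)
    sj = p_counts.sum(axis=0)
    return {
        f"Short{prefix_j}Emphasis": float(np.sum(p_counts / jj**2) / ns),
        f"Long{prefix_j}Emphasis": float(np.sum(p_counts * jj**2) / ns),
        "GrayLevelNonUniformity": float(np.sum(si**2) / ns),
        "GrayLevelNonUniformityNormalized": float(np.sum(si**2) / ns**2),
        f"{prefix_j}NonUniformity": float(np.sum(sj**2) / ns),
        f"{prefix_j}NonUniformityNormalized": float(np.sum(sj**2) / ns**2),
        f"{prefix_j}Percentage": float(ns / n_pixels),
        "GrayLevelVariance": float(np.sum(pn * (ii - mu_i) ** 2)),
        f"{prefix_j}Variance": float(np.sum(pn * (jj - mu_j) ** 2)),
        f"{prefix_j}Entropy": float(-np.sum(_plog2(pn))),
        f"Low{prefix_i}Emphasis": float(np.sum(p_counts / ii**2) / ns),
        f"High{prefix_i}Emphasis": float(np.sum(p_counts * ii**2) / ns),
        f"Short{prefix_j}Low{prefix_i}Emphasis": float(np.sum(p_counts / (ii**2 * jj**2)) / ns),
        f"Short{prefix_j}High{prefix_i}Emphasis": float(np.sum(p_counts * ii**2 / jj**2) / ns),
        f"Long{prefix_j}Low{prefix_i}Emphasis": float(np.sum(p_counts * jj**2 / ii**2) / ns),
        f"Long{prefix_j}High{prefix_i}Emphasis": float(np.sum(p_counts * ii**2 * jj**2) / ns),
    }


def glrlm(droi: DiscretizedROI) -> tuple[TextureMatrix, dict[str, float]]:
    """Gray-level run-length matrix (4 directions, features averaged)."""
    ng, npix = droi.ng, droi.n_pixels
    max_len = max(droi.bins.shape)
    mats, feats = [], []
    for dr, dc in _DIRECTIONS:
        counts = np.zeros((ng, max_len), dtype=np.int64)
        for line in _lines(droi.bins, dr, dc):
            for level, length in _run_lengths(line):
                counts[level - 1, length - 1] += 1
        mats.append(counts)
        f = _sz_features(counts, npix, "GrayLevelRun", "RunLength")
        feats.append(f)
    keymap = _glrlm_keymap()
    avg = {out: float(np.mean([f[src] for f in feats])) for out, src in keymap.items()}
    return TextureMatrix("GLRLM", tuple(mats), False), avg


def _glrlm_keymap() -> dict[str, str]:
    return {
        "ShortRunEmphasis": "ShortRunLengthEmphasis",
        "LongRunEmphasis": "LongRunLengthEmphasis",
        "GrayLevelNonUniformity": "GrayLevelNonUniformity",
        "GrayLevelNonUniformityNormalized": "GrayLevelNonUniformityNormalized",
        "RunLengthNonUniformity": "RunLengthNonUniformity",
        "RunLengthNonUniformityNormalized": "RunLengthNonUniformityNormalized",
        "RunPercentage": "RunLengthPercentage",
        "GrayLevelVariance": "GrayLevelVariance",
        "RunVariance": "RunLengthVariance",
        "RunEntropy": "RunLengthEntropy",
        "LowGrayLevelRunEmphasis": "LowGrayLevelRunEmphasis",
        "HighGrayLevelRunEmphasis": "HighGrayLevelRunEmphasis",
        "ShortRunLowGrayLevelEmphasis": "ShortRunLengthLowGrayLevelRunEmphasis",
        "ShortRunHighGrayLevelEmphasis": "ShortRunLengthHighGrayLevelRunEmphasis",
        "LongRunLowGrayLevelEmphasis": "LongRunLengthLowGrayLevelRunEmphasis",
        "LongRunHighGrayLevelEmphasis": "LongRunLengthHighGrayLevelRunEmphasis",
    }


# ---------------------------------------------------------------------------
# GLSZM

GLSZM_NAMES = (
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)


def glszm(droi: DiscretizedROI) -> tuple[TextureMatrix, dict[str, float]]:
    """Gray-level size-zone matrix over 8-connected equal-level zones."""
    ng, npix = droi.ng, droi.n_pixels
    counts = np.zeros((ng, npix), dtype=np.int64)
    for level in np.unique(droi.bins[droi.mask]):
        labeled, nz = ndimage.label(droi.bins == level, structure=_EIGHT)
        if nz:
            sizes = np.bincount(labeled.ravel())[1:]
            for sz in sizes:
                counts[level - 1, sz - 1] += 1
    f = _sz_features(counts, npix, "GrayLevelZone", "Zone")
    out = {
        "SmallAreaEmphasis": f["ShortZoneEmphasis"],
        "LargeAreaEmphasis": f["LongZoneEmphasis"],
        "GrayLevelNonUniformity": f["GrayLevelNonUniformity"],
        "GrayLevelNonUniformityNormalized": f["GrayLevelNonUniformityNormalized"],
        "SizeZoneNonUniformity": f["ZoneNonUniformity"],
        "SizeZoneNonUniformityNormalized": f["ZoneNonUniformityNormalized"],
        "ZonePercentage": f["ZonePercentage"],
        "GrayLevelVariance": f["GrayLevelVariance"],
        "ZoneVariance": f["ZoneVariance"],
        "ZoneEntropy": f["ZoneEntropy"],
        "LowGrayLevelZoneEmphasis": f["LowGrayLevelZoneEmphasis"],
        "HighGrayLevelZoneEmphasis": f["HighGrayLevelZoneEmphasis"],
        "SmallAreaLowGrayLevelEmphasis": f["ShortZoneLowGrayLevelZoneEmphasis"],
        "SmallAreaHighGrayLevelEmphasis": f["ShortZoneHighGrayLevelZoneEmphasis"],
        "LargeAreaLowGrayLevelEmphasis": f["LongZoneLowGrayLevelZoneEmphasis"],
        "LargeAreaHighGrayLevelEmphasis": f["LongZoneHighGrayLevelZoneEmphasis"],
    }
    return TextureMatrix("GLSZM", (counts,), False), out


# ---------------------------------------------------------------------------
# GLDM

GLDM_NAMES = (
    "SmallDependenceEmphasis",
    "LargeDependenceEmphasis",
    "GrayLevelNonUniformity",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "GrayLevelVariance",
    "DependenceVariance",
    "DependenceEntropy",
    "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)


def dependence_counts(droi: DiscretizedROI, alpha: int = 0) -> np.ndarray:
    """Per-pixel count of in-mask 8-neighbors within ``alpha`` gray levels."""
    bins = droi.bins
    mask = droi.mask
    h, w = bins.shape
    count = np.zeros((h, w), dtype=np.int64)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            r0, r1 = max(0, -dr), min(h, h - dr)
            c0, c1 = max(0, -dc), min(w, w - dc)
            a = bins[r0:r1, c0:c1]
            b = bins[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
            dep = (a > 0) & (b > 0) & (np.abs(a - b) <= alpha)
            count[r0:r1, c0:c1] += dep
    return count


def gldm(droi: DiscretizedROI, alpha: int = 0) -> tuple[TextureMatrix, dict[str, float]]:
    """Gray-level dependence matrix and its 14 features.

    Each in-mask pixel contributes at (its level, its dependence size), where
    the size is the dependent 8-neighbor count plus one for the center.
    """
    ng, npix = droi.ng, droi.n_pixels
    dep = dependence_counts(droi, alpha=alpha)
    counts = np.zeros((ng, 9), dtype=np.int64)
    levels = droi.bins[droi.mask] - 1
    sizes = dep[droi.mask]  # 0..8 neighbors -> columns 1..9 (sizes)
    np.add.at(counts, (levels, sizes), 1)
    f = _sz_features(counts, npix, "GrayLevel", "Dependence")
    out = {
        "SmallDependenceEmphasis": f["ShortDependenceEmphasis"],
        "LargeDependenceEmphasis": f["LongDependenceEmphasis"],
        "GrayLevelNonUniformity": f["GrayLevelNonUniformity"],
        "DependenceNonUniformity": f["DependenceNonUniformity"],
        "DependenceNonUniformityNormalized": f["DependenceNonUniformityNormalized"],
        "GrayLevelVariance": f["GrayLevelVariance"],
        "DependenceVariance": f["DependenceVariance"],
        "DependenceEntropy": f["DependenceEntropy"],
        "LowGrayLevelEmphasis": f["LowGrayLevelEmphasis"],
        "HighGrayLevelEmphasis": f["HighGrayLevelEmphasis"],
        "SmallDependenceLowGrayLevelEmphasis": f["ShortDependenceLowGrayLevelEmphasis"],
        "SmallDependenceHighGrayLevelEmphasis": f["ShortDependenceHighGrayLevelEmphasis"],
        "LargeDependenceLowGrayLevelEmphasis": f["LongDependenceLowGrayLevelEmphasis"],
        "LargeDependenceHighGrayLevelEmphasis": f["LongDependenceHighGrayLevelEmphasis"],
    }
    return TextureMatrix("GLDM", (counts,), False), out


# ---------------------------------------------------------------------------
# NGTDM

NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

#: epsilon guarding the Strength (and Coarseness) denominators on constant ROIs
NGTDM_EPS = 1e-16


def ngtdm_table(droi: DiscretizedROI) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-level (n_i, s_i) table and the count of valid pixels.

    s_i accumulates |i - mean of in-mask 8-neighbors| over pixels of level i;
    pixels with no in-mask neighbor are excluded from both n_i and s_i.
    """
    bins = droi.bins
    mask = droi.mask
    ksum = ndimage.correlate(np.where(mask, bins, 0).astype(float), _EIGHT, mode="constant") - np.where(mask, bins, 0)
    kcnt = ndimage.correlate(mask.astype(float), _EIGHT, mode="constant") - mask
    valid = mask & (kcnt > 0)
    ng = droi.ng
    n = np.zeros(ng, dtype=np.int64)
    s = np.zeros(ng, dtype=np.float64)
    lv = bins[valid]
    diff = np.abs(lv - ksum[valid] / kcnt[valid])
    np.add.at(n, lv - 1, 1)
    np.add.at(s, lv - 1, diff)
    return n, s, int(valid.sum())


def ngtdm(droi: DiscretizedROI) -> tuple[TextureMatrix, dict[str, float]]:
    """Neighborhood gray-tone difference features (5 features)."""
    n, s, nvp = ngtdm_table(droi)
    ng = len(n)
    if nvp == 0:
        # single isolated pixel: no neighborhood, all differences vanish
        n = np.array([droi.n_pixels], dtype=np.int64)
        s = np.zeros(1)
        nvp = droi.n_pixels
        ng = 1
    p = n / nvp
    i = np.arange(1, ng + 1, dtype=float)
    occ = n > 0
    ngp = int(occ.sum())
    io, po, so = i[occ], p[occ], s[occ]

    coarse_den = float(np.sum(p * s))
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6

    if ngp > 1:
        pij_d2 = np.sum(po[:, None] * po[None, :] * (io[:, None] - io[None, :]) ** 2)
        contrast = float(pij_d2 / (ngp * (ngp - 1)) * (s.sum() / nvp))
        bus_den = float(np.sum(np.abs(io[:, None] * po[:, None] - io[None, :] * po[None, :])))
        busyness = coarse_den / bus_den if bus_den > 0 else 0.0
        comp = np.abs(io[:, None] - io[None, :]) * (
            (po[:, None] * so[:, None] + po[None, :] * so[None, :])
            / (po[:, None] + po[None, :])
        )
        complexity = float(comp.sum() / nvp)
        strength_num = float(np.sum((po[:, None] + po[None, :]) * (io[:, None] - io[None, :]) ** 2))
        strength = strength_num / (NGTDM_EPS + s.sum())
    else:
        contrast = busyness = complexity = strength = 0.0

    table = np.stack([n.astype(float), s], axis=1)
    feats = {
        "Coarseness": float(coarseness),
        "Contrast": contrast,
        "Busyness": float(busyness),
        "Complexity": complexity,
        "Strength": float(strength),
    }
    return TextureMatrix("NGTDM", (table,), False), feats
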