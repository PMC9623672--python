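"""Local feature maps: per-pixel statistics over a sliding window in the ROI.

Each map assigns to every pixel the statistic of the in-ROI temperatures in a
window centered on it (stride 1).  With the default 10 x 10 window the window
rows and columns span offsets [-5, 4] around the center.  Pixels whose window
holds fewer than ``min_pixels`` ROI pixels are undefined (NaN).

Available statistics: ``mean``, ``skewness`` (population moment skewness, 0 on
zero-variance windows), ``gradient_magnitude`` (window average over ROI pixels
of sqrt(gx^2 + gy^2) from central differences of the degC image -- the
boundaries of isotherms) and ``entropy`` (Shannon entropy, bits, of the 0.1
degC histogram inside the window).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["FeatureMap", "local_map", "delta_map", "MAP_FEATURES"]

MAP_FEATURES = ("mean", "skewness", "gradient_magnitude", "entropy")

_VAR_TOL = 1e-12


@dataclass
class FeatureMap:
    """An H x W map of a local statistic; NaN where undefined."""

    values: np.ndarray
    feature: str
    window: int

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)


def _window_sum(x: np.ndarray, window: int) -> np.ndarray:
    return ndimage.correlate(x, np.ones((window, window)), mode="constant", cval=0.0)


def local_map(
    tmap,
    mask,
    feature: str,
    window: int = 10,
    min_pixels: int = 4,
    averaged_gradient: bool = True,
    nan_on_flat_skew: bool = False,
) -> FeatureMap:
    """Compute one local feature map over the ROI.

    ``averaged_gradient=False`` returns the raw per-pixel gradient magnitude
    (masked to the ROI) instead of the window average.  Zero-variance windows
    yield skewness 0, or NaN with ``nan_on_flat_skew``.
    """
    if feature not in MAP_FEATURES:
        raise ValueError(f"unknown feature {feature!r}; choose from {MAP_FEATURES}")
    if window < 2:
        raise ValueError("window must be at least 2")
    t = tmap.celsius if hasattr(tmap, "celsius") else np.asarray(tmap, dtype=float)
    m = mask.pixels if hasattr(mask, "pixels") else np.asarray(mask, dtype=bool)
    if t.shape != m.shape:
        raise ValueError("image and mask shapes differ")
    if window > min(t.shape):
        raise ValueError("window larger than the image")

    mf = m.astype(float)
    n = _window_sum(mf, window)
    with np.errstate(invalid="ignore", divide="ignore"):
        if feature == "mean":
            vals = _window_sum(t * mf, window) / n
        elif feature == "skewness":
            # skewness is shift-invariant: center on the ROI mean first so the
            # running-sum moments do not cancel catastrophically at ~30 degC
            tc = (t - t[m].mean()) * mf
            s1 = _window_sum(tc, window)
            s2 = _window_sum(tc**2, window)
            s3 = _window_sum(tc**3, window)
            mu = s1 / n
            m2 = s2 / n - mu**2
            m3 = s3 / n - 3 * mu * s2 / n + 2 * mu**3
            flat = m2 <= _VAR_TOL
            vals = np.where(flat, np.nan if nan_on_flat_skew else 0.0, m3 / np.maximum(m2, _VAR_TOL) ** 1.5)
        elif feature == "gradient_magnitude":
            gy, gx = np.gradient(t)
            g = np.sqrt(gx**2 + gy**2)
            if averaged_gradient:
                vals = _window_sum(g * mf, window) / n
            else:
                vals = np.where(m, g, np.nan)
                return FeatureMap(vals, feature, window)
        else:  # entropy over 0.1 degC bins within the window
            stored = np.floor(t * 10.0 + 0.5).astype(np.int64)
            vals = np.zeros_like(t, dtype=float)
            for v in np.unique(stored[m]):
                cnt = _window_sum(((stored == v) & m).astype(float), window)
                p = np.where(n > 0, cnt / np.maximum(n, 1), 0.0)
                pos = p > 0
                term = np.zeros_like(p)
                term[pos] = p[pos] * np.log2(p[pos])
                vals -= term

    vals = np.where(n >= max(min_pixels, 1), vals, np.nan)
    return FeatureMap(vals, feature, window)


def delta_map(map_pre: FeatureMap, map_post: FeatureMap) -> FeatureMap:
    """Post minus pre on the intersection of defined regions (NaN elsewhere).

    The ROIs may differ (the teat elongates after milking); disjoint defined
    regions simply yield a fully undefined map.
    """
    if map_pre.feature != map_post.feature:
        raise ValueError(
            f"feature mismatch: {map_pre.feature!r} vs {map_post.feature!r}"
        )
    if map_pre.values.shape != map_post.values.shape:
        raise ValueError("map shapes differ")
    both = map_pre.defined & map_post.defined
    vals = np.where(both, map_post.values - map_pre.values, np.nan)
    return FeatureMap(vals, map_pre.feature, map_pre.window)


def save_map_png(fmap: FeatureMap, path, cmap: str = "viridis") -> None:
    """Render a feature map to PNG with a colorbar (undefined pixels blank)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5), dpi=120)
    im = ax.imshow(fmap.values, cmap=cmap)
    ax.set_title(f"{fmap.feature} ({fmap.window}x{fmap.window} window)")
    ax.axis("off")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(str(path), bbox_inches="tight")
    plt.close(fig)


def save_map_csv(fmap: FeatureMap, path) -> None:
    np.savetxt(str(path), fmap.values, delimiter=",", fmt="%.6g")
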