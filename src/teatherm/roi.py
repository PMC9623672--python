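"""Teat segmentations: polygon traces, binary masks, and Dice agreement.

Segmentation of a teat on a thermogram is a manual trace of the outer
perimeter, closed with a straight chord where the teat meets the udder.  This
module represents those traces, rasterizes them to pixel masks (pixel-center
even-odd rule, boundary centers counted as inside), and quantifies
inter-observer agreement with the Dice similarity score plus a percentile
bootstrap confidence interval for a set of scores.

Coordinates are 0-based (row, col) with pixel centers at integer positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "PolygonROI",
    "Mask",
    "close_with_chord",
    "rasterize",
    "dice",
    "dice_summary",
    "mask_to_png",
    "mask_from_png",
]


@dataclass(frozen=True)
class PolygonROI:
    """An ordered (row, col) vertex trace of one teat outline.

    ``closed`` polygons implicitly join the last vertex back to the first.
    """

    vertices: np.ndarray  # (V, 2) float, (row, col)
    closed: bool = False
    label: str = ""

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("vertices must be a (V, 2) array of (row, col)")
        if self.closed and v.shape[0] < 3:
            raise ValueError("a closed polygon needs at least 3 vertices")
        object.__setattr__(self, "vertices", v)

    def area(self) -> float:
        """Shoelace area of the closed polygon."""
        if not self.closed:
            raise ValueError("area is defined only for closed polygons")
        r, c = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))

    def to_json_dict(self) -> dict:
        return {"label": self.label, "closed": self.closed, "vertices": self.vertices.tolist()}

    @classmethod
    def from_json_dict(cls, d: dict) -> "PolygonROI":
        return cls(np.asarray(d["vertices"], float), bool(d.get("closed", False)), d.get("label", ""))


@dataclass
class Mask:
    """Binary H x W segmentation mask."""

    pixels: np.ndarray
    label: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("mask must be 2-D")
        self.pixels = px.astype(bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area(self) -> int:
        return int(self.pixels.sum())

    def __and__(self, other: "Mask") -> "Mask":
        return Mask(self.pixels & other.pixels)


def close_with_chord(open_polyline: PolygonROI) -> PolygonROI:
    """Close an open teat trace with the straight chord between its endpoints.

    The interactive trace runs along the teat perimeter; the chord stands in
    for the tangent line drawn where the teat attaches to the udder.
    """
    if open_polyline.closed:
        raise ValueError("polyline is already closed")
    if open_polyline.vertices.shape[0] < 2:
        raise ValueError("need at least 2 vertices to close a trace")
    return replace(open_polyline, closed=True)


def _on_segment(pr, pc, r1, c1, r2, c2, tol=1e-9):
    """Boolean array: is each point (pr, pc) on segment (r1,c1)-(r2,c2)?"""
    cross = (r2 - r1) * (pc - c1) - (c2 - c1) * (pr - r1)
    seg_len2 = (r2 - r1) ** 2 + (c2 - c1) ** 2
    if seg_len2 == 0:
        return (np.abs(pr - r1) <= tol) & (np.abs(pc - c1) <= tol)
    t = ((pr - r1) * (r2 - r1) + (pc - c1) * (c2 - c1)) / seg_len2
    return (np.abs(cross) <= tol * np.sqrt(seg_len2)) & (t >= -tol) & (t <= 1 + tol)


def _points_in_polygon(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Even-odd point-in-polygon, with points on the boundary counted inside.

    Vectorized crossing-number test: a ray is cast in the +col direction and
    edge crossings counted with the half-open vertex rule.
    """
    pr, pc = points[:, 0], points[:, 1]
    inside = np.zeros(len(points), dtype=bool)
    boundary = np.zeros(len(points), dtype=bool)
    v = vertices
    n = len(v)
    for k in range(n):
        r1, c1 = v[k]
        r2, c2 = v[(k + 1) % n]
        boundary |= _on_segment(pr, pc, r1, c1, r2, c2)
        crosses = (r1 > pr) != (r2 > pr)
        if not crosses.any():
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            c_int = c1 + (pr - r1) * (c2 - c1) / (r2 - r1)
        inside ^= crosses & (pc < c_int)
    return inside | boundary


def rasterize(poly: PolygonROI, shape: tuple[int, int]) -> Mask:
    """Rasterize a closed polygon onto an H x W pixel grid.

    A pixel is foreground iff its center lies inside the polygon under the
    even-odd rule; centers exactly on the boundary count as inside.  Raises if
    the polygon misses the grid entirely or has zero area.
    """
    if not poly.closed:
        raise ValueError("polygon must be closed before rasterization")
    if poly.area() <= 0:
        raise ValueError("degenerate zero-area polygon yields an empty mask")
    h, w = shape
    v = poly.vertices
    r0 = max(int(np.floor(v[:, 0].min())), 0)
    r1 = min(int(np.ceil(v[:, 0].max())), h - 1)
    c0 = max(int(np.floor(v[:, 1].min())), 0)
    c1 = min(int(np.ceil(v[:, 1].max())), w - 1)
    mask = np.zeros((h, w), dtype=bool)
    if r1 >= r0 and c1 >= c0:
        rr, cc = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
        pts = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
        mask[r0 : r1 + 1, c0 : c1 + 1] = _points_in_polygon(pts, v).reshape(rr.shape)
    if not mask.any():
        raise ValueError("polygon rasterizes to an empty mask on this grid")
    return Mask(mask, label=poly.label)


def dice(a: Mask, b: Mask) -> float:
    """Dice similarity score 2|A∩B| / (|A| + |B|).

    1.00 is perfect overlap; 0.50 corresponds to a 50% area overlap of
    equal-area masks; disjoint masks score 0.
    """
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = a.area, b.area
    if na == 0 and nb == 0:
        raise ValueError("Dice is undefined for two empty masks")
    inter = int((a.pixels & b.pixels).sum())
    return 2.0 * inter / (na + nb)


def dice_summary(
    scores: Sequence[float],
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int | None = 0,
) -> tuple[float, float, float]:
    """Mean Dice score with a percentile bootstrap confidence interval.

    Returns ``(mean, lower, upper)`` at the requested coverage ``level``.
    Percentile bootstrap is used because observed Dice intervals are
    asymmetric near 1; results are reproducible for a fixed ``seed``.
    """
    s = np.asarray(list(scores), dtype=float)
    if s.size == 0:
        raise ValueError("no Dice scores supplied")
    if s.size < 2:
        raise ValueError("need at least 2 scores for an interval")
    if n_boot < 1000:
        raise ValueError("n_boot must be at least 1000 for a stable interval")
    rng = np.random.default_rng(seed)
    means = rng.choice(s, size=(n_boot, s.size), replace=True).mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(means, [alpha, 1.0 - alpha])
    return float(s.mean()), float(lower), float(upper)


# ---------------------------------------------------------------------------
# Mask file I/O (8-bit PNG, 0/255)


def mask_to_png(mask: Mask, path) -> None:
    import imageio.v3 as iio

    iio.imwrite(str(path), (mask.pixels.astype(np.uint8) * 255))


def mask_from_png(path, label: str = "") -> Mask:
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(str(path)))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return Mask(arr > 127, label=label)
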