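"""2-D shape descriptors of a teat mask (14 features).

Thermogram pixels carry no absolute spatial calibration, so the dimensioned
features (areas, lengths) are in pixel units; the ratio features (Sphericity,
Elongation, Eccentricity, Extent, Solidity, AspectRatio) are the ones usable
across images, being invariant to uniform scaling.

Mesh surface and perimeter come from the sub-pixel marching-squares contour of
the mask at level 0.5; axis lengths derive from the eigenvalues of the
foreground pixel-coordinate covariance (axis length = 4 * sqrt(lambda), the
full axis of the equivalent ellipse).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull
from skimage import measure
from skimage.morphology import convex_hull_image

__all__ = ["SHAPE_NAMES", "shape_features"]

SHAPE_NAMES = (
    "PixelSurface",
    "MeshSurface",
    "Perimeter",
    "PerimeterSurfaceRatio",
    "Sphericity",
    "SphericalDisproportion",
    "MaximumDiameter",
    "MajorAxisLength",
    "MinorAxisLength",
    "Elongation",
    "Eccentricity",
    "Extent",
    "Solidity",
    "AspectRatio",
)


def _contours(mask: np.ndarray) -> list[np.ndarray]:
    padded = np.pad(mask.astype(float), 1)
    return [c - 1.0 for c in measure.find_contours(padded, 0.5)]


def _shoelace(contour: np.ndarray) -> float:
    r, c = contour[:, 0], contour[:, 1]
    return 0.5 * abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))


def shape_features(mask) -> dict[str, float]:
    """The 14 shape features for one binary mask."""
    m = mask.pixels if hasattr(mask, "pixels") else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask has no shape")

    rows, cols = np.nonzero(m)
    npix = rows.size
    contours = _contours(m)
    mesh_surface = float(sum(_shoelace(c) for c in contours))
    # Crofton perimeter: unbiased on smooth outlines, unlike the staircase
    # length of the marching-squares contour
    perimeter = float(measure.perimeter_crofton(m, directions=4))

    coords = np.stack([rows, cols], axis=1).astype(float)
    if npix >= 2:
        hull_pts = coords
        if npix >= 4:
            try:
                hull_pts = coords[ConvexHull(coords).vertices]
            except Exception:  # collinear masks: qhull degenerates
                pass
        d2 = ((hull_pts[:, None, :] - hull_pts[None, :, :]) ** 2).sum(axis=2)
        max_diameter = float(np.sqrt(d2.max()))
    else:
        max_diameter = 0.0

    cov = np.cov(coords, rowvar=False, ddof=0) if npix >= 2 else np.zeros((2, 2))
    lam = np.sort(np.linalg.eigvalsh(np.atleast_2d(cov)))[::-1]
    lam = np.clip(lam, 0.0, None)
    major = 4.0 * float(np.sqrt(lam[0]))
    minor = 4.0 * float(np.sqrt(lam[1]))
    if lam[0] > 0:
        elongation = float(np.sqrt(lam[1] / lam[0]))
        eccentricity = float(np.sqrt(1.0 - lam[1] / lam[0]))
    else:
        elongation, eccentricity = 1.0, 0.0

    bbox_area = (rows.max() - rows.min() + 1) * (cols.max() - cols.min() + 1)
    hull_area = int(convex_hull_image(m).sum())

    sphericity = 2.0 * np.sqrt(np.pi * mesh_surface) / perimeter if perimeter > 0 else 1.0
    return {
        "PixelSurface": float(npix),
        "MeshSurface": mesh_surface,
        "Perimeter": perimeter,
        "PerimeterSurfaceRatio": perimeter / mesh_surface if mesh_surface > 0 else np.inf,
        "Sphericity": float(sphericity),
        "SphericalDisproportion": float(1.0 / sphericity) if sphericity > 0 else np.inf,
        "MaximumDiameter": max_diameter,
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "Elongation": elongation,
        "Eccentricity": eccentricity,
        "Extent": float(npix / bbox_area),
        "Solidity": float(npix / hull_area) if hull_area else 1.0,
        "AspectRatio": float(major / minor) if minor > 0 else np.inf,
    }
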