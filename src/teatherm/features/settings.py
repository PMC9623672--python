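"""Extraction settings and gray-level discretization.

Defaults pin the extraction exactly to the study conditions: no image
interpolation, fixed bin width of 0.1 degC, range re-segmentation off,
symmetric GLCM, no Laplacian-of-Gaussian filtering, and all wavelet sub-band
features enabled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

__all__ = ["ExtractionSettings", "DiscretizedROI", "discretize", "FEATURE_CLASSES"]

#: feature classes in output order
FEATURE_CLASSES: Tuple[str, ...] = (
    "shape",
    "firstorder",
    "glcm",
    "glrlm",
    "glszm",
    "gldm",
    "ngtdm",
)


@dataclass(frozen=True)
class ExtractionSettings:
    """Knobs of the radiomic extraction.

    bin_width
        Fixed gray-level bin width in degC (and in sub-band units for
        wavelet-filtered images).  0.1 degC matches the instrument precision,
        so on original images one bin is one stored unit.
    wavelet
        Compute the 93 intensity/texture features on each of the 8 stationary
        wavelet sub-bands (shape features are never recomputed).
    wavelet_name
        Kernel for the undecimated transform (any PyWavelets name).
    glcm_symmetric
        Symmetrize co-occurrence counts (P + P^T) before normalization.
    gldm_alpha
        Gray-level tolerance for dependence counting (0 = exact level).
    classes
        Feature classes to emit; the default is the full inventory.
    """

    bin_width: float = 0.1
    wavelet: bool = True
    wavelet_name: str = "coif1"
    glcm_symmetric: bool = True
    gldm_alpha: int = 0
    classes: Tuple[str, ...] = FEATURE_CLASSES
    interpolation: None = None  # no resampling, by design
    range_resegmentation: bool = False
    log_filter: bool = False

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        unknown = set(self.classes) - set(FEATURE_CLASSES)
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")
        if self.interpolation is not None:
            raise ValueError("image interpolation is not supported (extraction is native-grid)")
        if self.range_resegmentation:
            raise ValueError("range re-segmentation is off by design")
        if self.log_filter:
            raise ValueError("LoG filtering is disabled by design")


@dataclass(frozen=True)
class DiscretizedROI:
    """Gray-level bin indices for the in-mask pixels of one ROI.

    ``bins`` is the ROI bounding box with 0 outside the mask and bin indices
    1..Ng inside; bin 1 sits at the ROI minimum (min-anchored binning).
    ``values`` are the corresponding intensities (degC on original images) in
    row-major in-mask order, with ``positions`` their (row, col) coordinates
    inside the bounding box.
    """

    bins: np.ndarray  # (h, w) int32 crop; 0 = outside mask
    mask: np.ndarray  # (h, w) bool crop
    values: np.ndarray  # (n,) float, in-mask intensities
    bin_width: float
    offset: tuple[int, int]  # bounding-box origin in the full image

    @property
    def ng(self) -> int:
        """Highest occupied bin index (gray levels run 1..Ng)."""
        return int(self.bins.max())

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def bin_indices(self) -> np.ndarray:
        """Bin index of each in-mask pixel, aligned with ``values``."""
        return self.bins[self.mask]


def discretize(tmap, mask, settings: ExtractionSettings | None = None) -> DiscretizedROI:
    """Discretize a temperature map (or filtered image) over a mask.

    bin(x) = floor((x - min_in_mask) / bin_width) + 1.  With 0.1 degC bins on
    stored-unit images this reduces to ``stored - stored_min + 1``, so binning
    is exact and shift-invariant.  ``tmap`` may be a TemperatureMap or a plain
    float image (a wavelet sub-band).
    """
    settings = settings or ExtractionSettings()
    img = tmap.celsius if hasattr(tmap, "celsius") else np.asarray(tmap, dtype=float)
    m = mask.pixels if hasattr(mask, "pixels") else np.asarray(mask, dtype=bool)
    if img.shape != m.shape:
        raise ValueError(f"image {img.shape} and mask {m.shape} shapes differ")
    if not m.any():
        raise ValueError("empty mask: nothing to discretize")

    rows, cols = np.nonzero(m)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    crop_img = img[r0:r1, c0:c1]
    crop_m = m[r0:r1, c0:c1]

    vals = crop_img[crop_m]
    lo = vals.min()
    # nudge the quotient so that values landing a few ulp below a bin boundary
    # (0.1 degC is not exactly representable) still fall in the boundary's bin
    q = (crop_img - lo) / settings.bin_width
    idx = np.floor(q + 1e-9).astype(np.int64) + 1
    bins = np.where(crop_m, idx, 0).astype(np.int32)
    return DiscretizedROI(
        bins=bins,
        mask=crop_m.copy(),
        values=vals.astype(np.float64),
        bin_width=settings.bin_width,
        offset=(int(r0), int(c0)),
    )
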