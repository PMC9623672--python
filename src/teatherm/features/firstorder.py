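"""First-order intensity statistics of an ROI (18 features).

Computed on the raw intensities (degC on original images, sub-band units on
wavelet images); Entropy and Uniformity use the fixed-bin-width discretized
histogram.  Definitions follow the standardized image-biomarker conventions:
Variance, Skewness and Kurtosis are population moments (Kurtosis is the raw
fourth standardized moment, 3 for a Gaussian), and percentiles use linear
interpolation.
"""

from __future__ import annotations

import numpy as np

from .settings import DiscretizedROI

__all__ = ["FIRSTORDER_NAMES", "first_order"]

FIRSTORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def first_order(droi: DiscretizedROI) -> dict[str, float]:
    """The 18 first-order features for one discretized ROI."""
    x = droi.values
    if x.size == 0:
        raise ValueError("empty ROI")
    n = x.size
    mean = x.mean()
    dev = x - mean
    m2 = np.mean(dev**2)
    if m2 < (1e-12 * max(1.0, abs(mean))) ** 2:  # constant ROI up to rounding dust
        m2 = 0.0
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])

    # discretized histogram probabilities for Entropy / Uniformity
    counts = np.bincount(droi.bin_indices)[1:]
    p = counts[counts > 0] / n

    if m2 > 0:
        skew = np.mean(dev**3) / m2**1.5
        kurt = np.mean(dev**4) / m2**2
    else:
        skew, kurt = 0.0, 0.0

    robust = x[(x >= p10) & (x <= p90)]
    energy = float(np.sum(x**2))
    return {
        "Energy": energy,
        "TotalEnergy": energy,  # unit pixel area: total energy equals energy
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(dev))),
        "RobustMeanAbsoluteDeviation": float(np.mean(np.abs(robust - robust.mean()))),
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": float(skew),
        "Kurtosis": float(kurt),
        "Variance": float(m2),
        "Uniformity": float(np.sum(p**2)),
    }
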