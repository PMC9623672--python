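"""Assembly of the full named biomarker vector for one ROI.

Under default settings the vector has exactly 851 entries: 14 shape features,
93 intensity/texture features on the original temperature image
(18 first-order + 24 GLCM + 16 GLRLM + 16 GLSZM + 14 GLDM + 5 NGTDM), and the
same 93 recomputed on each of the 8 wavelet sub-bands (shape features are
geometric and are not recomputed on filtered images): 14 + 93 + 8 x 93 = 851.

Names follow ``<image>_<class>_<feature>`` with image ``original`` or
``wavelet-XXX``.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np
import pandas as pd

from .firstorder import first_order
from .settings import DiscretizedROI, ExtractionSettings, discretize
from .shape2d import shape_features
from .texture import glcm, gldm, glrlm, glszm, ngtdm
from .wavelet import SUBBAND_NAMES, wavelet_stack

__all__ = ["extract_all", "feature_names", "INTENSITY_CLASSES"]

INTENSITY_CLASSES = ("firstorder", "glcm", "glrlm", "glszm", "gldm", "ngtdm")


def _intensity_features(
    droi: DiscretizedROI, settings: ExtractionSettings, classes
) -> "OrderedDict[str, float]":
    out: "OrderedDict[str, float]" = OrderedDict()
    if "firstorder" in classes:
        for k, v in first_order(droi).items():
            out[f"firstorder_{k}"] = v
    if "glcm" in classes:
        for k, v in glcm(droi, symmetric=settings.glcm_symmetric)[1].items():
            out[f"glcm_{k}"] = v
    if "glrlm" in classes:
        for k, v in glrlm(droi)[1].items():
            out[f"glrlm_{k}"] = v
    if "glszm" in classes:
        for k, v in glszm(droi)[1].items():
            out[f"glszm_{k}"] = v
    if "gldm" in classes:
        for k, v in gldm(droi, alpha=settings.gldm_alpha)[1].items():
            out[f"gldm_{k}"] = v
    if "ngtdm" in classes:
        for k, v in ngtdm(droi)[1].items():
            out[f"ngtdm_{k}"] = v
    return out


def extract_all(tmap, mask, settings: ExtractionSettings | None = None) -> pd.Series:
    """Extract the named biomarker vector for one ROI.

    Parameters
    ----------
    tmap : TemperatureMap
        Calibrated temperature image.
    mask : Mask
        Binary ROI of the teat; must be nonempty.
    settings : ExtractionSettings, optional
        Defaults reproduce the study conditions (851 features).

    Returns
    -------
    pandas.Series
        Ordered feature name -> value; deterministic for identical inputs.
    """
    settings = settings or ExtractionSettings()
    m = mask.pixels if hasattr(mask, "pixels") else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")

    out: "OrderedDict[str, float]" = OrderedDict()
    if "shape" in settings.classes:
        for k, v in shape_features(m).items():
            out[f"original_shape_{k}"] = v

    intensity = tuple(c for c in settings.classes if c in INTENSITY_CLASSES)
    if intensity:
        droi = discretize(tmap, m, settings)
        for k, v in _intensity_features(droi, settings, intensity).items():
            out[f"original_{k}"] = v

        if settings.wavelet:
            for band, img in wavelet_stack(tmap, settings.wavelet_name).items():
                droi_b = discretize(img, m, settings)
                for k, v in _intensity_features(droi_b, settings, intensity).items():
                    out[f"wavelet-{band}_{k}"] = v

    return pd.Series(out, dtype=float)


def feature_names(settings: ExtractionSettings | None = None) -> list[str]:
    """The ordered feature-name inventory implied by the settings."""
    from .firstorder import FIRSTORDER_NAMES
    from .shape2d import SHAPE_NAMES
    from .texture import GLCM_NAMES, GLDM_NAMES, GLRLM_NAMES, GLSZM_NAMES, NGTDM_NAMES

    settings = settings or ExtractionSettings()
    per_class = {
        "firstorder": FIRSTORDER_NAMES,
        "glcm": GLCM_NAMES,
        "glrlm": GLRLM_NAMES,
        "glszm": GLSZM_NAMES,
        "gldm": GLDM_NAMES,
        "ngtdm": NGTDM_NAMES,
    }
    names: list[str] = []
    if "shape" in settings.classes:
        names += [f"original_shape_{k}" for k in SHAPE_NAMES]
    intensity = [c for c in settings.classes if c in INTENSITY_CLASSES]
    names += [f"original_{c}_{k}" for c in intensity for k in per_class[c]]
    if settings.wavelet:
        names += [
            f"wavelet-{band}_{c}_{k}"
            for band in SUBBAND_NAMES
            for c in intensity
            for k in per_class[c]
        ]
    return names
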