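"""One-level undecimated wavelet sub-bands of a temperature image.

The single thermogram slice is treated as a one-slice volume, so the filter
bank runs over three axes -- a singleton depth axis, then rows, then columns --
and emits the 8 sub-bands LLL..HHH (letter order: depth, row, column).  Each
axis applies the wavelet's decomposition filter by discrete convolution with
half-sample symmetric boundary extension and no downsampling, so every
sub-band keeps the input shape.

On the singleton depth axis the symmetric extension replicates the slice, so
the low-pass filter multiplies the image by sum(lo) (sqrt(2) for orthogonal
wavelets) and the high-pass filter, having zero sum, annihilates it: the four
depth-high-pass sub-bands are identically zero images.  They are retained --
their features are part of the fixed 851-biomarker inventory.

The default kernel is Coiflet-1 (``coif1``).
"""

from __future__ import annotations

import numpy as np
import pywt
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["SUBBAND_NAMES", "wavelet_stack", "convolve_symmetric"]

#: sub-band letter order: (depth, row, column); L = low-pass, H = high-pass
SUBBAND_NAMES = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")


def convolve_symmetric(x: np.ndarray, w: np.ndarray, axis: int) -> np.ndarray:
    """Same-size convolution along one axis with symmetric extension.

    out[i] = sum_k w[k] * x_ext[i + c - k] with center c = len(w) // 2 and
    half-sample symmetric extension (... b a | a b c ... ).
    """
    w = np.asarray(w, dtype=np.float64)
    n = len(w)
    c = n // 2
    if x.shape[axis] < n:
        raise ValueError(f"axis {axis} of length {x.shape[axis]} is shorter than the filter ({n})")
    pad = [(0, 0)] * x.ndim
    pad[axis] = (n - 1 - c, c)
    xe = np.pad(x, pad, mode="symmetric")
    win = sliding_window_view(xe, n, axis=axis)
    return np.tensordot(win, w[::-1], axes=([-1], [0]))


def wavelet_stack(tmap, wavelet_name: str = "coif1") -> dict[str, np.ndarray]:
    """The 8 undecimated sub-band images of a temperature map.

    ``tmap`` may be a TemperatureMap or a plain 2-D float image.  Raises if the
    image is smaller than the filter support along either axis.
    """
    img = tmap.celsius if hasattr(tmap, "celsius") else np.asarray(tmap, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    wav = pywt.Wavelet(wavelet_name)
    lo = np.asarray(wav.dec_lo, dtype=np.float64)
    hi = np.asarray(wav.dec_hi, dtype=np.float64)

    # row axis, then column axis
    planes = {}
    for rname, rfilt in (("L", lo), ("H", hi)):
        row_pass = convolve_symmetric(img, rfilt, axis=0)
        for cname, cfilt in (("L", lo), ("H", hi)):
            planes[rname + cname] = convolve_symmetric(row_pass, cfilt, axis=1)

    depth_gain = float(lo.sum())  # singleton axis: low-pass scales, high-pass kills
    stack = {}
    for name in SUBBAND_NAMES:
        d, rc = name[0], name[1:]
        stack[name] = planes[rc] * depth_gain if d == "L" else np.zeros_like(img)
    return stack
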