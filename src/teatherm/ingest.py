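"""Calibrated temperature images from colorized infrared thermograms.

Portable thermal cameras export a colorized JPG/PNG in which pixel color, not
pixel value, encodes skin temperature; the displayed colorbar range (min/max
degrees Celsius) travels alongside the image.  This module rebuilds the
quantitative image: a lookup table maps each colorbar color to a temperature,
every image pixel is assigned the temperature of its nearest colorbar color,
and the result is stored as unsigned integers in units of 0.1 degC
(stored = round(degC * 10)) so that downstream analysis inherits exactly the
instrument's 0.1 degC precision.  Temperature maps round-trip through
single-frame monochrome DICOM with rescale slope 0.1 so any medical-image
viewer displays degrees Celsius directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "ColorbarSpec",
    "ColorLUT",
    "TemperatureMap",
    "DEFAULT_ACQUISITION",
    "iron_colormap",
    "get_colormap",
    "build_lut",
    "convert",
    "write_dicom",
    "read_dicom",
    "discretization_steps",
    "MAX_DISTINCT_COLORS",
]

#: Capacity of a 3-channel 8-bit color space; a LUT can never exceed this.
MAX_DISTINCT_COLORS = 256 ** 3

#: Acquisition record carried by default on every TemperatureMap.  Emissivity
#: and reflected temperature are camera settings; atmosphere from the weather
#: station at acquisition.  Metadata only -- no radiometric correction is done.
DEFAULT_ACQUISITION: Mapping[str, object] = {
    "emissivity": 0.95,
    "reflected_temp_c": 20.0,
    "atmospheric_temp_c": 23.0,
    "relative_humidity_pct": 81.0,
}


def _quantize_01(t: np.ndarray | float) -> np.ndarray | float:
    """Quantize temperatures half-up to 0.1 degC."""
    return np.floor(np.asarray(t, dtype=float) * 10.0 + 0.5) / 10.0


@dataclass(frozen=True)
class ColorbarSpec:
    """A displayed colorbar: temperature range plus ordered color ramp.

    ``colors`` runs from the coldest to the hottest displayed color; list
    position is monotone in temperature even if individual colors repeat.
    """

    t_min: float
    t_max: float
    colors: np.ndarray  # (N, 3) uint8, low -> high temperature

    def __post_init__(self):
        colors = np.asarray(self.colors, dtype=np.uint8)
        if colors.ndim != 2 or colors.shape[1] != 3:
            raise ValueError("colors must be an (N, 3) array of 8-bit RGB")
        if colors.shape[0] < 2:
            raise ValueError("a colorbar needs at least 2 colors")
        if not self.t_max > self.t_min:
            raise ValueError(f"t_max ({self.t_max}) must exceed t_min ({self.t_min})")
        object.__setattr__(self, "colors", colors)


@dataclass(frozen=True)
class ColorLUT:
    """Color -> temperature lookup table at 0.1 degC precision.

    ``temps_c[k]`` is the temperature of ``colors[k]``; endpoints anchor to the
    colorbar range and interior entries are linear in list position, quantized
    half-up to 0.1 degC.
    """

    colors: np.ndarray  # (N, 3) uint8
    temps_c: np.ndarray  # (N,) float, multiples of 0.1
    t_min: float
    t_max: float

    def __len__(self) -> int:
        return self.colors.shape[0]

    @property
    def stored(self) -> np.ndarray:
        """Temperatures as stored unsigned integers (0.1 degC units)."""
        return np.floor(self.temps_c * 10.0 + 0.5).astype(np.uint16)

    @property
    def n_distinct_colors(self) -> int:
        return len(np.unique(self.colors.astype(np.uint32) @ np.array([65536, 256, 1])))

    def as_mapping(self) -> dict[tuple[int, int, int], float]:
        """Dict view; duplicate colors keep their first (coldest) entry."""
        out: dict[tuple[int, int, int], float] = {}
        for rgb, t in zip(map(tuple, self.colors.tolist()), self.temps_c):
            out.setdefault(rgb, float(t))
        return out


@dataclass
class TemperatureMap:
    """Single-channel temperature image in stored units of 0.1 degC.

    ``pixels`` holds non-negative integers with degC = stored / 10 exactly;
    ``meta`` carries the acquisition record (emissivity, reflected temperature,
    cow id, pre/post label, ...).
    """

    pixels: np.ndarray  # (H, W) uint16
    meta: dict = field(default_factory=lambda: dict(DEFAULT_ACQUISITION))

    #: stored-unit size in degC; fixed by the 0.1 degC instrument precision.
    SCALE: float = field(default=0.1, init=False, repr=False)

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty H x W array")
        if np.issubdtype(px.dtype, np.floating):
            if (px < 0).any():
                raise ValueError("stored values must be non-negative")
            px = np.floor(px + 0.5)
        self.pixels = px.astype(np.uint16)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def celsius(self) -> np.ndarray:
        """Temperatures in degC (float array, exact multiples of 0.1)."""
        return self.pixels.astype(np.float64) * self.SCALE

    @classmethod
    def from_celsius(cls, celsius: np.ndarray, meta: dict | None = None) -> "TemperatureMap":
        stored = np.floor(np.asarray(celsius, dtype=float) * 10.0 + 0.5)
        if (stored < 0).any():
            raise ValueError("temperatures below 0 degC cannot be stored as unsigned integers")
        return cls(stored.astype(np.uint16), meta=dict(meta or DEFAULT_ACQUISITION))


# ---------------------------------------------------------------------------
# Built-in colormaps


def iron_colormap(n_colors: int = 351) -> np.ndarray:
    """An iron-style ramp (black -> red -> orange -> white), monotone per channel.

    Every entry is a distinct color for ``n_colors`` up to 511, so
    nearest-color inversion is unambiguous: red saturates over the first half
    of the ramp while blue rises over the second, and green climbs linearly
    throughout.  The default 351 entries give one color per 0.1 degC step over
    a 35 degC display range.
    """
    if not 2 <= n_colors <= 511:
        raise ValueError("iron colormap supports 2..511 entries")
    x = np.linspace(0.0, 1.0, n_colors)
    r = np.floor(255 * np.minimum(1.0, 2 * x) + 0.5)
    g = np.floor(255 * x + 0.5)
    b = np.floor(255 * np.maximum(0.0, 2 * x - 1) + 0.5)
    return np.stack([r, g, b], axis=1).astype(np.uint8)


def gray_colormap(n_colors: int = 256) -> np.ndarray:
    """Plain grayscale ramp."""
    g = np.floor(np.linspace(0, 255, n_colors) + 0.5).astype(np.uint8)
    return np.stack([g, g, g], axis=1)


_BUILTIN_COLORMAPS = {"iron": iron_colormap, "gray": gray_colormap}


def get_colormap(name: str, n_colors: int | None = None) -> np.ndarray:
    """Resolve a built-in colormap name to an (N, 3) uint8 color list."""
    try:
        fn = _BUILTIN_COLORMAPS[name]
    except KeyError:
        raise ValueError(f"unknown colormap {name!r}; known: {sorted(_BUILTIN_COLORMAPS)}")
    return fn(n_colors) if n_colors is not None else fn()


def discretization_steps(t_min: float, t_max: float, precision: float = 0.1) -> int:
    """Number of distinct temperature steps the display range admits.

    A 5-40 degC range at 0.1 degC precision admits (40 - 5) / 0.1 = 350 steps,
    which bounds how many unique temperatures a converted image can contain.
    """
    if not t_max > t_min:
        raise ValueError("t_max must exceed t_min")
    return int(round((t_max - t_min) / precision))


# ---------------------------------------------------------------------------
# LUT construction and conversion


def build_lut(colorbar: ColorbarSpec) -> ColorLUT:
    """Build the color -> temperature lookup table for a colorbar.

    The first and last colors anchor to ``t_min`` and ``t_max``; interior
    colors are assigned temperatures linear in list position and quantized
    half-up to 0.1 degC.  Deterministic: the same colorbar always yields the
    same LUT.
    """
    n = colorbar.colors.shape[0]
    pos = np.arange(n, dtype=float) / (n - 1)
    temps = _quantize_01(colorbar.t_min + pos * (colorbar.t_max - colorbar.t_min))
    return ColorLUT(
        colors=colorbar.colors.copy(),
        temps_c=np.asarray(temps, dtype=float),
        t_min=colorbar.t_min,
        t_max=colorbar.t_max,
    )


def convert(image: np.ndarray, lut: ColorLUT, meta: dict | None = None) -> TemperatureMap:
    """Convert a 3-channel 8-bit colorized thermogram into a TemperatureMap.

    Each pixel receives the temperature of its nearest LUT color (unweighted
    Euclidean distance over the three channels; ties resolve to the lower LUT
    index, i.e. the colder entry).  Output pixels are stored as unsigned
    integers in 0.1 degC units, so the image holds at most ``len(lut)``
    distinct values.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an H x W x 3 color image")
    if img.dtype != np.uint8:
        if np.issubdtype(img.dtype, np.integer) and img.min() >= 0 and img.max() <= 255:
            img = img.astype(np.uint8)
        else:
            raise ValueError("image channels must be 8-bit")
    if len(lut) == 0:
        raise ValueError("empty LUT")

    flat = img.reshape(-1, 3).astype(np.float64)
    tree = cKDTree(lut.colors.astype(np.float64))
    dist, idx = tree.query(flat, k=2 if len(lut) > 1 else 1, workers=-1)
    if len(lut) > 1:
        nearest = idx[:, 0].copy()
        # enforce the documented tie-break (lower LUT index wins) where the two
        # nearest colors are equidistant; rare, so resolve exactly per pixel
        ties = np.isclose(dist[:, 0], dist[:, 1])
        if ties.any():
            cols = lut.colors.astype(np.float64)
            d2 = ((flat[ties, None, :] - cols[None, :, :]) ** 2).sum(axis=2)
            nearest[ties] = np.argmin(d2, axis=1)  # argmin takes the first = lowest index
    else:
        nearest = np.atleast_1d(idx)
    stored = lut.stored[nearest].reshape(img.shape[:2])
    return TemperatureMap(stored, meta=dict(meta or DEFAULT_ACQUISITION))


# ---------------------------------------------------------------------------
# DICOM I/O

_META_COMMENT_PREFIX = "teatherm-meta:"


def write_dicom(tmap: TemperatureMap, path) -> None:
    """Write a TemperatureMap as single-frame monochrome 16-bit DICOM.

    Rescale slope 0.1 with intercept 0 is declared so conforming viewers
    display degrees Celsius; the acquisition record is serialized to JSON in
    ImageComments.  ``read_dicom(write_dicom(x))`` is bit-exact on pixels.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    pixel_bytes = np.ascontiguousarray(tmap.pixels, dtype="<u2").tobytes()
    meta_json = json.dumps(tmap.meta, sort_keys=True)
    # content-derived instance UID: identical maps yield byte-identical files
    import hashlib

    digest = hashlib.sha256(pixel_bytes + meta_json.encode()).hexdigest()
    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    file_meta.MediaStorageSOPInstanceUID = generate_uid(entropy_srcs=[digest])
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = file_meta
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.SeriesDescription = "thermogram temperature map"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows, ds.Columns = tmap.pixels.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0  # unsigned
    ds.RescaleSlope = "0.1"
    ds.RescaleIntercept = "0"
    ds.RescaleType = "CEL"
    ds.ImageComments = _META_COMMENT_PREFIX + meta_json
    ds.PixelData = pixel_bytes
    pydicom.dcmwrite(str(path), ds, enforce_file_format=True)


def read_dicom(path) -> TemperatureMap:
    """Read a TemperatureMap written by :func:`write_dicom`.

    Any single-frame unsigned monochrome DICOM with rescale slope 0.1 (or a
    plain stored-unit image) is accepted; files lacking pixel data are
    rejected.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    if "PixelData" not in ds:
        raise ValueError(f"{path}: DICOM file has no pixel data")
    pixels = ds.pixel_array
    if pixels.ndim != 2:
        raise ValueError(f"{path}: expected a single-frame monochrome image")
    slope = float(getattr(ds, "RescaleSlope", 0.1))
    if not np.isclose(slope, 0.1):
        # stored units differ; convert through degC and re-quantize
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        return TemperatureMap.from_celsius(pixels * slope + intercept)
    meta = dict(DEFAULT_ACQUISITION)
    comment = str(getattr(ds, "ImageComments", ""))
    if comment.startswith(_META_COMMENT_PREFIX):
        try:
            meta = json.loads(comment[len(_META_COMMENT_PREFIX):])
        except json.JSONDecodeError:
            pass
    return TemperatureMap(pixels.astype(np.uint16), meta=meta)
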