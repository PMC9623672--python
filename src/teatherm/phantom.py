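"""Synthetic teat thermogram phantoms with known ground truth.

The generator stands in for parlor images: warm teat-shaped regions (rotated
superellipses with a longitudinal temperature ramp toward the apex and a
radial falloff) on a cooler background with a smooth vertical gradient.  The
analytic temperature field is quantized to 0.1 degC, rendered through a known
colorbar into a 3-channel 8-bit image, and returned together with the
ground-truth TemperatureMap, per-teat masks and boundary polygons -- so every
stage of the pipeline (color inversion, segmentation, feature extraction,
pre/post screening) can be tested without cow data.

Pre/post-milking pairs are built by applying an :class:`EffectSpec` to the
spec: a mean temperature shift, an apex-gradient change (which moves the
histogram skew), axis elongation (the post-milking teat is longer) and an
area factor.  All randomness flows from a single seed; cohort members use
spawned sub-seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .ingest import ColorbarSpec, TemperatureMap, build_lut, get_colormap
from .roi import Mask, PolygonROI

__all__ = [
    "TeatSpec",
    "PhantomSpec",
    "EffectSpec",
    "Phantom",
    "generate",
    "apply_effect",
    "generate_cohort",
    "superellipse_area",
]


@dataclass(frozen=True)
class TeatSpec:
    """Geometry and temperature model of one teat.

    The footprint is the superellipse |u/a|^p + |v/b|^p <= 1 in rotated
    coordinates (u along the teat axis, pointing to the apex).  Temperature
    falls from ``base_temp`` by ``apex_drop`` toward the apex (quadratic in the
    normalized axial position) and by ``edge_drop`` toward the rim (quadratic
    in the normalized radial position).
    """

    center: tuple[float, float]  # (row, col)
    half_length: float = 60.0  # a, px along the axis
    half_width: float = 22.0  # b, px across
    orientation_deg: float = 90.0  # axis direction, 90 = pointing down the image
    exponent: float = 2.5  # superellipse exponent (rounded apex)
    base_temp: float = 33.0  # degC at the teat base
    apex_drop: float = 1.5  # degC lost from base to apex
    edge_drop: float = 2.0  # degC lost from axis to rim
    label: str = "teat"


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic thermogram frame."""

    shape: tuple[int, int] = (480, 640)  # (rows, cols), camera resolution
    t_min: float = 5.0
    t_max: float = 40.0
    colormap: str = "iron"
    background_temp: float = 20.0
    background_gradient: float = 2.0  # degC top-to-bottom linear drift
    teats: tuple[TeatSpec, ...] = field(
        default_factory=lambda: (
            TeatSpec(center=(240.0, 250.0), label="left hind teat"),
            TeatSpec(center=(240.0, 390.0), label="right hind teat"),
        )
    )
    noise_sigma: float = 0.3  # degC Gaussian pixel noise
    impulse_fraction: float = 0.0  # salt-and-pepper fraction

    def __post_init__(self):
        if not self.t_max > self.t_min:
            raise ValueError("t_max must exceed t_min")
        if not 0 <= self.impulse_fraction < 0.1:
            raise ValueError("impulse_fraction must be in [0, 0.1)")
        h, w = self.shape
        for t in self.teats:
            r, c = t.center
            reach = max(t.half_length, t.half_width)
            if not (0 <= r - reach and r + reach < h and 0 <= c - reach and c + reach < w):
                raise ValueError(f"teat {t.label!r} extends outside the frame")
            if not (self.t_min <= t.base_temp - t.apex_drop - t.edge_drop and t.base_temp <= self.t_max):
                raise ValueError(f"teat {t.label!r} temperatures leave the colorbar range")

    def n_colors(self) -> int:
        """One color per 0.1 degC step, so color inversion is lossless."""
        return int(round((self.t_max - self.t_min) / 0.1)) + 1

    def colorbar(self) -> ColorbarSpec:
        return ColorbarSpec(self.t_min, self.t_max, get_colormap(self.colormap, self.n_colors()))


@dataclass(frozen=True)
class EffectSpec:
    """Milking effect applied to a phantom to produce the post condition.

    ``d_mean`` shifts the whole teat temperature (degC); the apex-gradient
    factor scales the base-to-apex drop, which is also what changes the
    histogram skewness direction; elongation and area factors rescale the teat
    geometry (elongation acts on the major axis only).
    """

    d_mean: float = 0.0
    apex_gradient_factor: float = 1.0
    elongation_factor: float = 1.0
    area_factor: float = 1.0

    def __post_init__(self):
        if self.elongation_factor <= 0 or self.area_factor <= 0:
            raise ValueError("geometry factors must be positive")

    @property
    def is_identity(self) -> bool:
        return (
            self.d_mean == 0.0
            and self.apex_gradient_factor == 1.0
            and self.elongation_factor == 1.0
            and self.area_factor == 1.0
        )


@dataclass
class Phantom:
    """One generated frame: colorized image plus full ground truth."""

    image: np.ndarray  # (H, W, 3) uint8
    tmap: TemperatureMap  # ground-truth temperatures
    masks: list[Mask]  # one per teat
    polygons: list[PolygonROI]  # closed boundary traces, one per teat
    spec: PhantomSpec


def superellipse_area(a: float, b: float, p: float) -> float:
    """Analytic area of |u/a|^p + |v/b|^p <= 1."""
    return 4.0 * a * b * math.gamma(1 + 1 / p) ** 2 / math.gamma(1 + 2 / p)


def _teat_fields(teat: TeatSpec, shape: tuple[int, int]):
    """(inside, axial in [0,1] toward apex, radial in [0,1]) over the frame."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    th = math.radians(teat.orientation_deg)
    dr = rr - teat.center[0]
    dc = cc - teat.center[1]
    u = dr * math.sin(th) + dc * math.cos(th)  # along axis, + toward apex
    v = -dr * math.cos(th) + dc * math.sin(th)
    s = (np.abs(u / teat.half_length)) ** teat.exponent + (np.abs(v / teat.half_width)) ** teat.exponent
    inside = s <= 1.0
    axial = np.clip((u / teat.half_length + 1.0) / 2.0, 0.0, 1.0)
    radial = np.clip(np.abs(v / teat.half_width), 0.0, 1.0)
    return inside, axial, radial


def _teat_boundary(teat: TeatSpec, n_points: int = 64) -> np.ndarray:
    """(row, col) boundary trace of the superellipse footprint."""
    th = math.radians(teat.orientation_deg)
    t = np.linspace(0.0, 2 * np.pi, n_points, endpoint=False)
    e = 2.0 / teat.exponent
    u = teat.half_length * np.sign(np.cos(t)) * np.abs(np.cos(t)) ** e
    v = teat.half_width * np.sign(np.sin(t)) * np.abs(np.sin(t)) ** e
    rows = teat.center[0] + u * math.sin(th) - v * math.cos(th)
    cols = teat.center[1] + u * math.cos(th) + v * math.sin(th)
    return np.stack([rows, cols], axis=1)


def render(tmap: TemperatureMap, colorbar: ColorbarSpec) -> np.ndarray:
    """Render a temperature map through a colorbar into an 8-bit color image.

    Each temperature maps to the colorbar entry nearest to it in temperature.
    With one color per 0.1 degC step this is the exact inverse of LUT-based
    conversion.
    """
    lut = build_lut(colorbar)
    t = tmap.celsius
    n = len(lut)
    idx = np.clip(
        np.floor((t - colorbar.t_min) / (colorbar.t_max - colorbar.t_min) * (n - 1) + 0.5),
        0,
        n - 1,
    ).astype(np.intp)
    return lut.colors[idx]


def generate(spec: PhantomSpec, seed: int | None = 0) -> Phantom:
    """Generate one phantom frame (reproducible per seed)."""
    rng = np.random.default_rng(seed)
    h, w = spec.shape
    rows = np.arange(h, dtype=float)[:, None]
    field_t = np.full((h, w), spec.background_temp, dtype=float)
    field_t -= spec.background_gradient * (rows / max(h - 1, 1) - 0.5)

    masks, polygons = [], []
    for teat in spec.teats:
        inside, axial, radial = _teat_fields(teat, spec.shape)
        t_teat = teat.base_temp - teat.apex_drop * axial**2 - teat.edge_drop * radial**2
        field_t = np.where(inside, t_teat, field_t)
        masks.append(Mask(inside, label=teat.label))
        polygons.append(PolygonROI(_teat_boundary(teat), closed=True, label=teat.label))

    for a, b in ((0, 1),) if len(masks) > 1 else ():
        if (masks[a].pixels & masks[b].pixels).any():
            raise ValueError("teats overlap")

    if spec.noise_sigma > 0:
        field_t = field_t + rng.normal(0.0, spec.noise_sigma, size=field_t.shape)
    if spec.impulse_fraction > 0:
        hit = rng.random(field_t.shape) < spec.impulse_fraction
        salt = rng.random(field_t.shape) < 0.5
        field_t = np.where(hit, np.where(salt, spec.t_max, spec.t_min), field_t)

    field_t = np.clip(field_t, spec.t_min, spec.t_max)
    tmap = TemperatureMap.from_celsius(field_t)
    image = render(tmap, spec.colorbar())
    return Phantom(image=image, tmap=tmap, masks=masks, polygons=polygons, spec=spec)


def apply_effect(spec: PhantomSpec, effect: EffectSpec) -> PhantomSpec:
    """Derive the post-milking spec; the identity effect returns an equal spec."""
    if effect.is_identity:
        return spec
    scale = math.sqrt(effect.area_factor)
    teats = []
    for t in spec.teats:
        new = replace(
            t,
            base_temp=t.base_temp + effect.d_mean,
            apex_drop=t.apex_drop * effect.apex_gradient_factor,
            half_length=t.half_length * effect.elongation_factor * scale,
            half_width=t.half_width * scale,
        )
        teats.append(new)
    return replace(spec, teats=tuple(teats))  # __post_init__ revalidates range/frame


def _single_teat_spec(base: PhantomSpec, teat: TeatSpec) -> PhantomSpec:
    return replace(base, teats=(teat,))


def generate_cohort(
    n_teats: int,
    spec: PhantomSpec | None = None,
    effect: EffectSpec | None = None,
    seed: int | None = 0,
    geometry_jitter: float = 0.1,
    base_temp_jitter: float = 0.5,
) -> list[dict]:
    """Generate a paired pre/post cohort of independent teat instances.

    Each record holds one teat rendered in its own frame before and after the
    effect: ``{"key", "pre": Phantom, "post": Phantom}``.  Per-teat jitter
    (relative geometry, absolute base-temperature in degC) emulates biological
    variation between teats; the default cohort size in the study design is 36
    teats from 18 cows.
    """
    if n_teats < 2:
        raise ValueError("a cohort needs at least 2 teats")
    spec = spec or PhantomSpec()
    effect = effect or EffectSpec()
    template = spec.teats[0]
    ss = np.random.SeedSequence(seed)
    records = []
    for k, child in enumerate(ss.spawn(n_teats)):
        rng = np.random.default_rng(child)
        g = 1.0 + rng.uniform(-geometry_jitter, geometry_jitter, size=2)
        teat = replace(
            template,
            half_length=template.half_length * g[0],
            half_width=template.half_width * g[1],
            base_temp=template.base_temp + rng.normal(0.0, base_temp_jitter),
            label=f"teat-{k:03d}",
        )
        pre_spec = _single_teat_spec(spec, teat)
        post_spec = apply_effect(pre_spec, effect)
        noise_seeds = rng.integers(0, 2**31 - 1, size=2)
        records.append(
            {
                "key": f"teat-{k:03d}",
                "pre": generate(pre_spec, seed=int(noise_seeds[0])),
                "post": generate(post_spec, seed=int(noise_seeds[1])),
            }
        )
    return records
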