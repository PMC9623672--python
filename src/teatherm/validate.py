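"""Cohort-level validation harnesses: screening power and false-expression rate.

These run the full pipeline path -- phantom rendering, colorized-to-temperature
conversion, feature extraction, expression screening -- over many simulated
pre/post cohorts, at a reduced frame size so hundreds of cohorts stay cheap.
They quantify what the screen can and cannot detect under the study design
(36 teats, +2 degC mean shift, 0.3 degC pixel noise, P < 0.01 and |d| > 1.2).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .delta import expression_screen
from .features import ExtractionSettings, extract_all
from .ingest import build_lut, convert
from .phantom import EffectSpec, PhantomSpec, TeatSpec, generate_cohort

__all__ = ["small_frame_spec", "cohort_feature_tables", "screening_rates"]


def small_frame_spec(frame: tuple[int, int] = (96, 128), noise_sigma: float = 0.3) -> PhantomSpec:
    """A single-teat phantom spec in a reduced frame for simulation studies."""
    rows, cols = frame
    scale = min(rows / 480.0, cols / 640.0)
    teat = TeatSpec(
        center=(rows / 2.0, cols / 2.0),
        half_length=60.0 * scale,
        half_width=22.0 * scale,
    )
    return PhantomSpec(shape=frame, teats=(teat,), noise_sigma=noise_sigma)


def cohort_feature_tables(
    n_teats: int,
    effect: EffectSpec,
    seed: int,
    spec: PhantomSpec | None = None,
    settings: ExtractionSettings | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one paired cohort and run it through convert + extract.

    Every teat's colorized pre/post images are converted back to temperature
    maps through the colorbar LUT (the same path real images take) before
    extraction.  Returns (pre, post) feature tables indexed by teat key.
    """
    spec = spec or small_frame_spec()
    settings = settings or ExtractionSettings(classes=("firstorder",), wavelet=False)
    lut = build_lut(spec.colorbar())
    rows_pre, rows_post, keys = [], [], []
    for rec in generate_cohort(n_teats, spec, effect, seed=seed):
        keys.append(rec["key"])
        for cond, sink in (("pre", rows_pre), ("post", rows_post)):
            ph = rec[cond]
            tmap = convert(ph.image, lut)
            sink.append(extract_all(tmap, ph.masks[0], settings))
    return (
        pd.DataFrame(rows_pre, index=keys),
        pd.DataFrame(rows_post, index=keys),
    )


def screening_rates(
    n_cohorts: int,
    n_teats: int,
    effect: EffectSpec,
    seed: int,
    p_thresh: float = 0.01,
    d_thresh: float = 1.2,
    spec: PhantomSpec | None = None,
    settings: ExtractionSettings | None = None,
) -> pd.DataFrame:
    """Per-feature expression rate across repeated simulated cohorts.

    With an injected effect this estimates detection power; with the identity
    effect it estimates the false-expression (type-I) rate per feature.
    Returns a feature-indexed frame with columns ``expressed`` (rate in [0,1])
    and ``n_cohorts``.
    """
    if n_cohorts < 1:
        raise ValueError("need at least one cohort")
    ss = np.random.SeedSequence(seed)
    flags = []
    for child in ss.spawn(n_cohorts):
        sub = int(child.generate_state(1)[0] % (2**31 - 1))
        pre, post = cohort_feature_tables(n_teats, effect, sub, spec=spec, settings=settings)
        res = expression_screen(pre, post, p_thresh=p_thresh, d_thresh=d_thresh)
        flags.append(res.table["expressed"])
    rate = pd.concat(flags, axis=1).mean(axis=1)
    out = rate.to_frame("expressed")
    out["n_cohorts"] = n_cohorts
    return out
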