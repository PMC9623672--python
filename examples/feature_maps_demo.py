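"""Local feature maps of a teat before and after milking, as image overlays.

Builds a paired phantom, computes 10 x 10-pixel sliding-window maps of the
mean temperature and its gradient magnitude, and reports the pre/post delta
over the teat.  PNG renderings are written next to this script.
"""

from pathlib import Path

import numpy as np

from teatherm import EffectSpec, PhantomSpec, TeatSpec, apply_effect, delta_map, generate, local_map
from teatherm.maps import save_map_png

spec = PhantomSpec(
    shape=(240, 320),
    teats=(TeatSpec(center=(120.0, 160.0), half_length=55.0, half_width=20.0),),
)
post_spec = apply_effect(spec, EffectSpec(d_mean=2.0, apex_gradient_factor=0.5))

pre = generate(spec, seed=3)
post = generate(post_spec, seed=4)

for feature in ("mean", "gradient_magnitude"):
    m_pre = local_map(pre.tmap, pre.masks[0], feature, window=10)
    m_post = local_map(post.tmap, post.masks[0], feature, window=10)
    d = delta_map(m_pre, m_post)
    print(
        f"{feature}: pre median {np.nanmedian(m_pre.values):.2f}, "
        f"post median {np.nanmedian(m_post.values):.2f}, "
        f"median delta {np.nanmedian(d.values):+.2f}"
    )
    out = Path(__file__).parent / f"map_{feature}_delta.png"
    save_map_png(d, out)
    print(f"  wrote {out.name}")
# The mean map shifts by ~+2 degC; gradient changes concentrate at the apex,
# where the post-milking axial profile is flatter.
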