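"""Convert a colorized thermogram to temperatures and extract its biomarkers.

Generates a synthetic two-teat thermogram (so the example is self-contained),
inverts the colorbar back to calibrated temperatures, and extracts the full
851-feature radiomic vector for the left teat.
"""

import numpy as np

from teatherm import PhantomSpec, build_lut, convert, extract_all, generate

spec = PhantomSpec()  # 640 x 480 frame, colorbar 5-40 degC, two teats
phantom = generate(spec, seed=7)

lut = build_lut(spec.colorbar())
tmap = convert(phantom.image, lut)
err = np.abs(tmap.celsius - phantom.tmap.celsius).max()
print(f"color->temperature inversion: max error {err:.3f} degC")

features = extract_all(tmap, phantom.masks[0])
print(f"extracted {len(features)} named biomarkers for {phantom.masks[0].label!r}")
for name in (
    "original_firstorder_Mean",
    "original_firstorder_90Percentile",
    "original_shape_Elongation",
    "original_glcm_SumAverage",
    "original_ngtdm_Strength",
):
    print(f"  {name:40s} {features[name]:10.4f}")
# Mean/percentiles are in degC; Elongation is the minor/major axis ratio;
# texture values are in discretized gray-level units (0.1 degC bins).
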