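import numpy as np
import pytest

from teatherm import PhantomSpec, TeatSpec, generate
from teatherm.features import DiscretizedROI


@pytest.fixture(scope="session")
def small_spec():
    """A quiet single-teat phantom in a small frame (fast to extract)."""
    return PhantomSpec(
        shape=(120, 160),
        teats=(TeatSpec(center=(60.0, 80.0), half_length=30.0, half_width=11.0),),
        noise_sigma=0.0,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate(small_spec, seed=11)


@pytest.fixture(scope="session")
def noisy_phantom(small_spec):
    from dataclasses import replace

    return generate(replace(small_spec, noise_sigma=0.3), seed=12)


def make_droi(bins: np.ndarray, bin_width: float = 0.1) -> DiscretizedROI:
    """Wrap a pre-binned array (0 = outside mask) as a DiscretizedROI."""
    bins = np.asarray(bins, dtype=np.int32)
    mask = bins > 0
    values = (bins[mask] - 1) * bin_width  # any values consistent with the bins
    return DiscretizedROI(
        bins=bins, mask=mask, values=values.astype(float), bin_width=bin_width, offset=(0, 0)
    )
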