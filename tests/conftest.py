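import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from canopyvol.imaging import RGBImage
from canopyvol.synthetic import GrowthParams, _default_varieties

settings.register_profile(
    "repeatable",
    derandomize=True,
    database=None,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repeatable")


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def random_image(rng):
    """A 16x16 image with the full DN range."""
    return RGBImage(rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8))


def heterogeneous_params(b_values=(2.8, 3.5, 4.2, 4.9)) -> GrowthParams:
    """Growth parameters with an amplified between-variety spread in the
    CC-CVP rate parameter b, keeping everything else at defaults. Used to
    probe local-vs-global modelling under strong group structure."""
    varieties = {
        name: dataclasses.replace(vp, cc_curve=(vp.cc_curve[0], b))
        for (name, vp), b in zip(_default_varieties().items(), b_values)
    }
    return GrowthParams(varieties=varieties)


def homogeneous_params() -> GrowthParams:
    """All varieties share one CC-CVP curve: no group structure."""
    varieties = {
        name: dataclasses.replace(vp, cc_curve=(0.20, 3.7))
        for name, vp in _default_varieties().items()
    }
    return GrowthParams(varieties=varieties)
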