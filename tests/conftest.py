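import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mirswitch import REFERENCE

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def ref():
    """Reference dimensionless parameter set (bistable, slow miRNA loop)."""
    return REFERENCE


@pytest.fixture
def with_params():
    """Helper: copy of the reference set with fields overridden."""

    def make(**kw):
        p = REFERENCE
        alpha = kw.pop("alpha", None)
        p = dataclasses.replace(p, **kw)
        if alpha is not None:
            p = p.with_alpha(alpha)
        return p

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
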