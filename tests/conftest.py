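import numpy as np
import pytest

from healthnpv import (
    CountryContext,
    DiscountSpec,
    EffectStream,
    GrowthSpec,
    ParameterPath,
)


@pytest.fixture
def worked_stream():
    """Single-period stream: 10 QALYs, 5000 health-care cost, 200 consumption cost."""
    return EffectStream("A", [10.0], [5000.0], [200.0])


@pytest.fixture
def worked_params():
    """k_h = 1000, k_c = 1, V_h = 3000 for one period."""
    return ParameterPath([1000.0], [1.0], [3000.0])


@pytest.fixture
def worked_context(worked_params):
    return CountryContext(
        id="A",
        params=worked_params,
        discount=DiscountSpec(delta=0.0, eta=1.0, growth=0.03, r_s=0.05),
        growth=GrowthSpec(g_c=0.03),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
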