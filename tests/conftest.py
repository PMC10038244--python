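import pytest

import mczones as mz


@pytest.fixture(scope="session")
def simple_case():
    """Hand-constructed 5x5-cell county with hand-derived class labels."""
    return mz.expected_simple_case()


@pytest.fixture(scope="session")
def small_bundle():
    """One small deterministic synthetic county (4-mi side) and its config."""
    params = mz.CountyParams(
        side=4 * 5280.0,
        n_rivers=2,
        n_lakes=3,
        n_preserves=2,
        wetland_fraction=0.3,
        n_addresses=150,
        seed=11,
    )
    return mz.generate_county(params), mz.default_config(params), params
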