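import pytest

from ntgcua import StrategyConfig, default_parameters, simulate_patients


@pytest.fixture(scope="session")
def params():
    """Packaged base-case parameter set (immutable, safe to share)."""
    return default_parameters()


@pytest.fixture(scope="session")
def big_panel(params):
    """Large seeded microsimulation of the traditional arm, shared across
    the distributional-agreement tests."""
    return simulate_patients(
        params, StrategyConfig(arm="traditional"), n=200_000, seed=20240212
    )
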