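import pytest

from beadquant import simassay


@pytest.fixture
def config():
    """Default noisy assay configuration, seed 1."""
    return simassay.AssayConfig(seed=1)


@pytest.fixture
def quiet_config():
    """All stochastic terms off (event scatter and background well variation)."""
    return simassay.AssayConfig(seed=1, event_cv=0.0, bg_well_sd=0.0)


@pytest.fixture
def panel():
    return simassay.default_panel()
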