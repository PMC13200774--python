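import pytest

from oncoflow import default_config


@pytest.fixture()
def config():
    """Fresh default parameterization (mutable per-test copy)."""
    return default_config()


@pytest.fixture()
def fast_config():
    """Default model shrunk to a 260-day horizon for quick kernel tests."""
    cfg = default_config()
    cfg.horizon_days = 260.0
    cfg.warmup_days = 60.0
    return cfg
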