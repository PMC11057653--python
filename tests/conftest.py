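import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import wearsleep as ws

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_config() -> ws.GeneratorConfig:
    return ws.GeneratorConfig(seed=42)


@pytest.fixture(scope="session")
def one_night(default_config) -> ws.SyntheticNight:
    hyp = ws.generate_hypnogram(default_config)
    return ws.generate_signals(hyp, default_config)


@pytest.fixture(scope="session")
def feature_pool() -> ws.EpochTable:
    """Six nights of per-epoch features at 60 s, concatenated."""
    cfg = ws.GeneratorConfig(seed=7, epoch_interval=60)
    nights = ws.generate_nights(cfg, 6, seed=7)
    frames = [ws.night_feature_table(n).frame for n in nights]
    return ws.EpochTable(pd.concat(frames), 60)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
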