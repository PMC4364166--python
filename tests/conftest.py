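import numpy as np
import pytest

from usvkit import DetectionConfig, PipelineConfig, StftParams


@pytest.fixture(scope="session")
def stft_params() -> StftParams:
    return StftParams()


@pytest.fixture(scope="session")
def det_cfg() -> DetectionConfig:
    return DetectionConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture()
def short_config() -> PipelineConfig:
    """Pipeline config for sub-minute synthetic sessions."""
    return PipelineConfig(session_length_s=2.0)
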