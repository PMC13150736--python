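from pathlib import Path

import numpy as np
import pytest

from nnmo import NetworkConfig, StreamConfig, TaskSpec


@pytest.fixture
def datadir() -> Path:
    return Path(__file__).parent / "data"


@pytest.fixture
def config6() -> NetworkConfig:
    """The minimal working configuration: 2 input, 2 output, 2 hidden."""
    return NetworkConfig(6)


@pytest.fixture
def task_a3() -> TaskSpec:
    return TaskSpec.from_name("A3")


@pytest.fixture
def task_c4() -> TaskSpec:
    return TaskSpec.from_name("C4")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


@pytest.fixture
def short_stream_cfg() -> StreamConfig:
    """A 20-symbol fragment for fast unit tests."""
    return StreamConfig(length_symbols=20)
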