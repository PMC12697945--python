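import numpy as np
import pytest

from psdcoex import ModelParams, parse_community


@pytest.fixture
def low_cost_params() -> ModelParams:
    """Low relative-cost combination, no jitter."""
    return ModelParams(
        g=1.0, cr=0.16, cd=1.4 * 0.16, cp=2.5 * 0.16, KP=40.0, KD=10.0,
        jitter_scale=0.0,
    )


@pytest.fixture
def high_cost_params() -> ModelParams:
    """High relative-cost combination, no jitter."""
    return ModelParams(
        g=1.0, cr=0.16, cd=2.2083 * 0.16, cp=2.7624 * 0.16, KP=40.0, KD=10.0,
        jitter_scale=0.0,
    )


@pytest.fixture
def circulant_2psd():
    return parse_community("[PD,SP,DS]")


@pytest.fixture
def circulant_3psd():
    return parse_community("[PDS,SPD,DSP]")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_community(rng: np.random.Generator, n: int, m: int):
    """Uniformly random phenotype matrix (rows need not be distinct)."""
    from psdcoex import Community

    return Community(
        tuple(tuple(int(v) for v in row) for row in rng.integers(0, 4, (n, m)))
    )
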