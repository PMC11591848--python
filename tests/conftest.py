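import numpy as np
import pytest

from corsistudy.task_engine import (
    Block,
    BoardLayout,
    SessionConfig,
    default_board,
)


@pytest.fixture
def board() -> BoardLayout:
    return default_board()


@pytest.fixture
def small_board() -> BoardLayout:
    """A 4-block board for exhaustive distributional checks."""
    return BoardLayout(
        blocks=(
            Block(1, 3.0, 3.0),
            Block(2, 9.0, 3.0),
            Block(3, 3.0, 9.0),
            Block(4, 9.0, 9.0),
        ),
        window_w_cm=12.0,
        window_h_cm=12.0,
    )


@pytest.fixture
def config() -> SessionConfig:
    return SessionConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
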