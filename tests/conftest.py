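import random

import numpy as np
import pytest

from smtgaze.boards import (
    Board,
    LevelSpec,
    ScreenLayout,
    SessionPlan,
    generate_board,
)


@pytest.fixture(scope="session")
def small_boards():
    """Four deterministic single-solution 5x5 boards with 5 tile types."""
    rng = random.Random(42)
    layout = ScreenLayout.centered(5, 5)
    return [generate_board(5, 5, 5, rng=rng, layout=layout) for _ in range(4)]


@pytest.fixture(scope="session")
def tiny_plan(small_boards):
    """A one-level test plan over the shared 5x5 boards."""
    return SessionPlan(levels=[LevelSpec(5, 5, 5, False, list(small_boards))], seed=42)


@pytest.fixture
def board_5x5(small_boards):
    return small_boards[0]


def make_board(grid, n_tile_types=8, cell_px=100.0):
    grid = np.asarray(grid)
    h, w = grid.shape
    return Board(w, h, n_tile_types, grid, ScreenLayout.centered(w, h, cell_px=cell_px))
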