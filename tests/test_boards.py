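"""Board engine: match detection, solvability oracle, generation, distractors."""

import itertools
import random

import numpy as np
import pytest

from conftest import make_board
from oracles import naive_distractor_pairs, naive_matches, naive_solving_swaps

from smtgaze.boards import (
    BoardError,
    Swap,
    apply_swap,
    build_session,
    detect_distractor_patterns,
    detect_matches,
    enumerate_solving_swaps,
    generate_board,
)


class TestDetectMatches:
    def test_single_horizontal_line(self):
        board = make_board([[0, 0, 0], [1, 2, 3], [4, 5, 6]])
        assert detect_matches(board) == {(((0, 0), (0, 1), (0, 2)))}

    def test_no_match_on_cyclic_rows(self):
        board = make_board([[0, 1, 2, 3], [3, 0, 1, 2], [2, 3, 0, 1], [1, 2, 3, 0]])
        assert detect_matches(board) == set()

    def test_run_of_four_decomposes_into_two_windows(self):
        board = make_board([[1, 1, 1, 1], [0, 2, 3, 0], [2, 3, 0, 2], [3, 0, 2, 3]])
        assert detect_matches(board) == {
            ((0, 0), (0, 1), (0, 2)),
            ((0, 1), (0, 2), (0, 3)),
        }

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_equal_exhaustive_window_scan(self, seed):
        rng = np.random.default_rng(seed)
        grid = rng.integers(0, 3, size=(5, 5))
        board = make_board(grid)
        assert detect_matches(board) == naive_matches(grid)

    def test_malformed_grids_rejected(self):
        from smtgaze.boards import Board

        with pytest.raises(BoardError):
            Board(3, 3, 8, np.zeros((2, 3), dtype=int))
        with pytest.raises(BoardError):
            Board(3, 3, 4, np.full((3, 3), 7))


class TestSolvingSwaps:
    def test_manual_column_example(self):
        # column 2 ends in two 0-tiles; the 0 at (1, 3) swaps left onto
        # (1, 2) to complete the vertical 0-line -- the only solving swap
        grid = [
            [1, 0, 3, 2],
            [0, 3, 2, 0],
            [2, 1, 0, 1],
            [0, 3, 0, 2],
        ]
        board = make_board(grid)
        swaps = enumerate_solving_swaps(board)
        assert [(s.cell_a, s.cell_b) for s, _ in swaps] == [((1, 2), (1, 3))]
        assert swaps[0][1] == (((1, 2), (2, 2), (3, 2)),)

    def test_far_apart_pairs_unsolvable(self):
        grid = [
            [0, 1, 2, 3],
            [4, 5, 6, 7],
            [2, 3, 0, 1],
            [6, 7, 4, 5],
        ]
        board = make_board(grid)
        assert enumerate_solving_swaps(board) == []
        assert naive_solving_swaps(np.asarray(grid)) == []

    def test_requires_matchless_board(self):
        board = make_board([[0, 0, 0, 1], [1, 2, 3, 0], [2, 3, 1, 2], [3, 1, 2, 3]])
        with pytest.raises(BoardError):
            enumerate_solving_swaps(board)

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_naive_enumeration(self, seed):
        rng = np.random.default_rng(seed + 100)
        while True:
            grid = rng.integers(0, 4, size=(5, 6))
            if not naive_matches(grid):
                break
        board = make_board(grid)
        got = sorted((s.cell_a, s.cell_b) for s, _ in enumerate_solving_swaps(board))
        assert got == sorted(naive_solving_swaps(grid))


class TestGenerateBoard:
    @pytest.mark.parametrize("w,h,t,seed", [(4, 4, 4, 1), (8, 8, 8, 7), (5, 7, 6, 3)])
    def test_single_solution_oracle(self, w, h, t, seed):
        board, target = generate_board(w, h, t, seed=seed)
        assert naive_matches(board.grid) == set()
        swaps = naive_solving_swaps(board.grid)
        assert len(swaps) == 1
        assert set(swaps[0]) == set(
            (target.solving_swap.cell_a, target.solving_swap.cell_b)
        )
        assert set(target.match_cells) | target.solving_swap.cells == target.aoi_cells

    @pytest.mark.parametrize("w,h,t", [(3, 4, 4), (4, 9, 4), (4, 4, 3), (4, 4, 9)])
    def test_out_of_range_parameters(self, w, h, t):
        with pytest.raises(BoardError):
            generate_board(w, h, t, seed=1)

    def test_seed_determinism(self):
        b1, t1 = generate_board(6, 5, 5, seed=99)
        b2, t2 = generate_board(6, 5, 5, seed=99)
        assert np.array_equal(b1.grid, b2.grid)
        assert t1 == t2

    def test_sweep_all_size_combinations(self):
        # larger boards pair with >=5 tile types, as difficulty levels do
        rng = random.Random(7)
        for (w, h) in itertools.product(range(4, 9), repeat=2):
            t = rng.randrange(4, 9) if w * h < 40 else rng.randrange(5, 9)
            board, _ = generate_board(w, h, t, rng=rng)
            assert naive_matches(board.grid) == set()
            assert len(naive_solving_swaps(board.grid)) == 1


class TestApplySwap:
    def test_solving_swap_is_unique_correct_move(self, board_5x5):
        board, target = board_5x5
        outcome = apply_swap(board, target.solving_swap)
        assert outcome.correct
        assert target.match_cells in outcome.matches
        # every other adjacent swap bounces back and leaves the board unchanged
        from smtgaze.boards import iter_adjacent_swaps

        for swap in iter_adjacent_swaps(board):
            if swap.cells == target.solving_swap.cells:
                continue
            other = apply_swap(board, swap)
            assert not other.correct
            assert other.board is board
            assert np.array_equal(other.board.grid, board.grid)

    def test_non_adjacent_swap_rejected(self):
        with pytest.raises(BoardError):
            Swap((0, 0), (0, 2))


class TestDistractors:
    def test_single_adjacent_pair(self):
        board, target = generate_board(4, 4, 4, seed=5)
        got = {(tuple(d.cells), d.shape) for d in detect_distractor_patterns(board, target)}
        assert got == naive_distractor_pairs(board.grid, set(target.aoi_cells))

    def test_gapped_pair_detected(self):
        grid = [
            [0, 1, 0, 2],
            [3, 2, 1, 3],
            [1, 3, 2, 0],
            [2, 0, 3, 1],
        ]
        board = make_board(grid)
        from smtgaze.boards import TargetPattern

        target = TargetPattern(
            Swap((3, 0), (3, 1)), ((3, 0), (3, 1), (3, 2)),
            frozenset({(3, 0), (3, 1), (3, 2)}),
        )
        pats = detect_distractor_patterns(board, target)
        assert (((0, 0), (0, 2)), "gapped-pair") in {(tuple(d.cells), d.shape) for d in pats}

    def test_pattern_inside_target_excluded(self, board_5x5):
        board, target = board_5x5
        for d in detect_distractor_patterns(board, target):
            assert not set(d.cells) <= target.aoi_cells

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_exhaustive_pair_scan(self, seed):
        board, target = generate_board(6, 6, 4, seed=seed)
        got = {(tuple(d.cells), d.shape) for d in detect_distractor_patterns(board, target)}
        assert got == naive_distractor_pairs(board.grid, set(target.aoi_cells))

    def test_deterministic_row_major_order(self, board_5x5):
        board, target = board_5x5
        pats = detect_distractor_patterns(board, target)
        firsts = [d.cells[0] for d in pats]
        assert firsts == sorted(firsts)


class TestBuildSession:
    def test_structure_counts_and_validity(self):
        plan = build_session(seed=0, boards_per_level=2)
        assert len(plan.levels) == 15
        assert sum(len(lv.boards) for lv in plan.levels) == 30
        training = [lv for lv in plan.levels if lv.training]
        assert [(lv.width, lv.height, lv.n_tile_types) for lv in training] == [
            (4, 4, 4), (5, 5, 5), (6, 6, 6),
        ]
        for lv in plan.levels:
            for board, target in lv.boards:
                assert detect_matches(board) == set()
                assert len(enumerate_solving_swaps(board)) == 1

    def test_seed_determinism_and_shuffling(self):
        p1 = build_session(seed=3, boards_per_level=1)
        p2 = build_session(seed=3, boards_per_level=1)
        for l1, l2 in zip(p1.levels, p2.levels):
            assert (l1.width, l1.height, l1.n_tile_types) == (l2.width, l2.height, l2.n_tile_types)
            assert np.array_equal(l1.boards[0][0].grid, l2.boards[0][0].grid)
        p3 = build_session(seed=4, boards_per_level=1)
        order3 = [(lv.width, lv.height) for lv in p3.levels[3:]]
        order1 = [(lv.width, lv.height) for lv in p1.levels[3:]]
        assert sorted(order1) == sorted(order3)

    def test_wrong_spec_count_rejected(self):
        with pytest.raises(BoardError):
            build_session(test_specs=[(4, 4, 4)] * 5, seed=0)
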