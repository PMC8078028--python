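"""Match-3 (tile-matching) puzzle boards with a unique solving swap.

A Search-and-Match board is a ``height x width`` grid of tile types. The
player must find the one pair of orthogonally adjacent tiles whose swap
creates a horizontal or vertical line of three identical tiles; any other
swap is a false move and bounces back. Boards are generated so that

* the initial grid contains no line of three, and
* exactly one adjacent swap solves the board (verified by exhaustive
  enumeration of all adjacent swaps).

Alongside the unique *target pattern*, every board carries a census of
*distractor patterns*: same-type tile pairs (adjacent, or gapped ``X.X``
in a line) that visually suggest a near-match but are not solvable.

Grid coordinates are 0-based ``(row, col)`` with row 0 at the top. Screen
rectangles are half-open pixel intervals with the origin at the top-left
of the screen, matching gaze-sample conventions.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

Cell = tuple[int, int]

MIN_DIM, MAX_DIM = 4, 8
MIN_TYPES, MAX_TYPES = 4, 8

#: adjacent-then-larger board specs used for the 12 test levels when the
#: caller does not supply their own (width, height, n_tile_types) triples.
DEFAULT_TEST_SPECS: tuple[tuple[int, int, int], ...] = (
    (4, 5, 4),
    (4, 6, 5),
    (5, 4, 4),
    (5, 5, 5),
    (5, 6, 6),
    (6, 4, 5),
    (6, 5, 6),
    (6, 6, 6),
    (7, 6, 6),
    (6, 8, 7),
    (7, 7, 7),
    (8, 8, 8),
)

TRAINING_SPECS: tuple[tuple[int, int, int], ...] = ((4, 4, 4), (5, 5, 5), (6, 6, 6))


class BoardError(ValueError):
    """Malformed board input (dimensions, grid values, swap geometry)."""


class GenerationError(RuntimeError):
    """Board generation exhausted its retry budget."""


@dataclass(frozen=True)
class ScreenLayout:
    """Placement of the tile grid on a pixel screen.

    Each grid cell ``(row, col)`` maps to the half-open pixel rectangle
    ``[x0, x0+cell_px) x [y0, y0+cell_px)``.
    """

    origin_x: float
    origin_y: float
    cell_px: float = 100.0

    @classmethod
    def centered(
        cls,
        width: int,
        height: int,
        screen: tuple[int, int] = (1920, 1080),
        cell_px: float = 100.0,
    ) -> "ScreenLayout":
        """Center a ``width x height`` board on the given screen."""
        return cls(
            origin_x=(screen[0] - width * cell_px) / 2.0,
            origin_y=(screen[1] - height * cell_px) / 2.0,
            cell_px=cell_px,
        )

    def cell_rect(self, cell: Cell) -> tuple[float, float, float, float]:
        """``(x0, y0, x1, y1)`` pixel rectangle of a grid cell."""
        r, c = cell
        x0 = self.origin_x + c * self.cell_px
        y0 = self.origin_y + r * self.cell_px
        return (x0, y0, x0 + self.cell_px, y0 + self.cell_px)

    def cell_center(self, cell: Cell) -> tuple[float, float]:
        x0, y0, x1, y1 = self.cell_rect(cell)
        return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)

    def cell_at(self, x: float, y: float) -> Cell | None:
        """Grid cell containing the pixel ``(x, y)``, or None if outside."""
        c = int(np.floor((x - self.origin_x) / self.cell_px))
        r = int(np.floor((y - self.origin_y) / self.cell_px))
        if x < self.origin_x or y < self.origin_y:
            return None
        return (r, c)


@dataclass(frozen=True)
class Swap:
    """An unordered pair of orthogonally adjacent grid cells."""

    cell_a: Cell
    cell_b: Cell

    def __post_init__(self) -> None:
        dr = abs(self.cell_a[0] - self.cell_b[0])
        dc = abs(self.cell_a[1] - self.cell_b[1])
        if dr + dc != 1:
            raise BoardError(
                f"swap cells must be orthogonally adjacent: {self.cell_a}, {self.cell_b}"
            )

    @property
    def adjacency(self) -> str:
        return "horizontal" if self.cell_a[0] == self.cell_b[0] else "vertical"

    @property
    def cells(self) -> frozenset[Cell]:
        return frozenset((self.cell_a, self.cell_b))


@dataclass(frozen=True)
class TargetPattern:
    """The unique solvable configuration of a generated board.

    ``match_cells`` are the three cells forming the line *after* the
    solving swap; ``aoi_cells`` is the pre-swap region of interest (the
    match cells together with both swap cells) used for fixation
    classification.
    """

    solving_swap: Swap
    match_cells: tuple[Cell, Cell, Cell]
    aoi_cells: frozenset[Cell]


@dataclass(frozen=True)
class DistractorPattern:
    """A same-type near-match: an adjacent pair or a gapped ``X.X`` pair."""

    cells: tuple[Cell, ...]
    shape: str  # "adjacent-pair" | "gapped-pair"
    tile_type: int


@dataclass
class Board:
    width: int
    height: int
    n_tile_types: int
    grid: np.ndarray
    layout: ScreenLayout = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.int8)
        if self.grid.ndim != 2 or self.grid.shape != (self.height, self.width):
            raise BoardError(
                f"grid shape {self.grid.shape} does not match "
                f"(height={self.height}, width={self.width})"
            )
        if self.grid.min() < 0 or self.grid.max() >= self.n_tile_types:
            raise BoardError("grid entries must lie in [0, n_tile_types)")
        if self.layout is None:
            self.layout = ScreenLayout.centered(self.width, self.height)

    def in_bounds(self, cell: Cell) -> bool:
        return 0 <= cell[0] < self.height and 0 <= cell[1] < self.width

    def copy(self) -> "Board":
        return Board(self.width, self.height, self.n_tile_types, self.grid.copy(), self.layout)

    def to_dict(self) -> dict:
        return {
            "width": self.width,
            "height": self.height,
            "n_tile_types": self.n_tile_types,
            "grid": self.grid.tolist(),
            "layout": {
                "origin_x": self.layout.origin_x,
                "origin_y": self.layout.origin_y,
                "cell_px": self.layout.cell_px,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Board":
        layout = ScreenLayout(**d["layout"]) if "layout" in d else None
        return cls(d["width"], d["height"], d["n_tile_types"], np.array(d["grid"]), layout)


@dataclass(frozen=True)
class SwapOutcome:
    """Result of applying a swap: a correct move with its matches, or a
    false move in which the tiles bounce back and the board is unchanged."""

    correct: bool
    matches: tuple[tuple[Cell, Cell, Cell], ...]
    board: Board


@dataclass
class LevelSpec:
    width: int
    height: int
    n_tile_types: int
    training: bool
    boards: list[tuple[Board, TargetPattern]]


@dataclass
class SessionPlan:
    """3 training levels plus 12 randomized test levels, 4 boards each."""

    levels: list[LevelSpec]
    seed: int
    boards_per_level: int = 4

    @property
    def boards(self) -> list[tuple[Board, TargetPattern]]:
        return [bt for lv in self.levels for bt in lv.boards]


# ---------------------------------------------------------------------------
# match detection


def _runs(line: np.ndarray) -> Iterator[tuple[int, int]]:
    """Yield (start, length) of maximal equal-value runs in a 1-D array."""
    start = 0
    for i in range(1, len(line) + 1):
        if i == len(line) or line[i] != line[start]:
            yield start, i - start
            start = i


def detect_matches(board: Board) -> set[tuple[Cell, Cell, Cell]]:
    """All 3-lines of identical tiles on the board.

    Maximal runs of length >= 3 are decomposed into every covering window
    of three cells, so a run of four yields two overlapping 3-lines.
    Returns the empty set for a valid initial board.
    """
    g = board.grid
    out: set[tuple[Cell, Cell, Cell]] = set()
    for r in range(board.height):
        for start, length in _runs(g[r, :]):
            for c in range(start, start + length - 2):
                out.add(((r, c), (r, c + 1), (r, c + 2)))
    for c in range(board.width):
        for start, length in _runs(g[:, c]):
            for r in range(start, start + length - 2):
                out.add(((r, c), (r + 1, c), (r + 2, c)))
    return out


def _match_through(g: np.ndarray, r: int, c: int) -> bool:
    """True if any 3-window through (r, c) is a line of identical tiles."""
    h, w = g.shape
    v = g[r, c]
    for c0 in range(max(0, c - 2), min(c, w - 3) + 1):
        if g[r, c0] == g[r, c0 + 1] == g[r, c0 + 2]:
            return True
    for r0 in range(max(0, r - 2), min(r, h - 3) + 1):
        if g[r0, c] == g[r0 + 1, c] == g[r0 + 2, c]:
            return True
    return False


def _matches_through(g: np.ndarray, cells: Sequence[Cell]) -> tuple[tuple[Cell, Cell, Cell], ...]:
    h, w = g.shape
    found: set[tuple[Cell, Cell, Cell]] = set()
    for (r, c) in cells:
        for c0 in range(max(0, c - 2), min(c, w - 3) + 1):
            if g[r, c0] == g[r, c0 + 1] == g[r, c0 + 2]:
                found.add(((r, c0), (r, c0 + 1), (r, c0 + 2)))
        for r0 in range(max(0, r - 2), min(r, h - 3) + 1):
            if g[r0, c] == g[r0 + 1, c] == g[r0 + 2, c]:
                found.add(((r0, c), (r0 + 1, c), (r0 + 2, c)))
    return tuple(sorted(found))


def iter_adjacent_swaps(board: Board) -> Iterator[Swap]:
    """Every unordered pair of orthogonally adjacent cells, each once."""
    for r in range(board.height):
        for c in range(board.width):
            if c + 1 < board.width:
                yield Swap((r, c), (r, c + 1))
            if r + 1 < board.height:
                yield Swap((r, c), (r + 1, c))


def enumerate_solving_swaps(
    board: Board,
) -> list[tuple[Swap, tuple[tuple[Cell, Cell, Cell], ...]]]:
    """Exhaustively try every adjacent swap and keep those creating a match.

    This is the solvability oracle: a generated board is valid iff the
    returned list has exactly one entry. Requires a board with no
    pre-existing match. A swap can only create lines through the two
    swapped cells, so detection is restricted to those windows.
    """
    if detect_matches(board):
        raise BoardError("enumerate_solving_swaps requires a board with no existing match")
    g = board.grid
    out = []
    for swap in iter_adjacent_swaps(board):
        (r1, c1), (r2, c2) = swap.cell_a, swap.cell_b
        if g[r1, c1] == g[r2, c2]:
            continue  # swapping identical tiles changes nothing
        g[r1, c1], g[r2, c2] = g[r2, c2], g[r1, c1]
        matches = _matches_through(g, [(r1, c1), (r2, c2)])
        g[r1, c1], g[r2, c2] = g[r2, c2], g[r1, c1]
        if matches:
            out.append((swap, matches))
    return out


def apply_swap(board: Board, swap: Swap) -> SwapOutcome:
    """Apply a move. A swap that creates a match is a correct move and the
    post-swap board is returned; otherwise the tiles bounce back."""
    if not (board.in_bounds(swap.cell_a) and board.in_bounds(swap.cell_b)):
        raise BoardError(f"swap cells out of bounds: {swap.cell_a}, {swap.cell_b}")
    new = board.copy()
    g = new.grid
    (r1, c1), (r2, c2) = swap.cell_a, swap.cell_b
    g[r1, c1], g[r2, c2] = g[r2, c2], g[r1, c1]
    matches = _matches_through(g, [(r1, c1), (r2, c2)])
    if matches:
        return SwapOutcome(correct=True, matches=matches, board=new)
    return SwapOutcome(correct=False, matches=(), board=board)


# ---------------------------------------------------------------------------
# distractor census


def detect_distractor_patterns(board: Board, target: TargetPattern) -> list[DistractorPattern]:
    """All same-type adjacent pairs and gapped (``X.X``) pairs in rows and
    columns, excluding patterns fully inside the target's AOI cells.

    Order is deterministic: row-major by first cell, adjacent pairs before
    gapped pairs at the same anchor, horizontal before vertical.
    """
    g = board.grid
    aoi = target.aoi_cells
    out: list[DistractorPattern] = []
    for r in range(board.height):
        for c in range(board.width):
            # horizontal / vertical adjacent pair anchored at (r, c)
            for (dr, dc) in ((0, 1), (1, 0)):
                r2, c2 = r + dr, c + dc
                if r2 < board.height and c2 < board.width and g[r, c] == g[r2, c2]:
                    cells = ((r, c), (r2, c2))
                    if not set(cells) <= aoi:
                        out.append(DistractorPattern(cells, "adjacent-pair", int(g[r, c])))
            # gapped pair X . X
            for (dr, dc) in ((0, 2), (2, 0)):
                r2, c2 = r + dr, c + dc
                mid = (r + dr // 2, c + dc // 2)
                if (
                    r2 < board.height
                    and c2 < board.width
                    and g[r, c] == g[r2, c2]
                    and g[mid] != g[r, c]
                ):
                    cells = ((r, c), (r2, c2))
                    if not set(cells) <= aoi:
                        out.append(DistractorPattern(cells, "gapped-pair", int(g[r, c])))
    return out


# ---------------------------------------------------------------------------
# generation


def _validate_params(width: int, height: int, n_tile_types: int) -> None:
    if not (MIN_DIM <= width <= MAX_DIM and MIN_DIM <= height <= MAX_DIM):
        raise BoardError(f"width/height must be in [{MIN_DIM}, {MAX_DIM}]: got {width}x{height}")
    if not (MIN_TYPES <= n_tile_types <= MAX_TYPES):
        raise BoardError(f"n_tile_types must be in [{MIN_TYPES}, {MAX_TYPES}]: got {n_tile_types}")


def _plant_target(w: int, h: int, t: int, rng: random.Random):
    """Choose a target geometry and pre-place its tiles.

    Post-swap, cell ``a`` (inside the match line) receives tile type T from
    its neighbor ``b``, completing the line. Pre-swap the grid holds T at
    the two remaining line cells and at ``b``, and some other type at ``a``.
    """
    while True:
        if rng.random() < 0.5:
            r = rng.randrange(h)
            c = rng.randrange(w - 2)
            line = [(r, c + i) for i in range(3)]
        else:
            c = rng.randrange(w)
            r = rng.randrange(h - 2)
            line = [(r + i, c) for i in range(3)]
        a = line[rng.randrange(3)]
        nbrs = [
            (a[0] + dr, a[1] + dc)
            for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0))
        ]
        nbrs = [p for p in nbrs if 0 <= p[0] < h and 0 <= p[1] < w and p not in line]
        if not nbrs:
            continue
        b = nbrs[rng.randrange(len(nbrs))]
        tile_t = rng.randrange(t)
        other = rng.choice([x for x in range(t) if x != tile_t])
        grid = [[-1] * w for _ in range(h)]
        for cell in line:
            grid[cell[0]][cell[1]] = tile_t
        grid[a[0]][a[1]] = other
        grid[b[0]][b[1]] = tile_t
        return grid, a, b, tuple(line)


def _cell_match(grid: list[list[int]], w: int, h: int, r: int, c: int) -> bool:
    """3-in-a-line through (r, c) on a partially filled grid (-1 = empty)."""
    for c0 in range(max(0, c - 2), min(c, w - 3) + 1):
        v = grid[r][c0]
        if v >= 0 and grid[r][c0 + 1] == v and grid[r][c0 + 2] == v:
            return True
    for r0 in range(max(0, r - 2), min(r, h - 3) + 1):
        v = grid[r0][c]
        if v >= 0 and grid[r0 + 1][c] == v and grid[r0 + 2][c] == v:
            return True
    return False


def _solving_swaps_raw(grid: list[list[int]], w: int, h: int) -> list[tuple[Cell, Cell]]:
    out = []
    for r in range(h):
        for c in range(w):
            for dr, dc in ((0, 1), (1, 0)):
                r2, c2 = r + dr, c + dc
                if r2 >= h or c2 >= w or grid[r][c] == grid[r2][c2]:
                    continue
                grid[r][c], grid[r2][c2] = grid[r2][c2], grid[r][c]
                hit = _cell_match(grid, w, h, r, c) or _cell_match(grid, w, h, r2, c2)
                grid[r][c], grid[r2][c2] = grid[r2][c2], grid[r][c]
                if hit:
                    out.append(((r, c), (r2, c2)))
    return out


def _post_swap_line_cells(grid: list[list[int]], w: int, h: int, s: tuple[Cell, Cell]) -> set[Cell]:
    """Cells of every match line the swap ``s`` would create."""
    (r1, c1), (r2, c2) = s
    grid[r1][c1], grid[r2][c2] = grid[r2][c2], grid[r1][c1]
    cells: set[Cell] = set()
    for (r, c) in s:
        for c0 in range(max(0, c - 2), min(c, w - 3) + 1):
            v = grid[r][c0]
            if v >= 0 and grid[r][c0 + 1] == v and grid[r][c0 + 2] == v:
                cells |= {(r, c0), (r, c0 + 1), (r, c0 + 2)}
        for r0 in range(max(0, r - 2), min(r, h - 3) + 1):
            v = grid[r0][c]
            if v >= 0 and grid[r0 + 1][c] == v and grid[r0 + 2][c] == v:
                cells |= {(r0, c), (r0 + 1, c), (r0 + 2, c)}
    grid[r1][c1], grid[r2][c2] = grid[r2][c2], grid[r1][c1]
    return cells


def generate_board(
    width: int,
    height: int,
    n_tile_types: int,
    seed: int | None = None,
    rng: random.Random | None = None,
    layout: ScreenLayout | None = None,
    max_restarts: int = 200,
    max_repair_iters: int = 4000,
) -> tuple[Board, TargetPattern]:
    """Generate a board with no initial match and exactly one solving swap.

    A target configuration is planted first (its tiles are protected), the
    rest of the grid is filled avoiding lines of three, and extra solving
    swaps are then removed by iteratively re-typing one tile of each
    unwanted post-swap match line. The result is re-verified with the
    exhaustive :func:`enumerate_solving_swaps` oracle; identical seeds
    yield identical boards.

    Raises :class:`GenerationError` if no valid board is found within the
    retry budget (dense boards pairing the largest grids with the fewest
    tile types can exhaust it).
    """
    _validate_params(width, height, n_tile_types)
    if rng is None:
        rng = random.Random(seed)
    w, h, t = width, height, n_tile_types

    for _restart in range(max_restarts):
        grid, a, b, line = _plant_target(w, h, t, rng)
        protected = set(line) | {b}
        planted = (min(a, b), max(a, b))

        # fill remaining cells, avoiding static 3-lines
        ok = True
        for r in range(h):
            for c in range(w):
                if grid[r][c] >= 0:
                    if _cell_match(grid, w, h, r, c):
                        ok = False
                        break
                    continue
                types = list(range(t))
                rng.shuffle(types)
                for v in types:
                    grid[r][c] = v
                    if not _cell_match(grid, w, h, r, c):
                        break
                    grid[r][c] = -1
                if grid[r][c] < 0:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue

        # repair: re-type tiles of unwanted solving swaps until unique
        done = False
        for _it in range(max_repair_iters):
            swaps = _solving_swaps_raw(grid, w, h)
            norm = [(min(s), max(s)) for s in swaps]
            if planted not in norm:
                break  # a repair destroyed the planted solution; restart
            extras = [s for s, n in zip(swaps, norm) if n != planted]
            if not extras:
                done = True
                break
            s = extras[rng.randrange(len(extras))]
            cand = [
                p
                for p in (_post_swap_line_cells(grid, w, h, s) | set(s))
                if p not in protected
            ]
            if not cand:
                break
            mr, mc = cand[rng.randrange(len(cand))]
            old = grid[mr][mc]
            types = [x for x in range(t) if x != old]
            rng.shuffle(types)
            for v in types:
                grid[mr][mc] = v
                if not _cell_match(grid, w, h, mr, mc):
                    break
                grid[mr][mc] = old
        if not done:
            continue

        board = Board(w, h, t, np.array(grid), layout)
        solutions = enumerate_solving_swaps(board)
        if len(solutions) != 1:  # pragma: no cover - repair loop guarantees this
            continue
        swap, matches = solutions[0]
        match_cells = matches[0]
        target = TargetPattern(
            solving_swap=swap,
            match_cells=match_cells,
            aoi_cells=frozenset(match_cells) | swap.cells,
        )
        return board, target

    raise GenerationError(
        f"no single-solution board found for {width}x{height} with "
        f"{n_tile_types} tile types after {max_restarts} restarts"
    )


def build_session(
    test_specs: Sequence[tuple[int, int, int]] | None = None,
    seed: int = 0,
    boards_per_level: int = 4,
    layout_screen: tuple[int, int] = (1920, 1080),
    cell_px: float = 100.0,
) -> SessionPlan:
    """Build a full session: 3 fixed training levels of incremental
    difficulty followed by the 12 test levels in seeded random order,
    ``boards_per_level`` single-solution boards each.
    """
    specs = tuple(test_specs) if test_specs is not None else DEFAULT_TEST_SPECS
    if len(specs) != 12:
        raise BoardError(f"expected 12 test-level specs, got {len(specs)}")
    for spec in specs:
        _validate_params(*spec)
    rng = random.Random(seed)
    order = list(specs)
    rng.shuffle(order)
    levels: list[LevelSpec] = []
    for training, spec_list in ((True, TRAINING_SPECS), (False, tuple(order))):
        for (w, h, t) in spec_list:
            layout = ScreenLayout.centered(w, h, screen=layout_screen, cell_px=cell_px)
            boards = [
                generate_board(w, h, t, rng=rng, layout=layout)
                for _ in range(boards_per_level)
            ]
            levels.append(LevelSpec(w, h, t, training, boards))
    return SessionPlan(levels=levels, seed=seed, boards_per_level=boards_per_level)
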