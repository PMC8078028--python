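"""Synthetic 120 Hz binocular gaze and mouse streams with known ground truth.

The generator emulates the statistical structure of a Search-and-Match
recording session so that every downstream stage (fixation extraction,
AOI classification, search-time metrics, cohort statistics) can be tested
without access to real participant data.

The scanpath model follows the inefficient-serial-search account of
match-3 play: before locating the target, a subject visits a random
number of distractor tiles. Per board the number of distractor dwells is
``k ~ Poisson(exec_slowness * n_distractors)``, dwelt cells are sampled
without immediate repetition, and the scanpath always ends on the target
region. Dwell durations are truncated-normal with a 120 ms floor so that
every ground-truth dwell is detectable under a 100 ms selection
threshold. Saccades between dwells are ballistic: at 120 Hz a saccade's
traverse fits within about one sample period, so gap samples sit on the
two endpoint tiles (first half of the gap on the departing tile, second
half on the arriving tile).

Rendering adds per-eye isotropic Gaussian noise, a fixed horizontal
inter-eye separation, and i.i.d. sample dropout. The mouse stream idles,
repositions to the solving swap's first tile, then drags to the second
tile with the button held; the drag release ends the board.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .boards import Board, Cell, DistractorPattern, SessionPlan, TargetPattern
from .io import MoveRecord
from .streams import NOMINAL_RATE_HZ, GazeStream, MouseStream

SCREEN = (1920, 1080)

#: saccadic gap bounds between dwells, seconds
GAP_RANGE = (0.020, 0.080)
#: pause between reaching the swap tile and starting the drag, seconds
PRE_DRAG_PAUSE = 0.25
INTER_BOARD_GAP = 1.0


@dataclass(frozen=True)
class SubjectProfile:
    """Latent parameters of one synthetic participant.

    ``exec_slowness`` scales the expected number of distractor visits per
    available distractor pattern before the target is found; it stands in
    for the executive-function component that drives fixation counts.
    """

    subject_id: str
    age: float = 70.0
    exec_slowness: float = 0.2
    fixation_duration_mean: float = 0.25
    fixation_duration_sd: float = 0.08
    noise_sd: float = 5.0
    inter_eye_offset: float = 10.0
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.exec_slowness < 0:
            raise ValueError("exec_slowness must be >= 0")
        for name in ("fixation_duration_mean", "fixation_duration_sd",
                     "noise_sd", "inter_eye_offset"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must be in [0, 1]")


@dataclass(frozen=True)
class Dwell:
    label: str  # "distractor" | "target"
    cell: Cell
    start: float
    end: float


@dataclass
class BoardGroundTruth:
    """Known truth for one rendered board, for parameter-recovery tests."""

    t0: float
    dwells: list[Dwell]
    first_target_time: float  # start of the first target dwell
    move_interval: tuple[float, float]  # mouse repositioning
    drag_interval: tuple[float, float]  # clicked drag performing the swap
    t_end: float  # board completion (drag release)

    @property
    def mouse_move_time(self) -> float:
        """Total time the mouse is in motion (reposition + drag)."""
        return (self.move_interval[1] - self.move_interval[0]) + (
            self.drag_interval[1] - self.drag_interval[0]
        )

    @property
    def n_distractor_dwells(self) -> int:
        return sum(1 for d in self.dwells if d.label == "distractor")

    @property
    def n_target_dwells(self) -> int:
        return sum(1 for d in self.dwells if d.label == "target")


@dataclass
class BoardRecord:
    board: Board
    target: TargetPattern
    distractors: list[DistractorPattern]
    truth: BoardGroundTruth
    gaze: GazeStream
    mouse: MouseStream
    move: MoveRecord
    level: int
    training: bool


@dataclass
class SubjectSession:
    profile: SubjectProfile
    records: list[BoardRecord]

    @property
    def gaze(self) -> GazeStream:
        return GazeStream.concatenate([r.gaze for r in self.records])

    @property
    def mouse(self) -> MouseStream:
        return MouseStream.concatenate([r.mouse for r in self.records])

    @property
    def board_windows(self) -> list[tuple[float, float]]:
        return [(r.truth.t0, r.truth.t_end) for r in self.records]


def _truncnorm(mean: float, sd: float, floor: float, rng: np.random.Generator) -> float:
    for _ in range(100):
        v = rng.normal(mean, sd)
        if v >= floor:
            return float(v)
    return floor


def simulate_board_scanpath(
    board: Board,
    target: TargetPattern,
    distractors: list[DistractorPattern],
    profile: SubjectProfile,
    rng: np.random.Generator,
    t0: float = 0.0,
) -> BoardGroundTruth:
    """Sample the ordered dwell sequence and mouse plan for one board.

    ``k ~ Poisson(exec_slowness * len(distractors))`` distractor dwells
    (cells sampled without immediate repetition) are followed by one or
    more dwells on target AOI cells; the final dwell is always on the
    target. Dwell onsets are separated by saccadic gaps of 20-80 ms.
    """
    # dwellable distractor tiles; tiles shared with the target AOI are
    # excluded so every dwell has an unambiguous ground-truth label
    distractor_cells = sorted(
        {c for d in distractors for c in d.cells} - set(target.aoi_cells)
    )
    k = int(rng.poisson(profile.exec_slowness * len(distractors))) if distractor_cells else 0

    cells: list[tuple[str, Cell]] = []
    prev: Cell | None = None
    for _ in range(k):
        options = [c for c in distractor_cells if c != prev] or distractor_cells
        cell = options[int(rng.integers(len(options)))]
        cells.append(("distractor", cell))
        prev = cell

    aoi = sorted(target.aoi_cells)
    n_target = 1 + int(rng.poisson(0.2)) if len(aoi) > 1 else 1
    for _ in range(n_target):
        options = [c for c in aoi if c != prev] or aoi
        cell = options[int(rng.integers(len(options)))]
        cells.append(("target", cell))
        prev = cell

    dwells: list[Dwell] = []
    landings: list[float] = []
    t = t0 + float(rng.uniform(0.10, 0.30))  # orientation delay before first dwell
    prev_gap = 0.0
    for label, cell in cells:
        dur = _truncnorm(
            profile.fixation_duration_mean, profile.fixation_duration_sd, 0.120, rng
        )
        dwells.append(Dwell(label, cell, t, t + dur))
        # gaze lands mid-saccade (ballistic), half the gap before dwell onset
        landings.append(t - prev_gap / 2.0)
        prev_gap = float(rng.uniform(*GAP_RANGE))
        t = t + dur + prev_gap

    first_target = next(
        landing for d, landing in zip(dwells, landings) if d.label == "target"
    )

    # mouse plan: reposition to the swap's first cell, pause, then drag
    last_end = dwells[-1].end
    move_dur = float(rng.uniform(0.3, 0.6))
    drag_dur = float(rng.uniform(0.4, 0.8))
    m0 = max(last_end - move_dur - PRE_DRAG_PAUSE, t0)
    m1 = m0 + move_dur
    # the drag starts only after the hand has arrived and the eyes have
    # settled on the target
    d0 = max(last_end, m1 + PRE_DRAG_PAUSE) + 0.05
    d1 = d0 + drag_dur
    return BoardGroundTruth(
        t0=t0,
        dwells=dwells,
        first_target_time=first_target,
        move_interval=(m0, m1),
        drag_interval=(d0, d1),
        t_end=d1 + 1.0 / NOMINAL_RATE_HZ,
    )


def render_streams(
    truth: BoardGroundTruth,
    board: Board,
    profile: SubjectProfile,
    rng: np.random.Generator,
    screen: tuple[int, int] = SCREEN,
) -> tuple[GazeStream, MouseStream]:
    """Render a ground-truth scanpath into gaze and mouse sample streams.

    Gaze samples run from the first dwell onset to board completion on the
    nominal 120 Hz grid anchored at the board's initiation time; each
    sample sits on the current dwell's tile center (the eyes stay on the
    target during the drag), offset by half the inter-eye separation per
    eye plus isotropic Gaussian noise, and is dropped i.i.d. with
    ``dropout_rate``.
    """
    rate = NOMINAL_RATE_HZ
    dwells = truth.dwells
    centers = np.array([board.layout.cell_center(d.cell) for d in dwells])

    # half-open sample grid [t0, t_end) anchored at board initiation
    n_total = int(math.ceil((truth.t_end - truth.t0) * rate - 1e-9))
    grid_ts = truth.t0 + np.arange(n_total) / rate
    gaze_mask = grid_ts >= dwells[0].start
    ts = grid_ts[gaze_mask]

    # ballistic dwell assignment: switch to the next dwell at the gap midpoint
    switch = np.array([(a.end + b.start) / 2.0 for a, b in zip(dwells, dwells[1:])])
    idx = np.searchsorted(switch, ts, side="right")
    base = centers[idx]

    half = profile.inter_eye_offset / 2.0
    noise = rng.normal(0.0, profile.noise_sd, size=(len(ts), 2, 2))
    left = base + noise[:, 0, :]
    right = base + noise[:, 1, :]
    left[:, 0] -= half
    right[:, 0] += half

    keep = rng.random(len(ts)) >= profile.dropout_rate
    gaze = GazeStream(
        ts[keep], left[keep, 0], left[keep, 1], right[keep, 0], right[keep, 1],
        np.ones(int(keep.sum()), dtype=bool),
    )

    # mouse: idle on the advance button (bottom-right screen corner)
    # -> reposition to the swap tile -> pause -> clicked drag
    start_pos = np.array([screen[0] - 40.0, screen[1] - 40.0])
    mouse_ts = grid_ts
    m0, m1 = truth.move_interval
    d0, d1 = truth.drag_interval
    p_move_to = getattr(truth, "_move_target", None)
    p_drag_to = getattr(truth, "_drag_target", None)
    if p_move_to is None or p_drag_to is None:
        raise ValueError("ground truth lacks mouse path annotations; "
                         "use attach_mouse_path() or simulate_board()")
    pos = np.tile(start_pos, (len(mouse_ts), 1))
    moving = (mouse_ts >= m0) & (mouse_ts < m1)
    frac = ((mouse_ts[moving] - m0) / (m1 - m0))[:, None]
    pos[moving] = start_pos + frac * (p_move_to - start_pos)
    pos[(mouse_ts >= m1) & (mouse_ts < d0)] = p_move_to
    dragging = (mouse_ts >= d0) & (mouse_ts <= d1)
    frac = ((mouse_ts[dragging] - d0) / (d1 - d0))[:, None]
    pos[dragging] = p_move_to + frac * (p_drag_to - p_move_to)
    pos[mouse_ts > d1] = p_drag_to
    mouse = MouseStream(mouse_ts, pos[:, 0], pos[:, 1], dragging)
    return gaze, mouse


def attach_mouse_path(truth: BoardGroundTruth, board: Board, target: TargetPattern) -> None:
    """Annotate ground truth with the pixel endpoints of the solving drag."""
    swap = target.solving_swap
    truth._move_target = np.array(board.layout.cell_center(swap.cell_a))  # type: ignore[attr-defined]
    truth._drag_target = np.array(board.layout.cell_center(swap.cell_b))  # type: ignore[attr-defined]


def simulate_board(
    board: Board,
    target: TargetPattern,
    distractors: list[DistractorPattern],
    profile: SubjectProfile,
    rng: np.random.Generator,
    t0: float = 0.0,
) -> tuple[BoardGroundTruth, GazeStream, MouseStream]:
    """Scanpath sampling plus stream rendering for one board."""
    truth = simulate_board_scanpath(board, target, distractors, profile, rng, t0)
    attach_mouse_path(truth, board, target)
    gaze, mouse = render_streams(truth, board, profile, rng)
    return truth, gaze, mouse


def simulate_subject(profile: SubjectProfile, plan: SessionPlan) -> SubjectSession:
    """Simulate a full session: one gaze/mouse stream pair and one move
    record per board, on a single session clock."""
    from .boards import detect_distractor_patterns

    rng = np.random.default_rng(profile.seed)
    records: list[BoardRecord] = []
    t0 = 0.0
    for level_idx, level in enumerate(plan.levels):
        for (board, target) in level.boards:
            distractors = detect_distractor_patterns(board, target)
            truth, gaze, mouse = simulate_board(
                board, target, distractors, profile, rng, t0
            )
            move = MoveRecord(
                trial_number=level_idx + 1,
                height=board.height,
                width=board.width,
                n_tile_types=board.n_tile_types,
                move_number=1,
                time_to_move=truth.t_end - truth.t0,
                correct=True,
                hint_used=False,
            )
            records.append(
                BoardRecord(
                    board=board, target=target, distractors=distractors,
                    truth=truth, gaze=gaze, mouse=mouse, move=move,
                    level=level_idx + 1, training=level.training,
                )
            )
            t0 = truth.t_end + INTER_BOARD_GAP
    return SubjectSession(profile=profile, records=records)


def cohort_profiles(
    n_subjects: int,
    seed: int,
    slowness_range: tuple[float, float] = (0.05, 0.6),
    tmtb_noise_sd: float = 8.0,
    **overrides,
) -> tuple[list[SubjectProfile], dict[str, float]]:
    """Profiles with exec_slowness coupled to a synthetic TMT-B score.

    Slowness values are evenly spread over ``slowness_range`` and the
    synthetic Trail-Making-B time increases linearly in slowness plus
    Gaussian noise, emulating the executive-function coupling the
    pipeline is meant to recover. Returns (profiles, tmtb by subject id).
    """
    rng = np.random.default_rng(seed)
    lo, hi = slowness_range
    slowness = np.linspace(lo, hi, n_subjects)
    rng.shuffle(slowness)
    profiles, tmtb = [], {}
    for i, s in enumerate(slowness):
        sid = f"S{i + 1:02d}"
        profiles.append(
            SubjectProfile(
                subject_id=sid,
                age=float(rng.uniform(63, 80)),
                exec_slowness=float(s),
                seed=int(rng.integers(2**31 - 1)),
                **overrides,
            )
        )
        tmtb[sid] = float(45.0 + 140.0 * (s - lo) / (hi - lo) + rng.normal(0, tmtb_noise_sd))
    return profiles, tmtb
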