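"""Per-board and per-subject eye-movement and game-performance metrics.

Fixations are classified against the board's areas of interest: the
target pattern's tiles and the recorded distractor-pattern tiles. A
fixation credits one hit per *target* tile whose rectangle intersects a
small tolerance disc around the fixation centroid — a centroid on the
shared edge of two target tiles therefore counts as two fixations on
targets. A fixation that hits no target tile but lies on a distractor
tile counts once on distractors; anything else is "other".

Board metrics derived from the classified fixations and mouse stream:

* **visual search time** — board initiation to the start of the first
  fixation on the target; missing when the board has none;
* **effective search time** — accumulated mouse-movement time (inter-
  sample displacement above a small threshold, or button-held drag),
  ending at the completing drag's release;
* **board completion time** — initiation to correct-move completion;
  summed over boards this is the game completion time.

Per-subject and per-set-size summaries report means and SDs in the same
row layout as per-participant results tables; a mean over a single value
reports an SD of 0, and missing values propagate explicitly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .boards import Board, DistractorPattern, TargetPattern
from .fixations import Fixation, Saccade
from .streams import MouseStream

EDGE_TOL_PX = 5.0
MOVEMENT_THRESHOLD_PX = 2.0

SUBJECT_COLUMNS = [
    "subject",
    "visual_search_time_mean", "visual_search_time_sd",
    "effective_search_time_mean", "effective_search_time_sd",
    "fixations_mean", "fixations_sd",
    "fixations_distractors_mean", "fixations_distractors_sd",
    "fixations_targets_mean", "fixations_targets_sd",
    "saccade_duration_mean", "saccade_duration_sd",
    "saccade_distance_mean", "saccade_distance_sd",
    "game_completion_time",
]


@dataclass(frozen=True)
class AOILabeledFixation:
    fixation: Fixation
    target_hits: int
    distractor_hits: int
    other: bool


@dataclass
class BoardMetrics:
    width: int
    height: int
    visual_search_time: float | None
    effective_search_time: float
    board_completion_time: float
    n_fixations: int
    n_fix_target: int
    n_fix_distractor: int
    n_false_moves: int = 0
    n_hints: int = 0
    saccades: tuple[Saccade, ...] = ()

    def __post_init__(self) -> None:
        if (
            self.visual_search_time is not None
            and self.visual_search_time > self.board_completion_time
        ):
            raise ValueError("visual search time cannot exceed board completion time")


def _disc_intersects_rect(
    cx: float, cy: float, r: float, rect: tuple[float, float, float, float]
) -> bool:
    x0, y0, x1, y1 = rect
    qx = min(max(cx, x0), x1)
    qy = min(max(cy, y0), y1)
    return math.hypot(cx - qx, cy - qy) <= r


def classify_fixation(
    fixation: Fixation,
    board: Board,
    target: TargetPattern,
    distractors: Sequence[DistractorPattern],
    edge_tol: float = EDGE_TOL_PX,
) -> AOILabeledFixation:
    """Label one fixation against target and distractor AOI tiles."""
    cx, cy = fixation.centroid
    board_w = board.width * board.layout.cell_px
    board_h = board.height * board.layout.cell_px
    on_screen = (
        board.layout.origin_x - edge_tol <= cx <= board.layout.origin_x + board_w + edge_tol
        and board.layout.origin_y - edge_tol <= cy <= board.layout.origin_y + board_h + edge_tol
    )
    if not on_screen:
        warnings.warn(
            f"fixation centroid ({cx:.0f}, {cy:.0f}) outside the board area",
            stacklevel=2,
        )
        return AOILabeledFixation(fixation, 0, 0, True)

    target_hits = sum(
        1
        for cell in target.aoi_cells
        if _disc_intersects_rect(cx, cy, edge_tol, board.layout.cell_rect(cell))
    )
    if target_hits:
        return AOILabeledFixation(fixation, target_hits, 0, False)

    distractor_cells = {c for d in distractors for c in d.cells}
    distractor_hit = any(
        _disc_intersects_rect(cx, cy, edge_tol, board.layout.cell_rect(cell))
        for cell in distractor_cells
    )
    if distractor_hit:
        return AOILabeledFixation(fixation, 0, 1, False)
    return AOILabeledFixation(fixation, 0, 0, True)


def visual_search_time(
    board_start_ts: float, labeled: Sequence[AOILabeledFixation]
) -> float | None:
    """Time from board initiation to the first fixation on the target, or
    None when no fixation hit the target."""
    starts = [lf.fixation.start_ts for lf in labeled]
    if any(b < a for a, b in zip(starts, starts[1:])):
        raise ValueError("labeled fixations must be time-ordered")
    for lf in labeled:
        if lf.target_hits > 0:
            return lf.fixation.start_ts - board_start_ts
    return None


def effective_search_time(
    mouse: MouseStream,
    movement_threshold: float = MOVEMENT_THRESHOLD_PX,
) -> float:
    """Accumulated mouse-movement time within a board window.

    An inter-sample interval counts as movement when the displacement
    exceeds ``movement_threshold`` pixels or the button is held (a slow
    drag is still purposeful movement). Accumulation stops at the final
    drag's release when the stream contains clicks.
    """
    if len(mouse) == 0:
        warnings.warn("empty mouse stream; effective search time is 0", stacklevel=2)
        return 0.0
    if len(mouse) == 1:
        return 0.0
    dt = np.diff(mouse.ts)
    disp = np.hypot(np.diff(mouse.x), np.diff(mouse.y))
    moving = (disp > movement_threshold) | mouse.clicked[1:]
    clicked_idx = np.flatnonzero(mouse.clicked)
    if len(clicked_idx):
        moving = moving & (np.arange(1, len(mouse)) <= clicked_idx[-1])
    return float(dt[moving].sum())


def game_completion_time(board_metrics: Sequence[BoardMetrics]) -> float:
    """Total search time across all boards of the session."""
    return float(sum(bm.board_completion_time for bm in board_metrics))


def board_metrics(
    board: Board,
    board_start_ts: float,
    board_end_ts: float,
    labeled: Sequence[AOILabeledFixation],
    saccades: Sequence[Saccade],
    mouse: MouseStream,
    n_false_moves: int = 0,
    n_hints: int = 0,
) -> BoardMetrics:
    """Assemble the per-board metric row from classified events."""
    return BoardMetrics(
        width=board.width,
        height=board.height,
        visual_search_time=visual_search_time(board_start_ts, labeled),
        effective_search_time=effective_search_time(mouse),
        board_completion_time=board_end_ts - board_start_ts,
        n_fixations=len(labeled),
        n_fix_target=sum(lf.target_hits for lf in labeled),
        n_fix_distractor=sum(lf.distractor_hits for lf in labeled),
        n_false_moves=n_false_moves,
        n_hints=n_hints,
        saccades=tuple(saccades),
    )


def _mean_sd(values: list[float]) -> tuple[float, float]:
    """Mean and sample SD over available values; the SD of a single value
    is reported as 0."""
    arr = np.asarray(values, dtype=float)
    if len(arr) == 0:
        return (np.nan, np.nan)
    if len(arr) == 1:
        return (float(arr[0]), 0.0)
    return (float(arr.mean()), float(arr.std(ddof=1)))


def summarize_subject(
    subject: str, per_board: Sequence[BoardMetrics]
) -> pd.Series:
    """One per-subject row of means/SDs across boards plus the game
    completion time, in the per-participant table layout."""
    vst = [bm.visual_search_time for bm in per_board if bm.visual_search_time is not None]
    est = [bm.effective_search_time for bm in per_board]
    nfix = [float(bm.n_fixations) for bm in per_board]
    nfixd = [float(bm.n_fix_distractor) for bm in per_board]
    nfixt = [float(bm.n_fix_target) for bm in per_board]
    sacc = [s for bm in per_board for s in bm.saccades]
    sdur = [s.duration for s in sacc]
    sdist = [s.distance for s in sacc]
    row = {"subject": subject}
    for name, vals in (
        ("visual_search_time", vst),
        ("effective_search_time", est),
        ("fixations", nfix),
        ("fixations_distractors", nfixd),
        ("fixations_targets", nfixt),
        ("saccade_duration", sdur),
        ("saccade_distance", sdist),
    ):
        m, s = _mean_sd(vals)
        row[f"{name}_mean"] = m
        row[f"{name}_sd"] = s
    row["game_completion_time"] = game_completion_time(per_board)
    return pd.Series(row)[SUBJECT_COLUMNS]


def summarize_cohort(per_subject: dict[str, Sequence[BoardMetrics]]) -> pd.DataFrame:
    """Stack per-subject rows into a per-participant metrics table."""
    return pd.DataFrame(
        [summarize_subject(sid, bms) for sid, bms in per_subject.items()]
    ).reset_index(drop=True)


def summarize_by_set_size(board_metrics_list: Sequence[BoardMetrics]) -> pd.DataFrame:
    """Group board metrics by board size ("WxH" label) and report the
    per-group means/SDs of each eye-movement metric."""
    rows = []
    for bm in board_metrics_list:
        rows.append(
            {
                "set_size": f"{bm.width}x{bm.height}",
                "visual_search_time": bm.visual_search_time,
                "effective_search_time": bm.effective_search_time,
                "fixations": bm.n_fixations,
                "fixations_distractors": bm.n_fix_distractor,
                "fixations_targets": bm.n_fix_target,
                "saccade_duration": np.mean([s.duration for s in bm.saccades])
                if bm.saccades else np.nan,
                "saccade_distance": np.mean([s.distance for s in bm.saccades])
                if bm.saccades else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    out = []
    for label, grp in df.groupby("set_size", sort=True):
        row = {"set_size": label}
        for col in df.columns[1:]:
            vals = grp[col].dropna().tolist()
            m, s = _mean_sd(vals)
            row[f"{col}_mean"] = m
            row[f"{col}_sd"] = s
        out.append(row)
    return pd.DataFrame(out)


@dataclass(frozen=True)
class FixationEllipse:
    """Rendering parameters of one fixation: center at the point mean,
    width/height twice the per-axis SD, opacity increasing with duration."""

    center: tuple[float, float]
    width: float
    height: float
    alpha: float


def fixation_ellipse(
    fixation: Fixation, alpha_scale: float = 0.5
) -> FixationEllipse:
    """Ellipse summary of a fixation's member points.

    ``alpha = clip(duration / alpha_scale, (0, 1])`` so shorter fixations
    render more transparent.
    """
    pts = fixation.points[:, 1:3]
    sd = pts.std(axis=0)
    alpha = min(1.0, max(fixation.duration / alpha_scale, 1e-3))
    return FixationEllipse(
        center=(float(pts[:, 0].mean()), float(pts[:, 1].mean())),
        width=2.0 * float(sd[0]),
        height=2.0 * float(sd[1]),
        alpha=alpha,
    )
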