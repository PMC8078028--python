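"""End-to-end session processing: streams in, metric tables out.

Chains the stages for one subject's session — per-board gaze slicing,
fixation extraction, saccade derivation, AOI classification, and board
metric assembly — and aggregates a cohort of sessions into the
per-subject metrics table consumed by the correlation layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .boards import Board, DistractorPattern, TargetPattern, detect_distractor_patterns
from .fixations import (
    Fixation,
    FixationParams,
    InclusionReport,
    compute_saccades,
    extract_fixations,
    subject_inclusion,
)
from .io import SessionBundle, match_streams
from .metrics import AOILabeledFixation, BoardMetrics, board_metrics, classify_fixation, summarize_cohort
from .simulate import SubjectSession
from .streams import GazeStream, MouseStream


@dataclass
class BoardResult:
    metrics: BoardMetrics
    fixations: list[Fixation]
    labeled: list[AOILabeledFixation]


def process_board(
    board: Board,
    target: TargetPattern,
    gaze: GazeStream,
    mouse: MouseStream,
    t0: float,
    t1: float,
    params: FixationParams | None = None,
    distractors: Sequence[DistractorPattern] | None = None,
) -> BoardResult:
    """Extract, classify and summarize the eye/mouse events of one board."""
    if distractors is None:
        distractors = detect_distractor_patterns(board, target)
    fixations = extract_fixations(gaze, params)
    labeled = [classify_fixation(f, board, target, distractors) for f in fixations]
    saccades = compute_saccades(fixations)
    return BoardResult(
        metrics=board_metrics(board, t0, t1, labeled, saccades, mouse),
        fixations=fixations,
        labeled=labeled,
    )


def process_session(
    session: SubjectSession | SessionBundle,
    params: FixationParams | None = None,
    include_training: bool = False,
) -> list[BoardResult]:
    """Per-board results for a simulated session or a loaded bundle.

    Training boards are skipped by default so that metrics cover the test
    block only; bundles do not distinguish training levels and are
    processed in full.
    """
    results = []
    if isinstance(session, SubjectSession):
        for rec in session.records:
            if rec.training and not include_training:
                continue
            results.append(
                process_board(
                    rec.board, rec.target, rec.gaze, rec.mouse,
                    rec.truth.t0, rec.truth.t_end, params, rec.distractors,
                )
            )
    else:
        for win in match_streams(session):
            results.append(
                process_board(
                    win.board, win.target, win.gaze, win.mouse,
                    win.t0, win.t1, params,
                )
            )
    return results


def cohort_metrics(
    sessions: dict[str, SubjectSession | SessionBundle],
    params: FixationParams | None = None,
    min_fixations: int = 10,
    apply_exclusion: bool = True,
) -> tuple[pd.DataFrame, InclusionReport]:
    """Per-subject metrics table for a cohort, with the fixation-count
    inclusion rule applied (subjects with too few recorded fixations are
    dropped from the table, mirroring pilot-study attrition)."""
    per_subject: dict[str, list[BoardMetrics]] = {}
    counts: dict[str, int] = {}
    for sid, session in sessions.items():
        results = process_session(session, params)
        per_subject[sid] = [r.metrics for r in results]
        counts[sid] = sum(len(r.fixations) for r in results)
    report = subject_inclusion(counts, min_fixations=min_fixations)
    kept = report.included if apply_exclusion else tuple(per_subject)
    table = summarize_cohort({sid: per_subject[sid] for sid in kept})
    return table, report
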