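"""Readers and writers for the study's stream formats and table fixtures.

Three plain-text formats carry one recorded session:

* **gaze XML** — root ``<gaze>``, one ``<s/>`` element per sample with
  attributes ``ts`` (seconds), ``lx ly rx ry`` (pixel coordinates, omitted
  for an untracked eye) and ``valid`` (0/1);
* **mouse CSV** — columns ``ts,x,y,clicked``;
* **move-summary CSV** — one row per move: ``trial_number, height, width,
  n_tile_types, move_number, time_to_move, correct, hint_used``.

Timestamps are seconds since session start on one shared clock.
:func:`load_fixtures` returns the packaged per-subject assessment table
(13 records) and per-subject eye-movement metrics table (8 records,
missing cells preserved as NaN).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from .boards import MAX_DIM, MIN_DIM, Board, TargetPattern, Swap
from .streams import SAMPLE_PERIOD, GazeStream, MouseStream


class FormatError(ValueError):
    """Malformed or schema-violating input file."""


class IntegrityError(RuntimeError):
    """Packaged fixture content does not match its recorded checksum."""


# ---------------------------------------------------------------------------
# gaze XML dialect


def write_gaze_xml(stream: GazeStream, path: str | Path) -> None:
    root = etree.Element("gaze")
    for i in range(len(stream)):
        attrs = {"ts": f"{stream.ts[i]:.9f}", "valid": "1" if stream.valid[i] else "0"}
        for name, arr in (
            ("lx", stream.left_x), ("ly", stream.left_y),
            ("rx", stream.right_x), ("ry", stream.right_y),
        ):
            if not np.isnan(arr[i]):
                attrs[name] = f"{arr[i]:.4f}"
        etree.SubElement(root, "s", attrs)
    etree.ElementTree(root).write(str(path), xml_declaration=True, encoding="utf-8")


def read_gaze_xml(path: str | Path) -> GazeStream:
    """Parse a gaze file. A sample missing either eye's coordinates is
    kept but marked invalid; non-monotone timestamps are rejected."""
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"malformed gaze XML in {path}: {exc}") from exc
    root = tree.getroot()
    n = len(root)
    ts = np.empty(n)
    cols = {k: np.full(n, np.nan) for k in ("lx", "ly", "rx", "ry")}
    valid = np.zeros(n, dtype=bool)
    for i, el in enumerate(root):
        try:
            ts[i] = float(el.get("ts"))
        except (TypeError, ValueError) as exc:
            raise FormatError(f"sample {i} in {path} has no numeric ts") from exc
        for k in cols:
            v = el.get(k)
            if v is not None:
                cols[k][i] = float(v)
        flagged = el.get("valid", "1") == "1"
        complete = not any(np.isnan(cols[k][i]) for k in cols)
        valid[i] = flagged and complete
    if n > 1 and np.any(np.diff(ts) <= 0):
        raise FormatError(f"non-monotone timestamps in {path}")
    return GazeStream(ts, cols["lx"], cols["ly"], cols["rx"], cols["ry"], valid)


# ---------------------------------------------------------------------------
# mouse CSV


def write_mouse_csv(stream: MouseStream, path: str | Path) -> None:
    df = stream.to_frame()
    df["clicked"] = df["clicked"].astype(int)
    df.to_csv(path, index=False, float_format="%.9f")


def read_mouse_csv(path: str | Path) -> MouseStream:
    df = pd.read_csv(path)
    missing = {"ts", "x", "y", "clicked"} - set(df.columns)
    if missing:
        raise FormatError(f"mouse CSV {path} missing columns: {sorted(missing)}")
    return MouseStream(
        df["ts"].to_numpy(float),
        df["x"].to_numpy(float),
        df["y"].to_numpy(float),
        df["clicked"].to_numpy().astype(bool),
    )


# ---------------------------------------------------------------------------
# move summary


@dataclass(frozen=True)
class MoveRecord:
    """One entry of the per-session move summary file."""

    trial_number: int
    height: int
    width: int
    n_tile_types: int
    move_number: int
    time_to_move: float
    correct: bool
    hint_used: bool

    def __post_init__(self) -> None:
        if not (MIN_DIM <= self.width <= MAX_DIM and MIN_DIM <= self.height <= MAX_DIM):
            raise FormatError(
                f"board dimensions out of range: {self.width}x{self.height}"
            )
        if self.move_number < 1:
            raise FormatError("move_number must be >= 1")


MOVE_COLUMNS = [
    "trial_number", "height", "width", "n_tile_types",
    "move_number", "time_to_move", "correct", "hint_used",
]


def write_move_summary(moves: list[MoveRecord], path: str | Path) -> None:
    df = pd.DataFrame([vars(m) for m in moves], columns=MOVE_COLUMNS)
    df["correct"] = df["correct"].astype(int)
    df["hint_used"] = df["hint_used"].astype(int)
    df.to_csv(path, index=False, float_format="%.9f")


def read_move_summary(path: str | Path) -> list[MoveRecord]:
    df = pd.read_csv(path)
    missing = set(MOVE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"move summary {path} missing columns: {sorted(missing)}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                MoveRecord(
                    int(row.trial_number), int(row.height), int(row.width),
                    int(row.n_tile_types), int(row.move_number),
                    float(row.time_to_move), bool(row.correct), bool(row.hint_used),
                )
            )
        except FormatError as exc:
            raise FormatError(f"{path} row {i}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# packaged fixtures (per-subject assessment scores and eye-movement metrics)

_FIXTURE_SHA256 = {
    "table1_assessments.csv": "384cf135e2523d6c11b7e3ac6fa4eb8b468d8b8488e6cc484e89e24567aaf684",
    "table2_eye_metrics.csv": "a0fc972c394f7da1ff7657aa29b55cc9a89f98fe7746b295db2c9f45393cafb9",
}


def _fixture_bytes(name: str) -> bytes:
    data = (resources.files("smtgaze") / "data" / name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise IntegrityError(
            f"fixture {name} checksum mismatch: got {digest}"
        )
    return data


def load_fixtures() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Packaged per-subject tables: (assessments, eye-movement metrics).

    Assessments hold 13 subjects (age, gender, glasses, MoCA, TMT-A/B,
    SnMT, IADL); metrics hold the 8 subjects retained after data
    exclusion, with unavailable cells as NaN.
    """
    import io as _io

    assessments = pd.read_csv(_io.BytesIO(_fixture_bytes("table1_assessments.csv")))
    metrics = pd.read_csv(_io.BytesIO(_fixture_bytes("table2_eye_metrics.csv")))
    return assessments, metrics


# ---------------------------------------------------------------------------
# session bundles


@dataclass
class SessionBundle:
    """All recorded data of one subject's session on one clock."""

    subject_id: str
    gaze: GazeStream
    mouse: MouseStream
    moves: list[MoveRecord]
    boards: list[tuple[Board, TargetPattern]]
    board_windows: list[tuple[float, float]]  # (initiation, completion) per board
    meta: dict = field(default_factory=dict)


@dataclass
class BoardWindowData:
    """Per-board aligned slice of a session bundle."""

    index: int
    t0: float
    t1: float
    board: Board
    target: TargetPattern
    gaze: GazeStream
    mouse: MouseStream
    no_gaze: bool


def write_session(bundle: SessionBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_gaze_xml(bundle.gaze, out / "gaze.xml")
    write_mouse_csv(bundle.mouse, out / "mouse.csv")
    write_move_summary(bundle.moves, out / "moves.csv")
    boards = []
    for (board, target) in bundle.boards:
        boards.append(
            {
                "board": board.to_dict(),
                "target": {
                    "swap": [list(target.solving_swap.cell_a), list(target.solving_swap.cell_b)],
                    "match_cells": [list(c) for c in target.match_cells],
                    "aoi_cells": sorted(list(c) for c in target.aoi_cells),
                },
            }
        )
    meta = dict(bundle.meta)
    meta.update(
        {
            "subject_id": bundle.subject_id,
            "board_windows": [list(w) for w in bundle.board_windows],
        }
    )
    (out / "boards.json").write_text(json.dumps(boards))
    (out / "meta.json").write_text(json.dumps(meta, indent=1))


def read_session(session_dir: str | Path) -> SessionBundle:
    d = Path(session_dir)
    meta = json.loads((d / "meta.json").read_text())
    raw_boards = json.loads((d / "boards.json").read_text())
    boards = []
    for item in raw_boards:
        board = Board.from_dict(item["board"])
        t = item["target"]
        swap = Swap(tuple(t["swap"][0]), tuple(t["swap"][1]))
        target = TargetPattern(
            solving_swap=swap,
            match_cells=tuple(tuple(c) for c in t["match_cells"]),
            aoi_cells=frozenset(tuple(c) for c in t["aoi_cells"]),
        )
        boards.append((board, target))
    return SessionBundle(
        subject_id=meta["subject_id"],
        gaze=read_gaze_xml(d / "gaze.xml"),
        mouse=read_mouse_csv(d / "mouse.csv"),
        moves=read_move_summary(d / "moves.csv"),
        boards=boards,
        board_windows=[tuple(w) for w in meta["board_windows"]],
        meta=meta,
    )


def _drag_releases(mouse: MouseStream) -> np.ndarray:
    """Timestamps at which a clicked run ends (mouse-button release)."""
    c = mouse.clicked.astype(int)
    if len(c) == 0:
        return np.empty(0)
    ends = np.flatnonzero(np.diff(np.append(c, 0)) == -1)
    return mouse.ts[ends]


def match_streams(bundle: SessionBundle, offset_tolerance: float = 2 * SAMPLE_PERIOD
                  ) -> list[BoardWindowData]:
    """Split the session streams into per-board windows by timestamp.

    Windows must be non-overlapping and sorted. Boards without any gaze
    sample are flagged ``no_gaze``. If the drag-release events of the
    mouse stream are systematically shifted against the board windows a
    clock-offset warning with the measured median offset is emitted.
    """
    windows = bundle.board_windows
    if len(windows) != len(bundle.boards):
        raise FormatError("one board window required per board")
    for (a0, a1), (b0, b1) in zip(windows, windows[1:]):
        if b0 < a1:
            raise FormatError(f"overlapping board windows: ({a0}, {a1}) and ({b0}, {b1})")

    releases = _drag_releases(bundle.mouse)
    if len(releases) == len(windows) and len(windows) > 0:
        offsets = releases - np.array([w[1] for w in windows])
        med = float(np.median(offsets))
        if abs(med) > offset_tolerance:
            warnings.warn(
                f"mouse stream appears clock-shifted against board windows "
                f"by {med:+.4f} s",
                stacklevel=2,
            )

    out = []
    for i, ((t0, t1), (board, target)) in enumerate(zip(windows, bundle.boards)):
        gaze = bundle.gaze.slice(t0, t1)
        mouse = bundle.mouse.slice(t0, t1)
        out.append(
            BoardWindowData(
                index=i, t0=t0, t1=t1, board=board, target=target,
                gaze=gaze, mouse=mouse, no_gaze=len(gaze) == 0,
            )
        )
    return out
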