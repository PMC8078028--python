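"""In-memory containers for 120 Hz binocular gaze and mouse sample streams.

Both streams are stored as flat numpy arrays (one entry per sample) with
strictly increasing timestamps in seconds on a single session clock.
A gaze sample is *valid* only when both eyes were tracked; invalid
samples keep their timestamp but carry NaN coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NOMINAL_RATE_HZ = 120.0
SAMPLE_PERIOD = 1.0 / NOMINAL_RATE_HZ


class StreamError(ValueError):
    """Malformed stream input (non-monotone timestamps, ragged arrays)."""


def _as_f64(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


@dataclass
class GazeStream:
    """Timestamped left/right eye screen coordinates at nominally 120 Hz."""

    ts: np.ndarray
    left_x: np.ndarray
    left_y: np.ndarray
    right_x: np.ndarray
    right_y: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.ts = _as_f64(self.ts)
        self.left_x = _as_f64(self.left_x)
        self.left_y = _as_f64(self.left_y)
        self.right_x = _as_f64(self.right_x)
        self.right_y = _as_f64(self.right_y)
        if self.valid is None:
            self.valid = ~(
                np.isnan(self.left_x)
                | np.isnan(self.left_y)
                | np.isnan(self.right_x)
                | np.isnan(self.right_y)
            )
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.ts)
        for arr in (self.left_x, self.left_y, self.right_x, self.right_y, self.valid):
            if len(arr) != n:
                raise StreamError("gaze stream arrays must have equal length")
        if n > 1 and np.any(np.diff(self.ts) <= 0):
            raise StreamError("gaze timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.ts)

    @property
    def combined_x(self) -> np.ndarray:
        """Per-sample mean of left and right eye x."""
        return (self.left_x + self.right_x) / 2.0

    @property
    def combined_y(self) -> np.ndarray:
        return (self.left_y + self.right_y) / 2.0

    def slice(self, t0: float, t1: float) -> "GazeStream":
        """Samples with ``t0 <= ts < t1``."""
        m = (self.ts >= t0) & (self.ts < t1)
        return GazeStream(
            self.ts[m], self.left_x[m], self.left_y[m],
            self.right_x[m], self.right_y[m], self.valid[m],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ts": self.ts,
                "left_x": self.left_x,
                "left_y": self.left_y,
                "right_x": self.right_x,
                "right_y": self.right_y,
                "valid": self.valid,
            }
        )

    @classmethod
    def empty(cls) -> "GazeStream":
        z = np.empty(0)
        return cls(z, z, z, z, z, np.empty(0, dtype=bool))

    @classmethod
    def concatenate(cls, parts: list["GazeStream"]) -> "GazeStream":
        if not parts:
            return cls.empty()
        return cls(
            np.concatenate([p.ts for p in parts]),
            np.concatenate([p.left_x for p in parts]),
            np.concatenate([p.left_y for p in parts]),
            np.concatenate([p.right_x for p in parts]),
            np.concatenate([p.right_y for p in parts]),
            np.concatenate([p.valid for p in parts]),
        )


@dataclass
class MouseStream:
    """Timestamped mouse positions with a clicked (button-down) flag."""

    ts: np.ndarray
    x: np.ndarray
    y: np.ndarray
    clicked: np.ndarray

    def __post_init__(self) -> None:
        self.ts = _as_f64(self.ts)
        self.x = _as_f64(self.x)
        self.y = _as_f64(self.y)
        self.clicked = np.asarray(self.clicked, dtype=bool)
        n = len(self.ts)
        for arr in (self.x, self.y, self.clicked):
            if len(arr) != n:
                raise StreamError("mouse stream arrays must have equal length")
        if n > 1 and np.any(np.diff(self.ts) <= 0):
            raise StreamError("mouse timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.ts)

    def slice(self, t0: float, t1: float) -> "MouseStream":
        m = (self.ts >= t0) & (self.ts < t1)
        return MouseStream(self.ts[m], self.x[m], self.y[m], self.clicked[m])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"ts": self.ts, "x": self.x, "y": self.y, "clicked": self.clicked})

    @classmethod
    def empty(cls) -> "MouseStream":
        z = np.empty(0)
        return cls(z, z, z, np.empty(0, dtype=bool))

    @classmethod
    def concatenate(cls, parts: list["MouseStream"]) -> "MouseStream":
        if not parts:
            return cls.empty()
        return cls(
            np.concatenate([p.ts for p in parts]),
            np.concatenate([p.x for p in parts]),
            np.concatenate([p.y for p in parts]),
            np.concatenate([p.clicked for p in parts]),
        )
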