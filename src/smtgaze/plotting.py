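"""Fixation-overlay rendering on puzzle boards.

Draws the tile grid, highlights the target region of interest, and
overlays each fixation as an ellipse centered on the mean of its member
points with width/height twice the per-axis SD; opacity encodes duration
(the more transparent, the shorter the fixation).
"""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
from matplotlib.patches import Ellipse, Rectangle

from .boards import Board, TargetPattern
from .fixations import Fixation
from .metrics import fixation_ellipse


def plot_board_fixations(
    board: Board,
    target: TargetPattern,
    fixations: Sequence[Fixation],
    path: str | None = None,
    ax: "plt.Axes | None" = None,
):
    """Render a board with its target AOI and fixation ellipses."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    cmap = plt.get_cmap("tab10")
    for r in range(board.height):
        for c in range(board.width):
            x0, y0, x1, y1 = board.layout.cell_rect((r, c))
            ax.add_patch(
                Rectangle(
                    (x0, y0), x1 - x0, y1 - y0,
                    facecolor=cmap(int(board.grid[r, c]) % 10),
                    edgecolor="white", alpha=0.35,
                )
            )
    for cell in target.aoi_cells:
        x0, y0, x1, y1 = board.layout.cell_rect(cell)
        ax.add_patch(
            Rectangle(
                (x0, y0), x1 - x0, y1 - y0,
                facecolor="turquoise", edgecolor="teal", alpha=0.45,
            )
        )
    for fix in fixations:
        ell = fixation_ellipse(fix)
        ax.add_patch(
            Ellipse(
                ell.center, max(ell.width, 2.0), max(ell.height, 2.0),
                facecolor="black", alpha=ell.alpha,
            )
        )
    x0, y0, _, _ = board.layout.cell_rect((0, 0))
    _, _, x1, y1 = board.layout.cell_rect((board.height - 1, board.width - 1))
    pad = board.layout.cell_px
    ax.set_xlim(x0 - pad, x1 + pad)
    ax.set_ylim(y1 + pad, y0 - pad)  # screen y grows downward
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    ax.set_aspect("equal")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
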