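"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (exhaustive window scans, full grid
copies, residual regressions) and shares no code with the package paths
it verifies.
"""

from __future__ import annotations

import numpy as np


def naive_matches(grid: np.ndarray) -> set:
    """Every identical 3-window, by exhaustive row/column window scan."""
    h, w = grid.shape
    out = set()
    for r in range(h):
        for c in range(w - 2):
            if grid[r, c] == grid[r, c + 1] == grid[r, c + 2]:
                out.add(((r, c), (r, c + 1), (r, c + 2)))
    for c in range(w):
        for r in range(h - 2):
            if grid[r, c] == grid[r + 1, c] == grid[r + 2, c]:
                out.add(((r, c), (r + 1, c), (r + 2, c)))
    return out


def naive_solving_swaps(grid: np.ndarray) -> list:
    """All adjacent swaps that create a match, each tried on a fresh copy."""
    h, w = grid.shape
    out = []
    for r in range(h):
        for c in range(w):
            for dr, dc in ((0, 1), (1, 0)):
                r2, c2 = r + dr, c + dc
                if r2 >= h or c2 >= w:
                    continue
                g = grid.copy()
                g[r, c], g[r2, c2] = g[r2, c2], g[r, c]
                if naive_matches(g):
                    out.append(((r, c), (r2, c2)))
    return out


def naive_distractor_pairs(grid: np.ndarray, aoi: set) -> set:
    """Same-type adjacent and gapped pairs not fully inside the AOI."""
    h, w = grid.shape
    out = set()
    for r in range(h):
        for c in range(w):
            for dr, dc in ((0, 1), (1, 0)):
                r2, c2 = r + dr, c + dc
                if r2 < h and c2 < w and grid[r, c] == grid[r2, c2]:
                    if not {(r, c), (r2, c2)} <= aoi:
                        out.add((((r, c), (r2, c2)), "adjacent-pair"))
            for dr, dc in ((0, 2), (2, 0)):
                r2, c2 = r + dr, c + dc
                mid = (r + dr // 2, c + dc // 2)
                if (
                    r2 < h and c2 < w
                    and grid[r, c] == grid[r2, c2]
                    and grid[mid] != grid[r, c]
                    and not {(r, c), (r2, c2)} <= aoi
                ):
                    out.add((((r, c), (r2, c2)), "gapped-pair"))
    return out


def check_fixation_constraints(ts, left, right, params) -> list[str]:
    """Re-check the five selection constraints on a candidate cluster from
    its raw member samples; returns the names of violated constraints."""
    ts = np.asarray(ts, float)
    left = np.asarray(left, float)
    right = np.asarray(right, float)
    comb = (left + right) / 2.0
    violated = []
    if ts[-1] - ts[0] < params.min_duration:
        violated.append("min_duration")
    if len(ts) < params.min_points:
        violated.append("min_points")
    steps = np.hypot(np.diff(comb[:, 0]), np.diff(comb[:, 1]))
    if np.any(steps >= params.max_step):
        violated.append("max_step")
    lc, rc = left.mean(axis=0), right.mean(axis=0)
    if np.hypot(*(lc - rc)) > params.max_inter_eye:
        violated.append("max_inter_eye")
    sd = np.sqrt(comb.var(axis=0).mean())
    if sd > params.max_position_sd:
        violated.append("max_position_sd")
    return violated


def midrank(values: np.ndarray) -> np.ndarray:
    """Average ranks computed by explicit sorting (no scipy)."""
    values = np.asarray(values, float)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_oracle(x, y) -> float:
    """Pearson correlation of explicitly computed mid-ranks."""
    rx, ry = midrank(x), midrank(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def partial_corr_residualized(x, y, z) -> float:
    """Partial correlation via explicit residual regressions on z."""
    x, y, z = (np.asarray(v, float) for v in (x, y, z))
    zc = np.column_stack((np.ones(len(z)), z))
    rx = x - zc @ np.linalg.lstsq(zc, x, rcond=None)[0]
    ry = y - zc @ np.linalg.lstsq(zc, y, rcond=None)[0]
    return float(np.corrcoef(rx, ry)[0, 1])
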