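"""Rank-based correlation layer for eye-movement vs assessment scores.

Small-cohort correlation analysis as used for exploratory eye-tracking
pilots: tie-corrected Spearman coefficients (Pearson on mid-ranks) with
two-sided p-values from the t approximation, first-order partial
correlations controlling for one covariate, an effect-size companion in
the Cramér-V form, and per-column descriptive summaries. Significance is
flagged at alpha = 0.05 with no multiple-testing adjustment (exploratory
analysis); missing values are removed pairwise so each pair reports its
own n.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


class CorrelationError(ValueError):
    """Undefined or degenerate correlation input."""


@dataclass(frozen=True)
class CorrelationResult:
    x_name: str
    y_name: str
    rho: float
    p_value: float
    n: int
    effect_size_v: float
    method: str  # "spearman" | "partial-spearman" | "partial-pearson"

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    def rounded(self, rho_dp: int = 2, p_dp: int = 3) -> tuple[float, float]:
        return (round(self.rho, rho_dp), round(self.p_value, p_dp))


def _pairwise_complete(*cols: Sequence[float]) -> list[np.ndarray]:
    arrs = [np.asarray(c, dtype=float) for c in cols]
    n = {len(a) for a in arrs}
    if len(n) != 1:
        raise CorrelationError("input vectors must have equal length")
    mask = ~np.any([np.isnan(a) for a in arrs], axis=0)
    return [a[mask] for a in arrs]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise CorrelationError("correlation undefined for a constant vector")
    r = ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
    return float(np.clip(r, -1.0, 1.0))


def _t_pvalue(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def _permutation_pvalue(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Exact two-sided permutation p for tiny n (all n! orderings)."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    count, total = 0, 0
    for perm in itertools.permutations(range(len(ry))):
        r = _pearson(rx, ry[list(perm)])
        total += 1
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
    return count / total


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    x_name: str = "x",
    y_name: str = "y",
    p_method: str = "t",
) -> CorrelationResult:
    """Tie-corrected Spearman correlation of two numeric vectors.

    rho is the Pearson correlation of mid-ranks (average ranks for ties);
    missing values are deleted pairwise. The two-sided p-value uses the
    t approximation by default; ``p_method="permutation"`` runs the exact
    permutation test (only sensible for n <= 9).
    """
    xv, yv = _pairwise_complete(x, y)
    if len(xv) < 3:
        raise CorrelationError(f"need at least 3 complete pairs, got {len(xv)}")
    rho = _pearson(sps.rankdata(xv), sps.rankdata(yv))
    if p_method == "permutation":
        p = _permutation_pvalue(xv, yv, rho)
    else:
        p = _t_pvalue(rho, len(xv))
    return CorrelationResult(
        x_name, y_name, rho, p, len(xv), cramers_v(rho, len(xv)), "spearman"
    )


def partial_correlation(
    x: Sequence[float],
    y: Sequence[float],
    covariate: Sequence[float],
    method: str = "spearman",
    x_name: str = "x",
    y_name: str = "y",
) -> CorrelationResult:
    """First-order partial correlation of x and y controlling for one
    covariate z:

        r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))

    with the three pairwise r's computed rank-based (``method="spearman"``)
    or product-moment (``method="pearson"``). The p-value uses the t
    approximation with n - 3 degrees of freedom.
    """
    xv, yv, zv = _pairwise_complete(x, y, covariate)
    if len(xv) < 4:
        raise CorrelationError(f"need at least 4 complete triples, got {len(xv)}")
    if method == "spearman":
        xv, yv, zv = (sps.rankdata(v) for v in (xv, yv, zv))
    elif method != "pearson":
        raise ValueError(f"unknown method: {method!r}")
    r_xy = _pearson(xv, yv)
    r_xz = _pearson(xv, zv)
    r_yz = _pearson(yv, zv)
    denom = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    if denom <= 1e-12:
        raise CorrelationError("covariate is perfectly correlated with an input")
    rho = (r_xy - r_xz * r_yz) / math.sqrt(denom)
    n = len(xv)
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 3) / (1.0 - rho * rho))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 3))
    return CorrelationResult(
        x_name, y_name, rho, p, n, cramers_v(rho, n), f"partial-{method}"
    )


def cramers_v(rho: float, n: int, df_min: int = 1) -> float:
    """Cramér-V-form effect size derived from a correlation coefficient.

    Taking chi-squared = n * rho**2 with one degree of freedom gives
    V = sqrt(chi2 / (n * df_min)) = |rho|. This association-strength
    reading is an interpretation — a correlation has no unique
    contingency-table equivalent — so the computation is isolated here
    and overridable via ``df_min``; it is monotone in |rho| and zero at
    rho = 0, and reported alongside rho and p without altering either.
    """
    if abs(rho) > 1:
        raise CorrelationError("|rho| cannot exceed 1")
    chi2 = n * rho * rho
    return float(math.sqrt(chi2 / (n * df_min)))


def descriptives(table: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """Per-column mean, sample SD (n-1), and min-max range, excluding
    missing values column-wise."""
    rows = []
    for col in columns:
        vals = table[col].dropna().astype(float)
        if len(vals) == 0:
            raise CorrelationError(f"column {col!r} has no non-missing values")
        rows.append(
            {
                "column": col,
                "n": int(len(vals)),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "min": float(vals.min()),
                "max": float(vals.max()),
            }
        )
    return pd.DataFrame(rows)


def correlation_table(
    subject_metrics: pd.DataFrame,
    assessments: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    alpha: float = 0.05,
    on: str = "subject",
) -> pd.DataFrame:
    """One Spearman result per requested (metric, assessment) column pair.

    Tables are merged on the subject id (inner join: only subjects present
    in both, i.e. those retained after exclusion). Pairwise deletion gives
    each pair its own n. Deliberately applies no multiple-testing
    correction; the significance flag marks p < alpha.
    """
    merged = subject_metrics.merge(assessments, on=on, suffixes=("", "_assessment"))
    rows = []
    for x_col, y_col in pairs:
        for col in (x_col, y_col):
            if col not in merged.columns:
                raise KeyError(f"unknown column in pair: {col!r}")
        res = spearman(merged[x_col], merged[y_col], x_name=x_col, y_name=y_col)
        rows.append(
            {
                "x": x_col,
                "y": y_col,
                "rho": res.rho,
                "p_value": res.p_value,
                "n": res.n,
                "effect_size_v": res.effect_size_v,
                "significant": res.p_value < alpha,
            }
        )
    return pd.DataFrame(rows)
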