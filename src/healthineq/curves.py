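"""Concentration-curve ordinates and dominance testing against equality.

The concentration curve L(p) plots the cumulative weighted share of the
health variable held by the poorest fraction p of children.  Perfect
equality is the 45-degree line L(p) = p; a curve above the line means the
outcome is concentrated among the poor, below the line among the rich.

Dominance against the line of equality is decided by the multiple
comparison approach (mca): per-point z statistics for L(p) − p at a grid of
quantile points (default 19 points, 0.05..0.95) against a critical value
adjusted for the number of comparisons (Šidák by default).  Verdicts:

* ``curve_dominates``  — at least one significant positive difference, none
  negative;
* ``line_dominates``   — the mirror case;
* ``crossing``         — significant differences of both signs;
* ``non_dominance``    — no significant difference at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .exceptions import DegenerateVarianceError, UndefinedIndexError

DEFAULT_GRID = np.round(np.linspace(0.05, 0.95, 19), 10)

VERDICT_CURVE = "curve_dominates"
VERDICT_LINE = "line_dominates"
VERDICT_NONE = "non_dominance"
VERDICT_CROSS = "crossing"


@dataclass
class CurveOrdinates:
    """Concentration-curve ordinates on a quantile grid.

    ``p`` holds interior grid points; ``with_endpoints()`` appends the exact
    endpoints L(0)=0 and L(1)=1 for plotting.
    """

    p: np.ndarray
    L: np.ndarray
    se: np.ndarray
    outcome: str = ""

    def with_endpoints(self):
        p = np.concatenate(([0.0], self.p, [1.0]))
        L = np.concatenate(([0.0], self.L, [1.0]))
        return p, L

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"p": self.p, "L": self.L, "se": self.se})


@dataclass
class DominanceResult:
    """Outcome of the mca dominance test against the 45-degree line."""

    verdict: str
    z: np.ndarray
    critical_value: float
    alpha: float
    n_points: int
    adjustment: str
    rule: str = "mca"
    significant_positive: int = 0
    significant_negative: int = 0

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "rule": self.rule,
            "alpha": self.alpha,
            "n_points": self.n_points,
            "adjustment": self.adjustment,
            "critical_value": self.critical_value,
            "significant_positive": self.significant_positive,
            "significant_negative": self.significant_negative,
        }


def curve_ordinates(h, r, w, grid=None, psu=None, outcome: str = "") -> CurveOrdinates:
    """Concentration-curve ordinates L(p) with per-ordinate standard errors.

    The empirical curve linearly interpolates the step points
    (cumulative weight share, cumulative outcome share) after sorting by
    rank; L(p) is read off at each grid point.  The SE is the
    influence-function (linearization) standard error of the cumulative
    share ratio, optionally aggregated within PSUs first.

    Parameters
    ----------
    h, r, w : array-like
        Outcome, fractional wealth ranks, weights.
    grid : array-like, optional
        Interior quantile points; default 19 points 0.05..0.95.
    psu : array-like, optional
        Cluster ids for cluster-aggregated SEs.
    """
    h = np.asarray(h, dtype=float)
    r = np.asarray(r, dtype=float)
    w = np.asarray(w, dtype=float)
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("grid points must lie strictly inside (0, 1)")

    total_wh = float(np.sum(w * h))
    if total_wh == 0:
        raise UndefinedIndexError("curve undefined: weighted outcome total is 0")
    total_w = float(np.sum(w))

    order = np.argsort(r, kind="stable")
    cum_w = np.cumsum(w[order]) / total_w
    cum_wh = np.cumsum((w * h)[order]) / total_wh
    L = np.interp(grid, np.concatenate(([0.0], cum_w)), np.concatenate(([0.0], cum_wh)))

    # IF variance of L = A/B with A = Σ w h 1[below p], B = Σ w h:
    # psi_i = w_i (h_i a_i − L h_i) / B, Var ≈ Σ psi_i², clusters summed first.
    se = np.empty_like(grid)
    w_sorted, h_sorted = w[order], h[order]
    if psu is not None:
        _, psu_inv = np.unique(np.asarray(psu)[order], return_inverse=True)
    for j, (pj, Lj) in enumerate(zip(grid, L)):
        # a record is "below p" if its cumulative weight share is within p
        below = cum_w <= pj + 1e-12
        psi = (w_sorted * (h_sorted * below - Lj * h_sorted)) / total_wh
        if psu is not None:
            psi = np.bincount(psu_inv, weights=psi)
        se[j] = np.sqrt(np.sum(psi**2))
    return CurveOrdinates(grid, L, se, outcome)


def _per_point_alpha(alpha: float, k: int, adjustment: str) -> float:
    if adjustment == "none":
        return alpha
    if adjustment == "sidak":
        return 1.0 - (1.0 - alpha) ** (1.0 / k)
    if adjustment == "bonferroni":
        return alpha / k
    raise ValueError(f"unknown adjustment {adjustment!r}")


def dominance_test(curve: CurveOrdinates, alpha: float = 0.05, adjustment: str = "sidak") -> DominanceResult:
    """mca dominance verdict of a concentration curve vs the equality line.

    Per-point z = (L(p) − p) / se(p) compared with the two-sided normal
    critical value at the multiplicity-adjusted level.  A point with zero SE
    and zero difference contributes z = 0; zero SE with a nonzero
    difference is a degenerate-variance error.
    """
    diff = curve.L - curve.p
    se = curve.se
    bad = (se == 0) & (diff != 0)
    if np.any(bad):
        raise DegenerateVarianceError(
            f"zero ordinate SE with nonzero difference at p={curve.p[bad]}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, diff / se, 0.0)
    k = len(curve.p)
    crit = float(norm.ppf(1.0 - _per_point_alpha(alpha, k, adjustment) / 2.0))
    n_pos = int(np.sum(z > crit))
    n_neg = int(np.sum(z < -crit))
    if n_pos and n_neg:
        verdict = VERDICT_CROSS
    elif n_pos:
        verdict = VERDICT_CURVE
    elif n_neg:
        verdict = VERDICT_LINE
    else:
        verdict = VERDICT_NONE
    return DominanceResult(verdict, z, crit, alpha, k, adjustment, "mca", n_pos, n_neg)


def plot_concentration_curves(curves, path=None, title: str = "Concentration curves"):
    """Plot one or more concentration curves against the 45-degree line.

    Returns the matplotlib Figure; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 5.5))
    ax.plot([0, 1], [0, 1], "k--", lw=1, label="line of equality")
    for curve in np.atleast_1d(curves):
        p, L = curve.with_endpoints()
        ax.plot(p, L, lw=1.6, label=curve.outcome or "outcome")
    ax.set_xlabel("cumulative share of children, poorest to richest")
    ax.set_ylabel("cumulative share of outcome")
    ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
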