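"""Weighted fractional socioeconomic ranks and wealth quintiles.

The fractional rank :math:`R_i` places each child in (0, 1) by household
wealth, weighting by survey weight: after sorting by wealth score,

.. math:: R_i = \\frac{\\sum_{j<i} w_j + w_i/2}{\\sum_j w_j}

(midpoint form).  Records with tied wealth scores are treated as one block
and share the block's midpoint rank, which equals the weighted average of
their individual midpoints.  Midpoint ranks make the weighted mean rank
exactly 0.5, the normalization the concentration index presumes.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ConfigurationError

_QUINTILE_CUTS = np.array([0.2, 0.4, 0.6, 0.8])


def _check_weights(w: np.ndarray) -> float:
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    total = float(w.sum())
    if total <= 0:
        raise ValueError("total weight must be positive")
    return total


def fractional_rank(wealth_score, w) -> np.ndarray:
    """Weighted midpoint fractional ranks in (0, 1), ties sharing one rank.

    Parameters
    ----------
    wealth_score : array-like
        Ordering key (household wealth index score).  Any strictly
        increasing transform yields identical ranks.
    w : array-like
        Nonnegative weights with positive total.

    Returns
    -------
    numpy.ndarray
        Rank per record, aligned with the input order.
    """
    x = np.asarray(wealth_score, dtype=float)
    w = np.asarray(w, dtype=float)
    if x.shape != w.shape:
        raise ValueError("wealth_score and weights must have equal length")
    total = _check_weights(w)

    order = np.argsort(x, kind="stable")
    xs, ws = x[order], w[order]
    # collapse tie blocks: one midpoint rank per distinct score
    _, block_start, block_id = np.unique(xs, return_index=True, return_inverse=True)
    block_w = np.bincount(block_id, weights=ws)
    cum_before = np.concatenate(([0.0], np.cumsum(block_w)[:-1]))
    block_rank = (cum_before + block_w / 2.0) / total

    ranks_sorted = block_rank[block_id]
    ranks = np.empty_like(ranks_sorted)
    ranks[order] = ranks_sorted
    return ranks


def assign_quintiles(wealth_score, w) -> np.ndarray:
    """Weighted wealth quintiles 1..5 with cut points at ranks 0.2..0.8.

    A tie block is assigned whole to the quintile containing its midpoint
    rank, so ties never straddle two quintiles.
    """
    r = fractional_rank(wealth_score, w)
    return quintiles_from_ranks(r)


def quintiles_from_ranks(ranks) -> np.ndarray:
    r = np.asarray(ranks, dtype=float)
    return (np.searchsorted(_QUINTILE_CUTS, r, side="left") + 1).astype(int)


def ranks_from_quintiles(quintile, w) -> np.ndarray:
    """Fractional ranks when only quintile labels are available.

    Each quintile group gets the midpoint of its weighted share band, i.e.
    the same block-midpoint rule applied with the quintile as the ordering
    key.
    """
    q = np.asarray(quintile)
    if not np.all(np.isin(q[~np.isnan(q.astype(float))], [1, 2, 3, 4, 5])):
        raise ConfigurationError("quintile labels must be in 1..5")
    return fractional_rank(q.astype(float), w)
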