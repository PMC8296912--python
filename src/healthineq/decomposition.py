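"""Regression-based decomposition of the Erreygers index.

For a binary outcome modelled by a linear probability model
``y = a + Σ_k β_k x_k + ε`` (weighted least squares, the same survey
weights as the index), the Erreygers index decomposes exactly as

.. math:: ENCI = 4\\,\\Big[\\sum_k (\\beta_k \\bar x_k)\\, CI_k\\Big] + R

where :math:`CI_k` is the (unnormalized) concentration index of covariate
:math:`x_k` against the wealth rank, :math:`\\beta_k \\bar x_k` is the
covariate's *elasticity*, and the residual :math:`R = 4\\,GC_\\varepsilon`
is four times the generalized concentration index of the regression error.
Each term ``4 · elasticity · CI_k`` is the covariate's absolute
contribution; percent contributions divide by the total ENCI.

The identity is algebraic: it holds to machine precision whenever the
regression, the covariate indices, and the ENCI share one set of weights
and ranks on one record subset.  Contributions are computed through the
covariance form ``8 β_k cov_w(x_k, r)``, which equals
``4 β_k x̄_k · (2 cov_w(x_k, r)/x̄_k)`` and stays defined even for a
zero-mean covariate (whose own CI is then undefined and reported as NaN).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .concentration import erreygers_index, weighted_cov, weighted_mean
from .exceptions import ClusterError, ZeroMeanCovariateError

#: |ENCI| below which percent contributions are suppressed as meaningless.
ENCI_PCT_FLOOR = 1e-8


@dataclass
class LpmFit:
    """Weighted linear-probability-model fit with cluster-robust SEs."""

    params: pd.Series
    bse: pd.Series
    resid: np.ndarray
    r_squared: float
    n: int
    cluster_count: int


def contribution(elasticity: float, ci_k: float) -> float:
    """Absolute Erreygers contribution of one covariate: 4 · elasticity · CI_k.

    This is the worked-example identity of the decomposition: applied to a
    published table's elasticity/CI pair it reproduces the printed
    contribution cell.
    """
    return 4.0 * float(elasticity) * float(ci_k)


def fit_lpm(y, X: pd.DataFrame, w, psu=None) -> LpmFit:
    """Weighted least-squares linear probability model.

    Parameters
    ----------
    y : array-like
        Binary (or bounded) outcome.
    X : pandas.DataFrame
        Numeric design, one column per covariate (no constant; added here).
        Categorical covariates must already be encoded — by default the
        pipeline encodes each multi-level covariate as one ordinal score
        against its lowest level (see :func:`encode_covariates`).
    w : array-like
        Survey weights (the same ones used for the index).
    psu : array-like, optional
        Cluster ids; cluster-robust SEs when given, HC1 otherwise.

    Raises
    ------
    ValueError
        Rank-deficient design; the message names the collinear columns.
    """
    X = pd.DataFrame(X).astype(float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)

    design = sm.add_constant(X, has_constant="add")
    mat = design.to_numpy() * np.sqrt(w)[:, None]
    rank = np.linalg.matrix_rank(mat)
    if rank < design.shape[1]:
        # identify offenders by greedy QR-style column scan
        bad, kept = [], []
        for col in design.columns:
            trial = design[kept + [col]].to_numpy() * np.sqrt(w)[:, None]
            if np.linalg.matrix_rank(trial) > len(kept):
                kept.append(col)
            else:
                bad.append(col)
        raise ValueError(f"design is rank deficient; collinear column(s): {bad}")

    model = sm.WLS(y, design, weights=w)
    if psu is None:
        fit = model.fit(cov_type="HC1")
        g = 0
    else:
        groups = np.unique(np.asarray(psu))
        if groups.size < 2:
            raise ClusterError("cluster-robust LPM needs >= 2 PSUs; pass psu=None")
        fit = model.fit(cov_type="cluster", cov_kwds={"groups": np.asarray(psu)})
        g = int(groups.size)
    with np.errstate(divide="ignore", invalid="ignore"):  # constant y: R² undefined
        r2 = float(fit.rsquared)
    return LpmFit(
        params=fit.params,
        bse=fit.bse,
        resid=np.asarray(fit.resid, dtype=float),
        r_squared=r2,
        n=len(y),
        cluster_count=g,
    )


def covariate_ci(x_k, r, w) -> float:
    """Unnormalized concentration index of a covariate: 2 cov_w(x, r) / x̄.

    Raises :class:`ZeroMeanCovariateError` when the covariate mean is zero
    (the index is undefined; the decomposition itself remains well defined
    through the covariance form).
    """
    x_k = np.asarray(x_k, dtype=float)
    xbar = weighted_mean(x_k, w)
    if xbar == 0:
        raise ZeroMeanCovariateError("covariate mean is 0: CI_k undefined")
    return 2.0 * weighted_cov(x_k, r, w) / xbar


@dataclass
class DecompositionTable:
    """Per-covariate decomposition of the ENCI plus the residual.

    ``table`` columns: beta, xbar, elasticity, ci_k, contribution, pct.
    ``pct`` is NaN throughout when |ENCI| is numerically zero (the
    denominator is meaningless); ``pct_suppressed`` flags that case.
    Sign convention: positive ENCI / contribution = pro-rich.
    """

    table: pd.DataFrame
    enci: float
    residual: float
    residual_pct: float
    lpm: LpmFit
    pct_suppressed: bool = False
    notes: list = field(default_factory=list)

    def check_adding_up(self, tol: float = 1e-10) -> bool:
        gap = abs(self.table["contribution"].sum() + self.residual - self.enci)
        return bool(gap <= tol * max(1.0, abs(self.enci)))


def decompose(y, X: pd.DataFrame, r, w, psu=None, enci: float | None = None) -> DecompositionTable:
    """Decompose the ENCI of ``y`` into covariate contributions.

    All inputs must be aligned on the identical record subset; the same
    weights and ranks feed the regression, the covariate indices and the
    ENCI, which is what makes the adding-up identity exact.

    Parameters
    ----------
    y, X, r, w, psu
        Outcome, encoded design, fractional ranks, weights, clusters.
    enci : float, optional
        Total ENCI to decompose; computed from ``y`` when omitted.
    """
    X = pd.DataFrame(X).astype(float)
    r = np.asarray(r, dtype=float)
    w = np.asarray(w, dtype=float)
    if enci is None:
        enci = erreygers_index(y, r, w, psu=psu).value
    lpm = fit_lpm(y, X, w, psu=psu)

    rows, notes = [], []
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        beta = float(lpm.params[col])
        xbar = weighted_mean(x, w)
        cov_xr = weighted_cov(x, r, w)
        contrib = 8.0 * beta * cov_xr  # == 4 * (beta*xbar) * (2 cov/xbar)
        if xbar == 0:
            ci_k = np.nan
            notes.append(f"{col}: zero weighted mean, CI_k undefined (excluded)")
        else:
            ci_k = 2.0 * cov_xr / xbar
        rows.append(
            {
                "covariate": col,
                "beta": beta,
                "xbar": xbar,
                "elasticity": beta * xbar,
                "ci_k": ci_k,
                "contribution": contrib,
            }
        )
    table = pd.DataFrame(rows).set_index("covariate")
    residual = float(enci - table["contribution"].sum())

    suppressed = abs(enci) < ENCI_PCT_FLOOR
    if suppressed:
        table["pct"] = np.nan
        residual_pct = np.nan
        notes.append("ENCI numerically zero: percent contributions suppressed")
    else:
        table["pct"] = table["contribution"] / enci * 100.0
        residual_pct = residual / enci * 100.0
    return DecompositionTable(table, float(enci), residual, residual_pct, lpm, suppressed, notes)


def encode_covariates(df: pd.DataFrame, covariates, encoding: str = "ordinal") -> pd.DataFrame:
    """Build a numeric design from raw covariate columns.

    ``encoding='ordinal'`` (default) maps each covariate to one numeric
    column: category codes in sorted-level order against the lowest level
    (numeric columns pass through).  ``encoding='dummy'`` expands
    multi-level categoricals into indicator columns, dropping the lowest
    level as reference.
    """
    if encoding not in ("ordinal", "dummy"):
        raise ValueError(f"unknown encoding {encoding!r}")
    out = {}
    for name in covariates:
        col = df[name]
        if pd.api.types.is_numeric_dtype(col):
            out[name] = col.astype(float)
            continue
        cat = pd.Categorical(col, ordered=True)
        if encoding == "ordinal":
            out[name] = pd.Series(cat.codes, index=df.index, dtype=float)
        else:
            for lev in cat.categories[1:]:
                out[f"{name}[{lev}]"] = (col == lev).astype(float)
    return pd.DataFrame(out, index=df.index)
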