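"""Concentration index, Erreygers normalization, and clustered uncertainty.

The concentration index of a health variable :math:`h` against weighted
fractional wealth rank :math:`r` is

.. math:: CI = \\frac{2\\,\\mathrm{cov}_w(h, r)}{\\mu},

twice the weighted covariance over the weighted mean — twice the area
between the concentration curve and the 45-degree line.  For a bounded
variable on :math:`[a, b]` (binary outcomes: :math:`[0, 1]`) the Erreygers
normalization

.. math:: ENCI = \\frac{4\\mu}{b - a}\\, CI

restores the mirror property and the full :math:`[-1, 1]` range.  Sign
convention: positive = concentrated among the rich (pro-rich), negative =
among the poor (pro-poor).

Standard errors come from the *convenient regression*: regressing the
suitably rescaled outcome on the rank gives the index as the OLS slope, so
a weighted least-squares fit with a cluster-robust (PSU-grouped) sandwich
covariance yields a design-consistent SE.  The slope is algebraically
identical to the covariance formula (same weights, same ranks), which the
test suite checks to 1e-10.

Weighted moments use the population form (divide by total weight), matching
the index's sum-form definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .exceptions import ClusterError, UndefinedIndexError

Z_95 = 1.959963984540054  # normal 97.5% quantile


def weighted_mean(x, w) -> float:
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    return float(np.sum(w * x) / np.sum(w))


def weighted_cov(x, y, w) -> float:
    """Population-form weighted covariance: sum w (x-x̄)(y-ȳ) / sum w."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    total = w.sum()
    xm = np.sum(w * x) / total
    ym = np.sum(w * y) / total
    return float(np.sum(w * (x - xm) * (y - ym)) / total)


@dataclass
class IndexEstimate:
    """A concentration-index estimate with its uncertainty.

    ``ci95`` is ``value ± 1.96 · std_error`` (normal quantile); NaN when no
    standard error was computed.
    """

    value: float
    std_error: float
    estimator: str  # "CI" or "ENCI"
    mean_outcome: float
    bounds: tuple = (0.0, 1.0)
    cluster_count: int = 0

    @property
    def ci95(self) -> tuple:
        if not np.isfinite(self.std_error):
            return (np.nan, np.nan)
        return (self.value - Z_95 * self.std_error, self.value + Z_95 * self.std_error)

    @property
    def z(self) -> float:
        return self.value / self.std_error if self.std_error > 0 else np.nan

    @property
    def p_value(self) -> float:
        from scipy.stats import norm

        z = self.z
        return float(2 * norm.sf(abs(z))) if np.isfinite(z) else np.nan

    def stars(self) -> str:
        p = self.p_value
        if not np.isfinite(p):
            return ""
        return "***" if p < 0.01 else "**" if p < 0.05 else "*" if p < 0.1 else ""


def _validate(h, r, w):
    h = np.asarray(h, dtype=float)
    r = np.asarray(r, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (h.shape == r.shape == w.shape):
        raise ValueError("h, r, w must have equal length")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive total")
    return h, r, w


def concentration_index(h, r, w, psu=None) -> IndexEstimate:
    """Standard (unnormalized) concentration index ``2 cov_w(h, r) / μ``.

    Parameters
    ----------
    h : array-like
        Health variable (binary or continuous), mean must be nonzero.
    r : array-like
        Weighted fractional wealth ranks (see :mod:`healthineq.ranking`).
    w : array-like
        Survey weights.
    psu : array-like, optional
        Cluster identifiers; when given, a PSU-cluster-robust standard
        error is attached, otherwise a heteroskedasticity-robust one.
    """
    h, r, w = _validate(h, r, w)
    mu = weighted_mean(h, w)
    if mu == 0:
        raise UndefinedIndexError("concentration index undefined: mean outcome is 0")
    value = 2.0 * weighted_cov(h, r, w) / mu
    se, g = _index_se(h, r, w, psu, scale=2.0 * weighted_cov(r, r, w) / mu)
    return IndexEstimate(value, se, "CI", mu, (np.nan, np.nan), g)


def erreygers_index(h, r, w, bounds=(0.0, 1.0), psu=None) -> IndexEstimate:
    """Erreygers-normalized concentration index ``4 μ (b−a)⁻¹ · CI``.

    For binary outcomes this is ``8 cov_w(h, r)``.  Ranges over [−1, 1];
    0 means the outcome is equally distributed across wealth; satisfies the
    mirror property ``ENCI(1−h) = −ENCI(h)``.
    """
    a, b = bounds
    if not b > a:
        raise ValueError(f"degenerate bounds {bounds}: need b > a")
    h, r, w = _validate(h, r, w)
    if np.any((h < a) | (h > b)):
        raise ValueError(f"outcome values fall outside bounds {bounds}")
    mu = weighted_mean(h, w)
    value = 8.0 * weighted_cov(h, r, w) / (b - a)
    se, g = _index_se(h, r, w, psu, scale=8.0 * weighted_cov(r, r, w) / (b - a))
    return IndexEstimate(value, se, "ENCI", mu, (a, b), g)


def _index_se(h, r, w, psu, scale: float):
    """Convenient-regression SE of the index with transform slope ``scale``.

    The regression of ``scale · h`` on ``r`` (WLS, weights ``w``) has slope
    equal to the index; the sandwich SE of that slope is returned.  With
    ``psu=None`` an HC1 robust SE is used; with clusters, the PSU-grouped
    cluster-robust sandwich.
    """
    if psu is None:
        fit = _convenient_fit(scale * h, r, w, None)
        return float(fit.bse[1]), 0
    psu = np.asarray(psu)
    groups = np.unique(psu)
    if groups.size < 2:
        raise ClusterError(
            "cluster-robust SE needs >= 2 PSUs; pass psu=None for the "
            "unclustered (heteroskedasticity-robust) fallback"
        )
    fit = _convenient_fit(scale * h, r, w, psu)
    return float(fit.bse[1]), int(groups.size)


def _convenient_fit(y, r, w, psu):
    X = sm.add_constant(np.asarray(r, dtype=float))
    model = sm.WLS(np.asarray(y, dtype=float), X, weights=np.asarray(w, dtype=float))
    if psu is None:
        return model.fit(cov_type="HC1")
    return model.fit(cov_type="cluster", cov_kwds={"groups": psu})


def convenient_regression_index(h, r, w, estimator: str = "CI", bounds=(0.0, 1.0)) -> float:
    """Index via the convenient-regression slope (cross-check route).

    Fits ``scale·h`` on ``r`` by WLS and returns the slope; equals the
    covariance-formula index exactly (same weights and ranks).
    """
    h, r, w = _validate(h, r, w)
    mu = weighted_mean(h, w)
    var_r = weighted_cov(r, r, w)
    if estimator == "CI":
        if mu == 0:
            raise UndefinedIndexError("mean outcome is 0")
        scale = 2.0 * var_r / mu
    elif estimator == "ENCI":
        a, b = bounds
        scale = 8.0 * var_r / (b - a)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    fit = sm.WLS(scale * h, sm.add_constant(r), weights=w).fit()
    return float(fit.params[1])


def index_std_error(h, r, w, psu, estimator: str = "ENCI", bounds=(0.0, 1.0)) -> float:
    """Cluster-robust standard error of the CI or ENCI (PSU-grouped)."""
    h, r, w = _validate(h, r, w)
    mu = weighted_mean(h, w)
    var_r = weighted_cov(r, r, w)
    if estimator == "CI":
        if mu == 0:
            raise UndefinedIndexError("mean outcome is 0")
        scale = 2.0 * var_r / mu
    else:
        a, b = bounds
        scale = 8.0 * var_r / (b - a)
    se, _ = _index_se(h, r, w, psu, scale=scale)
    return se
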