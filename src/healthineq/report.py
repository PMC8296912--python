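"""Pipeline orchestration and paper-style report tables.

This layer strings the modules together for whole-dataset runs: derive the
binary outcomes, rank children by household wealth, and produce

* an **index report** (one row per outcome: ENCI, cluster-robust SE,
  significance stars, sample and cluster counts),
* a **decomposition report** (per-covariate elasticity, covariate CI,
  absolute and percent contribution, residual row),
* a **dominance report** (per-outcome mca verdict against the 45-degree
  line) with optional concentration-curve plots.

Listwise deletion is per analysis: each outcome's rows are those complete
for that outcome's variables, so different outcomes may use different
sample sizes (the complex-survey convention).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from .concentration import erreygers_index
from .curves import DEFAULT_GRID, curve_ordinates, dominance_test, plot_concentration_curves
from .decomposition import decompose, encode_covariates
from .exceptions import ConfigurationError, EmptyDataError
from .microdata import AnalysisDataset
from .outcomes import DEFAULT_SCHEDULE, derive_outcomes
from .ranking import fractional_rank, ranks_from_quintiles

OUTCOMES = ("immunized", "food_insecure", "malnourished")

#: Covariates decomposed for each outcome (one ordinal regressor each).
#: Household wealth enters as the quintile: the continuous wealth index
#: score is centred near zero, which makes its own concentration index
#: (2 cov / mean) ill-scaled as a display quantity.
DEFAULT_COVARIATES = {
    "immunized": [
        "wealth_quintile", "urban", "mother_edu", "husband_edu", "mother_age",
        "head_female", "birth_order", "anc4", "facility_delivery", "pnc",
        "media_exposure",
    ],
    "food_insecure": [
        "wealth_quintile", "urban", "mother_edu", "husband_edu", "mother_age",
        "head_female", "child_female", "household_size", "birth_order",
    ],
    "malnourished": [
        "wealth_quintile", "urban", "mother_edu", "husband_edu", "mother_age",
        "head_female", "child_female", "household_size",
    ],
}


@dataclass
class RunConfig:
    """Everything needed to replay an analysis run."""

    input: str = ""
    column_map: dict = field(default_factory=dict)
    outcomes: tuple = OUTCOMES
    age_window: tuple | None = None  # (min, max) months, applied to immunization
    dd_threshold: int = 4
    alpha: float = 0.05
    n_points: int = 19
    adjustment: str = "sidak"
    covariates: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATES))
    encoding: str = "ordinal"
    use_provided_quintiles: bool = False
    output_dir: str = "."
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["outcomes"] = list(self.outcomes)
        if self.age_window is not None:
            d["age_window"] = list(self.age_window)
        return d


def wealth_ranks(df: pd.DataFrame, w, use_provided_quintiles: bool = False) -> np.ndarray:
    """Fractional ranks from the continuous score when present, else quintiles."""
    if not use_provided_quintiles and "wealth_score" in df.columns and df["wealth_score"].notna().all():
        return fractional_rank(df["wealth_score"].to_numpy(dtype=float), w)
    if "wealth_quintile" not in df.columns:
        raise ConfigurationError("no usable wealth score or quintile column")
    return ranks_from_quintiles(df["wealth_quintile"].to_numpy(dtype=float), w)


def prepare_outcome(
    dataset: AnalysisDataset,
    outcome: str,
    extra_columns=(),
    *,
    dd_threshold: int = 4,
    age_window=None,
    use_provided_quintiles: bool = False,
    schedule=DEFAULT_SCHEDULE,
):
    """Listwise-complete analysis arrays for one outcome.

    Returns ``(h, r, w, psu, sub_df)`` where rows are complete for the
    outcome, wealth and any ``extra_columns``; ranks are recomputed on the
    analysis subset.
    """
    df = derive_outcomes(dataset.df, schedule=schedule, dd_threshold=dd_threshold)
    if outcome not in df.columns:
        raise ConfigurationError(
            f"outcome {outcome!r} not derivable: missing ingredient columns"
        )
    if age_window is not None and "age_months" in df.columns:
        lo, hi = age_window
        df = df.loc[(df["age_months"] >= lo) & (df["age_months"] <= hi)]
    needed = [outcome, *extra_columns]
    mask = df[needed].notna().all(axis=1)
    sub = df.loc[mask].reset_index(drop=True)
    if len(sub) < 2:
        raise EmptyDataError(f"fewer than 2 complete records for {outcome!r}")
    w = sub["weight"].to_numpy(dtype=float)
    r = wealth_ranks(sub, w, use_provided_quintiles)
    h = sub[outcome].to_numpy(dtype=float)
    psu = sub["psu"].to_numpy()
    return h, r, w, psu, sub


def index_report(dataset: AnalysisDataset, config: RunConfig | None = None) -> pd.DataFrame:
    """Erreygers index table: one row per requested outcome, with stars."""
    config = config or RunConfig()
    rows = []
    for outcome in config.outcomes:
        h, r, w, psu, sub = prepare_outcome(
            dataset,
            outcome,
            dd_threshold=config.dd_threshold,
            age_window=config.age_window if outcome == "immunized" else None,
            use_provided_quintiles=config.use_provided_quintiles,
        )
        est = erreygers_index(h, r, w, psu=psu)
        rows.append(
            {
                "outcome": outcome,
                "enci": est.value,
                "std_error": est.std_error,
                "stars": est.stars(),
                "ci95_low": est.ci95[0],
                "ci95_high": est.ci95[1],
                "mean_outcome": est.mean_outcome,
                "n": len(sub),
                "psu_clusters": est.cluster_count,
            }
        )
    return pd.DataFrame(rows).set_index("outcome")


def decomposition_report(dataset: AnalysisDataset, outcome: str, config: RunConfig | None = None):
    """Full decomposition of one outcome's ENCI into covariate contributions.

    Returns the :class:`~healthineq.decomposition.DecompositionTable`; use
    :func:`format_decomposition` for the typeset-style table.
    """
    config = config or RunConfig()
    covariates = config.covariates.get(outcome, DEFAULT_COVARIATES.get(outcome))
    if not covariates:
        raise ConfigurationError(f"no covariate list configured for {outcome!r}")
    covariates = [c for c in covariates if c in dataset.df.columns]
    if not covariates:
        raise ConfigurationError(f"none of the configured covariates exist for {outcome!r}")
    h, r, w, psu, sub = prepare_outcome(
        dataset,
        outcome,
        extra_columns=covariates,
        dd_threshold=config.dd_threshold,
        age_window=config.age_window if outcome == "immunized" else None,
        use_provided_quintiles=config.use_provided_quintiles,
    )
    X = encode_covariates(sub, covariates, config.encoding)
    return decompose(h, X, r, w, psu=psu)


def format_decomposition(result) -> pd.DataFrame:
    """Typeset-ready layout: Elasticity / Concentration Index /
    Contribution / Contribution (%) rows plus a Residuals row (percent)."""
    tab = result.table
    out = pd.DataFrame(
        {
            "Elasticity": tab["elasticity"].round(4),
            "Concentration Index": tab["ci_k"].round(4),
            "Contribution": tab["contribution"].round(4),
            "Contribution (%)": tab["pct"].round(4),
        }
    )
    resid = pd.DataFrame(
        {
            "Elasticity": [np.nan],
            "Concentration Index": [np.nan],
            "Contribution": [round(result.residual, 4)],
            "Contribution (%)": [round(result.residual_pct, 4) if np.isfinite(result.residual_pct) else np.nan],
        },
        index=["Residuals"],
    )
    return pd.concat([out, resid])


def dominance_report(
    dataset: AnalysisDataset,
    config: RunConfig | None = None,
    plot_dir=None,
):
    """mca dominance verdicts per outcome, optionally with curve plots."""
    config = config or RunConfig()
    grid = np.linspace(0.05, 0.95, config.n_points)
    rows, curves = [], {}
    for outcome in config.outcomes:
        h, r, w, psu, sub = prepare_outcome(
            dataset,
            outcome,
            dd_threshold=config.dd_threshold,
            age_window=config.age_window if outcome == "immunized" else None,
            use_provided_quintiles=config.use_provided_quintiles,
        )
        curve = curve_ordinates(h, r, w, grid=grid, outcome=outcome)
        res = dominance_test(curve, alpha=config.alpha, adjustment=config.adjustment)
        curves[outcome] = curve
        rows.append(
            {
                "outcome": outcome,
                "significance_level": config.alpha,
                "n_points": res.n_points,
                "rule": res.rule,
                "verdict": res.verdict,
            }
        )
        if plot_dir is not None:
            plot_concentration_curves(
                [curve], path=f"{plot_dir}/curve_{outcome}.png",
                title=f"Concentration curve: {outcome}",
            )
    return pd.DataFrame(rows).set_index("outcome"), curves


def run_manifest(config: RunConfig, input_path=None) -> dict:
    """Replayable run description: config hash, input hash, versions."""
    cfg = config.to_dict()
    cfg_hash = hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()
    input_hash = None
    if input_path:
        with open(input_path, "rb") as fh:
            input_hash = hashlib.sha256(fh.read()).hexdigest()
    return {
        "config": cfg,
        "config_sha256": cfg_hash,
        "input_sha256": input_hash,
        "versions": {
            "healthineq": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
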