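"""DHS-like synthetic microdata with known-truth inequality.

The generator emulates the *structure* of a Demographic and Health Survey
child recode: clustered sampling (children nested in primary sampling
units), a latent log-normal household wealth score with a PSU-level random
intercept, wealth-correlated covariates, v005-scale survey weights, and
three binary outcomes drawn from linear probability models (LPMs) with
known coefficient vectors.  Because the outcome truth is an explicit LPM,
every estimator in the pipeline (ENCI, curve dominance, decomposition) can
be checked against a brute-force population oracle
(:func:`population_truth`).

Raw outcome *ingredients* are generated consistently with the drawn
labels: a fully-immunized child carries 15 card-dated doses, a
non-immunized child has at least one dose missing or verbal-only; the
food-group flags sum to a dietary diversity score on the correct side of
the threshold; the weight-for-age z-score falls on the correct side of
−2 SD.  Applying :mod:`healthineq.outcomes` to the ingredients therefore
reproduces the generator's labels exactly.

All distributional choices are configuration fields with the defaults
below; none come from any external dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .microdata import AnalysisDataset, WEIGHT_DIVISOR
from .outcomes import (
    CARD_DATED,
    FOOD_GROUPS,
    NONE,
    VERBAL_ONLY,
    DEFAULT_SCHEDULE,
)
from .ranking import assign_quintiles, fractional_rank
from .concentration import weighted_cov

#: Column map for files written by :func:`write_dataset`.
DEFAULT_COLUMN_MAP = {
    "weight": "v005",
    "psu": "psu",
    "wealth_score": "wealth_score",
    "wealth_quintile": "wealth_quintile",
}

#: Design columns entering the outcome LPMs (and the decomposition).
DESIGN_COLUMNS = (
    "wealth_z",
    "urban",
    "mother_edu",
    "husband_edu",
    "mother_age",
    "head_female",
    "child_female",
    "household_size",
    "birth_order",
    "anc4",
    "facility_delivery",
    "pnc",
    "media_exposure",
)


def _default_outcome_models() -> dict:
    # pro-rich immunization gradient; pro-poor food insecurity / malnutrition
    return {
        "immunized": {
            "intercept": 0.28,
            "wealth_z": 0.06,
            "urban": 0.02,
            "mother_edu": 0.03,
            "husband_edu": 0.01,
            "mother_age": 0.002,
            "head_female": -0.005,
            "birth_order": -0.012,
            "anc4": 0.06,
            "facility_delivery": 0.05,
            "pnc": 0.03,
            "media_exposure": 0.015,
        },
        "food_insecure": {
            "intercept": 0.80,
            "wealth_z": -0.05,
            "urban": -0.02,
            "mother_edu": -0.025,
            "husband_edu": -0.012,
            "head_female": -0.01,
            "child_female": 0.002,
            "household_size": 0.006,
            "birth_order": 0.008,
        },
        "malnourished": {
            "intercept": 0.42,
            "wealth_z": -0.07,
            "urban": -0.015,
            "mother_edu": -0.03,
            "husband_edu": -0.015,
            "mother_age": -0.001,
            "head_female": 0.005,
            "child_female": 0.005,
            "household_size": 0.005,
        },
    }


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic DHS-like population.

    Defaults give a survey of 20,000 children in 500 PSUs with a pro-rich
    immunization gradient and pro-poor food-insecurity / malnutrition
    gradients of realistic magnitude.
    """

    n_children: int = 20_000
    n_psu: int = 500
    #: share of latent log-wealth variance at the PSU level
    rho: float = 0.3
    #: v005-scale weight distribution: log-normal, mean and coefficient of variation
    weight_mean: float = float(WEIGHT_DIVISOR)
    weight_cv: float = 0.3
    #: outcome name -> {covariate: coefficient, "intercept": a}
    outcome_models: dict = field(default_factory=_default_outcome_models)
    #: LPM probabilities are clipped into this interval before the Bernoulli draw
    prob_clip: tuple = (0.01, 0.99)
    dd_threshold: int = 4
    #: SD of an optional PSU-level random effect added to every outcome
    #: probability (default 0: cluster effects enter through wealth only).
    #: Nonzero values induce within-PSU outcome correlation for SE testing.
    outcome_cluster_sd: float = 0.0

    def validate(self) -> "GeneratorConfig":
        if self.n_children < 2 or self.n_psu < 1:
            raise ConfigurationError("need n_children >= 2 and n_psu >= 1")
        if not 0.0 <= self.rho < 1.0:
            raise ConfigurationError("rho must be in [0, 1)")
        if self.weight_mean <= 0 or self.weight_cv < 0:
            raise ConfigurationError("weight_mean > 0 and weight_cv >= 0 required")
        if self.outcome_cluster_sd < 0:
            raise ConfigurationError("outcome_cluster_sd must be >= 0")
        lo, hi = self.prob_clip
        if not (0.0 < lo < hi < 1.0):
            raise ConfigurationError(f"prob_clip {self.prob_clip} must satisfy 0 < lo < hi < 1")
        for name, model in self.outcome_models.items():
            unknown = set(model) - set(DESIGN_COLUMNS) - {"intercept"}
            if unknown:
                raise ConfigurationError(f"outcome {name!r}: unknown covariates {sorted(unknown)}")
        return self

    @classmethod
    def null(cls, intercepts: float | dict = 0.5, **kwargs) -> "GeneratorConfig":
        """A no-gradient configuration: every coefficient zero.

        Under it the population ENCI of every outcome is exactly 0.
        """
        if not isinstance(intercepts, dict):
            intercepts = {k: intercepts for k in _default_outcome_models()}
        models = {k: {"intercept": float(v)} for k, v in intercepts.items()}
        return cls(outcome_models=models, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


def _covariates(config: GeneratorConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the latent wealth and the wealth-linked covariates."""
    psu = rng.integers(0, config.n_psu, size=n)
    z_psu = rng.normal(size=config.n_psu)
    zw = np.sqrt(config.rho) * z_psu[psu] + np.sqrt(1.0 - config.rho) * rng.normal(size=n)
    wealth_score = np.exp(zw)  # log-normal household score

    def sigmoid(x):
        return 1.0 / (1.0 + np.exp(-x))

    def ordered(latent, cuts):
        return np.searchsorted(np.asarray(cuts), latent, side="left").astype(float)

    urban = (rng.random(n) < sigmoid(-0.2 + 1.0 * zw)).astype(float)
    mother_edu = ordered(0.8 * zw + rng.normal(size=n), (-1.0, 0.0, 1.2))
    husband_edu = ordered(0.8 * zw + rng.normal(size=n), (-1.1, -0.1, 1.1))
    mother_age = np.clip(28.0 + 0.8 * zw + rng.normal(scale=6.0, size=n), 15.0, 49.0)
    head_female = (rng.random(n) < 0.15).astype(float)
    child_female = (rng.random(n) < 0.488).astype(float)
    household_size = 1.0 + rng.poisson(np.exp(1.25 - 0.15 * zw))
    birth_order = 1.0 + rng.poisson(np.exp(0.45 - 0.25 * zw))
    anc4 = (rng.random(n) < sigmoid(0.2 + 0.7 * zw)).astype(float)
    facility_delivery = (rng.random(n) < sigmoid(1.0 + 0.9 * zw)).astype(float)
    pnc = (rng.random(n) < sigmoid(-0.4 + 0.5 * zw)).astype(float)
    media_exposure = ordered(0.9 * zw + rng.normal(size=n), (-0.6, 0.6))

    return pd.DataFrame(
        {
            "psu": psu,
            "wealth_z": zw,
            "wealth_score": wealth_score,
            "urban": urban,
            "mother_edu": mother_edu,
            "husband_edu": husband_edu,
            "mother_age": mother_age,
            "head_female": head_female,
            "child_female": child_female,
            "household_size": household_size.astype(float),
            "birth_order": birth_order.astype(float),
            "anc4": anc4,
            "facility_delivery": facility_delivery,
            "pnc": pnc,
            "media_exposure": media_exposure,
        }
    )


def _probabilities(config: GeneratorConfig, cov: pd.DataFrame, rng=None) -> dict:
    """Clipped LPM success probabilities per outcome.

    With ``outcome_cluster_sd > 0`` (and an rng), a PSU-level mean-zero
    random effect is added before clipping, inducing within-cluster outcome
    correlation without shifting the wealth gradient.
    """
    lo, hi = config.prob_clip
    out = {}
    for name, model in config.outcome_models.items():
        p = np.full(len(cov), float(model.get("intercept", 0.0)))
        for col, beta in model.items():
            if col == "intercept":
                continue
            p = p + float(beta) * cov[col].to_numpy(dtype=float)
        if config.outcome_cluster_sd > 0 and rng is not None:
            u = rng.normal(scale=config.outcome_cluster_sd, size=config.n_psu)
            p = p + u[cov["psu"].to_numpy(dtype=int)]
        out[name] = np.clip(p, lo, hi)
    return out


def _immunization_ingredients(immunized: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Dose-status columns consistent with the immunization labels."""
    n = immunized.size
    cols = DEFAULT_SCHEDULE.dose_columns
    k = len(cols)
    status = np.full((n, k), CARD_DATED, dtype=object)
    not_full = ~immunized.astype(bool)
    idx = np.where(not_full)[0]
    # non-immunized: 0..k-1 card-dated doses, one possibly verbal-only
    n_card = rng.integers(0, k, size=idx.size)
    verbal = rng.random(idx.size) < 0.5
    for i, row in enumerate(idx):
        perm = rng.permutation(k)
        status[row, perm[n_card[i]:]] = NONE
        if verbal[i]:
            status[row, perm[n_card[i]]] = VERBAL_ONLY
    return pd.DataFrame({c: status[:, j] for j, c in enumerate(cols)})


def _food_ingredients(insecure: np.ndarray, threshold: int, rng: np.random.Generator) -> pd.DataFrame:
    """13 food-group flags whose count falls on the correct side of the cut."""
    n = insecure.size
    k = len(FOOD_GROUPS)
    dds = np.where(
        insecure.astype(bool),
        rng.integers(0, threshold, size=n),
        rng.integers(threshold, k + 1, size=n),
    )
    noise = rng.random((n, k))
    order = np.argsort(noise, axis=1)
    flags = np.zeros((n, k), dtype=int)
    rows = np.repeat(np.arange(n), dds)
    cols = np.concatenate([order[i, : dds[i]] for i in range(n)]) if rows.size else np.array([], int)
    flags[rows, cols] = 1
    return pd.DataFrame({f"fg_{g}": flags[:, j] for j, g in enumerate(FOOD_GROUPS)})


def _waz(malnourished: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Weight-for-age z-scores on the correct side of −2 SD (half-normal tails)."""
    n = malnourished.size
    below = -2.0 - np.abs(rng.normal(scale=0.8, size=n))
    above = -2.0 + np.abs(rng.normal(scale=1.2, size=n))
    return np.where(malnourished.astype(bool), below, above)


def generate_dataset(config: GeneratorConfig, seed: int):
    """Draw one synthetic survey; reproducible for a fixed seed.

    Returns
    -------
    (AnalysisDataset, dict)
        The dataset and the truth record: the exact coefficient vectors
        used, the design columns, and the seed.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_children

    df = _covariates(config, n, rng)

    # v005-scale weights: log-normal with the configured mean and CV
    if config.weight_cv == 0:
        raw_weight = np.full(n, config.weight_mean)
    else:
        s2 = np.log1p(config.weight_cv**2)
        raw_weight = np.exp(
            rng.normal(np.log(config.weight_mean) - s2 / 2.0, np.sqrt(s2), size=n)
        )
    raw_weight = np.round(raw_weight).astype(np.int64)
    df.insert(0, "child_id", np.arange(n))
    df["raw_weight"] = raw_weight
    df["weight"] = raw_weight / WEIGHT_DIVISOR

    probs = _probabilities(config, df, rng=rng)
    labels = {name: (rng.random(n) < p).astype(int) for name, p in probs.items()}

    df["wealth_quintile"] = assign_quintiles(df["wealth_score"], df["weight"])

    if "immunized" in labels:
        df = pd.concat([df, _immunization_ingredients(labels["immunized"], rng)], axis=1)
        df["immunized"] = labels["immunized"]
    if "food_insecure" in labels:
        df = pd.concat(
            [df, _food_ingredients(labels["food_insecure"], config.dd_threshold, rng)], axis=1
        )
        df["food_insecure"] = labels["food_insecure"]
    if "malnourished" in labels:
        df["waz"] = np.round(_waz(labels["malnourished"], rng), 4)
        df["malnourished"] = labels["malnourished"]

    truth = {
        "seed": int(seed),
        "config": config.to_dict(),
        "design_columns": list(DESIGN_COLUMNS),
        "outcome_models": {k: dict(v) for k, v in config.outcome_models.items()},
    }
    return AnalysisDataset(df).validate(), truth


def population_truth(config: GeneratorConfig, oracle_n: int = 200_000, seed: int = 0) -> dict:
    """Brute-force Monte-Carlo evaluation of the population inequality truth.

    Draws ``oracle_n`` children from the covariate model (equal weights —
    survey weights are independent of everything, so the weighted and
    unweighted populations coincide), uses the *clipped success
    probabilities* in place of Bernoulli draws to remove outcome noise, and
    evaluates for every outcome the population ENCI ``8 cov(p, r)``, the
    per-covariate contributions ``8 β̂_k cov(x_k, r)`` from a least-squares
    fit of p on the design, and the residual closing the identity.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    # The marginal law of each child's covariates does not depend on the
    # PSU count (the latent wealth is N(0,1) regardless), so the oracle
    # draws ~40 children per cluster to keep its own MC error small.
    oracle_cfg = GeneratorConfig(**{**config.to_dict(),
                                    "n_psu": max(config.n_psu, int(oracle_n) // 40)})
    cov = _covariates(oracle_cfg, int(oracle_n), rng)
    w = np.ones(len(cov))
    r = fractional_rank(cov["wealth_score"].to_numpy(), w)
    X = cov[list(DESIGN_COLUMNS)].to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(cov)), X])

    out = {}
    for name, p in _probabilities(config, cov).items():
        enci = 8.0 * weighted_cov(p, r, w)
        beta, *_ = np.linalg.lstsq(design, p, rcond=None)
        contribs = {
            col: 8.0 * beta[1 + j] * weighted_cov(X[:, j], r, w)
            for j, col in enumerate(DESIGN_COLUMNS)
        }
        out[name] = {
            "mean": float(p.mean()),
            "enci": float(enci),
            "contributions": {k: float(v) for k, v in contribs.items()},
            "residual": float(enci - sum(contribs.values())),
            "oracle_n": int(oracle_n),
        }
    return out


def write_dataset(dataset: AnalysisDataset, path, truth: dict | None = None, truth_path=None) -> None:
    """Write the standard delimited-text microdata file (+ truth sidecar).

    The weight is written on the raw v005 scale under the column name
    ``v005`` so the file round-trips through
    ``load_microdata(path, DEFAULT_COLUMN_MAP)``.
    """
    df = dataset.df.copy()
    if "raw_weight" in df.columns:
        df["v005"] = df.pop("raw_weight")
    else:
        df["v005"] = np.round(df["weight"] * WEIGHT_DIVISOR).astype(np.int64)
    df = df.drop(columns=["weight"])
    df.to_csv(path, index=False)
    if truth is not None and truth_path is not None:
        with open(truth_path, "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
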