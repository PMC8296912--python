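"""Binary child-health outcome definitions.

Three indicators, each coded 1 when the condition is present:

* **full immunization** — every dose of a national schedule (default:
  1 BCG, 4 OPV, 3 Pentavalent, 3 PCV, 2 Rotavirus, 1 Measles, 1 Yellow
  fever; 7 vaccines, 15 doses) documented by a *dated vaccination card*.
  Maternal recall without written confirmation does not count, to avoid
  recall bias.
* **food insecurity** — dietary diversity score (count of 13 IYCF food
  groups consumed) below a threshold, default 4 (i.e. at most 3 groups).
* **malnutrition** — weight-for-age z-score strictly below −2 SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

#: Dose status codes.
CARD_DATED = "card_dated"
VERBAL_ONLY = "verbal_only"
NONE = "none"

#: The 13 IYCF food groups used for the dietary diversity score.
FOOD_GROUPS = (
    "grains",
    "tubers",
    "eggs",
    "meat",
    "pumpkin_carrots",
    "green_leafy_veg",
    "vitamin_a_fruits",
    "other_fruits",
    "organ_meat",
    "fish",
    "legumes_nuts",
    "milk_products",
    "yoghurt",
)

_DEFAULT_DOSES = (
    ("bcg", 1),
    ("opv", 4),
    ("pentavalent", 3),
    ("pcv", 3),
    ("rota", 2),
    ("measles", 1),
    ("yellow_fever", 1),
)


@dataclass(frozen=True)
class ImmunizationSchedule:
    """A national immunization schedule as (vaccine, dose-number) entries.

    The default is the 7-vaccine, 15-dose schedule; alternates can be built
    from config because routine schedules differ between countries.
    """

    doses: tuple = field(
        default_factory=lambda: tuple(
            (name, k) for name, n in _DEFAULT_DOSES for k in range(1, n + 1)
        )
    )

    def __post_init__(self):
        if len(set(self.doses)) != len(self.doses):
            raise ConfigurationError("schedule contains duplicate doses")

    @property
    def n_doses(self) -> int:
        return len(self.doses)

    @property
    def vaccines(self) -> tuple:
        return tuple(dict.fromkeys(name for name, _ in self.doses))

    @property
    def dose_columns(self) -> tuple:
        """Canonical column names, e.g. ``dose_opv_3``."""
        return tuple(f"dose_{name}_{k}" for name, k in self.doses)

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "ImmunizationSchedule":
        """Build a schedule from vaccine -> number-of-doses counts."""
        doses = []
        for name, n in counts.items():
            if int(n) < 1:
                raise ConfigurationError(f"vaccine {name!r} needs >= 1 dose")
            doses.extend((name, k) for k in range(1, int(n) + 1))
        return cls(tuple(doses))


DEFAULT_SCHEDULE = ImmunizationSchedule()
assert DEFAULT_SCHEDULE.n_doses == 15 and len(DEFAULT_SCHEDULE.vaccines) == 7


def full_immunization(dose_status: Mapping, schedule: ImmunizationSchedule = DEFAULT_SCHEDULE) -> int:
    """1 iff every scheduled dose is card-dated.

    ``dose_status`` maps (vaccine, dose-number) pairs — or canonical
    ``dose_<vaccine>_<k>`` strings — to one of ``card_dated``,
    ``verbal_only``, ``none``.  Missing entries count as not received;
    ``verbal_only`` counts as *not* immunized (recall-bias rule).
    """
    for (name, k), col in zip(schedule.doses, schedule.dose_columns):
        status = dose_status.get((name, k), dose_status.get(col, NONE))
        if status != CARD_DATED:
            return 0
    return 1


def full_immunization_column(df: pd.DataFrame, schedule: ImmunizationSchedule = DEFAULT_SCHEDULE) -> pd.Series:
    """Vectorized :func:`full_immunization` over canonical dose columns."""
    out = np.ones(len(df), dtype=int)
    for col in schedule.dose_columns:
        if col not in df.columns:
            out[:] = 0
            break
        out &= (df[col] == CARD_DATED).to_numpy()
    return pd.Series(out, index=df.index, name="immunized")


def dietary_diversity_score(flags: Sequence) -> int:
    """Count of food groups consumed; requires exactly 13 flags."""
    arr = np.asarray(flags)
    if arr.ndim != 1 or arr.shape[0] != len(FOOD_GROUPS):
        raise ConfigurationError(
            f"expected exactly {len(FOOD_GROUPS)} food-group flags, got {arr.shape}"
        )
    return int(arr.astype(bool).sum())


def dietary_diversity_column(df: pd.DataFrame) -> pd.Series:
    cols = [f"fg_{g}" for g in FOOD_GROUPS]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing food-group columns: {missing}")
    return df[cols].astype(bool).sum(axis=1).rename("dd_score")


def food_insecure(score, threshold: int = 4):
    """1 iff the dietary diversity score falls below ``threshold``.

    Default threshold 4: consuming fewer than 4 of the 13 groups (at most 3)
    defines food insecurity, the minimum-dietary-diversity reading.  Scalar
    or vector ``score``.
    """
    if not 1 <= int(threshold) <= 13:
        raise ConfigurationError("dd_threshold must be in 1..13")
    arr = np.asarray(score)
    if np.any((arr < 0) | (arr > 13)):
        raise ValueError("dietary diversity score must be in 0..13")
    out = (arr < int(threshold)).astype(int)
    return int(out) if arr.ndim == 0 else out


def malnourished(waz):
    """1 iff weight-for-age z-score is strictly below −2 SD.

    Scalar or vector; NaN propagates as NaN so callers can listwise-delete.
    """
    arr = np.asarray(waz, dtype=float)
    out = np.where(np.isnan(arr), np.nan, (arr < -2.0).astype(float))
    if arr.ndim == 0:
        v = float(out)
        return v if np.isnan(v) else int(v)
    return out


def derive_outcomes(
    df: pd.DataFrame,
    *,
    schedule: ImmunizationSchedule = DEFAULT_SCHEDULE,
    dd_threshold: int = 4,
) -> pd.DataFrame:
    """Attach ``immunized``, ``food_insecure`` and ``malnourished`` columns.

    Each outcome is derived only where its ingredients exist; rows lacking
    an ingredient get NaN for that outcome (to be listwise-deleted per
    analysis, matching the per-outcome sample convention).
    """
    out = df.copy()
    if all(c in df.columns for c in schedule.dose_columns):
        out["immunized"] = full_immunization_column(df, schedule)
    if all(f"fg_{g}" in df.columns for g in FOOD_GROUPS):
        score = dietary_diversity_column(df)
        out["dd_score"] = score
        out["food_insecure"] = food_insecure(score.to_numpy(), dd_threshold)
    if "waz" in df.columns:
        out["malnourished"] = malnourished(df["waz"].to_numpy())
    return out
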