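"""Loading, validation and normalization of child-level survey microdata.

The working container is :class:`AnalysisDataset`, a thin wrapper around a
pandas DataFrame in *canonical column* layout:

``weight``
    normalized survey weight (DHS convention: raw ``v005`` divided by
    1,000,000);
``psu``
    primary sampling unit (cluster) identifier;
``wealth_score`` and/or ``wealth_quintile``
    household wealth index score (continuous) and/or DHS wealth quintile
    (1..5).

Any further columns (vaccine-dose status, food-group flags, weight-for-age
z-score, covariates) are carried through untouched; downstream modules look
them up by name.

Input files are delimited text; a *column map* translates the file's own
column names to the canonical ones.  Rows failing validation (negative or
unparseable weight, missing cluster id, missing wealth information,
out-of-range quintile) are dropped and tallied in a :class:`LoadReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, EmptyDataError

#: Divisor turning a raw DHS v005-scale weight into an analysis weight.
WEIGHT_DIVISOR = 1_000_000

#: Canonical columns a loaded dataset must provide.
REQUIRED_ROLES = ("weight", "psu")
WEALTH_ROLES = ("wealth_score", "wealth_quintile")


def normalize_weights(raw_weight):
    """Convert raw v005-scale survey weights to analysis weights.

    Parameters
    ----------
    raw_weight : float or array-like
        Nonnegative raw weight(s) on the DHS v005 scale.

    Returns
    -------
    float or numpy.ndarray
        ``raw_weight / 1_000_000``.

    Raises
    ------
    ValueError
        If any weight is negative.
    """
    arr = np.asarray(raw_weight, dtype=float)
    if np.any(arr < 0):
        raise ValueError("raw survey weights must be nonnegative")
    out = arr / WEIGHT_DIVISOR
    if np.isscalar(raw_weight) or arr.ndim == 0:
        return float(out)
    return out


@dataclass
class LoadReport:
    """Machine-readable summary of a microdata load."""

    n_read: int = 0
    n_kept: int = 0
    n_dropped: int = 0
    rejections: dict = field(default_factory=dict)

    def add_rejection(self, rule: str, count: int) -> None:
        if count:
            self.rejections[rule] = self.rejections.get(rule, 0) + int(count)

    def to_dict(self) -> dict:
        return {
            "n_read": self.n_read,
            "n_kept": self.n_kept,
            "n_dropped": self.n_dropped,
            "rejections": dict(self.rejections),
        }


@dataclass
class AnalysisDataset:
    """Validated child-level microdata with normalized weights.

    Attributes
    ----------
    df : pandas.DataFrame
        Canonical-layout table, one row per child.
    report : LoadReport
        Validation tally from loading (empty for generated data).
    """

    df: pd.DataFrame
    report: LoadReport = field(default_factory=LoadReport)

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def psu_count(self) -> int:
        return int(self.df["psu"].nunique())

    @property
    def weights(self) -> np.ndarray:
        return self.df["weight"].to_numpy(dtype=float)

    def validate(self) -> "AnalysisDataset":
        """Check the invariants downstream estimators rely on."""
        if self.n < 2:
            raise EmptyDataError(f"need at least 2 records, have {self.n}")
        if self.psu_count < 1:
            raise EmptyDataError("need at least one primary sampling unit")
        w = self.weights
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ValueError("normalized weights must be finite and nonnegative")
        return self

    def subset(self, mask) -> "AnalysisDataset":
        """Row subset (listwise deletion for one analysis), same metadata."""
        return AnalysisDataset(self.df.loc[mask].reset_index(drop=True))


def load_microdata(
    path,
    column_map: Mapping[str, str],
    *,
    delimiter: str = ",",
    encoding: str = "utf-8",
    weights_prenormalized: bool = False,
) -> AnalysisDataset:
    """Read a delimited-text microdata file into an :class:`AnalysisDataset`.

    Parameters
    ----------
    path : str or pathlib.Path
        Delimited text file, one row per child, with a header line.
    column_map : mapping
        Canonical role -> column name in the file.  Must name ``weight``,
        ``psu`` and at least one of ``wealth_score`` / ``wealth_quintile``.
        Extra entries rename additional columns to canonical names; columns
        not mentioned are kept under their file names.
    delimiter, encoding : str
        CSV dialect; defaults comma / UTF-8.
    weights_prenormalized : bool
        If True the weight column is already on the analysis scale and the
        division by 1,000,000 is skipped.

    Returns
    -------
    AnalysisDataset
        Validated dataset; ``dataset.report`` tallies dropped rows.

    Raises
    ------
    ConfigurationError
        A mapped column is missing from the file, or the map omits a
        required role.
    EmptyDataError
        No usable rows survive validation.
    """
    for role in REQUIRED_ROLES:
        if role not in column_map:
            raise ConfigurationError(f"column map must name the {role!r} column")
    if not any(role in column_map for role in WEALTH_ROLES):
        raise ConfigurationError(
            "column map must name 'wealth_score' or 'wealth_quintile'"
        )

    raw = pd.read_csv(path, sep=delimiter, encoding=encoding)
    missing = [col for col in column_map.values() if col not in raw.columns]
    if missing:
        raise ConfigurationError(f"input file is missing mapped column(s): {missing}")

    df = raw.rename(columns={v: k for k, v in column_map.items()})
    report = LoadReport(n_read=len(df))

    def drop(mask: pd.Series, rule: str) -> None:
        nonlocal df
        bad = int(mask.sum())
        if bad:
            report.add_rejection(rule, bad)
            df = df.loc[~mask]

    w = pd.to_numeric(df["weight"], errors="coerce")
    drop(w.isna(), "weight_not_numeric")
    w = pd.to_numeric(df["weight"], errors="coerce")
    drop(w < 0, "weight_negative")
    df["weight"] = pd.to_numeric(df["weight"])
    if not weights_prenormalized:
        df["weight"] = df["weight"] / WEIGHT_DIVISOR

    drop(df["psu"].isna(), "psu_missing")

    if "wealth_score" in df.columns:
        df["wealth_score"] = pd.to_numeric(df["wealth_score"], errors="coerce")
    if "wealth_quintile" in df.columns:
        q = pd.to_numeric(df["wealth_quintile"], errors="coerce")
        bad_q = q.notna() & ~q.isin([1, 2, 3, 4, 5])
        drop(bad_q, "quintile_out_of_range")
        df["wealth_quintile"] = pd.to_numeric(df["wealth_quintile"], errors="coerce")

    has_score = (
        df["wealth_score"].notna() if "wealth_score" in df.columns
        else pd.Series(False, index=df.index)
    )
    has_quint = (
        df["wealth_quintile"].notna() if "wealth_quintile" in df.columns
        else pd.Series(False, index=df.index)
    )
    drop(~(has_score | has_quint), "wealth_missing")

    report.n_kept = len(df)
    report.n_dropped = report.n_read - report.n_kept
    if report.n_kept == 0:
        raise EmptyDataError(f"no usable rows in {path}")

    ds = AnalysisDataset(df.reset_index(drop=True), report)
    return ds.validate()


def weighted_prevalence(dataset, outcome: str, by: str) -> pd.Series:
    """Weighted composition of the outcome-positive population by category.

    Among records with ``outcome == 1``, the weighted share (percent) of
    each category of ``by``; shares sum to 100 across categories.  This is
    the column-percentage convention of survey cross-tabulations that
    describe *who* the affected children are.

    Parameters
    ----------
    dataset : AnalysisDataset or pandas.DataFrame
    outcome : str
        Name of a binary (0/1) column.
    by : str
        Name of a categorical column.

    Returns
    -------
    pandas.Series
        Percent per category, indexed by category, summing to 100.
    """
    df = dataset.df if isinstance(dataset, AnalysisDataset) else dataset
    sub = df.loc[df[outcome].notna() & df[by].notna()]
    if sub.empty:
        raise EmptyDataError(f"grouping column {by!r} has no usable values")
    pos = sub.loc[sub[outcome].astype(float) == 1.0]
    total = float(pos["weight"].sum())
    if total <= 0:
        raise EmptyDataError(f"no weighted outcome-positive records for {outcome!r}")
    shares = pos.groupby(by, observed=True)["weight"].sum() / total * 100.0
    shares.name = f"{outcome}_pct"
    return shares
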