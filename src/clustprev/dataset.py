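"""Survey dataset container and delimited-text I/O.

A :class:`SurveyDataset` holds individual screening records with their nested
cluster labels (site > village/interviewer > household) and a binary outcome
that may be missing.  The on-disk format is a comma-separated file with a
header row::

    individual_id,site_id,village_id,household_id,interviewer_id,interviewer_sex,outcome

``outcome`` is ``0``, ``1`` or empty (missing).  ``interviewer_sex`` is ``F``
or ``M``.  Identifier columns are treated as opaque strings.
"""
from __future__ import annotations

import os

import numpy as np
import pandas as pd

COLUMNS = [
    "individual_id",
    "site_id",
    "village_id",
    "household_id",
    "interviewer_id",
    "interviewer_sex",
    "outcome",
]

ID_COLUMNS = COLUMNS[:5]


class DatasetError(ValueError):
    """Base class for dataset problems."""


class ParseError(DatasetError):
    """A malformed row or value in a dataset file."""


class IntegrityError(DatasetError):
    """A violation of the nested-cluster invariants."""


def _check_single_valued(df: pd.DataFrame, child: str, parent: str) -> None:
    counts = df.groupby(child, sort=False)[parent].nunique()
    bad = counts[counts > 1]
    if len(bad):
        raise IntegrityError(
            f"{child} {bad.index[0]!r} maps to {bad.iloc[0]} distinct values of {parent}; "
            f"each {child} must belong to exactly one {parent}"
        )


class SurveyDataset:
    """Individual survey records with nested cluster labels.

    Parameters
    ----------
    df
        Frame with the columns in :data:`COLUMNS`.  Identifier columns are
        normalised to strings; ``outcome`` to float64 with NaN for missing.
    validate
        Check the schema and the nesting invariants (household -> interviewer,
        household -> village, village -> site, interviewer -> site are all
        single-valued; outcomes in {0, 1, missing}).
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        if validate:
            missing_cols = [c for c in COLUMNS if c not in df.columns]
            if missing_cols:
                raise ParseError(f"missing columns: {missing_cols}")
            df = df.loc[:, COLUMNS].copy()
            for c in ID_COLUMNS:
                df[c] = df[c].astype(str)
            df["interviewer_sex"] = df["interviewer_sex"].astype(str)
            df["outcome"] = pd.to_numeric(df["outcome"], errors="coerce").astype(float)
            df = df.reset_index(drop=True)
            self.df = df
            self.validate()
        else:
            self.df = df.reset_index(drop=True)

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        df = self.df
        bad_sex = ~df["interviewer_sex"].isin(["F", "M"])
        if bad_sex.any():
            i = int(np.flatnonzero(bad_sex)[0])
            raise ParseError(
                f"record {df['individual_id'].iloc[i]!r}: interviewer_sex must be 'F' or 'M', "
                f"got {df['interviewer_sex'].iloc[i]!r}"
            )
        y = df["outcome"].to_numpy()
        bad_y = ~(np.isnan(y) | (y == 0.0) | (y == 1.0))
        if bad_y.any():
            i = int(np.flatnonzero(bad_y)[0])
            raise ParseError(
                f"record {df['individual_id'].iloc[i]!r}: outcome must be 0, 1 or empty, got {y[i]!r}"
            )
        if df["individual_id"].duplicated().any():
            dup = df["individual_id"][df["individual_id"].duplicated()].iloc[0]
            raise IntegrityError(f"duplicate individual_id {dup!r}")
        _check_single_valued(df, "household_id", "village_id")
        _check_single_valued(df, "household_id", "interviewer_id")
        _check_single_valued(df, "village_id", "site_id")
        _check_single_valued(df, "interviewer_id", "site_id")
        # same interviewer for a household implies the sex column is constant
        _check_single_valued(df, "interviewer_id", "interviewer_sex")

    # -- basic accessors ----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def outcome(self) -> np.ndarray:
        return self.df["outcome"].to_numpy()

    @property
    def n_missing(self) -> int:
        return int(self.df["outcome"].isna().sum())

    def complete_cases(self) -> "SurveyDataset":
        """Records with an observed outcome (complete-case analysis set)."""
        return SurveyDataset(self.df[self.df["outcome"].notna()], validate=False)

    def household_sizes(self) -> pd.Series:
        """Number of records per household, aligned to the records."""
        return self.df.groupby("household_id", sort=False)["individual_id"].transform("size")

    def copy(self) -> "SurveyDataset":
        return SurveyDataset(self.df.copy(), validate=False)

    def equals(self, other: "SurveyDataset") -> bool:
        return self.df.equals(other.df)

    def __eq__(self, other) -> bool:  # convenience for tests
        return isinstance(other, SurveyDataset) and self.equals(other)

    def __len__(self) -> int:
        return self.n

    def __repr__(self) -> str:
        return (
            f"SurveyDataset(n={self.n}, sites={self.df['site_id'].nunique()}, "
            f"interviewers={self.df['interviewer_id'].nunique()}, "
            f"households={self.df['household_id'].nunique()}, missing={self.n_missing})"
        )


def write_dataset(data: SurveyDataset, path: str | os.PathLike) -> None:
    """Write a dataset as comma-separated text (missing outcome -> empty cell)."""
    df = data.df.copy()
    y = df["outcome"]
    df["outcome"] = np.where(y.isna(), "", y.fillna(0).astype(int).astype(str))
    df.to_csv(path, index=False, lineterminator="\n")


def read_dataset(path: str | os.PathLike) -> SurveyDataset:
    """Read a dataset written by :func:`write_dataset`.

    Raises :class:`ParseError` naming the offending line for malformed rows and
    :class:`IntegrityError` for violated cluster invariants.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: missing columns {missing_cols}")
    n_fields = df.shape[1]
    if n_fields != len(COLUMNS):
        extra = [c for c in df.columns if c not in COLUMNS]
        raise ParseError(f"{path}: unexpected columns {extra}")
    raw = df["outcome"].str.strip()
    ok = raw.isin(["", "0", "1"])
    if not ok.all():
        i = int(np.flatnonzero(~ok.to_numpy())[0])
        # +2: header line plus 1-based numbering
        raise ParseError(f"{path}, line {i + 2}: outcome must be 0, 1 or empty, got {raw.iloc[i]!r}")
    df["outcome"] = pd.to_numeric(raw.replace("", np.nan))
    return SurveyDataset(df)
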