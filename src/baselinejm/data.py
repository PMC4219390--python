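"""Dataset containers, validation and CSV interchange.

Two tables describe a joint-model analysis:

* long format — one row per biomarker measurement: ``id``, ``time``,
  ``value``, plus baseline covariate columns repeated within subject;
* survival format — one row per subject: ``id``, ``time`` (observed
  follow-up, years), ``event`` (0/1), covariate columns and optionally
  ``baseline_obs`` (the first observed biomarker value, used by the naive
  comparator model).

Both are plain pandas DataFrames wrapped in thin validating containers so
that every modelling routine can rely on a checked schema.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "LongitudinalData",
    "SurvivalData",
    "read_long_csv",
    "read_surv_csv",
    "write_long_csv",
    "write_surv_csv",
    "validate_joint",
]

_LONG_REQUIRED = ("id", "time", "value")
_SURV_REQUIRED = ("id", "time", "event")


class SchemaError(ValueError):
    """A dataset does not satisfy the required schema or invariants."""


def _check_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} data is missing required columns {missing}")


def _check_numeric(df: pd.DataFrame, cols: Iterable[str], what: str) -> None:
    for c in cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        if vals.isna().any():
            bad = df.loc[vals.isna(), "id"].head(3).tolist()
            raise SchemaError(
                f"{what} column {c!r} has missing or non-numeric entries (e.g. subjects {bad})"
            )


class LongitudinalData:
    """Validated long-format repeated-measurement data.

    Rows are sorted by (id, time) on construction. Every subject must have at
    least one record with a non-missing response; times are non-negative.
    """

    def __init__(self, df: pd.DataFrame):
        _check_columns(df, _LONG_REQUIRED, "longitudinal")
        df = df.copy()
        _check_numeric(df, ("time", "value"), "longitudinal")
        df["time"] = df["time"].astype(float)
        df["value"] = df["value"].astype(float)
        if (df["time"] < 0).any():
            raise SchemaError("longitudinal times must be non-negative")
        if len(df) == 0:
            raise SchemaError("longitudinal data has no records")
        self.df = df.sort_values(["id", "time"], kind="stable").reset_index(drop=True)

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.df.columns if c not in _LONG_REQUIRED]

    @property
    def subject_ids(self) -> np.ndarray:
        return self.df["id"].unique()

    @property
    def n_subjects(self) -> int:
        return self.df["id"].nunique()

    def __len__(self) -> int:
        return len(self.df)


class SurvivalData:
    """Validated one-row-per-subject time-to-event data."""

    def __init__(self, df: pd.DataFrame):
        _check_columns(df, _SURV_REQUIRED, "survival")
        df = df.copy()
        _check_numeric(df, ("time", "event"), "survival")
        df["time"] = df["time"].astype(float)
        df["event"] = df["event"].astype(float)
        if (df["time"] <= 0).any():
            bad = df.loc[df["time"] <= 0, "id"].head(3).tolist()
            raise SchemaError(f"observed times must be positive (subjects {bad})")
        if not df["event"].isin([0.0, 1.0]).all():
            raise SchemaError("event indicator must be 0 or 1")
        df["event"] = df["event"].astype(int)
        dup = df["id"].duplicated()
        if dup.any():
            raise SchemaError(
                f"duplicate survival rows for subjects {df.loc[dup, 'id'].unique()[:3].tolist()}"
            )
        self.df = df.reset_index(drop=True)

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.df.columns if c not in _SURV_REQUIRED]

    @property
    def n_subjects(self) -> int:
        return len(self.df)

    def __len__(self) -> int:
        return len(self.df)


def validate_joint(long: LongitudinalData, surv: SurvivalData) -> None:
    """Cross-validate the two tables for a joint fit.

    Every survival subject needs at least one longitudinal record, and no
    measurement may be taken after the subject's observed event/censoring
    time (the data model assumes biomarker observation stops then).
    """
    long_ids = set(long.df["id"])
    missing = [i for i in surv.df["id"] if i not in long_ids]
    if missing:
        raise SchemaError(f"subjects without longitudinal records: {missing[:5]}")
    obs_time = surv.df.set_index("id")["time"]
    merged = long.df.join(obs_time.rename("_obs_time"), on="id")
    if merged["_obs_time"].isna().any():
        extra = merged.loc[merged["_obs_time"].isna(), "id"].unique()[:5].tolist()
        raise SchemaError(f"longitudinal subjects absent from survival data: {extra}")
    late = merged["time"] > merged["_obs_time"]
    if late.any():
        bad = merged.loc[late, "id"].unique()[:5].tolist()
        raise SchemaError(f"measurements after the observed time for subjects {bad}")


def read_long_csv(path) -> LongitudinalData:
    return LongitudinalData(pd.read_csv(path))


def read_surv_csv(path) -> SurvivalData:
    return SurvivalData(pd.read_csv(path))


def write_long_csv(data: LongitudinalData, path) -> None:
    data.df.to_csv(path, index=False)


def write_surv_csv(data: SurvivalData, path) -> None:
    data.df.to_csv(path, index=False)
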