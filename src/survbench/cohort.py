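"""Cohort table I/O, validation, horizon labeling, and descriptive summaries.

A cohort table holds one row per patient: two mortality risk scores (an
integer 0-100 index and a predicted 1-year death probability), follow-up
time in days from the index prediction date, a death indicator, and
demographic columns. Fixed-time analyses (AUC at a horizon, PPV of a
high-risk flag) require a binary outcome, which right censoring obscures:
patients lost to follow-up before the horizon have unknown status there.
:func:`label_at_horizon` implements the two conventions for such patients —
exclude them (primary) or count them as alive (sensitivity analysis).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "CATEGORICAL_COLUMNS",
    "SchemaError",
    "CohortValidationError",
    "LabeledAtT",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
    "label_at_horizon",
    "summarize_cohort",
]

#: Canonical column names of a cohort table.
REQUIRED_COLUMNS = (
    "patient_id",
    "eolci_score",
    "stanford_prob",
    "followup_days",
    "event",
    "age",
)

#: Demographic columns; missing values map to the literal category "Unknown".
CATEGORICAL_COLUMNS = ("sex", "race", "ethnicity", "clinic")


class SchemaError(ValueError):
    """A required column is missing or unmappable."""


class CohortValidationError(ValueError):
    """One or more rows violate a cohort invariant.

    Attributes
    ----------
    rows : list of int
        Zero-based positional indices of the offending rows.
    """

    def __init__(self, message: str, rows: list[int]):
        super().__init__(message)
        self.rows = rows


@dataclasses.dataclass(frozen=True)
class LabeledAtT:
    """Evaluable subset of a cohort at a fixed horizon with binary labels.

    ``data`` carries the evaluable rows plus a boolean ``is_case`` column:
    a case died on or before the horizon; a control is known alive at the
    horizon. ``n_excluded`` counts patients censored before the horizon
    (zero under the ``censored_as_alive`` convention).
    """

    horizon_days: float
    convention: str
    data: pd.DataFrame
    n_cases: int
    n_controls: int
    n_excluded: int

    @property
    def n_evaluable(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def labels(self) -> np.ndarray:
        """Boolean case indicator over the evaluable rows."""
        return self.data["is_case"].to_numpy()


def _coerce_bool(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False, "t": True, "f": False,
        "dead": True, "alive": False,
    }
    as_str = series.astype(str).str.strip().str.lower()
    unknown = ~as_str.isin(mapping)
    if unknown.any():
        # fall back to numeric 0/1
        numeric = pd.to_numeric(series, errors="coerce")
        if numeric.isna().any() or not numeric.isin([0, 1]).all():
            bad = list(np.flatnonzero(unknown))
            raise CohortValidationError(
                f"event column is not interpretable as boolean in rows {bad[:10]}",
                rows=bad,
            )
        return numeric.astype(bool)
    return as_str.map(mapping).astype(bool)


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a raw cohort frame and return it in canonical form.

    Checks required columns, uniqueness of ``patient_id``, score ranges
    (integer index in [0, 100], probability in [0, 1]) and positive
    follow-up. Missing demographic values become the category ``"Unknown"``.

    Raises
    ------
    SchemaError
        If a required column is absent.
    CohortValidationError
        If any row violates an invariant; the message names the rows.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    out = df.copy()
    out["eolci_score"] = pd.to_numeric(out["eolci_score"])
    out["stanford_prob"] = pd.to_numeric(out["stanford_prob"])
    out["followup_days"] = pd.to_numeric(out["followup_days"])
    out["age"] = pd.to_numeric(out["age"])
    out["event"] = _coerce_bool(out["event"])
    out["patient_id"] = out["patient_id"].astype(str)

    dup = out["patient_id"].duplicated(keep=False)
    if dup.any():
        rows = list(np.flatnonzero(dup))
        ids = sorted(out.loc[dup, "patient_id"].unique())[:5]
        raise CohortValidationError(
            f"duplicate patient_id values (e.g. {ids}) in rows {rows[:10]}", rows=rows
        )

    checks = {
        "eolci_score out of [0, 100]": ~out["eolci_score"].between(0, 100),
        "stanford_prob out of [0, 1]": ~out["stanford_prob"].between(0, 1),
        "followup_days not positive": ~(out["followup_days"] > 0),
    }
    problems = []
    bad_rows: list[int] = []
    for label, mask in checks.items():
        mask = mask | mask.isna()
        if mask.any():
            rows = list(np.flatnonzero(mask.to_numpy()))
            problems.append(f"{label} in rows {rows[:10]}")
            bad_rows.extend(rows)
    if problems:
        raise CohortValidationError("; ".join(problems), rows=sorted(set(bad_rows)))

    for col in CATEGORICAL_COLUMNS:
        if col not in out.columns:
            out[col] = "Unknown"
        else:
            out[col] = out[col].astype(object)
            blank = out[col].isna() | (out[col].astype(str).str.strip() == "")
            out.loc[blank, col] = "Unknown"
            out[col] = out[col].astype(str)
    return out.reset_index(drop=True)


def read_cohort(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> pd.DataFrame:
    """Read and validate a delimited cohort table.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Optional mapping from canonical column names to the file's actual
        header names, so external files can be adapted without code change.
    delimiter
        Field separator (default comma).
    """
    df = pd.read_csv(path, sep=delimiter)
    if schema:
        missing = [src for src in schema.values() if src not in df.columns]
        if missing:
            raise SchemaError(f"schema maps to absent column(s): {missing}")
        df = df.rename(columns={src: dst for dst, src in schema.items()})
    return validate_cohort(df)


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as CSV; :func:`read_cohort` round-trips it."""
    cohort.to_csv(path, index=False)


def label_at_horizon(
    cohort: pd.DataFrame,
    horizon_days: float,
    convention: Literal["exclude_censored", "censored_as_alive"] = "exclude_censored",
) -> LabeledAtT:
    """Binary case/control labels at a fixed horizon under right censoring.

    A case died on or before the horizon (death at exactly the horizon is
    a case). A control has follow-up strictly past the horizon — a patient
    who died *after* the horizon is a control — or was censored exactly at
    the horizon. Patients censored strictly before the horizon are excluded
    under ``exclude_censored`` (the primary convention) or counted as
    controls under ``censored_as_alive`` (the sensitivity analysis).
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    if not horizon_days > 0:
        raise ValueError("horizon_days must be positive")
    if convention not in ("exclude_censored", "censored_as_alive"):
        raise ValueError(f"unknown convention {convention!r}")

    t = cohort["followup_days"].to_numpy(float)
    e = cohort["event"].to_numpy(bool)
    case = e & (t <= horizon_days)
    control = (t > horizon_days) | (~e & (t == horizon_days))
    censored_early = ~case & ~control  # censored strictly before horizon

    if convention == "censored_as_alive":
        control = control | censored_early
        censored_early = np.zeros_like(censored_early)

    keep = case | control
    data = cohort.loc[keep].copy()
    data["is_case"] = case[keep]
    return LabeledAtT(
        horizon_days=float(horizon_days),
        convention=convention,
        data=data,
        n_cases=int(case.sum()),
        n_controls=int(control.sum()),
        n_excluded=int(censored_early.sum()),
    )


def summarize_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Descriptive summary: counts/percentages per categorical level and
    median (IQR) per continuous variable, percentages over nonmissing
    denominators ("Unknown" is a level, not missing)."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    rows = []
    n = len(cohort)
    for col in ("age", "eolci_score", "stanford_prob", "followup_days"):
        x = cohort[col].to_numpy(float)
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        rows.append(
            {"variable": col, "level": "", "n": n, "percent": np.nan,
             "median": med, "iqr_low": q1, "iqr_high": q3}
        )
    for col in CATEGORICAL_COLUMNS:
        if col not in cohort.columns:
            continue
        counts = cohort[col].value_counts()
        for level, count in counts.items():
            rows.append(
                {"variable": col, "level": level, "n": int(count),
                 "percent": 100.0 * count / n,
                 "median": np.nan, "iqr_low": np.nan, "iqr_high": np.nan}
            )
    return pd.DataFrame(rows)
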