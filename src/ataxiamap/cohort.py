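"""Long-format longitudinal cohort container, validation, and CSV I/O.

A cohort is a long table of visits: one row per (subject, visit) with the
subject's age in years, one ordinal score column per scale item, and optional
cofactors (SCA genotype, sex, expanded CAG repeat length, source cohort,
continent).  Missing item scores are empty CSV cells; visits where every item
is missing are dropped on load.  Ages are real-valued years; disease duration
is always derived, never stored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .scales import SARA, ScaleDefinition, sum_score

logger = logging.getLogger(__name__)

SCA_TYPES = ("SCA1", "SCA2", "SCA3", "SCA6")
COHORT_NAMES = ("EUROSCA", "CRC-SCA", "RISCA", "SPATAX")
COFACTOR_COLUMNS = ("sca_type", "sex", "cag", "cohort", "continent")


class CohortValidationError(ValueError):
    """Raised when a visit table violates the cohort contract."""


@dataclass
class Cohort:
    """Validated long-format visit table bound to a scale definition.

    ``df`` has columns ``subject_id``, ``age``, the scale's item columns
    (float dtype, NaN = missing) and any of the known cofactor columns.
    Within each subject, visit ages are strictly increasing.
    """

    df: pd.DataFrame
    scale: ScaleDefinition

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        df, scale = self.df, self.scale
        required = ["subject_id", "age", *scale.columns]
        missing_cols = [c for c in required if c not in df.columns]
        if missing_cols:
            raise CohortValidationError(f"missing required columns: {missing_cols}")
        known = set(required) | set(COFACTOR_COLUMNS)
        unknown = [c for c in df.columns if c not in known]
        if unknown:
            raise CohortValidationError(f"unknown columns: {unknown}")
        if len(df) == 0:
            return
        ages = pd.to_numeric(df["age"], errors="raise")
        if not np.all(ages > 0):
            bad = df.loc[~(ages > 0), "subject_id"].iloc[0]
            raise CohortValidationError(f"non-positive age for subject {bad!r}")
        for column, (item, maximum) in zip(scale.columns, scale.items):
            values = df[column]
            present = values.notna()
            levels = values[present]
            if len(levels) and (
                (levels < 0).any()
                or (levels > maximum).any()
                or (levels != levels.round()).any()
            ):
                row = df.loc[present & ((values < 0) | (values > maximum)
                                        | (values != values.round()))].iloc[0]
                raise CohortValidationError(
                    f"score {row[column]!r} out of range for item {item!r} "
                    f"(maximum {maximum}) at subject {row['subject_id']!r} "
                    f"age {row['age']}"
                )
        for subject, group in df.groupby("subject_id", sort=False):
            a = group["age"].to_numpy(dtype=float)
            if np.any(np.diff(a) <= 0):
                if np.any(np.diff(np.sort(a)) == 0):
                    raise CohortValidationError(
                        f"duplicate visit age for subject {subject!r}"
                    )
                raise CohortValidationError(
                    f"visit ages not strictly increasing for subject {subject!r}"
                )
        if "sca_type" in df.columns:
            bad = set(df["sca_type"].dropna()) - set(SCA_TYPES)
            if bad:
                raise CohortValidationError(f"unknown SCA types: {sorted(bad)}")
        if "cohort" in df.columns:
            bad = set(df["cohort"].dropna()) - set(COHORT_NAMES)
            if bad:
                raise CohortValidationError(f"unknown cohort names: {sorted(bad)}")
        if "cag" in df.columns:
            cag = pd.to_numeric(df["cag"], errors="raise")
            if (cag.dropna() < 1).any():
                raise CohortValidationError("CAG repeat length must be >= 1")

    # -- convenience --------------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return self.df["subject_id"].nunique()

    @property
    def n_visits(self) -> int:
        return len(self.df)

    @property
    def subject_ids(self) -> list[str]:
        return list(dict.fromkeys(self.df["subject_id"]))

    def total_scores(self) -> pd.Series:
        """Per-visit total score; NaN when any item is missing."""
        items = self.df[list(self.scale.columns)]
        totals = items.sum(axis=1)
        totals[items.isna().any(axis=1)] = np.nan
        return totals

    def baseline(self) -> pd.DataFrame:
        """First visit per subject (the minimum age row)."""
        return self.df.loc[self.df.groupby("subject_id")["age"].idxmin()]

    def subject_visits(self, subject_id: str) -> pd.DataFrame:
        return self.df[self.df["subject_id"] == subject_id]


def load_cohort(path: str | Path, scale: ScaleDefinition = SARA) -> Cohort:
    """Read and validate a long-format cohort CSV.

    Empty score cells become missing; visits with every item missing are
    dropped (their count is logged).  Raises
    :class:`CohortValidationError` for out-of-range scores, non-increasing
    or duplicate visit ages, and unknown columns.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    if "subject_id" not in df.columns or "age" not in df.columns:
        raise CohortValidationError("CSV must have subject_id and age columns")
    for column in scale.columns:
        if column not in df.columns:
            raise CohortValidationError(f"CSV missing item column {column!r}")
        df[column] = pd.to_numeric(df[column], errors="raise")
    all_missing = df[list(scale.columns)].isna().all(axis=1)
    if all_missing.any():
        logger.info("dropping %d visits with all items missing", int(all_missing.sum()))
        df = df[~all_missing]
    return Cohort(df=df, scale=scale)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the cohort back to CSV (UTF-8, comma, empty cell = missing).

    Integer-valued scores are written without a decimal part so that a
    load/write round-trip reproduces all non-missing values exactly.
    """
    df = cohort.df.copy()
    for column in cohort.scale.columns:
        df[column] = df[column].astype("Int64")
    if "cag" in df.columns:
        df["cag"] = df["cag"].astype("Int64")
    df.to_csv(path, index=False)


def summarize_cohort(cohort: Cohort, by: str | None = "sca_type") -> pd.DataFrame:
    """Descriptive summary: median/IQR of age, visits, follow-up, baseline total.

    One row per group of the ``by`` cofactor (if present) plus an ``overall``
    row.  Partially missing visits enter wherever their available values
    allow (available-case analysis); no hypothesis tests are computed.
    """
    if cohort.n_visits == 0:
        raise CohortValidationError("cannot summarize an empty cohort")
    df = cohort.df.copy()
    df["total"] = cohort.total_scores()

    def one_group(sub: pd.DataFrame, label: str) -> dict:
        per_subject = sub.groupby("subject_id")["age"].agg(["min", "max", "count"])
        baseline_idx = sub.groupby("subject_id")["age"].idxmin()
        baseline_total = sub.loc[baseline_idx, "total"].dropna()
        follow_up = per_subject["max"] - per_subject["min"]
        row = {
            "group": label,
            "n_subjects": len(per_subject),
            "n_visits": int(per_subject["count"].sum()),
            "age_median": sub["age"].median(),
            "age_iqr_low": sub["age"].quantile(0.25),
            "age_iqr_high": sub["age"].quantile(0.75),
            "visits_median": per_subject["count"].median(),
            "followup_median": follow_up.median(),
            "followup_iqr_low": follow_up.quantile(0.25),
            "followup_iqr_high": follow_up.quantile(0.75),
            "baseline_total_median": baseline_total.median(),
            "baseline_total_iqr_low": baseline_total.quantile(0.25),
            "baseline_total_iqr_high": baseline_total.quantile(0.75),
        }
        for cofactor in ("sex", "sca_type", "cohort", "continent"):
            if cofactor in sub.columns and cofactor != by:
                counts = sub.loc[baseline_idx, cofactor].value_counts()
                for value, count in counts.items():
                    row[f"{cofactor}={value}_n"] = int(count)
                    row[f"{cofactor}={value}_pct"] = 100.0 * count / len(per_subject)
        return row

    rows = [one_group(df, "overall")]
    if by is not None and by in df.columns:
        for value, sub in df.groupby(by, sort=True):
            rows.append(one_group(sub, str(value)))
    return pd.DataFrame(rows)
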