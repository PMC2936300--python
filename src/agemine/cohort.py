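"""Cohort container: subjects x mixed-type predictors plus survival outcome.

The :class:`CohortTable` is the universal currency of the pipeline.  It wraps
a :class:`pandas.DataFrame` of predictors, a metadata table describing each
predictor's class (continuous / ordinal / categorical / indicator), and the
outcome triple ``(time_years, event, cause)``.  Round-trips to plain-text CSV
(cohort) + TSV (variable metadata sidecar).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CAUSES = ("cardiovascular", "cancer", "other", "accidental", "alive")
OUTCOME_COLUMNS = ("time_years", "event", "cause")

VAR_CLASSES = ("continuous", "ordinal", "categorical", "indicator")


@dataclass
class VariableMeta:
    name: str
    var_class: str
    n_levels: int | None = None
    missing_fraction: float = 0.0
    log_transformed: bool = False
    source_var: str | None = None  # for indicators: the original categorical
    level: str | None = None       # for indicators: the encoded level

    def __post_init__(self) -> None:
        if self.var_class not in VAR_CLASSES:
            raise ValueError(f"unknown var_class {self.var_class!r}")
        if not 0.0 <= self.missing_fraction <= 1.0:
            raise ValueError("missing_fraction must be in [0, 1]")


class CohortTable:
    """One row per subject; mixed-type predictors plus (time, event, cause).

    Invariants enforced at construction: ``event == 0`` exactly for subjects
    whose cause is ``alive`` or ``accidental``; metadata covers every
    predictor column.
    """

    def __init__(
        self,
        predictors: pd.DataFrame,
        time_years: np.ndarray,
        event: np.ndarray,
        cause: np.ndarray,
        metadata: list[VariableMeta] | pd.DataFrame,
        outcomes: pd.DataFrame | None = None,
    ) -> None:
        self.predictors = predictors.reset_index(drop=True)
        self.time_years = np.asarray(time_years, dtype=float)
        self.event = np.asarray(event, dtype=int)
        self.cause = np.asarray(cause, dtype=object)
        if isinstance(metadata, pd.DataFrame):
            self.metadata = metadata.reset_index(drop=True)
        else:
            self.metadata = pd.DataFrame([vars(m) for m in metadata])
        self.outcomes = None if outcomes is None else outcomes.reset_index(drop=True)
        self._validate()

    # -- basic protocol -----------------------------------------------------

    def _validate(self) -> None:
        n = len(self.predictors)
        if not (len(self.time_years) == len(self.event) == len(self.cause) == n):
            raise ValueError("outcome vectors must match predictor row count")
        if np.any(self.time_years < 0):
            raise ValueError("time_years must be non-negative")
        unknown = set(self.cause) - set(CAUSES)
        if unknown:
            raise ValueError(f"unknown causes: {sorted(unknown)}")
        censored = np.isin(self.cause, ("alive", "accidental"))
        if not np.array_equal(self.event == 0, censored):
            raise ValueError("event=0 must coincide with cause in {alive, accidental}")
        meta_names = set(self.metadata["name"])
        cols = set(self.predictors.columns)
        if meta_names != cols:
            missing = cols - meta_names
            extra = meta_names - cols
            raise ValueError(
                f"metadata/predictor mismatch (uncovered={sorted(missing)[:5]}, "
                f"dangling={sorted(extra)[:5]})"
            )

    def __len__(self) -> int:
        return len(self.predictors)

    @property
    def n_subjects(self) -> int:
        return len(self)

    @property
    def variable_names(self) -> list[str]:
        return list(self.predictors.columns)

    def variables_of_class(self, var_class: str) -> list[str]:
        sel = self.metadata.loc[self.metadata["var_class"] == var_class, "name"]
        return list(sel)

    def meta_for(self, name: str) -> pd.Series:
        row = self.metadata.loc[self.metadata["name"] == name]
        if row.empty:
            raise KeyError(name)
        return row.iloc[0]

    def copy(self) -> "CohortTable":
        return CohortTable(
            self.predictors.copy(),
            self.time_years.copy(),
            self.event.copy(),
            self.cause.copy(),
            self.metadata.copy(),
            None if self.outcomes is None else self.outcomes.copy(),
        )

    def replace(self, predictors: pd.DataFrame | None = None,
                metadata: pd.DataFrame | None = None) -> "CohortTable":
        return CohortTable(
            self.predictors if predictors is None else predictors,
            self.time_years,
            self.event,
            self.cause,
            self.metadata if metadata is None else metadata,
            self.outcomes,
        )

    def subset(self, mask: np.ndarray) -> "CohortTable":
        mask = np.asarray(mask, dtype=bool)
        return CohortTable(
            self.predictors.loc[mask],
            self.time_years[mask],
            self.event[mask],
            self.cause[mask],
            self.metadata,
            None if self.outcomes is None else self.outcomes.loc[mask],
        )

    def design_matrix(self, variables: list[str]) -> np.ndarray:
        """Float design matrix for model fitting (no NaNs expected)."""
        X = self.predictors[variables].to_numpy(dtype=float)
        return X

    # -- I/O ----------------------------------------------------------------

    def to_csv(self, cohort_path, metadata_path) -> None:
        df = self.predictors.copy()
        df.insert(0, "subject_id", np.arange(len(df)))
        df["time_years"] = self.time_years
        df["event"] = self.event
        df["cause"] = self.cause
        if self.outcomes is not None:
            for col in self.outcomes.columns:
                df[col] = self.outcomes[col].to_numpy()
        df.to_csv(cohort_path, index=False)
        self.metadata.to_csv(metadata_path, sep="\t", index=False)

    @classmethod
    def read_csv(cls, cohort_path, metadata_path) -> "CohortTable":
        df = pd.read_csv(cohort_path)
        meta = pd.read_csv(metadata_path, sep="\t")
        meta = meta.where(pd.notna(meta), None)
        pred_cols = [c for c in meta["name"] if c in df.columns]
        outcome_cols = [
            c for c in df.columns
            if c not in pred_cols and c not in OUTCOME_COLUMNS and c != "subject_id"
        ]
        outcomes = df[outcome_cols] if outcome_cols else None
        return cls(
            df[pred_cols],
            df["time_years"].to_numpy(),
            df["event"].to_numpy(),
            df["cause"].to_numpy(),
            meta,
            outcomes,
        )
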