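"""Longitudinal ALSFRS-R trajectory containers and CSV input/output.

A cohort is stored long-format: one row per clinic visit with a patient
identifier, decimal months since symptom onset and either the total
ALSFRS-R score (0-48) or the 12 item sub-scores (0-4 each), which are
summed here.  Visits may arrive in any order and are rearranged in
increasing chronological order per patient; duplicate timestamps and
out-of-range scores are errors, never silently coerced.  Non-monotonic
score sequences (a patient transiently gaining points between visits) are
valid input — real trajectories show such gains.

Time is decimal months since onset; calendar dates are never parsed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConflictError,
    DuplicateVisitError,
    FormatError,
    MissingItemError,
    ValidationError,
)

__all__ = [
    "N_ITEMS",
    "Observation",
    "PatientTrajectory",
    "sum_subscores",
    "read_cohort",
    "write_cohort",
]

#: The ALSFRS-R instrument: 12 items, each scored 0 (worst) to 4 (normal).
N_ITEMS = 12
ITEM_COLUMNS = tuple(f"item_{i}" for i in range(1, N_ITEMS + 1))
BASE_COLUMNS = ("patient_id", "months_since_onset", "total_score")
DEMOGRAPHIC_COLUMNS = ("onset_age", "sex", "onset_site")

VALID_SEX = frozenset({"male", "female", "unknown"})
VALID_ONSET_SITE = frozenset({"bulbar", "lower_limb", "upper_limb", "unknown"})


@dataclass(frozen=True)
class Observation:
    """One clinic visit: months since symptom onset and the total score."""

    months_since_onset: float
    total_score: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.months_since_onset) or self.months_since_onset <= 0:
            raise ValidationError(
                f"months_since_onset must be finite and > 0, got {self.months_since_onset!r}"
            )
        if not math.isfinite(self.total_score) or not 0 <= self.total_score <= 48:
            raise ValidationError(
                f"total_score must be in [0, 48], got {self.total_score!r}"
            )


@dataclass(frozen=True)
class PatientTrajectory:
    """Chronologically ordered visits of one patient plus demographics.

    Fitting eligibility requires at least three observations; demographics
    are optional and never used by the progression model itself.
    """

    patient_id: str
    observations: tuple[Observation, ...]
    onset_age: float | None = None
    sex: str = "unknown"
    onset_site: str = "unknown"

    def __post_init__(self) -> None:
        object.__setattr__(self, "observations", tuple(self.observations))
        months = [o.months_since_onset for o in self.observations]
        if any(b <= a for a, b in zip(months, months[1:])):
            raise ValidationError(
                f"patient {self.patient_id}: observations must be strictly "
                "increasing in months_since_onset"
            )
        if self.sex not in VALID_SEX:
            raise ValidationError(f"sex must be one of {sorted(VALID_SEX)}")
        if self.onset_site not in VALID_ONSET_SITE:
            raise ValidationError(f"onset_site must be one of {sorted(VALID_ONSET_SITE)}")
        if self.onset_age is not None and not (
            math.isfinite(self.onset_age) and self.onset_age > 0
        ):
            raise ValidationError(f"onset_age must be > 0 years, got {self.onset_age!r}")

    @property
    def n_observations(self) -> int:
        return len(self.observations)

    @property
    def months(self) -> np.ndarray:
        """Visit times as a float array (months since onset)."""
        return np.array([o.months_since_onset for o in self.observations], dtype=float)

    @property
    def scores(self) -> np.ndarray:
        """Total ALSFRS-R scores as a float array."""
        return np.array([o.total_score for o in self.observations], dtype=float)

    @property
    def is_fit_eligible(self) -> bool:
        """At least three successive total scores are required for fitting."""
        return self.n_observations >= 3


def sum_subscores(item_scores: Sequence) -> int:
    """Sum the 12 ALSFRS-R item sub-scores into a total in [0, 48].

    Raises
    ------
    MissingItemError
        If fewer/more than 12 items are given or any item is missing (None/NaN).
    ValidationError
        If any item is not an integer in [0, 4].
    """
    items = list(item_scores)
    if len(items) != N_ITEMS:
        raise MissingItemError(f"expected {N_ITEMS} item scores, got {len(items)}")
    total = 0
    for i, v in enumerate(items, start=1):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise MissingItemError(f"item_{i} is missing")
        if isinstance(v, float) and not v.is_integer():
            raise ValidationError(f"item_{i} must be an integer score, got {v!r}")
        v = int(v)
        if not 0 <= v <= 4:
            raise ValidationError(f"item_{i} must be in [0, 4], got {v}")
        total += v
    return total


def _resolve_columns(df: pd.DataFrame, columns: Mapping[str, str] | None) -> pd.DataFrame:
    """Apply an optional {canonical: actual} column-name remapping."""
    if columns:
        rename = {actual: canonical for canonical, actual in columns.items()}
        df = df.rename(columns=rename)
    return df


def read_cohort(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
) -> list[PatientTrajectory]:
    """Read a long-format cohort CSV into validated trajectories.

    The file must provide ``patient_id``, ``months_since_onset`` and either
    ``total_score`` or the twelve ``item_1..item_12`` columns (summed here).
    When both are present they must agree row by row.  Optional demographic
    columns (``onset_age``, ``sex``, ``onset_site``) are taken from each
    patient's first row.  Visits are sorted ascending in time per patient.

    Parameters
    ----------
    path:
        CSV file path (RFC-4180, UTF-8).
    columns:
        Optional mapping from canonical column names to the names actually
        used in the file, e.g. ``{"patient_id": "subject"}``.
    """
    try:
        df = pd.read_csv(path, dtype={0: str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse CSV {path}: {exc}") from exc
    df = _resolve_columns(df, columns)

    for col in ("patient_id", "months_since_onset"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    has_total = "total_score" in df.columns
    has_items = all(c in df.columns for c in ITEM_COLUMNS)
    if not has_total and not has_items:
        raise FormatError("need either a total_score column or item_1..item_12")

    trajectories: list[PatientTrajectory] = []
    for pid, group in df.groupby("patient_id", sort=True):
        obs: list[tuple[float, Observation]] = []
        seen_times: set[float] = set()
        for idx, row in group.iterrows():
            try:
                months = float(row["months_since_onset"])
            except (TypeError, ValueError) as exc:
                raise FormatError("unparseable months_since_onset", row=int(idx)) from exc
            if months in seen_times:
                raise DuplicateVisitError(
                    f"patient {pid}: duplicate visit at {months} months (row {idx})"
                )
            seen_times.add(months)

            total: float | None = None
            if has_total and not pd.isna(row["total_score"]):
                total = float(row["total_score"])
            if has_items:
                raw = [None if pd.isna(row[c]) else row[c] for c in ITEM_COLUMNS]
                if any(v is not None for v in raw) or total is None:
                    item_total = float(sum_subscores(raw))
                    if total is not None and total != item_total:
                        raise ConflictError(
                            f"patient {pid} row {idx}: total_score {total} != "
                            f"sum of items {item_total}"
                        )
                    total = item_total
            if total is None:
                raise FormatError("row has neither total_score nor item scores", row=int(idx))
            try:
                obs.append((months, Observation(months, total)))
            except ValidationError as exc:
                raise ValidationError(f"patient {pid} row {idx}: {exc}") from exc

        obs.sort(key=lambda t: t[0])
        first = group.iloc[0]
        onset_age = None
        if "onset_age" in group.columns and not pd.isna(first.get("onset_age")):
            onset_age = float(first["onset_age"])
        sex = str(first["sex"]) if "sex" in group.columns and not pd.isna(first.get("sex")) else "unknown"
        site = (
            str(first["onset_site"])
            if "onset_site" in group.columns and not pd.isna(first.get("onset_site"))
            else "unknown"
        )
        trajectories.append(
            PatientTrajectory(
                patient_id=str(pid),
                observations=tuple(o for _, o in obs),
                onset_age=onset_age,
                sex=sex,
                onset_site=site,
            )
        )
    return trajectories


def write_cohort(cohort: Iterable[PatientTrajectory], path: str | Path) -> None:
    """Write trajectories as a long-format CSV, one row per visit.

    Columns are emitted in a stable order; real-valued fields keep full
    precision (Python ``repr`` round-trips doubles exactly).  An empty
    cohort produces a header-only file.
    """
    rows = []
    for traj in cohort:
        for o in traj.observations:
            rows.append(
                {
                    "patient_id": traj.patient_id,
                    "months_since_onset": o.months_since_onset,
                    "total_score": o.total_score,
                    "onset_age": traj.onset_age,
                    "sex": traj.sex,
                    "onset_site": traj.onset_site,
                }
            )
    df = pd.DataFrame(rows, columns=list(BASE_COLUMNS) + list(DEMOGRAPHIC_COLUMNS))
    df.to_csv(path, index=False)
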