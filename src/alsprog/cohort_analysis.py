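"""Cohort-level outputs: progressor classification, descriptive summaries
of initial vs optimal parameters, observed-vs-predicted agreement and
parameter-relationship regressions.

The slow/fast dichotomy uses the conventional decline rate in points/month
with the 0.365 cut-off from the ALS progression literature; the threshold
applies to the linear slope, never to the fitted shape parameter.
Agreement between observed and model-predicted scores is quantified by the
squared Pearson correlation, the two-way absolute-agreement single-measures
intraclass correlation (ICC) and Cronbach's alpha over the two measurement
columns.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .errors import ValidationError
from .model_fitting import FitResult

__all__ = [
    "SLOW_PROGRESSOR_THRESHOLD",
    "AgreementReport",
    "RegressionReport",
    "classify_progressor",
    "summarize_cohort",
    "agreement",
    "relate_parameters",
    "write_summary_csv",
]

#: Conventional decline rate (points/month) below which a patient is a slow
#: progressor; the boundary value itself is fast by the strict inequality.
SLOW_PROGRESSOR_THRESHOLD = 0.365

ProgressorClass = Literal["slow", "fast"]


def classify_progressor(conventional_slope: float) -> ProgressorClass:
    """Dichotomize a conventional decline rate at 0.365 points/month."""
    if not conventional_slope > 0:
        raise ValidationError(
            f"classification needs a positive decline rate, got {conventional_slope}"
        )
    return "slow" if conventional_slope < SLOW_PROGRESSOR_THRESHOLD else "fast"


def _describe(values: Sequence[float]) -> dict:
    arr = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    n = len(arr)
    return {
        "n": n,
        "minimum": float(arr.min()) if n else np.nan,
        "maximum": float(arr.max()) if n else np.nan,
        "mean": float(arr.mean()) if n else np.nan,
        # sample SD (n-1 denominator); undefined, not 0, for a single value
        "sd": float(arr.std(ddof=1)) if n >= 2 else np.nan,
    }


def summarize_cohort(fit_results: Iterable[FitResult]) -> pd.DataFrame:
    """Descriptive statistics of initial and optimal parameter values.

    Patients are grouped by fit outcome (``converged`` vs everything else)
    and, within each group, the initial and optimal ``dx`` and ``D50``
    values are summarized as n / minimum / maximum / mean / sample SD.
    For non-converged patients the optimizer never left the initial values,
    so their "optimal" columns echo the initials.
    """
    results = list(fit_results)
    if not results:
        raise ValidationError("summarize_cohort needs at least one fit result")
    rows = []
    for group_name, members in (
        ("converged", [r for r in results if r.status == "converged"]),
        ("non_converged", [r for r in results if r.status != "converged"]),
    ):
        quantities = {
            "initial_dx": [r.initials.init_dx for r in members if r.initials],
            "optimal_dx": [r.params.dx for r in members],
            "initial_d50": [r.initials.init_d50 for r in members if r.initials],
            "optimal_d50": [r.params.d50 for r in members],
        }
        for qname, values in quantities.items():
            rows.append({"group": group_name, "quantity": qname, **_describe(values)})
    return pd.DataFrame(rows)


def write_summary_csv(summary: pd.DataFrame, path: str | Path) -> None:
    summary.to_csv(path, index=False)


@dataclass(frozen=True)
class AgreementReport:
    """Absolute agreement between observed and model-predicted scores."""

    r_squared: float
    icc_absolute: float
    icc_ci: tuple[float, float]
    cronbach_alpha: float
    n_pairs: int
    degenerate: bool = False  # zero variance in a column

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def agreement(observed: Sequence[float], predicted: Sequence[float]) -> AgreementReport:
    """Reliability analysis of observed vs model-predicted scores.

    R-squared is the squared Pearson correlation; the ICC is the two-way
    random-effects, absolute-agreement, single-measures form (with its
    large-sample confidence interval); Cronbach's alpha treats the two
    columns as items.  Zero variance in either column sets the degenerate
    flag (metrics that remain well defined are still reported — identical
    columns are perfect agreement).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValidationError("observed and predicted must be equal-length 1-D lists")
    n = len(obs)
    if n < 3:
        raise ValidationError("agreement needs at least 3 pairs")
    degenerate = bool(np.isclose(obs.std(), 0.0) or np.isclose(pred.std(), 0.0))

    if np.allclose(obs, pred) and not degenerate:
        # identical columns: every agreement statistic is exactly 1
        return AgreementReport(1.0, 1.0, (1.0, 1.0), 1.0, n)

    if degenerate:
        r2 = float("nan")
    else:
        r2 = float(stats.pearsonr(obs, pred)[0] ** 2)

    long = pd.DataFrame(
        {
            "visit": np.tile(np.arange(n), 2),
            "rater": np.repeat(["observed", "predicted"], n),
            "score": np.concatenate([obs, pred]),
        }
    )
    icc_table = pg.intraclass_corr(
        data=long, targets="visit", raters="rater", ratings="score"
    ).set_index("Type")
    row = icc_table.loc["ICC(A,1)"]  # two-way random, absolute agreement, single measures
    icc = float(row["ICC"])
    ci = tuple(float(v) for v in row["CI95"])
    alpha = float(pg.cronbach_alpha(data=pd.DataFrame({"observed": obs, "predicted": pred}))[0])
    return AgreementReport(r2, icc, ci, alpha, n, degenerate)


@dataclass(frozen=True)
class RegressionReport:
    """Ordinary least-squares line through parameter pairs."""

    slope: float
    intercept: float
    r_squared: float
    n_pairs: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def relate_parameters(pairs: Sequence[tuple[float, float]]) -> RegressionReport:
    """OLS regression of y on x for parameter pairs such as (dx, D50) or
    (conventional D50, optimal D50)."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValidationError("relate_parameters needs at least 3 (x, y) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.isclose(x.std(), 0.0):
        raise ValidationError("zero variance in x: no regression line exists")
    res = stats.linregress(x, y)
    return RegressionReport(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_pairs=len(x),
    )
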