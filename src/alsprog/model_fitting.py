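"""Per-patient constrained nonlinear least-squares fitting of the logistic
decline model, with case-resampling bootstrap confidence intervals and
explicit degenerate-fit detection.

The objective is the sum of squared residuals between observed total
ALSFRS-R scores and the logistic curve; optimization uses a bounded
trust-region least-squares solver with an analytic Jacobian.  ``Ymax`` is
fixed at 48 by default (the instrument's theoretical maximum); a
free-but-bounded mode and a fully unconstrained diagnostic mode exist to
probe what happens without that constraint.

A fit can end in one of four states:

``converged``
    The optimizer succeeded and strictly improved on the initial values.
``degenerate_initial``
    The optimizer terminated at (or epsilon-close to) the initial values
    without improving the objective — the hallmark failure of slow
    progressors initialized with a points/month slope as ``dx``: the
    initial curve is a near-vertical cliff far from the data, the gradient
    is numerically zero, and the solver stops after 0 useful evaluations.
``boundary``
    A parameter finished pinned to a bound.
``failed``
    Anything else (including trajectories whose conventional slope is not
    a positive decline rate, for which no initialization exists).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit

from .errors import EligibilityError, ZeroSlopeError
from .initial_estimation import InitialEstimates, InitMode, SlopeMethod, estimate_initials
from .progression_model import YMAX_DEFAULT, LogisticParams, predict_score
from .trajectory_io import PatientTrajectory

__all__ = [
    "FitConfig",
    "FitResult",
    "BootstrapResult",
    "UnconstrainedDiagnostic",
    "fit_patient",
    "bootstrap_ci",
    "diagnose_unconstrained",
    "results_to_frame",
    "write_results_csv",
    "write_results_json",
]

FitStatus = Literal["converged", "degenerate_initial", "boundary", "failed"]


@dataclass(frozen=True)
class FitConfig:
    """Knobs of the per-patient fit.

    ``fix_ymax_at_48`` fixes the asymptote at the instrument maximum (the
    default analysis).  With it off, ``constrain_ymax`` keeps the free
    asymptote within (0, 48]; turning both off is the unconstrained
    diagnostic.  Bounds are in months.  ``seed`` drives every stochastic
    step (the bootstrap) and is recorded in all serialized output.
    """

    fix_ymax_at_48: bool = True
    constrain_ymax: bool = True
    bounds_d50: tuple[float, float] = (1e-3, 600.0)
    bounds_dx: tuple[float, float] = (1e-3, 200.0)
    init_mode: InitMode = "converted"
    slope_method: SlopeMethod = "two_point"
    max_iterations: int = 200
    tolerance: float = 1e-10
    n_bootstrap: int = 1000
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.bounds_d50, self.bounds_dx):
            if not (0 < lo < hi and np.isfinite(hi)):
                raise ValueError("bounds must be positive finite intervals")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass(frozen=True)
class FitResult:
    """Outcome of one patient's fit."""

    patient_id: str
    params: LogisticParams
    initials: InitialEstimates | None
    status: FitStatus
    sse: float
    sse_initial: float
    n_iterations: int
    predicted: tuple[float, ...]
    ci_d50: tuple[float, float] | None = None
    ci_dx: tuple[float, float] | None = None
    message: str = ""

    @property
    def converged(self) -> bool:
        return self.status == "converged"


@dataclass(frozen=True)
class BootstrapResult:
    """Percentile bootstrap intervals for (D50, dx)."""

    ci_d50: tuple[float, float]
    ci_dx: tuple[float, float]
    n_replicates: int
    n_failed: int
    wide_interval_warning: bool  # > 50% replicate fits failed

    @property
    def failure_rate(self) -> float:
        return self.n_failed / self.n_replicates if self.n_replicates else 0.0


@dataclass(frozen=True)
class UnconstrainedDiagnostic:
    """What an unconstrained-asymptote refit predicts.

    ``out_of_range`` is True when the refitted curve, evaluated from
    symptom onset through the last visit, predicts scores above 48 or
    below 0 — the pathology the 0-48 constraint exists to prevent.
    """

    fit: FitResult
    max_prediction: float
    min_prediction: float
    out_of_range: bool


def _sse(y: np.ndarray, pred: np.ndarray) -> float:
    return float(np.sum((y - pred) ** 2))


def _curve(theta: np.ndarray, x: np.ndarray, fixed_ymax: float | None) -> np.ndarray:
    if fixed_ymax is None:
        ymax, d50, dx = theta
    else:
        ymax, (d50, dx) = fixed_ymax, theta
    return ymax * expit(-(x - d50) / dx)


def _jac(theta: np.ndarray, x: np.ndarray, fixed_ymax: float | None) -> np.ndarray:
    """Jacobian of the residuals (observed - curve) wrt theta."""
    if fixed_ymax is None:
        ymax, d50, dx = theta
    else:
        ymax, (d50, dx) = fixed_ymax, theta
    z = (x - d50) / dx
    s = expit(-z)
    ds = s * (1.0 - s)  # d(expit(-z))/d(-z)
    # curve = ymax * s;  dz/d(d50) = -1/dx ; dz/d(dx) = -z/dx
    dcurve_dd50 = ymax * ds / dx
    dcurve_ddx = ymax * ds * z / dx
    cols = [-dcurve_dd50, -dcurve_ddx]
    if fixed_ymax is None:
        cols.insert(0, -s)
    return np.column_stack(cols)


def _fit_arrays(
    x: np.ndarray,
    y: np.ndarray,
    x0_d50: float,
    x0_dx: float,
    config: FitConfig,
    x0_ymax: float = YMAX_DEFAULT,
) -> tuple[LogisticParams, float, float, int, bool, np.ndarray]:
    """Bounded least-squares core shared by fit, bootstrap and diagnostics.

    Returns (params, sse, sse_initial, n_iterations, optimizer_success, x0).
    """
    if config.fix_ymax_at_48:
        fixed: float | None = YMAX_DEFAULT
        lb = np.array([config.bounds_d50[0], config.bounds_dx[0]])
        ub = np.array([config.bounds_d50[1], config.bounds_dx[1]])
        theta0 = np.array([x0_d50, x0_dx])
    else:
        fixed = None
        if config.constrain_ymax:
            ymax_lo, ymax_hi = 1e-6, YMAX_DEFAULT
        else:
            ymax_lo, ymax_hi = -np.inf, np.inf
        lb = np.array([ymax_lo, config.bounds_d50[0], config.bounds_dx[0]])
        ub = np.array([ymax_hi, config.bounds_d50[1], config.bounds_dx[1]])
        theta0 = np.array([x0_ymax, x0_d50, x0_dx])

    # keep the start strictly interior so TRF accepts it
    span = np.where(np.isfinite(ub - lb), ub - lb, 1.0)
    theta0 = np.clip(theta0, lb + 1e-9 * span, ub - 1e-9 * span)

    def residuals(theta: np.ndarray) -> np.ndarray:
        return y - _curve(theta, x, fixed)

    res = least_squares(
        residuals,
        theta0,
        jac=lambda t: _jac(t, x, fixed),
        bounds=(lb, ub),
        method="trf",
        xtol=config.tolerance,
        ftol=config.tolerance,
        gtol=config.tolerance,
        max_nfev=config.max_iterations * max(len(theta0), 2),
    )
    if fixed is None:
        ymax, d50, dx = res.x
    else:
        ymax, (d50, dx) = fixed, res.x
    params = LogisticParams(d50=float(d50), dx=float(dx), y_max=float(ymax))
    sse0 = _sse(y, _curve(theta0, x, fixed))
    sse1 = float(2.0 * res.cost)
    return params, sse1, sse0, int(res.nfev), bool(res.success), theta0


def _classify_status(
    theta0: np.ndarray,
    params: LogisticParams,
    sse: float,
    sse0: float,
    config: FitConfig,
    success: bool,
) -> FitStatus:
    if config.fix_ymax_at_48:
        theta1 = np.array([params.d50, params.dx])
        bounds = [config.bounds_d50, config.bounds_dx]
    else:
        theta1 = np.array([params.y_max, params.d50, params.dx])
        ymax_bounds = (1e-6, YMAX_DEFAULT) if config.constrain_ymax else (None, None)
        bounds = [ymax_bounds, config.bounds_d50, config.bounds_dx]
    moved = np.max(np.abs(theta1 - theta0) / (1.0 + np.abs(theta0)))
    improved = sse < sse0 * (1.0 - 1e-9) - 1e-12
    if moved < 1e-7 and not improved:
        return "degenerate_initial"
    at_bound = False
    for val, (lo, hi) in zip(theta1, bounds):
        if lo is not None and np.isfinite(lo) and abs(val - lo) <= 1e-8 * (1 + abs(lo)):
            at_bound = True
        if hi is not None and np.isfinite(hi) and abs(val - hi) <= 1e-8 * (1 + abs(hi)):
            at_bound = True
    if at_bound:
        return "boundary"
    if success and (improved or sse <= sse0):
        return "converged"
    return "failed"


def fit_patient(trajectory: PatientTrajectory, config: FitConfig | None = None) -> FitResult:
    """Fit the logistic decline model to one patient's trajectory.

    Requires at least three observations and a positive conventional slope;
    a flat or improving trajectory yields ``status='failed'`` with the
    zero-slope reason rather than an exception, so cohort loops keep going.
    """
    config = config or FitConfig()
    if trajectory.n_observations < 3:
        raise EligibilityError(
            f"patient {trajectory.patient_id}: fitting requires >= 3 observations, "
            f"got {trajectory.n_observations}"
        )
    x, y = trajectory.months, trajectory.scores
    try:
        initials = estimate_initials(trajectory, config.slope_method, config.init_mode)
    except ZeroSlopeError as exc:
        flat = LogisticParams(d50=max(x[-1], 1.0), dx=config.bounds_dx[1])
        return FitResult(
            patient_id=trajectory.patient_id,
            params=flat,
            initials=None,
            status="failed",
            sse=float("nan"),
            sse_initial=float("nan"),
            n_iterations=0,
            predicted=tuple(predict_score(flat, x)),
            message=str(exc),
        )

    params, sse, sse0, nit, success, theta0 = _fit_arrays(
        x, y, initials.init_d50, initials.init_dx, config
    )
    status = _classify_status(theta0, params, sse, sse0, config, success)
    return FitResult(
        patient_id=trajectory.patient_id,
        params=params,
        initials=initials,
        status=status,
        sse=sse,
        sse_initial=sse0,
        n_iterations=nit,
        predicted=tuple(float(v) for v in predict_score(params, x)),
    )


def bootstrap_ci(
    trajectory: PatientTrajectory,
    config: FitConfig | None = None,
    base: FitResult | None = None,
) -> BootstrapResult:
    """Case-resampling bootstrap percentile intervals for (D50, dx).

    Visits are resampled with replacement; draws with fewer than three
    distinct time points are redrawn.  Each replicate is refit starting
    from the base-fit parameters.  Deterministic for a fixed
    ``config.seed``.  If more than half the replicate fits fail, the result
    carries a wide-interval warning instead of raising.
    """
    config = config or FitConfig()
    base = base or fit_patient(trajectory, config)
    if base.status == "failed":
        raise EligibilityError(
            f"patient {trajectory.patient_id}: no base fit to bootstrap ({base.message})"
        )
    x, y = trajectory.months, trajectory.scores
    n = len(x)
    rng = np.random.default_rng(config.seed)
    d50s: list[float] = []
    dxs: list[float] = []
    n_failed = 0
    for _ in range(config.n_bootstrap):
        for _attempt in range(1000):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(x[idx])) >= 3:
                break
        xb, yb = x[idx], y[idx]
        order = np.argsort(xb)
        xb, yb = xb[order], yb[order]
        try:
            params, sse, sse0, _, success, _ = _fit_arrays(
                xb, yb, base.params.d50, base.params.dx, config, x0_ymax=base.params.y_max
            )
        except Exception:
            n_failed += 1
            continue
        if not success or not (np.isfinite(params.d50) and np.isfinite(params.dx)):
            n_failed += 1
            continue
        d50s.append(params.d50)
        dxs.append(params.dx)

    alpha = 1.0 - config.ci_level
    if d50s:
        qs = [100 * alpha / 2, 100 * (1 - alpha / 2)]
        lo50, hi50 = np.percentile(d50s, qs)
        lodx, hidx = np.percentile(dxs, qs)
    else:  # pragma: no cover - every replicate failed
        lo50 = hi50 = lodx = hidx = float("nan")
    return BootstrapResult(
        ci_d50=(float(lo50), float(hi50)),
        ci_dx=(float(lodx), float(hidx)),
        n_replicates=config.n_bootstrap,
        n_failed=n_failed,
        wide_interval_warning=n_failed > 0.5 * config.n_bootstrap,
    )


def diagnose_unconstrained(
    trajectory: PatientTrajectory, config: FitConfig | None = None
) -> UnconstrainedDiagnostic:
    """Refit with the asymptote unconstrained and look for impossible scores.

    The constrained model pins ``Ymax`` to the instrument range; releasing
    it lets the optimizer chase a better SSE with curves whose early-disease
    values exceed 48 (or, for pathological fits, fall below 0).  The refit's
    predictions are scanned on a dense grid from symptom onset through the
    last visit.
    """
    config = config or FitConfig()
    free = replace(config, fix_ymax_at_48=False, constrain_ymax=False)
    if trajectory.n_observations < 3:
        raise EligibilityError("diagnosis requires >= 3 observations")
    x, y = trajectory.months, trajectory.scores
    try:
        initials = estimate_initials(trajectory, free.slope_method, free.init_mode)
    except ZeroSlopeError:
        fit = fit_patient(trajectory, free)  # returns the flagged failed result
        return UnconstrainedDiagnostic(
            fit=fit, max_prediction=float("nan"), min_prediction=float("nan"),
            out_of_range=False,
        )
    params, sse, sse0, nit, success, theta0 = _fit_arrays(
        x, y, initials.init_d50, initials.init_dx, free
    )
    status = _classify_status(theta0, params, sse, sse0, free, success)
    fit = FitResult(
        patient_id=trajectory.patient_id,
        params=params,
        initials=initials,
        status=status,
        sse=sse,
        sse_initial=sse0,
        n_iterations=nit,
        predicted=tuple(float(v) for v in predict_score(params, x)),
    )
    grid = np.linspace(min(0.25, x[0]), x[-1], 512)
    pred = predict_score(params, grid)
    # the asymptote is the curve's predicted early-disease score: a fitted
    # y_max above 48 means the model claims better-than-maximal function
    hi = float(max(np.max(pred), params.y_max))
    lo = float(min(np.min(pred), params.y_max) if params.y_max < 0 else np.min(pred))
    return UnconstrainedDiagnostic(
        fit=fit,
        max_prediction=hi,
        min_prediction=lo,
        out_of_range=hi > YMAX_DEFAULT + 1e-9 or lo < -1e-9,
    )


def results_to_frame(results: Iterable[FitResult]) -> pd.DataFrame:
    """One row per patient: identifiers, status, parameters, SSE, CI bounds."""
    rows = []
    for r in results:
        ini = r.initials
        rows.append(
            {
                "patient_id": r.patient_id,
                "status": r.status,
                "d50": r.params.d50,
                "dx": r.params.dx,
                "y_max": r.params.y_max,
                "sse": r.sse,
                "conventional_slope": ini.conventional_slope if ini else np.nan,
                "initial_dx": ini.init_dx if ini else np.nan,
                "initial_d50": ini.init_d50 if ini else np.nan,
                "ci_d50_low": r.ci_d50[0] if r.ci_d50 else np.nan,
                "ci_d50_high": r.ci_d50[1] if r.ci_d50 else np.nan,
                "ci_dx_low": r.ci_dx[0] if r.ci_dx else np.nan,
                "ci_dx_high": r.ci_dx[1] if r.ci_dx else np.nan,
            }
        )
    return pd.DataFrame(rows)


def write_results_csv(results: Iterable[FitResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, index=False)


def write_results_json(results: Iterable[FitResult], path: str | Path) -> None:
    """Full-precision JSON report including per-visit predictions."""
    payload = []
    for r in results:
        ini = r.initials
        payload.append(
            {
                "patient_id": r.patient_id,
                "status": r.status,
                "params": {"y_max": r.params.y_max, "d50": r.params.d50, "dx": r.params.dx},
                "initials": None
                if ini is None
                else {
                    "conventional_slope": ini.conventional_slope,
                    "init_dx": ini.init_dx,
                    "init_d50": ini.init_d50,
                    "method": ini.method,
                    "mode": ini.mode,
                },
                "sse": r.sse,
                "sse_initial": r.sse_initial,
                "n_iterations": r.n_iterations,
                "predicted": list(r.predicted),
                "ci_d50": list(r.ci_d50) if r.ci_d50 else None,
                "ci_dx": list(r.ci_dx) if r.ci_dx else None,
                "message": r.message,
            }
        )
    Path(path).write_text(json.dumps(payload, indent=2))
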