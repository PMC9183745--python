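"""Sigmoidal logistic model of ALSFRS-R decline.

The revised ALS Functional Rating Scale (ALSFRS-R) runs from 48 (normal
function) down to 0 (maximum disability).  Disease progression is modelled
as a logistic decay in time since symptom onset::

    y(x) = Ymax / (1 + exp((x - D50) / dx))

where ``Ymax`` is the theoretical maximum score (48), ``D50`` is the time in
months at which the modelled score reaches half the maximum (24 points, the
curve's inflection point) and ``dx`` is the shape/steepness denominator in
months — smaller ``dx`` means a steeper functional cliff.  The tangent slope
at the inflection is ``-Ymax / (4 * dx)`` points/month; both quantities are
exposed here because the clinical literature uses "slope" loosely for
either.

All functions are pure and accept scalars or numpy arrays for ``x``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .errors import DomainError, ValidationError

__all__ = [
    "YMAX_DEFAULT",
    "LogisticParams",
    "predict_score",
    "time_at_score",
    "midpoint_slope",
    "truncate_display",
]

#: Theoretical maximum ALSFRS-R total score (12 items x 4 points).
YMAX_DEFAULT = 48.0


@dataclass(frozen=True)
class LogisticParams:
    """Parameters of the logistic decay curve.

    Attributes
    ----------
    d50:
        Months since symptom onset at which the curve crosses ``y_max / 2``
        (24 ALSFRS-R points for the standard ``y_max`` of 48). Must be > 0.
    dx:
        Shape/steepness denominator in months. Must be > 0; the decay
        convention is fixed (growth-shaped curves are fit failures, not
        valid parameters).
    y_max:
        Curve asymptote at early disease. 48 by default; the constrained
        fitter keeps it in (0, 48], but the diagnostic unconstrained fit
        may store values outside that range, so only finiteness and
        non-zeroness are enforced here.
    """

    d50: float
    dx: float
    y_max: float = YMAX_DEFAULT

    def __post_init__(self) -> None:
        for name in ("d50", "dx", "y_max"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise ValidationError(f"{name} must be a finite number, got {v!r}")
        if self.d50 <= 0:
            raise ValidationError(f"d50 must be > 0 months, got {self.d50}")
        if self.dx <= 0:
            raise ValidationError(f"dx must be > 0 months, got {self.dx}")
        if self.y_max == 0:
            raise ValidationError("y_max must be non-zero")


def predict_score(params: LogisticParams, x):
    """Evaluate the logistic decay curve at time(s) ``x`` (months since onset).

    Returns ``y_max / (1 + exp((x - d50) / dx))``, strictly decreasing in
    ``x`` and bounded in ``(0, y_max)`` for positive ``y_max``.  The
    exponential is evaluated through :func:`scipy.special.expit`, which
    saturates gracefully to the asymptotes for extreme ``x`` — the output is
    never non-finite.

    Scalar ``x`` returns a float; array ``x`` returns an ndarray.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("x must be finite")
    # y_max/(1+e^z) == y_max * expit(-z); expit handles |z| overflow.
    y = params.y_max * expit(-(arr - params.d50) / params.dx)
    return float(y) if np.isscalar(x) or arr.ndim == 0 else y


def time_at_score(params: LogisticParams, y: float) -> float:
    """Analytic inverse of :func:`predict_score`.

    Returns the months since onset at which the modelled score equals ``y``:
    ``d50 + dx * ln(y_max / y - 1)``.  The asymptotes ``y = 0`` and
    ``y = y_max`` are unreachable.

    Raises
    ------
    DomainError
        If ``y`` is outside the open interval ``(0, y_max)``.
    """
    if not (0 < y < params.y_max):
        raise DomainError(
            f"score {y} outside the model's open range (0, {params.y_max})"
        )
    return params.d50 + params.dx * math.log(params.y_max / y - 1.0)


def midpoint_slope(params: LogisticParams) -> float:
    """Tangent slope of the curve at its inflection point ``x = d50``.

    Equals ``-y_max / (4 * dx)`` points/month (negative: functional
    decline).  This is the quantity clinicians call the progression rate at
    the scale midpoint; it is distinct from the shape parameter ``dx``.
    """
    return -params.y_max / (4.0 * params.dx)


def truncate_display(value: float, decimals: int = 0) -> float:
    """Truncate ``value`` toward zero at ``decimals`` decimal places, then
    clamp to >= 0 for score display.

    This is the display convention for reported curve values: 31.88 prints
    as 31 (0 decimals), 0.9934 as 0.9 and 0.0931 as 0.0 (1 decimal).
    Internal computation always keeps full precision; use this only at the
    reporting boundary.
    """
    if not math.isfinite(value):
        raise ValidationError(f"cannot truncate non-finite value {value!r}")
    if decimals < 0:
        raise ValidationError("decimals must be >= 0")
    scale = 10.0**decimals
    return max(0.0, math.trunc(value * scale) / scale)
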