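"""Conventional-slope initialization of the logistic fit.

The nonlinear fit needs starting values for ``dx`` and ``D50``.  Both are
derived from the *conventional slope* — the simple linear ALSFRS-R decline
rate in points/month — computed from a minimum set of two scores:

``two_point``
    (first score - last score) / (last time - first time).
``onset_anchored``
    (48 - first score) / first time: the field-standard delta-FRS, which
    anchors the line at the presumed-normal score at symptom onset.

``D50`` is initialized by extending that line to the scale midpoint
(score 24).  For ``dx`` two modes exist because the two historically used
conventions differ by a factor of ``48/(4*slope)``:

``paper``
    The conventional slope (points/month) is passed through verbatim as the
    initial ``dx``.  This mismatches the shape parameter's units and, for
    slow progressors (slope well below 1), yields a near-vertical initial
    curve from which the optimizer cannot improve — a failure mode this
    package reproduces deliberately.
``converted``
    ``48 / (4 * slope)``: the shape-parameter value whose midpoint tangent
    equals the conventional slope.  The numerically sensible default for
    new analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .errors import EligibilityError, ValidationError, ZeroSlopeError
from .progression_model import YMAX_DEFAULT
from .trajectory_io import PatientTrajectory

__all__ = [
    "SCORE_MIDPOINT",
    "InitialEstimates",
    "conventional_slope",
    "initial_d50",
    "initial_dx",
    "estimate_initials",
]

SCORE_MIDPOINT = YMAX_DEFAULT / 2.0  # 24 ALSFRS-R points

SlopeMethod = Literal["two_point", "onset_anchored"]
InitMode = Literal["paper", "converted"]


@dataclass(frozen=True)
class InitialEstimates:
    """Starting values for the nonlinear fit, with their provenance."""

    conventional_slope: float  # points/month, > 0 for decliners
    init_dx: float  # units depend on mode (see module docstring)
    init_d50: float  # months
    method: SlopeMethod = "two_point"
    mode: InitMode = "converted"


def conventional_slope(trajectory: PatientTrajectory, method: SlopeMethod = "two_point") -> float:
    """Linear decline rate in points/month; positive for decliners.

    Returns 0.0 (or a negative value) for flat or improving trajectories —
    a flagged degenerate result, not an exception; downstream consumers
    that need a positive rate raise :class:`ZeroSlopeError`.
    """
    if method == "two_point":
        if trajectory.n_observations < 2:
            raise EligibilityError("two_point slope needs at least 2 observations")
        first, last = trajectory.observations[0], trajectory.observations[-1]
        dt = last.months_since_onset - first.months_since_onset
        if dt <= 0:
            raise ValidationError("elapsed time between first and last visit must be > 0")
        return (first.total_score - last.total_score) / dt
    if method == "onset_anchored":
        if trajectory.n_observations < 1:
            raise EligibilityError("onset_anchored slope needs at least 1 observation")
        first = trajectory.observations[0]
        return (YMAX_DEFAULT - first.total_score) / first.months_since_onset
    raise ValidationError(f"unknown slope method {method!r}")


def initial_d50(trajectory: PatientTrajectory, slope: float) -> float:
    """Months at which the conventional line reaches the scale midpoint (24).

    If the observed scores bracket 24, the crossing is linearly interpolated
    between the bracketing visits; otherwise the line through the last visit
    with the given slope is extrapolated forward (last score above 24) or
    backward (below 24).
    """
    if slope <= 0:
        raise ZeroSlopeError(slope)
    obs = trajectory.observations
    last = obs[-1]
    for a, b in zip(obs, obs[1:]):
        ya, yb = a.total_score, b.total_score
        if ya == SCORE_MIDPOINT:
            return a.months_since_onset
        if (ya - SCORE_MIDPOINT) * (yb - SCORE_MIDPOINT) < 0:
            frac = (ya - SCORE_MIDPOINT) / (ya - yb)
            return a.months_since_onset + frac * (b.months_since_onset - a.months_since_onset)
    if last.total_score == SCORE_MIDPOINT:
        return last.months_since_onset
    # decline rate `slope` is points lost per month, hence the sign flips
    return last.months_since_onset + (last.total_score - SCORE_MIDPOINT) / slope


def initial_dx(slope: float, mode: InitMode = "converted") -> float:
    """Initial value for the shape parameter ``dx`` from the conventional slope.

    ``paper`` passes the points/month slope through verbatim; ``converted``
    returns ``48 / (4 * slope)``, the shape value whose midpoint tangent
    matches the slope.
    """
    if slope <= 0:
        raise ZeroSlopeError(slope)
    if mode == "paper":
        return slope
    if mode == "converted":
        return YMAX_DEFAULT / (4.0 * slope)
    raise ValidationError(f"unknown init mode {mode!r}")


def estimate_initials(
    trajectory: PatientTrajectory,
    method: SlopeMethod = "two_point",
    mode: InitMode = "converted",
) -> InitialEstimates:
    """Bundle slope, initial ``dx`` and initial ``D50`` for one trajectory.

    Raises :class:`ZeroSlopeError` for flat or improving trajectories.
    """
    slope = conventional_slope(trajectory, method)
    if slope <= 0:
        raise ZeroSlopeError(slope)
    return InitialEstimates(
        conventional_slope=slope,
        init_dx=initial_dx(slope, mode),
        init_d50=initial_d50(trajectory, slope),
        method=method,
        mode=mode,
    )
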