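import numpy as np
import pytest

from alsprog import (
    FitConfig,
    LogisticParams,
    Observation,
    PatientTrajectory,
    simulate_trajectory,
)

#: Worked-example parameters of a representative fitted patient.
WORKED_EXAMPLE = LogisticParams(d50=51.724, dx=17.184)


@pytest.fixture
def worked_example_params() -> LogisticParams:
    return WORKED_EXAMPLE


@pytest.fixture
def fast_trajectory() -> PatientTrajectory:
    """Noise-free fast-progressor trajectory from known truth (d50=30, dx=8)."""
    true = LogisticParams(d50=30.0, dx=8.0)
    return simulate_trajectory(true, np.arange(6.0, 55.0, 6.0), 0.0, patient_id="fast")


@pytest.fixture
def slow_trajectory() -> PatientTrajectory:
    """Slow progressor observed entirely before the scale midpoint."""
    true = LogisticParams(d50=120.0, dx=80.0)
    return simulate_trajectory(
        true, np.linspace(6.0, 48.0, 5), 1.5, seed=3, integerize=True, patient_id="slow"
    )


@pytest.fixture
def quick_fit_config() -> FitConfig:
    return FitConfig(n_bootstrap=100, seed=7)


def make_trajectory(points, patient_id="t", **kw) -> PatientTrajectory:
    """Build a trajectory from (months, score) pairs."""
    return PatientTrajectory(
        patient_id=patient_id,
        observations=tuple(Observation(m, s) for m, s in points),
        **kw,
    )
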