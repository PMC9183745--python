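"""Constrained nonlinear fitting, degenerate-fit detection, bootstrap CIs
and the unconstrained-asymptote diagnostic."""

import numpy as np
import pytest

from alsprog import (
    FitConfig,
    LogisticParams,
    bootstrap_ci,
    diagnose_unconstrained,
    fit_patient,
    predict_score,
    simulate_trajectory,
)
from alsprog.errors import EligibilityError
from alsprog.model_fitting import results_to_frame
from conftest import make_trajectory


def grid_best_sse(traj, d50_grid, dx_grid):
    """Brute-force SSE minimum over a (d50, dx) grid — independent of the
    optimizer under test."""
    x, y = traj.months, traj.scores
    d50s, dxs = np.meshgrid(d50_grid, dx_grid, indexing="ij")
    z = (x[None, None, :] - d50s[..., None]) / dxs[..., None]
    pred = 48.0 / (1.0 + np.exp(np.clip(z, -700, 700)))
    sse = np.sum((y[None, None, :] - pred) ** 2, axis=-1)
    return float(sse.min())


class TestFitPatient:
    def test_noise_free_recovery_any_init_mode(self, fast_trajectory):
        for mode in ("paper", "converted"):
            r = fit_patient(fast_trajectory, FitConfig(init_mode=mode))
            assert r.status == "converged"
            assert r.params.d50 == pytest.approx(30.0, rel=1e-6)
            assert r.params.dx == pytest.approx(8.0, rel=1e-6)

    def test_converged_sse_never_worse_than_initials(self, fast_trajectory):
        r = fit_patient(fast_trajectory, FitConfig())
        assert r.sse <= r.sse_initial

    def test_one_prediction_per_visit(self, fast_trajectory):
        r = fit_patient(fast_trajectory, FitConfig())
        assert len(r.predicted) == fast_trajectory.n_observations

    def test_two_visits_ineligible(self):
        with pytest.raises(EligibilityError):
            fit_patient(make_trajectory([(5.0, 45.0), (10.0, 40.0)]), FitConfig())

    def test_flat_trajectory_fails_with_reason(self):
        traj = make_trajectory([(5.0, 40.0), (10.0, 40.0), (15.0, 40.0)])
        r = fit_patient(traj, FitConfig())
        assert r.status == "failed"
        assert "slope" in r.message

    def test_slow_progressor_paper_mode_never_silently_converges(self, slow_trajectory):
        r = fit_patient(slow_trajectory, FitConfig(init_mode="paper"))
        assert r.status in ("degenerate_initial", "boundary")
        # the degenerate fit sits at the initial values
        assert r.params.dx == pytest.approx(r.initials.init_dx, rel=1e-6)
        assert r.params.d50 == pytest.approx(r.initials.init_d50, rel=1e-6)

    def test_constrained_predictions_within_instrument_range(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            true = LogisticParams(d50=float(rng.uniform(15, 50)), dx=float(rng.uniform(2, 12)))
            visits = np.linspace(0.3 * true.d50, 1.7 * true.d50, 7)
            traj = simulate_trajectory(true, visits, 3.0, integerize=True, rng=rng)
            r = fit_patient(traj, FitConfig())
            assert all(0.0 <= p <= 48.0 for p in r.predicted)

    def test_fitted_sse_dominates_brute_force_grid(self):
        """Every converged fit must be at least as good as an exhaustive
        search over d50 in {1..120} x dx in {0.5, 1, ..., 60}."""
        rng = np.random.default_rng(5)
        d50_grid = np.arange(1.0, 121.0)
        dx_grid = np.arange(0.5, 60.5, 0.5)
        checked = 0
        for _ in range(20):
            true = LogisticParams(d50=float(rng.uniform(15, 50)), dx=float(rng.uniform(2, 12)))
            visits = np.linspace(0.3 * true.d50, 1.7 * true.d50, 9)
            traj = simulate_trajectory(true, visits, 2.0, integerize=True, rng=rng)
            r = fit_patient(traj, FitConfig())
            if r.status != "converged":
                continue
            assert r.sse <= grid_best_sse(traj, d50_grid, dx_grid) + 1e-9
            checked += 1
        assert checked >= 15

    def test_status_is_single_valued(self, fast_trajectory, slow_trajectory):
        for traj, mode in ((fast_trajectory, "converted"), (slow_trajectory, "paper")):
            r = fit_patient(traj, FitConfig(init_mode=mode))
            assert r.status in ("converged", "degenerate_initial", "boundary", "failed")

    def test_noisy_recovery_medians(self):
        """Fast progressors, 9 visits spanning the midpoint, score noise of
        2 points: parameter recovery stays accurate in the median."""
        rng = np.random.default_rng(123)
        d50_err, dx_rel = [], []
        for _ in range(200):
            d50 = float(rng.uniform(20, 45))
            dx = float(rng.uniform(4, 12))
            visits = np.linspace(0.3 * d50, 1.7 * d50, 9)
            traj = simulate_trajectory(
                LogisticParams(d50=d50, dx=dx), visits, 2.0, integerize=True, rng=rng
            )
            r = fit_patient(traj, FitConfig())
            if r.status == "failed":
                continue
            d50_err.append(abs(r.params.d50 - d50))
            dx_rel.append(abs(r.params.dx - dx) / dx)
        assert np.median(d50_err) < 2.0
        assert np.median(dx_rel) < 0.20


class TestBootstrap:
    def test_noise_free_interval_degenerates_to_point(self, fast_trajectory):
        cfg = FitConfig(n_bootstrap=100, seed=9)
        b = bootstrap_ci(fast_trajectory, cfg)
        assert b.ci_d50[1] - b.ci_d50[0] < 1e-6
        assert b.ci_dx[1] - b.ci_dx[0] < 1e-6

    def test_deterministic_for_fixed_seed(self, slow_trajectory, fast_trajectory):
        cfg = FitConfig(n_bootstrap=50, seed=21)
        assert bootstrap_ci(fast_trajectory, cfg) == bootstrap_ci(fast_trajectory, cfg)

    def test_noisy_interval_brackets_base_estimate(self):
        rng = np.random.default_rng(3)
        true = LogisticParams(d50=30.0, dx=8.0)
        traj = simulate_trajectory(true, np.linspace(9, 51, 9), 2.0, integerize=True, rng=rng)
        cfg = FitConfig(n_bootstrap=200, seed=4)
        r = fit_patient(traj, cfg)
        b = bootstrap_ci(traj, cfg, base=r)
        assert b.ci_d50[0] <= r.params.d50 <= b.ci_d50[1]
        assert not b.wide_interval_warning


class TestUnconstrainedDiagnostic:
    def test_well_behaved_fast_progressor_in_range(self):
        rng = np.random.default_rng(2)
        traj = simulate_trajectory(
            LogisticParams(d50=30.0, dx=8.0), np.arange(8.0, 52.0, 5.0), 1.0,
            integerize=True, rng=rng,
        )
        assert not diagnose_unconstrained(traj, FitConfig()).out_of_range

    def test_some_slow_progressors_flag_out_of_range(self):
        rng = np.random.default_rng(0)
        flags = []
        for seed in range(20):
            true = LogisticParams(
                d50=float(rng.uniform(59, 282)), dx=float(rng.uniform(30, 150))
            )
            traj = simulate_trajectory(
                true, np.linspace(4, 50, 6), 2.0, seed=seed + 100, integerize=True
            )
            flags.append(diagnose_unconstrained(traj, FitConfig()).out_of_range)
        assert any(flags)

    def test_constrained_refit_back_in_range(self, slow_trajectory):
        r = fit_patient(slow_trajectory, FitConfig())
        assert all(0.0 <= p <= 48.0 for p in r.predicted)


class TestSerialization:
    def test_frame_has_one_row_per_patient(self, fast_trajectory, slow_trajectory):
        rs = [fit_patient(fast_trajectory, FitConfig()),
              fit_patient(slow_trajectory, FitConfig(init_mode="paper"))]
        frame = results_to_frame(rs)
        assert list(frame["patient_id"]) == ["fast", "slow"]
        assert set(frame.columns) >= {"status", "d50", "dx", "sse", "ci_d50_low"}
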