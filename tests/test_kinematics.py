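"""Temporal normalization, velocity, direction angles and summaries."""

import numpy as np
import pytest

from conftest import make_profile
from hyoidkin.geometry import AnatomicalTrajectory, rebase_to_start
from hyoidkin.kinematics import (
    SwallowDetectionError,
    compute_direction_angles,
    compute_velocity,
    detect_swallow_window,
    mean_early_phase_angle,
    normalize_time,
    summarize,
)
from hyoidkin.pipeline import extract_profile
from hyoidkin.synthetic import generate_subject


def _traj(times, positions, rebased=True):
    return AnatomicalTrajectory(
        time=np.asarray(times, float),
        position_mm=np.asarray(positions, float),
        rebased=rebased,
    )


class TestNormalizeTime:
    def test_bookkeeping_54_frames(self):
        t = np.arange(54) / 30.0
        pos = np.column_stack([np.linspace(0, 10, 54), np.linspace(0, 5, 54)])
        prof = normalize_time(_traj(t, pos), (0, 53))
        assert len(prof.grid) == 101
        assert prof.duration_s == pytest.approx(53 / 30.0)
        assert prof.duration_s == pytest.approx(1.767, abs=1e-3)
        assert prof.disp_x[0] == 0.0 and prof.disp_y[0] == 0.0
        assert prof.disp_x[-1] == pytest.approx(10.0)

    def test_linear_path_exact_at_irregular_times(self, rng):
        t = np.sort(rng.uniform(0, 2, 40))
        t[0] = 0.0
        pos = np.column_stack([3.0 * t, -1.5 * t])
        prof = normalize_time(_traj(t, pos), (0, 39))
        # linear in time => linear in percentile, interpolation exact
        span = t[-1] - t[0]
        assert np.allclose(prof.disp_x, 3.0 * span * prof.grid / 100.0, atol=1e-12)
        assert np.allclose(prof.disp_y, -1.5 * span * prof.grid / 100.0, atol=1e-12)

    def test_window_too_short(self):
        t = np.arange(10) / 30.0
        pos = np.zeros((10, 2))
        with pytest.raises(ValueError, match="at least 4"):
            normalize_time(_traj(t, pos), (0, 2))

    def test_requires_rebased(self):
        t = np.arange(10) / 30.0
        pos = np.ones((10, 2))
        with pytest.raises(ValueError, match="rebased"):
            normalize_time(_traj(t, pos, rebased=False), (0, 9))

    def test_idempotent_on_gridded_profile(self):
        grid = np.linspace(0, 100, 101)
        disp = np.column_stack([np.sin(grid / 15.0), np.cos(grid / 20.0) - 1.0])
        disp -= disp[0]
        prof1 = normalize_time(_traj(grid, disp), (0, 100))
        prof2 = normalize_time(
            _traj(prof1.grid, np.column_stack([prof1.disp_x, prof1.disp_y])),
            (0, 100),
        )
        assert np.allclose(prof1.disp_x, prof2.disp_x, atol=1e-12)
        assert np.allclose(prof1.disp_y, prof2.disp_y, atol=1e-12)


class TestVelocity:
    def test_constant_displacement(self):
        prof = make_profile(np.full(101, 2.0) - 2.0, np.zeros(101), with_angle=False)
        assert np.allclose(prof.vel_x, 0.0)

    def test_linear_exact_everywhere(self):
        grid = np.linspace(0, 100, 101)
        prof = make_profile(0.1 * grid, np.zeros(101), with_angle=False)
        assert np.allclose(prof.vel_x, 0.1, atol=1e-14)

    def test_quadratic_exact_interior(self):
        grid = np.linspace(0, 100, 101)
        prof = make_profile(grid**2, np.zeros(101), with_angle=False)
        assert np.allclose(prof.vel_x[1:-1], 2.0 * grid[1:-1], atol=1e-9)

    def test_discrete_antiderivative_recovery(self, rng):
        # discrete fundamental theorem: build d by inverting the symmetric
        # quotient (d[k+1] = d[k-1] + 2 v[k]); velocity then recovers v
        # exactly at interior points
        v = rng.normal(size=101)
        d = np.zeros(101)
        d[1] = v[0]
        for k in range(1, 100):
            d[k + 1] = d[k - 1] + 2.0 * v[k]
        prof = make_profile(d - d[0], np.zeros(101), with_angle=False)
        assert np.allclose(prof.vel_x[1:-1], v[1:-1], atol=1e-12)


class TestDirectionAngle:
    @pytest.mark.parametrize(
        "vx, vy, expected",
        [(1, 0, 0.0), (0, 1, 90.0), (-1, 1, 135.0), (1, -1, 315.0), (-1, 0, 180.0)],
    )
    def test_cardinal_angles(self, vx, vy, expected):
        prof = make_profile(np.zeros(101), np.zeros(101), with_angle=False)
        prof.vel_x = np.full(101, float(vx))
        prof.vel_y = np.full(101, float(vy))
        compute_direction_angles(prof)
        assert np.allclose(prof.angle, expected)

    def test_below_floor_undefined(self):
        prof = make_profile(np.zeros(101), np.zeros(101), with_angle=False)
        prof.vel_x = np.zeros(101)
        prof.vel_y = np.zeros(101)
        compute_direction_angles(prof)
        assert np.all(np.isnan(prof.angle))
        assert not prof.angle_defined.any()

    def test_rotation_equivariance(self, rng):
        prof = make_profile(np.zeros(101), np.zeros(101), with_angle=False)
        prof.vel_x = rng.normal(size=101)
        prof.vel_y = rng.normal(size=101)
        compute_direction_angles(prof)
        base = prof.angle.copy()
        theta = 73.0
        c, s = np.cos(np.radians(theta)), np.sin(np.radians(theta))
        vx, vy = prof.vel_x.copy(), prof.vel_y.copy()
        prof.vel_x = c * vx - s * vy
        prof.vel_y = s * vx + c * vy
        compute_direction_angles(prof)
        assert np.allclose(prof.angle, (base + theta) % 360.0, atol=1e-9)


class TestEarlyPhaseAngle:
    def test_constant_angle(self):
        prof = make_profile(np.zeros(101), np.zeros(101), with_angle=False)
        mag = 1.0
        ang = np.radians(119.18)
        prof.vel_x = np.full(101, mag * np.cos(ang))
        prof.vel_y = np.full(101, mag * np.sin(ang))
        compute_direction_angles(prof)
        assert mean_early_phase_angle(prof) == pytest.approx(119.18)

    def test_alternating_angles(self):
        prof = make_profile(np.zeros(101), np.zeros(101), with_angle=False)
        angs = np.where(np.arange(101) % 2 == 0, 90.0, 180.0)
        prof.vel_x = np.cos(np.radians(angs))
        prof.vel_y = np.sin(np.radians(angs))
        compute_direction_angles(prof)
        # grid points 5..20: 8 even (90) and 8 odd (180)
        assert mean_early_phase_angle(prof) == pytest.approx(135.0)

    def test_circular_mean_handles_seam(self):
        prof = make_profile(np.zeros(101), np.zeros(101), with_angle=False)
        angs = np.where(np.arange(101) % 2 == 0, 350.0, 10.0)
        prof.vel_x = np.cos(np.radians(angs))
        prof.vel_y = np.sin(np.radians(angs))
        compute_direction_angles(prof)
        assert mean_early_phase_angle(prof, circular=True) == pytest.approx(
            0.0, abs=1e-9
        ) or mean_early_phase_angle(prof, circular=True) == pytest.approx(
            360.0, abs=1e-9
        )
        # arithmetic mean is fooled by the wrap
        assert mean_early_phase_angle(prof) == pytest.approx(180.0)

    def test_all_undefined_raises(self):
        prof = make_profile(np.zeros(101), np.zeros(101), with_angle=False)
        prof.vel_x = np.zeros(101)
        prof.vel_y = np.zeros(101)
        compute_direction_angles(prof)
        with pytest.raises(ValueError, match="no defined"):
            mean_early_phase_angle(prof)


class TestSummarize:
    def test_single_bump(self):
        grid = np.linspace(0, 100, 101)
        disp_x = 12.43 * np.exp(-((grid - 49.0) ** 2) / 200.0)
        disp_x -= disp_x[0]
        prof = make_profile(disp_x, np.sin(grid / 30.0))
        s = summarize(prof)
        assert s.max_forward_x == pytest.approx(np.max(disp_x))
        assert s.time_max_forward_x == 49.0

    def test_matches_bruteforce_scan(self, rng):
        for _ in range(20):
            dx = rng.normal(size=101)
            dx -= dx[0]
            dy = rng.normal(size=101)
            dy -= dy[0]
            prof = make_profile(dx, dy)
            s = summarize(prof)
            # independent exhaustive scan with earliest-tie-break
            def scan(v, want_max):
                best_i = 0
                for i, x in enumerate(v):
                    if (x > v[best_i]) if want_max else (x < v[best_i]):
                        best_i = i
                return v[best_i], float(prof.grid[best_i])
            assert (s.max_forward_x, s.time_max_forward_x) == scan(prof.disp_x, True)
            assert (s.max_backward_x, s.time_max_backward_x) == scan(prof.disp_x, False)
            assert (s.max_upward_y, s.time_max_upward_y) == scan(prof.disp_y, True)
            assert (s.max_forward_vx, s.time_max_forward_vx) == scan(prof.vel_x, True)
            assert (s.max_upward_vy, s.time_max_upward_vy) == scan(prof.vel_y, True)

    def test_signed_conventions(self, rng):
        dx = rng.normal(size=101)
        dx -= dx[0]
        prof = make_profile(dx, np.abs(rng.normal(size=101)))
        s = summarize(prof)
        assert s.max_forward_x >= 0.0 >= s.max_backward_x
        for t in (s.time_max_forward_x, s.time_max_backward_x, s.time_max_upward_y):
            assert 0.0 <= t <= 100.0


class TestDetectWindow:
    def test_generator_ground_truth(self, clean_config, rng):
        from hyoidkin.geometry import to_anatomical

        series, truth = generate_subject(clean_config, "good", rng, "t0")
        traj = to_anatomical(series, clean_config.calibration)
        start, end = detect_swallow_window(traj)
        assert abs(start - truth.window[0]) <= 1
        assert end > start

    def test_constant_trajectory_fails(self):
        t = np.arange(30) / 30.0
        traj = _traj(t, np.tile([3.0, 4.0], (30, 1)), rebased=False)
        with pytest.raises(SwallowDetectionError):
            detect_swallow_window(traj)

    def test_manual_override_wins(self):
        t = np.arange(30) / 30.0
        traj = _traj(t, np.tile([3.0, 4.0], (30, 1)), rebased=False)
        assert detect_swallow_window(traj, manual_window=(4, 20)) == (4, 20)

    def test_manual_out_of_range(self):
        t = np.arange(10) / 30.0
        traj = _traj(t, np.zeros((10, 2)), rebased=False)
        with pytest.raises(IndexError):
            detect_swallow_window(traj, manual_window=(0, 50))


def test_full_profile_invariants(small_cohort):
    """End-to-end profiles satisfy the structural invariants."""
    cfg, series, truths, labels = small_cohort
    for s in series[:4]:
        prof, summary = extract_profile(s, cfg.calibration)
        assert prof.disp_x[0] == 0.0 and prof.disp_y[0] == 0.0
        assert prof.grid[0] == 0.0 and prof.grid[-1] == 100.0
        assert np.all(np.isnan(prof.angle[~prof.angle_defined]))
        assert summary.duration_s > 0
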