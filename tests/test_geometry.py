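"""Vertebral-frame geometry: calibration, rigid transforms, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hyoidkin.geometry import (
    AmbiguousOrientationError,
    CalibrationError,
    DegenerateAxisError,
    LandmarkFrameSeries,
    ScaleCalibration,
    build_frame_transform,
    compute_scale_factor,
    rebase_to_start,
    to_anatomical,
)


class TestScaleCalibration:
    @pytest.mark.parametrize(
        "coin_px, expected", [(47.0, 0.5), (23.5, 1.0), (11.75, 2.0)]
    )
    def test_scale_factor(self, coin_px, expected):
        assert compute_scale_factor(ScaleCalibration(coin_px)) == pytest.approx(expected)

    @pytest.mark.parametrize("coin_px", [0.0, -3.0, np.nan])
    def test_invalid_coin(self, coin_px):
        with pytest.raises(CalibrationError):
            ScaleCalibration(coin_px)


class TestFrameTransform:
    def test_axis_aligned_identity(self):
        tr = build_frame_transform((0, 30), (0, 0), (10, 5), "math-up")
        assert np.allclose(tr.apply(np.array([0.0, 30.0])), [0, 30])
        assert np.allclose(tr.apply(np.array([10.0, 5.0])), [10, 5])

    def test_image_down_flip(self):
        # y increases downward in the image; C2 sits above C4 on screen
        tr = build_frame_transform((100, 40), (100, 100), (150, 90), "image-down")
        c2 = tr.apply(np.array([100.0, -40.0]))
        hint = tr.apply(np.array([150.0, -90.0]))
        assert np.allclose(c2, [0, 60])
        assert np.allclose(hint, [50, 10])

    def test_rotated_axis(self):
        # vertebral axis lying along +x; anterior side at negative y.
        # Oracle: the 90-degree rotation matrix [[0,-1],[1,0]] maps the
        # axis direction (1,0) to (0,1) and (0,-1) to (1,0).
        tr = build_frame_transform((30, 0), (0, 0), (0, -10), "math-up")
        assert np.allclose(tr.apply(np.array([30.0, 0.0])), [0, 30])
        assert np.allclose(tr.apply(np.array([0.0, -10.0])), [10, 0])
        R = np.array([[0.0, -1.0], [1.0, 0.0]])
        for p in [np.array([3.0, 4.0]), np.array([-1.0, 2.0])]:
            assert np.allclose(tr.apply(p), R @ p)

    def test_degenerate_axis(self):
        with pytest.raises(DegenerateAxisError):
            build_frame_transform((5, 5), (5, 5), (1, 0), "math-up")

    def test_hint_on_axis(self):
        with pytest.raises(AmbiguousOrientationError):
            build_frame_transform((0, 30), (0, 0), (0, 15), "math-up")

    @settings(max_examples=50, derandomize=True)
    @given(
        theta=st.floats(-np.pi, np.pi),
        tx=st.floats(-50, 50),
        ty=st.floats(-50, 50),
    )
    def test_distance_preservation_and_anchors(self, theta, tx, ty):
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        shift = np.array([tx, ty])
        c4 = R @ np.array([0.0, 0.0]) + shift
        c2 = R @ np.array([0.0, 30.0]) + shift
        hint = R @ np.array([25.0, 10.0]) + shift
        tr = build_frame_transform(c2, c4, hint, "math-up")
        assert np.allclose(tr.apply(c4), [0, 0], atol=1e-9)
        assert abs(tr.apply(c2)[0]) < 1e-9
        p, q = np.array([3.0, 7.0]), np.array([-11.0, 2.0])
        d_out = np.linalg.norm(tr.apply(p) - tr.apply(q))
        assert d_out == pytest.approx(np.linalg.norm(p - q), abs=1e-9)


def _series(hyoid, c2, c4, convention="math-up"):
    n = len(hyoid)
    return LandmarkFrameSeries(
        frame_index=np.arange(n),
        time=np.arange(n) / 30.0,
        hyoid_px=np.asarray(hyoid, float),
        c2_px=np.asarray(c2, float),
        c4_px=np.asarray(c4, float),
        y_axis_convention=convention,
    )


class TestToAnatomical:
    def _base(self, n=20, rng=None):
        rng = rng or np.random.default_rng(0)
        hyoid = np.column_stack(
            [60 + 5 * np.sin(np.linspace(0, 2, n)), 30 + np.linspace(0, 8, n)]
        )
        c2 = np.tile([0.0, 76.0], (n, 1))
        c4 = np.tile([0.0, 0.0], (n, 1))
        return hyoid, c2, c4

    def test_rigid_motion_invariance(self, rng):
        hyoid, c2, c4 = self._base()
        cal = ScaleCalibration(47.0)
        ref = to_anatomical(_series(hyoid, c2, c4), cal)
        n = len(hyoid)
        theta = rng.uniform(-np.pi, np.pi, n)
        shift = rng.uniform(-100, 100, (n, 2))
        def move(pts):
            c, s = np.cos(theta), np.sin(theta)
            return np.column_stack(
                [c * pts[:, 0] - s * pts[:, 1], s * pts[:, 0] + c * pts[:, 1]]
            ) + shift
        moved = to_anatomical(_series(move(hyoid), move(c2), move(c4)), cal)
        assert np.allclose(moved.position_mm, ref.position_mm, atol=1e-9)

    def test_uniform_scale_invariance(self):
        hyoid, c2, c4 = self._base()
        ref = to_anatomical(_series(hyoid, c2, c4), ScaleCalibration(47.0))
        s = 3.0
        scaled = to_anatomical(
            _series(hyoid * s, c2 * s, c4 * s), ScaleCalibration(47.0 * s)
        )
        assert np.allclose(scaled.position_mm, ref.position_mm, atol=1e-9)

    def test_stationary_landmarks_constant_output(self):
        hyoid = np.tile([60.0, 25.0], (10, 1))
        c2 = np.tile([0.0, 76.0], (10, 1))
        c4 = np.tile([0.0, 0.0], (10, 1))
        traj = to_anatomical(_series(hyoid, c2, c4), ScaleCalibration(47.0))
        assert np.allclose(traj.position_mm, traj.position_mm[0], atol=1e-12)
        # C2-C4 span 76 px = 38 mm; hyoid 60 px anterior = 30 mm
        assert np.allclose(traj.position_mm[0], [30.0, 12.5])

    def test_fixed_mode_matches_per_frame_for_static_vertebrae(self):
        hyoid, c2, c4 = self._base()
        cal = ScaleCalibration(47.0)
        a = to_anatomical(_series(hyoid, c2, c4), cal, mode="per-frame")
        b = to_anatomical(_series(hyoid, c2, c4), cal, mode="fixed")
        assert np.allclose(a.position_mm, b.position_mm, atol=1e-9)

    def test_degenerate_frame_reports_index(self):
        hyoid, c2, c4 = self._base(n=5)
        c2[3] = c4[3]
        with pytest.raises(DegenerateAxisError, match="frame 3"):
            to_anatomical(_series(hyoid, c2, c4), ScaleCalibration(47.0))


class TestRebase:
    def _traj(self, positions):
        from hyoidkin.geometry import AnatomicalTrajectory

        positions = np.asarray(positions, float)
        return AnatomicalTrajectory(
            time=np.arange(len(positions)) / 30.0, position_mm=positions
        )

    def test_constant_becomes_zero(self):
        out = rebase_to_start(self._traj(np.tile([5.0, 7.0], (6, 1))), 0)
        assert np.allclose(out.position_mm, 0.0)
        assert out.rebased

    def test_shift_example(self):
        out = rebase_to_start(self._traj([[1.0, 1.0], [3.0, 2.0]]), 0)
        assert np.allclose(out.position_mm, [[0, 0], [2, 1]])

    def test_idempotent(self):
        t = self._traj([[1.0, 1.0], [3.0, 2.0], [0.0, 5.0]])
        once = rebase_to_start(t, 1)
        twice = rebase_to_start(once, 1)
        assert np.allclose(once.position_mm, twice.position_mm)

    def test_out_of_range(self):
        with pytest.raises(IndexError):
            rebase_to_start(self._traj([[0.0, 0.0], [1.0, 1.0]]), 5)


class TestSeriesValidation:
    def test_rejects_unequal_lengths(self):
        with pytest.raises(ValueError):
            LandmarkFrameSeries(
                frame_index=[0, 1],
                time=[0.0, 0.1],
                hyoid_px=[[0, 0]],
                c2_px=[[0, 1], [0, 1]],
                c4_px=[[0, 0], [0, 0]],
            )

    def test_rejects_nonmonotone_time(self):
        with pytest.raises(ValueError, match="increasing"):
            LandmarkFrameSeries(
                frame_index=[0, 1],
                time=[0.1, 0.0],
                hyoid_px=[[0, 0], [1, 1]],
                c2_px=[[0, 1], [0, 1]],
                c4_px=[[2, 0], [2, 0]],
            )
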