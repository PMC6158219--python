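import numpy as np
import pytest

from wormfeatures import core
from wormfeatures.core import (
    BodySegmentMap,
    CoreSeries,
    classify_motion_state,
    default_eigenworm_basis,
)

from conftest import make_trajectory, straight_skeleton

P = 49
SEGMAP = BodySegmentMap(P)


def test_segment_map_partitions_points():
    ranges = SEGMAP.ranges
    assert [r.start for r in ranges.values()] == [0, 10, 20, 29, 39]
    assert list(ranges["midbody"]) == list(range(20, 29))
    sizes = [len(r) for r in ranges.values()]
    assert max(sizes) - min(sizes) <= 1
    assert sum(sizes) == P
    assert SEGMAP.head_base == 10 and SEGMAP.tail_base == 39


class TestMorphology:
    def test_collinear_length(self, straight_worm):
        np.testing.assert_allclose(
            core.compute_length(straight_worm).values, 960.0
        )

    def test_semicircle_length_matches_analytic(self):
        R = 500.0
        th = np.linspace(0, np.pi, P)
        pts = np.stack([R * np.cos(th), R * np.sin(th)], axis=1)
        traj = make_trajectory(pts[None].repeat(2, axis=0))
        np.testing.assert_allclose(
            core.compute_length(traj).values, np.pi * R, rtol=1e-3
        )

    def test_invalid_frame_is_nan(self):
        pts = straight_skeleton()
        pts[1] = np.nan
        values = core.compute_length(make_trajectory(pts)).values
        assert np.isnan(values[1]) and np.isfinite(values[[0, 2]]).all()

    def test_uniform_widths(self):
        traj = make_trajectory(straight_skeleton(), widths=np.full((3, P), 30.0))
        widths = core.compute_widths(traj, SEGMAP)
        for series in widths.values():
            np.testing.assert_allclose(series.values, 30.0)

    def test_linear_width_profile_segment_means(self):
        profile = np.arange(P, dtype=float)
        traj = make_trajectory(straight_skeleton(), widths=np.tile(profile, (3, 1)))
        widths = core.compute_widths(traj, SEGMAP)
        np.testing.assert_allclose(
            widths["midbody"].values, profile[20:29].mean()
        )
        np.testing.assert_allclose(widths["head_base"].values, profile[10])

    def test_missing_widths_give_nan_not_error(self, straight_worm):
        widths = core.compute_widths(straight_worm, SEGMAP)
        assert all(np.isnan(s.values).all() for s in widths.values())
        assert np.isnan(core.compute_area(straight_worm).values).all()

    def test_area_of_uniform_ribbon(self, straight_worm):
        traj = make_trajectory(straight_skeleton(), widths=np.full((3, P), 30.0))
        # rectangle: 960 um long x 30 um wide
        np.testing.assert_allclose(core.compute_area(traj).values, 960.0 * 30.0)


class TestAxesQuirkiness:
    def test_circle_is_not_quirky(self):
        t = np.linspace(0, 2 * np.pi, P, endpoint=False)
        pts = 200 * np.stack([np.cos(t), np.sin(t)], axis=1)
        res = core.compute_axes_and_quirkiness(make_trajectory(pts[None].repeat(2, 0)))
        assert res["quirkiness"].values[0] < 1e-6
        np.testing.assert_allclose(
            res["major_axis"].values, res["minor_axis"].values, rtol=1e-6
        )

    def test_collinear_points_fully_quirky(self, straight_worm):
        res = core.compute_axes_and_quirkiness(straight_worm)
        np.testing.assert_allclose(res["quirkiness"].values, 1.0)
        np.testing.assert_allclose(res["minor_axis"].values, 0.0, atol=1e-9)

    def test_ellipse_closed_form(self):
        t = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        pts = np.stack([400 * np.cos(t), 100 * np.sin(t)], axis=1)
        res = core.compute_axes_and_quirkiness(make_trajectory(pts[None].repeat(2, 0)))
        np.testing.assert_allclose(
            res["quirkiness"].values[0], np.sqrt(1 - 1 / 16), rtol=1e-6
        )


class TestCurvature:
    def test_straight_skeleton_zero(self, straight_worm):
        curv = core.compute_curvature(straight_worm, SEGMAP)
        for series in curv.values():
            np.testing.assert_allclose(series.values, 0.0, atol=1e-12)

    def test_circle_arc_interior_segments(self):
        R = 250.0
        th = np.linspace(0, np.pi, P)
        pts = np.stack([R * np.cos(th), R * np.sin(th)], axis=1)
        curv = core.compute_curvature(make_trajectory(pts[None].repeat(2, 0)), SEGMAP)
        for seg in ("neck", "midbody", "hips"):
            np.testing.assert_allclose(
                np.abs(curv[seg].values[0]), 1.0 / R, rtol=0.02
            )

    def test_mirroring_flips_sign(self, rng):
        th = np.linspace(0, np.pi, P)
        pts = np.stack([250 * np.cos(th), 250 * np.sin(th)], axis=1)
        pts = pts[None].repeat(2, 0)
        mirrored = pts.copy()
        mirrored[:, :, 1] *= -1
        a = core.compute_curvature(make_trajectory(pts), SEGMAP)
        b = core.compute_curvature(make_trajectory(mirrored), SEGMAP)
        for seg in a:
            np.testing.assert_allclose(a[seg].values, -b[seg].values, atol=1e-12)


def _rigid_translation(speed, n_frames=100, fps=25.0):
    base = np.zeros((P, 2))
    base[:, 0] = -np.arange(P) * 20.0  # head at x=0, tail behind
    times = np.arange(n_frames) / fps
    pts = base[None] + np.stack([speed * times, np.zeros(n_frames)], axis=1)[:, None, :]
    return make_trajectory(pts, fps=fps)


class TestVelocity:
    def test_rigid_translation_signed_speed(self):
        vel = core.compute_velocity(_rigid_translation(100.0), SEGMAP)
        for name in ("speed_midbody", "speed_head_tip", "speed_tail_tip"):
            np.testing.assert_allclose(
                vel[name].values[10:-10], 100.0, rtol=1e-9
            )
        vel_back = core.compute_velocity(_rigid_translation(-100.0), SEGMAP)
        np.testing.assert_allclose(
            vel_back["speed_midbody"].values[10:-10], -100.0, rtol=1e-9
        )

    def test_rigid_rotation_angular_velocity(self):
        omega, fps, n = 1.0, 25.0, 100
        base = np.zeros((P, 2))
        base[:, 0] = np.arange(P) * 20.0
        base -= base.mean(axis=0)
        times = np.arange(n) / fps
        pts = np.stack(
            [
                np.stack(
                    [
                        np.cos(a) * base[:, 0] - np.sin(a) * base[:, 1],
                        np.sin(a) * base[:, 0] + np.cos(a) * base[:, 1],
                    ],
                    axis=1,
                )
                for a in omega * times
            ]
        )
        traj = make_trajectory(pts, fps=fps)
        vel = core.compute_velocity(traj, SEGMAP)
        np.testing.assert_allclose(
            vel["angular_velocity_midbody"].values[10:-10], omega, rtol=1e-6
        )
        # worm centred on the rotation axis: midbody centroid barely moves
        assert np.nanmax(np.abs(vel["speed_midbody"].values)) < 0.05 * omega * 960

    def test_relative_velocity_cancels_under_translation(self):
        traj = _rigid_translation(100.0)
        rel = core.compute_relative_velocity(traj, SEGMAP, "head_tip", "head_base")
        np.testing.assert_allclose(rel["radial"].values[10:-10], 0.0, atol=1e-9)
        np.testing.assert_allclose(rel["angular"].values[10:-10], 0.0, atol=1e-9)

    def test_point_circling_reference(self):
        omega, fps, n, R = 2.0, 25.0, 200, 150.0
        pts = straight_skeleton(n_frames=n)
        times = np.arange(n) / fps
        centre = pts[0, SEGMAP.head_base]
        pts[:, 0, 0] = centre[0] + R * np.cos(omega * times)
        pts[:, 0, 1] = centre[1] + R * np.sin(omega * times)
        traj = make_trajectory(pts, fps=fps)
        rel = core.compute_relative_velocity(traj, SEGMAP, "head_tip", "head_base")
        np.testing.assert_allclose(rel["angular"].values[10:-10], omega, rtol=1e-2)
        np.testing.assert_allclose(rel["radial"].values[10:-10], 0.0, atol=1e-6)

    def test_oscillating_head_tip_radial_amplitude(self):
        f, A, fps, n = 0.2, 50.0, 25.0, 500
        pts = straight_skeleton(n_frames=n)
        times = np.arange(n) / fps
        # head tip oscillates along the body axis about a fixed head base
        pts[:, 0, 0] = pts[0, 0, 0] - 100.0 - A * np.sin(2 * np.pi * f * times)
        traj = make_trajectory(pts, fps=fps)
        rel = core.compute_relative_velocity(traj, SEGMAP, "head_tip", "head_base")
        measured = np.nanmax(np.abs(rel["radial"].values))
        np.testing.assert_allclose(measured, 2 * np.pi * f * A, rtol=0.05)


class TestMotionState:
    @staticmethod
    def _series(values):
        return CoreSeries("speed", np.asarray(values, float), "um/s", signed=True)

    def test_constant_forward(self):
        states = classify_motion_state(self._series([100.0] * 100), 25.0, 25, 5)
        assert (states.states == "forward").all()

    def test_constant_zero_is_paused(self):
        states = classify_motion_state(self._series([0.0] * 100), 25.0, 25, 5)
        assert (states.states == "paused").all()

    def test_square_wave_bout_structure(self):
        fps = 25.0
        v = np.concatenate(
            [np.full(int(10 * fps), s) for s in (100.0, -100.0, 100.0, -100.0)]
        )
        states = classify_motion_state(
            self._series(v), fps, 25.0, 5.0, min_duration=0.5
        )
        runs = [r for r in core._runs(states.states) if r[2] != "undefined"]
        assert [r[2] for r in runs] == ["forward", "backward", "forward", "backward"]
        assert len(runs) == 4  # sign changes + 1

    def test_fractions_sum_to_one(self, rng):
        v = rng.normal(0, 80, 500)
        v[rng.random(500) < 0.1] = np.nan
        states = classify_motion_state(self._series(v), 25.0, 50, 10)
        total = sum(states.fraction(s) for s in ("forward", "backward", "paused"))
        np.testing.assert_allclose(total, 1.0)


class TestEigenworms:
    def test_basis_orthonormal_and_mean_free(self):
        basis = default_eigenworm_basis(48, 7)
        np.testing.assert_allclose(basis @ basis.T, np.eye(7), atol=1e-10)
        np.testing.assert_allclose(basis.mean(axis=1), 0.0, atol=1e-12)

    def test_pure_mode_projects_onto_itself(self):
        basis = default_eigenworm_basis(P - 1, 7)
        a = 0.8
        theta = a * basis[0] + 0.3  # constant term = overall orientation
        tang = 20.0 * np.stack([np.cos(theta), np.sin(theta)], axis=1)
        pts = np.concatenate([np.zeros((1, 2)), np.cumsum(tang, axis=0)])
        traj = make_trajectory(pts[None].repeat(2, 0))
        amps = np.array(
            [s.values[0] for s in core.compute_eigen_projections(traj, basis)]
        )
        np.testing.assert_allclose(amps, [a, 0, 0, 0, 0, 0, 0], atol=1e-10)

    def test_straight_worm_has_zero_amplitudes(self, straight_worm):
        amps = core.compute_eigen_projections(straight_worm)
        assert all(abs(s.values[0]) < 1e-12 for s in amps)

    def test_reconstruction_residual_decreases_with_modes(self):
        basis = default_eigenworm_basis(P - 1, 7)
        x = np.linspace(0, 1, P - 1)
        theta = 0.5 * np.sin(3 * np.pi * x) + 0.2 * np.cos(7 * np.pi * x)
        theta -= theta.mean()
        residuals = []
        for k in range(1, 8):
            rec = (theta @ basis[:k].T) @ basis[:k]
            residuals.append(np.linalg.norm(theta - rec))
        assert all(np.diff(residuals) <= 1e-12)

    def test_dimension_mismatch_rejected(self, straight_worm):
        with pytest.raises(ValueError, match="basis"):
            core.compute_eigen_projections(straight_worm, np.zeros((3, 1)))


class TestPath:
    def test_straight_path_zero_curvature(self):
        traj = _rigid_translation(100.0, n_frames=200)
        path = core.compute_path_features(traj, SEGMAP)
        mid = path["path_curvature"].values[40:-40]
        np.testing.assert_allclose(mid, 0.0, atol=1e-9)

    def test_circular_path_curvature(self):
        R, fps, n = 1000.0, 25.0, 400
        omega = 0.2  # rad/s -> tangential speed 200 um/s
        times = np.arange(n) / fps
        base = np.zeros((P, 2))
        base[:, 0] = np.arange(P) * 5.0
        base -= base.mean(axis=0)
        centre = np.stack([R * np.cos(omega * times), R * np.sin(omega * times)], axis=1)
        pts = base[None] + centre[:, None, :]
        traj = make_trajectory(pts, fps=fps)
        path = core.compute_path_features(traj, SEGMAP)
        mid = path["path_curvature"].values[60:-60]
        np.testing.assert_allclose(np.abs(np.nanmedian(mid)), 1.0 / R, rtol=0.02)

    def test_stationary_worm(self, straight_worm):
        path = core.compute_path_features(straight_worm, SEGMAP)
        assert np.isnan(path["path_curvature"].values).all()
        np.testing.assert_allclose(path["dispersion"].values, 0.0, atol=1e-9)


class TestInvariances:
    """Rigid-motion and scaling behaviour on a realistic wiggly worm."""

    @staticmethod
    def _worm(seed=3):
        from wormfeatures.synthetic import WormModelParams, generate_worm

        return generate_worm(
            WormModelParams(schedule=[("forward", 8.0)], seed=seed)
        )

    def _transform(self, traj, fn):
        from dataclasses import replace

        return replace(traj, skeleton=fn(traj.skeleton.copy()))

    def test_translation_invariance(self):
        traj = self._worm()
        shifted = self._transform(traj, lambda s: s + np.array([123.0, -456.0]))
        np.testing.assert_allclose(
            core.compute_length(traj).values,
            core.compute_length(shifted).values,
            rtol=1e-9,
        )
        a = core.compute_curvature(traj, SEGMAP)
        b = core.compute_curvature(shifted, SEGMAP)
        for seg in a:
            np.testing.assert_allclose(a[seg].values, b[seg].values, atol=1e-12)

    def test_rotation_invariance_of_scalars(self):
        traj = self._worm()
        c, s = np.cos(0.7), np.sin(0.7)
        R = np.array([[c, -s], [s, c]])
        rotated = self._transform(traj, lambda x: x @ R.T)
        for fn in (core.compute_length, lambda t: core.compute_axes_and_quirkiness(t)["quirkiness"]):
            np.testing.assert_allclose(
                fn(traj).values, fn(rotated).values, rtol=1e-7, atol=1e-12
            )
        a = core.compute_curvature(traj, SEGMAP)["midbody"].values
        b = core.compute_curvature(rotated, SEGMAP)["midbody"].values
        np.testing.assert_allclose(a, b, rtol=1e-6, atol=1e-12)

    def test_scaling_behaviour(self):
        traj = self._worm()
        s = 2.0
        scaled = self._transform(traj, lambda x: x * s)
        np.testing.assert_allclose(
            core.compute_length(scaled).values,
            s * core.compute_length(traj).values,
            rtol=1e-9,
        )
        np.testing.assert_allclose(
            core.compute_curvature(scaled, SEGMAP)["midbody"].values,
            core.compute_curvature(traj, SEGMAP)["midbody"].values / s,
            rtol=1e-6,
            atol=1e-15,
        )
        va = core.compute_velocity(traj, SEGMAP)
        vb = core.compute_velocity(scaled, SEGMAP)
        np.testing.assert_allclose(
            vb["speed_midbody"].values, s * va["speed_midbody"].values,
            rtol=1e-9, atol=1e-12,
        )
        np.testing.assert_allclose(
            vb["angular_velocity_midbody"].values,
            va["angular_velocity_midbody"].values,
            rtol=1e-9, atol=1e-12,
        )
        qa = core.compute_axes_and_quirkiness(traj)["quirkiness"].values
        qb = core.compute_axes_and_quirkiness(scaled)["quirkiness"].values
        np.testing.assert_allclose(qa, qb, rtol=1e-9)
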