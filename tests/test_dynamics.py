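"""GRF prediction and inverse dynamics against closed-form statics oracles."""

import numpy as np
import pytest

from smithsquat import dynamics, kinematics, model
from smithsquat.kinematics import DRIVEN_NAMES, DrivenTrajectory
from smithsquat.model import GRAVITY
from tests.conftest import make_model


def _static_kin(body, ratio=0.0, theta=0.0, bar_load=267.0, n=3, **model_kw):
    im = make_model(body, ratio=ratio, theta=theta, bar_load=bar_load, **model_kw)
    t = np.linspace(0, 1, n)
    traj = DrivenTrajectory(t, {k: np.zeros(n) for k in DRIVEN_NAMES})
    pose = kinematics.solve_trajectory(im, traj)
    return im, kinematics.body_kinematics(pose)


class TestNetWrench:
    def test_static_pose_supports_weight_plus_bar(self, body, profile):
        im, kin = _static_kin(body)
        f, _ = dynamics.net_wrench(kin)
        expected = profile.mass_kg * GRAVITY + 267.0
        assert np.allclose(f[:, 2], expected, rtol=1e-9)
        assert np.allclose(f[:, 0], 0.0, atol=1e-8)

    def test_static_pose_without_bar(self, body, profile):
        im, kin = _static_kin(body, bar_load=0.0)
        f, _ = dynamics.net_wrench(kin)
        assert np.allclose(f[:, 2], profile.mass_kg * GRAVITY, rtol=1e-9)

    def test_free_fall_needs_no_support(self, body):
        im, kin = _static_kin(body)
        for b in kin.bodies.values():
            b.com_acc = np.broadcast_to([0.0, 0.0, -GRAVITY],
                                        b.com.shape).copy()
            b.tilt_acc = np.zeros_like(b.tilt)
        kin.bar_acc = np.full(kin.n_frames, -GRAVITY)  # falling along a
        # vertical guide (theta = 0)
        f, m = dynamics.net_wrench(kin)
        assert np.abs(f).max() < 1e-9
        assert np.abs(m).max() < 1e-9


class TestPredictGrf:
    def test_symmetric_standing_splits_evenly(self, body, profile):
        im, kin = _static_kin(body)
        grf = dynamics.predict_grf(im, kin)
        expected = (profile.mass_kg * GRAVITY + 267.0) / 2
        assert grf.force["L"][:, 2] == pytest.approx(expected, rel=1e-6)
        assert grf.force["R"][:, 2] == pytest.approx(expected, rel=1e-6)
        assert not grf.infeasible_frames

    def test_support_total_equals_net_wrench(self, cycle_kinematics):
        im, kin = cycle_kinematics
        grf = dynamics.predict_grf(im, kin)
        f_tot, m_tot = grf.total()
        f_req, m_req = dynamics.net_wrench(kin)
        scale_f = np.abs(f_req).max()
        scale_m = max(1.0, np.abs(m_req).max())
        assert np.abs(f_tot - f_req).max() / scale_f < 1e-6
        assert np.abs(m_tot - m_req).max() / scale_m < 1e-6

    def test_lateral_shift_follows_lever_rule(self, body):
        """A COM shifted toward the left foot loads it per 2-support statics."""
        im = make_model(body, ratio=0.0, theta=0.0, bar_load=0.0,
                        foot_half_width=0.0)
        w = body.dims["hip_half_width"]
        y0 = 0.4 * w
        mass = 70.0
        n = 1
        xc = im.foot_centers["L"][0]  # centred fore-aft over the contacts
        com = np.array([[xc, y0, 1.0]])
        blob = kinematics._Body("blob", mass, 0.0, com, np.zeros(n))
        blob.com_acc = np.zeros((n, 3))
        blob.tilt_acc = np.zeros(n)
        kin = kinematics.BodyKinematics(
            model=im, dt=1.0, bodies={"blob": blob},
            points={"bar": np.array([[0.0, 0.0, 1.5]])},
            bar_travel=np.zeros(n), bar_acc=np.zeros(n))
        grf = dynamics.predict_grf(im, kin)
        share_left = grf.force["L"][0, 2] / (mass * GRAVITY)
        assert share_left == pytest.approx(0.5 + y0 / (2 * w), rel=1e-6)

    def test_vertical_force_nonnegative(self, cycle_kinematics):
        im, kin = cycle_kinematics
        grf = dynamics.predict_grf(im, kin)
        for side in ("L", "R"):
            assert grf.force[side][:, 2].min() >= -1e-9


class TestInverseDynamics:
    def test_pendulum_closed_form(self):
        """A single pinned rod held at angle phi needs m g (L/2) sin(phi)."""
        mass, length, phi = 3.0, 0.8, np.radians(35.0)
        com = np.array([[0.5 * length * np.sin(phi), 0.0,
                         -0.5 * length * np.cos(phi)]])
        m = dynamics.moment_about(np.zeros((1, 3)), [com], [mass],
                                  [np.zeros((1, 3))])
        expected = mass * GRAVITY * 0.5 * length * np.sin(phi)
        assert abs(m[0, 1]) == pytest.approx(expected, rel=1e-12)

    def test_zero_gravity_static_gives_zero_moments(self, body, monkeypatch):
        im, kin = _static_kin(body, bar_load=0.0)
        monkeypatch.setattr(dynamics, "_G_VEC", np.zeros(3))
        grf = dynamics.predict_grf(im, kin)
        mom = dynamics.inverse_dynamics(im, kin, grf)
        for series in mom.moments.values():
            assert np.abs(series).max() < 1e-9

    def test_static_knee_moment_matches_planar_statics(self, body, profile):
        """Knee moment = GRF wrench about the knee minus shank/foot gravity."""
        im, kin = _static_kin(body, ratio=0.14, theta=0.0)
        grf = dynamics.predict_grf(im, kin)
        mom = dynamics.inverse_dynamics(im, kin, grf)
        knee = kin.points["knee_R"][0]
        cop = grf.reference_point["R"]
        f = grf.force["R"][0]
        m_grf = grf.moment["R"][0]
        lever = np.cross(cop - knee, f) + m_grf
        gravity_term = 0.0
        for name in ("foot_R", "shank_R"):
            b = kin.bodies[name]
            r = b.com[0] - knee
            gravity_term += np.cross(r, b.mass * np.array([0, 0, -GRAVITY]))[1]
        expected = -gravity_term - lever[1]
        assert mom.moments["knee_R"][0] == pytest.approx(expected, rel=1e-9)

    def test_symmetric_cycle_gives_equal_sides(self, cycle_kinematics):
        im, kin = cycle_kinematics
        grf = dynamics.predict_grf(im, kin)
        mom = dynamics.inverse_dynamics(im, kin, grf)
        scale = np.abs(mom.moments["knee_L"]).max()
        assert np.abs(mom.moments["knee_L"] - mom.moments["knee_R"]).max() \
            < 1e-6 * scale
        assert np.abs(mom.moments["hip_L"] - mom.moments["hip_R"]).max() \
            < 1e-6 * max(1.0, np.abs(mom.moments["hip_L"]).max())

    def test_asymmetric_trajectory_gives_unequal_sides(self, body, clean_trial):
        """Bilateral asymmetry must be emergent, never hard-coded away."""
        im = make_model(body, 0.14, 10.0)
        traj = clean_trial.trajectory
        angles = {k: v.copy() for k, v in traj.angles.items()}
        angles["knee_L"] = angles["knee_L"] * 1.15  # 15% deeper left knee
        atraj = DrivenTrajectory(traj.cycle_fraction, angles,
                                 closure_tol=1e-6)
        pose = kinematics.solve_trajectory(im, atraj)
        kin = kinematics.body_kinematics(pose)
        grf = dynamics.predict_grf(im, kin)
        mom = dynamics.inverse_dynamics(im, kin, grf)
        diff = np.abs(mom.moments["knee_L"] - mom.moments["knee_R"]).max()
        assert diff > 1.0  # N m

    def test_magnitude_mode_is_abs(self, cycle_kinematics):
        im, kin = cycle_kinematics
        grf = dynamics.predict_grf(im, kin)
        signed = dynamics.inverse_dynamics(im, kin, grf)
        mags = dynamics.inverse_dynamics(im, kin, grf, signed=False)
        for j in signed.moments:
            assert np.array_equal(mags.moments[j], np.abs(signed.moments[j]))
            assert mags.moments[j].min() >= 0.0

    def test_length_mismatch_rejected(self, cycle_kinematics):
        im, kin = cycle_kinematics
        grf = dynamics.predict_grf(im, kin)
        grf.force = {s: f[:-1] for s, f in grf.force.items()}
        grf.moment = {s: m[:-1] for s, m in grf.moment.items()}
        with pytest.raises(ValueError):
            dynamics.inverse_dynamics(im, kin, grf)
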