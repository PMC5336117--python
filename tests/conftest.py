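"""Shared fixtures: scaled models, noise-free trajectories and a fully
analyzed squat cycle, plus an independent planar trigonometry oracle for the
closed-loop pose."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from smithsquat import kinematics, model, synthdata


@pytest.fixture(scope="session")
def profile():
    return model.default_profile()


@pytest.fixture(scope="session")
def body(profile):
    return model.build_body_model(profile)


def make_model(body, ratio=0.14, theta=10.0, bar_load=267.0, **kwargs):
    return model.build_integrated_model(
        body, model.MachineSpec(guide_angle_deg=theta, bar_load_n=bar_load),
        model.CaseSpec(ratio, theta), **kwargs)


@pytest.fixture(scope="session")
def integrated(body):
    return make_model(body)


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free single-subject generator settings on a light grid."""
    return synthdata.GeneratorConfig(trial_noise_sd_deg=0.0,
                                     subject_style_sd_deg=0.0, n_frames=41)


@pytest.fixture(scope="session")
def clean_trial(clean_config, profile):
    case = model.CaseSpec(0.14, 10.0)
    return synthdata.generate_trajectory(clean_config, profile, case)


@pytest.fixture(scope="session")
def solved_cycle(body, clean_trial):
    im = make_model(body, 0.14, 10.0)
    pose = kinematics.solve_trajectory(im, clean_trial.trajectory)
    return im, pose


@pytest.fixture(scope="session")
def cycle_kinematics(solved_cycle):
    im, pose = solved_cycle
    return im, kinematics.body_kinematics(pose)


# ---------------------------------------------------------------------------
# Independent planar oracle
# ---------------------------------------------------------------------------

def planar_pose_oracle(profile, ratio, theta_deg, pt_deg, hip_deg, knee_deg):
    """Closed-form 2-D pose for symmetric driven angles.

    Works upward from the welded ankle by plain trigonometry, solving the
    pelvis pitch from the shoulder-on-guide-line condition with a scalar
    root find.  Returns pelvis position, pelvis pitch, shoulder point and
    bar travel -- independent of the package's least-squares solver.
    """
    h = profile.stature_m
    lf = profile.segment_length_fractions
    l_sh, l_th = lf["shank"] * h, lf["thigh"] * h
    l_pel, l_tor = lf["pelvis"] * h, lf["thorax"] * h
    h_ank = lf["ankle_height"] * h
    D = ratio * h
    theta = math.radians(theta_deg)
    p, alpha, beta = (math.radians(v) for v in (pt_deg, hip_deg, knee_deg))

    l_tot = l_sh + l_th + l_pel + l_tor
    z0 = h_ank + math.sqrt(l_tot ** 2 - D ** 2)

    def chain(phi):
        t_th = alpha - phi            # anterior tilt of the thigh
        t_sh = alpha - phi - beta     # anterior tilt of the shank
        knee = (D - l_sh * math.sin(t_sh), h_ank + l_sh * math.cos(t_sh))
        pelvis = (knee[0] - l_th * math.sin(t_th), knee[1] + l_th * math.cos(t_th))
        pt = (pelvis[0] + l_pel * math.sin(phi), pelvis[1] + l_pel * math.cos(phi))
        sh = (pt[0] + l_tor * math.sin(phi + p), pt[1] + l_tor * math.cos(phi + p))
        return pelvis, sh

    def gap(phi):
        _, sh = chain(phi)
        # bar line: x = -(z0 - z) tan(theta), posterior drift on descent
        return sh[0] + (z0 - sh[1]) * math.tan(theta)

    phi = brentq(gap, math.radians(-85), math.radians(85), xtol=1e-13)
    pelvis, sh = chain(phi)
    travel = (z0 - sh[1]) / math.cos(theta)
    return {"pelvis": pelvis, "pitch": phi, "shoulder": sh,
            "bar_travel": travel, "z0": z0}
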