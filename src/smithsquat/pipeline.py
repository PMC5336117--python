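"""End-to-end experiments: database -> GPR training -> synthesis ->
biomechanical analysis -> validation reports and the 25-case design sweep."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dynamics, gpr, kinematics, metrics, muscle, synthdata
from .model import (CaseSpec, MachineSpec, build_body_model,
                    build_integrated_model, default_profile)

__all__ = [
    "SWEEP_CASES",
    "CaseAnalysis",
    "SweepResult",
    "fit_models",
    "analyze_trajectory",
    "analyze_case",
    "run_sweep",
    "validate_synthesis",
]

#: The 5 x 5 design grid: D/h in 0.07 steps, theta in 5 deg steps.
SWEEP_CASES = tuple(
    CaseSpec(round(d, 2), th)
    for d in (0.0, 0.07, 0.14, 0.21, 0.28)
    for th in (0.0, 5.0, 10.0, 15.0, 20.0)
)


def fit_models(records=None, config=None, params=gpr.DEFAULT_KERNEL,
               subsample: int = 4, optimize: bool = False, seed: int = 0) -> dict:
    """Train the five per-joint GPs on per-case mean curves of a database."""
    if records is None:
        config = config or synthdata.GeneratorConfig(seed=seed)
        records = synthdata.generate_database(config)
    sets = synthdata.training_sets(records, subsample=subsample)
    models = {}
    for name, train in sets.items():
        p = params
        if optimize:
            p = gpr.optimize_hyperparameters(train, init=params, seed=seed)
        models[name] = gpr.fit_gpr(train, p)
    return models


@dataclass
class CaseAnalysis:
    """Full biomechanical analysis of one trajectory on one model."""

    case: CaseSpec
    trajectory: kinematics.DrivenTrajectory
    pose: kinematics.PoseSeries
    grf: dynamics.WrenchSeries
    moments: dynamics.MomentSeries
    recruitment: muscle.RecruitmentResult


def analyze_trajectory(trajectory, case: CaseSpec, profile=None,
                       bar_load_n: float = 267.0, muscles=None) -> CaseAnalysis:
    """Kinematics -> GRF prediction -> inverse dynamics -> recruitment."""
    profile = profile or default_profile()
    body = build_body_model(profile)
    machine = MachineSpec(guide_angle_deg=case.guide_angle_deg,
                          bar_load_n=bar_load_n)
    model = build_integrated_model(body, machine, case)
    pose = kinematics.solve_trajectory(model, trajectory)
    kin = kinematics.body_kinematics(pose)
    grf = dynamics.predict_grf(model, kin)
    moments = dynamics.inverse_dynamics(model, kin, grf)
    rec = muscle.recruit(moments, muscles=muscles)
    return CaseAnalysis(case=case, trajectory=trajectory, pose=pose,
                        grf=grf, moments=moments, recruitment=rec)


def analyze_case(models: dict, case: CaseSpec, profile=None,
                 bar_load_n: float = 267.0, n_frames: int = 101) -> CaseAnalysis:
    """Synthesize the case's motion with the GPs, then analyze it."""
    trajectory = gpr.synthesize_motion(models, case, n_frames=n_frames)
    return analyze_trajectory(trajectory, case, profile=profile,
                              bar_load_n=bar_load_n)


@dataclass
class SweepResult:
    """Per-case maxima of joint-moment magnitudes and cycle-average muscle
    activities over the design grid."""

    table: pd.DataFrame
    failures: dict = field(default_factory=dict)
    analyses: dict = field(default_factory=dict)


def run_sweep(models: dict, profile=None, cases=SWEEP_CASES,
              bar_load_n: float = 267.0, n_frames: int = 101,
              keep_analyses: bool = False) -> SweepResult:
    """The design sweep: synthesize and analyze every grid case.

    Stage failures are recorded per case and the sweep continues.  Moments
    are reported as magnitudes (N m); activities as cycle averages.
    """
    rows, failures, analyses = [], {}, {}
    for case in cases:
        try:
            res = analyze_case(models, case, profile=profile,
                               bar_load_n=bar_load_n, n_frames=n_frames)
        except Exception as err:  # sweep must survive per-case failures
            failures[case] = f"{type(err).__name__}: {err}"
            continue
        mags = res.moments.magnitudes()
        row = {
            "foot_ratio": case.foot_position_ratio,
            "guide_deg": case.guide_angle_deg,
            "provenance": "synthesized",
        }
        for j in ("hip_L", "hip_R", "knee_L", "knee_R", "pelvis_thorax"):
            row[f"max_moment_{j}_nm"] = float(mags.moments[j].max())
        for name in res.recruitment.muscle_names:
            row[f"mean_activity_{name}"] = float(
                res.recruitment.activity(name).mean())
        rows.append(row)
        if keep_analyses:
            analyses[case] = res
    return SweepResult(table=pd.DataFrame(rows), failures=failures,
                       analyses=analyses)


def validate_synthesis(models: dict, config=None,
                       holdout_cases=synthdata.HOLDOUT_CASES,
                       profile=None, with_moments: bool = True,
                       n_frames: int = 101):
    """Held-out-case validation of the synthesis pipeline.

    For each holdout case the GP prediction is compared with the generator's
    noise-free truth curves (per-joint NRMSE and Pearson r), and optionally
    the joint moments of the synthesized vs truth trajectories after full
    biomechanical analysis.  Returns ``{"angles": df, "moments": df}``.
    """
    if not holdout_cases:
        raise ValueError("empty holdout case list")
    config = config or synthdata.GeneratorConfig()
    profile = profile or default_profile()

    angle_rows, moment_rows = [], []
    for case in holdout_cases:
        truth_rec = synthdata.generate_trajectory(
            synthdata.GeneratorConfig(
                seed=config.seed, effects=config.effects,
                trial_noise_sd_deg=0.0, subject_style_sd_deg=0.0,
                n_frames=n_frames),
            profile, case)
        synth = gpr.synthesize_motion(models, case, n_frames=n_frames)
        row = {"foot_ratio": case.foot_position_ratio,
               "guide_deg": case.guide_angle_deg}
        for joint in kinematics.DRIVEN_NAMES:
            ref = truth_rec.truth[joint]
            test = synth.angles[joint]
            row[f"nrmse_{joint}"] = metrics.nrmse(ref, test)
            row[f"r_{joint}"] = metrics.pearson(ref, test)[0]
        angle_rows.append(row)

        if with_moments:
            a_truth = analyze_trajectory(truth_rec.trajectory, case, profile)
            a_synth = analyze_trajectory(synth, case, profile)
            mrow = {"foot_ratio": case.foot_position_ratio,
                    "guide_deg": case.guide_angle_deg}
            for joint in ("hip_L", "hip_R", "knee_L", "knee_R"):
                ref = a_truth.moments.moments[joint]
                test = a_synth.moments.moments[joint]
                mrow[f"nrmse_{joint}"] = metrics.nrmse(ref, test)
                mrow[f"r_{joint}"] = metrics.pearson(ref, test)[0]
            moment_rows.append(mrow)

    out = {"angles": pd.DataFrame(angle_rows)}
    if with_moments:
        out["moments"] = pd.DataFrame(moment_rows)
    return out
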