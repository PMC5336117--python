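"""Synthetic Smith-squat motion database.

The lab database the framework was validated on (14 subjects x 9 cases x 5
repetitions of parallel back squats at 267 N) is not publicly available, so
this module generates a surrogate with the same structure: smooth
single-cycle flexion/extension curves for the five driven angles, modulated
by foot position D/h and guide angle theta, with subject-level
anthropometric variation and smooth trial noise.

Each trial's truth curve is built from an exactly consistent bottom posture:
the shank tilt at the bottom is an effect-coefficient function of (D/h,
theta); the thigh is horizontal (parallel squat); the trunk angle follows
from the shoulder-on-guide-line constraint; hip and knee peak flexions are
read off that geometry.  Every curve is a raised cosine between the initial
posture (all driven angles zero) and the bottom posture, so cycles close
exactly and the mid-cycle thigh is horizontal by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .kinematics import DRIVEN_NAMES, DrivenTrajectory
from .model import AnthropometricProfile, CaseSpec, default_profile

__all__ = [
    "EffectCoefficients",
    "GeneratorConfig",
    "TrialRecord",
    "DEFAULT_CASES",
    "HOLDOUT_CASES",
    "generate_subject",
    "generate_trajectory",
    "generate_database",
    "generate_emg_like",
    "case_mean_curves",
    "training_sets",
    "export_database",
]

#: The 9-case measurement grid: D/h x theta.
DEFAULT_CASES = tuple(
    CaseSpec(d, th) for d in (0.0, 0.14, 0.28) for th in (0.0, 10.0, 20.0)
)

#: The 4 intermediate validation cases.
HOLDOUT_CASES = tuple(
    CaseSpec(d, th) for d in (0.07, 0.21) for th in (5.0, 15.0)
)


@dataclass(frozen=True)
class EffectCoefficients:
    """Smooth dependence of the bottom posture on (D/h, theta).

    ``shank_tilt_deg = base + per_ratio * (D/h) + cross * (D/h)(theta/20)``
    gives the bottom shank forward tilt; the pelvis-thorax bottom flexion is
    ``pt_base + pt_per_ratio * (D/h) * (1 - pt_theta_atten * theta/20)``.
    Defaults encode only qualitative directions (feet forward -> shins more
    vertical, larger guide tilt -> less trunk-flexion demand) at moderate
    magnitude; they are stand-ins, not measured values.
    """

    shank_base_deg: float = 22.0
    shank_per_ratio_deg: float = -25.0
    shank_cross_deg: float = 3.0
    pt_base_deg: float = 8.0
    pt_per_ratio_deg: float = 36.0
    pt_theta_atten: float = 0.6

    def shank_tilt(self, ratio: float, theta: float) -> float:
        return (self.shank_base_deg + self.shank_per_ratio_deg * ratio
                + self.shank_cross_deg * ratio * (theta / 20.0))

    def pt_flexion(self, ratio: float, theta: float) -> float:
        return (self.pt_base_deg + self.pt_per_ratio_deg * ratio
                * (1.0 - self.pt_theta_atten * theta / 20.0))


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition defaults: 14 subjects x 9 cases x 5 reps, population
    anthropometry 1770 +/- 82.6 mm and 78 +/- 11.6 kg, 6 s cycles on a
    101-point grid."""

    n_subjects: int = 14
    cases: tuple = DEFAULT_CASES
    reps_per_case: int = 5
    seed: int = 0
    stature_mean_mm: float = 1770.0
    stature_sd_mm: float = 82.6
    mass_mean_kg: float = 78.0
    mass_sd_kg: float = 11.6
    trial_noise_sd_deg: float = 1.5
    subject_style_sd_deg: float = 1.5
    effects: EffectCoefficients = field(default_factory=EffectCoefficients)
    n_frames: int = 101
    cycle_duration: float = 6.0

    def __post_init__(self):
        if self.n_subjects <= 0 or self.reps_per_case <= 0 or not self.cases:
            raise ValueError("counts must be positive and cases non-empty")
        if min(self.stature_sd_mm, self.mass_sd_kg, self.trial_noise_sd_deg) < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass
class TrialRecord:
    subject: int
    case: CaseSpec
    rep: int
    trajectory: DrivenTrajectory
    truth: dict  # joint -> noise-free curve (deg)
    profile: AnthropometricProfile


def _rng(config: GeneratorConfig, *key) -> np.random.Generator:
    """One RNG stream per (seed, key...) for reproducible parallel generation."""
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, *key])


def _truncated_normal(rng, mean, sd, n_sd=3.0):
    if sd == 0.0:
        return mean
    while True:
        x = rng.normal(mean, sd)
        if abs(x - mean) <= n_sd * sd:
            return x


def generate_subject(config: GeneratorConfig, index: int) -> AnthropometricProfile:
    """Deterministic subject anthropometry, truncated at +/-3 SD."""
    rng = _rng(config, 1, index)
    stature = _truncated_normal(rng, config.stature_mean_mm, config.stature_sd_mm)
    mass = _truncated_normal(rng, config.mass_mean_kg, config.mass_sd_kg)
    return default_profile(stature_mm=stature, mass_kg=mass)


def _subject_style(config: GeneratorConfig, index: int):
    """Per-subject habitual offsets on shank tilt and trunk flexion (deg)."""
    rng = _rng(config, 2, index)
    sd = config.subject_style_sd_deg
    return rng.normal(0.0, sd) if sd else 0.0, rng.normal(0.0, sd * 0.6) if sd else 0.0


def bottom_posture(profile: AnthropometricProfile, case: CaseSpec,
                   effects: EffectCoefficients = EffectCoefficients(),
                   shank_offset_deg: float = 0.0,
                   pt_offset_deg: float = 0.0) -> dict:
    """Planar full-down posture: driven angles with the thigh horizontal.

    Solves the trunk angle from the shoulder-on-guide-line constraint and
    returns the five bottom driven angles (deg) plus the pelvis pitch.
    """
    h = profile.stature_m
    lf = profile.segment_length_fractions
    l_sh, l_th = lf["shank"] * h, lf["thigh"] * h
    l_pel, l_tor = lf["pelvis"] * h, lf["thorax"] * h
    h_ank = lf["ankle_height"] * h
    D = case.foot_position_ratio * h
    theta = math.radians(case.guide_angle_deg)

    sigma = math.radians(effects.shank_tilt(case.foot_position_ratio,
                                            case.guide_angle_deg) + shank_offset_deg)
    pt = math.radians(effects.pt_flexion(case.foot_position_ratio,
                                         case.guide_angle_deg) + pt_offset_deg)

    # guide line through the initial-pose shoulder point
    l_tot = l_sh + l_th + l_pel + l_tor
    if D >= l_tot:
        raise ValueError("foot distance exceeds body length")
    z0 = h_ank + math.sqrt(l_tot ** 2 - D ** 2)

    knee = np.array([D + l_sh * math.sin(sigma), h_ank + l_sh * math.cos(sigma)])
    hip = knee - np.array([l_th, 0.0])

    def line_gap(phi):
        sx = hip[0] + l_pel * math.sin(phi) + l_tor * math.sin(phi + pt)
        sz = hip[1] + l_pel * math.cos(phi) + l_tor * math.cos(phi + pt)
        # bar drifts posteriorly as it descends (machine guide convention)
        return sx + (z0 - sz) * math.tan(theta)

    lo, hi = math.radians(-85.0), math.radians(85.0)
    if line_gap(lo) * line_gap(hi) > 0:
        raise ValueError("bottom posture unreachable for this case")
    phi = brentq(line_gap, lo, hi, xtol=1e-12)

    hip_flex = 90.0 + math.degrees(phi)
    knee_flex = 90.0 + math.degrees(sigma)
    for name, val in (("hip", hip_flex), ("knee", knee_flex),
                      ("pelvis_thorax", math.degrees(pt))):
        if abs(val) > 170.0:
            raise ValueError(f"non-physical bottom {name} flexion {val:.1f} deg")
    return {
        "pelvis_thorax": math.degrees(pt),
        "hip": hip_flex,
        "knee": knee_flex,
        "pelvis_pitch": math.degrees(phi),
    }


def _raised_cosine(t: np.ndarray) -> np.ndarray:
    """0 at the endpoints, 1 at mid-cycle, C^1-smooth."""
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * t))


def _smooth_noise(rng, t: np.ndarray, sd: float, length_scale: float = 0.15):
    """One draw of a smooth (squared-exponential) noise process, windowed by
    sin^2(pi t) so it vanishes at both endpoints (cycle closure)."""
    if sd == 0.0:
        return np.zeros_like(t)
    diff = (t[:, None] - t[None, :]) / length_scale
    cov = sd ** 2 * np.exp(-0.5 * diff * diff)
    cov[np.diag_indices_from(cov)] += 1e-10
    draw = rng.multivariate_normal(np.zeros(t.size), cov, method="cholesky")
    return draw * np.sin(np.pi * t) ** 2


def generate_trajectory(config: GeneratorConfig, profile: AnthropometricProfile,
                        case: CaseSpec, subject_index: int = 0,
                        rep: int = 0) -> TrialRecord:
    """One synthetic trial: truth curves plus a smooth noise realisation."""
    style_sh, style_pt = _subject_style(config, subject_index)
    bottom = bottom_posture(profile, case, config.effects,
                            shank_offset_deg=style_sh, pt_offset_deg=style_pt)
    t = np.linspace(0.0, 1.0, config.n_frames)
    w = _raised_cosine(t)
    truth = {
        "pelvis_thorax": bottom["pelvis_thorax"] * w,
        "hip_L": bottom["hip"] * w,
        "hip_R": bottom["hip"] * w,
        "knee_L": bottom["knee"] * w,
        "knee_R": bottom["knee"] * w,
    }
    case_index = list(config.cases).index(case) if case in config.cases else 99
    rng = _rng(config, 3, subject_index, case_index, rep)
    angles = {name: truth[name] + _smooth_noise(rng, t, config.trial_noise_sd_deg)
              for name in DRIVEN_NAMES}
    traj = DrivenTrajectory(cycle_fraction=t, angles=angles,
                            cycle_duration=config.cycle_duration,
                            closure_tol=1e-6)
    return TrialRecord(subject=subject_index, case=case, rep=rep,
                       trajectory=traj, truth=truth, profile=profile)


def generate_database(config: GeneratorConfig = GeneratorConfig()) -> list:
    """The full synthetic database: n_subjects x |cases| x reps trials."""
    records = []
    for s in range(config.n_subjects):
        profile = generate_subject(config, s)
        for case in config.cases:
            for rep in range(config.reps_per_case):
                records.append(generate_trajectory(config, profile, case,
                                                   subject_index=s, rep=rep))
    return records


def generate_emg_like(activity: np.ndarray, noise_sd: float, seed: int = 0,
                      length_scale: float = 0.1) -> np.ndarray:
    """An EMG-shaped surrogate: activity plus smooth noise, clipped at zero,
    then max-normalised (used to exercise the validation metrics)."""
    a = np.asarray(activity, float)
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("activity series must lie in [0, 1]")
    t = np.linspace(0.0, 1.0, a.size)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        diff = (t[:, None] - t[None, :]) / length_scale
        cov = noise_sd ** 2 * np.exp(-0.5 * diff * diff)
        cov[np.diag_indices_from(cov)] += 1e-10
        a = a + rng.multivariate_normal(np.zeros(t.size), cov, method="cholesky")
    a = np.clip(a, 0.0, None)
    peak = a.max()
    return a / peak if peak > 0 else a


# ---------------------------------------------------------------------------
# Training-set assembly
# ---------------------------------------------------------------------------

def case_mean_curves(records: list) -> dict:
    """Per-case mean curves over subjects and reps: case -> joint -> (n,)."""
    grouped = {}
    for rec in records:
        grouped.setdefault(rec.case, []).append(rec.trajectory)
    out = {}
    for case, trajs in grouped.items():
        out[case] = {
            name: np.mean([tr.angles[name] for tr in trajs], axis=0)
            for name in DRIVEN_NAMES
        }
    return out


def training_sets(records: list, subsample: int = 4) -> dict:
    """Per-joint GPR training sets from per-case mean curves.

    ``subsample`` keeps every k-th time sample (endpoint included) to keep
    the Gram matrices small; the curves are smooth so little is lost.
    """
    from .gpr import TrainingSet, case_features

    means = case_mean_curves(records)
    n = next(iter(means.values()))[DRIVEN_NAMES[0]].size
    t = np.linspace(0.0, 1.0, n)
    keep = np.unique(np.r_[np.arange(0, n, subsample), n - 1])
    out = {}
    for name in DRIVEN_NAMES:
        X_rows, y_rows = [], []
        for case, curves in means.items():
            X_rows.append(case_features(case, t[keep]))
            y_rows.append(curves[name][keep])
        out[name] = TrainingSet(X=np.vstack(X_rows),
                                y=np.concatenate(y_rows), joint_name=name)
    return out


def export_database(records: list, directory) -> pd.DataFrame:
    """One trajectory CSV per trial plus a manifest CSV; returns the manifest."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        fname = (f"trial_s{rec.subject:02d}_d{rec.case.foot_position_ratio:.2f}"
                 f"_g{rec.case.guide_angle_deg:02.0f}_r{rec.rep}.csv")
        rec.trajectory.to_csv(directory / fname)
        rows.append({
            "subject": rec.subject,
            "stature_mm": rec.profile.stature_mm,
            "mass_kg": rec.profile.mass_kg,
            "foot_ratio": rec.case.foot_position_ratio,
            "guide_deg": rec.case.guide_angle_deg,
            "rep": rec.rep,
            "file": fname,
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(directory / "manifest.csv", index=False)
    return manifest
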