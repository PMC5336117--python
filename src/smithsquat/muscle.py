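"""Static-optimization muscle recruitment.

Joint moments from the inverse dynamics are distributed over a reduced
parametric lower-limb muscle set (eight muscles per leg, constant moment
arms from a packaged literature table) plus ideal torque actuators for the
pelvis-thorax joint.  Each muscle's maximum force is its PCSA times the
90 N/cm^2 maximum muscle stress.  Recruitment minimises the maximum activity
(solved as a per-frame LP), with a minimum-sum-of-squared-activities
tie-break for uniqueness.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.optimize import linprog, minimize

__all__ = [
    "MAX_MUSCLE_STRESS_N_PER_CM2",
    "MuscleSpec",
    "RecruitmentResult",
    "max_muscle_force",
    "load_default_muscles",
    "recruit",
    "activity_series",
]

#: Maximum muscle stress, 9.0e5 Pa = 90 N/cm^2.
MAX_MUSCLE_STRESS_N_PER_CM2 = 90.0

#: Joint DOFs spanned by the recruitment problem, in canonical order.
RECRUIT_DOFS = ("pelvis_thorax", "hip_L", "hip_R", "knee_L", "knee_R")


def max_muscle_force(pcsa_cm2: float) -> float:
    """Maximum contraction force (N) = PCSA (cm^2) x 90 N/cm^2."""
    if pcsa_cm2 < 0:
        raise ValueError("PCSA must be non-negative")
    return pcsa_cm2 * MAX_MUSCLE_STRESS_N_PER_CM2


@dataclass(frozen=True)
class MuscleSpec:
    """One muscle (or ideal actuator): PCSA and signed moment arms.

    ``moment_arms`` maps a joint DOF name to the signed arm in metres under
    the flexion-positive convention: a positive arm means the muscle's pull
    produces a flexion moment at that joint.
    """

    name: str
    side: str  # L | R | C (central / trunk)
    pcsa_cm2: float
    moment_arms: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.pcsa_cm2 <= 0:
            raise ValueError(f"PCSA must be positive for {self.name}")
        if not any(abs(v) > 0 for v in self.moment_arms.values()):
            raise ValueError(f"{self.name} has no nonzero moment arm")

    @property
    def fmax(self) -> float:
        return max_muscle_force(self.pcsa_cm2)


def load_default_muscles() -> list:
    """The packaged reduced lower-limb set plus ideal trunk actuators."""
    muscles = []
    path = resources.files("smithsquat").joinpath("data", "muscles.csv")
    with path.open("r") as fh:
        for row in csv.DictReader(fh):
            side = row["side"]
            arms = {}
            hip = float(row["moment_arm_hip_m"])
            knee = float(row["moment_arm_knee_m"])
            if hip:
                arms[f"hip_{side}"] = hip
            if knee:
                arms[f"knee_{side}"] = knee
            muscles.append(MuscleSpec(name=f"{row['name']}_{side}", side=side,
                                      pcsa_cm2=float(row["pcsa_cm2"]),
                                      moment_arms=arms))
    # ideal pelvis-thorax actuators (extensor/flexor), 30 cm^2 at a 0.10 m arm
    muscles.append(MuscleSpec("trunk_extensor_ideal", "C", 30.0,
                              {"pelvis_thorax": -0.10}))
    muscles.append(MuscleSpec("trunk_flexor_ideal", "C", 30.0,
                              {"pelvis_thorax": +0.10}))
    return muscles


@dataclass
class RecruitmentResult:
    """Per-frame muscle forces, dimensionless activities and bookkeeping."""

    muscle_names: list
    forces: np.ndarray        # (n, m) N
    activities: np.ndarray    # (n, m) force / fmax
    objective: np.ndarray     # (n,) min-max activity level
    residual: np.ndarray      # (n,) relative moment-balance residual
    moments: dict             # the joint moments that were balanced
    infeasible_frames: list = field(default_factory=list)

    def activity(self, name: str) -> np.ndarray:
        try:
            j = self.muscle_names.index(name)
        except ValueError:
            raise KeyError(f"unknown muscle {name}") from None
        return self.activities[:, j]


def _recruit_frame(R, fmax, m_vec, tiebreak: bool):
    """Solve one frame.  Returns (forces, gamma, relative residual)."""
    nm = R.shape[1]
    # LP: minimise gamma  s.t.  R f = m,  0 <= f_i <= gamma * fmax_i
    c = np.zeros(nm + 1)
    c[-1] = 1.0
    a_eq = np.hstack([R, np.zeros((R.shape[0], 1))])
    a_ub = np.hstack([np.eye(nm), -fmax[:, None]])
    res = linprog(c, A_ub=a_ub, b_ub=np.zeros(nm), A_eq=a_eq, b_eq=m_vec,
                  bounds=[(0, None)] * nm + [(0, None)], method="highs")
    if not res.success:
        return None
    f, gamma = res.x[:nm], res.x[-1]
    if tiebreak and nm > 1:
        ub = gamma * fmax * (1 + 1e-12)
        w = 1.0 / fmax**2

        def obj(x):
            return float(np.sum(w * x * x))

        def jac(x):
            return 2.0 * w * x

        cons = {"type": "eq", "fun": lambda x: R @ x - m_vec,
                "jac": lambda x: R}
        qp = minimize(obj, np.clip(f, 0, ub), jac=jac, method="SLSQP",
                      bounds=[(0, u) for u in ub], constraints=[cons],
                      options={"maxiter": 200, "ftol": 1e-14})
        if qp.success:
            r_qp = np.linalg.norm(R @ qp.x - m_vec)
            r_lp = np.linalg.norm(R @ f - m_vec)
            if r_qp <= max(r_lp, 1e-8):
                f = qp.x
    scale = max(1.0, float(np.max(np.abs(m_vec))))
    rel = float(np.linalg.norm(R @ f - m_vec) / scale)
    return f, gamma, rel


def recruit(moments, muscles=None, criterion: str = "minmax",
            tiebreak: bool = True) -> RecruitmentResult:
    """Distribute joint moments over the muscle set frame by frame.

    ``moments`` is a :class:`~smithsquat.dynamics.MomentSeries` (or any
    object with ``moments`` mapping DOF name -> series).  Frames whose
    moment exceeds total capacity are solved with activities above 1 and
    flagged rather than failed.
    """
    if criterion != "minmax":
        raise ValueError("only the min-max activity criterion is implemented")
    if muscles is None:
        muscles = load_default_muscles()

    dofs = [d for d in RECRUIT_DOFS if d in moments.moments]
    for dof in dofs:
        for sign in (+1, -1):
            if not any(sign * m.moment_arms.get(dof, 0.0) > 0 for m in muscles):
                raise ValueError(f"no muscle can produce {'+' if sign > 0 else '-'}"
                                 f" moment at {dof}")

    series = np.column_stack([np.asarray(moments.moments[d], float) for d in dofs])
    n, nd = series.shape
    nm = len(muscles)
    R = np.zeros((nd, nm))
    for j, mus in enumerate(muscles):
        for i, dof in enumerate(dofs):
            R[i, j] = mus.moment_arms.get(dof, 0.0)
    fmax = np.array([m.fmax for m in muscles])

    forces = np.zeros((n, nm))
    objective = np.zeros(n)
    residual = np.zeros(n)
    infeasible = []
    for k in range(n):
        sol = _recruit_frame(R, fmax, series[k], tiebreak)
        if sol is None:
            infeasible.append(k)
            continue
        f, gamma, rel = sol
        forces[k] = f
        objective[k] = gamma
        residual[k] = rel
        if gamma > 1.0 + 1e-9:
            infeasible.append(k)
    activities = forces / fmax
    return RecruitmentResult(
        muscle_names=[m.name for m in muscles],
        forces=forces, activities=activities, objective=objective,
        residual=residual, moments=dict(moments.moments),
        infeasible_frames=infeasible)


def activity_series(result: RecruitmentResult, muscle_name: str,
                    normalize: bool = False):
    """Activity series of one muscle, optionally scaled to its own maximum.

    Normalising an all-zero series returns zeros with ``warned=True``.
    Returns ``(series, warned)``.
    """
    a = result.activity(muscle_name).copy()
    if not normalize:
        return a, False
    peak = float(a.max())
    if peak <= 0.0:
        return a, True
    return a / peak, False
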