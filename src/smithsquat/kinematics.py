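"""Closed-loop kinematics of the integrated squat model.

The motion is prescribed by five driven flexion/extension angles (pelvis-
thorax, both hips, both knees).  Everything else -- the 6-DOF pelvis pose,
the dependent ankle angles and the bar travel -- follows from the contact
constraints (feet welded to the ground, shoulder riding on the guide line,
trunk roll/yaw locked to the bar).  Each frame is solved as a damped
least-squares problem on the constraint residuals, warm-started from the
previous frame; with asymmetric driven angles exact closure is impossible
for rigid welds and the weighted least-squares pose is returned with its
residual surfaced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model import IntegratedModel

__all__ = [
    "DRIVEN_NAMES",
    "DrivenTrajectory",
    "PoseSeries",
    "BodyKinematics",
    "resample_cycle",
    "solve_pose",
    "solve_trajectory",
    "frame_geometry",
]

#: Canonical order of the driven angle channels (degrees in I/O).
DRIVEN_NAMES = ("pelvis_thorax", "hip_L", "hip_R", "knee_L", "knee_R")

_CSV_COLUMNS = {
    "pelvis_thorax": "pelvis_thorax_flex_deg",
    "hip_L": "hip_flex_L_deg",
    "hip_R": "hip_flex_R_deg",
    "knee_L": "knee_flex_L_deg",
    "knee_R": "knee_flex_R_deg",
}


@dataclass
class DrivenTrajectory:
    """Time-normalized series of the five driven angles over one squat cycle.

    ``angles`` maps channel name -> (n,) array in degrees on the uniform
    ``cycle_fraction`` grid over [0, 1].  The cycle closes: each channel
    starts and ends within ``closure_tol`` degrees.
    """

    cycle_fraction: np.ndarray
    angles: dict
    cycle_duration: float = 6.0
    closure_tol: float = 1.0  # deg

    def __post_init__(self):
        t = np.asarray(self.cycle_fraction, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("cycle_fraction must be a 1-D grid with >= 2 points")
        if abs(t[0]) > 1e-12 or abs(t[-1] - 1.0) > 1e-12 or np.any(np.diff(t) <= 0):
            raise ValueError("cycle_fraction must increase strictly from 0 to 1")
        self.cycle_fraction = t
        missing = set(DRIVEN_NAMES) - set(self.angles)
        if missing:
            raise ValueError(f"missing driven channels: {sorted(missing)}")
        for name in DRIVEN_NAMES:
            a = np.asarray(self.angles[name], dtype=float)
            if a.shape != t.shape or not np.all(np.isfinite(a)):
                raise ValueError(f"bad series for channel {name}")
            if abs(a[0] - a[-1]) > self.closure_tol:
                raise ValueError(f"cycle does not close for channel {name}")
            self.angles[name] = a

    @property
    def n_frames(self) -> int:
        return self.cycle_fraction.size

    def stacked(self) -> np.ndarray:
        """(n, 5) array in canonical channel order."""
        return np.column_stack([self.angles[k] for k in DRIVEN_NAMES])

    def to_frame(self) -> pd.DataFrame:
        data = {"cycle_fraction": self.cycle_fraction}
        for name in DRIVEN_NAMES:
            data[_CSV_COLUMNS[name]] = self.angles[name]
        return pd.DataFrame(data)

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf, cycle_duration: float = 6.0) -> "DrivenTrajectory":
        df = pd.read_csv(path_or_buf)
        angles = {name: df[col].to_numpy() for name, col in _CSV_COLUMNS.items()}
        return cls(cycle_fraction=df["cycle_fraction"].to_numpy(),
                   angles=angles, cycle_duration=cycle_duration)


def resample_cycle(cycle_fraction, angles: dict, n_frames: int,
                   cycle_duration: float = 6.0) -> DrivenTrajectory:
    """Linearly interpolate raw series onto a uniform ``n_frames`` grid."""
    t = np.asarray(cycle_fraction, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 samples to resample")
    if np.any(np.diff(t) <= 0):
        raise ValueError("input cycle fractions must be strictly increasing")
    if n_frames < 4:
        raise ValueError("n_frames must be >= 4")
    grid = np.linspace(0.0, 1.0, n_frames)
    out = {name: np.interp(grid, t, np.asarray(series, float))
           for name, series in angles.items()}
    return DrivenTrajectory(cycle_fraction=grid, angles=out,
                            cycle_duration=cycle_duration)


# ---------------------------------------------------------------------------
# Forward geometry
# ---------------------------------------------------------------------------

def _rx(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _ry(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rz(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


_DOWN = np.array([0.0, 0.0, -1.0])
_UP = np.array([0.0, 0.0, 1.0])


def frame_geometry(model: IntegratedModel, q: np.ndarray, driven_deg: np.ndarray) -> dict:
    """Forward kinematics of one frame.

    ``q = (px, py, pz, roll, pitch, yaw, bar_travel)`` are the dependent
    coordinates (pelvis pose at the hip centre, bar travel along the guide);
    ``driven_deg`` are the five driven angles in canonical order (degrees).
    Returns all joint centres, segment direction vectors and sagittal tilt
    angles needed by the constraint residuals and the dynamics.
    """
    d = model.body.dims
    px, py, pz, roll, pitch, yaw = q[:6]
    s = q[6]
    pt_flex, hip_l, hip_r, knee_l, knee_r = np.radians(driven_deg)

    rp = _rz(yaw) @ _ry(pitch) @ _rx(roll)
    pelvis = np.array([px, py, pz])
    out = {"pelvis": pelvis, "R_pelvis": rp, "bar_travel": s}

    w = d["hip_half_width"]
    for side, sign, hip_a, knee_a in (("L", +1, hip_l, knee_l),
                                      ("R", -1, hip_r, knee_r)):
        hip = pelvis + rp @ np.array([0.0, sign * w, 0.0])
        r_thigh = rp @ _ry(-hip_a)          # flexion carries thigh anterior
        d_thigh = r_thigh @ _DOWN
        knee = hip + d["thigh"] * d_thigh
        r_shank = r_thigh @ _ry(knee_a)     # knee flexion carries shank posterior
        d_shank = r_shank @ _DOWN
        ankle = knee + d["shank"] * d_shank
        out[f"hip_{side}"] = hip
        out[f"knee_{side}"] = knee
        out[f"ankle_{side}"] = ankle
        out[f"d_thigh_{side}"] = d_thigh
        out[f"d_shank_{side}"] = d_shank
        # sagittal tilt from straight-down, positive anterior
        out[f"tilt_thigh_{side}"] = np.arctan2(d_thigh[0], -d_thigh[2])
        out[f"tilt_shank_{side}"] = np.arctan2(d_shank[0], -d_shank[2])

    pt_joint = pelvis + rp @ np.array([0.0, 0.0, d["pelvis"]])
    d_thorax = rp @ _ry(pt_flex) @ _UP      # flexion tilts thorax anterior
    shoulder = pt_joint + d["thorax"] * d_thorax
    out["pt_joint"] = pt_joint
    out["d_thorax"] = d_thorax
    out["shoulder"] = shoulder
    out["tilt_thorax"] = np.arctan2(d_thorax[0], d_thorax[2])
    out["bar"] = model.bar_initial + s * model.machine.guide_direction
    return out


_DEFAULT_WEIGHTS = {"foot": 1.0, "shoulder": 10.0, "orientation": 1.0}


def _residuals(model, q, driven_deg, anchors, weights):
    g = frame_geometry(model, q, driven_deg)
    wf, ws, wo = weights["foot"], weights["shoulder"], weights["orientation"]
    bar = g["bar"]
    res = np.concatenate([
        wf * (g["ankle_L"] - anchors["L"]),
        wf * (g["ankle_R"] - anchors["R"]),
        ws * np.array([g["shoulder"][0] - bar[0], g["shoulder"][2] - bar[2]]),
        wo * np.array([q[3], q[5]]),    # trunk roll / yaw locked to the bar
    ])
    return res


class UnsolvablePoseError(RuntimeError):
    """Raised when the constraint solver diverges beyond the hard residual cap."""


def _initial_guess(model: IntegratedModel) -> np.ndarray:
    d = model.body.dims
    D = model.foot_distance
    L = model.straight_length
    lean = np.arcsin(min(D / L, 1.0))
    leg = d["shank"] + d["thigh"]
    pelvis_x = D - leg * np.sin(lean)
    pelvis_z = d["ankle_height"] + leg * np.cos(lean)
    return np.array([pelvis_x, 0.0, pelvis_z, 0.0, -lean, 0.0, 0.0])


def solve_pose(model: IntegratedModel, driven_deg, q0=None, weights=None,
               tol: float = 1e-10, hard_cap: float = 0.05):
    """Solve the dependent coordinates for one frame of driven angles.

    Returns ``(q, residual)`` where ``residual`` is the unweighted RMS
    constraint violation in metre-equivalents.  Raises
    :class:`UnsolvablePoseError` if the residual exceeds ``hard_cap``.
    """
    driven_deg = np.asarray(driven_deg, dtype=float)
    if driven_deg.shape != (5,):
        raise ValueError("driven angles must have 5 components")
    if np.any(np.abs(driven_deg) > 180.0):
        raise ValueError("driven angles outside +/-180 deg")
    weights = {**_DEFAULT_WEIGHTS, **(weights or {})}
    if q0 is None:
        q0 = _initial_guess(model)
    anchors = model.ankle_anchors
    sol = least_squares(
        lambda q: _residuals(model, q, driven_deg, anchors, weights),
        q0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000,
    )
    unweighted = _residuals(model, sol.x, driven_deg, anchors,
                            {"foot": 1.0, "shoulder": 1.0, "orientation": 1.0})
    residual = float(np.sqrt(np.mean(unweighted ** 2)))
    if residual > hard_cap:
        worst = int(np.argmax(np.abs(unweighted)))
        labels = ["foot_L_x", "foot_L_y", "foot_L_z", "foot_R_x", "foot_R_y",
                  "foot_R_z", "shoulder_x", "shoulder_z", "roll", "yaw"]
        raise UnsolvablePoseError(
            f"pose solver diverged (residual {residual:.3g} m); "
            f"worst constraint: {labels[worst]}")
    return sol.x, residual


@dataclass
class PoseSeries:
    """Solved generalized coordinates over a cycle plus constraint residuals."""

    model: IntegratedModel
    driven: DrivenTrajectory
    q: np.ndarray                    # (n, 7)
    constraint_residual: np.ndarray  # (n,), m-equivalent RMS

    @property
    def n_frames(self) -> int:
        return self.q.shape[0]

    @property
    def dt(self) -> float:
        return self.driven.cycle_duration / (self.n_frames - 1)

    @property
    def bar_travel(self) -> np.ndarray:
        return self.q[:, 6]

    def geometry(self, i: int) -> dict:
        return frame_geometry(self.model, self.q[i], self.driven.stacked()[i])


def solve_trajectory(model: IntegratedModel, driven: DrivenTrajectory,
                     weights=None, max_jump: float = 0.5) -> PoseSeries:
    """Solve the whole cycle frame by frame with warm starts.

    ``max_jump`` bounds the frame-to-frame change of any coordinate
    (m or rad); a violation indicates the solver jumped branches.
    """
    angles = driven.stacked()
    n = driven.n_frames
    q = np.empty((n, 7))
    res = np.empty(n)
    guess = None
    for i in range(n):
        try:
            q[i], res[i] = solve_pose(model, angles[i], q0=guess, weights=weights)
        except UnsolvablePoseError as err:
            raise UnsolvablePoseError(f"frame {i}: {err}") from err
        if i > 0 and np.max(np.abs(q[i] - q[i - 1])) > max_jump:
            raise UnsolvablePoseError(f"coordinate jump at frame {i}")
        guess = q[i]
    return PoseSeries(model=model, driven=driven, q=q, constraint_residual=res)


# ---------------------------------------------------------------------------
# Lumped-body kinematics for the dynamics stage
# ---------------------------------------------------------------------------

def _diff(series: np.ndarray, dt: float) -> np.ndarray:
    """Central differences, one-sided at the endpoints (any trailing shape)."""
    out = np.empty_like(series)
    out[1:-1] = (series[2:] - series[:-2]) / (2 * dt)
    out[0] = (series[1] - series[0]) / dt
    out[-1] = (series[-1] - series[-2]) / dt
    return out


@dataclass
class _Body:
    name: str
    mass: float
    inertia_y: float          # transverse-axis inertia about COM
    com: np.ndarray           # (n, 3)
    tilt: np.ndarray          # (n,) body rotation angle about +Y, rad
    com_acc: np.ndarray = field(default=None)
    tilt_acc: np.ndarray = field(default=None)


@dataclass
class BodyKinematics:
    """Per-frame COM positions/accelerations of the lumped mass model.

    Bodies: feet, shanks, thighs (incl. patellae), pelvis, upper (thorax +
    head + arms, rigid with the thorax) and the bar.  ``points`` carries the
    joint centres used by the inverse dynamics.
    """

    model: IntegratedModel
    dt: float
    bodies: dict              # name -> _Body
    points: dict              # name -> (n, 3)
    bar_travel: np.ndarray    # (n,)
    bar_acc: np.ndarray       # (n,)

    @property
    def n_frames(self) -> int:
        return self.bar_travel.size

    def human_bodies(self) -> list:
        return [b for b in self.bodies.values() if b.name != "bar"]


def _upper_body_properties(model: IntegratedModel):
    """Mass, COM offset along the thorax axis (from the PT joint) and inertia
    of the lump that rides rigidly with the thorax: thorax + head + both arms
    (hands gripping the bar beside the shoulders)."""
    segs = model.body.segments
    d = model.body.dims
    l_tor, l_head = d["thorax"], d["head"]
    arm_names = [f"{b}_{s}" for s in ("L", "R")
                 for b in ("clavicle", "scapula", "humerus", "ulna", "radius", "hand")]
    parts = [(segs["thorax"].mass, 0.50 * l_tor),
             (segs["head"].mass, l_tor + 0.5 * l_head)]
    parts += [(segs[nm].mass, 0.95 * l_tor) for nm in arm_names]
    mass = sum(m for m, _ in parts)
    z_com = sum(m * z for m, z in parts) / mass
    inertia = sum(m * (z - z_com) ** 2 for m, z in parts) + \
        segs["thorax"].mass * (0.35 * l_tor) ** 2
    return mass, z_com, inertia


def body_kinematics(pose: PoseSeries) -> BodyKinematics:
    """Build the lumped-body kinematic series from a solved pose series."""
    model = pose.model
    segs = model.body.segments
    d = model.body.dims
    n = pose.n_frames
    dt = pose.dt

    geoms = [pose.geometry(i) for i in range(n)]
    pts = {key: np.array([g[key] for g in geoms])
           for key in ("pelvis", "pt_joint", "shoulder", "bar",
                       "hip_L", "hip_R", "knee_L", "knee_R",
                       "ankle_L", "ankle_R")}

    bodies = {}

    def add(name, mass, iy, com, tilt):
        bodies[name] = _Body(name=name, mass=mass, inertia_y=iy,
                             com=com, tilt=np.asarray(tilt, float))

    for side in ("L", "R"):
        anchor = model.ankle_anchors[side]
        foot_mass = segs[f"foot_{side}"].mass + segs[f"talus_{side}"].mass
        com_foot = np.tile(anchor + np.array([0.2 * d["foot_length"], 0, -0.5 * d["ankle_height"]]), (n, 1))
        add(f"foot_{side}", foot_mass, 1e-4, com_foot, np.zeros(n))

        # rotation angle about +Y of a down-pointing segment = -anterior tilt
        tilt_sh = -np.array([g[f"tilt_shank_{side}"] for g in geoms])
        com_sh = pts[f"knee_{side}"] + 0.433 * (pts[f"ankle_{side}"] - pts[f"knee_{side}"])
        m_sh = segs[f"shank_{side}"].mass
        add(f"shank_{side}", m_sh, m_sh * (0.302 * d["shank"]) ** 2, com_sh, tilt_sh)

        tilt_th = -np.array([g[f"tilt_thigh_{side}"] for g in geoms])
        com_th = pts[f"hip_{side}"] + 0.433 * (pts[f"knee_{side}"] - pts[f"hip_{side}"])
        m_th = segs[f"thigh_{side}"].mass + segs[f"patella_{side}"].mass
        add(f"thigh_{side}", m_th, m_th * (0.323 * d["thigh"]) ** 2, com_th, tilt_th)

    pitch = pose.q[:, 4]
    m_pel = segs["pelvis"].mass
    up_pel = (pts["pt_joint"] - pts["pelvis"]) / d["pelvis"]
    com_pel = pts["pelvis"] + 0.35 * d["pelvis"] * up_pel
    add("pelvis", m_pel, m_pel * (0.31 * d["pelvis"]) ** 2, com_pel, pitch)

    m_up, z_up, i_up = _upper_body_properties(model)
    tilt_tor = np.array([g["tilt_thorax"] for g in geoms])
    d_tor = (pts["shoulder"] - pts["pt_joint"]) / d["thorax"]
    com_up = pts["pt_joint"] + z_up * d_tor
    add("upper", m_up, i_up, com_up, tilt_tor)

    add("bar", model.machine.bar_mass, 0.0, pts["bar"], np.zeros(n))

    for b in bodies.values():
        b.com_acc = _diff(_diff(b.com, dt), dt)
        b.tilt_acc = _diff(_diff(b.tilt, dt), dt)

    s = pose.bar_travel
    return BodyKinematics(model=model, dt=dt, bodies=bodies, points=pts,
                          bar_travel=s, bar_acc=_diff(_diff(s, dt), dt))
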