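"""Ground-reaction-force prediction and inverse dynamics.

The human and the bar are treated as one system supported by two external
load paths: the foot-ground contacts and the Smith machine's rails.  The
net wrench this system needs (Newton-Euler aggregation over the lumped
segments and the bar) is distributed over eight ground contact points
(heel/toe x medial/lateral per foot, non-negative normals) plus the rail
reaction, which acts at the bar centre perpendicular to the guide
direction -- frictionless rails cannot push along their own track.  The
distribution minimises the total squared force, which reduces to the even
split in the symmetric static limit and leaves the rails unloaded whenever
the feet alone can carry the wrench.

Net joint moments follow from a recursive Newton-Euler pass: feet upward
for the leg joints (using each foot's predicted wrench), top down for the
pelvis-thorax joint with the bar's shoulder force
``F_bar = N_rail - m_bar (a_bar - g)`` from the bar's own balance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinematics import BodyKinematics
from .model import GRAVITY, IntegratedModel

__all__ = [
    "WrenchSeries",
    "MomentSeries",
    "bar_force_on_human",
    "net_wrench",
    "predict_grf",
    "inverse_dynamics",
    "moment_about",
]

_G_VEC = np.array([0.0, 0.0, -GRAVITY])

MOMENT_JOINTS = ("pelvis_thorax", "hip_L", "hip_R", "knee_L", "knee_R")


@dataclass
class WrenchSeries:
    """Per-foot ground reaction wrench about the foot centres, plus the rail
    reaction on the bar."""

    force: dict          # side -> (n, 3) N
    moment: dict         # side -> (n, 3) N m, about reference_point[side]
    reference_point: dict
    rail_force: np.ndarray        # (n, 3) N, at the bar centre
    bar_point: np.ndarray         # (n, 3) bar centre positions
    infeasible_frames: list = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return next(iter(self.force.values())).shape[0]

    def total(self) -> tuple:
        """Summed support wrench (feet + rails) about the world origin."""
        f = self.force["L"] + self.force["R"] + self.rail_force
        m = np.cross(self.bar_point, self.rail_force)
        for side in ("L", "R"):
            m += self.moment[side] + np.cross(
                np.broadcast_to(self.reference_point[side],
                                self.force[side].shape),
                self.force[side])
        return f, m

    def feet_total(self) -> tuple:
        """Summed two-foot wrench about the origin (no rail contribution)."""
        f = self.force["L"] + self.force["R"]
        m = np.zeros_like(f)
        for side in ("L", "R"):
            m += self.moment[side] + np.cross(
                np.broadcast_to(self.reference_point[side], f.shape),
                self.force[side])
        return f, m


@dataclass
class MomentSeries:
    """Flexion/extension net joint moments (N m), flexion positive."""

    cycle_fraction: np.ndarray
    moments: dict  # joint -> (n,)

    def magnitudes(self) -> "MomentSeries":
        """Pointwise absolute values (the default reporting mode)."""
        return MomentSeries(self.cycle_fraction,
                            {k: np.abs(v) for k, v in self.moments.items()})

    def stacked(self) -> np.ndarray:
        return np.column_stack([self.moments[j] for j in MOMENT_JOINTS])


def net_wrench(kin: BodyKinematics):
    """Required support wrench (force, moment about the origin) for the
    human + bar system: sum over bodies of ``m (a - g)`` plus the planar
    rate-of-angular-momentum terms."""
    n = kin.n_frames
    force = np.zeros((n, 3))
    moment = np.zeros((n, 3))
    for b in kin.bodies.values():
        if b.com_acc is None:
            raise ValueError(f"body {b.name} has no accelerations")
        f = b.mass * (b.com_acc - _G_VEC)
        force += f
        moment += np.cross(b.com, f)
        moment[:, 1] += b.inertia_y * b.tilt_acc  # rotation about +Y
    return force, moment


def bar_force_on_human(model: IntegratedModel, bar_acc: np.ndarray,
                       rail_force: np.ndarray) -> np.ndarray:
    """(n, 3) force the bar applies at the shoulder, from the bar's balance:
    ``F = N_rail - m_bar (a_bar - g)`` with ``a_bar = s_ddot d_hat``."""
    d_hat = model.machine.guide_direction
    m_bar = model.machine.bar_mass
    a_bar = np.outer(np.asarray(bar_acc, float), d_hat)
    return np.asarray(rail_force, float) - m_bar * (a_bar - _G_VEC)


def _rail_basis(model: IntegratedModel) -> np.ndarray:
    """Directions the rails can push along: perpendicular to the guide."""
    th = np.radians(model.machine.guide_angle_deg)
    e1 = np.array([np.cos(th), 0.0, np.sin(th)])  # sagittal, perp. to travel
    e2 = np.array([0.0, 1.0, 0.0])
    return np.column_stack([e1, e2])


def _min_norm_support(A: np.ndarray, b: np.ndarray, normal_idx, tol: float = 1e-9):
    """min ||f||^2 s.t. A f = b, f[normal_idx] >= 0 (deterministic active set)."""
    m = A.shape[1]
    active: list = []
    f = np.zeros(m)
    for _ in range(len(normal_idx) + 1):
        keep = [i for i in range(m) if i not in active]
        Ak = A[:, keep]
        AtA = Ak @ Ak.T
        try:
            lam = np.linalg.solve(AtA, b)
            fk = Ak.T @ lam
        except np.linalg.LinAlgError:
            fk, *_ = np.linalg.lstsq(Ak, b, rcond=None)
        f = np.zeros(m)
        f[keep] = fk
        viol = [i for i in normal_idx if f[i] < -tol and i not in active]
        if not viol:
            break
        active.append(min(viol, key=lambda i: f[i]))
    feasible = np.linalg.norm(A @ f - b) <= 1e-8 * max(1.0, np.linalg.norm(b))
    f[normal_idx] = np.maximum(f[normal_idx], 0.0)
    return f, feasible


def predict_grf(model: IntegratedModel, kin: BodyKinematics) -> WrenchSeries:
    """Distribute the net wrench over foot contacts and the rail reaction.

    Frames whose wrench cannot be realised with unilateral foot contact are
    flagged in ``infeasible_frames``.
    """
    contacts = model.contact_points
    pts = np.vstack([contacts["L"], contacts["R"]])  # (8, 3)
    npts = pts.shape[0]
    A_contact = np.zeros((6, 3 * npts))
    for i, p in enumerate(pts):
        A_contact[:3, 3 * i:3 * i + 3] = np.eye(3)
        px, py, pz = p
        A_contact[3:, 3 * i:3 * i + 3] = np.array(
            [[0, -pz, py], [pz, 0, -px], [-py, px, 0]])
    normal_idx = list(np.arange(2, 3 * npts, 3))
    rail_dirs = _rail_basis(model)  # (3, 2)
    # no bar load means no shoulder contact, hence no rail load path
    use_rail = model.machine.bar_load_n > 0.0

    f_req, m_req = net_wrench(kin)
    bar_pts = kin.points["bar"]
    n = kin.n_frames
    force = {s: np.zeros((n, 3)) for s in ("L", "R")}
    moment = {s: np.zeros((n, 3)) for s in ("L", "R")}
    rail = np.zeros((n, 3))
    centers = model.foot_centers
    infeasible = []
    for k in range(n):
        if use_rail:
            rail_cols = np.zeros((6, 2))
            for j in range(2):
                e = rail_dirs[:, j]
                rail_cols[:3, j] = e
                rail_cols[3:, j] = np.cross(bar_pts[k], e)
            A = np.hstack([A_contact, rail_cols])
        else:
            A = A_contact
        b = np.concatenate([f_req[k], m_req[k]])
        x, ok = _min_norm_support(A, b, normal_idx)
        if not ok:
            infeasible.append(k)
        fc = x[:3 * npts].reshape(npts, 3)
        if use_rail:
            rail[k] = rail_dirs @ x[3 * npts:]
        for s, sl in (("L", slice(0, 4)), ("R", slice(4, 8))):
            force[s][k] = fc[sl].sum(axis=0)
            moment[s][k] = np.sum(np.cross(pts[sl] - centers[s], fc[sl]), axis=0)
    return WrenchSeries(force=force, moment=moment,
                        reference_point=dict(centers),
                        rail_force=rail, bar_point=bar_pts,
                        infeasible_frames=infeasible)


def moment_about(joint_point, coms, masses, accs, hdots_y=None,
                 ext_forces=(), ext_moments=()):
    """Net joint moment about ``joint_point`` for a cut subsystem.

    ``coms``/``masses``/``accs`` describe the bodies on the cut side;
    ``ext_forces`` is a sequence of ``(application_point, force)`` pairs and
    ``ext_moments`` of pure moments already acting on that side.  Point and
    series arguments are per-frame ``(n, 3)`` arrays (masses scalar per
    body).  Returns the (n, 3) moment the rest of the system must apply.
    """
    joint_point = np.atleast_2d(joint_point)
    total = np.zeros_like(joint_point, dtype=float)
    for i, (com, mass, acc) in enumerate(zip(coms, masses, accs)):
        f = mass * (np.atleast_2d(acc) - _G_VEC)
        total += np.cross(np.atleast_2d(com) - joint_point, f)
        if hdots_y is not None:
            total[:, 1] += hdots_y[i]
    for point, force in ext_forces:
        total -= np.cross(np.atleast_2d(point) - joint_point,
                          np.atleast_2d(force))
    for m in ext_moments:
        total -= np.atleast_2d(m)
    return total


def _leg_moment(kin: BodyKinematics, grf: WrenchSeries, side: str,
                joint_key: str, distal: list) -> np.ndarray:
    jp = kin.points[joint_key]
    bodies = [kin.bodies[name] for name in distal]
    hdots = [b.inertia_y * b.tilt_acc for b in bodies]
    m = moment_about(
        jp,
        [b.com for b in bodies],
        [b.mass for b in bodies],
        [b.com_acc for b in bodies],
        hdots_y=hdots,
        ext_forces=[(grf.reference_point[side], grf.force[side])],
        ext_moments=[grf.moment[side]],
    )
    return m[:, 1]


def inverse_dynamics(model: IntegratedModel, kin: BodyKinematics,
                     grf: WrenchSeries, signed: bool = True) -> MomentSeries:
    """Net flexion/extension moments at the pelvis-thorax, hips and knees.

    Leg joints take the distal (ground-side) cut with the predicted foot
    wrenches; the pelvis-thorax joint takes the cranial cut with the bar's
    shoulder force.  Flexion positive; ``signed=False`` returns magnitudes.
    """
    if grf.n_frames != kin.n_frames:
        raise ValueError("series length mismatch between GRF and kinematics")
    moments = {}
    for side in ("L", "R"):
        distal_knee = [f"foot_{side}", f"shank_{side}"]
        moments[f"knee_{side}"] = _leg_moment(kin, grf, side,
                                              f"knee_{side}", distal_knee)
        distal_hip = distal_knee + [f"thigh_{side}"]
        # hip flexion carries the thigh anteriorly = rotation about -Y, so
        # the flexion-positive moment is the negative +Y component
        moments[f"hip_{side}"] = -_leg_moment(kin, grf, side,
                                              f"hip_{side}", distal_hip)

    up = kin.bodies["upper"]
    f_bar = bar_force_on_human(model, kin.bar_acc, grf.rail_force)
    m_pt = moment_about(
        kin.points["pt_joint"],
        [up.com], [up.mass], [up.com_acc],
        hdots_y=[up.inertia_y * up.tilt_acc],
        ext_forces=[(kin.points["shoulder"], f_bar)],
    )
    moments["pelvis_thorax"] = m_pt[:, 1]

    for name, series in moments.items():
        if not np.all(np.isfinite(series)):
            bad = int(np.flatnonzero(~np.isfinite(series))[0])
            raise FloatingPointError(f"NaN in {name} moment at frame {bad}")

    frac = np.linspace(0.0, 1.0, kin.n_frames)
    out = MomentSeries(cycle_fraction=frac, moments=moments)
    return out if signed else out.magnitudes()
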