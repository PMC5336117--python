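"""Anthropometrically scaled human body model, Smith machine model, and the
integrated human-machine-ground model with contact constraints.

Conventions used throughout the package
---------------------------------------
* World frame: X anterior, Y to the subject's left, Z up.  The sagittal plane
  is XZ.  Units are SI internally (m, kg, N, rad); user-facing I/O is in the
  habitual units of the field (mm for stature, deg for angles).
* Flexion is positive.  A positive hip or pelvis-thorax flexion carries the
  distal segment anteriorly; positive knee flexion carries the shank
  posteriorly relative to the thigh.
* The bar's guide line passes through the initial-pose shoulder point and is
  tilted ``guide_angle`` from vertical in the sagittal plane, moving anterior
  as the bar descends.  Foot position D is the horizontal distance from the
  guide line to the ankles, expressed as a ratio of stature h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "GRAVITY",
    "JOINT_DOF",
    "AnthropometricProfile",
    "SegmentSpec",
    "JointSpec",
    "MachineSpec",
    "CaseSpec",
    "BodyModel",
    "ConstraintRecord",
    "IntegratedModel",
    "build_body_model",
    "build_integrated_model",
    "count_dofs",
    "default_profile",
]

GRAVITY = 9.81  # m/s^2

#: DOF count per joint kind.
JOINT_DOF = {
    "spherical": 3,
    "cylindrical": 1,
    "revolute": 1,
    "prismatic": 1,
    "universal": 2,
    "trans_spherical": 4,
    "weld": 0,
}


def _load_packaged_yaml(name: str) -> dict:
    with resources.files("smithsquat").joinpath("data", name).open("r") as fh:
        return yaml.safe_load(fh)


_SIDES = ("L", "R")
#: Segments that exist once per body side; their mass fraction applies per side.
_SIDED_SEGMENTS = (
    "clavicle", "scapula", "humerus", "ulna", "radius", "hand",
    "thigh", "patella", "shank", "talus", "foot",
)
_AXIAL_SEGMENTS = ("pelvis", "thorax", "head")


@dataclass(frozen=True)
class AnthropometricProfile:
    """Subject anthropometry: stature, mass and per-segment scaling fractions.

    Lengths scale linearly with stature; masses with body mass.  The default
    fractions are a Winter-style proportional table shipped with the package
    (``data/anthropometry.yaml``) and can be swapped via config.
    """

    stature_mm: float
    mass_kg: float
    segment_length_fractions: Mapping[str, float]
    segment_mass_fractions: Mapping[str, float]

    def __post_init__(self):
        if self.stature_mm <= 0:
            raise ValueError("stature must be positive")
        if self.mass_kg <= 0:
            raise ValueError("mass must be positive")
        total = sum(
            (2.0 if name in _SIDED_SEGMENTS else 1.0) * frac
            for name, frac in self.segment_mass_fractions.items()
        )
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"segment mass fractions sum to {total}, expected 1")
        for name, frac in self.segment_length_fractions.items():
            if frac <= 0:
                raise ValueError(f"non-positive length fraction for {name}")

    @property
    def stature_m(self) -> float:
        return self.stature_mm / 1000.0

    def length(self, key: str) -> float:
        """Scaled length (m) of a named dimension."""
        try:
            return self.segment_length_fractions[key] * self.stature_m
        except KeyError:
            raise KeyError(f"unknown segment/dimension name: {key}") from None


def default_profile(stature_mm: float = 1770.0, mass_kg: float = 78.0) -> AnthropometricProfile:
    """Profile with the packaged fraction tables at the given stature/mass.

    Defaults are the study population means (1770 mm, 78 kg).
    """
    data = _load_packaged_yaml("anthropometry.yaml")
    return AnthropometricProfile(
        stature_mm=stature_mm,
        mass_kg=mass_kg,
        segment_length_fractions=data["length_fractions"],
        segment_mass_fractions=data["mass_fractions"],
    )


@dataclass(frozen=True)
class SegmentSpec:
    name: str
    length: float  # m
    mass: float  # kg
    com_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))  # m, segment frame
    inertia: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))  # kg m^2, about COM

    def __post_init__(self):
        if self.mass < 0:
            raise ValueError(f"negative mass for segment {self.name}")
        inertia = np.asarray(self.inertia, dtype=float)
        if not np.allclose(inertia, inertia.T, atol=1e-12):
            raise ValueError(f"inertia not symmetric for segment {self.name}")
        if np.any(np.linalg.eigvalsh(inertia) < -1e-12):
            raise ValueError(f"inertia not PSD for segment {self.name}")
        if np.linalg.norm(np.asarray(self.com_offset, float)) > self.length + 1e-12:
            raise ValueError(f"COM offset outside segment {self.name}")


@dataclass(frozen=True)
class JointSpec:
    name: str
    kind: str
    parent: str
    child: str

    def __post_init__(self):
        if self.kind not in JOINT_DOF:
            raise ValueError(f"unknown joint kind {self.kind}")
        if self.parent == self.child:
            raise ValueError(f"joint {self.name} connects a segment to itself")

    @property
    def dof_count(self) -> int:
        return JOINT_DOF[self.kind]


@dataclass(frozen=True)
class MachineSpec:
    """Smith machine: a bar sliding on rails tilted ``guide_angle_deg`` from
    vertical in the sagittal plane.  ``bar_load_n`` is the external load the
    bar applies (default 267 N)."""

    guide_angle_deg: float = 0.0
    bar_load_n: float = 267.0

    def __post_init__(self):
        if not (0.0 <= self.guide_angle_deg <= 20.0):
            raise ValueError("guide angle outside the supported 0-20 deg sweep")
        if self.bar_load_n < 0:
            raise ValueError("bar load must be non-negative")

    @property
    def guide_direction(self) -> np.ndarray:
        """Unit vector of descending bar travel.

        Tilting the rails makes the descending bar drift posteriorly,
        tracking the hips as they move back -- the tilt sense that unloads
        the trunk and hips as the guide angle grows.
        """
        th = math.radians(self.guide_angle_deg)
        return np.array([-math.sin(th), 0.0, -math.cos(th)])

    @property
    def bar_mass(self) -> float:
        return self.bar_load_n / GRAVITY


@dataclass(frozen=True)
class CaseSpec:
    """One design case: foot position D as a ratio of stature, guide angle."""

    foot_position_ratio: float
    guide_angle_deg: float

    def __post_init__(self):
        if not (0.0 <= self.foot_position_ratio <= 0.28):
            raise ValueError("foot position ratio outside supported range [0, 0.28]")
        if not (0.0 <= self.guide_angle_deg <= 20.0):
            raise ValueError("guide angle outside supported range [0, 20] deg")


# ---------------------------------------------------------------------------
# Body model
# ---------------------------------------------------------------------------

#: Published model bookkeeping carried as registry metadata.
REGISTRY_METADATA = {
    "segments": 25,
    "joints": 16,
    "muscles": {"arm_each": 140, "leg_each": 159, "trunk_head": 206},
}


def registry_muscle_total(metadata: Mapping = REGISTRY_METADATA) -> int:
    m = metadata["muscles"]
    return 2 * m["arm_each"] + 2 * m["leg_each"] + m["trunk_head"]


@dataclass(frozen=True)
class BodyModel:
    """Scaled rigid-body linkage: 25 segments, 16 counted joints.

    ``dims`` caches the handful of scaled lengths the kinematics and dynamics
    modules actually use (thigh, shank, pelvis, thorax, ankle height, hip
    half-width, foot length), all in metres.
    """

    profile: AnthropometricProfile
    segments: Mapping[str, SegmentSpec]
    joints: Sequence[JointSpec]
    welds: Sequence[JointSpec]
    dims: Mapping[str, float]

    @property
    def joint_dof_total(self) -> int:
        return sum(j.dof_count for j in self.joints)

    @property
    def total_mass(self) -> float:
        return sum(s.mass for s in self.segments.values())


def _rod_inertia(mass: float, length: float, rg_fraction: float = 0.3) -> np.ndarray:
    """Transverse-axis inertia for a slender segment, I = m (rg L)^2."""
    i = mass * (rg_fraction * length) ** 2
    return np.diag([i, i, 0.02 * i + 1e-12])


def build_body_model(profile: AnthropometricProfile) -> BodyModel:
    """Build the 25-segment, 16-joint body model scaled to ``profile``."""
    lf = profile.segment_length_fractions
    mf = profile.segment_mass_fractions
    h = profile.stature_m
    m_total = profile.mass_kg

    names = list(_AXIAL_SEGMENTS) + [
        f"{base}_{side}" for side in _SIDES for base in _SIDED_SEGMENTS
    ]
    segments = {}
    for name in names:
        base = name.rsplit("_", 1)[0] if name.endswith(("_L", "_R")) else name
        if base not in lf:
            raise KeyError(f"no length fraction for segment {base}")
        if base not in mf and name not in mf:
            raise KeyError(f"no mass fraction for segment {base}")
        length = lf[base] * h
        # sided segments each carry the per-side fraction
        mass = mf[base] * m_total
        segments[name] = SegmentSpec(
            name=name,
            length=length,
            mass=mass,
            com_offset=np.array([0.0, 0.0, -0.433 * length]),
            inertia=_rod_inertia(mass, length),
        )
    if abs(sum(s.mass for s in segments.values()) - m_total) > 1e-6 * m_total:
        raise ValueError("segment masses do not sum to body mass")

    joints = [
        JointSpec("pelvis_thorax", "spherical", "pelvis", "thorax"),
        JointSpec("neck", "spherical", "thorax", "head"),
    ]
    for side in _SIDES:
        joints += [
            JointSpec(f"sternoclavicular_{side}", "spherical", "thorax", f"clavicle_{side}"),
            JointSpec(f"glenohumeral_{side}", "spherical", f"scapula_{side}", f"humerus_{side}"),
            JointSpec(f"elbow_{side}", "universal", f"humerus_{side}", f"ulna_{side}"),
            JointSpec(f"wrist_{side}", "universal", f"radius_{side}", f"hand_{side}"),
            JointSpec(f"hip_{side}", "spherical", "pelvis", f"thigh_{side}"),
            JointSpec(f"knee_{side}", "revolute", f"thigh_{side}", f"shank_{side}"),
            JointSpec(f"ankle_{side}", "universal", f"shank_{side}", f"talus_{side}"),
        ]
    welds = [
        JointSpec(f"{a}_{b}_weld_{side}", "weld", f"{a}_{side}", f"{b}_{side}")
        for side in _SIDES
        for a, b in (("clavicle", "scapula"), ("ulna", "radius"),
                     ("thigh", "patella"), ("talus", "foot"))
    ]

    dims = {
        "thigh": lf["thigh"] * h,
        "shank": lf["shank"] * h,
        "pelvis": lf["pelvis"] * h,          # hip centre -> pelvis-thorax joint
        "thorax": lf["thorax"] * h,          # pelvis-thorax joint -> shoulder
        "ankle_height": lf["ankle_height"] * h,
        "hip_half_width": lf["hip_half_width"] * h,
        "foot_length": lf["foot"] * h,
        "head": lf["head"] * h,
    }
    return BodyModel(profile=profile, segments=segments, joints=joints,
                     welds=welds, dims=dims)


# ---------------------------------------------------------------------------
# Integrated model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConstraintRecord:
    """A contact/posture constraint and the generalized coordinates it removes."""

    name: str
    kind: str  # weld | revolute | frozen
    removes: tuple

    @property
    def removed_dofs(self) -> int:
        return len(self.removes)


def _constraint_records() -> list:
    frozen = ConstraintRecord(
        "frozen_initial_posture", "frozen",
        tuple(f"neck_{ax}" for ax in "xyz")
        + tuple(f"sternoclavicular_{s}_{ax}" for s in _SIDES for ax in "xyz")
        + tuple(f"glenohumeral_{s}_flexion" for s in _SIDES),
    )  # 11
    hand = ConstraintRecord(
        "hand_bar_welds", "weld",
        tuple(f"elbow_{s}_{ax}" for s in _SIDES for ax in ("flexion", "pronation"))
        + tuple(f"wrist_{s}_{ax}" for s in _SIDES for ax in ("flexion", "deviation"))
        + tuple(f"glenohumeral_{s}_{ax}" for s in _SIDES for ax in ("abduction", "rotation"))
        + ("pelvis_thorax_lateral_bending", "pelvis_thorax_axial_rotation"),
    )  # 14
    ground_shoulder = ConstraintRecord(
        "foot_ground_welds_and_shoulder_bar_revolute", "weld",
        tuple(f"hip_{s}_{ax}" for s in _SIDES for ax in ("abduction", "rotation"))
        + tuple(f"ankle_{s}_{ax}" for s in _SIDES for ax in ("dorsiflexion", "abduction"))
        + tuple(f"pelvis_{c}" for c in ("tx", "ty", "tz", "rx", "ry", "rz"))
        + ("bar_travel",),
    )  # 15
    return [frozen, hand, ground_shoulder]


#: The five driven flexion/extension coordinates that remain after constraints.
DRIVEN_COORDINATES = (
    "pelvis_thorax_flexion", "hip_L_flexion", "hip_R_flexion",
    "knee_L_flexion", "knee_R_flexion",
)


@dataclass(frozen=True)
class IntegratedModel:
    """Human body + Smith machine + contact constraints for one case."""

    body: BodyModel
    machine: MachineSpec
    case: CaseSpec
    constraints: Sequence[ConstraintRecord]
    registry_metadata: Mapping = field(default_factory=lambda: dict(REGISTRY_METADATA))
    #: half-width of each foot's contact patch (m); None = scaled default
    foot_half_width: float = None

    # --- geometry (derived once) ---
    @property
    def foot_distance(self) -> float:
        """D in metres: horizontal ankle distance from the guide line."""
        return self.case.foot_position_ratio * self.body.profile.stature_m

    @property
    def straight_length(self) -> float:
        """Ankle-to-shoulder length of the straightened body."""
        d = self.body.dims
        return d["shank"] + d["thigh"] + d["pelvis"] + d["thorax"]

    @property
    def ankle_anchors(self) -> dict:
        """Welded ankle positions {side: (3,)}; feet under the hips."""
        d = self.body.dims
        D = self.foot_distance
        w = d["hip_half_width"]
        return {
            "L": np.array([D, +w, d["ankle_height"]]),
            "R": np.array([D, -w, d["ankle_height"]]),
        }

    @property
    def bar_initial(self) -> np.ndarray:
        """Initial bar centre = shoulder point of the straight leaning pose."""
        D = self.foot_distance
        L = self.straight_length
        if D >= L:
            raise ValueError("foot distance exceeds body length; case unreachable")
        z0 = self.body.dims["ankle_height"] + math.sqrt(L * L - D * D)
        return np.array([0.0, 0.0, z0])

    @property
    def contact_points(self) -> dict:
        """4 ground contact points per foot (heel/toe x medial/lateral), world."""
        d = self.body.dims
        fl = d["foot_length"]
        wf = self.foot_half_width
        if wf is None:
            wf = 0.045 * self.body.profile.stature_m / 1.77
        out = {}
        for side, anchor in self.ankle_anchors.items():
            pts = []
            for dx in (-0.3 * fl, 0.7 * fl):
                for dy in (-wf, wf):
                    pts.append([anchor[0] + dx, anchor[1] + dy, 0.0])
            out[side] = np.array(pts)
        return out

    @property
    def foot_centers(self) -> dict:
        """Per-foot wrench reference point: geometric centre of the contacts."""
        return {s: pts.mean(axis=0) for s, pts in self.contact_points.items()}


def build_integrated_model(body: BodyModel, machine: MachineSpec,
                           case: CaseSpec, foot_half_width: float = None
                           ) -> IntegratedModel:
    """Assemble the integrated model and its constraint list for one case."""
    if abs(machine.guide_angle_deg - case.guide_angle_deg) > 1e-9:
        machine = MachineSpec(guide_angle_deg=case.guide_angle_deg,
                              bar_load_n=machine.bar_load_n)
    model = IntegratedModel(body=body, machine=machine, case=case,
                            constraints=_constraint_records(),
                            foot_half_width=foot_half_width)
    segment_names = set(model.body.segments)
    for required in ("hand_L", "hand_R", "foot_L", "foot_R", "thorax"):
        if required not in segment_names:
            raise KeyError(f"constraint attachment segment missing: {required}")
    model.bar_initial  # validates reachability
    return model


def count_dofs(model, after_constraints: bool = False) -> int:
    """DOF bookkeeping.

    For an :class:`IntegratedModel`, the pre-constraint count is joint DOFs +
    6 floating-base pelvis DOFs + 1 bar DOF (=45 for the default model); with
    ``after_constraints=True`` the constraint-removed coordinates are
    subtracted, leaving the driven coordinates (=5).  A :class:`BodyModel`
    counts 38+6=44; a :class:`MachineSpec` counts 1.
    """
    if isinstance(model, MachineSpec):
        return 1
    if isinstance(model, BodyModel):
        return model.joint_dof_total + 6
    if isinstance(model, IntegratedModel):
        total = model.body.joint_dof_total + 6 + 1
        if not after_constraints:
            return total
        removed = sum(c.removed_dofs for c in model.constraints)
        return total - removed
    raise TypeError(f"cannot count DOFs of {type(model).__name__}")
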