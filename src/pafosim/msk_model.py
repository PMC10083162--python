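"""Planar lower-limb musculoskeletal model and orthosis mass modification.

The model is a sagittal-plane chain pelvis → thigh → shank → foot with hinge
joints at the hip, knee and ankle.  Segment inertial properties are scaled
from subject height and body mass using a configurable anthropometric
fraction table.  A powered ankle–foot orthosis (PAFO) is represented purely
as added mass: 80% of the device mass is a point mass at the actuator
position on the shank, 10% is distributed over the shank (brace) and 10%
over the foot (foot plate).  Composite segment properties are obtained by
mass-weighted centre-of-mass combination and the parallel-axis theorem.

Coordinate conventions
----------------------
Sagittal plane, x forward (direction of progression), y up.  Each segment
has a local frame with origin at its proximal joint; the long axis points
distally.  Joint angles are in radians: hip and knee are flexion-positive,
the ankle is dorsiflexion-positive.  With all angles zero the leg hangs
straight down and the foot axis points forward (along +x).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable

import numpy as np
import yaml

GRAVITY = 9.80665  # m/s^2

POSITION_LABELS = ("A_S", "L_S", "L_B", "M_S", "M_B", "U_S", "U_B")

#: Longitudinal actuator position measured distally from the knee joint,
#: as a fraction of shank length.  A = ankle-aligned, L/M/U = lower/middle/
#: upper shank (75/50/25% of shank length below the knee).
_POSITION_LEVEL = {"A": 1.00, "L": 0.75, "M": 0.50, "U": 0.25}

ACTUATOR_FRACTION = 0.80
SHANK_FRACTION = 0.10
FOOT_FRACTION = 0.10


class Situation(Enum):
    """The four simulated orthosis situations."""

    NO_PAFO = "no_pafo"
    ACTUATION_ONLY = "actuation_only"
    MASS_ONLY = "mass_only"
    MASS_AND_ACTUATION = "mass_and_actuation"

    @property
    def has_mass(self) -> bool:
        return self in (Situation.MASS_ONLY, Situation.MASS_AND_ACTUATION)

    @property
    def has_actuation(self) -> bool:
        return self in (Situation.ACTUATION_ONLY, Situation.MASS_AND_ACTUATION)


@dataclass
class Segment:
    """Rigid segment with planar inertial properties.

    ``com_offset`` is measured from the proximal joint along the segment
    axis; ``inertia_com`` is about the mediolateral axis through the CoM.
    """

    name: str
    length: float
    mass: float
    com_offset: float
    inertia_com: float
    #: in-plane CoM offset perpendicular to the segment axis (m), used when
    #: posterior point masses shift the composite CoM off the axis
    com_perp: float = 0.0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"segment {self.name}: length must be > 0")
        if self.mass < 0:
            raise ValueError(f"segment {self.name}: mass must be >= 0")
        if not (0.0 <= self.com_offset <= self.length):
            raise ValueError(
                f"segment {self.name}: com_offset must lie within [0, length]"
            )
        if self.inertia_com < 0:
            raise ValueError(f"segment {self.name}: inertia_com must be >= 0")

    def with_point_mass(self, m: float, along: float, perp: float = 0.0) -> "Segment":
        """Composite body of this segment and a point mass.

        The point mass sits at ``(along, perp)`` in the segment frame
        (longitudinal / perpendicular from the proximal joint).  Mass,
        CoM and inertia follow from the mass-weighted CoM and the
        parallel-axis theorem.
        """
        if m < 0:
            raise ValueError("point mass must be >= 0")
        if m == 0:
            return replace(self)
        total = self.mass + m
        com_along = (self.mass * self.com_offset + m * along) / total
        com_perp = (self.mass * self.com_perp + m * perp) / total
        d_seg2 = (self.com_offset - com_along) ** 2 + (self.com_perp - com_perp) ** 2
        d_pt2 = (along - com_along) ** 2 + (perp - com_perp) ** 2
        inertia = self.inertia_com + self.mass * d_seg2 + m * d_pt2
        # composite CoM may fall slightly outside [0, length] for extreme
        # offsets; clamp is wrong physically, so bypass validation instead
        seg = replace(self)
        seg.mass = total
        seg.com_offset = com_along
        seg.com_perp = com_perp
        seg.inertia_com = inertia
        return seg

    def inertia_about(self, along: float, perp: float = 0.0) -> float:
        """Moment of inertia about an in-plane point (parallel-axis)."""
        d2 = (self.com_offset - along) ** 2 + (self.com_perp - perp) ** 2
        return self.inertia_com + self.mass * d2


@dataclass
class Joint:
    name: str
    parent: str
    child: str
    #: +1 if the joint's positive direction (flexion / dorsiflexion) is a
    #: counter-clockwise rotation of the child segment in the x-forward,
    #: y-up sagittal view; hip +1, knee -1, ankle +1.
    sign: int
    limits: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.limits
        if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
            raise ValueError(f"joint {self.name}: limits must be finite with lo < hi")


@dataclass
class Muscle:
    """Lumped musculotendon actuator with rigid tendon.

    ``moment_arms`` maps joint name → signed moment arm (m); positive means
    the muscle acts in the joint's positive direction (flexion for hip and
    knee, dorsiflexion for the ankle).  Moment arms are constant by default;
    a callable of joint angle may be supplied instead.
    """

    name: str
    max_isometric_force: float
    optimal_fiber_length: float
    moment_arms: dict[str, float | Callable[[float], float]]
    max_contraction_velocity: float = 10.0  # optimal fiber lengths / s
    groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.max_isometric_force <= 0:
            raise ValueError(f"muscle {self.name}: Fmax must be > 0")
        if self.optimal_fiber_length <= 0:
            raise ValueError(f"muscle {self.name}: optimal fiber length must be > 0")
        if not 1 <= len(self.moment_arms) <= 2:
            raise ValueError(f"muscle {self.name}: must span 1 or 2 joints")

    def moment_arm(self, joint: str, angle: float = 0.0) -> float:
        r = self.moment_arms[joint]
        return r(angle) if callable(r) else r

    def spans(self, joint: str) -> bool:
        return joint in self.moment_arms


# --- anthropometric scaling -------------------------------------------------

#: Default anthropometric fraction table (Winter-style).  Segment masses as
#: fractions of body mass; lengths as fractions of height; CoM position as a
#: fraction of segment length from the proximal joint; radius of gyration
#: about the CoM as a fraction of segment length.  The pelvis entry lumps
#: pelvis + head-arms-trunk so that the configured fractions sum to 1.
DEFAULT_ANTHROPOMETRY: dict = {
    "pelvis": {"mass_frac": 0.678, "length_frac": 0.100, "com_frac": 0.5, "rog_frac": 0.40},
    "thigh": {"mass_frac": 0.100, "length_frac": 0.245, "com_frac": 0.433, "rog_frac": 0.323},
    "shank": {"mass_frac": 0.0465, "length_frac": 0.246, "com_frac": 0.433, "rog_frac": 0.302},
    # foot segment axis runs ankle → toe; length = 0.75 of the heel-toe foot
    # length (0.152 H), CoM mid-axis
    "foot": {"mass_frac": 0.0145, "length_frac": 0.114, "com_frac": 0.5, "rog_frac": 0.475},
}

#: Default marker layout: marker name → (segment, along-axis coord as a
#: fraction of segment length, perpendicular coord in m).  Two or more
#: markers per segment so planar IK is over-determined.
DEFAULT_MARKER_LAYOUT: dict[str, tuple[str, float, float]] = {
    "SACR": ("pelvis", 0.5, -0.08),
    "ASIS": ("pelvis", 0.2, 0.10),
    "THI": ("thigh", 0.5, 0.04),
    "KNE": ("thigh", 1.0, 0.05),
    "TIB": ("shank", 0.45, 0.035),
    "ANK": ("shank", 1.0, 0.04),
    "HEE": ("foot", -0.25, -0.02),
    "TOE": ("foot", 1.0, 0.0),
    "MT5": ("foot", 0.7, 0.02),
}

DEFAULT_JOINT_LIMITS = {
    "hip": (-0.7, 2.1),
    "knee": (-0.15, 2.4),
    "ankle": (-0.9, 0.7),
}

#: Reference posture (rad) at which every default muscle fiber sits at its
#: optimal length; roughly mid-range of the gait trajectories.
DEFAULT_REFERENCE_POSE = {"hip": 0.15, "knee": 0.35, "ankle": -0.05}


def default_muscles() -> list[Muscle]:
    """Twelve-muscle sagittal set covering the muscles discussed individually.

    The four foot-drop-affected dorsiflexors (tibialis anterior, extensor
    digitorum longus, extensor hallucis longus, peroneus tertius) are lumped
    into one dorsiflexor-group actuator.  Vasti lumps the three vastus
    heads.  Parameters are representative literature-scale values for lumped
    actuators; moment arms are constant and signed (positive = flexion /
    dorsiflexion).
    """
    return [
        Muscle("iliopsoas", 3000.0, 0.11, {"hip": 0.040}, groups=("hip_flexor",)),
        Muscle("gluteus_maximus", 1950.0, 0.15, {"hip": -0.060}, groups=("gluteal",)),
        Muscle("adductor_magnus", 1650.0, 0.14, {"hip": -0.030}, groups=("adductor",)),
        Muscle("rectus_femoris", 1170.0, 0.11, {"hip": 0.035, "knee": -0.045},
               groups=("quadriceps",)),
        Muscle("vasti", 5000.0, 0.10, {"knee": -0.045}, groups=("quadriceps",)),
        Muscle("semimembranosus", 1540.0, 0.11, {"hip": -0.055, "knee": 0.035},
               groups=("hamstring",)),
        Muscle("semitendinosus", 410.0, 0.19, {"hip": -0.055, "knee": 0.040},
               groups=("hamstring",)),
        Muscle("biceps_femoris_sh", 800.0, 0.17, {"knee": 0.035}, groups=("hamstring",)),
        Muscle("gastrocnemius_med", 1560.0, 0.09, {"knee": 0.020, "ankle": -0.045},
               groups=("plantarflexor", "triceps_surae")),
        Muscle("gastrocnemius_lat", 680.0, 0.09, {"knee": 0.020, "ankle": -0.045},
               groups=("plantarflexor", "triceps_surae")),
        Muscle("soleus", 3550.0, 0.10, {"ankle": -0.048},
               groups=("plantarflexor", "triceps_surae")),
        Muscle("dorsiflexors", 1400.0, 0.11, {"ankle": 0.040}, groups=("dorsiflexor",)),
    ]


@dataclass
class LowerLimbModel:
    """A scaled planar lower-limb model for one subject."""

    subject_id: str
    height: float
    body_mass: float
    segments: dict[str, Segment]
    joints: dict[str, Joint]
    muscles: list[Muscle]
    markers: dict[str, tuple[str, float, float]]
    reference_pose: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REFERENCE_POSE)
    )

    @property
    def shank_length(self) -> float:
        """Knee-to-ankle distance, the length the actuator positions scale to."""
        return self.segments["shank"].length

    @property
    def total_segment_mass(self) -> float:
        return sum(s.mass for s in self.segments.values())

    def muscle(self, name: str) -> Muscle:
        for m in self.muscles:
            if m.name == name:
                return m
        raise KeyError(name)

    def copy(self) -> "LowerLimbModel":
        return copy.deepcopy(self)

    def validate(self) -> None:
        for j in self.joints.values():
            if j.parent not in self.segments or j.child not in self.segments:
                raise ValueError(f"joint {j.name} references unknown segment")
        for m in self.muscles:
            for jname in m.moment_arms:
                if jname not in self.joints:
                    raise ValueError(f"muscle {m.name} spans unknown joint {jname}")
        for name, (seg, _, _) in self.markers.items():
            if seg not in self.segments:
                raise ValueError(f"marker {name} on unknown segment {seg}")

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "height": self.height,
            "body_mass": self.body_mass,
            "segments": {
                n: {"length": s.length, "mass": s.mass, "com_offset": s.com_offset,
                    "inertia_com": s.inertia_com, "com_perp": s.com_perp}
                for n, s in self.segments.items()
            },
            "joints": {
                n: {"parent": j.parent, "child": j.child, "sign": j.sign,
                    "limits": list(j.limits)}
                for n, j in self.joints.items()
            },
            "muscles": [
                {"name": m.name, "max_isometric_force": m.max_isometric_force,
                 "optimal_fiber_length": m.optimal_fiber_length,
                 "moment_arms": {k: v for k, v in m.moment_arms.items()
                                 if not callable(v)},
                 "max_contraction_velocity": m.max_contraction_velocity,
                 "groups": list(m.groups)}
                for m in self.muscles
            ],
            "markers": {n: [seg, along, perp]
                        for n, (seg, along, perp) in self.markers.items()},
            "reference_pose": dict(self.reference_pose),
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "LowerLimbModel":
        segments = {n: Segment(n, **p) for n, p in d["segments"].items()}
        joints = {n: Joint(n, p["parent"], p["child"], p["sign"],
                           tuple(p["limits"])) for n, p in d["joints"].items()}
        muscles = [Muscle(m["name"], m["max_isometric_force"],
                          m["optimal_fiber_length"], dict(m["moment_arms"]),
                          m.get("max_contraction_velocity", 10.0),
                          tuple(m.get("groups", ())))
                   for m in d["muscles"]]
        markers = {n: (v[0], v[1], v[2]) for n, v in d["markers"].items()}
        model = cls(d["subject_id"], d["height"], d["body_mass"], segments,
                    joints, muscles, markers,
                    dict(d.get("reference_pose", DEFAULT_REFERENCE_POSE)))
        model.validate()
        return model

    @classmethod
    def from_yaml(cls, path) -> "LowerLimbModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class PAFOConfig:
    """Powered ankle–foot orthosis configuration.

    The actuator (80% of the device mass) is a point mass at one of seven
    shank positions; 10% of the mass is spread over the shank brace and 10%
    over the foot plate.  Side-mounted positions offset the actuator
    laterally (out of the sagittal plane, hence no in-plane offset); back-
    mounted positions offset it posteriorly in the plane.
    """

    total_mass: float = 0.0
    position: str = "A_S"
    situation: Situation = Situation.NO_PAFO
    actuator_fraction: float = ACTUATOR_FRACTION
    shank_fraction: float = SHANK_FRACTION
    foot_fraction: float = FOOT_FRACTION
    lateral_offset: float = 0.05
    posterior_offset: float = 0.05

    def __post_init__(self) -> None:
        if isinstance(self.situation, str):
            self.situation = Situation(self.situation)
        if self.total_mass < 0:
            raise ValueError("PAFO total mass must be >= 0")
        fr = self.actuator_fraction + self.shank_fraction + self.foot_fraction
        if abs(fr - 1.0) > 1e-12:
            raise ValueError("mass-split fractions must sum to 1")
        if self.position not in POSITION_LABELS:
            raise ValueError(f"unknown actuator position {self.position!r}")

    @property
    def effective_mass(self) -> float:
        """Mass actually added to the model under this situation."""
        return self.total_mass if self.situation.has_mass else 0.0


def pafo_mass_split(total_mass: float,
                    actuator_fraction: float = ACTUATOR_FRACTION,
                    shank_fraction: float = SHANK_FRACTION,
                    foot_fraction: float = FOOT_FRACTION,
                    ) -> tuple[float, float, float]:
    """Split a device mass into actuator / shank-brace / foot-plate parts.

    Defaults implement the 80/10/10 rule.  The parts sum to ``total_mass``
    exactly.
    """
    if total_mass < 0:
        raise ValueError("PAFO total mass must be >= 0")
    if abs(actuator_fraction + shank_fraction + foot_fraction - 1.0) > 1e-12:
        raise ValueError("fractions must sum to 1")
    act = actuator_fraction * total_mass
    shank = shank_fraction * total_mass
    # Sterbenz: act + shank is within [total/2, 2*total], so the remainder
    # is exact and the three parts sum to total_mass to the last bit
    foot = total_mass - (act + shank)
    return act, shank, foot


def actuator_position(model: LowerLimbModel, position: str,
                      lateral_offset: float = 0.05,
                      posterior_offset: float = 0.05,
                      ) -> tuple[float, float]:
    """Actuator point in shank-fixed coordinates (along, perpendicular).

    ``along`` is measured distally from the knee joint: 25/50/75% of the
    shank length for upper/middle/lower, 100% for the ankle-aligned
    position.  Side-mounted positions (and A_S) are offset laterally, i.e.
    out of the sagittal plane: their in-plane perpendicular coordinate is 0.
    Back-mounted positions are offset posteriorly, which in the x-forward
    convention is a negative perpendicular coordinate.
    """
    if position not in POSITION_LABELS:
        raise ValueError(f"unknown actuator position {position!r}")
    level, mount = position.split("_")
    along = _POSITION_LEVEL[level] * model.shank_length
    perp = -posterior_offset if mount == "B" else 0.0
    return along, perp


def scale_model(height: float, mass: float, subject_id: str = "subject",
                anthropometry: dict | None = None,
                marker_layout: dict | None = None,
                muscles: list[Muscle] | None = None) -> LowerLimbModel:
    """Scale a planar lower-limb model to a subject's height and body mass.

    Segment lengths are fractions of height, masses fractions of body mass,
    and CoM / radius-of-gyration positions fractions of segment length, all
    taken from ``anthropometry`` (default: the Winter-style table).
    Deterministic: identical inputs give identical models.
    """
    if height <= 0 or mass <= 0:
        raise ValueError("height and mass must be > 0")
    table = anthropometry or DEFAULT_ANTHROPOMETRY
    layout = marker_layout or DEFAULT_MARKER_LAYOUT

    segments: dict[str, Segment] = {}
    for name, fr in table.items():
        for key in ("mass_frac", "length_frac", "com_frac", "rog_frac"):
            if not (0.0 < fr[key] < 1.0):
                raise ValueError(f"{name}.{key} must be in (0, 1)")
        L = fr["length_frac"] * height
        m = fr["mass_frac"] * mass
        segments[name] = Segment(
            name=name, length=L, mass=m, com_offset=fr["com_frac"] * L,
            inertia_com=m * (fr["rog_frac"] * L) ** 2,
        )

    joints = {
        "hip": Joint("hip", "pelvis", "thigh", +1, DEFAULT_JOINT_LIMITS["hip"]),
        "knee": Joint("knee", "thigh", "shank", -1, DEFAULT_JOINT_LIMITS["knee"]),
        "ankle": Joint("ankle", "shank", "foot", +1, DEFAULT_JOINT_LIMITS["ankle"]),
    }

    markers = {name: (seg, along_frac * segments[seg].length, perp)
               for name, (seg, along_frac, perp) in layout.items()}

    model = LowerLimbModel(
        subject_id=subject_id, height=height, body_mass=mass,
        segments=segments, joints=joints,
        muscles=muscles if muscles is not None else default_muscles(),
        markers=markers,
    )
    model.validate()
    return model


def save_anthropometry(path, table: dict | None = None) -> None:
    """Write an anthropometric fraction table as YAML (swappable config)."""
    with open(path, "w") as fh:
        yaml.safe_dump(table or DEFAULT_ANTHROPOMETRY, fh, sort_keys=False)


def load_anthropometry(path) -> dict:
    """Read an anthropometric fraction table written by
    :func:`save_anthropometry`."""
    with open(path) as fh:
        return yaml.safe_load(fh)


def apply_pafo(model: LowerLimbModel, config: PAFOConfig) -> LowerLimbModel:
    """Return a copy of ``model`` carrying the orthosis mass.

    Only situations that include mass modify the model; otherwise an
    unmodified copy is returned.  The actuator point mass merges into the
    shank at its configured position; the brace and foot-plate masses are
    spread over their components and merge at the segment geometric
    midpoints (a fixed anatomical location, so repeated applications
    compose exactly like a single heavier device).  Total model mass
    increases by exactly ``config.total_mass``.
    """
    out = model.copy()
    m_add = config.effective_mass
    if m_add == 0.0:
        return out
    act_m, shank_m, foot_m = pafo_mass_split(
        m_add, config.actuator_fraction, config.shank_fraction,
        config.foot_fraction)
    along, perp = actuator_position(model, config.position,
                                    config.lateral_offset,
                                    config.posterior_offset)
    shank = out.segments["shank"].with_point_mass(act_m, along, perp)
    shank = shank.with_point_mass(shank_m, 0.5 * shank.length, 0.0)
    out.segments["shank"] = shank
    foot = out.segments["foot"]
    out.segments["foot"] = foot.with_point_mass(foot_m, 0.5 * foot.length, 0.0)
    return out
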