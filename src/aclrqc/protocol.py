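"""Loading-protocol definition and crosshead motion kinematics.

The compressive ACL-rupture procedure is a fixed five-phase program executed
by a uniaxial testing machine:

1. 1 N compressive preload, held 10 s (load-controlled);
2. ten sinusoidal preconditioning cycles between 1 and 3 N at 0.5 Hz
   (load-controlled);
3. 1 N preload, held 10 s (load-controlled);
4. injury ramp: 1.5 mm downward crosshead displacement at 10 mm/s
   (displacement-controlled);
5. return ramp: 5 mm upward at 5 mm/s to offload the limb.

Sign convention is compression-positive for both load and downward
displacement; the upward return ramp carries a ``direction`` flag of -1
rather than a negative distance, so all magnitudes stay positive.

Crosshead motion during displacement-controlled ramps is modelled as an
ideal jerk-free piecewise-constant-acceleration profile (trapezoidal
velocity, collapsing to triangular for short moves).  Defaults match the
performance envelope of the portable electromechanical testers used for
this procedure: 650 mm/s^2 acceleration, 604.5 mm/s^2 deceleration,
10 mm/s peak velocity.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np

__all__ = [
    "ControlMode",
    "PhaseShape",
    "ProtocolPhase",
    "LoadingProtocol",
    "MotionLimits",
    "MotionProfile",
    "DEFAULT_LIMITS",
    "default_protocol",
    "motion_profile",
    "command_displacement",
    "phase_duration",
    "protocol_duration",
    "protocol_to_toml",
    "protocol_from_toml",
]


class ControlMode(str, Enum):
    LOAD = "load_controlled"
    DISPLACEMENT = "displacement_controlled"


class PhaseShape(str, Enum):
    HOLD = "hold"
    SINUSOID = "sinusoid"
    RAMP = "ramp"


@dataclass(frozen=True)
class ProtocolPhase:
    """One control phase of the loading program.

    ``target`` is in newtons for load-controlled phases and millimetres for
    displacement-controlled ones, always positive (compression-positive).
    Sinusoids oscillate between ``secondary_target`` (lower bound) and
    ``target`` (upper bound) and run for a whole number of cycles.
    ``direction`` is +1 for downward (compressive) ramps, -1 for upward.
    """

    mode: ControlMode
    shape: PhaseShape
    target: float
    secondary_target: Optional[float] = None
    rate: Optional[float] = None  # mm/s, ramps only
    frequency: Optional[float] = None  # Hz, sinusoids only
    duration: Optional[float] = None  # s, holds only
    cycle_count: Optional[int] = None  # sinusoids only
    direction: int = 1

    def __post_init__(self) -> None:
        if self.target <= 0:
            raise ValueError("target must be positive (compression-positive)")
        if self.direction not in (1, -1):
            raise ValueError("direction must be +1 (down) or -1 (up)")
        if self.shape is PhaseShape.HOLD:
            if self.duration is None or self.duration <= 0:
                raise ValueError("hold phase requires duration > 0")
        elif self.shape is PhaseShape.SINUSOID:
            if self.cycle_count is None or self.cycle_count <= 0:
                raise ValueError("sinusoid phase requires cycle_count > 0")
            if self.frequency is None or self.frequency <= 0:
                raise ValueError("sinusoid phase requires frequency > 0")
            if self.secondary_target is None or not (
                self.secondary_target < self.target
            ):
                raise ValueError("sinusoid requires secondary_target < target")
        elif self.shape is PhaseShape.RAMP:
            if self.rate is None or self.rate <= 0:
                raise ValueError("ramp phase requires rate > 0")

    @property
    def nominal_duration(self) -> Optional[float]:
        """Duration in seconds; ``None`` for ramps (depends on kinematics)."""
        if self.shape is PhaseShape.HOLD:
            return self.duration
        if self.shape is PhaseShape.SINUSOID:
            assert self.cycle_count is not None and self.frequency is not None
            return self.cycle_count / self.frequency
        return None


@dataclass(frozen=True)
class LoadingProtocol:
    phases: Tuple[ProtocolPhase, ...]
    name: str = "protocol"

    def __post_init__(self) -> None:
        if len(self.phases) == 0:
            raise ValueError("protocol must contain at least one phase")
        object.__setattr__(self, "phases", tuple(self.phases))

    @property
    def injury_ramp(self) -> ProtocolPhase:
        """The first downward displacement-controlled ramp."""
        for ph in self.phases:
            if ph.shape is PhaseShape.RAMP and ph.direction == 1:
                return ph
        raise ValueError("protocol has no downward ramp phase")


@dataclass(frozen=True)
class MotionLimits:
    """Crosshead kinematic limits (all strictly positive)."""

    accel: float = 650.0  # mm/s^2
    decel: float = 604.5  # mm/s^2
    v_max: float = 10.0  # mm/s

    def __post_init__(self) -> None:
        if min(self.accel, self.decel, self.v_max) <= 0:
            raise ValueError("motion limits must be strictly positive")


DEFAULT_LIMITS = MotionLimits()


@dataclass(frozen=True)
class MotionProfile:
    """Piecewise-constant-acceleration displacement profile.

    ``times`` are the cumulative boundaries (end of accel, end of cruise,
    total) in seconds; ``distances`` the matching sub-segment distances in
    mm.  Triangular profiles have a zero-length cruise segment.
    """

    times: Tuple[float, float, float]
    distances: Tuple[float, float, float]
    total_time: float
    total_distance: float
    v_peak: float
    accel: float
    decel: float
    profile_kind: str  # "trapezoidal" | "triangular" | "empty"

    @property
    def t_accel(self) -> float:
        return self.times[0]

    @property
    def t_cruise_end(self) -> float:
        return self.times[1]

    @property
    def d_accel(self) -> float:
        return self.distances[0]


def default_protocol() -> LoadingProtocol:
    """The standard five-phase compressive ACL-rupture loading program."""
    phases = (
        ProtocolPhase(ControlMode.LOAD, PhaseShape.HOLD, target=1.0, duration=10.0),
        ProtocolPhase(
            ControlMode.LOAD,
            PhaseShape.SINUSOID,
            target=3.0,
            secondary_target=1.0,
            frequency=0.5,
            cycle_count=10,
        ),
        ProtocolPhase(ControlMode.LOAD, PhaseShape.HOLD, target=1.0, duration=10.0),
        ProtocolPhase(
            ControlMode.DISPLACEMENT, PhaseShape.RAMP, target=1.5, rate=10.0
        ),
        ProtocolPhase(
            ControlMode.DISPLACEMENT,
            PhaseShape.RAMP,
            target=5.0,
            rate=5.0,
            direction=-1,
        ),
    )
    return LoadingProtocol(phases=phases, name="aclr_injury")


def motion_profile(distance: float, limits: MotionLimits = DEFAULT_LIMITS) -> MotionProfile:
    """Ideal jerk-free motion profile covering ``distance`` millimetres.

    The profile is trapezoidal (accelerate - cruise at ``v_max`` -
    decelerate) when the distance allows reaching ``v_max``, i.e. when
    distance >= v_max^2/(2 a) + v_max^2/(2 d), and triangular otherwise.
    """
    if distance < 0:
        raise ValueError("distance must be non-negative")
    a, d, v = limits.accel, limits.decel, limits.v_max
    if distance == 0:
        return MotionProfile(
            times=(0.0, 0.0, 0.0),
            distances=(0.0, 0.0, 0.0),
            total_time=0.0,
            total_distance=0.0,
            v_peak=0.0,
            accel=a,
            decel=d,
            profile_kind="empty",
        )
    d_acc_full = v * v / (2.0 * a)
    d_dec_full = v * v / (2.0 * d)
    if distance >= d_acc_full + d_dec_full:
        t_acc = v / a
        t_dec = v / d
        d_cruise = distance - d_acc_full - d_dec_full
        t_cruise = d_cruise / v
        return MotionProfile(
            times=(t_acc, t_acc + t_cruise, t_acc + t_cruise + t_dec),
            distances=(d_acc_full, d_cruise, d_dec_full),
            total_time=t_acc + t_cruise + t_dec,
            total_distance=distance,
            v_peak=v,
            accel=a,
            decel=d,
            profile_kind="trapezoidal",
        )
    # triangular: peak velocity from equal-area accel/decel triangles
    v_peak = math.sqrt(2.0 * distance * a * d / (a + d))
    t_acc = v_peak / a
    t_dec = v_peak / d
    d_acc = v_peak * v_peak / (2.0 * a)
    return MotionProfile(
        times=(t_acc, t_acc, t_acc + t_dec),
        distances=(d_acc, 0.0, distance - d_acc),
        total_time=t_acc + t_dec,
        total_distance=distance,
        v_peak=v_peak,
        accel=a,
        decel=d,
        profile_kind="triangular",
    )


def command_displacement(
    t: Union[float, np.ndarray], profile: MotionProfile
) -> Union[float, np.ndarray]:
    """Commanded displacement (mm) at time ``t`` seconds into the profile.

    Continuous, non-decreasing, and equal to ``total_distance`` for
    ``t >= total_time``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    t1, t2, t3 = profile.times
    a, d = profile.accel, profile.decel
    vp = profile.v_peak
    d1 = profile.distances[0]
    d12 = d1 + profile.distances[1]

    tc = np.minimum(t_arr, t3)
    out = np.where(
        tc <= t1,
        0.5 * a * tc * tc,
        np.where(
            tc <= t2,
            d1 + vp * (tc - t1),
            d12 + vp * (tc - t2) - 0.5 * d * (tc - t2) ** 2,
        ),
    )
    out = np.minimum(out, profile.total_distance)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


def phase_duration(phase: ProtocolPhase, limits: MotionLimits = DEFAULT_LIMITS) -> float:
    """Duration of a phase in seconds, including ramp kinematics."""
    nominal = phase.nominal_duration
    if nominal is not None:
        return nominal
    ramp_limits = limits
    if phase.rate is not None and phase.rate != limits.v_max:
        ramp_limits = dataclasses.replace(limits, v_max=phase.rate)
    return motion_profile(phase.target, ramp_limits).total_time


def protocol_duration(
    protocol: LoadingProtocol, limits: MotionLimits = DEFAULT_LIMITS
) -> float:
    return sum(phase_duration(ph, limits) for ph in protocol.phases)


# ---------------------------------------------------------------------------
# flat TOML-style (de)serialization, one section per phase

def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, float):
        return repr(v)
    return '"%s"' % v


def protocol_to_toml(protocol: LoadingProtocol) -> str:
    lines = ['name = "%s"' % protocol.name, ""]
    for i, ph in enumerate(protocol.phases, start=1):
        lines.append("[phase%d]" % i)
        lines.append("mode = %s" % _toml_value(ph.mode.value))
        lines.append("shape = %s" % _toml_value(ph.shape.value))
        lines.append("target = %s" % _toml_value(float(ph.target)))
        for field in ("secondary_target", "rate", "frequency", "duration"):
            val = getattr(ph, field)
            if val is not None:
                lines.append("%s = %s" % (field, _toml_value(float(val))))
        if ph.cycle_count is not None:
            lines.append("cycle_count = %s" % _toml_value(ph.cycle_count))
        lines.append("direction = %s" % _toml_value(ph.direction))
        lines.append("")
    return "\n".join(lines)


def protocol_from_toml(source: Union[str, Path]) -> LoadingProtocol:
    """Parse a protocol from TOML text or a file path."""
    import tomllib

    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and source.endswith(".toml")
    ):
        with open(source, "rb") as fh:
            data = tomllib.load(fh)
    else:
        data = tomllib.loads(source)
    name = data.get("name", "protocol")
    keys = sorted(
        (k for k in data if k.startswith("phase")), key=lambda k: int(k[5:])
    )
    if not keys:
        raise ValueError("no [phaseN] sections found")
    phases = []
    for k in keys:
        sec = dict(data[k])
        sec["mode"] = ControlMode(sec["mode"])
        sec["shape"] = PhaseShape(sec["shape"])
        phases.append(ProtocolPhase(**sec))
    return LoadingProtocol(phases=tuple(phases), name=name)
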