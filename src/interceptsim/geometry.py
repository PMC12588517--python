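"""Geometric and temporal model of the virtual interception task.

The task is two coupled 1-D kinematic problems. A virtual target appears
213 cm from the center of a strike zone and travels toward it at constant
speed (145 cm/s at baseline; an unannounced perturbation may switch it to
200 or 90 cm/s once per trial). The participant slides a pen 27.7 cm along
a groove; the pen drives a virtual effector on the projected rail. The
interception *time window* is the period during which target and effector
rectangles can overlap inside the strike zone:

    time_window = (target_width + effector_width) / target_speed

Constant error (CE) is the signed distance between target center and
strike-zone center at the instant the effector center reaches the
strike-zone center line. Positive CE means the target is already past the
center, i.e. the effector arrived late; negative CE means it arrived early.
A trial is a hit when |CE| <= the 5-cm bandwidth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional, Tuple

import numpy as np

from .errors import InvalidParameterError, NoCrossingError

__all__ = [
    "TaskConfig",
    "TargetState",
    "CrossingEvent",
    "time_window",
    "required_speed_bounds",
    "constant_error",
    "hit_test",
    "target_position",
    "target_arrival_time",
    "find_crossing",
]


@dataclass(frozen=True)
class TaskConfig:
    """Task geometry and timing constants (units: cm, cm/s, ms, Hz).

    Defaults reproduce the study conditions: a 4 x 6 cm target traveling
    213 cm at 145 cm/s, a 2 x 4 cm effector moved 27.7 cm, a 5 cm hit
    bandwidth around the strike-zone center, and an instructed movement
    time of 200-250 ms sampled at 200 Hz.
    """

    target_width_motion: float = 6.0
    target_height: float = 4.0
    effector_width_motion: float = 4.0
    effector_height: float = 2.0
    target_travel_distance: float = 213.0
    rail_length: float = 304.0
    pen_travel_distance: float = 27.7
    strike_zone_halfwidth: float = 5.0
    base_velocity: float = 145.0
    fast_velocity: float = 200.0
    slow_velocity: float = 90.0
    mt_lo: float = 200.0
    mt_hi: float = 250.0
    sample_rate: float = 200.0

    def __post_init__(self) -> None:
        positive = (
            "target_width_motion", "target_height", "effector_width_motion",
            "effector_height", "target_travel_distance", "rail_length",
            "pen_travel_distance", "strike_zone_halfwidth", "base_velocity",
            "fast_velocity", "slow_velocity", "mt_lo", "mt_hi", "sample_rate",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if not self.mt_lo < self.mt_hi:
            raise InvalidParameterError("mt_lo must be < mt_hi")
        if not self.slow_velocity < self.base_velocity < self.fast_velocity:
            raise InvalidParameterError(
                "velocities must satisfy slow < base < fast"
            )

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidParameterError(f"unknown TaskConfig keys: {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class TargetState:
    """Piecewise-constant-velocity target along its 1-D approach axis.

    ``position`` is distance traveled toward (and past) the strike zone
    from the appearance point; the strike-zone center sits at
    ``TaskConfig.target_travel_distance``. At most one velocity change per
    trial, at ``change_time`` (absolute trial time, seconds).
    """

    start_time: float = 0.0
    base_velocity: float = 145.0
    change_time: Optional[float] = None
    new_velocity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.base_velocity <= 0:
            raise InvalidParameterError("base_velocity must be > 0")
        if (self.change_time is None) != (self.new_velocity is None):
            raise InvalidParameterError(
                "change_time and new_velocity must be given together"
            )
        if self.change_time is not None:
            if self.change_time < self.start_time:
                raise InvalidParameterError("change before target start")
            if self.new_velocity <= 0:
                raise InvalidParameterError("new_velocity must be > 0")

    def position(self, t):
        change = None
        if self.change_time is not None:
            change = (self.change_time, self.new_velocity)
        return target_position(t, self.start_time, self.base_velocity, change)

    def arrival_time(self, distance: float) -> float:
        return target_arrival_time(
            distance, self.start_time, self.base_velocity,
            None if self.change_time is None else (self.change_time, self.new_velocity),
        )


@dataclass(frozen=True)
class CrossingEvent:
    """Moment the effector center crosses the strike-zone center line."""

    t_effector_cross: float          # s, absolute trial time
    target_center_at_cross: float    # cm traveled by the target center


def time_window(target_width_motion: float, effector_width_motion: float,
                velocity: float) -> float:
    """Interception time window in ms.

    ``(target_width + effector_width) / velocity``: the duration for which
    effector/target contact is geometrically possible at the strike zone.
    Strictly decreasing in velocity, linear in the summed widths.
    """
    if velocity <= 0:
        raise InvalidParameterError("velocity must be > 0")
    if target_width_motion < 0 or effector_width_motion < 0:
        raise InvalidParameterError("widths must be >= 0")
    return (target_width_motion + effector_width_motion) / velocity * 1000.0


def required_speed_bounds(pen_travel: float, mt_lo: float, mt_hi: float
                          ) -> Tuple[float, float]:
    """Mean hand-speed range (cm/s) implied by the instructed MT range (ms).

    ``(pen_travel/mt_hi, pen_travel/mt_lo)`` — the slowest admissible
    movement covers the groove in ``mt_hi``, the fastest in ``mt_lo``.
    """
    if not (0 < mt_lo < mt_hi):
        raise InvalidParameterError("require 0 < mt_lo < mt_hi")
    if pen_travel <= 0:
        raise InvalidParameterError("pen_travel must be > 0")
    return pen_travel / (mt_hi / 1000.0), pen_travel / (mt_lo / 1000.0)


def constant_error(crossing: CrossingEvent, strike_zone_center: float) -> float:
    """Signed constant error (cm): target center minus strike-zone center
    at the effector's crossing instant. Positive = target already past the
    center (effector late); negative = target short of it (effector early).
    """
    if crossing is None:
        raise NoCrossingError("effector never crossed the strike-zone center")
    return crossing.target_center_at_cross - strike_zone_center


def hit_test(ce: float, bandwidth: float) -> bool:
    """True iff |CE| <= bandwidth (bandwidth inclusive, per the 5-cm rule)."""
    if bandwidth <= 0:
        raise InvalidParameterError("bandwidth must be > 0")
    return abs(ce) <= bandwidth


def target_position(t, start_time: float, base_v: float,
                    change: Optional[Tuple[float, float]] = None):
    """Distance traveled by the target center at time(s) ``t``.

    Exact piecewise-linear integration of a piecewise-constant velocity,
    continuous at the change time. Vectorized over ``t``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < start_time):
        raise InvalidParameterError("t must be >= start_time")
    if base_v <= 0:
        raise InvalidParameterError("base_v must be > 0")
    pos = base_v * (t - start_time)
    if change is not None:
        t_c, new_v = change
        if t_c < start_time:
            raise InvalidParameterError("change time before target start")
        if new_v <= 0:
            raise InvalidParameterError("new velocity must be > 0")
        after = t > t_c
        pos = np.where(after, base_v * (t_c - start_time) + new_v * (t - t_c), pos)
    return pos if pos.ndim else float(pos)


def target_arrival_time(distance: float, start_time: float, base_v: float,
                        change: Optional[Tuple[float, float]] = None) -> float:
    """Time at which the target center has traveled ``distance`` cm."""
    if distance < 0:
        raise InvalidParameterError("distance must be >= 0")
    t_plain = start_time + distance / base_v
    if change is None:
        return t_plain
    t_c, new_v = change
    if t_plain <= t_c:
        return t_plain
    traveled_at_change = base_v * (t_c - start_time)
    return t_c + (distance - traveled_at_change) / new_v


def find_crossing(t: np.ndarray, x: np.ndarray, line: float) -> float:
    """First time the trace ``x`` crosses ``line`` from below.

    Linear interpolation between samples avoids the 5-ms quantization of
    the 200-Hz grid. Raises :class:`NoCrossingError` if the trace never
    reaches the line.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    above = x >= line
    if not above.any():
        raise NoCrossingError(f"trace never reaches {line}")
    i = int(np.argmax(above))
    if i == 0:
        return float(t[0])
    x0, x1 = x[i - 1], x[i]
    frac = (line - x0) / (x1 - x0) if x1 != x0 else 1.0
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))
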