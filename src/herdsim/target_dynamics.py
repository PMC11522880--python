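"""Target-agent (TA) point-mass dynamics.

A target is a unit-mass particle repelled radially from the herder while the
herder is within the influence radius, with linear drag and wall contact
forces:

    x_ddot = alpha_r * (x - y) / ||x - y||^2  -  beta * x_dot  +  wall(x)

The herder-repulsion magnitude (alpha_r / distance) is clamped at ``f_max``;
the clamp applies to that term only.  Repulsion is central (directed from the
herder straight through the target), so an approaching herder drives the
target directly away from its own position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .environment import Arena, wall_force
from .geometry import GeometryError

__all__ = ["TargetState", "TAParams", "ta_acceleration", "ta_step"]


@dataclass(frozen=True)
class TargetState:
    """Position, velocity and containment flag of one target."""

    position: tuple[float, float]
    velocity: tuple[float, float] = (0.0, 0.0)
    contained: bool = False

    @property
    def speed(self) -> float:
        return math.hypot(self.velocity[0], self.velocity[1])


@dataclass(frozen=True)
class TAParams:
    """Constants of the target dynamics.

    alpha_r : repulsion strength (m^2/s^2); active within the influence radius.
    beta    : drag coefficient (1/s).
    f_max   : clamp on the herder-repulsion magnitude (N, unit mass).
    """

    alpha_r: float = 20.0
    beta: float = 0.2
    f_max: float = 30.0

    def __post_init__(self) -> None:
        if min(self.alpha_r, self.beta, self.f_max) <= 0:
            raise ValueError("all target-dynamics constants must be positive")

    def to_dict(self) -> dict:
        return {"alpha_r": self.alpha_r, "beta": self.beta, "f_max": self.f_max}

    @classmethod
    def from_dict(cls, d: dict) -> "TAParams":
        return cls(**d)


def ta_acceleration(
    ta: TargetState,
    ha: tuple[float, float],
    params: TAParams,
    arena: Arena,
) -> tuple[float, float]:
    """Instantaneous target acceleration (m/s^2, unit mass)."""
    px, py = ta.position
    dx = px - ha[0]
    dy = py - ha[1]
    d = math.hypot(dx, dy)
    rx = ry = 0.0
    if d <= arena.influence_radius:
        if d == 0.0:
            raise GeometryError("repulsion direction undefined: herder on top of target")
        mag = min(params.alpha_r / d, params.f_max)
        rx = mag * dx / d
        ry = mag * dy / d
    wx, wy = wall_force(ta, arena)
    return (rx + wx - params.beta * ta.velocity[0],
            ry + wy - params.beta * ta.velocity[1])


def ta_step(
    ta: TargetState,
    ha: tuple[float, float],
    dt: float,
    params: TAParams,
    arena: Arena,
) -> TargetState:
    """One semi-implicit Euler step of the target dynamics.

    Velocity is updated from the acceleration at the current state, then the
    position is advanced with the new velocity; the position is finally
    clamped to the field.  Contained targets are frozen.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if ta.contained:
        return ta
    ax, ay = ta_acceleration(ta, ha, params, arena)
    vx = ta.velocity[0] + ax * dt
    vy = ta.velocity[1] + ay * dt
    raw = (ta.position[0] + vx * dt, ta.position[1] + vy * dt)
    pos = arena.clamp(raw)
    # inelastic wall contact: the fence absorbs the outward momentum, else a
    # pinned target would accumulate unbounded speed while its position is
    # clamped
    if pos[0] != raw[0]:
        vx = 0.0
    if pos[1] != raw[1]:
        vy = 0.0
    return replace(ta, position=pos, velocity=(vx, vy))
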