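"""The game arena: field, walls, containment zone and trial lifecycle predicates.

The arena is a 120 m x 90 m fenced field centred on the origin, with a 4 m
circular containment zone at the centre.  Walls repel target agents with a
fixed 4 N force (unit mass) while they are in contact; the herder is simply
clamped to the field.  A herder influences a target when within the 10 m
influence radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .target_dynamics import TargetState

__all__ = ["Arena", "is_influencing", "wall_force", "ta_contained", "trial_complete"]


@dataclass(frozen=True)
class Arena:
    """Field geometry and task constants.

    width, height
        Field extent in metres; the field spans [-width/2, width/2] x
        [-height/2, height/2].
    containment_radius
        Radius of the circular containment zone at the origin (m).
    wall_force_magnitude
        Inward force a wall exerts on a target in contact with it (N, unit mass).
    influence_radius
        Herder-target distance below which the repulsion of the target
        dynamics is active (m).
    ta_stop_speed
        Speed below which a target counts as having come to rest (m/s).
    """

    width: float = 120.0
    height: float = 90.0
    containment_radius: float = 4.0
    wall_force_magnitude: float = 4.0
    influence_radius: float = 10.0
    ta_stop_speed: float = 0.1

    def __post_init__(self) -> None:
        if min(self.width, self.height) / 2.0 <= self.containment_radius:
            raise ValueError("containment zone must lie strictly inside the field")
        if self.influence_radius <= self.containment_radius:
            raise ValueError("influence radius must exceed the containment radius")
        for name in ("width", "height", "containment_radius", "wall_force_magnitude",
                     "influence_radius", "ta_stop_speed"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def half_width(self) -> float:
        return self.width / 2.0

    @property
    def half_height(self) -> float:
        return self.height / 2.0

    def contains(self, p: tuple[float, float]) -> bool:
        return abs(p[0]) <= self.half_width and abs(p[1]) <= self.half_height

    def clamp(self, p: tuple[float, float]) -> tuple[float, float]:
        """Project a position back onto the field (used for the herder)."""
        return (
            max(-self.half_width, min(self.half_width, p[0])),
            max(-self.half_height, min(self.half_height, p[1])),
        )

    def to_dict(self) -> dict:
        return {
            "width": self.width,
            "height": self.height,
            "containment_radius": self.containment_radius,
            "wall_force_magnitude": self.wall_force_magnitude,
            "influence_radius": self.influence_radius,
            "ta_stop_speed": self.ta_stop_speed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Arena":
        return cls(**d)


def is_influencing(ha: tuple[float, float], ta: tuple[float, float], arena: Arena) -> bool:
    """True iff the herder at ``ha`` is within the influence radius of ``ta``."""
    return math.hypot(ha[0] - ta[0], ha[1] - ta[1]) <= arena.influence_radius


def wall_force(ta: "TargetState | tuple[float, float]", arena: Arena) -> tuple[float, float]:
    """Repulsive wall force on a target (N, unit mass).

    Zero strictly inside the field; on/outside a wall line the force is the
    wall-magnitude along that wall's inward normal, with normals summing at
    corners.  Continuous contact, no restitution.
    """
    x, y = (ta.position if hasattr(ta, "position") else ta)
    fx = 0.0
    fy = 0.0
    f = arena.wall_force_magnitude
    if x >= arena.half_width:
        fx -= f
    elif x <= -arena.half_width:
        fx += f
    if y >= arena.half_height:
        fy -= f
    elif y <= -arena.half_height:
        fy += f
    return (fx, fy)


def ta_contained(ta: "TargetState", arena: Arena) -> bool:
    """True iff the target sits inside the containment zone and has come to rest."""
    px, py = ta.position
    vx, vy = ta.velocity
    return (math.hypot(px, py) <= arena.containment_radius
            and math.hypot(vx, vy) < arena.ta_stop_speed)


def trial_complete(states: Sequence["TargetState"], arena: Arena) -> bool:
    """True iff every target is contained.  Errors on an empty target list."""
    if len(states) == 0:
        raise ValueError("trial_complete requires at least one target")
    return all(ta_contained(s, arena) for s in states)
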