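"""Planar geometry and angle conventions.

All positions live in the game plane with the origin at the centre of the
containment zone.  Angles are measured from the +y ("vertical") axis,
clockwise positive, and are kept in the canonical range (-180, 180] degrees
(equivalently (-pi, pi] radians).  Only *relative* angles enter the herder
model, so the handedness and zero direction are free conventions; they are
fixed here once so that every module agrees.
"""

from __future__ import annotations

import math

__all__ = [
    "wrap_angle",
    "wrap_rad",
    "bearing_from_vertical",
    "bearing_rad",
    "subtended_angle",
    "norm",
    "GeometryError",
]


class GeometryError(ValueError):
    """Raised for degenerate directions (zero-length vectors) or non-finite input."""


def wrap_angle(a: float) -> float:
    """Wrap an angle in degrees into the canonical range (-180, 180].

    The canonical range makes every difference ``phi - theta`` the shortest
    signed angle, which the heading-coupling terms require.
    """
    if not math.isfinite(a):
        raise GeometryError(f"non-finite angle: {a!r}")
    a = math.fmod(a, 360.0)
    if a > 180.0:
        a -= 360.0
    elif a <= -180.0:
        a += 360.0
    return a


def wrap_rad(a: float) -> float:
    """Wrap an angle in radians into (-pi, pi]."""
    if not math.isfinite(a):
        raise GeometryError(f"non-finite angle: {a!r}")
    a = math.fmod(a, 2.0 * math.pi)
    if a > math.pi:
        a -= 2.0 * math.pi
    elif a <= -math.pi:
        a += 2.0 * math.pi
    return a


def norm(v: tuple[float, float]) -> float:
    return math.hypot(v[0], v[1])


def bearing_rad(origin: tuple[float, float], point: tuple[float, float]) -> float:
    """Signed bearing (radians) of ``point`` seen from ``origin``.

    Zero along +y, clockwise (towards +x) positive, range (-pi, pi].
    """
    dx = point[0] - origin[0]
    dy = point[1] - origin[1]
    if dx == 0.0 and dy == 0.0:
        raise GeometryError("bearing undefined: point coincides with origin")
    return math.atan2(dx, dy)


def bearing_from_vertical(origin: tuple[float, float], point: tuple[float, float]) -> float:
    """Signed bearing in degrees from the vertical (+y) axis, clockwise positive."""
    return wrap_angle(math.degrees(bearing_rad(origin, point)))


def subtended_angle(p: tuple[float, float], q: tuple[float, float]) -> float:
    """Unsigned angle in degrees between position vectors ``p`` and ``q``.

    This is the angle subtended at the containment-zone centre (the origin)
    when ``p`` and ``q`` are agent positions; it is the quantity both the
    phase-transition gate of the herder model and the angular target-selection
    criteria are built on.  Result in [0, 180]; symmetric in its arguments.
    """
    np_ = norm(p)
    nq = norm(q)
    if np_ == 0.0 or nq == 0.0:
        raise GeometryError("subtended angle undefined for a zero vector")
    c = (p[0] * q[0] + p[1] * q[1]) / (np_ * nq)
    c = max(-1.0, min(1.0, c))
    return math.degrees(math.acos(c))
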