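"""Steering-dynamics controller of the herder agent (HA).

The herder moves at constant speed v0; only its heading phi is controlled,
by damped angular dynamics driven by three environmentally coupled terms:

    phi_ddot = -b*phi_dot + psi_G + psi_T + sum_i psi_O_i

* ``psi_G`` attracts the heading towards the *offset goal*: the point
  ``c`` metres radially beyond the target as seen from the containment-zone
  centre ("behind" the target), with a gain that decays with distance to the
  offset but never vanishes (``e^(-c1*dc) + c2``).
* ``psi_T`` repels the heading from the currently targeted TA, gated by the
  sigmoid ``zeta`` of the herder-target angle subtended at the zone centre:
  the repulsion is on while the herder is off the target-zone line (approach
  phase) and switches off smoothly as the herder aligns behind the target
  (corral phase).
* ``psi_O`` terms (form ``psi_C``) repel the heading from point obstacles:
  the containment-zone centre and, in multi-target trials, every
  non-targeted TA.

Angular differences in the coupling terms are in radians (the fitted gains
are radian-scale); the ``zeta`` gate is evaluated on the angle in degrees so
that the approach->corral transition is sharp around the transition angle
epsilon (in radians the logistic would barely move over the relevant range).
The heading ODE is integrated with fixed-step RK4, holding targets constant
within a step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, fields

from .geometry import GeometryError, wrap_rad, subtended_angle

__all__ = [
    "HerderState",
    "ModelParams",
    "offset_goal",
    "zeta",
    "psi_g",
    "psi_t",
    "psi_c",
    "heading_acceleration",
    "herder_step",
    "goal_coupling",
    "target_coupling",
    "obstacle_coupling",
]

_DEG = math.pi / 180.0


@dataclass(frozen=True)
class HerderState:
    """Herder position, heading and heading rate (degrees at this surface)."""

    position: tuple[float, float]
    heading_deg: float = 0.0
    heading_rate_deg: float = 0.0


@dataclass(frozen=True)
class ModelParams:
    """All constants of the heading model.

    b            damping on the heading rate (1/s); fixed at 3.5 in fitting.
    kg           goal-attraction gain (radian scale).
    ko           obstacle/target repulsion gain, shared by psi_T and psi_C
                 unless ``ko_obstacle`` overrides the latter.
    c1, c2       goal-gain decay shape: coefficient is e^(-c1*dc) + c2 (1/m, -).
    c3, c4       target-repulsion decay in heading error (1/rad) and herder-
                 target distance (1/m).
    c5, c6       obstacle-repulsion decay, same roles as c3, c4.
    c_offset     offset-goal distance beyond the target (m); 8.5 by default,
                 deliberately inside the 10 m influence radius.
    epsilon_deg  transition angle of the zeta gate (degrees).
    v0           constant herder speed (m/s).
    zeta_gain    scale applied to the (degree-valued) zeta argument.
    """

    b: float = 3.5
    kg: float = 42.5
    ko: float = 200.0
    c1: float = 0.5
    c2: float = 0.5
    c3: float = 0.5
    c4: float = 0.15
    c5: float = 0.5
    c6: float = 0.5
    c_offset: float = 8.5
    epsilon_deg: float = 5.0
    v0: float = 5.0
    zeta_gain: float = 1.0
    ko_obstacle: float | None = None

    def __post_init__(self) -> None:
        for f in ("b", "kg", "ko", "c1", "c2", "c3", "c4", "c5", "c6",
                  "c_offset", "epsilon_deg", "v0", "zeta_gain"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")

    @property
    def ko_c(self) -> float:
        return self.ko if self.ko_obstacle is None else self.ko_obstacle

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        if d["ko_obstacle"] is None:
            del d["ko_obstacle"]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)


def offset_goal(ta: tuple[float, float], c: float) -> tuple[float, float]:
    """The point ``c`` metres radially beyond ``ta`` as seen from the origin."""
    n = math.hypot(ta[0], ta[1])
    if n == 0.0:
        raise GeometryError("offset goal undefined: target at the containment centre")
    s = 1.0 + c / n
    return (ta[0] * s, ta[1] * s)


def zeta(ha: tuple[float, float], ta: tuple[float, float],
         eps_deg: float = 5.0, gain: float = 1.0) -> float:
    """Sigmoidal approach/corral gate: 1 - sigma(eps - angle(ha, ta)).

    ``angle`` is the herder-target angle subtended at the zone centre, in
    degrees.  zeta ~ 1 while the herder is well off the target-zone line and
    drops through 0.5 at ``eps_deg``, releasing the target-as-repeller term
    as the herder aligns behind the target.
    """
    a = subtended_angle(ta, ha)
    z = gain * (eps_deg - a)
    return 1.0 - 1.0 / (1.0 + math.exp(-z))


# -- raw coupling formulas (radian heading differences) ----------------------

def goal_coupling(delta: float, dc: float, kg: float, c1: float, c2: float) -> float:
    """-kg * delta * (e^(-c1*dc) + c2): attraction toward the offset goal."""
    return -kg * delta * (math.exp(-c1 * dc) + c2)


def target_coupling(delta: float, dist: float, z: float,
                    ko: float, c3: float, c4: float) -> float:
    """zeta * ko * delta * e^(-c3*|delta|) * e^(-c4*dist): repulsion from the target."""
    return z * ko * delta * math.exp(-c3 * abs(delta)) * math.exp(-c4 * dist)


def obstacle_coupling(delta: float, dist: float,
                      ko: float, c5: float, c6: float) -> float:
    """ko * delta * e^(-c5*|delta|) * e^(-c6*dist): repulsion from a point obstacle."""
    return ko * delta * math.exp(-c5 * abs(delta)) * math.exp(-c6 * dist)


# -- geometric wrappers on HerderState ---------------------------------------

def _bearing(frm: tuple[float, float], to: tuple[float, float]) -> float:
    dx = to[0] - frm[0]
    dy = to[1] - frm[1]
    if dx == 0.0 and dy == 0.0:
        raise GeometryError("bearing undefined: coincident points")
    return math.atan2(dx, dy)


def psi_g(ha: HerderState, ta: tuple[float, float], params: ModelParams) -> float:
    """Goal-attraction contribution (rad/s^2)."""
    goal = offset_goal(ta, params.c_offset)
    phi = ha.heading_deg * _DEG
    delta = wrap_rad(phi - _bearing(ha.position, goal))
    dc = math.hypot(goal[0] - ha.position[0], goal[1] - ha.position[1])
    return goal_coupling(delta, dc, params.kg, params.c1, params.c2)


def psi_t(ha: HerderState, ta: tuple[float, float], params: ModelParams) -> float:
    """Targeted-TA repulsion contribution (rad/s^2), gated by zeta."""
    phi = ha.heading_deg * _DEG
    delta = wrap_rad(phi - _bearing(ha.position, ta))
    dist = math.hypot(ta[0] - ha.position[0], ta[1] - ha.position[1])
    z = zeta(ha.position, ta, params.epsilon_deg, params.zeta_gain)
    return target_coupling(delta, dist, z, params.ko, params.c3, params.c4)


def psi_c(ha: HerderState, obstacle: tuple[float, float], params: ModelParams) -> float:
    """Point-obstacle repulsion contribution (rad/s^2).

    Used for the containment-zone centre and for every non-targeted TA.
    """
    phi = ha.heading_deg * _DEG
    delta = wrap_rad(phi - _bearing(ha.position, obstacle))
    dist = math.hypot(obstacle[0] - ha.position[0], obstacle[1] - ha.position[1])
    return obstacle_coupling(delta, dist, params.ko_c, params.c5, params.c6)


def heading_acceleration(
    ha: HerderState,
    targeted_ta: tuple[float, float],
    obstacles: list[tuple[float, float]],
    params: ModelParams,
) -> float:
    """Total heading acceleration (rad/s^2).

    ``obstacles`` must contain the containment-zone centre plus every
    non-targeted TA, i.e. 1 + (N_TAs - 1) entries for an N_TA trial.
    """
    phi_dot = ha.heading_rate_deg * _DEG
    acc = -params.b * phi_dot
    acc += psi_g(ha, targeted_ta, params)
    acc += psi_t(ha, targeted_ta, params)
    for ob in obstacles:
        acc += psi_c(ha, ob, params)
    return acc


# -- fast radian-state integrator (used by the simulator) --------------------

def _accel_raw(
    x: float, y: float, phi: float, phi_dot: float,
    tax: float, tay: float,
    obstacles: list[tuple[float, float]],
    p: ModelParams,
    bounds: tuple[float, float] | None = None,
) -> float:
    """Heading acceleration for raw radian state; hot path of the rollout.

    ``bounds`` = (half_width, half_height) clamps the offset goal to the
    field: for a target near a wall the nominal offset lies outside the
    fence, which the herder cannot reach.
    """
    # offset goal
    tn = math.hypot(tax, tay)
    if tn == 0.0:
        raise GeometryError("offset goal undefined: target at the containment centre")
    s = 1.0 + p.c_offset / tn
    ogx = tax * s
    ogy = tay * s
    if bounds is not None:
        ogx = max(-bounds[0], min(bounds[0], ogx))
        ogy = max(-bounds[1], min(bounds[1], ogy))
    gx = ogx - x
    gy = ogy - y
    dc = math.hypot(gx, gy)
    dg = wrap_rad(phi - math.atan2(gx, gy))
    acc = -p.b * phi_dot - p.kg * dg * (math.exp(-p.c1 * dc) + p.c2)

    # targeted TA as gated repeller
    rx = tax - x
    ry = tay - y
    dist = math.hypot(rx, ry)
    if dist > 0.0:
        hn = math.hypot(x, y)
        if hn > 0.0:
            cosa = (tax * x + tay * y) / (tn * hn)
            cosa = max(-1.0, min(1.0, cosa))
            a_deg = math.degrees(math.acos(cosa))
        else:
            a_deg = 0.0
        z = 1.0 - 1.0 / (1.0 + math.exp(-p.zeta_gain * (p.epsilon_deg - a_deg)))
        dt_ = wrap_rad(phi - math.atan2(rx, ry))
        acc += z * p.ko * dt_ * math.exp(-p.c3 * abs(dt_)) * math.exp(-p.c4 * dist)

    # obstacles: zone centre + non-targeted TAs
    ko_c = p.ko_c
    for ox, oy in obstacles:
        ox -= x
        oy -= y
        d = math.hypot(ox, oy)
        if d == 0.0:
            continue
        do = wrap_rad(phi - math.atan2(ox, oy))
        acc += ko_c * do * math.exp(-p.c5 * abs(do)) * math.exp(-p.c6 * d)
    return acc


def step_raw(
    x: float, y: float, phi: float, phi_dot: float,
    ta: tuple[float, float],
    obstacles: list[tuple[float, float]],
    p: ModelParams,
    dt: float,
    bounds: tuple[float, float] | None = None,
) -> tuple[float, float, float, float]:
    """One RK4 step of (x, y, phi, phi_dot) with the target held constant."""
    tax, tay = ta
    v0 = p.v0

    def deriv(st):
        sx, sy, sphi, sphid = st
        return (v0 * math.sin(sphi), v0 * math.cos(sphi), sphid,
                _accel_raw(sx, sy, sphi, sphid, tax, tay, obstacles, p, bounds))

    s0 = (x, y, phi, phi_dot)
    k1 = deriv(s0)
    s1 = tuple(s0[i] + 0.5 * dt * k1[i] for i in range(4))
    k2 = deriv(s1)
    s2 = tuple(s0[i] + 0.5 * dt * k2[i] for i in range(4))
    k3 = deriv(s2)
    s3 = tuple(s0[i] + dt * k3[i] for i in range(4))
    k4 = deriv(s3)
    out = [s0[i] + dt / 6.0 * (k1[i] + 2 * k2[i] + 2 * k3[i] + k4[i]) for i in range(4)]
    out[2] = wrap_rad(out[2])
    # Rescale the position increment to exactly v0*dt: RK4 stage-averaging of
    # unit heading vectors shortens the step while turning, and the constant
    # forward speed is a hard model constraint, not a numerical target.
    dx = out[0] - x
    dy = out[1] - y
    n = math.hypot(dx, dy)
    if n > 0.0:
        sc = v0 * dt / n
        out[0] = x + dx * sc
        out[1] = y + dy * sc
    else:  # degenerate half-turn cancellation: fall back to the end heading
        out[0] = x + v0 * dt * math.sin(out[2])
        out[1] = y + v0 * dt * math.cos(out[2])
    return (out[0], out[1], out[2], out[3])


def herder_step(
    ha: HerderState,
    ta: tuple[float, float],
    obstacles: list[tuple[float, float]],
    params: ModelParams,
    dt: float,
) -> HerderState:
    """Advance the herder one step: heading via RK4, position at constant v0."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    x, y, phi, phid = step_raw(
        ha.position[0], ha.position[1],
        ha.heading_deg * _DEG, ha.heading_rate_deg * _DEG,
        ta, obstacles, params, dt,
    )
    return HerderState((x, y), math.degrees(phi), math.degrees(phid))
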