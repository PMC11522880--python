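import math

import numpy as np
import pytest

from herdsim.geometry import GeometryError
from herdsim.herder_model import (
    HerderState,
    ModelParams,
    goal_coupling,
    heading_acceleration,
    herder_step,
    obstacle_coupling,
    offset_goal,
    psi_c,
    psi_g,
    psi_t,
    target_coupling,
    zeta,
)

P = ModelParams()


# ------------------------------------------------------------ offset goal --

@pytest.mark.parametrize("ta, expected", [
    ((0.0, 20.0), (0.0, 28.5)),
    ((-10.0, 0.0), (-18.5, 0.0)),
])
def test_offset_goal_radial_extension(ta, expected):
    assert offset_goal(ta, 8.5) == pytest.approx(expected, abs=1e-12)


def test_offset_goal_distance_property(rng):
    for _ in range(50):
        ta = tuple(rng.uniform(-40, 40, 2))
        if math.hypot(*ta) < 1e-6:
            continue
        g = offset_goal(ta, 8.5)
        assert math.hypot(*g) == pytest.approx(math.hypot(*ta) + 8.5)


def test_offset_goal_degenerate():
    with pytest.raises(GeometryError):
        offset_goal((0.0, 0.0), 8.5)


# ------------------------------------------------------------------- zeta --

def test_zeta_half_at_transition_angle():
    # subtended angle exactly epsilon -> logistic at 0 -> 1/2
    ha = (math.sin(math.radians(5.0)) * 20, math.cos(math.radians(5.0)) * 20)
    assert zeta(ha, (0.0, 30.0), eps_deg=5.0) == pytest.approx(0.5, abs=1e-9)


def test_zeta_aligned_nearly_zero():
    assert zeta((0.0, 25.0), (0.0, 15.0), eps_deg=5.0) == pytest.approx(
        1.0 - 1.0 / (1.0 + math.exp(-5.0)), abs=1e-12)


def test_zeta_saturates_at_right_angle():
    assert zeta((20.0, 0.0), (0.0, 15.0), eps_deg=5.0) > 0.999


def test_zeta_increasing_in_angle():
    angles = np.linspace(0.5, 30.0, 40)
    vals = [zeta((20 * math.sin(math.radians(a)), 20 * math.cos(math.radians(a))),
                 (0.0, 30.0)) for a in angles]
    assert all(b > a for a, b in zip(vals, vals[1:]))
    assert zeta((20.0, 0.0), (0.0, 30.0)) <= 1.0


# -------------------------------------------------------- coupling terms --

def test_goal_coupling_hand_value():
    # kg=40, delta=+0.1 rad, c1=0.5, c2=0.5, dc=2
    val = goal_coupling(0.1, 2.0, 40.0, 0.5, 0.5)
    assert val == pytest.approx(-40.0 * 0.1 * (math.exp(-1.0) + 0.5), abs=1e-9)
    assert val == pytest.approx(-3.4715177646858, abs=1e-6)


def test_target_coupling_hand_value():
    # zeta=1, ko=200, delta=0.2, c3=0.5, c4=0.5, dist=4
    val = target_coupling(0.2, 4.0, 1.0, 200.0, 0.5, 0.5)
    assert val == pytest.approx(200 * 0.2 * math.exp(-0.1) * math.exp(-2.0),
                                abs=1e-9)
    assert val == pytest.approx(4.8982571301, abs=1e-6)


def test_goal_coupling_longrange_floor():
    # attraction coefficient tends to kg*c2, never vanishing
    big = goal_coupling(1.0, 1e6, 40.0, 0.5, 0.5)
    assert big == pytest.approx(-40.0 * 0.5, abs=1e-9)


def test_psi_g_zero_when_aligned():
    ha = HerderState((0.0, 40.0), heading_deg=180.0)  # facing the goal below
    assert psi_g(ha, (0.0, 20.0), P) == pytest.approx(0.0, abs=1e-12)


def test_psi_t_suppressed_when_aligned_behind():
    # herder directly behind the target on the zone line: the zeta gate cuts
    # the repulsion below 0.7% of its ungated value
    ha = HerderState((0.0, 30.0), heading_deg=90.0)
    ta = (0.0, 20.0)
    gated = psi_t(ha, ta, P)
    ungated = target_coupling(-math.pi / 2, 10.0, 1.0, P.ko, P.c3, P.c4)
    assert abs(gated) < 0.007 * abs(ungated)


def test_psi_c_odd_symmetry():
    for d in (0.1, -0.1):
        ha = HerderState((0.0, 15.0), heading_deg=180.0 + math.degrees(d))
        vals = psi_c(ha, (0.0, 0.0), P)
        if d > 0:
            pos = vals
        else:
            neg = vals
    assert pos == pytest.approx(-neg, abs=1e-9)


def test_obstacle_coupling_decays_with_distance():
    assert obstacle_coupling(0.3, 100.0, 200.0, 0.5, 0.5) == pytest.approx(
        0.0, abs=1e-12)
    near = obstacle_coupling(0.3, 2.0, 200.0, 0.5, 0.5)
    far = obstacle_coupling(0.3, 8.0, 200.0, 0.5, 0.5)
    assert abs(near) > abs(far) > 0


# --------------------------------------------------- heading acceleration --

def test_damping_only():
    # all couplings geometrically zeroed: heading at goal, both repulsors
    # exponentially dead at huge distance -> phi_ddot ~ -b*phi_dot
    ha = HerderState((0.0, 1000.0), heading_deg=0.0,
                     heading_rate_deg=math.degrees(2.0))
    ta = (0.0, 2000.0)
    # goal bearing is 0 deg; heading aligned; target far beyond
    acc = heading_acceleration(ha, ta, [(0.0, 0.0)], P)
    assert acc == pytest.approx(-3.5 * 2.0, abs=1e-3)


def test_single_target_reduces_to_zone_obstacle_only():
    ha = HerderState((10.0, 25.0), heading_deg=40.0, heading_rate_deg=10.0)
    ta = (-5.0, 18.0)
    full = heading_acceleration(ha, ta, [(0.0, 0.0)], P)
    manual = (-P.b * math.radians(10.0) + psi_g(ha, ta, P)
              + psi_t(ha, ta, P) + psi_c(ha, (0.0, 0.0), P))
    assert full == pytest.approx(manual, abs=1e-12)


def test_multi_target_obstacle_count():
    ha = HerderState((10.0, 25.0), heading_deg=40.0)
    ta = (-5.0, 18.0)
    others = [(20.0, -10.0), (-15.0, -20.0)]
    full = heading_acceleration(ha, ta, [(0.0, 0.0)] + others, P)
    base = heading_acceleration(ha, ta, [(0.0, 0.0)], P)
    extra = sum(psi_c(ha, o, P) for o in others)
    assert full == pytest.approx(base + extra, abs=1e-12)


# ------------------------------------------------------------ integration --

def test_straight_line_step():
    ha = HerderState((0.0, 1000.0), heading_deg=0.0)
    out = herder_step(ha, (0.0, 2000.0), [(0.0, 0.0)], P, 0.02)
    assert out.position[1] == pytest.approx(1000.0 + 5.0 * 0.02, abs=1e-9)
    assert out.position[0] == pytest.approx(0.0, abs=1e-9)
    assert out.heading_deg == pytest.approx(0.0, abs=1e-6)


def test_speed_invariant_every_step(rng):
    ha = HerderState((20.0, -10.0), heading_deg=77.0)
    ta = (-10.0, 15.0)
    for _ in range(300):
        nxt = herder_step(ha, ta, [(0.0, 0.0)], P, 0.02)
        step = math.hypot(nxt.position[0] - ha.position[0],
                          nxt.position[1] - ha.position[1])
        assert step / 0.02 == pytest.approx(P.v0, rel=1e-12)
        ha = nxt


def test_heading_rate_decays_under_pure_damping():
    ha = HerderState((0.0, 1000.0), heading_deg=0.0, heading_rate_deg=50.0)
    rates = [ha.heading_rate_deg]
    for _ in range(50):
        ha = herder_step(ha, (0.0, 2000.0), [(0.0, 0.0)], P, 0.02)
        rates.append(abs(ha.heading_rate_deg))
    assert rates[-1] < 0.1 * rates[0]


def test_invalid_dt():
    with pytest.raises(ValueError):
        herder_step(HerderState((0.0, 10.0)), (0.0, 20.0), [], P, -0.1)


def test_params_validation():
    with pytest.raises(ValueError):
        ModelParams(kg=-1.0)
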