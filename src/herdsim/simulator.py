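"""Trial rollouts: couple the herder model, target dynamics and a
target-selection policy into a 50 Hz trajectory log.

A rollout advances herder and targets on a fixed dt grid (default 0.02 s,
identical to the logging rate).  The herder integrates its heading ODE with
RK4 against targets frozen within the step; targets take a semi-implicit
Euler step against the herder position at the start of the step (operator
splitting).  In multi-target trials the target-selection policy runs on a
0.25 s clock.

Containment latch.  A target that reaches the containment zone is latched as
corralled and frozen (``latch_mode="entry"``, the default): the model herder
moves at constant speed and cannot stop, so the literal game rule — inside
the zone *and* at rest, which requires the herder to back off — is
generically unreachable for model rollouts (a herder parked at the 8.5 m
offset goal keeps every resting target inside its 10 m influence radius).
``latch_mode="rest"`` applies the literal inside-and-slow rule instead; with
it, model rollouts typically bat the target back and forth through the zone
until the time limit.  See docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .environment import Arena
from .geometry import GeometryError
from .herder_model import ModelParams, step_raw
from .policies import PolicySpec, predict_order_from_initial, select_next
from .target_dynamics import TAParams, TargetState, ta_step

__all__ = [
    "TrialConfig",
    "TrajectoryLog",
    "run_trial",
    "trim_simulation_tail",
    "herding_end_index",
]

_DEG = math.pi / 180.0


@dataclass(frozen=True)
class TrialConfig:
    """Everything needed to reproduce one rollout."""

    ha_position: tuple[float, float]
    ha_heading_deg: float
    ta_positions: tuple[tuple[float, float], ...]
    arena: Arena = field(default_factory=Arena)
    model: ModelParams = field(default_factory=ModelParams)
    ta_params: TAParams = field(default_factory=TAParams)
    policy: Optional[PolicySpec] = None
    dt: float = 0.02
    max_duration: float = 120.0
    policy_period: float = 0.25
    latch_mode: str = "entry"
    policy_mode: str = "locked"

    def __post_init__(self) -> None:
        if len(self.ta_positions) < 1:
            raise ValueError("at least one target is required")
        if self.dt <= 0 or self.max_duration <= 0:
            raise ValueError("dt and max_duration must be positive")
        if self.latch_mode not in ("entry", "rest"):
            raise ValueError("latch_mode must be 'entry' or 'rest'")
        if self.policy_mode not in ("locked", "online"):
            raise ValueError("policy_mode must be 'locked' or 'online'")
        for p in (self.ha_position, *self.ta_positions):
            if not self.arena.contains(p):
                raise ValueError(f"initial position {p} outside the field")
            if math.hypot(p[0], p[1]) <= self.arena.containment_radius:
                raise ValueError(
                    f"initial position {p} inside the containment zone")


@dataclass
class TrajectoryLog:
    """Uniformly sampled multi-agent state series; the unit of all analysis."""

    t: np.ndarray                 # (n,)
    ha: np.ndarray                # (n, 2)
    ha_heading_deg: np.ndarray    # (n,)
    ta: np.ndarray                # (n, k, 2)
    ta_vel: np.ndarray            # (n, k, 2)
    influenced: np.ndarray        # (n, k) bool
    contained: np.ndarray         # (n, k) bool
    targeted: np.ndarray          # (n,) int, id of the currently targeted TA
    dt: float
    completed: bool = True
    participant: Optional[str] = None

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def n_tas(self) -> int:
        return self.ta.shape[1]

    def slice(self, stop: int) -> "TrajectoryLog":
        return TrajectoryLog(
            t=self.t[:stop], ha=self.ha[:stop],
            ha_heading_deg=self.ha_heading_deg[:stop],
            ta=self.ta[:stop], ta_vel=self.ta_vel[:stop],
            influenced=self.influenced[:stop], contained=self.contained[:stop],
            targeted=self.targeted[:stop], dt=self.dt,
            completed=self.completed, participant=self.participant,
        )

    def first_influence_indices(self) -> np.ndarray:
        """First sample index at which each TA is influenced; -1 if never."""
        out = np.full(self.n_tas, -1, dtype=int)
        for j in range(self.n_tas):
            idx = np.flatnonzero(self.influenced[:, j])
            if idx.size:
                out[j] = idx[0]
        return out

    def containment_indices(self) -> np.ndarray:
        """First sample index at which each TA is contained; -1 if never."""
        out = np.full(self.n_tas, -1, dtype=int)
        for j in range(self.n_tas):
            idx = np.flatnonzero(self.contained[:, j])
            if idx.size:
                out[j] = idx[0]
        return out


class _Selector:
    """Locked, event-driven target selection shared by all policy timings.

    The first target is chosen from the initial state.  The next target is
    decided when the current one is corralled, with the deciding herder
    position depending on the policy timing: at the current target's
    engagement instant (successive), at its corral instant (dynamic), or
    from the fixed initial-state ranking (initial).
    """

    def __init__(self, policy: PolicySpec, ha0: tuple[float, float],
                 ta0: list[tuple[float, float]]):
        self.policy = policy
        self.remaining = list(range(len(ta0)))
        if policy.timing == "initial":
            self.initial_order = predict_order_from_initial(policy, ha0, ta0)
            self.current = self.initial_order[0]
        else:
            self.initial_order = None
            self.current = select_next(policy, ha0, ta0, self.remaining)
        self.remaining.remove(self.current)
        self.engage_pos: Optional[tuple[float, float]] = None

    def note_engagement(self, ha: tuple[float, float]) -> None:
        if self.engage_pos is None:
            self.engage_pos = ha

    def advance(self, ha: tuple[float, float],
                ta_now: list[tuple[float, float]]) -> None:
        """Called once the current target is contained, on the policy clock."""
        if not self.remaining:
            return
        if self.policy.timing == "initial":
            nxt = next(i for i in self.initial_order if i in self.remaining)
        elif self.policy.timing == "successive":
            ref = self.engage_pos if self.engage_pos is not None else ha
            nxt = select_next(self.policy, ref, ta_now, self.remaining)
        else:  # dynamic
            nxt = select_next(self.policy, ha, ta_now, self.remaining)
        self.current = nxt
        self.remaining.remove(nxt)
        self.engage_pos = None


def run_trial(config: TrialConfig) -> TrajectoryLog:
    """Deterministic rollout of one trial; bit-identical across repeats."""
    arena = config.arena
    mp = config.model
    tp = config.ta_params
    dt = config.dt
    n_tas = len(config.ta_positions)

    hx, hy = config.ha_position
    phi = config.ha_heading_deg * _DEG
    phid = 0.0
    tas = [TargetState(p) for p in config.ta_positions]

    n_max = int(round(config.max_duration / dt))
    tick_every = max(1, int(round(config.policy_period / dt)))

    selector: Optional[_Selector] = None
    target_id = 0
    if n_tas > 1:
        policy = config.policy
        if policy is None:
            raise ValueError("multi-target trials require a policy")
        if config.policy_mode == "locked":
            selector = _Selector(policy, (hx, hy),
                                 [t.position for t in tas])
            target_id = selector.current
        else:
            target_id = select_next(policy, (hx, hy),
                                    [t.position for t in tas],
                                    list(range(n_tas)))

    L_t, L_ha, L_head, L_ta, L_vel = [], [], [], [], []
    L_inf, L_con, L_tgt = [], [], []
    completed = False

    for i in range(n_max + 1):
        # containment latch (before logging so flags match positions)
        for j, s in enumerate(tas):
            if s.contained:
                continue
            r = math.hypot(s.position[0], s.position[1])
            if r <= arena.containment_radius:
                if config.latch_mode == "entry" or s.speed < arena.ta_stop_speed:
                    tas[j] = replace(s, velocity=(0.0, 0.0), contained=True)

        inf = [
            (not s.contained)
            and math.hypot(hx - s.position[0], hy - s.position[1])
            <= arena.influence_radius
            for s in tas
        ]

        # selection bookkeeping
        if selector is not None:
            if inf[selector.current]:
                selector.note_engagement((hx, hy))
            if i % tick_every == 0 and tas[selector.current].contained:
                selector.advance((hx, hy), [s.position for s in tas])
                target_id = selector.current
        elif n_tas > 1 and config.policy_mode == "online" and i % tick_every == 0:
            remaining = [j for j, s in enumerate(tas) if not s.contained]
            if remaining:
                target_id = select_next(config.policy, (hx, hy),
                                        [s.position for s in tas], remaining)

        L_t.append(i * dt)
        L_ha.append((hx, hy))
        L_head.append(math.degrees(phi))
        L_ta.append([s.position for s in tas])
        L_vel.append([s.velocity for s in tas])
        L_inf.append(inf)
        L_con.append([s.contained for s in tas])
        L_tgt.append(target_id)

        if all(s.contained for s in tas):
            completed = True
            break
        if i == n_max:
            break

        tgt = tas[target_id]
        if tgt.contained and math.hypot(*tgt.position) == 0.0:
            raise GeometryError("targeted TA at the containment centre")
        obstacles = [(0.0, 0.0)] + [
            s.position for j, s in enumerate(tas) if j != target_id
        ]
        ha_prev = (hx, hy)
        hx, hy, phi, phid = step_raw(hx, hy, phi, phid, tgt.position,
                                     obstacles, mp, dt,
                                     bounds=(arena.half_width, arena.half_height))
        hx, hy = arena.clamp((hx, hy))
        new_tas = []
        for s in tas:
            if s.position == ha_prev:
                # exact contact (wall clamping can coincide both agents):
                # resolve deterministically by pushing along the herder heading
                ref = (ha_prev[0] - 1e-6 * math.sin(phi),
                       ha_prev[1] - 1e-6 * math.cos(phi))
            else:
                ref = ha_prev
            new_tas.append(ta_step(s, ref, dt, tp, arena))
        tas = new_tas

    return TrajectoryLog(
        t=np.asarray(L_t),
        ha=np.asarray(L_ha),
        ha_heading_deg=np.asarray(L_head),
        ta=np.asarray(L_ta),
        ta_vel=np.asarray(L_vel),
        influenced=np.asarray(L_inf, dtype=bool),
        contained=np.asarray(L_con, dtype=bool),
        targeted=np.asarray(L_tgt, dtype=int),
        dt=dt,
        completed=completed,
    )


def trim_simulation_tail(log: TrajectoryLog, keep: float = 0.8) -> TrajectoryLog:
    """Drop the final (1-keep) fraction of samples (floor on the kept count).

    Simulated herders end a trial circling in place; the tail is removed
    before trajectory comparison.  Not idempotent by definition.
    """
    if log.n_samples == 0:
        raise ValueError("empty log")
    return log.slice(max(1, int(log.n_samples * keep)))


def herding_end_index(log: TrajectoryLog) -> int:
    """Index of the last sample at which any target is influenced.

    Used to strip post-herding transients (players withdrawing) from logs.
    """
    idx = np.flatnonzero(log.influenced.any(axis=1))
    if idx.size == 0:
        raise ValueError("no influence event in log")
    return int(idx[-1])
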